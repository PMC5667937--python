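"""Genetic validation: alternative-first-exon usage QTL mapping.

Per-individual AFE Ψ values are residualized on known covariates (lab,
population) and the first five principal components, then rank-based
inverse-normal quantile normalized per event.  A cis scan regresses the
normalized phenotype on SNP dosage for footprint SNPs within 10 kb of
either TSS, and a Fisher exact test asks whether QTL signal is enriched
among SNPs predicted to disrupt factor binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .formats_io import EventAnnotation

MIN_INDIVIDUALS = 200
CIS_WINDOW = 10_000
MIN_MINOR_ALLELE_COUNT = 10
N_PCS = 5
SEX_CHROMS = ("chrX", "chrY", "X", "Y")


@dataclass
class QtlResult:
    event_id: str
    snp_id: str
    beta: float
    se: float
    p: float
    n: int
    binding_effect: str | None = None


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares residuals of y on covariates, NaN-aware per row."""
    resid = np.full_like(y, np.nan)
    for i in range(y.shape[0]):
        obs = ~np.isnan(y[i])
        if obs.sum() < covariates.shape[1] + 1:
            continue
        C = covariates[obs]
        coef, *_ = np.linalg.lstsq(C, y[i, obs], rcond=None)
        resid[i, obs] = y[i, obs] - C @ coef
    return resid


def _covariate_matrix(covariates: pd.DataFrame,
                      columns: tuple[str, ...] = ("lab", "population")) -> np.ndarray:
    """Intercept plus dummy-coded covariates, dropping collinear constants."""
    parts = [np.ones((len(covariates), 1))]
    for col in columns:
        if col not in covariates:
            continue
        values = covariates[col].astype(str)
        levels = sorted(values.unique())[1:]  # first level absorbed by intercept
        for lv in levels:
            parts.append((values == lv).to_numpy(float)[:, None])
    return np.hstack(parts)


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal: Φ⁻¹((rank − 0.5) / n) over non-missing entries."""
    out = np.full_like(values, np.nan, dtype=float)
    obs = ~np.isnan(values)
    n = obs.sum()
    if n == 0:
        return out
    ranks = stats.rankdata(values[obs], method="average")
    out[obs] = ndtri((ranks - 0.5) / n)
    return out


def normalize_afe_psi(
    psi: pd.DataFrame,
    covariates: pd.DataFrame,
    annotations: dict[str, EventAnnotation] | None = None,
    n_pcs: int = N_PCS,
    min_individuals: int = MIN_INDIVIDUALS,
    drop_sex_chromosomes: bool = True,
) -> pd.DataFrame:
    """Covariate + PC removal followed by per-event quantile normalization.

    Events assessable in fewer than ``min_individuals`` individuals are
    dropped, as are events on sex chromosomes when annotations are given.
    PCs are computed from the covariate-residualized, mean-imputed Ψ matrix
    (imputation is used only for PC extraction, never for association);
    residualization on covariates and PCs uses each event's observed
    individuals.  The final per-event values are exactly the
    Φ⁻¹((rank − 0.5)/n) order statistics.
    """
    psi = psi.copy()
    if annotations is not None and drop_sex_chromosomes:
        keep = [
            e for e in psi.index
            if e not in annotations or annotations[e].chrom not in SEX_CHROMS
        ]
        psi = psi.loc[keep]
    enough = psi.notna().sum(axis=1) >= min_individuals
    psi = psi.loc[enough]
    if psi.empty:
        return psi

    covariates = covariates.set_index("individual").loc[psi.columns].reset_index()
    C = _covariate_matrix(covariates)
    Y = psi.to_numpy(dtype=float)
    resid = _residualize(Y, C)

    if n_pcs > 0:
        imputed = np.where(np.isnan(resid), 0.0, resid)  # residuals are centered
        # individual-space principal components of the event × individual matrix
        _, _, vt = np.linalg.svd(imputed - imputed.mean(axis=1, keepdims=True),
                                 full_matrices=False)
        pcs = vt[: min(n_pcs, vt.shape[0])].T
        resid = _residualize(resid, np.hstack([np.ones((pcs.shape[0], 1)), pcs]))

    normalized = np.vstack([inverse_normal_transform(row) for row in resid])
    return pd.DataFrame(normalized, index=psi.index, columns=psi.columns)


# ---------------------------------------------------------------------------
# cis scan
# ---------------------------------------------------------------------------

def _cis_snps(annotation: EventAnnotation, snps: pd.DataFrame,
              window: int = CIS_WINDOW) -> pd.DataFrame:
    """SNPs within ``window`` bp of either TSS of an AFE event."""
    near = snps[snps["chrom"] == annotation.chrom]
    d_up = (near["pos"] - annotation.upstream_tss).abs()
    d_down = (near["pos"] - annotation.downstream_tss).abs()
    return near[(d_up <= window) | (d_down <= window)]


def afe_qtl_scan(
    phenotype: pd.DataFrame,
    genotypes: pd.DataFrame,
    snps: pd.DataFrame,
    annotations: dict[str, EventAnnotation],
    cis_window: int = CIS_WINDOW,
    min_mac: int = MIN_MINOR_ALLELE_COUNT,
) -> list[QtlResult]:
    """Standard linear-model association of normalized Ψ with SNP dosage.

    ``phenotype`` is the normalized events × individuals matrix,
    ``genotypes`` the SNPs × individuals dosage matrix, and ``snps`` the SNP
    annotation (snp_id, chrom, pos, optional binding_effect).  Monomorphic
    SNPs and SNPs below the minor-allele-count threshold among phenotyped
    individuals are skipped.
    """
    results: list[QtlResult] = []
    common = [c for c in phenotype.columns if c in genotypes.columns]
    pheno = phenotype[common]
    geno = genotypes[common]
    for event_id in pheno.index:
        a = annotations.get(event_id)
        if a is None:
            continue
        y_full = pheno.loc[event_id].to_numpy(dtype=float)
        for snp in _cis_snps(a, snps, cis_window).itertuples(index=False):
            if snp.snp_id not in geno.index:
                continue
            g_full = geno.loc[snp.snp_id].to_numpy(dtype=float)
            obs = ~np.isnan(y_full) & ~np.isnan(g_full)
            y, g = y_full[obs], g_full[obs]
            mac = min(g.sum(), 2 * len(g) - g.sum())
            if mac < min_mac or np.ptp(g) == 0:
                continue
            res = stats.linregress(g, y)
            results.append(
                QtlResult(
                    event_id=event_id,
                    snp_id=snp.snp_id,
                    beta=float(res.slope),
                    se=float(res.stderr),
                    p=float(res.pvalue),
                    n=int(len(y)),
                    binding_effect=getattr(snp, "binding_effect", None),
                )
            )
    return results


def qtl_table(results: list[QtlResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": r.event_id,
                "snp_id": r.snp_id,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "n": r.n,
                "binding_effect": r.binding_effect,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# binding enrichment
# ---------------------------------------------------------------------------

def binding_enrichment(results: list[QtlResult] | pd.DataFrame,
                       p_threshold: float = 0.05) -> dict:
    """Fisher enrichment of QTL signal among binding-affecting SNPs.

    Builds the 2×2 table {QTL significant at ``p_threshold`` vs not} ×
    {binding-affecting vs not} and returns the sample odds ratio, Fisher
    exact p, and per-class sorted p-values for QQ plotting.
    """
    df = results if isinstance(results, pd.DataFrame) else qtl_table(results)
    if df.empty:
        raise ValueError("no QTL results")
    affecting = df["binding_effect"] == "affecting"
    if affecting.all() or (~affecting).all():
        missing = "neutral" if affecting.all() else "affecting"
        raise ValueError(f"binding-effect class {missing!r} is empty")
    sig = df["p"] < p_threshold
    a = int((sig & affecting).sum())
    b = int((sig & ~affecting).sum())
    c = int((~sig & affecting).sum())
    d = int((~sig & ~affecting).sum())
    odds_ratio, fisher_p = stats.fisher_exact([[a, b], [c, d]])
    return {
        "table": ((a, b), (c, d)),
        "odds_ratio": float(odds_ratio),
        "fisher_p": float(fisher_p),
        "qq": {
            "affecting": np.sort(df.loc[affecting, "p"].to_numpy()),
            "neutral": np.sort(df.loc[~affecting, "p"].to_numpy()),
        },
    }
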