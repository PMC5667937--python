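"""Calling significant RNA-processing shifts.

The detection procedure: Bayes factors from treatment-vs-control comparisons
are converted to empirical p-values against the null distribution of Bayes
factors from control-vs-control (CO2 vs CO1) comparisons passing the same
coverage filters, built separately per event type.  Each empirical p becomes
a signed Z

    Z = sign(ΔΨ) × |Q(p/2)|        (Q = standard-normal quantile)

and Z-scores are combined across the individuals measured for an event in an
environment by Stouffer's method (ΣZ/√k), requiring k >= 2 of the 3
individuals.  Combined Z-scores are ranked and Benjamini-Hochberg corrected;
an event shifts significantly at BH FDR < 15% (default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from statsmodels.stats.multitest import multipletests

from .event_quant import Comparison

DEFAULT_FDR = 0.15
#: individual-level empirical-p threshold used for the positive-individual count
INDIVIDUAL_P = 0.05
MIN_NULL = 500
MIN_INDIVIDUALS = 2


@dataclass
class NullDistribution:
    """Sorted control-vs-control Bayes factors for one event type.

    Any fixed monotone transform of the BF scale (e.g. log BF) is admissible
    as long as observed values are queried on the same scale — empirical
    p-values depend on ranks only.
    """

    event_type: str
    sorted_null_bfs: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.sorted_null_bfs = np.sort(np.asarray(self.sorted_null_bfs, dtype=float))
        self.n = len(self.sorted_null_bfs)


@dataclass
class CombinedShift:
    event_id: str
    environment: tuple
    z_combined: float
    k: int
    n_positive: int = 0
    q_value: float = float("nan")
    significant: bool = False

    @property
    def direction(self) -> int:
        return int(np.sign(self.z_combined))


@dataclass
class Exclusion:
    event_id: str
    environment: tuple
    reason: str


def build_null(cc_comparisons: list[Comparison], event_type: str,
               min_n: int = MIN_NULL) -> NullDistribution:
    """Empirical null from filter-passing CO2-vs-CO1 comparisons of one type."""
    types = {c.event_type for c in cc_comparisons}
    if types - {event_type}:
        raise ValueError(
            f"null for {event_type} mixes event types: {sorted(types)}"
        )
    values = np.array([c.bayes_factor for c in cc_comparisons], dtype=float)
    return build_null_from_values(values, event_type, min_n=min_n)


def build_null_from_values(values, event_type: str,
                           min_n: int = MIN_NULL) -> NullDistribution:
    values = np.asarray(values, dtype=float)
    if len(values) < min_n:
        raise ValueError(
            f"{event_type}: only {len(values)} null comparisons (< {min_n}); "
            "generate more control-vs-control comparisons or pool plates"
        )
    return NullDistribution(event_type, values)


def empirical_pvalue(bf, null: NullDistribution):
    """Add-one empirical p: (1 + #{null >= bf}) / (1 + n), ties counted as >=.

    The add-one rule keeps p strictly positive, so the downstream normal
    quantile is always finite.  Vectorized over ``bf``.
    """
    bf = np.asarray(bf, dtype=float)
    if np.isnan(bf).any():
        raise ValueError("NaN Bayes factor passed to empirical_pvalue")
    n_ge = null.n - np.searchsorted(null.sorted_null_bfs, bf, side="left")
    p = (1.0 + n_ge) / (1.0 + null.n)
    return float(p) if p.ndim == 0 else p


def signed_z(p, delta_psi):
    """Eq-style signed Z: sign(ΔΨ) × |Φ⁻¹(p/2)| (vectorized)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("empirical p must lie in (0, 1]")
    z = np.sign(delta_psi) * np.abs(ndtri(p / 2.0))
    return float(z) if z.ndim == 0 else z


def combine_individuals(zs, event_id: str = "", environment: tuple = (),
                        min_individuals: int = MIN_INDIVIDUALS):
    """Stouffer combination ΣZ/√k across individuals for one event × environment.

    Events measured in fewer than ``min_individuals`` are excluded (an
    :class:`Exclusion` record, not an error)."""
    zs = np.asarray(zs, dtype=float)
    if zs.size == 0:
        return Exclusion(event_id, environment, "no individuals passed filters")
    if zs.size < min_individuals:
        return Exclusion(event_id, environment,
                         f"fewer than {min_individuals} individuals")
    z = float(zs.sum() / np.sqrt(zs.size))
    return CombinedShift(event_id, environment, z_combined=z, k=int(zs.size))


def call_shifts(combined: list[CombinedShift],
                alpha: float = DEFAULT_FDR) -> list[CombinedShift]:
    """BH-correct two-sided p-values from combined Z and flag q < alpha.

    The input list defines the BH family (callers should pass all tested
    events of one event type across environments jointly)."""
    if not combined:
        return []
    z = np.array([c.z_combined for c in combined], dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("non-finite combined Z")
    p = 2.0 * ndtr(-np.abs(z))
    q = multipletests(p, method="fdr_bh")[1]
    for c, qi in zip(combined, q):
        c.q_value = float(qi)
        c.significant = bool(qi < alpha)
    return combined


# ---------------------------------------------------------------------------
# vectorized table path
# ---------------------------------------------------------------------------

def call_shifts_table(comparisons: pd.DataFrame, null_comparisons: pd.DataFrame,
                      alpha: float = DEFAULT_FDR, min_null: int = MIN_NULL,
                      min_individuals: int = MIN_INDIVIDUALS) -> pd.DataFrame:
    """Run the whole calling procedure on cohort comparison tables.

    Parameters
    ----------
    comparisons
        One row per (event, environment, individual) treatment-vs-control
        comparison passing filters, with columns ``event_id, event_type,
        cell_type, treatment, individual, delta_psi, log_bf``.
    null_comparisons
        Same layout for control-vs-control comparisons (``treatment`` holds
        the control-pair label).
    Returns
    -------
    DataFrame with one row per event × environment combined call: columns
    ``event_id, event_type, cell_type, treatment, k, n_positive, mean_delta_psi,
    z_combined, p_value, q_value, significant, direction``.  BH is applied per
    event type across all environments jointly.
    """
    out = []
    for event_type, comp in comparisons.groupby("event_type", sort=True):
        nulls = null_comparisons.loc[
            null_comparisons["event_type"] == event_type, "log_bf"
        ].to_numpy()
        null = build_null_from_values(nulls, event_type, min_n=min_null)
        p_ind = empirical_pvalue(comp["log_bf"].to_numpy(), null)
        z_ind = signed_z(p_ind, comp["delta_psi"].to_numpy())
        work = comp[["event_id", "cell_type", "treatment",
                     "delta_psi"]].copy()
        work["z"] = z_ind
        work["ind_sig"] = p_ind < INDIVIDUAL_P
        work["pos_sig"] = (comp["delta_psi"].to_numpy() > 0) & (p_ind < INDIVIDUAL_P)
        grouped = work.groupby(["event_id", "cell_type", "treatment"], sort=True)
        agg = grouped.agg(
            k=("z", "size"),
            z_sum=("z", "sum"),
            n_p05=("ind_sig", "sum"),
            n_positive=("pos_sig", "sum"),
            mean_delta_psi=("delta_psi", "mean"),
        ).reset_index()
        agg = agg[agg["k"] >= min_individuals].copy()
        if agg.empty:
            continue
        agg["z_combined"] = agg["z_sum"] / np.sqrt(agg["k"])
        agg["p_value"] = 2.0 * ndtr(-np.abs(agg["z_combined"].to_numpy()))
        agg["q_value"] = multipletests(agg["p_value"].to_numpy(), method="fdr_bh")[1]
        agg["significant"] = agg["q_value"] < alpha
        agg["direction"] = np.sign(agg["z_combined"]).astype(int)
        agg["event_type"] = event_type
        out.append(agg.drop(columns="z_sum"))
    if not out:
        return pd.DataFrame(
            columns=["event_id", "cell_type", "treatment", "k", "n_p05",
                     "n_positive", "mean_delta_psi", "z_combined", "p_value",
                     "q_value", "significant", "direction", "event_type"]
        )
    return pd.concat(out, ignore_index=True)


_S2_COLUMNS = [
    "shift_id", "plate", "event_name", "chrom", "strand", "exon_starts",
    "exon_ends", "treatment_id", "treatment_name", "cell_type", "control_id",
    "control_name", "event_type", "n_individuals", "n_individuals_p05",
    "n_individuals_positive", "z_combined", "q_value", "gene_id", "gene_symbol",
]


def to_shift_table(calls: pd.DataFrame, annotations: dict,
                   control_of: dict | None = None,
                   significant_only: bool = True) -> pd.DataFrame:
    """Render combined calls as the 20-column released-table layout.

    ``annotations`` maps event_id -> :class:`~spliceshift.formats_io.EventAnnotation`;
    ``control_of`` maps treatment name -> control id.
    """
    rows = calls[calls["significant"]] if significant_only else calls
    records = []
    for i, r in enumerate(rows.itertuples(index=False), start=1):
        a = annotations[r.event_id]
        exons = sorted(a.isoform1_exons + a.isoform2_exons)
        ctrl = (control_of or {}).get(r.treatment, "CO1")
        records.append(
            {
                "shift_id": f"shift_{i:06d}",
                "plate": f"{r.cell_type}_plate1",
                "event_name": r.event_id,
                "chrom": a.chrom,
                "strand": a.strand,
                "exon_starts": ",".join(str(s + 1) for s, _ in exons),
                "exon_ends": ",".join(str(e) for _, e in exons),
                "treatment_id": r.treatment,
                "treatment_name": r.treatment,
                "cell_type": r.cell_type,
                "control_id": ctrl,
                "control_name": ctrl,
                "event_type": r.event_type,
                "n_individuals": r.k,
                "n_individuals_p05": r.n_p05,
                "n_individuals_positive": r.n_positive,
                "z_combined": r.z_combined,
                "q_value": r.q_value,
                "gene_id": a.gene_id,
                "gene_symbol": a.gene_id,
            }
        )
    return pd.DataFrame(records, columns=_S2_COLUMNS)
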