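"""Trans-factor association: correlate factor expression changes with
RNA-processing behavior across environments.

Two analyses: (i) per factor, Spearman correlation of its expression
log-fold change against the percent positive events (PPE) of one event type
across environments, BH-corrected within the factor family of that event
type; (ii) per treatment × event type, Spearman correlation of per-gene
expression log-fold change against the gene's mean ΔΨ across individuals,
reported for groups with at least 30 assessable shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_ENVIRONMENTS = 10
MIN_SHIFTS = 30


@dataclass
class AssociationResult:
    factor_id: str
    event_type: str
    spearman_rho: float
    p: float
    q: float
    n: int


def factor_ppe_correlation(expr: pd.DataFrame, ppe_by_env: pd.DataFrame,
                           event_type: str,
                           min_environments: int = MIN_ENVIRONMENTS,
                           ) -> list[AssociationResult]:
    """Correlate each factor's log-fold change with one event type's PPE.

    ``expr`` columns: factor_id, cell_type, treatment, log_fold_change;
    ``ppe_by_env`` columns: cell_type, treatment, ppe.  Factors observed in
    fewer than ``min_environments`` environments with a defined PPE are
    skipped; a constant PPE vector leaves rho undefined and the factor is
    excluded from the BH family.
    """
    merged = expr.merge(ppe_by_env, on=["cell_type", "treatment"])
    results: list[AssociationResult] = []
    for factor, grp in merged.groupby("factor_id", sort=True):
        grp = grp.dropna(subset=["log_fold_change", "ppe"])
        if len(grp) < min_environments:
            continue
        if grp["ppe"].nunique() < 2 or grp["log_fold_change"].nunique() < 2:
            results.append(AssociationResult(factor, event_type, float("nan"),
                                             float("nan"), float("nan"), len(grp)))
            continue
        rho, p = stats.spearmanr(grp["log_fold_change"], grp["ppe"])
        results.append(AssociationResult(factor, event_type, float(rho),
                                         float(p), float("nan"), len(grp)))
    defined = [r for r in results if np.isfinite(r.p)]
    if defined:
        q = multipletests([r.p for r in defined], method="fdr_bh")[1]
        for r, qi in zip(defined, q):
            r.q = float(qi)
    return results


def expression_deltapsi_correlation(table: pd.DataFrame,
                                    min_shifts: int = MIN_SHIFTS,
                                    report_p: float = 0.05) -> pd.DataFrame:
    """Per treatment × event type, correlate gene logFC with mean ΔΨ.

    ``table`` columns: treatment, event_type, gene_id, log_fold_change,
    mean_delta_psi — one row per significant shift with assessable
    expression.  Groups with fewer than ``min_shifts`` rows are skipped;
    rows of the output carry ``reported`` = True when p < ``report_p``
    (the released-table convention).
    """
    rows = []
    for (treat, etype), grp in table.groupby(["treatment", "event_type"], sort=True):
        grp = grp.dropna(subset=["log_fold_change", "mean_delta_psi"])
        if len(grp) < min_shifts:
            continue
        rho, p = stats.spearmanr(grp["log_fold_change"], grp["mean_delta_psi"])
        rows.append(
            {
                "treatment": treat,
                "event_type": etype,
                "spearman_rho": float(rho),
                "p": float(p),
                "n": len(grp),
                "reported": bool(p < report_p),
            }
        )
    return pd.DataFrame(
        rows, columns=["treatment", "event_type", "spearman_rho", "p", "n",
                       "reported"]
    )


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "factor_id": r.factor_id,
                "event_type": r.event_type,
                "spearman_rho": r.spearman_rho,
                "p": r.p,
                "q": r.q,
                "n": r.n,
            }
            for r in results
        ]
    )
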