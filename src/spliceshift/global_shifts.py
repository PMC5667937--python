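"""Environment-level directional statistics.

For each environment (cell type × treatment) and directional event type:
the percent positive events PPE = n_pos / n_sig among significant shifts, an
exact two-sided binomial test of the positive:negative split against 50:50,
a two-sample Kolmogorov-Smirnov comparison of all ΔΨ (significant or not)
against the control-vs-control ΔΨ distribution, and a logistic
significant ~ treatment × event_type + cell_type enrichment model whose
treatment-by-type interactions flag event types over-represented among a
treatment's significant shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .formats_io import DIRECTIONAL_TYPES

BINOMIAL_ALPHA = 0.05
MIN_KS_SAMPLE = 30
#: environments reported in figure-style directional output need this many
#: significant events
MIN_SIG_REPORT = 10


@dataclass
class DirectionalSummary:
    environment: tuple
    event_type: str
    n_sig: int
    n_pos: int
    ppe: float
    binom_p: float
    label: str  # {"positive-enriched", "negative-enriched", "none"}


@dataclass
class EnrichmentModel:
    coefficients: pd.DataFrame       # term, beta, se, z, p
    interaction_pvalues: pd.DataFrame  # treatment, event_type, beta, p
    proportions: pd.DataFrame        # treatment × event_type proportion among significant
    baseline: dict
    ridge_fallback: bool = False
    fitted: np.ndarray = field(default=None, repr=False)


def ppe(n_pos: int, n_sig: int) -> float:
    """Percent positive events: positive significant shifts / significant shifts."""
    if n_sig < 1:
        raise ValueError("PPE undefined for n_sig = 0")
    return n_pos / n_sig


def directional_binomial(n_pos: int, n_sig: int,
                         alpha: float = BINOMIAL_ALPHA) -> tuple[float, str]:
    """Exact two-sided binomial test of the positive fraction against 0.5."""
    if n_sig < 1:
        raise ValueError("directional test undefined for n_sig = 0")
    p = stats.binomtest(n_pos, n_sig, 0.5, alternative="two-sided").pvalue
    if p < alpha and n_pos > n_sig / 2:
        label = "positive-enriched"
    elif p < alpha and n_pos < n_sig / 2:
        label = "negative-enriched"
    else:
        label = "none"
    return float(p), label


def summarize_directions(calls: pd.DataFrame,
                         min_sig: int = 1) -> pd.DataFrame:
    """Per-environment, per-directional-type summaries from combined calls.

    ``calls`` is the output of :func:`spliceshift.shift_calling.call_shifts_table`.
    Environments with fewer than ``min_sig`` significant events are dropped
    (figure-style reporting uses ``min_sig=MIN_SIG_REPORT``).
    """
    sig = calls[calls["significant"]
                & calls["event_type"].isin(DIRECTIONAL_TYPES)]
    rows = []
    for (cell, treat, etype), grp in sig.groupby(
            ["cell_type", "treatment", "event_type"], sort=True):
        n_sig = len(grp)
        if n_sig < min_sig:
            continue
        n_pos = int((grp["z_combined"] > 0).sum())
        p, label = directional_binomial(n_pos, n_sig)
        rows.append(
            {
                "cell_type": cell,
                "treatment": treat,
                "event_type": etype,
                "n_sig": n_sig,
                "n_pos": n_pos,
                "ppe": ppe(n_pos, n_sig),
                "binom_p": p,
                "label": label,
            }
        )
    return pd.DataFrame(
        rows, columns=["cell_type", "treatment", "event_type", "n_sig",
                       "n_pos", "ppe", "binom_p", "label"]
    )


def ecdf_ks(deltas_env, deltas_null, min_n: int = MIN_KS_SAMPLE):
    """Two-sample KS test of an environment's ΔΨ ECDF against the CC null ΔΨ.

    All shifts enter, not only significant ones.  Returns (D, p) or None when
    either sample is below ``min_n`` (skipped with that reason logged by the
    caller)."""
    deltas_env = np.asarray(deltas_env, dtype=float)
    deltas_null = np.asarray(deltas_null, dtype=float)
    if len(deltas_env) < min_n or len(deltas_null) < min_n:
        return None
    res = stats.ks_2samp(deltas_env, deltas_null, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# event-type enrichment GLM
# ---------------------------------------------------------------------------

def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float = 1.0):
    """Ridge-stabilized IRLS logistic fit used when the MLE separates."""
    n, p = X.shape
    beta = np.zeros(p)
    pen = alpha * np.eye(p)
    pen[0, 0] = 0.0  # do not penalize the intercept
    for _ in range(100):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        H = X.T @ (X * w[:, None]) + pen
        new = np.linalg.solve(H, X.T @ (w * z))
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = X.T @ (X * w[:, None]) + pen
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.diag(cov)), mu


def event_type_enrichment(rows: pd.DataFrame) -> EnrichmentModel:
    """Fit logit(p_l) ~ treatment × event_type + cell_type.

    ``rows`` has one line per tested event with boolean ``significant`` and
    categorical ``treatment``, ``event_type``, ``cell_type``.  The first
    level of each factor is the baseline; interaction Wald p-values test
    whether an event type is enriched among a treatment's significant events
    beyond the marginal rates.  Per-treatment event-type proportions among
    significant events are the fitted cell probabilities reweighted by the
    number of events tested in each (treatment, event type) cell and
    normalized within treatment.

    On complete separation the fit falls back to a ridge-stabilized IRLS
    with a warning.
    """
    rows = rows.copy()
    rows["significant"] = rows["significant"].astype(int)
    formula = "significant ~ C(treatment) * C(event_type)"
    if rows["cell_type"].nunique() > 1:
        formula += " + C(cell_type)"
    model = smf.glm(formula, data=rows, family=sm.families.Binomial())
    terms = list(model.exog_names)
    ridge = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit()
        beta = np.asarray(fit.params)
        se = np.asarray(fit.bse)
        fitted = np.asarray(fit.fittedvalues)
        if not np.isfinite(se).all() or np.max(np.abs(beta)) > 20:
            ridge = True
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        ridge = True
    if ridge:
        warnings.warn("complete separation: ridge-stabilized logistic fallback",
                      stacklevel=2)
        beta, se, fitted = _ridge_logit(np.asarray(model.exog),
                                        np.asarray(model.endog).ravel())
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    coef = pd.DataFrame({"term": terms, "beta": beta, "se": se, "z": z, "p": p})

    inter = coef[coef["term"].str.contains(":")].copy()
    inter["treatment"] = inter["term"].str.extract(r"C\(treatment\)\[T\.([^\]]+)\]")
    inter["event_type"] = inter["term"].str.extract(r"C\(event_type\)\[T\.([^\]]+)\]")
    interaction_pvalues = inter[["treatment", "event_type", "beta", "p"]].reset_index(drop=True)

    rows["fitted"] = fitted
    cell = rows.groupby(["treatment", "event_type"], sort=True).agg(
        p_hat=("fitted", "mean"), n=("fitted", "size")
    ).reset_index()
    cell["weight"] = cell["p_hat"] * cell["n"]
    cell["proportion"] = cell.groupby("treatment")["weight"].transform(
        lambda w: w / w.sum()
    )
    proportions = cell[["treatment", "event_type", "p_hat", "n", "proportion"]]

    baseline = {
        "treatment": sorted(rows["treatment"].unique())[0],
        "event_type": sorted(rows["event_type"].unique())[0],
        "cell_type": sorted(rows["cell_type"].unique())[0],
    }
    return EnrichmentModel(coef, interaction_pvalues, proportions, baseline,
                           ridge_fallback=ridge, fitted=fitted)


# ---------------------------------------------------------------------------
# plotting (aesthetics are not contractual)
# ---------------------------------------------------------------------------

def plot_direction_summary(summary: pd.DataFrame, path):
    """Bar plot of PPE per environment for one event type."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(summary) * 0.4), 3))
    labels = summary["cell_type"] + "/" + summary["treatment"]
    ax.bar(labels, summary["ppe"], color="steelblue")
    ax.axhline(0.5, color="grey", ls="--", lw=0.8)
    ax.set_ylabel("PPE")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_ecdf(deltas_env, deltas_null, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    for values, label in ((deltas_env, "environment"), (deltas_null, "CC null")):
        x = np.sort(np.asarray(values))
        ax.step(x, np.arange(1, len(x) + 1) / len(x), where="post", label=label)
    ax.set_xlabel("oriented $\\Delta\\Psi$")
    ax.set_ylabel("ECDF")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
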