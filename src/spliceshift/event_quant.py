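"""Per-comparison quantification of alternative-processing events.

This module is a documented beta-binomial stand-in for MISO's per-event
output: given isoform-unique read counts it produces a Ψ posterior, a ΔΨ
between treatment and control, and a Bayes factor BF₁₀ for the two-Ψ
alternative against a shared Ψ.  The BF scale need not match MISO's —
downstream calling calibrates Bayes factors against their own empirical
null, so only the within-pipeline ranking matters.

Model
-----
Reads unique to the inclusion isoform are Binomial(n, Ψ) given n = total
isoform-unique reads, with a conjugate Beta(a, b) prior on Ψ (uniform by
default).  Under H₁ treatment and control have independent Ψ; under H₀ they
share one Ψ.  Binomial coefficients cancel in the marginal-likelihood
ratio, leaving Beta functions only::

    BF₁₀ = B(a+k_t, b+n_t−k_t) · B(a+k_c, b+n_c−k_c) / B(a,b)
           ─────────────────────────────────────────────────
               B(a+k_t+k_c, b+n_t+n_c−k_t−k_c) · B(a,b)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln
from scipy.stats import beta as beta_dist

from .formats_io import EventAnnotation

DEFAULT_PRIOR = (1.0, 1.0)

#: Event types whose oriented ΔΨ is a biological direction (others pass
#: through orient_delta unchanged and are flagged non-directional).
_ORIENTABLE = {"SE", "RI", "TandemUTR", "AFE", "ALE"}


@dataclass
class EventCounts:
    """Isoform-unique read counts for one event in one library.

    For TandemUTR events ``n_inc`` is the count specific to the *longer* UTR
    isoform and ``n_exc`` the remaining reads covering either isoform, so
    ``n_inc + n_exc`` is the total informative count (n_long <= n_total holds
    by construction).
    """

    event_id: str
    library_id: str
    n_inc: int
    n_exc: int

    def __post_init__(self) -> None:
        if self.n_inc < 0 or self.n_exc < 0:
            raise ValueError(f"{self.event_id}/{self.library_id}: negative read count")

    @property
    def n_total(self) -> int:
        return self.n_inc + self.n_exc


@dataclass
class PsiPosterior:
    mean: float
    ci_low: float
    ci_high: float
    prior: tuple[float, float]


@dataclass
class FilterResult:
    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.passed


class CoverageFilterError(Exception):
    """Raised when a comparison is attempted on counts failing the coverage filter."""

    def __init__(self, result: FilterResult):
        super().__init__(result.reason)
        self.result = result


@dataclass
class OrientedDelta:
    value: float
    directional: bool


@dataclass
class Comparison:
    """ΔΨ and Bayes factor for one treatment-vs-control pair in one individual."""

    event_id: str
    event_type: str
    individual_id: str
    environment: tuple  # (cell_type, treatment) or similar key
    delta_psi: float  # oriented
    bayes_factor: float

    def __post_init__(self) -> None:
        if abs(self.delta_psi) > 1.0 + 1e-12:
            raise ValueError(f"{self.event_id}: |delta_psi| > 1")
        if self.bayes_factor < 0:
            raise ValueError(f"{self.event_id}: negative Bayes factor")


# ---------------------------------------------------------------------------
# Ψ posterior
# ---------------------------------------------------------------------------

def posterior_mean(n_inc, n_exc, prior=DEFAULT_PRIOR):
    """Posterior mean of Ψ under the conjugate Beta prior (vectorized)."""
    a, b = prior
    n_inc = np.asarray(n_inc, dtype=float)
    n_exc = np.asarray(n_exc, dtype=float)
    return (a + n_inc) / (a + b + n_inc + n_exc)


def estimate_psi(counts: EventCounts, prior: tuple[float, float] = DEFAULT_PRIOR,
                 ci: float = 0.95) -> PsiPosterior:
    """Beta posterior for Ψ from isoform-unique counts.

    With zero counts the prior itself is returned; negative counts are
    rejected at construction of :class:`EventCounts`.
    """
    a, b = prior
    a_post, b_post = a + counts.n_inc, b + counts.n_exc
    alpha = (1.0 - ci) / 2.0
    return PsiPosterior(
        mean=a_post / (a_post + b_post),
        ci_low=float(beta_dist.ppf(alpha, a_post, b_post)),
        ci_high=float(beta_dist.ppf(1.0 - alpha, a_post, b_post)),
        prior=(a, b),
    )


# ---------------------------------------------------------------------------
# Bayes factor
# ---------------------------------------------------------------------------

def log_bf10(k_t, n_t, k_c, n_c, prior=DEFAULT_PRIOR):
    """log BF₁₀ for independent-Ψ vs shared-Ψ (vectorized closed form)."""
    a, b = prior
    k_t = np.asarray(k_t, dtype=float)
    n_t = np.asarray(n_t, dtype=float)
    k_c = np.asarray(k_c, dtype=float)
    n_c = np.asarray(n_c, dtype=float)
    log_m1 = (
        betaln(a + k_t, b + n_t - k_t)
        + betaln(a + k_c, b + n_c - k_c)
        - 2.0 * betaln(a, b)
    )
    log_m0 = betaln(a + k_t + k_c, b + n_t + n_c - k_t - k_c) - betaln(a, b)
    return log_m1 - log_m0


def bayes_factor(k_t, n_t, k_c, n_c, prior=DEFAULT_PRIOR):
    return np.exp(log_bf10(k_t, n_t, k_c, n_c, prior))


# ---------------------------------------------------------------------------
# coverage filter
# ---------------------------------------------------------------------------

def apply_coverage_filter(event_type: str, treat: EventCounts,
                          ctrl: EventCounts) -> FilterResult:
    """Minimum-coverage rule applied to one treatment/control pair.

    Non-TandemUTR types require, in *both* samples, >= 2 reads unique to each
    isoform and >= 10 isoform-unique reads total.  TandemUTR (whose shorter
    isoform has no unique region) requires >= 5 reads specific to the longer
    isoform and >= 10 total informative reads in both samples.
    """
    for label, c in (("treat", treat), ("ctrl", ctrl)):
        if event_type == "TandemUTR":
            if c.n_inc < 5:
                return FilterResult(False, f"{label} n_long < 5")
            if c.n_total < 10:
                return FilterResult(False, f"{label} n_total < 10")
        else:
            if c.n_inc < 2:
                return FilterResult(False, f"{label} n_inc < 2")
            if c.n_exc < 2:
                return FilterResult(False, f"{label} n_exc < 2")
            if c.n_total < 10:
                return FilterResult(False, f"{label} n_inc + n_exc < 10")
    return FilterResult(True)


def coverage_filter_mask(event_type, n_inc_t, n_exc_t, n_inc_c, n_exc_c):
    """Vectorized coverage filter over aligned count arrays."""
    n_inc_t = np.asarray(n_inc_t)
    n_exc_t = np.asarray(n_exc_t)
    n_inc_c = np.asarray(n_inc_c)
    n_exc_c = np.asarray(n_exc_c)
    if event_type == "TandemUTR":
        return (
            (n_inc_t >= 5) & (n_inc_t + n_exc_t >= 10)
            & (n_inc_c >= 5) & (n_inc_c + n_exc_c >= 10)
        )
    return (
        (n_inc_t >= 2) & (n_exc_t >= 2) & (n_inc_t + n_exc_t >= 10)
        & (n_inc_c >= 2) & (n_exc_c >= 2) & (n_inc_c + n_exc_c >= 10)
    )


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def orientation_sign(annotation: EventAnnotation) -> int:
    """Sign applied to raw (isoform-1 minus isoform-2) ΔΨ so that positive
    oriented ΔΨ means: more exon inclusion (SE), more intron retention (RI),
    longer tandem UTR, more *upstream* AFE, more *downstream* ALE — all on
    the transcribed strand.

    SE/RI/TandemUTR already satisfy this in MISO's isoform ordering and pass
    through with +1.  For AFE the sign flips when isoform 1 is not the
    upstream-TSS isoform; for ALE when isoform 1 is not the downstream-end
    isoform.  Non-directional types return +1.
    """
    t = annotation.event_type
    if t == "AFE":
        return 1 if annotation.isoform1_is_upstream_tss else -1
    if t == "ALE":
        return 1 if annotation.isoform1_is_downstream_tes else -1
    return 1


def orient_delta(event_type: str, raw_delta: float,
                 annotation: EventAnnotation | None = None) -> OrientedDelta:
    """Orient a raw MISO-convention ΔΨ; see :func:`orientation_sign`.

    A3SS/A5SS/MXE have no global direction convention and are returned
    unchanged with ``directional=False``.
    """
    if event_type not in _ORIENTABLE:
        return OrientedDelta(raw_delta, directional=False)
    if event_type in ("AFE", "ALE"):
        if annotation is None:
            raise ValueError(f"{event_type} orientation requires the event annotation")
        return OrientedDelta(orientation_sign(annotation) * raw_delta, directional=True)
    return OrientedDelta(raw_delta, directional=True)


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def compare_conditions(treat: EventCounts, ctrl: EventCounts,
                       annotation: EventAnnotation,
                       individual_id: str = "",
                       environment: tuple = (),
                       prior: tuple[float, float] = DEFAULT_PRIOR) -> Comparison:
    """Full per-event comparison of one treatment library against its control.

    Raises :class:`CoverageFilterError` (a typed rejection, never a silent
    omission) when either sample fails the coverage filter.
    """
    result = apply_coverage_filter(annotation.event_type, treat, ctrl)
    if not result:
        raise CoverageFilterError(result)
    raw_delta = float(
        posterior_mean(treat.n_inc, treat.n_exc, prior)
        - posterior_mean(ctrl.n_inc, ctrl.n_exc, prior)
    )
    oriented = orient_delta(annotation.event_type, raw_delta, annotation)
    bf = float(bayes_factor(treat.n_inc, treat.n_total, ctrl.n_inc, ctrl.n_total, prior))
    return Comparison(
        event_id=annotation.event_id,
        event_type=annotation.event_type,
        individual_id=individual_id,
        environment=environment,
        delta_psi=oriented.value,
        bayes_factor=bf,
    )


# ---------------------------------------------------------------------------
# cohort-level quantification (vectorized)
# ---------------------------------------------------------------------------

_KEYS = ["event_id", "event_type", "cell_type", "individual"]


def _vector_compare(treat: pd.DataFrame, ctrl: pd.DataFrame, flip: pd.Series,
                    prior) -> pd.DataFrame:
    """Filter, ΔΨ and log BF for aligned treatment/control pooled counts."""
    merged = treat.merge(ctrl, on=_KEYS + ["control_id"], suffixes=("_t", "_c"))
    tandem = merged["event_type"].to_numpy() == "TandemUTR"
    mask = np.where(
        tandem,
        coverage_filter_mask("TandemUTR", merged["n_inc_t"], merged["n_exc_t"],
                             merged["n_inc_c"], merged["n_exc_c"]),
        coverage_filter_mask("SE", merged["n_inc_t"], merged["n_exc_t"],
                             merged["n_inc_c"], merged["n_exc_c"]),
    )
    raw_delta = (
        posterior_mean(merged["n_inc_t"], merged["n_exc_t"], prior)
        - posterior_mean(merged["n_inc_c"], merged["n_exc_c"], prior)
    )
    lbf = log_bf10(
        merged["n_inc_t"], merged["n_inc_t"] + merged["n_exc_t"],
        merged["n_inc_c"], merged["n_inc_c"] + merged["n_exc_c"], prior,
    )
    out = merged[_KEYS].copy()
    cond_col = "condition_t" if "condition_t" in merged else "condition"
    out["treatment"] = merged[cond_col].to_numpy()
    out["raw_delta"] = np.asarray(raw_delta)
    out["delta_psi"] = np.asarray(raw_delta) * flip.reindex(out["event_id"]).to_numpy()
    out["log_bf"] = np.asarray(lbf)
    n_filtered = int((~mask).sum())
    out = out[mask].reset_index(drop=True)
    out.attrs["n_filtered"] = n_filtered
    return out


def compare_cohort(counts: pd.DataFrame,
                   annotations: dict[str, EventAnnotation],
                   prior: tuple[float, float] = DEFAULT_PRIOR,
                   controls: list[str] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every treatment-vs-control and control-vs-control comparison.

    ``counts`` is the library-level count table (synthetic_cohort layout or
    equivalent from parsed MISO files): one row per event × library with
    ``role`` in {treatment, control}, ``condition`` the compound, and
    ``control_id`` the assigned control for treatment rows.  Technical
    control replicates are pooled by summation before comparison.  Returns
    ``(comparisons, null_comparisons)`` with oriented ΔΨ and log Bayes
    factors, restricted to filter-passing rows (the number filtered is kept
    in ``DataFrame.attrs['n_filtered']``).

    Control-vs-control (empirical null) comparisons pair each control with
    its predecessor in sorted order (CO2 vs CO1, ...), mirroring the
    treatment-vs-control pairing within individual and cell type.
    """
    flip = pd.Series(
        {eid: orientation_sign(a) for eid, a in annotations.items()}, dtype=float
    )
    pooled = (
        counts.groupby(_KEYS + ["role", "condition", "control_id"], sort=True,
                       observed=True)[["n_inc", "n_exc"]]
        .sum()
        .reset_index()
    )
    treat = pooled[pooled["role"] == "treatment"]
    ctrl = pooled[pooled["role"] == "control"]

    ctrl_side = ctrl.rename(columns={"condition": "control_id_drop"})
    ctrl_side = ctrl_side.drop(columns=["role", "control_id_drop"])
    comparisons = _vector_compare(
        treat.drop(columns=["role"]),
        ctrl_side.rename(columns={"control_id": "control_id"}),
        flip, prior,
    )

    if controls is None:
        controls = sorted(ctrl["condition"].unique())
    null_parts = []
    for c1, c2 in zip(controls[:-1], controls[1:]):
        side2 = ctrl[ctrl["condition"] == c2].drop(columns=["role"])
        side2 = side2.assign(control_id=c1)
        side1 = ctrl[ctrl["condition"] == c1].drop(columns=["role", "condition"])
        part = _vector_compare(side2, side1, flip, prior)
        part["treatment"] = f"{c2}_vs_{c1}"
        null_parts.append(part)
    null_comparisons = (
        pd.concat(null_parts, ignore_index=True) if null_parts else pd.DataFrame()
    )
    return comparisons, null_comparisons
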