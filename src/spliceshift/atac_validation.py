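"""ATAC-seq validation of first-exon-choice mechanism.

Tn5 insertion-site arithmetic, fragment-length binning, normalized
accessibility profiles around the two TSSs of shifted AFE events, and
per-motif treatment/control accessibility-ratio tests contrasting
footprints near the treatment-preferred TSS against those near the
non-preferred TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import EventAnnotation, FootprintRecord

#: fragment-length bins for global accessibility work
LENGTH_BINS = ((39, 99), (100, 139), (140, 179), (180, 250))
#: open-chromatin fragment-length filter for TSS profiles
OPEN_LENGTH = (30, 140)
TSS_HALF_WINDOW = 500
MOTIF_HALF_WINDOW = 100
RELAXED_FDR = 0.25
PSEUDOCOUNT = 1.0


@dataclass
class MotifAccessibilityTest:
    motif_id: str
    n_preferred: int
    n_nonpreferred: int
    mean_ratio_preferred: float
    mean_ratio_nonpreferred: float
    t_statistic: float
    p: float
    q: float = float("nan")
    degenerate: bool = False


# ---------------------------------------------------------------------------
# insertion sites and bins
# ---------------------------------------------------------------------------

def insertion_sites(start: int, end: int) -> tuple[int, int]:
    """Tn5 insertion positions for one fragment [start, end).

    Each mate's 5' end is shifted 4 bp in its own 5'→3' direction: the left
    site is ``start + 4`` and the right site ``end − 1 − 4``.  Fragments
    shorter than 9 bp would cross their sites and must be skipped by the
    caller.
    """
    if end - start < 9:
        raise ValueError(f"fragment [{start},{end}) shorter than 9 bp")
    return start + 4, end - 1 - 4


def length_bin(length: int) -> int | None:
    """Index of the fragment-length bin, or None outside [39, 250]."""
    for i, (lo, hi) in enumerate(LENGTH_BINS):
        if lo <= length <= hi:
            return i
    return None


def insertion_site_table(fragments: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Left/right Tn5 sites and length-bin per fragment.

    Returns (table with ``site_left``, ``site_right``, ``length_bin``
    columns added; count of skipped too-short fragments).  Fragments outside
    all four length bins keep ``length_bin`` = −1.
    """
    length = fragments["end"] - fragments["start"]
    ok = length >= 9
    out = fragments[ok].copy()
    out["site_left"] = out["start"] + 4
    out["site_right"] = out["end"] - 5
    lb = np.full(len(out), -1)
    lengths = (out["end"] - out["start"]).to_numpy()
    for i, (lo, hi) in enumerate(LENGTH_BINS):
        lb[(lengths >= lo) & (lengths <= hi)] = i
    out["length_bin"] = lb
    return out, int((~ok).sum())


# ---------------------------------------------------------------------------
# fragment index
# ---------------------------------------------------------------------------

class _FragmentIndex:
    """Per-chromosome sorted starts/ends for interval-overlap counting."""

    def __init__(self, fragments: pd.DataFrame):
        self.total = len(fragments)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, grp in fragments.groupby("chrom"):
            self._starts[chrom] = np.sort(grp["start"].to_numpy())
            self._ends[chrom] = np.sort(grp["end"].to_numpy())

    def count_overlap(self, chrom: str, win_start: int, win_end: int) -> int:
        """Number of fragments overlapping [win_start, win_end)."""
        starts = self._starts.get(chrom)
        if starts is None:
            return 0
        ends = self._ends[chrom]
        n = len(starts)
        n_right = n - np.searchsorted(starts, win_end, side="left")
        n_left = np.searchsorted(ends, win_start, side="right")
        return int(n - n_right - n_left)

    def profile(self, chrom: str, center: int, half: int) -> np.ndarray:
        """Per-bp fragment-overlap counts over [center−half, center+half]."""
        starts = self._starts.get(chrom)
        if starts is None:
            return np.zeros(2 * half + 1)
        ends = self._ends[chrom]
        lo, hi = center - half, center + half + 1
        grid = np.arange(lo, hi)
        covered_start = np.searchsorted(starts, grid + 1, side="left")
        covered_end = np.searchsorted(ends, grid, side="right")
        return (covered_start - covered_end).astype(float)


def classify_tss(calls: pd.DataFrame, annotations: dict[str, EventAnnotation],
                 q_threshold: float = RELAXED_FDR) -> pd.DataFrame:
    """Preferred / non-preferred TSS assignment for shifted AFE events.

    Uses AFE calls at the relaxed threshold (q < ``q_threshold``); the
    preferred TSS is the one usage shifts *toward* under treatment
    (upstream TSS for positive oriented ΔΨ).  Ties (direction 0) are
    excluded.
    """
    afe = calls[(calls["event_type"] == "AFE")
                & (calls["q_value"] < q_threshold)
                & (calls["direction"] != 0)]
    rows = []
    for rec in afe.itertuples(index=False):
        a = annotations[rec.event_id]
        up, down = a.upstream_tss, a.downstream_tss
        preferred = up if rec.direction > 0 else down
        other = down if rec.direction > 0 else up
        rows.append({"event_id": rec.event_id, "chrom": a.chrom,
                     "tss": preferred, "tss_class": "preferred"})
        rows.append({"event_id": rec.event_id, "chrom": a.chrom,
                     "tss": other, "tss_class": "nonpreferred"})
    return pd.DataFrame(rows, columns=["event_id", "chrom", "tss", "tss_class"])


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def tss_accessibility_profile(
    fragments: pd.DataFrame,
    tss_table: pd.DataFrame,
    half_window: int = TSS_HALF_WINDOW,
    length_range: tuple[int, int] = OPEN_LENGTH,
) -> dict[tuple[str, str], np.ndarray]:
    """Normalized accessibility around preferred / non-preferred TSSs.

    Counts fragment overlap per bp within ±``half_window`` of each TSS,
    restricted to open-chromatin fragment lengths, summed within each TSS
    class and divided by the library's total fragment count — so doubling
    every count and the library total leaves profiles unchanged.  Returns
    ``{(tss_class, condition): profile}`` with profiles of length
    ``2·half_window + 1``; empty inputs give all-zero profiles.
    """
    lo, hi = length_range
    keep = fragments[(fragments["length"] >= lo) & (fragments["length"] <= hi)]
    out: dict[tuple[str, str], np.ndarray] = {}
    for condition, cond_frags in fragments.groupby("condition"):
        total = len(cond_frags)  # normalization uses all mapped fragments
        index = _FragmentIndex(keep[keep["condition"] == condition])
        for tss_class, sites in tss_table.groupby("tss_class"):
            profile = np.zeros(2 * half_window + 1)
            for rec in sites.itertuples(index=False):
                profile += index.profile(rec.chrom, rec.tss, half_window)
            out[(tss_class, condition)] = profile / max(total, 1)
    return out


# ---------------------------------------------------------------------------
# per-motif accessibility ratio test
# ---------------------------------------------------------------------------

def footprint_accessibility_test(
    fragments: pd.DataFrame,
    footprints: list[FootprintRecord],
    tss_table: pd.DataFrame,
    half_window: int = MOTIF_HALF_WINDOW,
    tss_half_window: int = TSS_HALF_WINDOW,
    welch: bool = True,
) -> list[MotifAccessibilityTest]:
    """Per-motif t-test of treatment/control accessibility ratios by TSS class.

    Footprints are assigned to the preferred or non-preferred class when
    they fall within ``tss_half_window`` of a TSS of that class.  For each
    footprint the normalized read counts within ±``half_window`` of the
    motif (pseudocount 1 added to both conditions) form the ratio
    r = (c_treat/N_treat)/(c_ctrl/N_ctrl); ratios at preferred-class
    footprints are compared with the non-preferred class by a two-tailed
    two-sample t-test (Welch by default, pooled-variance Student via
    ``welch=False``), BH-corrected across motifs.  Motifs with fewer than 2
    footprints in either class are skipped; degenerate (zero-variance)
    ratio sets report p = 1 flagged.
    """
    cond_index = {
        cond: _FragmentIndex(grp) for cond, grp in fragments.groupby("condition")
    }
    n_treat = cond_index.get("treatment", _FragmentIndex(fragments.iloc[0:0])).total
    n_ctrl = cond_index.get("control", _FragmentIndex(fragments.iloc[0:0])).total

    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for rec in tss_table.itertuples(index=False):
        tss_by_chrom.setdefault(rec.chrom, []).append((rec.tss, rec.tss_class))

    ratios: dict[str, dict[str, list[float]]] = {}
    for f in footprints:
        center = (f.start + f.end) // 2
        classes = {
            cls
            for tss, cls in tss_by_chrom.get(f.chrom, [])
            if abs(center - tss) <= tss_half_window
        }
        if not classes:
            continue
        c_t = cond_index["treatment"].count_overlap(
            f.chrom, center - half_window, center + half_window + 1
        ) if "treatment" in cond_index else 0
        c_c = cond_index["control"].count_overlap(
            f.chrom, center - half_window, center + half_window + 1
        ) if "control" in cond_index else 0
        r = ((c_t + PSEUDOCOUNT) / max(n_treat, 1)) / (
            (c_c + PSEUDOCOUNT) / max(n_ctrl, 1)
        )
        for cls in classes:
            ratios.setdefault(f.motif_id, {}).setdefault(cls, []).append(r)

    results: list[MotifAccessibilityTest] = []
    for motif in sorted(ratios):
        pref = np.asarray(ratios[motif].get("preferred", []), dtype=float)
        nonpref = np.asarray(ratios[motif].get("nonpreferred", []), dtype=float)
        if len(pref) < 2 or len(nonpref) < 2:
            continue
        if np.ptp(pref) == 0 and np.ptp(nonpref) == 0:
            results.append(
                MotifAccessibilityTest(motif, len(pref), len(nonpref),
                                       float(pref.mean()), float(nonpref.mean()),
                                       0.0, 1.0, degenerate=True)
            )
            continue
        t, p = stats.ttest_ind(pref, nonpref, equal_var=not welch)
        results.append(
            MotifAccessibilityTest(motif, len(pref), len(nonpref),
                                   float(pref.mean()), float(nonpref.mean()),
                                   float(t), float(p))
        )
    if results:
        q = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, qi in zip(results, q):
            r.q = float(qi)
    return results


def accessibility_table(results: list[MotifAccessibilityTest],
                        fdr: float = 0.05) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "motif_id": r.motif_id,
                "n_preferred": r.n_preferred,
                "n_nonpreferred": r.n_nonpreferred,
                "mean_ratio_preferred": r.mean_ratio_preferred,
                "mean_ratio_nonpreferred": r.mean_ratio_nonpreferred,
                "t_statistic": r.t_statistic,
                "p": r.p,
                "q": r.q,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
    if not df.empty:
        df["significant"] = df["q"] < fdr
    return df
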