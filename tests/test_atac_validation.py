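import numpy as np
import pandas as pd
import pytest

from spliceshift.atac_validation import (
    _FragmentIndex,
    accessibility_table,
    classify_tss,
    footprint_accessibility_test,
    insertion_site_table,
    insertion_sites,
    length_bin,
    tss_accessibility_profile,
)
from spliceshift.formats_io import FootprintRecord


class TestInsertionSites:
    def test_hundred_bp_fragment(self):
        assert insertion_sites(1000, 1100) == (1004, 1095)

    def test_short_fragment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            insertion_sites(100, 108)

    def test_mate_label_swap_invariance(self):
        # sites come from fragment ends, so relabeling mates changes nothing
        left, right = insertion_sites(2000, 2180)
        assert (left, right) == tuple(sorted(insertion_sites(2000, 2180)))

    @pytest.mark.parametrize("length,expected",
                             [(39, 0), (99, 0), (100, 1), (139, 1),
                              (140, 2), (179, 2), (180, 3), (250, 3),
                              (38, None), (251, None)])
    def test_length_bins(self, length, expected):
        assert length_bin(length) == expected

    def test_table_skips_short_fragments_with_count(self):
        frags = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [0, 0, 0], "end": [100, 8, 38]}
        )
        table, skipped = insertion_site_table(frags)
        assert skipped == 1
        assert table["length_bin"].tolist() == [1, -1]


def _uniform_fragments(rng, n, condition, chrom="chr1", lo=0, hi=5000):
    start = rng.integers(lo, hi, size=n)
    length = rng.integers(40, 120, size=n)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + length,
            "length": length,
            "library_id": f"lib_{condition}",
            "condition": condition,
        }
    )


class TestProfiles:
    def test_additive_over_disjoint_subsets(self, rng):
        frags = _uniform_fragments(rng, 400, "treatment")
        tss = pd.DataFrame(
            {"event_id": ["e"], "chrom": ["chr1"], "tss": [2500],
             "tss_class": ["preferred"]}
        )
        full = _FragmentIndex(frags).profile("chr1", 2500, 200)
        half1 = _FragmentIndex(frags.iloc[:200]).profile("chr1", 2500, 200)
        half2 = _FragmentIndex(frags.iloc[200:]).profile("chr1", 2500, 200)
        assert np.allclose(full, half1 + half2)

    def test_normalization_invariant_to_depth_doubling(self, rng):
        frags = _uniform_fragments(rng, 500, "treatment")
        tss = pd.DataFrame(
            {"event_id": ["e"], "chrom": ["chr1"], "tss": [2500],
             "tss_class": ["preferred"]}
        )
        p1 = tss_accessibility_profile(frags, tss)
        doubled = pd.concat([frags, frags], ignore_index=True)
        p2 = tss_accessibility_profile(doubled, tss)
        assert np.allclose(p1[("preferred", "treatment")],
                           p2[("preferred", "treatment")])

    def test_flat_coverage_gives_unit_ratio(self, rng):
        t = _uniform_fragments(rng, 4000, "treatment")
        c = _uniform_fragments(rng, 4000, "control")
        frags = pd.concat([t, c], ignore_index=True)
        tss = pd.DataFrame(
            {"event_id": ["e"], "chrom": ["chr1"], "tss": [2500],
             "tss_class": ["preferred"]}
        )
        prof = tss_accessibility_profile(frags, tss)
        center = slice(400, 601)
        ratio = (prof[("preferred", "treatment")][center].mean()
                 / prof[("preferred", "control")][center].mean())
        assert ratio == pytest.approx(1.0, abs=0.1)


class TestFootprintAccessibility:
    def _setup(self, rng, depletion_pref=0.0, depletion_nonpref=0.0,
               n_per_class=30):
        frames = []
        footprints = []
        tss_rows = []
        pos = 10_000
        for cls, depletion in (("preferred", depletion_pref),
                               ("nonpreferred", depletion_nonpref)):
            for i in range(n_per_class):
                tss_rows.append({"event_id": f"{cls}{i}", "chrom": "chr1",
                                 "tss": pos, "tss_class": cls})
                footprints.append(
                    FootprintRecord("chr1", pos - 56, pos - 44, "MOT", 1.0, "+")
                )
                for cond in ("treatment", "control"):
                    n = 60
                    start = rng.integers(pos - 400, pos + 400, size=n)
                    keep = np.ones(n, bool)
                    if cond == "treatment" and depletion > 0:
                        near = np.abs(start + 40 - (pos - 50)) <= 120
                        keep &= ~(near & (rng.random(n) < depletion))
                    length = rng.integers(40, 120, size=keep.sum())
                    frames.append(pd.DataFrame(
                        {"chrom": "chr1", "start": start[keep],
                         "end": start[keep] + length, "length": length,
                         "library_id": cond, "condition": cond}
                    ))
                pos += 5_000
        return pd.concat(frames, ignore_index=True), footprints, pd.DataFrame(tss_rows)

    def test_planted_differential_depletion_detected(self, rng):
        frags, fps, tss = self._setup(rng, depletion_pref=0.1,
                                      depletion_nonpref=0.6, n_per_class=40)
        (res,) = footprint_accessibility_test(frags, fps, tss)
        assert res.mean_ratio_preferred > res.mean_ratio_nonpreferred
        assert res.p < 0.01

    def test_no_depletion_not_significant(self, rng):
        frags, fps, tss = self._setup(rng)
        (res,) = footprint_accessibility_test(frags, fps, tss)
        assert res.p > 0.01

    def test_single_footprint_class_skipped(self, rng):
        frags, fps, tss = self._setup(rng, n_per_class=5)
        tss_one = tss[(tss["tss_class"] == "preferred") | (tss.index == 5)]
        fps_kept = [f for f in fps if any(
            abs((f.start + f.end) // 2 - t) <= 500
            for t in tss_one["tss"]
        )]
        results = footprint_accessibility_test(frags, fps_kept, tss_one)
        assert results == []

    def test_t_invariant_under_common_positive_scaling(self, rng):
        # scaling every ratio by a constant (here: quadrupling one library's
        # total) scales means and SDs equally, leaving t unchanged
        frags, fps, tss = self._setup(rng, depletion_pref=0.1,
                                      depletion_nonpref=0.5)
        (res1,) = footprint_accessibility_test(frags, fps, tss)
        far = pd.DataFrame(
            {
                "chrom": "chr9",
                "start": np.arange(3000),
                "end": np.arange(3000) + 80,
                "length": 80,
                "library_id": "control",
                "condition": "control",
            }
        )
        (res2,) = footprint_accessibility_test(
            pd.concat([frags, far], ignore_index=True), fps, tss
        )
        assert res2.t_statistic == pytest.approx(res1.t_statistic, rel=1e-9)

    def test_degenerate_variance_flagged(self):
        frags = pd.DataFrame(
            {"chrom": [], "start": [], "end": [], "length": [],
             "library_id": [], "condition": []}
        )
        fps = [FootprintRecord("chr1", 100 + i * 3000, 112 + i * 3000, "MOT", 1.0, "+")
               for i in range(4)]
        tss = pd.DataFrame(
            {"event_id": [f"e{i}" for i in range(4)],
             "chrom": "chr1",
             "tss": [106 + i * 3000 for i in range(4)],
             "tss_class": ["preferred", "preferred",
                           "nonpreferred", "nonpreferred"]}
        )
        (res,) = footprint_accessibility_test(frags, fps, tss)
        assert res.degenerate
        assert res.p == 1.0


def test_classify_tss_uses_relaxed_threshold(plus_afe):
    calls = pd.DataFrame(
        {
            "event_id": ["afe_plus", "afe_plus"],
            "event_type": ["AFE", "AFE"],
            "q_value": [0.2, 0.2],
            "direction": [1, -1],
        }
    )
    table = classify_tss(calls.iloc[[0]], {"afe_plus": plus_afe})
    pref = table[table["tss_class"] == "preferred"]["tss"].iloc[0]
    assert pref == plus_afe.upstream_tss
    table_down = classify_tss(calls.iloc[[1]], {"afe_plus": plus_afe})
    pref_down = table_down[table_down["tss_class"] == "preferred"]["tss"].iloc[0]
    assert pref_down == plus_afe.downstream_tss
    strict = calls.assign(q_value=0.3)
    assert classify_tss(strict, {"afe_plus": plus_afe}).empty
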