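import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spliceshift.synthetic_cohort import (
    CohortConfig,
    generate_atac,
    generate_counts,
    generate_events,
    generate_factor_expression,
    generate_footprint_landscape,
    generate_qtl_panel,
    motif_ids,
)


class TestConfig:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError, match="pi_pos"):
            CohortConfig(pi_pos=1.5)

    def test_two_controls_required(self):
        with pytest.raises(ValueError, match="n_controls"):
            CohortConfig(n_controls=1)

    def test_unknown_event_type_rejected(self):
        with pytest.raises(ValueError, match="unknown event types"):
            CohortConfig(event_types=("SE", "XX"))


class TestCounts:
    def test_same_seed_gives_identical_tables(self):
        cfg = CohortConfig(event_types=("SE",), n_events_per_type=50, seed=9)
        a = generate_counts(cfg)
        b = generate_counts(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_zero_effect_fraction_plants_no_shifts(self):
        cfg = CohortConfig(event_types=("SE",), n_events_per_type=50,
                           effect_fraction=0.0, seed=2)
        cohort = generate_counts(cfg)
        assert not cohort.truth["is_shift"].any()
        assert (cohort.truth["true_delta"] == 0).all()

    def test_positive_fraction_tracks_pi_pos(self):
        cfg = CohortConfig(event_types=("SE",), n_events_per_type=500,
                           n_cell_types=1, n_treatments=2,
                           effect_fraction=0.3, pi_pos=0.9, seed=5)
        truth = generate_counts(cfg).truth
        shifted = truth[truth["is_shift"]]
        n = len(shifted)
        observed = (shifted["true_delta"] > 0).sum()
        lo, hi = stats.binom.interval(0.99, n, 0.9)
        assert lo <= observed <= hi

    def test_control_replicates_share_condition(self, small_cohort):
        ctrl = small_cohort.counts[small_cohort.counts["role"] == "control"]
        reps = ctrl.groupby(
            ["event_id", "cell_type", "condition", "individual"]
        )["replicate"].nunique()
        assert (reps == small_cohort.config.replicates_per_control).all()

    def test_counts_nonnegative(self, small_cohort):
        assert (small_cohort.counts[["n_inc", "n_exc"]] >= 0).all().all()

    def test_baseline_psi_moments_match_beta(self):
        # marginal condition-level Ψ in controls should match the configured
        # Beta(2,2) baseline: mean 0.5, variance 1/20 (binomial noise adds
        # ~1/(4*depth), negligible at depth 300)
        cfg = CohortConfig(event_types=("SE",), n_events_per_type=5000,
                           n_cell_types=1, n_treatments=1, seed=3)
        cohort = generate_counts(cfg)
        ctrl = cohort.counts[cohort.counts["role"] == "control"]
        pooled = ctrl.groupby("event_id")[["n_inc", "n_exc"]].sum()
        psi_hat = pooled["n_inc"] / (pooled["n_inc"] + pooled["n_exc"])
        assert psi_hat.mean() == pytest.approx(0.5, abs=0.01)
        assert psi_hat.var() == pytest.approx(0.05, abs=0.005)

    def test_every_dataset_carries_its_truth(self, small_cohort):
        envs = {(c, t) for c in small_cohort.config.cell_types
                for t in small_cohort.config.treatments}
        truth_envs = set(map(tuple,
                             small_cohort.truth[["cell_type", "treatment"]]
                             .drop_duplicates().to_numpy()))
        assert truth_envs == envs
        assert set(small_cohort.truth["event_id"]) == set(small_cohort.annotations)


class TestFootprints:
    def _directions(self, cfg, value=None, seed=0):
        annotations = generate_events(cfg)
        afe = sorted(a for a, v in annotations.items() if v.event_type == "AFE")
        rng = np.random.default_rng(seed)
        if value is None:
            dirs = rng.choice([-1, 1], size=len(afe))
        else:
            dirs = np.full(len(afe), value)
        return annotations, pd.Series(dirs, index=afe)

    def test_no_afe_events_gives_empty_set(self):
        cfg = CohortConfig(event_types=("SE",), n_events_per_type=20, seed=1)
        annotations = generate_events(cfg)
        assert generate_footprint_landscape(cfg, annotations, pd.Series(dtype=int)) == []

    def test_full_coupling_forces_sign_agreement(self):
        cfg = CohortConfig(event_types=("AFE",), n_events_per_type=150,
                           footprint_coupling=1.0, seed=11)
        annotations, directions = self._directions(cfg)
        fps = generate_footprint_landscape(cfg, annotations, directions)
        planted = motif_ids(cfg)[0][0]
        agree = 0
        total = 0
        for event_id, direction in directions.items():
            a = annotations[event_id]
            near_up = sum(
                1 for f in fps
                if f.motif_id == planted and f.chrom == a.chrom
                and abs((f.start + f.end) // 2 - a.upstream_tss) <= 1006
            )
            near_dn = sum(
                1 for f in fps
                if f.motif_id == planted and f.chrom == a.chrom
                and abs((f.start + f.end) // 2 - a.downstream_tss) <= 1006
            )
            total += 1
            if np.sign(near_up - near_dn) == direction:
                agree += 1
        assert agree / total >= 0.95

    def test_zero_coupling_leaves_direction_uninformative(self):
        cfg = CohortConfig(event_types=("AFE",), n_events_per_type=300,
                           footprint_coupling=0.0, seed=12)
        annotations, directions = self._directions(cfg)
        fps = generate_footprint_landscape(cfg, annotations, directions)
        planted = motif_ids(cfg)[0][0]
        diffs = []
        for event_id in directions.index:
            a = annotations[event_id]
            up = sum(1 for f in fps if f.motif_id == planted and f.chrom == a.chrom
                     and abs((f.start + f.end) // 2 - a.upstream_tss) <= 1006)
            dn = sum(1 for f in fps if f.motif_id == planted and f.chrom == a.chrom
                     and abs((f.start + f.end) // 2 - a.downstream_tss) <= 1006)
            diffs.append(up - dn)
        diffs = np.asarray(diffs)
        informative = diffs != 0
        agreement = np.mean(
            np.sign(diffs[informative]) == directions.to_numpy()[informative]
        )
        # permutation-style check: agreement indistinguishable from coin flip
        lo, hi = stats.binom.interval(0.999, informative.sum(), 0.5)
        assert lo <= (np.sign(diffs[informative])
                      == directions.to_numpy()[informative]).sum() <= hi


class TestAtac:
    def test_fragments_well_formed_and_deterministic(self):
        cfg = CohortConfig(event_types=("AFE",), n_events_per_type=20,
                           atac_fragments_per_tss=50, seed=4)
        annotations = generate_events(cfg)
        afe = sorted(annotations)
        directions = pd.Series(1, index=afe)
        frags1 = generate_atac(cfg, annotations, directions)
        frags2 = generate_atac(cfg, annotations, directions)
        pd.testing.assert_frame_equal(frags1, frags2)
        assert (frags1["start"] < frags1["end"]).all()
        assert frags1["length"].between(39, 250).all()

    def test_zero_depletion_balances_conditions(self):
        cfg = CohortConfig(event_types=("AFE",), n_events_per_type=60,
                           atac_depletion_preferred=0.0,
                           atac_depletion_nonpreferred=0.0,
                           atac_fragments_per_tss=200, seed=6)
        annotations = generate_events(cfg)
        directions = pd.Series(1, index=sorted(annotations))
        frags = generate_atac(cfg, annotations, directions)
        by_cond = frags.groupby("condition").size()
        ratio = by_cond["treatment"] / by_cond["control"]
        assert ratio == pytest.approx(1.0, abs=0.05)


class TestQtlPanel:
    def test_dosages_and_missingness(self):
        cfg = CohortConfig(event_types=("AFE",), n_events_per_type=30,
                           qtl_n_individuals=120, seed=8)
        panel = generate_qtl_panel(cfg, generate_events(cfg))
        assert set(np.unique(panel.genotypes.to_numpy())) <= {0, 1, 2}
        observed = panel.psi.notna().to_numpy().mean()
        assert observed == pytest.approx(cfg.qtl_obs_rate, abs=0.05)
        assert panel.psi.to_numpy()[panel.psi.notna().to_numpy()].min() >= 0
        assert panel.psi.to_numpy()[panel.psi.notna().to_numpy()].max() <= 1

    def test_affecting_snps_enriched_for_effects(self):
        cfg = CohortConfig(event_types=("AFE",), n_events_per_type=200,
                           qtl_n_individuals=50, seed=9)
        panel = generate_qtl_panel(cfg, generate_events(cfg))
        merged = panel.snps.merge(panel.truth, on="snp_id")
        rate = merged.groupby("binding_effect")["true_beta"].apply(
            lambda b: (b != 0).mean()
        )
        assert rate["affecting"] > rate["neutral"]


def test_factor_expression_couples_planted_factors(small_cohort):
    expr, truth = generate_factor_expression(small_cohort.config,
                                             small_cohort.truth)
    planted = truth[truth["planted"] & (truth["target_event_type"] == "AFE")]
    assert not planted.empty
    n_env = (small_cohort.config.n_cell_types
             * small_cohort.config.n_treatments)
    assert len(expr) == (len(truth)) * n_env
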