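"""Synthetic study generator with planted truth for every downstream stage.

The generator emulates a perturbation-response study design: a grid of cell
types × treatments (an *environment* is one cell type under one treatment),
three unrelated individuals per environment, and >= 2 control compounds each
applied in three technical replicates.  Inclusion read counts follow a
beta-binomial: each *condition* (event × cell type × individual × compound)
draws a latent Ψ around its mean with intra-class correlation ``rho``, and
its libraries draw binomial reads from that latent Ψ.  Technical control
replicates are library splits of one condition and therefore share the
latent Ψ; ``read_depth`` is the expected isoform-informative read count per
event per condition, so pooled control replicates match a treatment library
in depth and control-vs-control comparisons are exchangeable with null
treatment-vs-control comparisons — the property empirical-null calibration
relies on.

Every generated dataset is accompanied by its planted truth; the generator
never emits unrecorded signal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import EVENT_TYPES, EventAnnotation, FootprintRecord

_CHROMS = ("chr1", "chr2", "chr3", "chr4")
_SLOT = 50_000
_MOTIF_WIDTH = 12


def rng_for(seed: int, *key) -> np.random.Generator:
    """Split-stream RNG keyed by (module, entity) labels under one global seed."""
    words = [int(seed) & 0xFFFFFFFF]
    words += [zlib.crc32(str(k).encode()) for k in key]
    return np.random.default_rng(np.random.SeedSequence(words))


@dataclass
class CohortConfig:
    """Declarative description of one synthetic study.

    Fractions must lie in [0, 1]; ``n_controls >= 2`` so a control-vs-control
    (CO2 vs CO1) empirical null exists.  Identical seeds give byte-identical
    outputs.
    """

    n_cell_types: int = 2
    n_treatments: int = 5
    n_controls: int = 2
    n_individuals: int = 3
    replicates_per_control: int = 3
    event_types: tuple[str, ...] = EVENT_TYPES
    n_events_per_type: int = 400
    read_depth: float = 300.0          # mean informative reads per event per condition
    overdispersion: float = 0.01       # beta-binomial intra-class correlation rho
    baseline_beta: tuple[float, float] = (2.0, 2.0)
    # effect model
    effect_fraction: float = 0.3       # fraction of event × environment cells shifted
    effect_min: float = 0.15
    effect_max: float = 0.45
    pi_pos: float = 0.5                # per-environment probability of a positive shift
    # trans-factor model
    n_splicing_factors: int = 40
    n_transcription_factors: int = 60
    n_planted_factors: int = 5
    factor_coupling: float = 0.8
    factor_noise_sd: float = 0.15
    # footprint model
    n_motifs: int = 20
    n_planted_motifs: int = 3
    footprint_density: float = 1.5     # mean footprints per motif per TSS window
    footprint_coupling: float = 0.9
    # ATAC model
    atac_fragments_per_tss: int = 300
    atac_depletion_preferred: float = 0.15
    atac_depletion_nonpreferred: float = 0.40
    # QTL model
    qtl_n_individuals: int = 373
    qtl_snps_per_event: int = 2
    qtl_maf_range: tuple[float, float] = (0.05, 0.5)
    qtl_frac_affecting: float = 0.3
    qtl_effect_prob_affecting: float = 0.6
    qtl_effect_prob_neutral: float = 0.15
    qtl_beta_scale: float = 0.8
    qtl_obs_rate: float = 0.85
    qtl_n_labs: int = 2
    qtl_n_populations: int = 3
    qtl_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("effect_fraction", "pi_pos", "overdispersion",
                     "footprint_coupling", "factor_coupling", "qtl_obs_rate",
                     "atac_depletion_preferred", "atac_depletion_nonpreferred",
                     "qtl_frac_affecting", "qtl_effect_prob_affecting",
                     "qtl_effect_prob_neutral"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.n_controls < 2:
            raise ValueError("n_controls must be >= 2 (control-vs-control null)")
        unknown = set(self.event_types) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types: {sorted(unknown)}")

    @property
    def cell_types(self) -> list[str]:
        return [f"CellType{i + 1}" for i in range(self.n_cell_types)]

    @property
    def treatments(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_treatments)]

    @property
    def controls(self) -> list[str]:
        return [f"CO{i + 1}" for i in range(self.n_controls)]

    def control_of(self, treatment: str) -> str:
        """Round-robin assignment of treatments to control compounds."""
        i = self.treatments.index(treatment)
        return self.controls[i % self.n_controls]


@dataclass
class SyntheticCohort:
    """Counts plus planted truth for one simulated study."""

    config: CohortConfig
    annotations: dict[str, EventAnnotation]
    counts: pd.DataFrame
    truth: pd.DataFrame  # event × environment planted effects (oriented scale)

    def truth_direction(self, cell_type: str, treatment: str) -> pd.Series:
        """Planted AFE shift direction (−1/0/+1) per event for one environment."""
        t = self.truth
        sub = t[(t["cell_type"] == cell_type) & (t["treatment"] == treatment)]
        return pd.Series(
            np.sign(sub["true_delta"].to_numpy()).astype(int),
            index=sub["event_id"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# event annotations
# ---------------------------------------------------------------------------

def _make_event(event_type: str, index: int, strand: str,
                iso1_first: bool) -> EventAnnotation:
    chrom = _CHROMS[index % len(_CHROMS)]
    base = 10_000 + (index // len(_CHROMS)) * _SLOT
    eid = f"{event_type}_{index:05d}"

    def ann(iso1, iso2):
        return EventAnnotation(eid, f"gene_{eid}", event_type, chrom, strand,
                               tuple(iso1), tuple(iso2))

    up = (base, base + 150)
    dn = (base + 1270, base + 1420)
    if event_type == "SE":
        mid = (base + 650, base + 770)
        return ann([up, mid, dn], [up, dn])
    if event_type == "RI":
        return ann([(base, base + 1000)], [(base, base + 300), (base + 700, base + 1000)])
    if event_type == "A3SS":
        return ann([up, (base + 600, base + 900)], [up, (base + 700, base + 900)])
    if event_type == "A5SS":
        return ann([(base, base + 250), dn], [(base, base + 150), dn])
    if event_type == "MXE":
        a = (base + 500, base + 620)
        b = (base + 800, base + 920)
        return ann([up, a, dn], [up, b, dn])
    if event_type == "AFE":
        # alternative first exons sit at the transcription-start side:
        # low coordinates on '+', high coordinates on '-'
        if strand == "+":
            e1, e2 = (base, base + 200), (base + 3000, base + 3200)
            shared = (base + 8000, base + 8200)
        else:
            e1, e2 = (base + 8000, base + 8200), (base + 5000, base + 5200)
            shared = (base, base + 200)
        first = [e1, shared] if iso1_first else [e2, shared]
        second = [e2, shared] if iso1_first else [e1, shared]
        return ann(sorted(first), sorted(second))
    if event_type == "ALE":
        # alternative last exons sit at the transcription-end side
        if strand == "+":
            shared = (base, base + 200)
            e1, e2 = (base + 5000, base + 5200), (base + 8000, base + 8200)
        else:
            shared = (base + 8000, base + 8200)
            e1, e2 = (base, base + 200), (base + 3000, base + 3200)
        first = [shared, e1] if iso1_first else [shared, e2]
        second = [shared, e2] if iso1_first else [shared, e1]
        return ann(sorted(first), sorted(second))
    if event_type == "TandemUTR":
        return ann([(base, base + 2000)], [(base, base + 1000)])
    raise ValueError(event_type)


def generate_events(config: CohortConfig) -> dict[str, EventAnnotation]:
    """Synthetic event annotations laid out on a small artificial genome."""
    rng = rng_for(config.seed, "events")
    annotations: dict[str, EventAnnotation] = {}
    for event_type in config.event_types:
        strands = rng.choice(["+", "-"], size=config.n_events_per_type)
        iso1_first = rng.random(config.n_events_per_type) < 0.5
        for i in range(config.n_events_per_type):
            a = _make_event(event_type, i, strands[i], bool(iso1_first[i]))
            annotations[a.event_id] = a
    return annotations


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _beta_jitter(rng: np.random.Generator, mu: np.ndarray, rho: float) -> np.ndarray:
    """Latent condition Ψ ~ Beta with mean mu and intra-class correlation rho."""
    mu = np.clip(mu, 1e-3, 1.0 - 1e-3)
    if rho <= 0:
        return mu
    c = (1.0 - rho) / rho
    return rng.beta(mu * c, (1.0 - mu) * c)


def _orientation_signs(annotations: dict[str, EventAnnotation],
                       event_ids: np.ndarray) -> np.ndarray:
    from .event_quant import orientation_sign

    return np.array([orientation_sign(annotations[e]) for e in event_ids])


def generate_counts(config: CohortConfig) -> SyntheticCohort:
    """Generate the full count table and its planted truth.

    Planted effects live on the *oriented* ΔΨ scale; they are converted to the
    raw isoform-1 scale through each event's orientation sign before counts
    are drawn, so the quantification stage must re-orient to recover them.
    Effects are clipped so condition means stay inside (0.02, 0.98); the
    *realized* post-clip effect is what the truth table records.
    """
    annotations = generate_events(config)
    cells = config.cell_types
    treatments = config.treatments
    controls = config.controls
    individuals = [f"Ind{i + 1}" for i in range(config.n_individuals)]
    reps = config.replicates_per_control
    counts_parts: list[pd.DataFrame] = []
    truth_parts: list[pd.DataFrame] = []

    for event_type in config.event_types:
        rng = rng_for(config.seed, "counts", event_type)
        ids = np.array(sorted(a for a, v in annotations.items()
                              if v.event_type == event_type))
        m = len(ids)
        flip = _orientation_signs(annotations, ids)
        baseline = rng.beta(*config.baseline_beta, size=m)
        baseline = np.clip(baseline, 0.02, 0.98)

        n_env = len(cells) * len(treatments)
        shifted = rng.random((m, n_env)) < config.effect_fraction
        magnitude = rng.uniform(config.effect_min, config.effect_max, size=(m, n_env))
        sign = np.where(rng.random((m, n_env)) < config.pi_pos, 1.0, -1.0)
        oriented = np.where(shifted, sign * magnitude, 0.0)
        raw_delta = oriented * flip[:, None]
        mu_treat = np.clip(baseline[:, None] + raw_delta, 0.02, 0.98)
        realized_oriented = (mu_treat - baseline[:, None]) * flip[:, None]

        env_index = pd.MultiIndex.from_product([cells, treatments],
                                               names=["cell_type", "treatment"])
        truth_parts.append(
            pd.DataFrame(
                {
                    "event_id": np.repeat(ids, n_env),
                    "event_type": event_type,
                    "cell_type": np.tile(env_index.get_level_values(0), m),
                    "treatment": np.tile(env_index.get_level_values(1), m),
                    "is_shift": shifted.ravel(),
                    "true_delta": realized_oriented.ravel(),
                }
            )
        )

        # treatment libraries: one per event × cell × treatment × individual
        n_ind = len(individuals)
        mu_t = np.repeat(mu_treat[:, :, None], n_ind, axis=2)  # (m, n_env, ind)
        psi_t = _beta_jitter(rng, mu_t, config.overdispersion)
        depth_t = rng.poisson(config.read_depth, size=psi_t.shape)
        inc_t = rng.binomial(depth_t, psi_t)
        env_cell = np.tile(env_index.get_level_values(0), m)
        env_treat = np.tile(env_index.get_level_values(1), m)
        counts_parts.append(
            pd.DataFrame(
                {
                    "event_id": np.repeat(ids, n_env * n_ind),
                    "event_type": event_type,
                    "cell_type": np.repeat(env_cell, n_ind),
                    "individual": np.tile(individuals, m * n_env),
                    "condition": np.repeat(env_treat, n_ind),
                    "role": "treatment",
                    "control_id": np.repeat(
                        [config.control_of(t) for t in env_treat], n_ind
                    ),
                    "replicate": 0,
                    "n_inc": inc_t.ravel(),
                    "n_exc": (depth_t - inc_t).ravel(),
                }
            )
        )

        # control libraries: replicates share the condition's latent psi
        n_ctrl = len(controls)
        mu_c = np.broadcast_to(
            baseline[:, None, None, None], (m, len(cells), n_ctrl, n_ind)
        )
        psi_c = _beta_jitter(rng, np.ascontiguousarray(mu_c), config.overdispersion)
        depth_c = rng.poisson(config.read_depth / reps,
                              size=psi_c.shape + (reps,))
        inc_c = rng.binomial(depth_c, psi_c[..., None])
        idx = pd.MultiIndex.from_product(
            [ids, cells, controls, individuals, range(reps)],
            names=["event_id", "cell_type", "condition", "individual", "replicate"],
        )
        df_c = idx.to_frame(index=False)
        df_c["event_type"] = event_type
        df_c["role"] = "control"
        df_c["control_id"] = df_c["condition"]
        df_c["n_inc"] = inc_c.ravel()
        df_c["n_exc"] = (depth_c - inc_c).ravel()
        counts_parts.append(df_c[counts_parts[-1].columns])

    counts = pd.concat(counts_parts, ignore_index=True)
    truth = pd.concat(truth_parts, ignore_index=True)
    return SyntheticCohort(config, annotations, counts, truth)


# ---------------------------------------------------------------------------
# trans-factor expression
# ---------------------------------------------------------------------------

def generate_factor_expression(config: CohortConfig,
                               truth: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-factor, per-environment expression log-fold changes.

    Planted splicing factors track the RI percent-positive-events (PPE)
    across environments; planted transcription factors track the AFE PPE.
    Decoy factors are pure noise.  Returns (expression table, factor truth).
    """
    rng = rng_for(config.seed, "factors")
    ppe = (
        truth[truth["is_shift"]]
        .assign(positive=lambda d: d["true_delta"] > 0)
        .groupby(["event_type", "cell_type", "treatment"])["positive"]
        .mean()
    )
    env_keys = [(c, t) for c in config.cell_types for t in config.treatments]

    rows = []
    truth_rows = []
    specs = [("SF", config.n_splicing_factors, "RI"),
             ("TF", config.n_transcription_factors, "AFE")]
    for cls, n_factors, target_type in specs:
        for j in range(n_factors):
            factor = f"{cls}_{j + 1:03d}"
            planted = j < config.n_planted_factors and target_type in config.event_types
            coupling_sign = 1 if rng.random() < 0.5 else -1
            truth_rows.append(
                {
                    "factor_id": factor,
                    "factor_class": cls,
                    "planted": planted,
                    "target_event_type": target_type if planted else "",
                    "coupling_sign": coupling_sign if planted else 0,
                }
            )
            noise = rng.normal(0.0, config.factor_noise_sd, size=len(env_keys))
            for k, (cell, treat) in enumerate(env_keys):
                lfc = noise[k]
                if planted:
                    p = ppe.get((target_type, cell, treat), np.nan)
                    if not np.isnan(p):
                        lfc += (
                            coupling_sign * 2.0 * config.factor_coupling * (p - 0.5)
                        )
                rows.append(
                    {
                        "factor_id": factor,
                        "factor_class": cls,
                        "cell_type": cell,
                        "treatment": treat,
                        "log_fold_change": lfc,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def motif_ids(config: CohortConfig) -> tuple[list[str], list[str]]:
    """(planted, decoy) motif identifier lists."""
    all_ids = [f"M{i + 1:03d}" for i in range(config.n_motifs)]
    return all_ids[: config.n_planted_motifs], all_ids[config.n_planted_motifs:]


def generate_footprint_landscape(
    config: CohortConfig,
    annotations: dict[str, EventAnnotation],
    directions: pd.Series,
) -> list[FootprintRecord]:
    """Footprints around AFE TSS pairs with a planted direction coupling.

    ``directions`` maps AFE event_id -> −1/0/+1 true shift direction.  For a
    planted motif, with probability ``footprint_coupling`` the footprint count
    difference (upstream-TSS window minus downstream-TSS window) is forced to
    the sign of the event's direction; decoy motifs are placed independently.
    """
    rng = rng_for(config.seed, "footprints")
    planted, decoys = motif_ids(config)
    afe = [a for a in annotations.values() if a.event_type == "AFE"]
    records: list[FootprintRecord] = []
    for a in sorted(afe, key=lambda x: x.event_id):
        direction = int(directions.get(a.event_id, 0))
        planted_centers: list[int] = []
        for motif in planted + decoys:
            n_up = rng.poisson(config.footprint_density)
            n_dn = rng.poisson(config.footprint_density)
            if (motif in planted and direction != 0
                    and rng.random() < config.footprint_coupling):
                if direction > 0 and n_up <= n_dn:
                    n_up = n_dn + 1 + rng.poisson(0.5)
                elif direction < 0 and n_dn <= n_up:
                    n_dn = n_up + 1 + rng.poisson(0.5)
            for tss, n in ((a.upstream_tss, n_up), (a.downstream_tss, n_dn)):
                for _ in range(n):
                    # decoys avoid planted footprints (motifs compete for
                    # the same DNA), so planted accessibility perturbations
                    # stay local to the planted motif's own windows
                    start = None
                    for _attempt in range(12):
                        cand = max(0, tss + int(
                            rng.integers(-1000, 1001 - _MOTIF_WIDTH)
                        ))
                        center = cand + _MOTIF_WIDTH // 2
                        if motif in planted or all(
                            abs(center - pc) > 220 for pc in planted_centers
                        ):
                            start = cand
                            break
                    if start is None:
                        continue
                    if motif in planted:
                        planted_centers.append(start + _MOTIF_WIDTH // 2)
                    records.append(
                        FootprintRecord(
                            chrom=a.chrom,
                            start=start,
                            end=start + _MOTIF_WIDTH,
                            motif_id=motif,
                            posterior=float(rng.uniform(0.991, 0.9999)),
                            strand="+" if rng.random() < 0.5 else "-",
                        )
                    )
    return records


# ---------------------------------------------------------------------------
# ATAC fragments
# ---------------------------------------------------------------------------

_LENGTH_BINS = ((39, 99), (100, 139), (140, 179), (180, 250))
_LENGTH_PROBS = (0.45, 0.25, 0.20, 0.10)


def _fragment_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    bins = rng.choice(len(_LENGTH_BINS), size=n, p=_LENGTH_PROBS)
    lows = np.array([b[0] for b in _LENGTH_BINS])[bins]
    highs = np.array([b[1] for b in _LENGTH_BINS])[bins]
    return rng.integers(lows, highs + 1)


def generate_atac(
    config: CohortConfig,
    annotations: dict[str, EventAnnotation],
    directions: pd.Series,
    footprints: list[FootprintRecord] | None = None,
    depleted_motif: str | None = None,
) -> pd.DataFrame:
    """Paired treatment/control ATAC fragment tables around AFE TSS pairs.

    Fragment lengths span the [39, 250] mixture; in the treatment library,
    fragments whose midpoint falls within ±100 bp of a ``depleted_motif``
    footprint near a TSS are thinned by the class-specific depletion
    (``atac_depletion_preferred`` at the shift-preferred TSS,
    ``atac_depletion_nonpreferred`` at the other TSS).
    """
    rng = rng_for(config.seed, "atac")
    if depleted_motif is None:
        depleted_motif = motif_ids(config)[0][0]
    fp_by_chrom: dict[str, np.ndarray] = {}
    if footprints:
        sel = [f for f in footprints if f.motif_id == depleted_motif]
        for f in sel:
            fp_by_chrom.setdefault(f.chrom, []).append((f.start + f.end) // 2)
        fp_by_chrom = {c: np.sort(np.array(v)) for c, v in fp_by_chrom.items()}

    afe = sorted(
        (a for a in annotations.values() if a.event_type == "AFE"),
        key=lambda x: x.event_id,
    )
    rows = []
    for a in afe:
        direction = int(directions.get(a.event_id, 0))
        if direction == 0:
            preferred = None
        else:
            preferred = a.upstream_tss if direction > 0 else a.downstream_tss
        for tss in (a.upstream_tss, a.downstream_tss):
            if preferred is None:
                depletion = 0.0
            elif tss == preferred:
                depletion = config.atac_depletion_preferred
            else:
                depletion = config.atac_depletion_nonpreferred
            centers_near = fp_by_chrom.get(a.chrom, np.empty(0, dtype=int))
            windows = centers_near[np.abs(centers_near - tss) <= 500]
            for condition in ("treatment", "control"):
                n = rng.poisson(config.atac_fragments_per_tss)
                mid = rng.integers(tss - 600, tss + 601, size=n)
                length = _fragment_lengths(rng, n)
                keep = np.ones(n, dtype=bool)
                if condition == "treatment" and depletion > 0 and len(windows):
                    near = np.min(
                        np.abs(mid[:, None] - windows[None, :]), axis=1
                    ) <= 100
                    keep &= ~(near & (rng.random(n) < depletion))
                start = mid[keep] - length[keep] // 2
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": a.chrom,
                            "start": start,
                            "end": start + length[keep],
                            "length": length[keep],
                            "library_id": f"atac_{condition}",
                            "condition": condition,
                        }
                    )
                )
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "length", "library_id", "condition"]
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# QTL panel
# ---------------------------------------------------------------------------

@dataclass
class QtlPanel:
    genotypes: pd.DataFrame   # SNPs × individuals dosages in {0,1,2}
    psi: pd.DataFrame         # events × individuals Ψ in [0,1] with NaN missingness
    latent: pd.DataFrame      # events × individuals latent linear phenotype
    snps: pd.DataFrame        # snp_id, chrom, pos, event_id, binding_effect, maf
    covariates: pd.DataFrame  # individual, lab, population
    truth: pd.DataFrame       # snp_id, true_beta


def generate_qtl_panel(config: CohortConfig,
                       annotations: dict[str, EventAnnotation]) -> QtlPanel:
    """Genotypes and per-individual AFE Ψ with planted cis effects.

    Ψ = logistic(baseline + Σ β·(dosage − 2·MAF) + lab + population + noise);
    binding-affecting SNPs carry nonzero β with higher probability than
    neutral ones (``qtl_effect_prob_affecting`` vs ``qtl_effect_prob_neutral``).
    The pre-logistic linear phenotype is returned as ``latent`` so effect
    recovery can be assessed on the scale the effects were planted on.
    """
    rng = rng_for(config.seed, "qtl")
    n = config.qtl_n_individuals
    individuals = [f"G{i + 1:04d}" for i in range(n)]
    lab = rng.integers(0, config.qtl_n_labs, size=n)
    pop = rng.integers(0, config.qtl_n_populations, size=n)
    lab_eff = rng.normal(0.0, 0.3, size=config.qtl_n_labs)
    pop_eff = rng.normal(0.0, 0.3, size=config.qtl_n_populations)
    covariates = pd.DataFrame(
        {
            "individual": individuals,
            "lab": [f"lab{v + 1}" for v in lab],
            "population": [f"pop{v + 1}" for v in pop],
        }
    )

    afe = sorted(
        (a for a in annotations.values() if a.event_type == "AFE"),
        key=lambda x: x.event_id,
    )
    snp_rows, truth_rows, geno_rows, geno_index = [], [], [], []
    psi_rows, latent_rows, event_index = [], [], []
    for a in afe:
        base = rng.normal(0.0, 0.8)
        linear = np.full(n, base) + lab_eff[lab] + pop_eff[pop]
        for j in range(config.qtl_snps_per_event):
            snp_id = f"rs_{a.event_id}_{j + 1}"
            tss = a.upstream_tss if j % 2 == 0 else a.downstream_tss
            pos = int(tss + rng.integers(-9_500, 9_501))
            maf = rng.uniform(*config.qtl_maf_range)
            dosage = rng.binomial(2, maf, size=n)
            affecting = rng.random() < config.qtl_frac_affecting
            p_eff = (config.qtl_effect_prob_affecting if affecting
                     else config.qtl_effect_prob_neutral)
            beta = 0.0
            if rng.random() < p_eff:
                beta = float(rng.choice([-1.0, 1.0]) * config.qtl_beta_scale)
            linear = linear + beta * (dosage - 2.0 * maf)
            snp_rows.append(
                {
                    "snp_id": snp_id,
                    "chrom": a.chrom,
                    "pos": pos,
                    "event_id": a.event_id,
                    "binding_effect": "affecting" if affecting else "neutral",
                    "maf": maf,
                }
            )
            truth_rows.append({"snp_id": snp_id, "true_beta": beta})
            geno_rows.append(dosage)
            geno_index.append(snp_id)
        linear = linear + rng.normal(0.0, config.qtl_noise_sd, size=n)
        observed = rng.random(n) < config.qtl_obs_rate
        psi = 1.0 / (1.0 + np.exp(-linear))
        psi = np.where(observed, psi, np.nan)
        latent = np.where(observed, linear, np.nan)
        psi_rows.append(psi)
        latent_rows.append(latent)
        event_index.append(a.event_id)

    return QtlPanel(
        genotypes=pd.DataFrame(geno_rows, index=geno_index, columns=individuals),
        psi=pd.DataFrame(psi_rows, index=event_index, columns=individuals),
        latent=pd.DataFrame(latent_rows, index=event_index, columns=individuals),
        snps=pd.DataFrame(snp_rows),
        covariates=covariates,
        truth=pd.DataFrame(truth_rows),
    )
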