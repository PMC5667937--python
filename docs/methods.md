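# Methods

`spliceshift` implements an end-to-end analysis of environment-induced
changes in RNA processing: per-event quantification of isoform usage,
calibrated detection of shifts, environment-level directional statistics,
trans-factor association, sequence-feature prediction of shift direction,
and two mechanistic validation arms (ATAC-seq accessibility and QTL
mapping).  A synthetic-cohort generator with fully recorded planted truth
exercises every stage.  This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic tests do and do not
establish about real data.

## Event quantification

Eight event types are handled: skipped exons (SE), retained introns (RI),
alternative 3'/5' splice sites (A3SS/A5SS), mutually exclusive exons (MXE),
alternative first/last exons (AFE/ALE), and tandem 3' UTRs (TandemUTR).
Quantification is a conjugate beta-binomial stand-in for a full
isoform-assignment sampler: given `n_inc` reads unique to the inclusion
isoform and `n_exc` unique to the exclusion isoform, the Ψ (percent spliced
in) posterior is Beta(a + n_inc, b + n_exc) under a Beta(a, b) prior
(uniform Beta(1,1) by default; the choice is configurable and matters little
at the read depths where the coverage filters pass).  ΔΨ is the difference
of posterior means between treatment and control.

The per-comparison Bayes factor BF₁₀ contrasts independent treatment and
control Ψ values against a single shared Ψ.  With conjugate priors the
marginal likelihoods are Beta functions and the binomial coefficients
cancel:

    BF₁₀ = B(a+k_t, b+n_t−k_t) · B(a+k_c, b+n_c−k_c) / B(a,b)
           ─────────────────────────────────────────────────
               B(a+k_t+k_c, b+n_t+n_c−k_t−k_c) · B(a,b)

computed in log space (`scipy.special.betaln`); the test suite verifies the
closed form against numeric double integration of the marginals to 1e-6
relative error.  This BF's absolute scale is not meant to match any
particular sampler's — downstream calling calibrates Bayes factors against
their own empirical null, so only within-pipeline ranking matters.

**Coverage filters.** A comparison is evaluated only when both samples have
≥ 2 reads unique to each isoform and ≥ 10 isoform-unique reads total; for
TandemUTR (whose short isoform has no unique region) the rule is ≥ 5 reads
specific to the long isoform and ≥ 10 informative reads.  Filters are
applied per individual comparison; the ≥ 2-of-3-individuals rule is applied
downstream at combination time.

**Orientation.** Positive oriented ΔΨ means: more exon inclusion (SE), more
intron retention (RI), longer tandem UTR, more upstream AFE, more
downstream ALE — all defined on the transcribed strand.  SE/RI/TandemUTR
pass through; AFE/ALE flip sign when the annotation's isoform 1 is not the
upstream-TSS (resp. downstream-end) isoform.  A3SS/A5SS/MXE carry no global
direction and are flagged non-directional.  Internally all coordinates are
0-based half-open; GFF conversion happens only at I/O.

## Shift calling

For each event type, Bayes factors from control-vs-control comparisons
(CO2 vs CO1, same individual and batch, same filters) form an empirical
null.  An observed BF maps to an add-one empirical p-value
p = (1 + #{null ≥ BF}) / (1 + n), ties counted as ≥; the add-one rule keeps
p > 0 so the normal quantile is finite.  Each comparison becomes a signed
Z = sign(ΔΨ)·|Φ⁻¹(p/2)|; Z-scores are combined across the 2–3 individuals
measured for an event in an environment by Stouffer's method ΣZ/√k.
Two-sided p-values from combined Z are Benjamini–Hochberg corrected per
event type across all environments jointly (the pooling choice is
configurable), and events with q < 0.15 are called significant, with
direction carried by the sign of the combined Z.

## Environment-level statistics

Per environment and directional event type: PPE (percent positive events) =
positive significant shifts / significant shifts; an exact two-sided
binomial test of the positive:negative split against 50:50 at p < 0.05
labels environments positive- or negative-enriched (environments are
reported when they reach 10 significant events); and a two-sample
Kolmogorov–Smirnov test compares the full ΔΨ distribution (all shifts, not
only significant ones) against the control-vs-control ΔΨ distribution.

Event-type enrichment per treatment is a logistic model
logit(p_l) ~ T_l × E_l + C_l over all tested events (significant = response;
treatment, event type, cell type categorical; first levels as baseline);
treatment-by-type interactions test enrichment.  Per-treatment proportions
among significant events are the mean fitted cell probabilities reweighted
by cell sizes and normalized within treatment — the normalization arithmetic
is a declared design choice.  Complete separation triggers a
ridge-stabilized IRLS fallback (unpenalized intercept, warning emitted).

## Trans-factor association

Per factor (splicing factor or transcription factor), Spearman correlation
of its expression log-fold change with one event type's PPE across
environments; BH within the factor family of that event type; a minimum of
10 environments guards rank-test degeneracy.  A second analysis correlates
per-gene log-fold change with the gene's mean ΔΨ within treatment × event
type groups holding ≥ 30 assessable shifts.  Differential-expression
estimation itself is out of scope: log-fold changes are inputs.

## Direction prediction

For significant SE/RI shifts, features are per-motif indicators over five
regions on the transcribed strand (SE: upstream intron, the exon, downstream
intron, ±100 bp of the exon's 3' splice site; RI: upstream exon, intron,
downstream exon, ±100 bp of the intron's 5' splice site), set by any-overlap
with same-strand motif hits, so a hit straddling a boundary marks both
windows.  For significant AFE shifts, features are per-motif footprint-count
differences between closed ±1000 bp windows around the upstream and
downstream TSS (overlapping windows double-count by design).

The classifier is an elastic-net logistic model (mixing α = 0.5 by default)
over a 40-point geometric penalty path from the smallest all-zero penalty
down three decades.  Ten stratified, seeded CV folds (features standardized
on each training split) yield per-λ CV AUC; λ.1se is the largest penalty
whose mean CV AUC is within one fold-standard-error of the best, and the
reported AUC and refit coefficients are taken there.  Environments with
fewer than 100 significant shifts are refused.  Note that the AUC at the
selected penalty inherits a small optimistic selection bias (maximum over a
noisy path); under permuted labels it is chance-level in distribution but
individual runs can land a few hundredths above 0.5 — the reference R
implementation of the same procedure shows the same spread.

## ATAC-seq validation

Tn5 insertion sites of a fragment [start, end) are start+4 and end−1−4
(each mate's 5' end shifted 4 bp in its 5'→3' direction); fragments shorter
than 9 bp are skipped with a count.  Fragment lengths partition into bins
[39–99], [100–139], [140–179], [180–250] for global work; TSS profiles use
open-chromatin lengths 30–140 bp.  For AFE events shifted at a relaxed
q < 0.25, the preferred TSS is the one usage shifts toward; per-bp
fragment-overlap profiles within ±500 bp of each TSS class are normalized
by library totals (doubling counts and totals leaves profiles unchanged).
Per motif, footprints within 500 bp of a classified TSS contribute a
treatment/control normalized-count ratio over ±100 bp windows (pseudocount
1 in both conditions); preferred-class ratios are compared with
non-preferred by a two-tailed t-test (Welch by default; pooled-variance
Student via flag), BH across motifs at 5%.  Fragment–window overlap counts
any overlap (midpoint counting available).

## AFE QTL mapping

Per-individual AFE Ψ matrices keep events assessable in ≥ 200 individuals,
excluding sex chromosomes.  Each event is residualized on lab and
population indicators, then on the first five principal components of the
covariate-residualized, mean-imputed Ψ matrix (imputation is used only for
PC extraction, never for association), and finally rank-inverse-normal
transformed with offset (rank − 0.5)/n, so each event's phenotype vector is
exactly the Φ⁻¹ order statistics.  The cis scan regresses normalized Ψ on
dosage for footprint SNPs within 10 kb of either TSS (minor-allele count
≥ 10), by ordinary least squares.  Binding-effect enrichment is a Fisher
exact test on {QTL p < 0.05 vs not} × {binding-affecting vs not} (the QTL
significance rule is configurable to BH), with per-class sorted p-values
exported for QQ plots.

## Synthetic cohort

The generator emulates the study design: cell types × treatments (an
*environment* is one cell type under one treatment), three individuals, and
≥ 2 control compounds each applied in three technical replicates whose reads
are pooled before analysis.  Baseline Ψ per event is Beta(2, 2).  Per event
× environment, a shift is planted with probability 0.3 (default), magnitude
uniform on [0.15, 0.45] on the oriented scale, and sign positive with
per-environment probability π_pos; effects are converted through each
event's orientation sign before counts are drawn, and the realized
(post-clipping) effect is what the truth table records.

Counts are beta-binomial with intra-class correlation ρ = 0.01 attached to
the *condition* (event × cell type × individual × compound): technical
replicates are modeled as library splits of one treated RNA pool and share
the condition's latent Ψ, while biological/batch variation enters between
conditions.  `read_depth` (default 300) is the expected informative count
per event per condition, split across control replicates, so pooled
controls match treatment libraries in depth and control-vs-control
comparisons are exchangeable with null treatment-vs-control comparisons —
the property on which empirical-null calibration relies, and one the
calibration tests verify rather than assume.

The footprint generator plants, for a configurable subset of motifs, a
monotone coupling between the upstream-minus-downstream footprint count
difference and the event's true AFE direction (coupling strength = the
probability the sign is forced); decoy motifs are placed independently of
direction, with a 220-bp steric exclusion around planted footprints
(motifs compete for the same DNA) so that planted accessibility
perturbations stay local to the planted motif's windows.  The ATAC
generator draws fragment lengths from a mixture spanning [39, 250] and
thins treatment fragments near planted footprints with class-specific
depletion (defaults 0.15 at the preferred TSS, 0.40 at the non-preferred).
The QTL generator plants Ψ = logistic(baseline + Σβ·(dosage − 2·MAF) + lab
+ population + noise) for 373 individuals with ~15% missingness;
binding-affecting SNPs carry nonzero β with probability 0.6 versus 0.15
for neutral ones, and the pre-logistic linear phenotype is emitted so
effect recovery can be judged on the scale effects were planted on.

All randomness flows from one global seed through split streams keyed by
(module, entity), so identical configurations reproduce byte-identical
outputs and any submodule can be regenerated alone.

**What the synthetic tests do not show.** The generator has no
mapping/alignment artifacts, no isoform-length read-assignment bias, no
correlated events within genes, no linkage disequilibrium, and
environments' effects are independent across events; power and calibration
results transfer to real data only to the extent those features are benign.
Problem sizes in the test suite (typically 5,000 events per type for
calibration checks, 300–500 events for power checks, 20 seeded replicates)
were chosen so the full suite documents each property at useful precision
on a single CPU.

## Orchestration

`spliceshift` (CLI) exposes simulate / quant / call / global / transassoc /
predict / atac / qtl / all as thin wrappers over `pipeline.run_pipeline`.
Stages communicate only through declared TSV/BED/GFF/JSON files; each run
writes a manifest with the config hash, seed, and per-stage input/output
SHA-256 digests and row counts.  A stage is skipped when its recorded input
digests match and its outputs are intact, and identical config + seed
reproduce byte-identical manifests.
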