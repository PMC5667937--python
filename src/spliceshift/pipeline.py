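"""End-to-end pipeline orchestration.

Stages communicate exclusively through declared files in the output
directory; each run writes a manifest recording the config hash, seed, and
per-stage input/output digests and row counts.  Re-running with identical
config and seed reproduces identical manifests byte-for-byte.  A stage is
skipped when its recorded input digests match the previous manifest and its
outputs are intact (digest-keyed caching).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import afe_qtl, atac_validation, event_quant, global_shifts, shift_calling
from . import shift_prediction, synthetic_cohort, trans_assoc
from .formats_io import read_event_gff, read_footprints_bed, write_event_gff, write_footprints_bed
from .synthetic_cohort import CohortConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quant", "call", "global", "transassoc", "predict",
          "atac", "qtl")

_STAGE_INPUTS = {
    "simulate": (),
    "quant": ("counts.tsv", "events.gff"),
    "call": ("comparisons.tsv", "null_comparisons.tsv"),
    "global": ("calls.tsv", "comparisons.tsv", "null_comparisons.tsv"),
    "transassoc": ("calls.tsv", "factor_expression.tsv"),
    "predict": ("calls.tsv", "footprints.bed", "events.gff"),
    "atac": ("calls.tsv", "footprints.bed", "events.gff", "atac_fragments.tsv"),
    "qtl": ("events.gff", "qtl_psi.tsv", "qtl_genotypes.tsv", "qtl_covariates.tsv",
            "qtl_snps.tsv"),
}


class PipelineError(RuntimeError):
    pass


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: CohortConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()


def _focal_environment(config: CohortConfig) -> tuple[str, str]:
    return config.cell_types[0], config.treatments[0]


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(config: CohortConfig, out: Path) -> dict[str, int]:
    cohort = synthetic_cohort.generate_counts(config)
    write_event_gff(
        sorted(cohort.annotations.values(), key=lambda a: a.event_id),
        out / "events.gff",
    )
    _write_tsv(cohort.counts, out / "counts.tsv")
    _write_tsv(cohort.truth, out / "truth.tsv")

    expr, factor_truth = synthetic_cohort.generate_factor_expression(
        config, cohort.truth
    )
    _write_tsv(expr, out / "factor_expression.tsv")
    _write_tsv(factor_truth, out / "factor_truth.tsv")

    rows = {"counts.tsv": len(cohort.counts), "truth.tsv": len(cohort.truth)}
    if "AFE" in config.event_types:
        cell, treat = _focal_environment(config)
        directions = cohort.truth_direction(cell, treat)
        footprints = synthetic_cohort.generate_footprint_landscape(
            config, cohort.annotations, directions
        )
        write_footprints_bed(footprints, out / "footprints.bed")
        fragments = synthetic_cohort.generate_atac(
            config, cohort.annotations, directions, footprints
        )
        _write_tsv(fragments, out / "atac_fragments.tsv")
        panel = synthetic_cohort.generate_qtl_panel(config, cohort.annotations)
        _write_tsv(panel.genotypes, out / "qtl_genotypes.tsv", index=True)
        _write_tsv(panel.psi, out / "qtl_psi.tsv", index=True)
        _write_tsv(panel.latent, out / "qtl_latent.tsv", index=True)
        _write_tsv(panel.snps, out / "qtl_snps.tsv")
        _write_tsv(panel.covariates, out / "qtl_covariates.tsv")
        _write_tsv(panel.truth, out / "qtl_truth.tsv")
        rows["footprints.bed"] = len(footprints)
        rows["atac_fragments.tsv"] = len(fragments)
    return rows


def _stage_quant(config: CohortConfig, out: Path) -> dict[str, int]:
    counts = pd.read_csv(out / "counts.tsv", sep="\t")
    annotations = {a.event_id: a for a in read_event_gff(out / "events.gff")}
    comparisons, null_comparisons = event_quant.compare_cohort(counts, annotations)
    _write_tsv(comparisons, out / "comparisons.tsv")
    _write_tsv(null_comparisons, out / "null_comparisons.tsv")
    return {"comparisons.tsv": len(comparisons),
            "null_comparisons.tsv": len(null_comparisons)}


def _stage_call(config: CohortConfig, out: Path) -> dict[str, int]:
    comparisons = pd.read_csv(out / "comparisons.tsv", sep="\t")
    nulls = pd.read_csv(out / "null_comparisons.tsv", sep="\t")
    calls = shift_calling.call_shifts_table(comparisons, nulls)
    _write_tsv(calls, out / "calls.tsv")
    annotations = {a.event_id: a for a in read_event_gff(out / "events.gff")}
    control_of = {t: config.control_of(t) for t in config.treatments}
    table = shift_calling.to_shift_table(calls, annotations, control_of)
    _write_tsv(table, out / "shift_table.tsv")
    return {"calls.tsv": len(calls), "shift_table.tsv": len(table)}


def _stage_global(config: CohortConfig, out: Path) -> dict[str, int]:
    calls = pd.read_csv(out / "calls.tsv", sep="\t")
    comparisons = pd.read_csv(out / "comparisons.tsv", sep="\t")
    nulls = pd.read_csv(out / "null_comparisons.tsv", sep="\t")
    summary = global_shifts.summarize_directions(
        calls, min_sig=global_shifts.MIN_SIG_REPORT
    )
    _write_tsv(summary, out / "direction_summary.tsv")

    ks_rows = []
    null_deltas = nulls["delta_psi"].to_numpy()
    for (cell, treat, etype), grp in comparisons.groupby(
            ["cell_type", "treatment", "event_type"], sort=True):
        res = global_shifts.ecdf_ks(grp["delta_psi"].to_numpy(),
                                    null_deltas[nulls["event_type"] == etype]
                                    if (nulls["event_type"] == etype).any()
                                    else null_deltas)
        if res is None:
            continue
        ks_rows.append({"cell_type": cell, "treatment": treat,
                        "event_type": etype, "ks_d": res[0], "ks_p": res[1]})
    _write_tsv(pd.DataFrame(ks_rows), out / "ks_tests.tsv")

    rows = calls[["significant", "treatment", "event_type", "cell_type"]]
    model = global_shifts.event_type_enrichment(rows)
    _write_tsv(model.coefficients, out / "enrichment_coefficients.tsv")
    _write_tsv(model.proportions, out / "enrichment_proportions.tsv")
    return {"direction_summary.tsv": len(summary), "ks_tests.tsv": len(ks_rows)}


def _stage_transassoc(config: CohortConfig, out: Path) -> dict[str, int]:
    calls = pd.read_csv(out / "calls.tsv", sep="\t")
    expr = pd.read_csv(out / "factor_expression.tsv", sep="\t")
    summary = global_shifts.summarize_directions(calls, min_sig=1)
    tables = []
    for cls, etype in (("SF", "RI"), ("TF", "AFE")):
        ppe_env = summary[summary["event_type"] == etype][
            ["cell_type", "treatment", "ppe"]
        ]
        if ppe_env.empty:
            continue
        results = trans_assoc.factor_ppe_correlation(
            expr[expr["factor_class"] == cls], ppe_env, etype
        )
        tables.append(trans_assoc.association_table(results))
    table = (pd.concat(tables, ignore_index=True)
             if tables else pd.DataFrame())
    _write_tsv(table, out / "factor_associations.tsv")
    return {"factor_associations.tsv": len(table)}


def _stage_predict(config: CohortConfig, out: Path) -> dict[str, int]:
    calls = pd.read_csv(out / "calls.tsv", sep="\t")
    annotations = {a.event_id: a for a in read_event_gff(out / "events.gff")}
    footprints = read_footprints_bed(out / "footprints.bed")
    # footprint landscapes are environment-specific: model the focal
    # environment the simulated landscape belongs to
    env = _focal_environment(config)
    report: dict = {}
    n_coef = 0
    if env is None:
        report = {"refused": "no significant directional AFE shifts"}
    else:
        cell, treat = env
        events = calls[
            (calls["event_type"] == "AFE") & calls["significant"]
            & (calls["direction"] != 0)
            & (calls["cell_type"] == cell) & (calls["treatment"] == treat)
        ][["event_id", "direction"]]
        X, y = shift_prediction.build_afe_features(events, annotations, footprints)
        try:
            fit = shift_prediction.fit_direction_classifier(
                X, y, seed=config.seed
            )
            coefs = fit.coefficients
            _write_tsv(coefs, out / "predict_coefficients.tsv")
            n_coef = len(coefs)
            report = {
                "environment": list(env),
                "n_events": fit.n_events,
                "alpha": fit.alpha,
                "lambda_1se": fit.lambda_1se,
                "lambda_max_auc": fit.lambda_max_auc,
                "cv_auc": fit.cv_auc,
                "n_nonzero_coefficients": n_coef,
            }
        except shift_prediction.InsufficientEventsError as err:
            report = {"refused": str(err), "environment": list(env)}
    (out / "predict_report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1) + "\n"
    )
    return {"predict_report.json": 1, "predict_coefficients.tsv": n_coef}


def _stage_atac(config: CohortConfig, out: Path) -> dict[str, int]:
    calls = pd.read_csv(out / "calls.tsv", sep="\t")
    annotations = {a.event_id: a for a in read_event_gff(out / "events.gff")}
    footprints = read_footprints_bed(out / "footprints.bed")
    fragments = pd.read_csv(out / "atac_fragments.tsv", sep="\t")
    cell, treat = _focal_environment(config)
    focal = calls[(calls["cell_type"] == cell) & (calls["treatment"] == treat)]
    tss_table = atac_validation.classify_tss(focal, annotations)
    profiles = atac_validation.tss_accessibility_profile(fragments, tss_table)
    prof_df = pd.DataFrame(
        {f"{cls}_{cond}": values for (cls, cond), values in sorted(profiles.items())}
    )
    prof_df.insert(0, "offset", np.arange(-atac_validation.TSS_HALF_WINDOW,
                                          atac_validation.TSS_HALF_WINDOW + 1))
    _write_tsv(prof_df, out / "atac_tss_profiles.tsv")
    tests = atac_validation.footprint_accessibility_test(
        fragments, footprints, tss_table
    )
    table = atac_validation.accessibility_table(tests)
    _write_tsv(table, out / "atac_motif_tests.tsv")
    return {"atac_motif_tests.tsv": len(table),
            "atac_tss_profiles.tsv": len(prof_df)}


def _stage_qtl(config: CohortConfig, out: Path) -> dict[str, int]:
    annotations = {a.event_id: a for a in read_event_gff(out / "events.gff")}
    psi = pd.read_csv(out / "qtl_psi.tsv", sep="\t", index_col=0)
    genotypes = pd.read_csv(out / "qtl_genotypes.tsv", sep="\t", index_col=0)
    covariates = pd.read_csv(out / "qtl_covariates.tsv", sep="\t")
    snps = pd.read_csv(out / "qtl_snps.tsv", sep="\t")
    normalized = afe_qtl.normalize_afe_psi(psi, covariates, annotations)
    results = afe_qtl.afe_qtl_scan(normalized, genotypes, snps, annotations)
    table = afe_qtl.qtl_table(results)
    _write_tsv(table, out / "qtl_results.tsv")
    enrichment: dict = {}
    if not table.empty and table["binding_effect"].nunique() > 1:
        enr = afe_qtl.binding_enrichment(table)
        enrichment = {
            "table": enr["table"],
            "odds_ratio": enr["odds_ratio"],
            "fisher_p": enr["fisher_p"],
        }
    (out / "qtl_enrichment.json").write_text(
        json.dumps(enrichment, sort_keys=True, indent=1) + "\n"
    )
    return {"qtl_results.tsv": len(table)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quant": _stage_quant,
    "call": _stage_call,
    "global": _stage_global,
    "transassoc": _stage_transassoc,
    "predict": _stage_predict,
    "atac": _stage_atac,
    "qtl": _stage_qtl,
}


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config: CohortConfig, out_dir: str | Path,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the selected stages, returning (and writing) the run manifest.

    Stages read their inputs from ``out_dir``; requesting a stage whose
    inputs are missing raises :class:`PipelineError` naming the stage to run
    first.  Unchanged stages (same config hash and input digests as the
    previous manifest, outputs intact) are skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
    cfg_hash = _config_hash(config)
    if previous.get("config_hash") != cfg_hash:
        previous = {}

    manifest = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "stages": dict(previous.get("stages", {})),
    }
    producer = {}
    for stage in STAGES:
        for f in _STAGE_INPUTS[stage]:
            producer.setdefault(f, "simulate")

    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise PipelineError(f"unknown stage {stage!r}")
        inputs = {}
        for fname in _STAGE_INPUTS[stage]:
            fpath = out / fname
            if not fpath.exists():
                needed = _producing_stage(fname)
                raise PipelineError(
                    f"stage {stage!r} requires {fname}; run stage {needed!r} first"
                )
            inputs[fname] = _digest(fpath)
        prev_stage = manifest["stages"].get(stage)
        if prev_stage and prev_stage.get("inputs") == inputs and all(
            (out / f).exists() and _digest(out / f) == d
            for f, d in prev_stage.get("outputs", {}).items()
        ):
            logger.info("stage %s: cached, skipping", stage)
            continue
        logger.info("stage %s: running", stage)
        rows = _STAGE_FUNCS[stage](config, out)
        outputs = {
            f: _digest(out / f) for f in rows if (out / f).exists()
        }
        manifest["stages"][stage] = {
            "inputs": inputs,
            "outputs": outputs,
            "rows": rows,
        }
        manifest_path.write_text(
            json.dumps(manifest, sort_keys=True, indent=1) + "\n"
        )
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest


def _producing_stage(fname: str) -> str:
    produced_by = {
        "counts.tsv": "simulate", "events.gff": "simulate",
        "truth.tsv": "simulate", "factor_expression.tsv": "simulate",
        "footprints.bed": "simulate", "atac_fragments.tsv": "simulate",
        "qtl_psi.tsv": "simulate", "qtl_genotypes.tsv": "simulate",
        "qtl_covariates.tsv": "simulate", "qtl_snps.tsv": "simulate",
        "comparisons.tsv": "quant", "null_comparisons.tsv": "quant",
        "calls.tsv": "call",
    }
    return produced_by.get(fname, "simulate")
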