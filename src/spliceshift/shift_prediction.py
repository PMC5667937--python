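"""Predicting the direction of significant shifts from sequence features.

For skipped exons and retained introns the features are per-motif indicators
over five regions around the event (defined on the transcribed strand); for
alternative first exons the features are per-motif footprint-count
differences between the two TSS windows (±1000 bp, upstream minus
downstream).  Direction (sign of the oriented ΔΨ) is classified with an
elastic-net logistic model; the reported AUC is the cross-validated AUC at
lambda.1se, the largest penalty whose CV AUC is within one standard error
of the best along the path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .formats_io import EventAnnotation, FootprintRecord

MIN_EVENTS = 100
AFE_TSS_WINDOW = 1000
SS_WINDOW = 100


class InsufficientEventsError(ValueError):
    """Raised when an environment has too few significant shifts to model."""


@dataclass
class ClassifierReport:
    n_events: int
    alpha: float
    lambda_path: np.ndarray
    cv_auc_mean: np.ndarray
    cv_auc_se: np.ndarray
    lambda_max_auc: float
    lambda_1se: float
    cv_auc: float                    # CV AUC at lambda.1se
    coefficients: pd.DataFrame = field(repr=False)  # feature, coefficient (nonzero)


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def _tx_sorted(exons, strand):
    """Exons in transcription order."""
    ordered = sorted(exons)
    return ordered if strand == "+" else ordered[::-1]


def _ss_windows(ss_boundary: int, strand: str) -> dict[str, tuple[int, int]]:
    """100 bp windows on either transcribed side of a splice-site boundary.

    ``ss_boundary`` is the genomic coordinate of the boundary (half-open
    convention: the first base of the downstream feature on '+', the end of
    it on '-')."""
    if strand == "+":
        return {
            "ss_upstream_100": (ss_boundary - SS_WINDOW, ss_boundary),
            "ss_downstream_100": (ss_boundary, ss_boundary + SS_WINDOW),
        }
    return {
        "ss_upstream_100": (ss_boundary, ss_boundary + SS_WINDOW),
        "ss_downstream_100": (ss_boundary - SS_WINDOW, ss_boundary),
    }


def event_regions(annotation: EventAnnotation) -> dict[str, tuple[int, int]]:
    """The five feature regions for an SE or RI event (genomic half-open).

    SE: upstream intron, the skipped exon, downstream intron, and 100 bp on
    either side of the skipped exon's 3' splice site (acceptor).  RI: the
    upstream exon, the intron, the downstream exon, and 100 bp on either
    side of the intron's 5' splice site (donor).  Upstream/downstream follow
    the direction of transcription.
    """
    strand = annotation.strand
    if annotation.event_type == "SE":
        exons = _tx_sorted(annotation.isoform1_exons, strand)
        if len(exons) != 3:
            raise ValueError(f"{annotation.event_id}: SE lacks flanking exons")
        up, skipped, down = exons
        if strand == "+":
            regions = {
                "upstream_intron": (up[1], skipped[0]),
                "event_exon": skipped,
                "downstream_intron": (skipped[1], down[0]),
            }
            acceptor = skipped[0]
        else:
            regions = {
                "upstream_intron": (skipped[1], up[0]),
                "event_exon": skipped,
                "downstream_intron": (down[1], skipped[0]),
            }
            acceptor = skipped[1]
        regions.update(_ss_windows(acceptor, strand))
        return regions
    if annotation.event_type == "RI":
        exons = _tx_sorted(annotation.isoform2_exons, strand)
        if len(exons) != 2:
            raise ValueError(f"{annotation.event_id}: RI lacks flanking exons")
        up, down = exons
        if strand == "+":
            regions = {
                "upstream_exon": up,
                "intron": (up[1], down[0]),
                "downstream_exon": down,
            }
            donor = up[1]
        else:
            regions = {
                "upstream_exon": up,
                "intron": (down[1], up[0]),
                "downstream_exon": down,
            }
            donor = up[0]
        regions.update(_ss_windows(donor, strand))
        return regions
    raise ValueError(f"{annotation.event_id}: regions defined for SE/RI only")


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def build_se_ri_features(
    events: pd.DataFrame,
    annotations: dict[str, EventAnnotation],
    motif_hits: list[FootprintRecord],
) -> tuple[pd.DataFrame, pd.Series, list[tuple[str, str]]]:
    """Motif × region indicator features for significant SE or RI shifts.

    ``events`` has columns ``event_id`` and ``direction`` (±1 from oriented
    ΔΨ).  A feature is 1 iff at least one motif hit on the event's strand
    overlaps the region (a hit straddling a boundary sets both adjacent
    windows).  Events whose annotation lacks the flanking exons are excluded
    and returned in the exclusion list with the reason.
    """
    hits_by_chrom: dict[str, list[FootprintRecord]] = {}
    motifs = sorted({h.motif_id for h in motif_hits})
    for h in motif_hits:
        hits_by_chrom.setdefault(h.chrom, []).append(h)

    rows, labels, index = [], [], []
    exclusions: list[tuple[str, str]] = []
    for rec in events.itertuples(index=False):
        a = annotations[rec.event_id]
        try:
            regions = event_regions(a)
        except ValueError as err:
            exclusions.append((rec.event_id, str(err)))
            continue
        row = {}
        local = [h for h in hits_by_chrom.get(a.chrom, []) if h.strand == a.strand]
        for motif in motifs:
            for region, (rs, re) in regions.items():
                row[f"{motif}|{region}"] = int(
                    any(
                        _overlaps(h.start, h.end, rs, re)
                        for h in local
                        if h.motif_id == motif
                    )
                )
        rows.append(row)
        labels.append(int(rec.direction))
        index.append(rec.event_id)
    X = pd.DataFrame(rows, index=index, dtype=int)
    y = pd.Series(labels, index=index, name="direction")
    return X, y, exclusions


def build_afe_features(
    events: pd.DataFrame,
    annotations: dict[str, EventAnnotation],
    footprints: list[FootprintRecord],
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-motif footprint-count differences for significant AFE shifts.

    For each motif the feature is the number of footprints within 1000 bp
    (either direction, closed interval — a footprint exactly 1000 bp away
    counts) of the upstream TSS minus the count near the downstream TSS,
    both on the transcribed strand.  Overlapping TSS windows double-count by
    design.  Footprints from all cell types enter, since binding is expected
    to change under treatment.
    """
    motifs = sorted({f.motif_id for f in footprints})
    by_key: dict[tuple[str, str], list[FootprintRecord]] = {}
    for f in footprints:
        by_key.setdefault((f.chrom, f.motif_id), []).append(f)

    rows, labels, index = [], [], []
    for rec in events.itertuples(index=False):
        a = annotations[rec.event_id]
        row = {}
        for motif in motifs:
            local = by_key.get((a.chrom, motif), [])
            counts = {}
            for name, tss in (("up", a.upstream_tss), ("down", a.downstream_tss)):
                lo, hi = tss - AFE_TSS_WINDOW, tss + AFE_TSS_WINDOW + 1
                counts[name] = sum(
                    1 for f in local if _overlaps(f.start, f.end, lo, hi)
                )
            row[motif] = counts["up"] - counts["down"]
        rows.append(row)
        labels.append(int(rec.direction))
        index.append(rec.event_id)
    X = pd.DataFrame(rows, index=index, dtype=int)
    y = pd.Series(labels, index=index, name="direction")
    return X, y


# ---------------------------------------------------------------------------
# elastic-net direction classifier
# ---------------------------------------------------------------------------

def _lambda_path(X: np.ndarray, y01: np.ndarray, alpha: float,
                 n_lambdas: int, eps: float = 1e-3) -> np.ndarray:
    n = len(y01)
    resid = y01 - y01.mean()
    grad = np.abs(X.T @ resid) / n
    lam_max = grad.max() / max(alpha, 1e-3)
    lam_max = max(lam_max, 1e-4)
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


def fit_direction_classifier(
    features: pd.DataFrame,
    labels: pd.Series,
    cv_folds: int = 10,
    alpha: float = 0.5,
    seed: int = 0,
    n_lambdas: int = 40,
    min_events: int = MIN_EVENTS,
) -> ClassifierReport:
    """Elastic-net logistic classification of shift direction with CV AUC.

    The regularization path runs from the smallest penalty that zeroes all
    coefficients down by three decades; each fold standardizes features on
    its training split.  ``lambda.1se`` is the largest penalty whose mean CV
    AUC is within one fold-standard-error of the best; the reported AUC and
    the refit (whole-data) nonzero coefficients are taken there.

    Environments with fewer than ``min_events`` events are refused
    (:class:`InsufficientEventsError`), mirroring the inclusion rule for
    this analysis; single-class label vectors are rejected.
    """
    X = features.to_numpy(dtype=float)
    y = labels.to_numpy()
    if len(y) < min_events:
        raise InsufficientEventsError(
            f"{len(y)} events < required {min_events}"
        )
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both direction classes must be present")
    y01 = (y == classes.max()).astype(int)

    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    lambdas = _lambda_path((X - mu) / sd, y01, alpha, n_lambdas)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    aucs = np.zeros((cv_folds, len(lambdas)))
    for fold, (tr, te) in enumerate(skf.split(X, y01)):
        mu_f, sd_f = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd_f[sd_f == 0] = 1.0
        Xtr, Xte = (X[tr] - mu_f) / sd_f, (X[te] - mu_f) / sd_f
        clf = LogisticRegression(
            solver="saga", l1_ratio=alpha,
            C=1.0, warm_start=True, max_iter=5000, tol=1e-6,
        )
        for j, lam in enumerate(lambdas):
            clf.C = 1.0 / (len(tr) * lam)
            clf.fit(Xtr, y01[tr])
            score = clf.decision_function(Xte)
            if np.ptp(score) == 0:
                aucs[fold, j] = 0.5
            else:
                aucs[fold, j] = roc_auc_score(y01[te], score)

    mean = aucs.mean(axis=0)
    se = aucs.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    best = int(np.argmax(mean))
    threshold = mean[best] - se[best]
    idx_1se = int(np.flatnonzero(mean >= threshold)[0])  # path is descending
    lam_1se = float(lambdas[idx_1se])

    Xs = (X - mu) / sd
    final = LogisticRegression(
        solver="saga", l1_ratio=alpha,
        C=1.0 / (len(y01) * lam_1se), max_iter=5000, tol=1e-6,
    ).fit(Xs, y01)
    coefs = pd.DataFrame(
        {"feature": features.columns, "coefficient": final.coef_.ravel()}
    )
    coefs = coefs[coefs["coefficient"] != 0.0].reset_index(drop=True)
    return ClassifierReport(
        n_events=len(y01),
        alpha=alpha,
        lambda_path=lambdas,
        cv_auc_mean=mean,
        cv_auc_se=se,
        lambda_max_auc=float(lambdas[best]),
        lambda_1se=lam_1se,
        cv_auc=float(mean[idx_1se]),
        coefficients=coefs,
    )
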