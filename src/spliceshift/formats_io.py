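"""Readers and writers for the external file dialects the pipeline touches.

Coordinate conventions
----------------------
All *internal* coordinates are 0-based half-open (BED-native).  On-disk GFF
coordinates are 1-based inclusive; the conversion happens at I/O time and
nowhere else.  MISO-style event names are treated as opaque keys and never
re-parsed for coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: The eight admissible alternative-RNA-processing event types.
EVENT_TYPES = ("SE", "RI", "A3SS", "A5SS", "MXE", "AFE", "ALE", "TandemUTR")

#: Event types whose oriented ΔΨ carries a biological direction.
DIRECTIONAL_TYPES = ("SE", "RI", "TandemUTR", "AFE", "ALE")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MisoComparisonRecord:
    """One row of a MISO ``*_vs_*.miso_bf`` comparison file.

    ``sample1`` is the treatment, ``sample2`` the control; ``diff`` is the
    posterior-mean ΔΨ (sample1 − sample2) and ``bayes_factor`` the BF₁₀ for
    distinct Ψ against shared Ψ.  Counts are the isoform-unique read counts
    per sample.
    """

    event_name: str
    sample1_psi_mean: float
    sample2_psi_mean: float
    diff: float
    bayes_factor: float
    sample1_counts: tuple[int, int] = (0, 0)  # (inclusion-unique, exclusion-unique)
    sample2_counts: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.bayes_factor < 0:
            raise ValueError(f"{self.event_name}: bayes_factor must be >= 0")
        if abs(self.diff - (self.sample1_psi_mean - self.sample2_psi_mean)) > 1e-6:
            raise ValueError(
                f"{self.event_name}: diff is not sample1_psi_mean - sample2_psi_mean"
            )


@dataclass
class FootprintRecord:
    """A transcription-factor footprint interval (0-based half-open).

    ``posterior`` is the binding posterior from the upstream footprint caller
    (bound sites carry posterior > 0.99 in the source data).  ``binding_effect``
    optionally flags per-allele consequences for QTL work.
    """

    chrom: str
    start: int
    end: int
    motif_id: str
    posterior: float = 1.0
    strand: str = "."
    binding_effect: str | None = None  # {"affecting", "neutral"} or None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"footprint {self.motif_id} {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if not 0.0 <= self.posterior <= 1.0:
            raise ValueError(f"footprint {self.motif_id}: posterior outside [0,1]")


@dataclass
class EventAnnotation:
    """One alternative-processing event with its two isoform exon chains.

    ``isoform1_exons`` corresponds to MISO's first (inclusion) isoform and
    ``isoform2_exons`` to the second (exclusion); higher raw Ψ means more of
    isoform 1.  Exons are (start, end) 0-based half-open tuples.  For AFE/ALE
    the alternative first/last exon is the *first* exon of each chain in
    transcription order.
    """

    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    isoform1_exons: tuple[tuple[int, int], ...]
    isoform2_exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"{self.event_id}: unknown event_type {self.event_type!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.event_id}: strand must be '+' or '-'")
        if self.event_type != "TandemUTR" and not self.isoform2_exons:
            raise ValueError(
                f"{self.event_id}: event of type {self.event_type} has a single isoform"
            )
        for exons in (self.isoform1_exons, self.isoform2_exons):
            for s, e in exons:
                if s >= e:
                    raise ValueError(f"{self.event_id}: degenerate exon [{s},{e})")

    # -- AFE/ALE geometry -------------------------------------------------
    def _tss(self, exons: Sequence[tuple[int, int]]) -> int:
        """First transcribed base of an exon chain (0-based)."""
        if self.strand == "+":
            return min(s for s, _ in exons)
        return max(e for _, e in exons) - 1

    def _tes(self, exons: Sequence[tuple[int, int]]) -> int:
        """Last transcribed base of an exon chain (0-based)."""
        if self.strand == "+":
            return max(e for _, e in exons) - 1
        return min(s for s, _ in exons)

    @property
    def isoform1_tss(self) -> int:
        return self._tss(self.isoform1_exons)

    @property
    def isoform2_tss(self) -> int:
        return self._tss(self.isoform2_exons)

    @property
    def upstream_tss(self) -> int:
        """AFE: TSS earlier in transcription order (larger coordinate on '-')."""
        self._require_afe()
        t1, t2 = self.isoform1_tss, self.isoform2_tss
        if self.strand == "+":
            return min(t1, t2)
        return max(t1, t2)

    @property
    def downstream_tss(self) -> int:
        self._require_afe()
        t1, t2 = self.isoform1_tss, self.isoform2_tss
        if self.strand == "+":
            return max(t1, t2)
        return min(t1, t2)

    @property
    def isoform1_is_upstream_tss(self) -> bool:
        self._require_afe()
        return self.isoform1_tss == self.upstream_tss

    @property
    def isoform1_is_downstream_tes(self) -> bool:
        """ALE: whether isoform 1 ends at the transcriptionally later end site."""
        if self.event_type != "ALE":
            raise ValueError(f"{self.event_id}: not an ALE event")
        t1, t2 = self._tes(self.isoform1_exons), self._tes(self.isoform2_exons)
        if self.strand == "+":
            return t1 >= t2
        return t1 <= t2

    def _require_afe(self) -> None:
        if self.event_type != "AFE":
            raise ValueError(f"{self.event_id}: not an AFE event")
        if self.isoform1_tss == self.isoform2_tss:
            raise ValueError(f"{self.event_id}: AFE with identical TSS positions")


class MisoComparisonTable(list):
    """List of :class:`MisoComparisonRecord` with a ``n_skipped`` attribute."""

    def __init__(self, records: Iterable[MisoComparisonRecord] = (), n_skipped: int = 0):
        super().__init__(records)
        self.n_skipped = n_skipped


# ---------------------------------------------------------------------------
# MISO comparison dialect
# ---------------------------------------------------------------------------

_MISO_COLUMNS = (
    "event_name",
    "sample1_posterior_mean",
    "sample2_posterior_mean",
    "diff",
    "bayes_factor",
    "sample1_counts",
    "sample2_counts",
)

_COUNT_CLASS_RE = re.compile(r"\((\d+),(\d+)\):(\d+)")


def _parse_counts_field(text: str) -> tuple[int, int]:
    """Parse MISO's ``(1,0):k,(0,1):m`` class-count syntax.

    Class (1,0) holds reads unique to the inclusion isoform and (0,1) reads
    unique to the exclusion isoform; any other classes are ignored.
    """
    inc = exc = 0
    for m in _COUNT_CLASS_RE.finditer(text):
        cls = (int(m.group(1)), int(m.group(2)))
        if cls == (1, 0):
            inc = int(m.group(3))
        elif cls == (0, 1):
            exc = int(m.group(3))
    return inc, exc


def _format_counts_field(counts: tuple[int, int]) -> str:
    return f"(1,0):{counts[0]},(0,1):{counts[1]}"


def read_miso_comparison(path: str | Path) -> MisoComparisonTable:
    """Read a MISO comparison (``.miso_bf``) file.

    Columns are located by name so both annotation-version layouts parse.
    Rows with a non-numeric Bayes factor or Ψ (MISO emits ``NA`` for
    under-covered events) are skipped with a logged warning; the number of
    skipped rows is available as ``.n_skipped`` on the returned table.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file, expected a header line")
        columns = header.split("\t")
        index: dict[str, int] = {c: i for i, c in enumerate(columns)}
        for required in _MISO_COLUMNS[:5]:
            if required not in index:
                raise ValueError(f"{path}: missing required column {required!r}")
        records = MisoComparisonTable()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(columns)} fields, got {len(fields)}"
                )

            def get(col: str, default: str | None = None) -> str:
                i = index.get(col)
                return fields[i] if i is not None else default  # type: ignore[return-value]

            raw = {c: get(c) for c in _MISO_COLUMNS[:5]}
            try:
                rec = MisoComparisonRecord(
                    event_name=raw["event_name"],
                    sample1_psi_mean=float(raw["sample1_posterior_mean"]),
                    sample2_psi_mean=float(raw["sample2_posterior_mean"]),
                    diff=float(raw["diff"]),
                    bayes_factor=float(raw["bayes_factor"]),
                    sample1_counts=_parse_counts_field(get("sample1_counts", "") or ""),
                    sample2_counts=_parse_counts_field(get("sample2_counts", "") or ""),
                )
            except ValueError as err:
                if any(_is_na(raw[c]) for c in ("sample1_posterior_mean",
                                                "sample2_posterior_mean",
                                                "diff", "bayes_factor")):
                    logger.warning("%s: line %d skipped (non-numeric field): %s",
                                   path, lineno, line[:80])
                    records.n_skipped += 1
                    continue
                raise ValueError(f"{path}: line {lineno}: {err}") from err
            records.append(rec)
    return records


def _is_na(text: str) -> bool:
    try:
        float(text)
        return False
    except ValueError:
        return True


def write_miso_comparison(records: Iterable[MisoComparisonRecord], path: str | Path) -> None:
    """Write records in the comparison dialect ``read_miso_comparison`` accepts."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_MISO_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    (
                        r.event_name,
                        _fmt(r.sample1_psi_mean),
                        _fmt(r.sample2_psi_mean),
                        _fmt(r.diff),
                        _fmt(r.bayes_factor),
                        _format_counts_field(r.sample1_counts),
                        _format_counts_field(r.sample2_counts),
                    )
                )
                + "\n"
            )


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


# ---------------------------------------------------------------------------
# footprint BED6+
# ---------------------------------------------------------------------------

def read_footprints_bed(path: str | Path) -> list[FootprintRecord]:
    """Read BED6+ footprints: chrom start end motif_id posterior strand [binding_effect].

    BED is 0-based half-open, which is also the internal convention, so
    intervals pass through unchanged.  A missing posterior column defaults to
    1.0 with a warning.
    """
    path = Path(path)
    records: list[FootprintRecord] = []
    warned = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >= 4 BED fields")
            chrom, start, end, motif_id = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            if len(fields) >= 5 and fields[4] not in (".", ""):
                posterior = float(fields[4])
            else:
                if not warned:
                    logger.warning("%s: posterior column absent; defaulting to 1.0", path)
                    warned = True
                posterior = 1.0
            strand = fields[5] if len(fields) >= 6 else "."
            binding_effect = fields[6] if len(fields) >= 7 and fields[6] != "." else None
            records.append(
                FootprintRecord(chrom, start, end, motif_id, posterior, strand, binding_effect)
            )
    return records


def write_footprints_bed(records: Iterable[FootprintRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.motif_id}\t"
                f"{_fmt(r.posterior)}\t{r.strand}\t{r.binding_effect or '.'}\n"
            )


# ---------------------------------------------------------------------------
# event annotation GFF
# ---------------------------------------------------------------------------

def read_event_gff(path: str | Path) -> list[EventAnnotation]:
    """Read event annotations from a MISO-style GFF3 dialect.

    On disk, each event is a parent feature whose ``type`` column is the
    event type, with child ``exon`` features carrying ``Parent=<event_id>``
    and ``isoform=1|2`` attributes.  Coordinates are 1-based inclusive on
    disk and converted to 0-based half-open internally.
    """
    path = Path(path)
    parents: dict[str, dict] = {}
    exons: dict[str, dict[str, list[tuple[int, int]]]] = {}
    order: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF fields")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs_text = fields
            attrs = dict(
                item.split("=", 1) for item in attrs_text.split(";") if "=" in item
            )
            start0, end0 = int(start1) - 1, int(end1)  # 1-based inclusive -> half-open
            if ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}: line {lineno}: exon without Parent")
                iso = attrs.get("isoform", "1")
                exons.setdefault(parent, {}).setdefault(iso, []).append((start0, end0))
            else:
                if ftype not in EVENT_TYPES:
                    raise ValueError(f"{path}: line {lineno}: unknown event type {ftype!r}")
                event_id = attrs.get("ID")
                if event_id is None:
                    raise ValueError(f"{path}: line {lineno}: event without ID")
                parents[event_id] = {
                    "gene_id": attrs.get("gene_id", event_id),
                    "event_type": ftype,
                    "chrom": chrom,
                    "strand": strand,
                }
                order.append(event_id)
    annotations = []
    for event_id in order:
        meta = parents[event_id]
        iso = exons.get(event_id, {})
        annotations.append(
            EventAnnotation(
                event_id=event_id,
                gene_id=meta["gene_id"],
                event_type=meta["event_type"],
                chrom=meta["chrom"],
                strand=meta["strand"],
                isoform1_exons=tuple(sorted(iso.get("1", []))),
                isoform2_exons=tuple(sorted(iso.get("2", []))),
            )
        )
    return annotations


def write_event_gff(annotations: Iterable[EventAnnotation], path: str | Path) -> None:
    """Write annotations in the GFF3 dialect ``read_event_gff`` accepts."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            span = [s for s, _ in a.isoform1_exons + a.isoform2_exons]
            span_end = [e for _, e in a.isoform1_exons + a.isoform2_exons]
            fh.write(
                f"{a.chrom}\tspliceshift\t{a.event_type}\t{min(span) + 1}\t{max(span_end)}"
                f"\t.\t{a.strand}\t.\tID={a.event_id};gene_id={a.gene_id}\n"
            )
            for iso_label, chain in (("1", a.isoform1_exons), ("2", a.isoform2_exons)):
                for s, e in chain:
                    fh.write(
                        f"{a.chrom}\tspliceshift\texon\t{s + 1}\t{e}\t.\t{a.strand}\t.\t"
                        f"Parent={a.event_id};isoform={iso_label}\n"
                    )
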