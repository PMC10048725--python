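"""Readers for chromosome sequences and annotations.

All coordinates are 0-based half-open internally. GenBank locations
(1-based inclusive) are converted on read; BED is consumed natively.
Softmasked (lowercase) bases are uppercased and treated as ordinary
sequence; runs of N are recorded as gap spans.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

#: Default minimum chromosome length (bp) for downstream statistics.
#: Binomial approximations and cross-chromosome correlations are unstable
#: on very short records.
DEFAULT_MIN_LENGTH = 10_000

_N_RUN = re.compile(r"N+")


class SequenceIOError(ValueError):
    """Raised for malformed sequence or annotation input."""


@dataclass
class AnnotationSet:
    """Feature intervals on one chromosome, 0-based half-open.

    Strands are stored in parallel lists (``+``/``-``); interval
    arithmetic ignores strand.
    """

    gene_spans: list[Interval] = field(default_factory=list)
    gene_strands: list[str] = field(default_factory=list)
    mrna_spans: list[Interval] = field(default_factory=list)
    mrna_strands: list[str] = field(default_factory=list)
    cds_spans: list[Interval] = field(default_factory=list)
    cds_strands: list[str] = field(default_factory=list)
    enhancer_spans: list[Interval] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.gene_spans or self.mrna_spans or self.cds_spans or self.enhancer_spans
        )


@dataclass
class ChromosomeRecord:
    """One chromosome: sequence plus gap and feature intervals."""

    id: str
    species: str
    sequence: str
    gap_spans: list[Interval] = field(default_factory=list)
    annotations: AnnotationSet = field(default_factory=AnnotationSet)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def n_gaps(self) -> int:
        """Total bases covered by gap spans."""
        return merged_base_count(self.gap_spans)


def _check_interval(span: Sequence[int]) -> Interval:
    start, end = int(span[0]), int(span[1])
    if start < 0 or end < start:
        raise SequenceIOError(f"invalid interval ({start}, {end})")
    return start, end


def merge_intervals(spans: Iterable[Sequence[int]]) -> list[Interval]:
    """Merge overlapping/adjacent intervals into a sorted disjoint list."""
    ivs = sorted(_check_interval(s) for s in spans)
    merged: list[Interval] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1]:
            if end > merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def merged_base_count(spans: Iterable[Sequence[int]]) -> int:
    """Number of distinct positions covered by the union of intervals."""
    return sum(end - start for start, end in merge_intervals(spans))


def find_gap_spans(sequence: str) -> list[Interval]:
    """Intervals covering every N in an (uppercase) sequence."""
    return [m.span() for m in _N_RUN.finditer(sequence)]


def _record_from_seq(rec_id: str, species: str, sequence: str) -> ChromosomeRecord:
    seq = sequence.upper()
    return ChromosomeRecord(
        id=rec_id.split()[0] if rec_id else rec_id,
        species=species,
        sequence=seq,
        gap_spans=find_gap_spans(seq),
    )


def read_fasta(path: str | Path, species: str = "") -> list[ChromosomeRecord]:
    """Read a (multi-)FASTA file into chromosome records.

    Gap spans are inferred from runs of N; annotations are left empty.
    Raises :class:`SequenceIOError` on an empty or malformed file.
    """
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(_record_from_seq(rec.id, species, str(rec.seq)))
    except ValueError as exc:  # Biopython parse errors
        raise SequenceIOError(f"malformed FASTA in {path}: {exc}") from exc
    if not records:
        raise SequenceIOError(f"no FASTA records in {path}")
    return records


def _feature_intervals(feature, length: int, rec_id: str) -> list[Interval]:
    """Exon intervals of a (possibly compound) feature location, clipped to [0, L)."""
    out = []
    for part in feature.location.parts:
        start, end = int(part.start), int(part.end)
        if start < 0 or end > length:
            logger.warning(
                "feature %s at (%d, %d) extends outside %s [0, %d); clipping",
                feature.type, start, end, rec_id, length,
            )
            start, end = max(start, 0), min(end, length)
        if end > start:
            out.append((start, end))
    return out


def read_genbank(path: str | Path) -> list[ChromosomeRecord]:
    """Read a GenBank flat file with sequence and gene/mRNA/CDS/gap features.

    Locations are converted from 1-based inclusive to 0-based half-open;
    ``join(...)`` locations are expanded to their exon intervals.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = str(rec.seq).upper()
        if not seq or set(seq) == {"?"}:  # Biopython's undefined-sequence marker
            raise SequenceIOError(f"record {rec.id} in {path} has no ORIGIN sequence")
        species = rec.annotations.get("organism", "") or ""
        record = _record_from_seq(rec.id, species, seq)
        ann = record.annotations
        gap_spans = list(record.gap_spans)
        for feature in rec.features:
            ivs = _feature_intervals(feature, len(seq), rec.id)
            strand = "-" if feature.location.strand == -1 else "+"
            if feature.type == "gene":
                ann.gene_spans.extend(ivs)
                ann.gene_strands.extend(strand for _ in ivs)
            elif feature.type == "mRNA":
                ann.mrna_spans.extend(ivs)
                ann.mrna_strands.extend(strand for _ in ivs)
            elif feature.type == "CDS":
                ann.cds_spans.extend(ivs)
                ann.cds_strands.extend(strand for _ in ivs)
            elif feature.type in ("gap", "assembly_gap"):
                gap_spans.extend(ivs)
        record.gap_spans = merge_intervals(gap_spans)
        records.append(record)
    if not records:
        raise SequenceIOError(f"no GenBank records in {path}")
    return records


def read_bed(path: str | Path) -> dict[str, list[Interval]]:
    """Read a BED (3+ column) file into per-chromosome interval lists.

    BED is already 0-based half-open; no conversion is applied.
    """
    path = Path(path)
    spans: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SequenceIOError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise SequenceIOError(f"{path}:{lineno}: non-integer coordinates") from exc
            spans.setdefault(fields[0], []).append(_check_interval((start, end)))
    return spans


def filter_short_records(
    records: Iterable[ChromosomeRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> list[ChromosomeRecord]:
    """Drop chromosomes shorter than ``min_length`` bp, with a logged warning."""
    kept = []
    for rec in records:
        if rec.length_bp < min_length:
            logger.warning(
                "excluding chromosome %s (%d bp < %d bp minimum)",
                rec.id, rec.length_bp, min_length,
            )
        else:
            kept.append(rec)
    return kept
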