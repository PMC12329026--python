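"""Genomic file formats with one fixed coordinate convention.

All internal coordinates are 0-based, half-open ``[start, end)`` (BED-native).
Conversion to/from other conventions (GFF3 is 1-based, closed) happens only at
format boundaries, never inside the pipeline.

FASTA/FASTQ records go through Biopython; BED/BEDGRAPH are parsed here because
the pipeline guarantees byte-identical round trips for canonical records.
"""

from __future__ import annotations

import io
import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

from Bio import SeqIO

log = logging.getLogger(__name__)

STRANDS = ("+", "-")

_RNA_TO_DNA = str.maketrans("uU", "tT")


class FormatError(ValueError):
    """Malformed record in a genomic text format."""


def _open_text(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    return open(source, "rt")


# ---------------------------------------------------------------------------
# intervals / BED
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open genomic interval (BED semantics)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"empty or negative interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


def _fmt_score(score: float) -> str:
    # keep integers integral so BED round trips byte-identically
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def parse_bed(source, n_cols: int = 6) -> list[GenomicInterval]:
    """Parse BED3 or BED6 into intervals, in file order.

    For ``n_cols == 3`` the name/score/strand columns default to ".", 0, "+".
    Malformed coordinates raise :class:`FormatError` naming the line number.
    """
    if n_cols not in (3, 6):
        raise ValueError("n_cols must be 3 or 6")
    out: list[GenomicInterval] = []
    stream = _open_text(source)
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < n_cols:
            raise FormatError(f"line {lineno}: expected >= {n_cols} columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer coordinate") from exc
        name, score, strand = ".", 0.0, "+"
        if n_cols == 6:
            name = fields[3]
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric score") from exc
            strand = fields[5]
        try:
            out.append(GenomicInterval(fields[0], start, end, strand, name, score))
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], stream: TextIO) -> None:
    """Write BED6, tab-separated, newline-terminated."""
    for iv in intervals:
        stream.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{_fmt_score(iv.score)}\t{iv.strand}\n"
        )


# ---------------------------------------------------------------------------
# per-nucleotide tracks / BEDGRAPH
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackPoint:
    """One crosslink-count record at a single nucleotide."""

    chrom: str
    pos: int
    strand: str
    count: int

    def __post_init__(self):
        if self.pos < 0:
            raise FormatError(f"negative position {self.pos}")
        if self.count < 1:
            raise FormatError("materialized track points must have count >= 1")
        if self.strand not in STRANDS:
            raise FormatError(f"bad strand {self.strand!r}")


def write_bedgraph(
    track: Sequence[TrackPoint], strand: str, stream: TextIO, signed: bool = False
) -> None:
    """Write single-nucleotide BEDGRAPH lines for one strand.

    Input must already be sorted by (chrom, pos); unsorted input is an error,
    never silently re-sorted.  With ``signed`` set, minus-strand counts are
    emitted negated (the single-file signed dialect); default is one
    non-negative file per strand.
    """
    if strand not in STRANDS:
        raise ValueError(f"bad strand {strand!r}")
    prev: tuple[str, int] | None = None
    for pt in track:
        if pt.strand != strand:
            raise ValueError(f"point on strand {pt.strand} in {strand} track")
        key = (pt.chrom, pt.pos)
        if prev is not None and key < prev:
            raise ValueError("track not sorted by (chrom, pos)")
        prev = key
        count = -pt.count if (signed and strand == "-") else pt.count
        stream.write(f"{pt.chrom}\t{pt.pos}\t{pt.pos + 1}\t{count}\n")


def parse_bedgraph(source, strand: str) -> list[TrackPoint]:
    """Parse single-nucleotide BEDGRAPH back into track points."""
    out: list[TrackPoint] = []
    for lineno, line in enumerate(_open_text(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"line {lineno}: expected 4 columns")
        start, end, count = int(fields[1]), int(fields[2]), int(float(fields[3]))
        if end != start + 1:
            raise FormatError(f"line {lineno}: not single-nucleotide resolution")
        out.append(TrackPoint(fields[0], start, strand, abs(count)))
    return out


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivs = sorted(ivs)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _subtract(blocks, holes) -> tuple[tuple[int, int], ...]:
    """Set difference of sorted disjoint interval lists."""
    out = []
    for s, e in blocks:
        cur = s
        for hs, he in holes:
            if he <= cur or hs >= e:
                continue
            if hs > cur:
                out.append((cur, hs))
            cur = max(cur, he)
        if cur < e:
            out.append((cur, e))
    return tuple(out)


@dataclass(frozen=True)
class GeneModel:
    """Representative transcript with exon/CDS structure.

    UTRs and introns are derived, never stored: exonic sequence that is not
    CDS is UTR (5' vs 3' resolved by strand); gaps between exons are introns.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise FormatError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise FormatError(f"{self.transcript_id}: transcript without exons")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise FormatError(f"{self.transcript_id}: bad exon [{s},{e})")
            if s < prev_end:
                raise FormatError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise FormatError(
                    f"{self.transcript_id}: CDS [{cs},{ce}) outside exons"
                )

    @property
    def biotype(self) -> str:
        return "coding" if self.cds else "non-coding"

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        )

    def _utrs(self) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]:
        """(left-of-CDS, right-of-CDS) exonic non-CDS intervals."""
        if not self.cds:
            return (), ()
        utr = _subtract(self.exons, self.cds)
        cds_start, cds_end = self.cds[0][0], self.cds[-1][1]
        left = tuple((s, e) for s, e in utr if e <= cds_start)
        right = tuple((s, e) for s, e in utr if s >= cds_end)
        return left, right

    def five_prime_utr(self) -> tuple[tuple[int, int], ...]:
        left, right = self._utrs()
        return left if self.strand == "+" else right

    def three_prime_utr(self) -> tuple[tuple[int, int], ...]:
        left, right = self._utrs()
        return right if self.strand == "+" else left

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def _bed12_line_to_model(fields: Sequence[str], lineno: int) -> GeneModel:
    chrom = fields[0]
    start, end = int(fields[1]), int(fields[2])
    name, strand = fields[3], fields[5]
    thick_start, thick_end = int(fields[6]), int(fields[7])
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise FormatError(f"line {lineno}: blockCount does not match block lists")
    exons = tuple((start + o, start + o + sz) for o, sz in zip(starts, sizes))
    if exons[-1][1] != end:
        raise FormatError(f"line {lineno}: blocks do not span chromEnd")
    cds: tuple[tuple[int, int], ...] = ()
    if thick_end > thick_start:  # zero-length thick span = non-coding
        cds = tuple(
            (max(s, thick_start), min(e, thick_end))
            for s, e in exons
            if min(e, thick_end) > max(s, thick_start)
        )
    gene_id = name.split(".")[0]
    return GeneModel(gene_id, name, chrom, strand, exons, cds)


def _parse_bed12(stream: TextIO) -> list[GeneModel]:
    models = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise FormatError(f"line {lineno}: expected 12 columns")
        try:
            models.append(_bed12_line_to_model(fields, lineno))
        except FormatError as exc:
            log.warning("rejecting gene model: %s", exc)
    return models


def _parse_gff3(stream: TextIO) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        stream.read(),
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for tx in db.features_of_type(("mRNA", "transcript", "ncRNA")):
        gene_id = tx.attributes.get("Parent", [tx.id])[0]
        exons = _merge_intervals(
            (f.start - 1, f.end) for f in db.children(tx, featuretype="exon")
        )
        cds = _merge_intervals(
            (f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")
        )
        if not exons:
            log.warning("rejecting %s: no exons", tx.id)
            continue
        try:
            models.append(GeneModel(gene_id, tx.id, tx.seqid, tx.strand, exons, cds))
        except FormatError as exc:
            log.warning("rejecting gene model: %s", exc)
    return models


def parse_gene_models(source, dialect: str = "bed12") -> list[GeneModel]:
    """Parse gene models from BED12 or GFF3.

    BED12 thickStart/thickEnd encode the CDS span (equal values mean
    non-coding).  GFF3 coordinates are converted from 1-based closed to the
    internal 0-based half-open convention on ingestion.  If several
    transcripts share a gene, the one with the greatest exonic length is kept
    as the representative model (warning logged).
    """
    stream = _open_text(source)
    if dialect == "bed12":
        models = _parse_bed12(stream)
    elif dialect == "gff3":
        models = _parse_gff3(stream)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    by_gene: dict[str, GeneModel] = {}
    for m in models:
        cur = by_gene.get(m.gene_id)
        if cur is None:
            by_gene[m.gene_id] = m
        else:
            log.warning(
                "gene %s has multiple transcripts; keeping the longest", m.gene_id
            )
            if m.exonic_length() > cur.exonic_length():
                by_gene[m.gene_id] = m
    return list(by_gene.values())


def write_bed12(models: Iterable[GeneModel], stream: TextIO) -> None:
    for m in models:
        start, end = m.start, m.end
        if m.cds:
            thick_start, thick_end = m.cds[0][0], m.cds[-1][1]
        else:
            thick_start = thick_end = start
        sizes = ",".join(str(e - s) for s, e in m.exons) + ","
        starts = ",".join(str(s - start) for s, e in m.exons) + ","
        stream.write(
            f"{m.chrom}\t{start}\t{end}\t{m.transcript_id}\t0\t{m.strand}\t"
            f"{thick_start}\t{thick_end}\t0\t{len(m.exons)}\t{sizes}\t{starts}\n"
        )


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeqRead:
    """A sequence record; ``quals`` is empty for FASTA records."""

    id: str
    seq: str
    quals: tuple[int, ...] = ()

    def __post_init__(self):
        if self.quals and len(self.quals) != len(self.seq):
            raise FormatError(f"{self.id}: sequence/quality length mismatch")


def _normalize(seq: str) -> str:
    return str(seq).upper().translate(_RNA_TO_DNA).replace("U", "T")


def read_fasta(source) -> list[SeqRead]:
    """Read FASTA; sequences upper-cased, RNA alphabet (U) mapped to DNA."""
    stream = _open_text(source)
    return [SeqRead(rec.id, _normalize(rec.seq)) for rec in SeqIO.parse(stream, "fasta")]


def read_fastq(source) -> list[SeqRead]:
    """Read FASTQ (Phred+33); truncated or mismatched records raise."""
    stream = _open_text(source)
    out = []
    try:
        for rec in SeqIO.parse(stream, "fastq"):
            out.append(
                SeqRead(
                    rec.id,
                    _normalize(rec.seq),
                    tuple(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise FormatError(str(exc)) from exc
    return out


def write_fasta(records: Iterable[SeqRead], stream: TextIO) -> None:
    for rec in records:
        stream.write(f">{rec.id}\n{rec.seq}\n")


def write_fastq(records: Iterable[SeqRead], stream: TextIO) -> None:
    for rec in records:
        quals = "".join(chr(q + 33) for q in rec.quals)
        stream.write(f"@{rec.id}\n{rec.seq}\n+\n{quals}\n")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
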