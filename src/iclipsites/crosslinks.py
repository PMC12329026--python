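"""From alignments to deduplicated single-nucleotide crosslink tracks.

In truncation-mode iCLIP the reverse transcriptase stops immediately 3' of the
crosslinked nucleotide, so the protein-RNA contact is the position one
nucleotide 5' of the mapped read start (in read orientation): ``start - 1`` on
the plus strand, and the (half-open) alignment ``end`` on the minus strand.

PCR duplicates are removed by grouping reads on (chrom, strand, 5'-end
position, UMI) and keeping one representative per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

from .formats import FormatError, TrackPoint

log = logging.getLogger(__name__)

TSV_COLUMNS = ("read_id", "chrom", "start", "end", "strand", "umi", "replicate")


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    umi: str
    replicate: str
    unique: bool = True

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(f"{self.read_id}: empty alignment span")
        if not self.umi:
            raise FormatError(f"{self.read_id}: missing UMI")

    @property
    def five_prime_pos(self) -> int:
        """Genomic position of the read's 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


def ingest_alignments(source, dialect: str = "tsv") -> list[AlignedRead]:
    """Read alignments from the 7-column TSV dialect or from text SAM.

    SAM: UMI recovered from the read-ID suffix after the last ':'; records
    flagged secondary, or with an NH tag > 1, are marked non-unique.
    """
    if dialect == "tsv":
        return _ingest_tsv(source)
    if dialect == "sam":
        return _ingest_sam(source)
    raise ValueError(f"unknown dialect {dialect!r}")


def _ingest_tsv(source) -> list[AlignedRead]:
    stream = source if hasattr(source, "read") else open(source, "rt")
    out = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("read_id\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 7:
            raise FormatError(f"line {lineno}: expected {len(TSV_COLUMNS)} columns")
        out.append(
            AlignedRead(
                read_id=fields[0],
                chrom=fields[1],
                start=int(fields[2]),
                end=int(fields[3]),
                strand=fields[4],
                umi=fields[5],
                replicate=fields[6],
            )
        )
    return out


def _ingest_sam(source) -> list[AlignedRead]:
    import pysam

    out = []
    path = source if isinstance(source, str) else None
    if path is None:
        raise ValueError("SAM ingestion requires a file path")
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if ":" not in rec.query_name:
                raise FormatError(f"record {rec.query_name}: no UMI suffix in read ID")
            umi = rec.query_name.rsplit(":", 1)[1]
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            rg = rec.get_tag("RG") if rec.has_tag("RG") else "library"
            out.append(
                AlignedRead(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    umi=umi,
                    replicate=str(rg),
                    unique=not rec.is_secondary and nh == 1,
                )
            )
    return out


def write_alignments_tsv(reads: Iterable[AlignedRead], stream: TextIO) -> None:
    for r in reads:
        stream.write(
            f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.umi}\t{r.replicate}\n"
        )


def dedup(
    reads: Sequence[AlignedRead], anchor: str = "five_prime"
) -> tuple[list[AlignedRead], int]:
    """Collapse PCR duplicates: identical mapping start position + UMI.

    Groups are keyed by (chrom, strand, anchor position, UMI); the first read
    in input order represents each group.  ``anchor`` is the strand-aware 5'
    end by default (truncation biology anchors the 5' end), or the left
    genomic coordinate with ``anchor="left_coordinate"``.
    Idempotent and order-stable.
    """
    if anchor not in ("five_prime", "left_coordinate"):
        raise ValueError(f"unknown dedup anchor {anchor!r}")
    seen: set[tuple] = set()
    kept: list[AlignedRead] = []
    for r in reads:
        pos = r.five_prime_pos if anchor == "five_prime" else r.start
        key = (r.chrom, r.strand, pos, r.umi)
        if key not in seen:
            seen.add(key)
            kept.append(r)
    return kept, len(reads) - len(kept)


def xlink_site(
    read: AlignedRead, chrom_lengths: Mapping[str, int] | None = None
) -> TrackPoint | None:
    """Crosslink position of one uniquely mapped read; None if out of bounds.

    Plus strand: ``start - 1``; minus strand: the alignment ``end`` -- in both
    cases the nucleotide immediately 5' of the read's 5' end in read
    orientation.
    """
    if not read.unique:
        raise ValueError(f"{read.read_id}: crosslink sites require unique mappings")
    pos = read.start - 1 if read.strand == "+" else read.end
    if pos < 0:
        return None
    if chrom_lengths is not None and pos >= chrom_lengths[read.chrom]:
        return None
    return TrackPoint(read.chrom, pos, read.strand, 1)


class CrosslinkTrack:
    """Strand-aware per-position crosslink event counts for one library."""

    def __init__(self, label: str, counts: Mapping[tuple[str, str, int], int] | None = None):
        self.label = label
        # (chrom, strand, pos) -> count
        self.counts: dict[tuple[str, str, int], int] = dict(counts or {})

    def add(self, chrom: str, strand: str, pos: int, count: int = 1) -> None:
        self.counts[(chrom, strand, pos)] = self.counts.get((chrom, strand, pos), 0) + count

    def total_events(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def count_at(self, chrom: str, strand: str, pos: int) -> int:
        return self.counts.get((chrom, strand, pos), 0)

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> int:
        return sum(self.counts.get((chrom, strand, p), 0) for p in range(start, end))

    def positions_in_window(self, chrom: str, strand: str, start: int, end: int) -> list[int]:
        return [p for p in range(start, end) if (chrom, strand, p) in self.counts]

    def to_points(self, strand: str | None = None) -> list[TrackPoint]:
        """Sorted track points, optionally restricted to one strand."""
        keys = sorted(k for k in self.counts if strand is None or k[1] == strand)
        return [TrackPoint(c, p, s, self.counts[(c, s, p)]) for c, s, p in keys]


def build_track(
    reads: Sequence[AlignedRead],
    label: str,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[CrosslinkTrack, int]:
    """Accumulate crosslink sites of deduplicated reads into a track.

    Returns the track and the number of reads discarded because their
    crosslink position fell outside the chromosome.
    """
    track = CrosslinkTrack(label)
    discarded = 0
    for r in reads:
        if not r.unique:
            continue
        pt = xlink_site(r, chrom_lengths)
        if pt is None:
            discarded += 1
            continue
        track.add(pt.chrom, pt.strand, pt.pos)
    if discarded:
        log.warning("%s: %d reads with out-of-bounds crosslink discarded", label, discarded)
    return track, discarded


def merge_tracks(tracks: Sequence[CrosslinkTrack], label: str = "merged") -> CrosslinkTrack:
    """Pointwise sum of per-library tracks; library labels must be distinct."""
    labels = [t.label for t in tracks]
    if len(set(labels)) != len(labels):
        raise ValueError(f"colliding library labels: {labels}")
    merged = CrosslinkTrack(label)
    for t in tracks:
        for key, count in t.counts.items():
            merged.counts[key] = merged.counts.get(key, 0) + count
    return merged
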