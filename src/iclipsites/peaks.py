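"""Peak resolution and fixed-width binding-site construction.

A binding site is a 9-nt window: a resolved single-nucleotide crosslink peak
extended by 4 nt in both directions.  Runs of directly adjacent peaks are
first reduced to their best-scoring member; windows holding only a single
crosslinked position are discarded as likely mapping artifacts.

External narrow-peak caller output (single-nucleotide BED6) is ingested
as-is.  ``call_peaks_naive`` is a deliberately simple local-enrichment
stand-in for such a caller -- not a reimplementation of any HMM -- and its
defaults (min_count 2, flank 15, min_fold 3) are this package's own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence, TextIO

from .crosslinks import CrosslinkTrack
from .formats import FormatError, GenomicInterval, parse_bed

log = logging.getLogger(__name__)

DEFAULT_EXT = 4  # nt added each side of the peak -> 9-nt window
DEFAULT_MIN_XL_POSITIONS = 2


@dataclass(frozen=True)
class Peak:
    chrom: str
    pos: int
    strand: str
    score: float

    @property
    def sort_key(self):
        return (self.chrom, self.strand, self.pos)


@dataclass
class BindingSite:
    """A fixed-width window around a resolved crosslink peak."""

    chrom: str
    start: int
    end: int
    strand: str
    peak_pos: int
    score: float
    n_xl_positions: int = 0
    counts_by_replicate: dict[str, int] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "BindingSite") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )

    def to_interval(self, name: str | None = None, score: float | None = None) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            self.start,
            self.end,
            self.strand,
            str(self.peak_pos) if name is None else name,
            self.score if score is None else score,
        )


def ingest_peaks(source) -> list[Peak]:
    """Read single-nucleotide peaks from 6-column BED (narrow-peak style)."""
    peaks = []
    for iv in parse_bed(source, n_cols=6):
        if iv.width != 1:
            raise FormatError(
                f"peak {iv.chrom}:{iv.start}-{iv.end} is not single-nucleotide; "
                "supply narrow-peak calls"
            )
        peaks.append(Peak(iv.chrom, iv.start, iv.strand, iv.score))
    return peaks


def call_peaks_naive(
    track: CrosslinkTrack,
    min_count: int = 2,
    flank: int = 15,
    min_fold: float = 3.0,
) -> list[Peak]:
    """Local-enrichment peak calling on a crosslink track (caller stand-in).

    A position is a peak when its count is at least ``min_count`` and at
    least ``min_fold`` times the mean count over the ``+-flank`` neighbourhood
    (the position itself excluded, plus a pseudocount of 1).  The fold ratio
    is the peak score.  Output sorted by (chrom, strand, pos).
    """
    if min_count < 1 or flank < 1:
        raise ValueError("min_count and flank must be >= 1")
    peaks = []
    for (chrom, strand, pos), count in track.counts.items():
        if count < min_count:
            continue
        neighbourhood = sum(
            track.counts.get((chrom, strand, p), 0)
            for p in range(pos - flank, pos + flank + 1)
            if p != pos
        )
        mean = neighbourhood / (2 * flank)
        fold = count / (mean + 1.0)
        if fold >= min_fold:
            peaks.append(Peak(chrom, pos, strand, round(fold, 6)))
    peaks.sort(key=lambda p: p.sort_key)
    return peaks


def resolve_adjacent(peaks: Sequence[Peak]) -> list[Peak]:
    """Reduce each maximal run of directly adjacent peaks to its best member.

    Peaks at single-nucleotide resolution that sit at genomic distance 1 on
    the same chrom+strand form one run; only the highest-scoring peak of each
    run is retained (ties: the 5'-most, i.e. smallest, position).  Input must
    be sorted by (chrom, strand, pos).
    """
    if any(
        peaks[i].sort_key >= peaks[i + 1].sort_key for i in range(len(peaks) - 1)
    ):
        raise ValueError("peaks must be sorted by (chrom, strand, pos)")
    out: list[Peak] = []
    run: list[Peak] = []

    def flush():
        if run:
            out.append(max(run, key=lambda p: (p.score, -p.pos)))

    for p in peaks:
        if run and (p.chrom, p.strand) == (run[-1].chrom, run[-1].strand) and p.pos == run[-1].pos + 1:
            run.append(p)
        else:
            flush()
            run = [p]
    flush()
    return out


def make_sites(
    peaks: Sequence[Peak],
    ext: int = DEFAULT_EXT,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[BindingSite]:
    """Extend each resolved peak by ``ext`` nt on both sides.

    Windows that would be clipped at chromosome bounds are dropped (with a
    warning): the site width must stay exactly ``2*ext + 1``.
    """
    if ext < 0:
        raise ValueError("ext must be >= 0")
    sites = []
    dropped = 0
    for p in peaks:
        start, end = p.pos - ext, p.pos + ext + 1
        if start < 0 or (
            chrom_lengths is not None and end > chrom_lengths[p.chrom]
        ):
            dropped += 1
            continue
        sites.append(BindingSite(p.chrom, start, end, p.strand, p.pos, p.score))
    if dropped:
        log.warning("%d sites dropped at chromosome bounds", dropped)
    return sites


def filter_single_xl(
    sites: Sequence[BindingSite],
    merged_track: CrosslinkTrack,
    min_positions: int = DEFAULT_MIN_XL_POSITIONS,
) -> list[BindingSite]:
    """Drop windows supported by fewer than ``min_positions`` distinct
    crosslinked positions on the merged (across-replicate) track.

    Single-position windows are considered mapping artifacts.  The number of
    distinct crosslinked positions is recorded on each retained site.
    """
    retained = []
    for s in sites:
        n = len(merged_track.positions_in_window(s.chrom, s.strand, s.start, s.end))
        if n >= min_positions:
            s.n_xl_positions = n
            retained.append(s)
    return retained


def write_peaks_bed(peaks: Sequence[Peak], stream: TextIO) -> None:
    from .formats import write_bed

    write_bed(
        [
            GenomicInterval(p.chrom, p.pos, p.pos + 1, p.strand, f"peak_{i}", round(p.score, 6))
            for i, p in enumerate(peaks, start=1)
        ],
        stream,
    )


def write_sites_bed(sites: Sequence[BindingSite], stream: TextIO) -> None:
    from .formats import write_bed

    write_bed([s.to_interval() for s in sites], stream)
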