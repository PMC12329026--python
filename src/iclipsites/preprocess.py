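"""Read-level cleanup: 3' adapter trimming, barcode demultiplexing with UMI
extraction, and the minimum-length filter.

The barcode layout follows the iCLIP RT-primer design: a 9-nt prefix
``NN BBBB NNN`` where N positions are random (UMI) nucleotides and B positions
carry the experimental (replicate) barcode.  The 5 UMI nucleotides are kept
both as a record field and appended to the read ID after a ':' separator, so
downstream deduplication also works on externally preprocessed files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .formats import SeqRead

DEFAULT_LAYOUT = "NNBBBBNNN"
DEFAULT_MIN_LEN = 24  # below this, unique genomic mapping is unreliable

#: Replicate barcodes of the AtGRP8 iCLIP RT primers (GRP8clip1-3).
DEFAULT_BARCODES: Mapping[str, str] = {"ACAA": "rep1", "CCGG": "rep2", "GACC": "rep3"}


@dataclass(frozen=True)
class BarcodeScheme:
    """Positional layout of UMI (N) and experimental barcode (B) bases."""

    layout: str = DEFAULT_LAYOUT
    barcode_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_BARCODES))

    def __post_init__(self):
        if not self.layout or set(self.layout) - {"N", "B"}:
            raise ValueError("layout must be a non-empty string over {N, B}")
        n_b = self.layout.count("B")
        for bc in self.barcode_map:
            if len(bc) != n_b:
                raise ValueError(f"barcode {bc!r} does not match layout {self.layout!r}")
        if len(set(self.barcode_map)) != len(self.barcode_map):
            raise ValueError("duplicate barcodes")

    @property
    def barcode_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.layout) if c == "B")

    @property
    def umi_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.layout) if c == "N")

    @property
    def umi_len(self) -> int:
        return len(self.umi_positions)


@dataclass(frozen=True)
class ProcessedRead:
    """A demultiplexed read: insert only, with its UMI and replicate label."""

    read_id: str
    insert: str
    quals: tuple[int, ...]
    umi: str
    replicate: str

    def __post_init__(self):
        if len(self.insert) != len(self.quals):
            raise ValueError(f"{self.read_id}: insert/quality length mismatch")


def find_adapter(
    seq: str, adapter: str, min_overlap: int = 3, max_error_rate: float = 0.1
) -> int:
    """Return the cut index of the leftmost qualifying adapter occurrence.

    Semi-global scan: a suffix of ``seq`` is matched against a prefix of
    ``adapter``; the occurrence qualifies if the overlap is at least
    ``min_overlap`` and the mismatch fraction is at most ``max_error_rate``.
    Indels are not modelled.  Returns ``len(seq)`` when nothing qualifies.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not (0 <= max_error_rate < 0.5):
        raise ValueError("max_error_rate must be in [0, 0.5)")
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        overlap = min(n - i, len(adapter))
        mismatches = sum(a != b for a, b in zip(seq[i : i + overlap], adapter[:overlap]))
        if mismatches <= max_error_rate * overlap:
            return i
    return n


def trim_adapter(
    seq: str, adapter: str, min_overlap: int = 3, max_error_rate: float = 0.1
) -> str:
    """Remove the 3' adapter from ``seq`` (everything from its first
    qualifying occurrence onward); pure and idempotent."""
    return seq[: find_adapter(seq, adapter, min_overlap, max_error_rate)]


def trim_record(
    rec: SeqRead, adapter: str, min_overlap: int = 3, max_error_rate: float = 0.1
) -> SeqRead:
    cut = find_adapter(rec.seq, adapter, min_overlap, max_error_rate)
    return SeqRead(rec.id, rec.seq[:cut], rec.quals[:cut])


def demultiplex_read(rec: SeqRead, scheme: BarcodeScheme) -> ProcessedRead | None:
    """Assign a read to a replicate by exact barcode match; None = unassigned.

    The UMI (all N-position bases, in read order) is appended to the read ID
    after ':'; the insert is the remainder after the layout prefix.
    """
    layout_len = len(scheme.layout)
    if len(rec.seq) <= layout_len:
        return None
    barcode = "".join(rec.seq[i] for i in scheme.barcode_positions)
    replicate = scheme.barcode_map.get(barcode)
    if replicate is None:
        return None
    umi = "".join(rec.seq[i] for i in scheme.umi_positions)
    return ProcessedRead(
        read_id=f"{rec.id}:{umi}",
        insert=rec.seq[layout_len:],
        quals=tuple(rec.quals[layout_len:]) if rec.quals else tuple([40] * (len(rec.seq) - layout_len)),
        umi=umi,
        replicate=replicate,
    )


def demultiplex(
    records: Iterable[SeqRead], scheme: BarcodeScheme
) -> tuple[dict[str, list[ProcessedRead]], int]:
    """Partition reads into per-replicate sinks plus an unassigned count.

    Every input read lands in exactly one sink.
    """
    sinks: dict[str, list[ProcessedRead]] = {r: [] for r in scheme.barcode_map.values()}
    unassigned = 0
    for rec in records:
        pr = demultiplex_read(rec, scheme)
        if pr is None:
            unassigned += 1
        else:
            sinks[pr.replicate].append(pr)
    return sinks, unassigned


def length_filter(
    reads: Sequence[ProcessedRead], min_len: int = DEFAULT_MIN_LEN
) -> tuple[list[ProcessedRead], int]:
    """Drop inserts shorter than ``min_len`` nucleotides; order preserved."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    retained = [r for r in reads if len(r.insert) >= min_len]
    return retained, len(reads) - len(retained)


def summarize_reads(reads: Sequence) -> dict:
    """Per-library read summary: n, mean base quality, mean/sd read length.

    Accepts anything exposing ``.quals`` and a sequence attribute (``insert``
    for processed reads, ``seq`` for raw records).  Empty input reports NaN
    statistics (rendered as NA in text reports).
    """
    n = len(reads)
    if n == 0:
        return {"n": 0, "mean_quality": math.nan, "mean_length": math.nan, "sd_length": math.nan}
    lengths = []
    qual_sum = 0
    qual_n = 0
    for r in reads:
        seq = getattr(r, "insert", None)
        if seq is None:
            seq = r.seq
        lengths.append(len(seq))
        qual_sum += sum(r.quals)
        qual_n += len(r.quals)
    mean_len = sum(lengths) / n
    var = sum((x - mean_len) ** 2 for x in lengths) / n
    return {
        "n": n,
        "mean_quality": (qual_sum / qual_n) if qual_n else math.nan,
        "mean_length": mean_len,
        "sd_length": math.sqrt(var),
    }
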