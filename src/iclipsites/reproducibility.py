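"""Replicate-reproducibility classification and control subtraction.

Per replicate, a support threshold is the 30% quantile (empirical CDF
inversion, no interpolation) of the strictly positive crosslink counts over
all binding-site windows.  A site is reproducible when its count reaches the
threshold in at least k of n replicates (default 2 of 3).  Sites overlapping
any site called from control libraries (RNA-binding-dead or GFP-only) by at
least one same-strand nucleotide are subtracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .crosslinks import CrosslinkTrack
from .peaks import BindingSite

DEFAULT_QUANTILE = 0.30
DEFAULT_K_OF_N = 2


@dataclass
class SupportMatrix:
    """Sites x replicates crosslink-support counts with derived thresholds."""

    sites: list[BindingSite]
    replicates: list[str]
    counts: np.ndarray  # shape (n_sites, n_replicates), ints
    thresholds: dict[str, float] = field(default_factory=dict)
    supported: np.ndarray | None = None  # bool, same shape as counts

    def threshold_vector(self) -> np.ndarray:
        return np.array([self.thresholds[r] for r in self.replicates])


def count_support(
    sites: Sequence[BindingSite], replicate_tracks: Mapping[str, CrosslinkTrack]
) -> SupportMatrix:
    """Sum each replicate's crosslink events inside each site window."""
    replicates = list(replicate_tracks)
    for label, track in replicate_tracks.items():
        if track.label != label:
            raise ValueError(f"replicate label mismatch: {label} vs track {track.label}")
    counts = np.zeros((len(sites), len(replicates)), dtype=int)
    for i, s in enumerate(sites):
        for j, r in enumerate(replicates):
            counts[i, j] = replicate_tracks[r].window_sum(s.chrom, s.strand, s.start, s.end)
        s.counts_by_replicate = {r: int(counts[i, j]) for j, r in enumerate(replicates)}
    return SupportMatrix(sites=list(sites), replicates=replicates, counts=counts)


def quantile_threshold(counts_column: Iterable[int], q: float = DEFAULT_QUANTILE) -> float:
    """Empirical q-quantile over the strictly positive counts of one replicate.

    Returns the smallest observed positive count c such that the fraction of
    positive values <= c is at least q (type-1 empirical CDF inversion, no
    interpolation).  A column without positive counts yields +inf: that
    replicate supports nothing.
    """
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    positive = sorted(c for c in counts_column if c > 0)
    if not positive:
        return math.inf
    idx = math.ceil(q * len(positive)) - 1
    return float(positive[idx])


def classify_reproducible(
    matrix: SupportMatrix,
    k: int = DEFAULT_K_OF_N,
    q: float = DEFAULT_QUANTILE,
    cmp: str = "ge",
) -> tuple[np.ndarray, np.ndarray, dict[int, int]]:
    """Flag sites supported at/above the per-replicate quantile threshold in
    at least k replicates.

    Fills ``matrix.thresholds`` and ``matrix.supported`` in place and returns
    (reproducible flags, per-site number of supporting replicates, histogram
    of sites by number of supporting replicates).  The histogram's 0 bin
    tallies sites below threshold in every replicate.  The printed thresholds
    are minimal supporting counts, so attainment passes (``>=``); a strict
    comparator is available via ``cmp="gt"``.
    """
    n_reps = len(matrix.replicates)
    if not (1 <= k <= n_reps):
        raise ValueError("k must be between 1 and the number of replicates")
    if cmp not in ("ge", "gt"):
        raise ValueError("cmp must be 'ge' or 'gt'")
    matrix.thresholds = {
        r: quantile_threshold(matrix.counts[:, j], q)
        for j, r in enumerate(matrix.replicates)
    }
    thr = matrix.threshold_vector()
    if cmp == "ge":
        matrix.supported = matrix.counts >= thr
    else:
        matrix.supported = matrix.counts > thr
    n_supported = matrix.supported.sum(axis=1)
    flags = n_supported >= k
    histogram = {i: int((n_supported == i).sum()) for i in range(n_reps + 1)}
    return flags, n_supported, histogram


def subtract_controls(
    sites: Sequence[BindingSite], control_site_sets: Sequence[Sequence[BindingSite]]
) -> list[BindingSite]:
    """Remove sites sharing >= 1 same-strand nucleotide with any control site.

    Controls are site sets produced by the same pipeline from background-only
    libraries; union semantics across control sets.
    """
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for cset in control_site_sets:
        for c in cset:
            by_key.setdefault((c.chrom, c.strand), []).append((c.start, c.end))
    retained = []
    for s in sites:
        spans = by_key.get((s.chrom, s.strand), ())
        if not any(s.start < ce and cs < s.end for cs, ce in spans):
            retained.append(s)
    return retained


def set_overlap(ids_a: Iterable, ids_b: Iterable) -> dict[str, int]:
    """Transcript-level set algebra between two target collections.

    Accepts iterables of transcript ids, or of objects carrying a
    ``transcript_id`` attribute.
    """

    def to_ids(items) -> set:
        out = set()
        for x in items:
            out.add(getattr(x, "transcript_id", x))
        return out

    a, b = to_ids(ids_a), to_ids(ids_b)
    return {
        "only_a": len(a - b),
        "only_b": len(b - a),
        "shared": len(a & b),
    }
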