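"""Sequence windows around binding sites and k-mer motif enrichment.

Site windows are extended by 30 nt on both sides and extracted strand
specifically (minus-strand sites reverse-complemented).  Enrichment is an
exhaustive k-mer z-score against per-sequence dinucleotide-preserving
shuffles -- a deliberately simple, fully documented stand-in for an external
discovery tool's objective, producing the same deliverables: ranked enriched
motifs plus each motif's positional density relative to site centres.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats import revcomp
from .peaks import BindingSite

log = logging.getLogger(__name__)

DEFAULT_EXT = 30
DEFAULT_KS = (4, 5, 6)
MAX_N_FRACTION = 0.10

ALPHABET = "ACGT"


def _chrom_seq(genome, chrom: str) -> str:
    """Uppercase chromosome sequence from a dict or pyfaidx-like object."""
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} absent from genome") from exc
    return str(seq).upper()


def extract_site_sequences(
    sites: Sequence[BindingSite], genome: Mapping[str, str], ext: int = DEFAULT_EXT
) -> list[str]:
    """Strand-specific sequence of each site window extended by ``ext`` nt.

    Output length is site width + 2*ext for every sequence (69 at defaults);
    sites whose extended window leaves the chromosome are dropped with a
    warning.  Minus-strand windows are reverse-complemented so all sequences
    read 5'->3' along the bound transcript.
    """
    out = []
    dropped = 0
    for s in sites:
        seq = _chrom_seq(genome, s.chrom)
        start, end = s.start - ext, s.end + ext
        if start < 0 or end > len(seq):
            dropped += 1
            continue
        window = seq[start:end]
        out.append(window if s.strand == "+" else revcomp(window))
    if dropped:
        log.warning("%d sites dropped: extended window out of bounds", dropped)
    return out


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 64) -> str:
    """Shuffle a sequence preserving its exact dinucleotide composition.

    Eulerian-walk shuffle on the dinucleotide transition multigraph: each
    vertex's out-edge list is permuted, then a walk from the original first
    base consumes edges in list order; walks that strand early are rejected
    and retried.  Any complete walk preserves all dinucleotide counts.
    """
    n = len(seq)
    if n <= 2:
        return seq
    for _ in range(max_tries):
        adj: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            adj.setdefault(a, []).append(b)
        for targets in adj.values():
            rng.shuffle(targets)
        walk = [seq[0]]
        cursor = {v: 0 for v in adj}
        v = seq[0]
        while True:
            targets = adj.get(v)
            if targets is None or cursor[v] >= len(targets):
                break
            nxt = targets[cursor[v]]
            cursor[v] += 1
            walk.append(nxt)
            v = nxt
        if len(walk) == n:
            return "".join(walk)
    return seq  # pathological composition; keep original


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


@dataclass
class MotifHit:
    """One enriched k-mer with its shuffle-background statistics."""

    kmer: str
    fg_count: int
    bg_mean: float
    bg_sd: float
    zscore: float
    density: np.ndarray | None = None  # positional density over offsets
    offsets: np.ndarray | None = None


def _count_kmers(seqs: Sequence[str], k: int) -> Counter:
    counts: Counter = Counter()
    valid = set(ALPHABET)
    for s in seqs:
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if set(kmer) <= valid:
                counts[kmer] += 1
    return counts


def _drop_ambiguous(seqs: Sequence[str]) -> list[str]:
    kept = [s for s in seqs if s.count("N") <= MAX_N_FRACTION * len(s)]
    if len(kept) < len(seqs):
        log.warning("%d windows dropped for >10%% ambiguous bases", len(seqs) - len(kept))
    return kept


def kmer_enrichment(
    seqs: Sequence[str],
    k: int,
    n_shuffles: int = 50,
    seed: int | np.random.Generator = 0,
    shuffle: str = "dinucleotide",
) -> list[MotifHit]:
    """Rank k-mers by z-score against dinucleotide-shuffled backgrounds.

    The foreground count of each k-mer is compared with its mean and SD over
    ``n_shuffles`` independently shuffled copies of the corpus; z = (fg -
    bg_mean) / max(bg_sd, 1), the SD floor guarding degenerate (single-letter)
    corpora.  Ranking is by z descending, ties lexicographic; identical seeds
    give identical rankings, and results are invariant to input order.
    """
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("all sequences must have equal length")
    if lengths and k > max(lengths):
        raise ValueError("k exceeds sequence length")
    shuffler = {"dinucleotide": dinucleotide_shuffle, "mononucleotide": mononucleotide_shuffle}[shuffle]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    seqs = _drop_ambiguous(sorted(seqs))  # canonical order: order-invariant output
    fg = _count_kmers(seqs, k)

    bg_rounds: list[Counter] = []
    for _ in range(n_shuffles):
        shuffled = [shuffler(s, rng) for s in seqs]
        bg_rounds.append(_count_kmers(shuffled, k))

    kmers = sorted(set(fg) | set().union(*bg_rounds) if bg_rounds else set(fg))
    hits = []
    for kmer in kmers:
        bg = np.array([r.get(kmer, 0) for r in bg_rounds], dtype=float)
        bg_mean, bg_sd = float(bg.mean()), float(bg.std())
        z = (fg.get(kmer, 0) - bg_mean) / max(bg_sd, 1.0)
        hits.append(MotifHit(kmer, fg.get(kmer, 0), bg_mean, bg_sd, z))
    hits.sort(key=lambda h: (-h.zscore, h.kmer))
    return hits


def positional_density(kmer: str, seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray, int]:
    """Distribution of a k-mer's start offsets relative to sequence centres.

    Offsets are measured from the centre position (L-1)//2 of the equal-length
    sequences; the histogram is normalized to sum 1.  Returns (offsets,
    density, n_hits); with no hits the profile is all-zero.
    """
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("all sequences must have equal length")
    L = lengths.pop()
    k = len(kmer)
    center = (L - 1) // 2
    offsets = np.arange(-center, L - k + 1 - center)
    counts = np.zeros(len(offsets), dtype=float)
    n_hits = 0
    for s in seqs:
        start = 0
        while True:
            i = s.find(kmer, start)
            if i == -1:
                break
            counts[i] += 1  # i - center - offsets[0] == i
            n_hits += 1
            start = i + 1
    density = counts / n_hits if n_hits else counts
    return offsets, density, n_hits
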