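"""Transcript-region assignment of binding sites and region distributions.

Each site is anchored at its peak position (the window centre) and located
within same-strand representative gene models; among all features covering
that nucleotide, one label is chosen by a fixed priority.  The resulting
per-region site percentages are compared against the share of cumulative
feature length in the annotation (the genomic-length background).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .formats import GeneModel, _merge_intervals
from .peaks import BindingSite

FIVE_PRIME_UTR = "five_prime_utr"
CDS = "cds"
INTRON = "intron"
THREE_PRIME_UTR = "three_prime_utr"
NONCODING = "noncoding"
INTERGENIC = "intergenic"

#: Labels a site inside a transcript can receive, in assignment priority
#: order (UTRs outrank CDS: boundary-straddling centres are resolved toward
#: the untranslated regions, where this protein family predominantly binds).
PRIORITY = (THREE_PRIME_UTR, FIVE_PRIME_UTR, CDS, INTRON, NONCODING)

TRANSCRIPT_LABELS = frozenset(PRIORITY)


def model_features(model: GeneModel) -> list[tuple[str, int, int]]:
    """Derived (label, start, end) features of one gene model."""
    feats: list[tuple[str, int, int]] = []
    if model.biotype == "coding":
        for s, e in model.five_prime_utr():
            feats.append((FIVE_PRIME_UTR, s, e))
        for s, e in model.cds:
            feats.append((CDS, s, e))
        for s, e in model.three_prime_utr():
            feats.append((THREE_PRIME_UTR, s, e))
    else:
        for s, e in model.exons:
            feats.append((NONCODING, s, e))
    for s, e in model.introns():
        feats.append((INTRON, s, e))
    return feats


class RegionIndex:
    """Gene models indexed by (chrom, strand) for point lookups."""

    def __init__(self, models: Iterable[GeneModel]):
        self._by_key: dict[tuple[str, str], list[GeneModel]] = {}
        for m in models:
            self._by_key.setdefault((m.chrom, m.strand), []).append(m)
        self.models = [m for ms in self._by_key.values() for m in ms]

    def covering(self, chrom: str, strand: str, pos: int) -> list[tuple[str, str]]:
        """(label, transcript_id) of every feature covering the position,
        same strand only (iCLIP signal is strand-specific)."""
        hits = []
        for m in self._by_key.get((chrom, strand), ()):
            if not (m.start <= pos < m.end):
                continue
            for label, s, e in model_features(m):
                if s <= pos < e:
                    hits.append((label, m.transcript_id))
        return hits


def assign_region(
    site: BindingSite, index: RegionIndex, priority: Sequence[str] = PRIORITY
) -> tuple[str, str | None]:
    """Label one site by its peak position; (intergenic, None) if uncovered."""
    hits = index.covering(site.chrom, site.strand, site.peak_pos)
    if not hits:
        return INTERGENIC, None
    rank = {label: i for i, label in enumerate(priority)}
    label, transcript_id = min(hits, key=lambda h: (rank[h[0]], h[1]))
    return label, transcript_id


def annotate_sites(
    sites: Sequence[BindingSite],
    models: Sequence[GeneModel],
    priority: Sequence[str] = PRIORITY,
) -> list[tuple[BindingSite, str, str | None]]:
    index = RegionIndex(models)
    return [(s, *assign_region(s, index, priority)) for s in sites]


@dataclass
class RegionDistribution:
    """Observed site shares per region vs cumulative-feature-length shares."""

    site_count: dict[str, int]
    site_percent: dict[str, float]
    background_percent: dict[str, float]


def background_lengths(models: Sequence[GeneModel]) -> dict[str, int]:
    """Cumulative genomic length per region label across all models.

    Overlapping intervals within one label are merged before summing.
    """
    per_label: dict[str, list[tuple[str, int, int]]] = {}
    for m in models:
        for label, s, e in model_features(m):
            per_label.setdefault(label, []).append((m.chrom, s, e))
    out = {}
    for label, ivs in per_label.items():
        total = 0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in ivs:
            by_chrom.setdefault(chrom, []).append((s, e))
        for spans in by_chrom.values():
            total += sum(e - s for s, e in _merge_intervals(spans))
        out[label] = total
    return out


def region_distribution(
    assignments: Sequence[tuple[BindingSite, str, str | None]],
    models: Sequence[GeneModel],
    include_intergenic: bool = False,
) -> RegionDistribution:
    """Per-region site percentages and the genomic-length background.

    Intergenic sites are excluded from both numerator and background by
    default (the background is annotation-derived feature length, which has
    no intergenic share).
    """
    labels = [lab for _, lab, _ in assignments]
    if not include_intergenic:
        labels = [lab for lab in labels if lab != INTERGENIC]
    if not labels:
        raise ValueError("no assigned sites to summarize")
    site_count = {lab: labels.count(lab) for lab in sorted(set(labels))}
    total = sum(site_count.values())
    site_percent = {lab: 100.0 * n / total for lab, n in site_count.items()}

    bg = background_lengths(models)
    bg_total = sum(bg.values())
    background_percent = {lab: 100.0 * n / bg_total for lab, n in bg.items()}
    return RegionDistribution(site_count, site_percent, background_percent)


def target_transcripts(
    assignments: Sequence[tuple[BindingSite, str, str | None]]
) -> list[str]:
    """Distinct transcripts carrying at least one (reproducible) site."""
    return sorted({tid for _, _, tid in assignments if tid is not None})
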