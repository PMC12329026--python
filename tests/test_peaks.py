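import numpy as np
import pytest

from iclipsites.crosslinks import CrosslinkTrack
from iclipsites.formats import FormatError
from iclipsites.peaks import (
    Peak,
    call_peaks_naive,
    filter_single_xl,
    ingest_peaks,
    make_sites,
    resolve_adjacent,
)


def track_from(counts: dict[int, int], strand="+", label="t") -> CrosslinkTrack:
    return CrosslinkTrack(label, {("chr1", strand, p): n for p, n in counts.items()})


class TestIngestPeaks:
    def test_bed6_single_nucleotide(self):
        import io

        (p,) = ingest_peaks(io.StringIO("chr1\t99\t100\tp\t3.2\t+\n"))
        assert (p.chrom, p.pos, p.strand, p.score) == ("chr1", 99, "+", 3.2)

    def test_wide_interval_rejected(self):
        import io

        with pytest.raises(FormatError, match="narrow-peak"):
            ingest_peaks(io.StringIO("chr1\t99\t101\tp\t3.2\t+\n"))


class TestNaiveCaller:
    def test_flat_track_has_no_peaks(self):
        flat = track_from({p: 1 for p in range(100, 200)})
        assert call_peaks_naive(flat, min_count=1, min_fold=3.0) == []

    def test_isolated_spike_is_a_peak(self):
        (p,) = call_peaks_naive(track_from({150: 10}))
        assert p.pos == 150 and p.score == 10.0

    def test_recovers_planted_peaks(self, sim_fixture, pipeline_result):
        called = {(p.chrom, p.strand, p.pos) for p in pipeline_result.peaks_resolved}
        recovered = 0
        for s in sim_fixture.truth.sites:
            if any(
                (s.chrom, s.strand, s.peak_pos + d) in called for d in range(-4, 5)
            ):
                recovered += 1
        assert recovered / len(sim_fixture.truth.sites) >= 0.90


def brute_force_resolve(peaks):
    """Independent grouping oracle: connected components under distance-1
    adjacency, each reduced to (max score, then smallest position)."""
    groups = []
    for p in sorted(peaks, key=lambda p: p.sort_key):
        if (
            groups
            and groups[-1][-1].chrom == p.chrom
            and groups[-1][-1].strand == p.strand
            and p.pos - groups[-1][-1].pos == 1
        ):
            groups[-1].append(p)
        else:
            groups.append([p])
    return [sorted(g, key=lambda p: (-p.score, p.pos))[0] for g in groups]


class TestResolveAdjacent:
    def test_run_of_three_keeps_best(self):
        peaks = [Peak("chr1", 10, "+", 2.0), Peak("chr1", 11, "+", 5.0), Peak("chr1", 12, "+", 3.0)]
        assert [p.pos for p in resolve_adjacent(peaks)] == [11]

    def test_gap_of_one_not_adjacent(self):
        peaks = [Peak("chr1", 10, "+", 2.0), Peak("chr1", 12, "+", 5.0)]
        assert len(resolve_adjacent(peaks)) == 2

    def test_tie_keeps_five_prime_most(self):
        peaks = [Peak("chr1", 10, "+", 2.0), Peak("chr1", 11, "+", 2.0)]
        assert [p.pos for p in resolve_adjacent(peaks)] == [10]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        unique = {}
        for p in rng.integers(0, 300, size=150):
            strand = "+" if rng.random() < 0.5 else "-"
            unique.setdefault(("chr1", strand, int(p)), float(rng.integers(1, 6)))
        peaks = sorted(
            (Peak(c, p, s, score) for (c, s, p), score in unique.items()),
            key=lambda p: p.sort_key,
        )
        assert resolve_adjacent(peaks) == brute_force_resolve(peaks)

    def test_no_adjacent_pair_in_output(self):
        rng = np.random.default_rng(4)
        unique = {int(p): float(rng.random()) for p in rng.integers(0, 100, 80)}
        peaks = sorted(
            (Peak("chr1", p, "+", score) for p, score in unique.items()),
            key=lambda p: p.sort_key,
        )
        resolved = resolve_adjacent(peaks)
        for a, b in zip(resolved, resolved[1:]):
            if (a.chrom, a.strand) == (b.chrom, b.strand):
                assert b.pos - a.pos > 1


class TestMakeSites:
    def test_nine_nucleotide_window(self):
        (s,) = make_sites([Peak("chr1", 99, "+", 1.0)])
        assert (s.start, s.end, s.width, s.peak_pos) == (95, 104, 9, 99)

    def test_zero_extension(self):
        (s,) = make_sites([Peak("chr1", 99, "+", 1.0)], ext=0)
        assert (s.start, s.end) == (99, 100)

    def test_clipped_windows_dropped(self):
        assert make_sites([Peak("chr1", 2, "+", 1.0)], ext=4) == []
        assert make_sites([Peak("chr1", 98, "+", 1.0)], ext=4, chrom_lengths={"chr1": 100}) == []


class TestSingleCrosslinkFilter:
    def test_single_position_excluded_regardless_of_count(self):
        sites = make_sites([Peak("chr1", 99, "+", 1.0)])
        assert filter_single_xl(sites, track_from({99: 50})) == []

    def test_two_positions_count_one_each_retained(self):
        sites = make_sites([Peak("chr1", 99, "+", 1.0)])
        kept = filter_single_xl(sites, track_from({99: 1, 101: 1}))
        assert len(kept) == 1 and kept[0].n_xl_positions == 2

    def test_brute_force_distinct_position_recount(self):
        rng = np.random.default_rng(7)
        track = track_from({int(p): int(rng.integers(1, 5)) for p in rng.integers(0, 2000, 400)})
        sites = make_sites(
            [Peak("chr1", int(p), "+", 1.0) for p in sorted(set(rng.integers(10, 1990, 1000)))]
        )
        kept = filter_single_xl(sites, track)
        for s in kept:
            brute = sum(
                1 for p in range(s.start, s.end) if track.count_at("chr1", "+", p) >= 1
            )
            assert s.n_xl_positions == brute >= 2


class TestPipelineMonotonicity:
    def test_counts_never_increase_along_the_chain(self, pipeline_result):
        c = pipeline_result.manifest["stage_counts"]
        assert (
            c["peaks_called"]
            >= c["peaks_resolved"]
            >= c["sites"]
            >= c["sites_after_single_xl_filter"]
            >= c["sites_reproducible"]
            >= c["sites_final"]
        )

    def test_every_retained_site_is_nine_wide_and_centred(self, pipeline_result):
        for s in pipeline_result.sites_final:
            assert s.width == 9
            assert s.start + 4 == s.peak_pos
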