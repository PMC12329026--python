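from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iclipsites.formats import revcomp
from iclipsites.motifs import (
    dinucleotide_shuffle,
    extract_site_sequences,
    kmer_enrichment,
    positional_density,
)
from iclipsites.peaks import BindingSite


def site(start, strand="+", chrom="chr1"):
    return BindingSite(chrom, start, start + 9, strand, start + 4, 1.0)


def toy_genome(length=400, seed=0):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])}


class TestExtraction:
    def test_window_arithmetic(self):
        genome = toy_genome()
        (seq,) = extract_site_sequences([site(95)], genome, ext=30)
        assert seq == genome["chr1"][65:134]
        assert len(seq) == 69

    def test_minus_strand_is_reverse_complement(self):
        genome = toy_genome()
        (plus,) = extract_site_sequences([site(95, "+")], genome, ext=30)
        (minus,) = extract_site_sequences([site(95, "-")], genome, ext=30)
        assert minus == revcomp(plus)

    def test_out_of_bounds_window_dropped(self):
        assert extract_site_sequences([site(10)], toy_genome(), ext=30) == []

    def test_missing_chromosome_errors(self):
        with pytest.raises(KeyError, match="chr9"):
            extract_site_sequences([site(95, chrom="chr9")], toy_genome(), ext=30)

    def test_planted_motif_recovered_at_centre_offset(self):
        genome = toy_genome()
        seq = genome["chr1"]
        genome["chr1"] = seq[:97] + "TTCTT" + seq[102:]  # centred on peak 99
        (window,) = extract_site_sequences([site(95)], genome, ext=30)
        assert window[32:37] == "TTCTT"  # centre 34, start offset -2


def dinuc_counts(s):
    return Counter(s[i : i + 2] for i in range(len(s) - 1))


class TestDinucleotideShuffle:
    @settings(max_examples=40, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=80))
    def test_preserves_dinucleotide_composition(self, seq):
        shuffled = dinucleotide_shuffle(seq, np.random.default_rng(0))
        assert dinuc_counts(shuffled) == dinuc_counts(seq)
        assert (shuffled[0], len(shuffled)) == (seq[0], len(seq))

    def test_actually_shuffles(self):
        rng = np.random.default_rng(1)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        outcomes = {dinucleotide_shuffle(seq, rng) for _ in range(10)}
        assert len(outcomes) > 1


def motif_corpus(n=200, planted_frac=0.8, motif="TTCTT", length=41, seed=5, offset=None):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    center = (length - 1) // 2
    start = center - len(motif) // 2 if offset is None else center + offset
    seqs = []
    for i in range(n):
        s = "".join(bases[rng.integers(0, 4, length)])
        if i < planted_frac * n:
            s = s[:start] + motif + s[start + len(motif) :]
        seqs.append(s)
    return seqs


class TestEnrichment:
    def test_single_letter_corpus_is_shuffle_fixed_point(self):
        hits = kmer_enrichment(["A" * 30] * 5, k=4, n_shuffles=10, seed=0)
        (aaaa,) = [h for h in hits if h.kmer == "AAAA"]
        assert aaaa.zscore == 0.0

    def test_planted_motif_ranks_first(self):
        hits = kmer_enrichment(motif_corpus(), k=5, n_shuffles=20, seed=0)
        assert hits[0].kmer == "TTCTT"
        assert hits[0].fg_count >= 160

    def test_order_invariance(self):
        seqs = motif_corpus(n=40)
        a = kmer_enrichment(seqs, k=4, n_shuffles=10, seed=3)
        b = kmer_enrichment(seqs[::-1], k=4, n_shuffles=10, seed=3)
        assert [(h.kmer, h.zscore) for h in a] == [(h.kmer, h.zscore) for h in b]

    def test_seed_reproducibility(self):
        seqs = motif_corpus(n=40)
        a = kmer_enrichment(seqs, k=5, n_shuffles=12, seed=9)
        b = kmer_enrichment(seqs, k=5, n_shuffles=12, seed=9)
        assert [(h.kmer, h.zscore) for h in a] == [(h.kmer, h.zscore) for h in b]

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            kmer_enrichment(["ACGT", "ACG"], k=2, n_shuffles=10)


class TestPositionalDensity:
    def test_point_mass_at_centre_start_offset(self):
        seqs = motif_corpus(n=50, planted_frac=1.0)
        offsets, density, n_hits = positional_density("TTCTT", seqs)
        assert n_hits >= 50
        assert offsets[np.argmax(density)] == -2  # -floor(k/2)
        assert density.max() > 0.9

    def test_downstream_offset_mode(self):
        seqs = motif_corpus(n=50, planted_frac=1.0, motif="GTGAC", offset=10)
        offsets, density, _ = positional_density("GTGAC", seqs)
        assert offsets[np.argmax(density)] == 10

    def test_uniform_placement_is_flat(self):
        from scipy import stats

        rng = np.random.default_rng(11)
        length, motif = 41, "GGGG"
        seqs = []
        for _ in range(3000):
            start = int(rng.integers(0, length - 4 + 1))
            s = "".join(np.array(list("ACT"))[rng.integers(0, 3, length)])
            seqs.append(s[:start] + motif + s[start + 4 :])
        offsets, density, n_hits = positional_density(motif, seqs)
        counts = density * n_hits
        assert stats.chisquare(counts).pvalue > 0.01

    def test_density_sums_to_one_when_hits_exist(self):
        _, density, n_hits = positional_density("TTCTT", motif_corpus(n=30))
        assert n_hits > 0 and density.sum() == pytest.approx(1.0)

    def test_no_hits_gives_zero_profile(self):
        _, density, n_hits = positional_density("GGGGGG", ["ACATACATACA"] * 3)
        assert n_hits == 0 and not density.any()
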