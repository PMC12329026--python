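import json

import numpy as np
import pytest

from conftest import tree_digest
from iclipsites import annotation as ann
from iclipsites.crosslinks import dedup, ingest_alignments, xlink_site
from iclipsites.formats import parse_gene_models, read_fasta
from iclipsites.simulate import (
    end_to_end_fixture,
    make_genome_and_models,
    plant_sites,
    small_config,
)


def tiny_config(seed=0, **overrides):
    # no noncoding share: a 12-gene draw may contain no non-coding model
    defaults = dict(
        chrom_length=30_000,
        n_genes=12,
        n_sites=15,
        n_noise_sites=8,
        n_control_libs=1,
        region_bias={
            ann.FIVE_PRIME_UTR: 0.40,
            ann.THREE_PRIME_UTR: 0.30,
            ann.CDS: 0.20,
            ann.INTRON: 0.10,
        },
    )
    defaults.update(overrides)
    return small_config(seed, **defaults)


class TestGenomeAndModels:
    def test_models_satisfy_structural_invariants(self):
        cfg = tiny_config(2)
        genome, models = make_genome_and_models(cfg, np.random.default_rng(2))
        assert len(models) == cfg.n_genes
        for m in models:  # constructor already validates; check derivations
            if m.biotype == "coding":
                exonic = m.exonic_length()
                cds = sum(e - s for s, e in m.cds)
                utr5 = sum(e - s for s, e in m.five_prime_utr())
                utr3 = sum(e - s for s, e in m.three_prime_utr())
                assert utr5 + cds + utr3 == exonic
        # genes do not overlap
        spans = sorted((m.chrom, m.start, m.end) for m in models)
        for a, b in zip(spans, spans[1:]):
            assert a[0] != b[0] or a[2] <= b[1]

    def test_no_genes_means_no_models(self):
        cfg = tiny_config(0, n_genes=0, n_sites=0, n_noise_sites=0)
        _, models = make_genome_and_models(cfg, np.random.default_rng(0))
        assert models == []

    def test_overfull_genome_is_an_error(self):
        cfg = tiny_config(0, chrom_length=5000, n_genes=30)
        with pytest.raises(ValueError, match="cannot place"):
            make_genome_and_models(cfg, np.random.default_rng(0))


class TestPlanting:
    def test_region_bias_all_on_one_label(self):
        cfg = tiny_config(3, region_bias={ann.FIVE_PRIME_UTR: 1.0}, n_sites=8)
        genome, models = make_genome_and_models(cfg, np.random.default_rng(3))
        truth = plant_sites(cfg, models, genome, np.random.default_rng(4))
        assert all(s.region == ann.FIVE_PRIME_UTR for s in truth.sites)

    def test_minimum_spacing_respected(self, sim_fixture):
        sites = sim_fixture.truth.sites
        by_chrom = {}
        for s in sites:
            by_chrom.setdefault(s.chrom, []).append(s.peak_pos)
        for positions in by_chrom.values():
            positions.sort()
            for a, b in zip(positions, positions[1:]):
                assert b - a >= sim_fixture.config.min_site_spacing

    def test_expected_counts_are_positive(self, sim_fixture):
        for s in sim_fixture.truth.sites:
            assert all(v >= 1 for v in s.expected.values())


class TestFixture:
    def test_same_seed_is_byte_identical(self, tmp_path):
        end_to_end_fixture(tiny_config(7), tmp_path / "a")
        end_to_end_fixture(tiny_config(7), tmp_path / "b")
        assert tree_digest(tmp_path / "a") == tree_digest(tmp_path / "b")

    def test_emits_every_declared_file(self, sim_fixture):
        d = sim_fixture.paths["genome"].parent
        for name in [
            "genome.fa",
            "models.bed12",
            "truth.json",
            "rep1.fastq",
            "rep1.aligned.tsv",
            "control1.fastq",
            "control1.aligned.tsv",
        ]:
            assert (d / name).exists()
        truth = json.loads((d / "truth.json").read_text())
        assert len(truth["sites"]) == sim_fixture.config.n_sites

    def test_models_round_trip_through_bed12(self, sim_fixture):
        reparsed = parse_gene_models(str(sim_fixture.paths["models"]), "bed12")
        originals = {m.transcript_id: m for m in sim_fixture.models}
        assert len(reparsed) == len(originals)
        for m in reparsed:
            assert m.exons == originals[m.transcript_id].exons
            assert m.cds == originals[m.transcript_id].cds


@pytest.fixture(scope="module")
def clean_fixture(tmp_path_factory):
    """No background, no noise, no PCR duplication, collision-free UMIs:
    every aligned read is one site molecule."""
    cfg = tiny_config(
        13,
        background_rate=0.0,
        n_noise_sites=0,
        pcr_dup=1.0,
        truncation_prob=1.0,
        umi_collision_free=True,
    )
    return end_to_end_fixture(cfg, tmp_path_factory.mktemp("clean_fixture"))


class TestReadModel:
    def test_dedup_recovers_unique_molecule_counts_exactly(self, clean_fixture):
        for rep in clean_fixture.config.replicates:
            reads = ingest_alignments(str(clean_fixture.paths[f"{rep}.tsv"]), "tsv")
            molecules, removed = dedup(reads)
            assert removed == 0  # pcr_dup = 1.0 -> single copies
            expected = sum(s.mappable_molecules[rep] for s in clean_fixture.truth.sites)
            assert len(molecules) == expected

    def test_xlink_site_recovers_true_crosslink_positions(self, clean_fixture):
        truth_by_read = {r.read_id: r for r in clean_fixture.truth.reads}
        checked = 0
        for rep in clean_fixture.config.replicates:
            for aligned in ingest_alignments(str(clean_fixture.paths[f"{rep}.tsv"]), "tsv"):
                prov = truth_by_read[aligned.read_id.rsplit(":", 1)[0]]
                pt = xlink_site(aligned)
                assert (pt.chrom, pt.strand, pt.pos) == (prov.chrom, prov.strand, prov.xl)
                checked += 1
        assert checked > 100

    def test_crosslinks_stay_within_the_site_window(self, clean_fixture):
        peak_by_id = {s.site_id: s.peak_pos for s in clean_fixture.truth.sites}
        for prov in clean_fixture.truth.reads:
            if prov.origin.startswith("site:"):
                peak = peak_by_id[prov.origin.split(":", 1)[1]]
                assert abs(prov.xl - peak) <= 4

    def test_pcr_duplication_inflates_reads_not_molecules(self, tmp_path):
        cfg = tiny_config(17, background_rate=0.0, n_noise_sites=0, pcr_dup=0.4,
                          umi_collision_free=True)
        fx = end_to_end_fixture(cfg, tmp_path / "dup")
        reads = ingest_alignments(str(fx.paths["rep1.tsv"]), "tsv")
        molecules, removed = dedup(reads)
        assert removed > 0
        assert len(molecules) == sum(s.mappable_molecules["rep1"] for s in fx.truth.sites)

    def test_controls_contain_only_background(self, tmp_path):
        cfg = tiny_config(19, background_rate=0.0)
        fx = end_to_end_fixture(cfg, tmp_path / "ctrl")
        assert ingest_alignments(str(fx.paths["control1.tsv"]), "tsv") == []

    def test_every_read_has_provenance(self, clean_fixture):
        from iclipsites.formats import read_fastq

        prov_ids = {r.read_id for r in clean_fixture.truth.reads}
        for rep in clean_fixture.config.replicates:
            for rec in read_fastq(str(clean_fixture.paths[f"{rep}.fastq"])):
                assert rec.id in prov_ids
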