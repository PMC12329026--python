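import io

import numpy as np
import pytest

from iclipsites.crosslinks import (
    AlignedRead,
    build_track,
    dedup,
    ingest_alignments,
    merge_tracks,
    write_alignments_tsv,
    xlink_site,
)


def read(read_id="r", chrom="chr1", start=100, end=130, strand="+", umi="GTCCG", rep="rep1"):
    return AlignedRead(read_id, chrom, start, end, strand, umi, rep)


def random_reads(n: int, seed: int = 0) -> list[AlignedRead]:
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out = []
    for i in range(n):
        start = int(rng.integers(1, 500))  # few positions -> many duplicates
        out.append(
            read(
                read_id=f"r{i}",
                start=start,
                end=start + 30,
                strand="+" if rng.random() < 0.5 else "-",
                umi="".join(bases[rng.integers(0, 4, size=3)]),
            )
        )
    return out


class TestDedup:
    def test_exact_duplicate_removed(self):
        kept, removed = dedup([read("a"), read("b")])
        assert [r.read_id for r in kept] == ["a"] and removed == 1

    def test_distinct_umis_both_retained(self):
        kept, removed = dedup([read("a", umi="GTCCG"), read("b", umi="GTCCA")])
        assert len(kept) == 2 and removed == 0

    def test_brute_force_grouping_oracle(self):
        reads = random_reads(10_000)
        kept, removed = dedup(reads)
        # oracle: first occurrence per (chrom, strand, 5' position, umi)
        seen, expected = set(), []
        for r in reads:
            key = (r.chrom, r.strand, r.five_prime_pos, r.umi)
            if key not in seen:
                seen.add(key)
                expected.append(r.read_id)
        assert [r.read_id for r in kept] == expected
        assert removed == len(reads) - len(expected)

    def test_idempotent_and_order_stable(self):
        reads = random_reads(500, seed=3)
        once, _ = dedup(reads)
        twice, removed = dedup(once)
        assert twice == once and removed == 0

    def test_left_coordinate_anchor(self):
        a = read("a", start=100, end=130, strand="-")
        b = read("b", start=100, end=140, strand="-")
        assert len(dedup([a, b], anchor="left_coordinate")[0]) == 1
        assert len(dedup([a, b], anchor="five_prime")[0]) == 2


class TestXlinkSite:
    def test_plus_strand_read_start_minus_one(self):
        assert xlink_site(read(start=100, end=130, strand="+")).pos == 99

    def test_minus_strand_mirror(self):
        assert xlink_site(read(start=100, end=130, strand="-")).pos == 130

    def test_chromosome_start_boundary_discards(self):
        assert xlink_site(read(start=0, end=30, strand="+")) is None

    def test_chromosome_end_boundary_discards(self):
        r = read(start=100, end=130, strand="-")
        assert xlink_site(r, {"chr1": 130}) is None


class TestTracks:
    def test_counting(self):
        reads = [read(f"r{i}", start=100, umi=f"AA{i}") for i in range(3)]
        reads.append(read("r9", start=103, umi="CCC"))
        track, _ = build_track(reads, "rep1")
        assert track.count_at("chr1", "+", 99) == 3
        assert track.count_at("chr1", "+", 102) == 1

    def test_merge_pointwise_sum_and_conservation(self):
        from iclipsites.crosslinks import CrosslinkTrack

        a = CrosslinkTrack("a", {("chr1", "+", 99): 3})
        b = CrosslinkTrack("b", {("chr1", "+", 99): 2, ("chr1", "+", 50): 1})
        merged = merge_tracks([a, b])
        assert merged.counts == {("chr1", "+", 99): 5, ("chr1", "+", 50): 1}
        assert merged.total_events() == a.total_events() + b.total_events()

    def test_merge_rejects_colliding_labels(self):
        from iclipsites.crosslinks import CrosslinkTrack

        with pytest.raises(ValueError, match="colliding"):
            merge_tracks([CrosslinkTrack("x"), CrosslinkTrack("x")])

    def test_strand_symmetry(self):
        """Mirroring the genome (and every read) mirrors the track exactly."""
        L = 1000
        reads = [r for r in random_reads(400, seed=5) if r.end <= L]
        mirrored = [
            AlignedRead(r.read_id, r.chrom, L - r.end, L - r.start,
                        "-" if r.strand == "+" else "+", r.umi, r.replicate)
            for r in reads
        ]
        fwd, _ = build_track(dedup(reads)[0], "f", {"chr1": L})
        rev, _ = build_track(dedup(mirrored)[0], "r", {"chr1": L})
        remapped = {
            (c, "-" if s == "+" else "+", L - 1 - p): n
            for (c, s, p), n in fwd.counts.items()
        }
        assert remapped == rev.counts


class TestIngest:
    def test_tsv_round_trip(self):
        reads = [read("r1:GTCCG"), read("r2:AAAAA", strand="-", umi="AAAAA")]
        buf = io.StringIO()
        write_alignments_tsv(reads, buf)
        assert ingest_alignments(io.StringIO(buf.getvalue()), "tsv") == reads

    def test_sam_flags_and_uniqueness(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "r1:GTCCG\t0\tchr1\t101\t255\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\tNH:i:1\n"
            "r2:ACGTA\t16\tchr1\t101\t255\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\tNH:i:1\n"
            "r3:CCCCC\t0\tchr1\t201\t3\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\tNH:i:2\n"
        )
        reads = ingest_alignments(str(sam), "sam")
        assert (reads[0].start, reads[0].end, reads[0].strand) == (100, 130, "+")
        assert reads[1].strand == "-"
        assert [r.unique for r in reads] == [True, True, False]

    def test_missing_umi_suffix_errors(self, tmp_path):
        from iclipsites.formats import FormatError

        sam = tmp_path / "bad.sam"
        sam.write_text(
            "@SQ\tSN:chr1\tLN:1000\n"
            "read1\t0\tchr1\t101\t255\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\n"
        )
        with pytest.raises(FormatError, match="read1"):
            ingest_alignments(str(sam), "sam")

    def test_accounting_chain_is_non_increasing(self, pipeline_result):
        for counts in pipeline_result.manifest["per_replicate"].values():
            assert counts["mapped"] >= counts["unique"] >= counts["after_dedup"]
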