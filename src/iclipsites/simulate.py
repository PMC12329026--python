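"""Seeded miniature iCLIP experiment with a machine-readable truth record.

The generator emulates the statistical structure of a truncation-mode iCLIP
experiment on a small random genome:

* non-overlapping genes on both strands with derivable 5'UTR/CDS/intron/3'UTR
  structure (~10% non-coding models);
* planted binding sites placed by a region bias (UTR-dominant), each with
  per-replicate expected molecule counts drawn log-normally -- real per-site
  crosslink support is well described as log-normal;
* a recognition motif written into the genome at each site (configurable
  sequence, offset and penetrance);
* a population of weak "noise pileups" (one or two crosslinked positions,
  ~1-2 molecules per replicate): the spurious low-support sites that quantile
  reproducibility filtering exists to remove, and the analogue of the
  below-threshold site population seen in real libraries;
* uniform background crosslinks, the only signal in control libraries
  (RNA-binding-dead / GFP-only);
* reads that start one nucleotide 3' of the crosslink (reverse transcription
  terminates right before the crosslinked residue), carry the NN-BBBB-NNN
  barcode/UMI prefix, read into the 3' adapter when the fragment is short,
  and are PCR-duplicated geometrically.

Reads are genomic (no splicing), so the emitted aligned-read TSV is exact by
construction and every stage can be tested without an aligner.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import annotation as ann
from .crosslinks import AlignedRead
from .formats import GeneModel, SeqRead, revcomp, write_bed12, write_fasta, write_fastq
from .preprocess import BarcodeScheme

log = logging.getLogger(__name__)

DEFAULT_ADAPTER = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAG"

#: Crosslink offset distribution around a planted peak (within the 9-nt
#: window): a sharp mode at the peak with symmetric decay.
XLINK_OFFSETS = tuple(range(-4, 5))
XLINK_WEIGHTS = (0.01, 0.03, 0.07, 0.14, 0.50, 0.14, 0.07, 0.03, 0.01)

DEFAULT_REGION_BIAS = {
    ann.FIVE_PRIME_UTR: 0.40,
    ann.THREE_PRIME_UTR: 0.30,
    ann.CDS: 0.15,
    ann.INTRON: 0.10,
    ann.NONCODING: 0.05,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic experiment (defaults = the 'small' preset)."""

    seed: int = 0
    # genome / annotation
    n_chroms: int = 1
    chrom_length: int = 100_000
    n_genes: int = 40
    noncoding_frac: float = 0.10
    utr5_len_range: tuple[int, int] = (60, 180)
    cds_len_range: tuple[int, int] = (300, 900)
    utr3_len_range: tuple[int, int] = (80, 250)
    n_introns_range: tuple[int, int] = (0, 3)
    intron_len_range: tuple[int, int] = (60, 200)
    noncoding_len_range: tuple[int, int] = (200, 600)
    intergenic_gap_range: tuple[int, int] = (120, 500)
    # planted binding sites
    n_sites: int = 60
    region_bias: dict = field(default_factory=lambda: dict(DEFAULT_REGION_BIAS))
    site_strength_mu: float = 2.5  # ln expected molecules / site / replicate
    site_strength_sigma: float = 0.5
    min_site_spacing: int = 20
    site_edge_margin: int = 6
    motifs: tuple = (("TTCTT", None, 1.0),)  # (seq, start offset | None=centred, fraction)
    # noise pileups and background
    n_noise_sites: int = 50
    noise_strength_mu: float = 0.2  # ln expected molecules at the pileup centre
    noise_strength_sigma: float = 0.5
    noise_satellite_rate: float = 0.5  # expected satellite molecules / replicate
    background_rate: float = 0.2  # molecules / kb / replicate
    control_background_rate: float | None = None  # default: same as background
    # read model
    truncation_prob: float = 1.0
    read_len: int = 50
    insert_len_range: tuple[int, int] = (20, 41)
    min_mappable_len: int = 24
    pcr_dup: float = 0.5  # geometric success prob; copies per molecule >= 1
    adapter: str = DEFAULT_ADAPTER
    scheme: BarcodeScheme = field(default_factory=BarcodeScheme)
    base_quality: int = 40
    n_control_libs: int = 2
    umi_collision_free: bool = False

    def __post_init__(self):
        if abs(sum(self.region_bias.values()) - 1.0) > 1e-9:
            raise ValueError("region_bias must sum to 1")
        if not (0 <= self.truncation_prob <= 1):
            raise ValueError("truncation_prob must be in [0, 1]")
        max_insert = self.read_len - len(self.scheme.layout)
        if self.insert_len_range[1] > max_insert:
            raise ValueError(f"insert length cannot exceed {max_insert}")

    @property
    def replicates(self) -> list[str]:
        return list(self.scheme.barcode_map.values())


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """The default miniature experiment: 1 chrom x 100 kb, 40 genes,
    60 planted sites, 3 replicates + 2 background-only controls."""
    return SimConfig(seed=seed, **overrides)


@dataclass
class PlantedSite:
    site_id: str
    chrom: str
    peak_pos: int
    strand: str
    region: str
    transcript_id: str
    expected: dict[str, int]  # replicate -> expected molecules
    molecules: dict[str, int] = field(default_factory=dict)  # realized, per library
    mappable_molecules: dict[str, int] = field(default_factory=dict)
    motif_offsets: list[int] = field(default_factory=list)


@dataclass
class NoisePileup:
    chrom: str
    pos: int
    strand: str
    center_rate: float
    satellite_offsets: tuple[int, ...]


@dataclass
class ReadProvenance:
    read_id: str
    molecule_id: str
    origin: str  # "site:<id>" | "noise:<i>" | "background"
    duplicate_of: str | None  # molecule's first read id, None for the first copy
    chrom: str = ""
    xl: int = -1  # the molecule's true crosslink position
    strand: str = "+"
    truncated: bool = True


@dataclass
class SimTruth:
    """Ground truth emitted by the generator for parameter-recovery tests."""

    sites: list[PlantedSite]
    noise: list[NoisePileup]
    motifs: list[tuple[str, int, float]]  # (seq, resolved start offset, fraction)
    reads: list[ReadProvenance] = field(default_factory=list)

    def site_by_id(self, site_id: str) -> PlantedSite:
        return next(s for s in self.sites if s.site_id == site_id)


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------


def _tx_to_genomic(blocks, strand: str, t0: int, t1: int) -> tuple[tuple[int, int], ...]:
    """Map a half-open transcript-coordinate interval onto genomic blocks."""
    order = blocks if strand == "+" else blocks[::-1]
    out = []
    acc = 0
    for s, e in order:
        blen = e - s
        lo, hi = max(t0 - acc, 0), min(t1 - acc, blen)
        if lo < hi:
            out.append((s + lo, s + hi) if strand == "+" else (e - hi, e - lo))
        acc += blen
    return tuple(sorted(out))


def _build_gene(cfg: SimConfig, rng: np.random.Generator, gene_start: int, idx: int, noncoding: bool):
    """One gene's (model, genomic_length)."""
    strand = "+" if rng.random() < 0.5 else "-"
    gene_id = f"G{idx:03d}"
    tx_id = f"{gene_id}.1"
    if noncoding:
        length = int(rng.integers(*cfg.noncoding_len_range))
        exons = ((gene_start, gene_start + length),)
        return GeneModel(gene_id, tx_id, "chr1", strand, exons, ()), length

    u5 = int(rng.integers(*cfg.utr5_len_range))
    cds_len = int(rng.integers(*cfg.cds_len_range))
    u3 = int(rng.integers(*cfg.utr3_len_range))
    tx_len = u5 + cds_len + u3
    n_introns = int(rng.integers(cfg.n_introns_range[0], cfg.n_introns_range[1] + 1))
    # intron insertion points inside the CDS, pairwise >= 30 nt apart
    points: list[int] = []
    for _ in range(200):
        if len(points) == n_introns:
            break
        p = int(rng.integers(u5 + 20, u5 + cds_len - 20))
        if all(abs(p - q) >= 30 for q in points):
            points.append(p)
    points.sort()
    exons = []
    cursor_g = gene_start
    prev_t = 0
    for p in points:
        exons.append((cursor_g, cursor_g + (p - prev_t)))
        cursor_g += (p - prev_t) + int(rng.integers(*cfg.intron_len_range))
        prev_t = p
    exons.append((cursor_g, cursor_g + (tx_len - prev_t)))
    exons = tuple(exons)
    # 5'UTR occupies the strand-wise first u5 transcript nt
    if strand == "+":
        cds = _tx_to_genomic(exons, strand, u5, u5 + cds_len)
    else:
        cds = _tx_to_genomic(exons, strand, u3, u3 + cds_len)
    model = GeneModel(gene_id, tx_id, "chr1", strand, exons, cds)
    return model, exons[-1][1] - gene_start


def make_genome_and_models(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], list[GeneModel]]:
    """Uniform-random genome with non-overlapping genes on both strands.

    The genome is returned as mutable per-chromosome character arrays so that
    motif instances can be written in at planting time.
    """
    genome: dict[str, np.ndarray] = {}
    models: list[GeneModel] = []
    bases = np.array(list("ACGT"))
    genes_per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    genes_per_chrom[0] += cfg.n_genes - sum(genes_per_chrom)
    # stratified biotype assignment: the configured non-coding share is met
    # exactly (a Bernoulli draw could leave a region bias without features)
    n_noncoding = round(cfg.n_genes * cfg.noncoding_frac)
    noncoding_flags = np.array([True] * n_noncoding + [False] * (cfg.n_genes - n_noncoding))
    rng.shuffle(noncoding_flags)
    gene_idx = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        genome[chrom] = bases[rng.integers(0, 4, size=cfg.chrom_length)]
        cursor = 400
        for _ in range(genes_per_chrom[ci]):
            cursor += int(rng.integers(*cfg.intergenic_gap_range))
            model, length = _build_gene(cfg, rng, cursor, gene_idx + 1, bool(noncoding_flags[gene_idx]))
            gene_idx += 1
            if cursor + length > cfg.chrom_length - 400:
                raise ValueError(
                    f"cannot place {cfg.n_genes} genes in {cfg.chrom_length} nt; "
                    "increase chrom_length"
                )
            model = dataclasses.replace(model, chrom=chrom)
            models.append(model)
            cursor += length
    return genome, models


# ---------------------------------------------------------------------------
# site planting
# ---------------------------------------------------------------------------


def _feature_pool(models: Sequence[GeneModel], label: str):
    """(model, start, end) features usable for planting a site of ``label``."""
    pool = []
    for m in models:
        for lab, s, e in ann.model_features(m):
            if lab == label:
                pool.append((m, s, e))
    return pool


def plant_sites(
    cfg: SimConfig,
    models: Sequence[GeneModel],
    genome: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> SimTruth:
    """Place binding sites by region bias, write motifs into the genome, and
    draw per-replicate expected molecule counts (log-normal, rounded, >= 1)."""
    labels = list(cfg.region_bias)
    probs = np.array([cfg.region_bias[l] for l in labels])
    pools = {l: _feature_pool(models, l) for l in labels}
    for l in labels:
        if cfg.region_bias[l] > 0 and not pools[l]:
            raise ValueError(f"no features available for region {l}")

    planted: list[PlantedSite] = []
    occupied: dict[str, list[int]] = {}
    for i in range(cfg.n_sites):
        label = labels[int(rng.choice(len(labels), p=probs))]
        pool = pools[label]
        weights = np.array([max(e - s - 2 * cfg.site_edge_margin, 0) for _, s, e in pool], dtype=float)
        if weights.sum() == 0:
            raise ValueError(f"no feature long enough to plant a {label} site")
        placed = False
        for _ in range(300):
            m, s, e = pool[int(rng.choice(len(pool), p=weights / weights.sum()))]
            pos = int(rng.integers(s + cfg.site_edge_margin, e - cfg.site_edge_margin))
            if all(abs(pos - q) >= cfg.min_site_spacing for q in occupied.get(m.chrom, ())):
                placed = True
                break
        if not placed:
            raise ValueError("infeasible site placement; enlarge genome or reduce n_sites")
        occupied.setdefault(m.chrom, []).append(pos)
        expected = {
            rep: max(1, round(float(rng.lognormal(cfg.site_strength_mu, cfg.site_strength_sigma))))
            for rep in cfg.replicates
        }
        site = PlantedSite(
            site_id=f"S{i:03d}",
            chrom=m.chrom,
            peak_pos=pos,
            strand=m.strand,
            region=label,
            transcript_id=m.transcript_id,
            expected=expected,
        )
        for seq, start_offset, fraction in cfg.motifs:
            off = -(len(seq) // 2) if start_offset is None else int(start_offset)
            if rng.random() < fraction:
                _write_motif(genome, site, seq, off)
                site.motif_offsets.append(off)
        planted.append(site)

    noise = _plant_noise(cfg, genome, occupied, rng)
    motifs = [
        (seq, -(len(seq) // 2) if off is None else int(off), frac)
        for seq, off, frac in cfg.motifs
    ]
    return SimTruth(sites=planted, noise=noise, motifs=motifs)


def _write_motif(genome: dict[str, np.ndarray], site: PlantedSite, seq: str, off: int):
    """Write a motif so it starts at strand-wise offset ``off`` from the peak."""
    k = len(seq)
    arr = genome[site.chrom]
    if site.strand == "+":
        start = site.peak_pos + off
        arr[start : start + k] = list(seq)
    else:
        start = site.peak_pos - off - k + 1
        arr[start : start + k] = list(revcomp(seq))


def _plant_noise(cfg, genome, occupied, rng) -> list[NoisePileup]:
    """Weak artifact pileups, kept clear of planted peaks."""
    noise = []
    chroms = sorted(genome)
    margin = cfg.read_len + 20
    for _ in range(cfg.n_noise_sites):
        for _ in range(300):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(margin, len(genome[chrom]) - margin))
            strand = "+" if rng.random() < 0.5 else "-"
            if all(abs(pos - q) >= 50 for q in occupied.get(chrom, ())):
                break
        else:
            raise ValueError("infeasible noise placement")
        occupied.setdefault(chrom, []).append(pos)
        n_sat = 1 + int(rng.integers(0, 2))
        sats = tuple(
            int(o) for o in rng.choice([-3, -2, -1, 1, 2, 3], size=n_sat, replace=False)
        )
        rate = float(rng.lognormal(cfg.noise_strength_mu, cfg.noise_strength_sigma))
        noise.append(NoisePileup(chrom, pos, strand, rate, sats))
    return noise


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


class _UmiSource:
    def __init__(self, umi_len: int, rng: np.random.Generator, collision_free: bool):
        self.umi_len = umi_len
        self.rng = rng
        self.collision_free = collision_free
        self.used: dict[tuple, set[str]] = {}

    def draw(self, key: tuple) -> str:
        for _ in range(4**self.umi_len):
            umi = "".join(_BASES[self.rng.integers(0, 4, size=self.umi_len)])
            if not self.collision_free:
                return umi
            used = self.used.setdefault(key, set())
            if umi not in used:
                used.add(umi)
                return umi
        raise RuntimeError("UMI space exhausted at one position")


def _molecule_span(cfg, rng, chrom_len: int, xl: int, strand: str) -> tuple[int, int, bool]:
    """Genomic span of one molecule's insert (read starts 1 nt 3' of the
    crosslink in read orientation; occasional read-through covers it)."""
    insert_len = int(rng.integers(cfg.insert_len_range[0], cfg.insert_len_range[1] + 1))
    truncated = rng.random() < cfg.truncation_prob
    if truncated:
        five_prime = xl + 1 if strand == "+" else xl - 1
    else:
        shift = int(rng.integers(3, 11))
        five_prime = xl - shift if strand == "+" else xl + shift
    if strand == "+":
        start, end = five_prime, min(five_prime + insert_len, chrom_len)
    else:
        start, end = max(five_prime - insert_len + 1, 0), five_prime + 1
    return start, end, truncated


def simulate_library(
    cfg: SimConfig,
    truth: SimTruth,
    genome: dict[str, np.ndarray],
    library: str,
    kind: str,
    rng: np.random.Generator,
) -> tuple[list[SeqRead], list[AlignedRead]]:
    """Emit one library's FASTQ records and true-alignment rows.

    ``kind="replicate"``: Poisson molecules per planted site (at the site's
    expected count for this replicate) plus noise pileups plus uniform
    background.  ``kind="control"``: uniform background only.  Each molecule
    is PCR-amplified geometrically; every copy becomes a FASTQ read, and
    copies whose genomic insert is long enough for unique mapping also become
    aligned-TSV rows.  Truth counters are updated in place.
    """
    if kind not in ("replicate", "control"):
        raise ValueError(f"unknown library kind {kind!r}")
    scheme = cfg.scheme
    barcode_by_label = {v: k for k, v in scheme.barcode_map.items()}
    barcode = barcode_by_label.get(library, next(iter(scheme.barcode_map)))
    umis = _UmiSource(scheme.umi_len, rng, cfg.umi_collision_free)

    offsets = np.array(XLINK_OFFSETS)
    weights = np.array(XLINK_WEIGHTS) / sum(XLINK_WEIGHTS)

    molecules: list[tuple[str, str, int, str]] = []  # (origin, chrom, xl, strand)
    if kind == "replicate":
        for site in truth.sites:
            n = int(rng.poisson(site.expected[library]))
            for _ in range(n):
                xl = site.peak_pos + int(offsets[int(rng.choice(len(offsets), p=weights))])
                molecules.append((f"site:{site.site_id}", site.chrom, xl, site.strand))
        for i, pile in enumerate(truth.noise):
            for _ in range(int(rng.poisson(pile.center_rate))):
                molecules.append((f"noise:{i}", pile.chrom, pile.pos, pile.strand))
            sat_rate = cfg.noise_satellite_rate / len(pile.satellite_offsets)
            for off in pile.satellite_offsets:
                for _ in range(int(rng.poisson(sat_rate))):
                    molecules.append((f"noise:{i}", pile.chrom, pile.pos + off, pile.strand))
        bg_rate = cfg.background_rate
    else:
        bg_rate = (
            cfg.background_rate
            if cfg.control_background_rate is None
            else cfg.control_background_rate
        )
    margin = cfg.read_len + 5
    for chrom in sorted(genome):
        chrom_len = len(genome[chrom])
        n_bg = int(rng.poisson(bg_rate * chrom_len / 1000.0))
        for _ in range(n_bg):
            pos = int(rng.integers(margin, chrom_len - margin))
            strand = "+" if rng.random() < 0.5 else "-"
            molecules.append(("background", chrom, pos, strand))

    fastq: list[SeqRead] = []
    aligned: list[AlignedRead] = []
    site_mols: dict[str, int] = {}
    site_mappable: dict[str, int] = {}
    for mol_idx, (origin, chrom, xl, strand) in enumerate(molecules):
        chrom_len = len(genome[chrom])
        start, end, truncated = _molecule_span(cfg, rng, chrom_len, xl, strand)
        if end <= start:
            continue
        insert = "".join(genome[chrom][start:end])
        if strand == "-":
            insert = revcomp(insert)
        mappable = (end - start) >= cfg.min_mappable_len
        five_prime = start if strand == "+" else end - 1
        umi = umis.draw((chrom, strand, five_prime))
        prefix = _layout_prefix(scheme.layout, barcode, umi)
        raw = (prefix + insert + cfg.adapter)[: cfg.read_len]
        copies = int(rng.geometric(cfg.pcr_dup))
        mol_id = f"{library}_m{mol_idx}"
        first_read_id = f"{mol_id}_c1"
        if origin.startswith("site:"):
            sid = origin.split(":", 1)[1]
            site_mols[sid] = site_mols.get(sid, 0) + 1
            if mappable:
                site_mappable[sid] = site_mappable.get(sid, 0) + 1
        for c in range(1, copies + 1):
            read_id = f"{mol_id}_c{c}"
            fastq.append(SeqRead(read_id, raw, tuple([cfg.base_quality] * len(raw))))
            if mappable:
                aligned.append(
                    AlignedRead(f"{read_id}:{umi}", chrom, start, end, strand, umi, library)
                )
            truth.reads.append(
                ReadProvenance(
                    read_id,
                    mol_id,
                    origin,
                    None if c == 1 else first_read_id,
                    chrom,
                    xl,
                    strand,
                    truncated,
                )
            )
    for site in truth.sites:
        site.molecules[library] = site_mols.get(site.site_id, 0)
        site.mappable_molecules[library] = site_mappable.get(site.site_id, 0)
    return fastq, aligned


def _layout_prefix(layout: str, barcode: str, umi: str) -> str:
    out = []
    bi = ui = 0
    for c in layout:
        if c == "B":
            out.append(barcode[bi])
            bi += 1
        else:
            out.append(umi[ui])
            ui += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# fixture
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    config: SimConfig
    truth: SimTruth
    genome: dict[str, str]
    models: list[GeneModel]
    paths: dict[str, Path]


def end_to_end_fixture(cfg: SimConfig, outdir) -> Fixture:
    """Write a self-contained fixture directory able to drive every stage.

    Emits genome.fa, models.bed12, per-replicate FASTQ + aligned TSV, control
    FASTQ + TSV, and truth.json.  Fully deterministic for a given config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.seed)
    genome_arr, models = make_genome_and_models(cfg, np.random.default_rng([seed, 1]))
    truth = plant_sites(cfg, models, genome_arr, np.random.default_rng([seed, 2]))

    paths: dict[str, Path] = {}
    for li, library in enumerate(cfg.replicates):
        rng = np.random.default_rng([seed, 10 + li])
        fastq, aligned = simulate_library(cfg, truth, genome_arr, library, "replicate", rng)
        paths[f"{library}.fastq"] = _write_fastq(outdir / f"{library}.fastq", fastq)
        paths[f"{library}.tsv"] = _write_tsv(outdir / f"{library}.aligned.tsv", aligned)
    for ci in range(cfg.n_control_libs):
        library = f"control{ci + 1}"
        rng = np.random.default_rng([seed, 50 + ci])
        fastq, aligned = simulate_library(cfg, truth, genome_arr, library, "control", rng)
        paths[f"{library}.fastq"] = _write_fastq(outdir / f"{library}.fastq", fastq)
        paths[f"{library}.tsv"] = _write_tsv(outdir / f"{library}.aligned.tsv", aligned)

    genome = {c: "".join(a) for c, a in genome_arr.items()}
    paths["genome"] = outdir / "genome.fa"
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    paths["models"] = outdir / "models.bed12"
    with open(paths["models"], "w") as fh:
        write_bed12(models, fh)
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth_to_dict(cfg, truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return Fixture(cfg, truth, genome, models, paths)


def _write_fastq(path: Path, records) -> Path:
    with open(path, "w") as fh:
        write_fastq(records, fh)
    return path


def _write_tsv(path: Path, aligned) -> Path:
    from .crosslinks import write_alignments_tsv

    with open(path, "w") as fh:
        write_alignments_tsv(aligned, fh)
    return path


def truth_to_dict(cfg: SimConfig, truth: SimTruth) -> dict:
    """JSON-serializable truth record (per-site counts; no per-read rows)."""
    return {
        "replicates": cfg.replicates,
        "motifs": [list(m) for m in truth.motifs],
        "sites": [
            {
                "site_id": s.site_id,
                "chrom": s.chrom,
                "peak_pos": s.peak_pos,
                "strand": s.strand,
                "region": s.region,
                "transcript_id": s.transcript_id,
                "expected": s.expected,
                "molecules": s.molecules,
                "mappable_molecules": s.mappable_molecules,
                "motif_offsets": s.motif_offsets,
            }
            for s in truth.sites
        ],
        "noise_sites": [
            {"chrom": n.chrom, "pos": n.pos, "strand": n.strand}
            for n in truth.noise
        ],
    }
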