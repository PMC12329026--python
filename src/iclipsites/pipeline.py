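"""End-to-end orchestration: reads -> tracks -> sites -> reproducible set ->
annotation -> motifs, with per-stage outputs, an accounting table and a JSON
run manifest.

Execution is single-threaded and deterministic: all outputs are stably
sorted before writing and all randomness (motif shuffles) flows from the one
config seed, so identical config + inputs reproduce identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from . import motifs as mot
from .crosslinks import CrosslinkTrack, build_track, dedup, ingest_alignments, merge_tracks
from .formats import (
    GeneModel,
    parse_gene_models,
    read_fasta,
    read_fastq,
    write_bedgraph,
    write_fasta,
)
from .peaks import (
    BindingSite,
    call_peaks_naive,
    filter_single_xl,
    ingest_peaks,
    make_sites,
    resolve_adjacent,
    write_peaks_bed,
    write_sites_bed,
)
from .preprocess import (
    BarcodeScheme,
    demultiplex,
    length_filter,
    summarize_reads,
    trim_record,
)
from .reproducibility import (
    SupportMatrix,
    classify_reproducible,
    count_support,
    subtract_controls,
)
from .simulate import DEFAULT_ADAPTER

log = logging.getLogger(__name__)

#: Upstream read-mapping settings echoed (not executed) in the run manifest
#: for provenance; alignment itself is outside this package.  Two intron
#: ceilings circulate for this protocol configuration (280000 vs the 28000
#: flag value); both are recorded as a documented ambiguity.
ALIGNER_CONFIG_ECHO = {
    "aligner": "STAR",
    "max_mismatches": 2,
    "align_ends_type": "Extend5pOfRead1",
    "align_intron_min": 11,
    "align_intron_max_documented": 280000,
    "align_intron_max_flag": 28000,
    "out_filter_multimap_nmax": 1,
}


@dataclass
class RunConfig:
    """Effective parameters of one pipeline run.

    Defaults are the protocol's canonical values (24-nt length floor, 9-nt
    sites, 30% quantile, 2-of-3 replicates, 30-nt motif extension); the
    naive-caller settings are this package's own stand-in defaults.
    """

    seed: int = 0
    # preprocessing
    adapter: str = DEFAULT_ADAPTER
    min_len: int = 24
    # dedup / tracks
    dedup_anchor: str = "five_prime"
    # peak calling (stand-in caller, used when no external peak BED given)
    naive_min_count: int = 2
    naive_flank: int = 15
    naive_min_fold: float = 3.0
    # binding sites
    ext: int = 4
    min_xl_positions: int = 2
    # reproducibility
    q: float = 0.30
    k_of_n: int = 2
    support_cmp: str = "ge"
    # annotation
    region_priority: tuple = ann.PRIORITY
    # motif
    motif_ext: int = 30
    motif_ks: tuple = (4, 5, 6)
    n_shuffles: int = 50
    n_density_top: int = 3


@dataclass
class PipelineResult:
    config: RunConfig
    outdir: Path
    accounting: pd.DataFrame
    replicate_tracks: dict[str, CrosslinkTrack]
    merged_track: CrosslinkTrack
    peaks_resolved: list
    sites_all: list[BindingSite]
    sites_filtered: list[BindingSite]
    matrix: SupportMatrix
    thresholds: dict[str, float]
    histogram: dict[int, int]
    sites_reproducible: list[BindingSite]
    control_site_sets: dict[str, list[BindingSite]]
    sites_final: list[BindingSite]
    assignments: list
    region_dist: ann.RegionDistribution | None
    target_transcripts: list[str]
    motif_hits: dict[int, list[mot.MotifHit]]
    site_sequences: list[str]
    manifest: dict


def _tsv_to_sites(
    tsv_path,
    label: str,
    config: RunConfig,
    chrom_lengths: Mapping[str, int],
) -> tuple[list[BindingSite], CrosslinkTrack, dict]:
    """Single-library site calling (used for control libraries)."""
    reads = ingest_alignments(tsv_path, "tsv")
    unique_reads, _ = dedup(reads, config.dedup_anchor)
    track, _ = build_track(unique_reads, label, chrom_lengths)
    peaks = call_peaks_naive(
        track, config.naive_min_count, config.naive_flank, config.naive_min_fold
    )
    sites = filter_single_xl(
        make_sites(resolve_adjacent(peaks), config.ext, chrom_lengths),
        track,
        config.min_xl_positions,
    )
    counts = {"mapped": len(reads), "unique_molecules": len(unique_reads), "sites": len(sites)}
    return sites, track, counts


def run_pipeline(
    outdir,
    replicate_tsvs: Mapping[str, object],
    genome_fasta,
    models_path,
    replicate_fastqs: Mapping[str, object] | None = None,
    control_tsvs: Mapping[str, object] | None = None,
    peaks_bed=None,
    scheme: BarcodeScheme | None = None,
    config: RunConfig | None = None,
    models_dialect: str = "bed12",
) -> PipelineResult:
    """Run every stage in workflow order and persist per-stage outputs.

    ``replicate_tsvs`` maps replicate labels to aligned-read TSVs (the
    contractual alignment interchange); ``replicate_fastqs`` is optional and
    only feeds the read-level accounting stages.  ``peaks_bed`` supplies
    external narrow-peak calls; without it the naive stand-in caller runs on
    the merged crosslink track.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    scheme = scheme or BarcodeScheme()
    for label in sorted(control_tsvs or {}):
        if not Path(str(control_tsvs[label])).exists():
            raise FileNotFoundError(f"control alignments missing: {control_tsvs[label]}")

    genome = {rec.id: rec.seq for rec in read_fasta(genome_fasta)}
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    models = parse_gene_models(models_path, models_dialect)

    # --- stage 1: read-level preprocessing (accounting) -------------------
    accounting_rows = []
    if replicate_fastqs:
        for fq_label, path in sorted(replicate_fastqs.items()):
            raw = read_fastq(path)
            trimmed = [trim_record(r, config.adapter) for r in raw]
            sinks, unassigned = demultiplex(trimmed, scheme)
            for rep in sorted(sinks):
                kept, dropped = length_filter(sinks[rep], config.min_len)
                stats = summarize_reads(kept)
                accounting_rows.append(
                    {
                        "fastq": str(fq_label),
                        "replicate": rep,
                        "reads_in": len(raw),
                        "unassigned": unassigned,
                        "demultiplexed": len(sinks[rep]),
                        "dropped_short": dropped,
                        "retained": len(kept),
                        "mean_quality": round(stats["mean_quality"], 3) if kept else "NA",
                        "mean_length": round(stats["mean_length"], 3) if kept else "NA",
                    }
                )

    # --- stage 2: alignments -> deduplicated crosslink tracks -------------
    replicate_tracks: dict[str, CrosslinkTrack] = {}
    per_rep_counts: dict[str, dict] = {}
    for rep in sorted(replicate_tsvs):
        reads = ingest_alignments(replicate_tsvs[rep], "tsv")
        unique = [r for r in reads if r.unique]
        molecules, removed = dedup(unique, config.dedup_anchor)
        track, discarded = build_track(molecules, rep, chrom_lengths)
        replicate_tracks[rep] = track
        per_rep_counts[rep] = {
            "mapped": len(reads),
            "unique": len(unique),
            "after_dedup": len(molecules),
            "pcr_duplicates_removed": removed,
            "out_of_bounds": discarded,
        }
    merged = merge_tracks(list(replicate_tracks.values()))

    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for label, track in list(replicate_tracks.items()) + [("merged", merged)]:
        for strand, suffix in (("+", "plus"), ("-", "minus")):
            with open(tracks_dir / f"{label}.{suffix}.bedgraph", "w") as fh:
                write_bedgraph(track.to_points(strand), strand, fh)

    # --- stage 3: peaks -> binding sites ----------------------------------
    if peaks_bed is not None:
        peaks = sorted(ingest_peaks(peaks_bed), key=lambda p: p.sort_key)
    else:
        peaks = call_peaks_naive(
            merged, config.naive_min_count, config.naive_flank, config.naive_min_fold
        )
    resolved = resolve_adjacent(peaks)
    sites_all = make_sites(resolved, config.ext, chrom_lengths)
    sites_filtered = filter_single_xl(sites_all, merged, config.min_xl_positions)

    sites_dir = outdir / "sites"
    sites_dir.mkdir(exist_ok=True)
    with open(sites_dir / "peaks_resolved.bed", "w") as fh:
        write_peaks_bed(resolved, fh)
    with open(sites_dir / "sites_filtered.bed", "w") as fh:
        write_sites_bed(sites_filtered, fh)

    # --- stage 4: replicate reproducibility -------------------------------
    matrix = count_support(sites_filtered, replicate_tracks)
    flags, n_supported, histogram = classify_reproducible(
        matrix, config.k_of_n, config.q, config.support_cmp
    )
    sites_reproducible = [s for s, f in zip(sites_filtered, flags) if f]

    rep_dir = outdir / "reproducibility"
    rep_dir.mkdir(exist_ok=True)
    support_df = pd.DataFrame(matrix.counts, columns=matrix.replicates)
    support_df.insert(0, "site", [f"{s.chrom}:{s.start}-{s.end}({s.strand})" for s in matrix.sites])
    support_df["n_replicates_supported"] = n_supported
    support_df["reproducible"] = flags
    support_df.to_csv(rep_dir / "support_matrix.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"n_replicates": list(histogram), "n_sites": list(histogram.values())}
    ).to_csv(rep_dir / "replicate_histogram.tsv", sep="\t", index=False)

    # --- stage 5: control subtraction -------------------------------------
    control_site_sets: dict[str, list[BindingSite]] = {}
    control_counts = {}
    for label in sorted(control_tsvs or {}):
        csites, _, ccounts = _tsv_to_sites(str(control_tsvs[label]), label, config, chrom_lengths)
        control_site_sets[label] = csites
        control_counts[label] = ccounts
    sites_final = subtract_controls(sites_reproducible, list(control_site_sets.values()))
    with open(sites_dir / "sites_reproducible.bed", "w") as fh:
        write_sites_bed(sites_reproducible, fh)
    with open(sites_dir / "sites_final.bed", "w") as fh:
        write_sites_bed(sites_final, fh)

    # --- stage 6: region annotation ---------------------------------------
    assignments = ann.annotate_sites(sites_final, models, config.region_priority)
    region_dist = ann.region_distribution(assignments, models) if any(
        lab != ann.INTERGENIC for _, lab, _ in assignments
    ) else None
    targets = ann.target_transcripts(assignments)

    ann_dir = outdir / "annotation"
    ann_dir.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "peak_pos": s.peak_pos,
                "region": lab,
                "transcript_id": tid or ".",
            }
            for s, lab, tid in assignments
        ]
    ).to_csv(ann_dir / "sites_annotated.tsv", sep="\t", index=False)
    if region_dist is not None:
        pd.DataFrame(
            [
                {
                    "region": lab,
                    "site_count": region_dist.site_count.get(lab, 0),
                    "site_percent": round(region_dist.site_percent.get(lab, 0.0), 3),
                    "background_percent": round(region_dist.background_percent.get(lab, 0.0), 3),
                }
                for lab in sorted(
                    set(region_dist.site_percent) | set(region_dist.background_percent)
                )
            ]
        ).to_csv(ann_dir / "region_distribution.tsv", sep="\t", index=False)
    (ann_dir / "target_transcripts.txt").write_text("".join(t + "\n" for t in targets))

    # --- stage 7: motif enrichment ----------------------------------------
    site_seqs = mot.extract_site_sequences(sites_final, genome, config.motif_ext)
    motif_dir = outdir / "motif"
    motif_dir.mkdir(exist_ok=True)
    with open(motif_dir / "windows.fa", "w") as fh:
        from .formats import SeqRead

        write_fasta(
            [SeqRead(f"site_{i}", s) for i, s in enumerate(site_seqs, start=1)], fh
        )
    motif_hits: dict[int, list[mot.MotifHit]] = {}
    density_rows = []
    for k in config.motif_ks:
        hits = mot.kmer_enrichment(
            site_seqs, k, config.n_shuffles, np.random.default_rng([config.seed, 90 + k])
        )
        motif_hits[k] = hits
        pd.DataFrame(
            [
                {
                    "kmer": h.kmer,
                    "fg_count": h.fg_count,
                    "bg_mean": round(h.bg_mean, 4),
                    "bg_sd": round(h.bg_sd, 4),
                    "zscore": round(h.zscore, 4),
                }
                for h in hits
            ]
        ).to_csv(motif_dir / f"kmers_k{k}.tsv", sep="\t", index=False)
        for h in hits[: config.n_density_top]:
            offsets, density, n_hits = mot.positional_density(h.kmer, site_seqs)
            h.offsets, h.density = offsets, density
            for off, d in zip(offsets, density):
                density_rows.append(
                    {"kmer": h.kmer, "offset": int(off), "density": round(float(d), 6)}
                )
    pd.DataFrame(density_rows).to_csv(motif_dir / "density_top.tsv", sep="\t", index=False)

    # --- manifest ----------------------------------------------------------
    accounting = pd.DataFrame(accounting_rows)
    if not accounting.empty:
        accounting.to_csv(outdir / "accounting.tsv", sep="\t", index=False)
    stage_counts = {
        "peaks_called": len(peaks),
        "peaks_resolved": len(resolved),
        "sites": len(sites_all),
        "sites_after_single_xl_filter": len(sites_filtered),
        "sites_reproducible": len(sites_reproducible),
        "sites_final": len(sites_final),
        "target_transcripts": len(targets),
    }
    manifest = {
        "config": dataclasses.asdict(config),
        "aligner_config_echo": ALIGNER_CONFIG_ECHO,
        "inputs": {
            "replicate_tsvs": {k: str(v) for k, v in replicate_tsvs.items()},
            "genome": str(genome_fasta),
            "models": str(models_path),
            "controls": {k: str(v) for k, v in (control_tsvs or {}).items()},
            "peaks_bed": str(peaks_bed) if peaks_bed is not None else None,
        },
        "per_replicate": per_rep_counts,
        "controls": control_counts,
        "thresholds": {
            k: (v if np.isfinite(v) else "inf") for k, v in matrix.thresholds.items()
        },
        "replicate_histogram": {str(k): v for k, v in histogram.items()},
        "stage_counts": stage_counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", stage_counts)

    return PipelineResult(
        config=config,
        outdir=outdir,
        accounting=accounting,
        replicate_tracks=replicate_tracks,
        merged_track=merged,
        peaks_resolved=resolved,
        sites_all=sites_all,
        sites_filtered=sites_filtered,
        matrix=matrix,
        thresholds=matrix.thresholds,
        histogram=histogram,
        sites_reproducible=sites_reproducible,
        control_site_sets=control_site_sets,
        sites_final=sites_final,
        assignments=assignments,
        region_dist=region_dist,
        target_transcripts=targets,
        motif_hits=motif_hits,
        site_sequences=site_seqs,
        manifest=manifest,
    )


def run_on_fixture(fixture_dir, outdir, config: RunConfig | None = None) -> PipelineResult:
    """Run the pipeline on a generator fixture directory (standard names)."""
    fixture_dir = Path(fixture_dir)
    scheme = BarcodeScheme()
    reps = sorted(scheme.barcode_map.values())
    replicate_tsvs = {r: fixture_dir / f"{r}.aligned.tsv" for r in reps}
    replicate_fastqs = {r: fixture_dir / f"{r}.fastq" for r in reps}
    control_tsvs = {
        p.name.split(".")[0]: p for p in sorted(fixture_dir.glob("control*.aligned.tsv"))
    }
    return run_pipeline(
        outdir,
        replicate_tsvs={k: str(v) for k, v in replicate_tsvs.items()},
        genome_fasta=str(fixture_dir / "genome.fa"),
        models_path=str(fixture_dir / "models.bed12"),
        replicate_fastqs={k: str(v) for k, v in replicate_fastqs.items()},
        control_tsvs={k: str(v) for k, v in control_tsvs.items()},
        scheme=scheme,
        config=config,
    )
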