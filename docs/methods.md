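# Methods

## Signal model

iCLIP reads are modelled as truncation products: reverse transcription stops
immediately 3′ of the crosslinked nucleotide, so the contact position is one
nucleotide 5′ of the read's 5′ end in read orientation. With 0-based
half-open alignment coordinates this is `start − 1` on the plus strand and
`end` on the minus strand. The minus-strand convention is the exact strand
mirror of the plus rule and is covered by a strand-symmetry property test
(reverse-complementing the genome and flipping every read reproduces the
mirrored track exactly). Crosslink positions falling outside the chromosome
(reads starting at position 0) are discarded and counted.

PCR duplicates are collapsed on the key (chrom, strand, anchor, UMI). The
anchor is the strand-aware 5′-end position by default, because truncation
biology fixes the 5′ end of the cDNA; a `left_coordinate` anchor is
available for compatibility with tools that group on the left genomic
coordinate regardless of strand. The first read in input order represents
each group, making deduplication idempotent and order-stable. Spliced
alignments are not modelled (the generator emits contiguous genomic reads);
for real spliced input the 5′ terminal block determines the anchor.

## Pipeline parameters

| parameter | default | role |
|---|---|---|
| `min_len` | 24 nt | minimum insert length for unique mapping |
| `ext` | 4 nt | peak → site extension (9-nt windows) |
| `min_xl_positions` | 2 | distinct crosslinked positions a window must hold |
| `q` | 0.30 | support-quantile threshold per replicate |
| `k_of_n` | 2 (of 3) | replicates required for reproducibility |
| `motif_ext` | 30 nt | site → sequence-window extension (69-nt windows) |
| adapter trimming | min_overlap 3, max error 0.1 | suffix-vs-prefix scan, no indels |
| naive caller | min_count 2, flank 15, min_fold 3 | stand-in for an external HMM caller |

The quantile threshold is a type-1 (no interpolation) empirical-CDF
inversion over the **strictly positive** counts of a replicate's column: the
smallest observed count `c` with `F(c) ≥ q`. Zeros are excluded because a
zero-inflated column would otherwise collapse the threshold to the point of
meaninglessness; a replicate with no positive counts supports nothing
(threshold +∞). Printed thresholds are minimal supporting counts, so a site
*at* the threshold passes (`count ≥ c`); a strict comparator is available.
Raising `q` can never increase the reproducible count (tested).

Adjacent-peak resolution groups maximal runs of peaks at genomic distance
exactly 1 (same chrom and strand) and keeps the best-scoring member, ties
resolved to the smallest (5′-most on plus) position for determinism. The
single-crosslink exclusion counts distinct positions on the merged
(across-replicate) track, because that filter precedes the per-replicate
reproducibility assessment in the workflow order; peak calling likewise runs
on the merged track by default, with per-replicate support assessed
downstream. Control libraries are processed through the identical
single-library chain (dedup → track → peaks → sites → single-crosslink
filter) and their site sets subtracted under union semantics with a
same-strand ≥1-nt overlap predicate.

Region assignment anchors at the site's peak position so each site gets
exactly one label. Among features covering that nucleotide the priority is
3′UTR > 5′UTR > CDS > intron > non-coding: boundary-straddling centres are
resolved toward the untranslated regions, where this protein family
predominantly binds; the order is configurable and echoed in the manifest.
Only same-strand gene models are considered (iCLIP is strand-specific). If
an annotation carries several transcripts per gene, the transcript with the
greatest exonic length becomes the representative model (warning logged).

## Motif enrichment stand-in

The external discovery tool's objective is deliberately **not**
re-implemented. Instead, exhaustive k-mers (k = 4, 5, 6) are scored as
`z = (fg − bg_mean) / max(bg_sd, 1)` against `n_shuffles` per-sequence
dinucleotide-preserving (Eulerian-walk) shuffles of the corpus; the SD floor
of 1 guards degenerate single-letter corpora, for which the shuffle is a
fixed point and z is exactly 0. Sequences are canonically sorted before
counting, so rankings are invariant to input order and fully determined by
the seed. Windows with more than 10% ambiguous bases are dropped; remaining
`N`s simply match no k-mer. Positional density is the normalized histogram
of k-mer start offsets relative to the window centre `(L−1)//2`; a motif
planted centred therefore shows its mode at `−⌊k/2⌋`, and a motif planted at
start offset +10 shows its mode at exactly +10.

## What the generator emulates

One 100-kb chromosome carries 40 non-overlapping genes (exactly 10%
non-coding by stratified assignment; coding genes have 5′UTR 60–180 nt, CDS
300–900 nt with 0–3 introns of 60–200 nt, 3′UTR 80–250 nt). Sixty binding
sites are planted by a UTR-dominant region bias (40/30/15/10/5% for
5′UTR/3′UTR/CDS/intron/non-coding), at least 20 nt apart and ≥6 nt inside
their feature. Design choices, in the order they matter downstream:

* **Site strength.** Expected molecules per site per replicate are
  LogNormal(μ=2.5, σ=0.5) (median ≈ 12), drawn independently per replicate,
  rounded, floored at 1 — per-site crosslink support in real libraries is
  well described as log-normal, and the resulting support thresholds (4–6
  crosslinks on the small fixture) sit on the same scale as real
  single-digit per-replicate thresholds. Realized molecule numbers are
  Poisson at the expected count.
* **Crosslink spread.** Offsets from the peak are drawn from a symmetric
  distribution over ±4 nt (50% mass at the peak), so windows genuinely
  contain multiple crosslinked positions and the single-crosslink filter has
  a non-trivial job.
* **Noise pileups.** Fifty weak single-position pileups (expected ≈ 1.2
  molecules per replicate at the centre, plus ~0.5 satellite molecules
  within ±3 nt) emulate the spurious low-support sites — abundant-RNA
  contamination and residual amplification artifacts — that quantile
  reproducibility filtering exists to remove. They are what populates the
  below-threshold bins of the replicate histogram; without such a population
  a 30% quantile would, by construction, cut into genuine sites.
* **Reads.** Insert lengths are uniform on 20–41 nt (50-nt raw reads minus
  the 9-nt barcode prefix, adapter fill when shorter), matching a ~31 ± 7 nt
  post-trimming regime; inserts under 24 nt are unmappable and appear only
  in FASTQ. Base qualities are constant Q40. Each molecule is amplified
  geometrically (p = 0.5, mean 2 copies). UMIs are uniform 5-mers; collisions
  are possible by design, and a collision-free mode (rejection sampling
  within each 5′-position group, valid for ≤ 4^5 molecules per position)
  exists for exact-conservation tests.
* **Background and controls.** Uniform background at 0.2 molecules/kb per
  replicate; control libraries contain background only.

The generator does **not** model sequencing errors, splicing, fragment-size
selection, barcode mutations, crosslinking sequence preference, or
transcript-abundance structure in the background. Passing recovery tests
therefore demonstrates that the pipeline's rules are implemented correctly
and that the statistical machinery (quantile thresholds, k-of-n, shuffle
backgrounds) behaves as designed — not that these defaults are optimal for
any particular real library.

## Problem sizes and determinism

The default fixture (60 sites, ~12k reads across 3 replicates + 2 controls)
runs the full pipeline in a few seconds on one CPU; the test suite and the
acceptance script are sized accordingly. All randomness derives from one
seed via named substreams; stable sorts precede every write, so identical
seed + config + inputs reproduce every BED/BEDGRAPH/TSV/JSON output
byte-identically (asserted by digest in the tests).

## Known limitations

* The naive peak caller is a labelled stand-in: a count-and-local-fold rule,
  not a covariate-aware HMM; external narrow-peak BED input is the intended
  production path.
* Exact barcode matching only (the replicate barcodes differ pairwise at ≥3
  positions, so one mismatch cannot misassign, but mutated barcodes are
  simply unassigned).
* Genome-scale data structures are plain dictionaries keyed by position —
  appropriate for the fixture scale and for per-chromosome batches, not for
  whole-mammalian-genome tracks in one pass.
* BED12/GFF3 ingestion assumes one representative transcript per gene is
  wanted; isoform-aware assignment is out of scope.
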