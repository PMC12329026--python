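# iclipsites

Determination of RNA-binding protein binding sites from iCLIP data:
deduplicated single-nucleotide crosslink tracks, 9-nt binding-site windows,
replicate-reproducibility classification, control subtraction,
transcript-region assignment and k-mer motif enrichment — plus a fully
ground-truthed synthetic iCLIP read generator that lets the entire pipeline
be validated end to end without any external data.

## The problem

In individual-nucleotide-resolution CLIP (iCLIP), UV light crosslinks an RNA-
binding protein to its target RNAs in vivo; after immunoprecipitation and
reverse transcription, the cDNA truncates immediately 3′ of the crosslinked
nucleotide. The protein–RNA contact is therefore not inside the read but one
nucleotide 5′ of the mapped read start (in read orientation):

* plus strand: `xl = read_start − 1`
* minus strand: `xl = alignment_end` (half-open coordinates)

Random-barcode (UMI) prefixes on the RT primer distinguish unique cDNA
molecules from PCR duplicates. The motivating system is the *Arabidopsis
thaliana* glycine-rich RNA-binding protein AtGRP8 (barcode layout
`NN-BBBB-NNN`: 5 UMI nt flanking a 4-nt replicate barcode), but every
parameter — barcode scheme, window sizes, thresholds — is configurable.

## The method

For three replicate libraries plus background-only controls (GFP-only /
RNA-binding-dead):

1. **Preprocess** — 3′ adapter trimming, exact-match demultiplexing with UMI
   extraction (`read_id:UMI`), and a 24-nt minimum insert length.
2. **Crosslink tracks** — PCR duplicates collapsed on (chrom, strand,
   5′ position, UMI); each unique molecule contributes one crosslink event;
   per-replicate and merged strand-aware tracks are written as BEDGRAPH.
3. **Binding sites** — single-nucleotide peaks (external narrow-peak calls,
   or the built-in local-enrichment stand-in caller) are resolved so that no
   two retained peaks are directly adjacent (best score wins, 5′-most on
   ties), then extended by ±4 nt into 9-nt windows; windows with only a
   single distinct crosslinked position are discarded as mapping artifacts.
4. **Reproducibility** — per replicate, the 30% quantile of the strictly
   positive per-site crosslink counts is that replicate's minimal support
   threshold; a site is reproducible when it reaches the threshold in at
   least 2 of 3 replicates. Sites overlapping any control-library site
   (same strand, ≥1 nt) are subtracted.
5. **Annotation** — each site is assigned by its peak position to
   5′UTR / CDS / intron / 3′UTR / non-coding / intergenic using
   representative gene models, and the region shares are compared with the
   cumulative feature-length background.
6. **Motifs** — site windows extended by ±30 nt are extracted strand
   specifically; k-mers (k = 4, 5, 6) are ranked by z-score against
   dinucleotide-preserving shuffles, with each motif's positional density
   relative to site centres.

The synthetic generator plants sites with log-normal per-replicate molecule
counts (UTR-dominant region bias), writes a recognition motif into the
genome at each site, adds weak noise pileups and uniform background, and
emits FASTQ, exact aligned-read TSVs and a machine-readable truth record —
so recall, precision and motif recovery are measurable exactly.

## Worked example

```sh
$ iclipsites simulate --seed 7 --out fixture/
fixture with 60 planted sites -> fixture/

$ iclipsites run --fixture fixture/ --out results/ --seed 7
56 reproducible binding sites on 28 target transcripts -> results/
```

Of the 60 planted sites, 56 survive the full chain (peak calling, adjacent-
peak resolution, single-crosslink exclusion, 30% quantile + 2-of-3
reproducibility, control subtraction). The manifest echoes the derived
per-replicate thresholds — here 5/5/5 crosslinks — and the replicate
histogram `{0: 12, 1: 10, 2: 12, 3: 44}`: the 22 sites supported in fewer
than two replicates are the low-support population the quantile filter
exists to remove.

```sh
$ cat results/annotation/region_distribution.tsv
region           site_count  site_percent  background_percent
cds              6           10.714        51.517
five_prime_utr   20          35.714        12.942
intron           10          17.857        16.557
noncoding        5           8.929         4.803
three_prime_utr  15          26.786        14.180
```

Binding is UTR-dominant (62.5% of sites vs a 27% length background), as
planted. The motif table recovers the planted recognition element at rank 1:

```sh
$ head -2 results/motif/kmers_k5.tsv
kmer   fg_count  bg_mean  bg_sd   zscore
TTCTT  60        8.58     2.8291  18.1756
```

Every stage is also exposed separately (`preprocess`, `xlinks`, `sites`,
`annotate`, `motif`) for externally preprocessed or externally called input
(e.g. narrow-peak BED from a dedicated caller).

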