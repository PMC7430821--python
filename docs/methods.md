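# Methods

This note documents the models and procedures implemented in
`riboscope`, the defaults chosen where the field has no single
convention, and what the simulator does and does not emulate.

## Coordinates and the transcript catalog

GTF input is parsed as 1-based closed intervals (the format standard);
all internal coordinates are 0-based half-open on the spliced transcript,
5′→3′ on the transcript strand, with codon 1 the first CDS codon. One
representative transcript is kept per protein-coding gene: the one with
the greatest spliced length (a `by="cds"` mode selects by CDS length
instead), with ties broken to the lexicographically smallest transcript
id so runs are reproducible. A gene counts as coding when its biotype
says so, or — in GTF dialects without biotype tags — when it has CDS
records. Separate `stop_codon` features are merged into CDS space, so
CDS length is divisible by three and includes the stop in both dialects.
The stop codon counts toward CDS length but never toward the amino-acid
sequence or identity-level statistics. Malformed records (CDS outside
exon space, CDS length not a multiple of 3, exons beyond chromosome
ends) exclude the transcript with a warning rather than aborting.

Not handled: selenocysteine recoding, polycistronic CDS, circular
chromosomes.

## P-site calibration and density vectors

Only primary alignments are counted (secondary/supplementary flags are
dropped), and transcriptome alignments must be forward-strand. For each
read length in 25–35 nt (configurable; tests use wider screens), 5′-end
positions relative to start codons are pooled over all transcripts and
the mode is searched in the window [−18, −6] nt — wide enough for known
Ribo-seq geometries. The offset is the negated mode. A length is
accepted only if count(mode) / (count(mode−1) + count(mode) +
count(mode+1)) ≥ 0.5; fragments with random 5′ ends sit near 1/3 and are
rejected. The mode is well defined in any library with the universal
initiation pile-up at the start codon; on deliberately flat data
(possible in simulation) offsets should be supplied directly, and the
CLI accepts an offsets file for that reason. Ties in the mode break to
the most upstream position.

P-site = 5′ end + offset(length). Reads with uncalibrated lengths or
out-of-transcript P-sites are skipped *and counted*, so
assigned + skipped = input holds exactly on every run. Codon-unit
vectors cover all CDS codons including the stop (keeping the
conservation identity `codon sum + UTR tallies = assigned P-sites`
exact); UTR P-sites go to per-transcript 5′/3′ tallies used by the
5′UTR/CDS ratio analysis. Per-mean normalization divides by the mean
over *sense* codons (stop excluded); this makes the occurrence-weighted
mean over codon identities exactly 1 and is the natural normalizer for
identity-level statistics. An optional trim (default 5 codons in
metagene profiles) further excludes both CDS ends from the normalizer,
since start/stop pile-ups would deflate relative densities elsewhere;
the returned vector still covers every position. rpm normalization is
reads × 10⁶ / library size.

## Quality control

Genome-mapped reads are classified by a single nucleotide — the 5′ end —
into exon (union of exons of *all* annotated transcripts, not just the
chosen ones), else intron (inside any gene span), else intergenic. A
single-nt rule gives an exact three-way partition; junction-spanning
reads count as exonic. For reverse-strand spliced alignments the 5′ end
is the last aligned base (reference end − 1), respecting N operations in
the CIGAR. Chromosomes present in the BAM but absent from the annotation
count as intergenic with a warning. The pooled ("all lengths")
periodicity histogram shifts each accepted length by its offset, i.e.
reads aligned by their P-sites; the per-length in-frame fraction is the
share of window counts in the modal frame (mod 3).

## Metagene analysis

Transcripts enter metagene and feature analyses only if they pass a
coverage filter: ≥ 32 CDS P-sites and mean CDS density ≥ 0.1
reads/codon (both configurable). Per-mean normalization is unstable on
sparse transcripts; these thresholds are deliberate package defaults.

Whole-region profiles interpolate each transcript's codon densities onto
90 equal-width bins (default) with fractional assignment at bin edges —
binning conserves total mass, and a uniform transcript maps to a flat
profile of 1. Anchored profiles average normalized densities at fixed
codon distances from the start/stop codon (CDS mode) or at nt
resolution spanning the anchor (UTR mode); transcripts shorter than the
window contribute only where defined, and per-position *n* is reported.
Confidence bands are nonparametric bootstrap over transcripts (1000
resamples by default, seeded); the band is a 95% percentile interval.

The polarity score uses weights wᵢ = (2i − (L+1))/(L−1) over CDS codons,
giving −1/+1 for all mass on the first/last codon, 0 for uniform
density, and exact antisymmetry under coordinate reversal. Genes with
zero CDS density are excluded and counted.

## Feature analysis

*Codon/AA occupancy* is the mean normalized density over all CDS
positions encoding each identity across the gene set; the AA table is
the occurrence-weighted mean of its synonymous codons. Ratios between
conditions are reported as log2.

*Pausing scores*: there is no universal convention for which codon of a
tri-AA motif carries the pause, so the default scores the motif's
A-site codon (third residue) — pauses are conventionally
attributed to the decoding site — with `site` selectable among E/P/A or
the sum of all three. A motif's score is the mean over occurrences in
the gene set; motifs with fewer than 10 occurrences are dropped (8000
possible motifs invite sparse-noise artifacts).

*cAI*: within each synonymous family, w = f/max(f) from codon counts
over a user-supplied reference set (typically top-expressed genes);
zero-count codons take half a count before normalization, the standard
small-sample convention — note this makes weights exactly
duplication-invariant only when every codon is observed, which any
realistic reference satisfies. Single-codon families (Met, Trp) have
w = 1 and are excluded from the geometric mean, per standard practice.

*tAI*: each sense codon's absolute adaptiveness is Σ (1 − s) · tGCN over
anticodons able to decode it; Watson–Crick pairs have s = 0 and the
non-WC penalties default to the yeast-fitted set in wide use (G:U 0.41,
I:C 0.28, I:A 0.9999, U:G 0.68; wobble-position A is treated as
inosine). Weights are normalized to the global maximum; codons with no
recognizing tRNA get the geometric mean of the nonzero weights. The
penalty table is an ordinary mapping and fully overridable.

*Residue profiles* use the bundled Kyte–Doolittle hydropathy scale and a
net-charge scale (K, R = +1; D, E = −1; H = 0 at cytosolic pH), averaged
per codon position over the gene set and smoothed with a centered moving
average (default width 5, odd; width 1 disables smoothing). Local
cAI/tAI profiles are unsmoothed by default.

*Classification*: genes are labeled up/down/unblocked by the ratio of
mean rpm density over codons 1–100 between treated and control, with
threshold 1.5 (and its reciprocal); genes with fewer than 10 raw control
reads in the window are excluded. The statistic is threshold-monotone by
construction. Group features are compared with a Welch two-sample
t-test; two zero-variance groups with equal means give p = 1 by
convention.

*RPFdist* is the raw 5′UTR/CDS P-site count ratio per gene, excluding
genes with fewer than 16 CDS reads.

## Enrichment analysis

Both samples are rpm-normalized so sequencing depth cancels; replicates
are averaged position-wise first. The per-codon ratio is
(ip + ε)/(total + ε) with ε defaulting to 1/mean(total) per transcript —
zero-coverage codons stay finite while covered codons are barely
perturbed — followed by a centered moving average of 7 codons.
Transcripts whose total-sample coverage is below 0.2 raw reads/codon are
suppressed rather than shown noisy. Engagement onset is the first codon
where the smoothed ratio holds ≥ threshold (default 2.0) for ≥ 5
consecutive codons. Normalization is by library size only; per-transcript
mean-ratio scaling of IP to total is deliberately not applied, so the
ratio level carries the library-composition signal (targets rise above
1, non-targets sit slightly below). The module makes no SeRP-specific
assumptions and can compare any two libraries.

## The simulator

The generator emulates a good-quality yeast-like library: footprint
lengths peaked at 28–30 nt (probabilities 0.5/0.3/0.2) with offsets
12/13/13 nt, perfect frame-0 phasing by default, a 5× initiation
pile-up on the start codon, and gene structures with 1–3 exons on both
strands of two chromosomes. Optional plantings reproduce the regimes
the analyses are designed to detect: an unphased short-read class
(contaminant fragments with random 5′ ends), uniform intergenic/intronic
contamination on the genome, 5′UTR footprints, an early-elongation
stall (multiplier over codons 1–k on a labeled gene subset), pauses at
chosen tri-AA motifs (written into the CDS sequences so occurrences are
guaranteed), and SeRP engagement (multiplier from an onset codon on a
labeled target subset — keeping targets a minority mirrors real
selective profiling, where library renormalization leaves non-targets
near ratio 1). Reads are drawn by a single multinomial over (transcript,
codon) weights, 5′ ends are placed at P-site − offset, and genome
records are produced by lifting transcript intervals through the exon
blocks (spliced N CIGARs, reverse-complemented on minus-strand genes).
Output is plain SAM, byte-deterministic given (scenario, seed).

What it does **not** emulate: sequencing errors, duplicates/UMIs,
multi-mapping, isoform ambiguity, biased fragment ends, nucleotide-level
codon dwell-time variation, or RNA-seq counterparts. Passing tests
therefore demonstrate correctness of the computations on data matching
the stated read model, not robustness to every artifact of real
libraries.

Typical problem sizes in the test-suite and acceptance runs — 15–50
genes and 25k–100k reads per sample — were chosen so each planted effect
is detected with a comfortable statistical margin while a full run stays
in the minutes range on one core.

## Numerical choices and edge cases

- Deterministic tie-breaks throughout (transcript ids, most-upstream
  mode, sorted iteration) make reruns byte-identical.
- Bootstrap and simulation randomness always flow from an explicit seed.
- Per-mean normalization of an already normalized vector is a no-op
  (idempotence contract).
- Moving averages are NaN-aware and shrink at the edges, so smoothing
  conserves interior means and never widens the value range.
- Degenerate inputs raise informative errors rather than returning
  silent zeros: empty alignment sets, no length passing the periodicity
  screen, windows larger than every transcript, empty gene sets,
  all-zero tRNA tables.

## Known limitations

- Densities count P-site nucleotides, not whole-footprint coverage; a
  coverage mode is not implemented.
- A-site/E-site density views are available only as the fixed ±1-codon
  site options in motif scoring, not as a general density shift.
- Multi-mapped reads are resolved by keeping primary alignments only;
  weighted assignment is not implemented.
- No statistical test for differential engagement between SeRP
  conditions, and no peak deconvolution.
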