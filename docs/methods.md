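# Methods

`methdyn` implements a whole-genome-bisulfite (WGBS) analysis chain for a
three-time-point developmental study of a tissue methylome: per-cytosine
methylation calls are segmented into unmethylated and low-methylated
regions (UMRs/LMRs), differentially methylated regions (DMRs) are called
between consecutive time points, regions are annotated against chromatin
tracks and gene models, motif enrichment and interaction maps connect
regions to transcription factors and target genes, and the combined
evidence is assembled into per-transition regulatory networks.  A
synthetic-data generator with planted ground truth provides the validation
surface for every stage.

## Data model and conventions

Cytosine calls follow the Bismark cytosine-report dialect: 1-based
position of the cytosine on its strand, methylated/unmethylated read
counts, sequence context (CG / CHG / CHH, H = A, T or C), and the
strand-local trinucleotide.  All interval coordinates are 0-based,
half-open (BED convention) everywhere except inside the cytosine-report
dialect itself.  Symmetric CpG dyads are pooled onto the plus-strand
cytosine before segmentation and differential testing; counts are
conserved by construction.  Per-cytosine methylation level is
`n_meth / (n_meth + n_unmeth)`, undefined (NaN) at zero coverage, and
cytosines with fewer than 5 reads (configurable) are excluded from
region-level statistics — a standard WGBS coverage floor.

### Library QC

Fold coverage defaults to aligned bases over genome size
(`reads x read_length / genome_size`); the bare read-count quotient is
available behind a flag (`use_aligned_bases=False`).  Bisulfite conversion
rate is estimated from an unmethylated spike-in control as
`1 - sum(meth) / sum(total)` and reported as missing — never silently
1.0 — when no control is given.  For the methylation-context composition,
a cytosine counts as methylated either by a per-site binomial test of its
methylated count against the conversion-error rate (BH-corrected,
q < 0.05) when a spike-in is available, or by a simple level threshold
(default 0.1) otherwise; the criterion is configurable because different
published maps use different call rules.

## Segmentation (UMRs and LMRs)

Hypomethylated regions are detected with a transparent smoothing / merge /
threshold scheme:

1. each CpG's level is smoothed with a centred 3-CpG running mean
   (shrinking at chromosome edges);
2. a CpG is flagged hypomethylated when its smoothed level is < 0.5 *and*
   its own raw level is < 0.6 — the raw bound stops isolated
   high-methylation sites flanked by low neighbours from seeding or
   bridging candidates, which matters for the permutation null below;
3. consecutive flagged CpGs with inter-CpG gaps ≤ 300 bp (configurable
   `max_gap`; chosen to keep CpG-island-scale regions intact without
   fusing distal elements) merge into candidates;
4. candidates need more than 5 CpGs and are classified by raw mean
   methylation: UMR < 0.10, LMR in [0.10, 0.50) — the lower LMR bound is
   taken as inclusive; candidates at or above 0.50 are dropped;
5. any UMR/LMR pair sharing ≥ 1 bp would be removed (cannot arise from a
   single scan; the check guards merged segment lists).

The candidate set as a whole is gated by a permutation FDR: levels are
shuffled within each chromosome (positions fixed), candidates recounted
under B = 10 shuffles, and `FDR = mean(null count) / max(observed, 1)`
must be below 0.05.  Shuffling preserves the marginal level distribution
and CpG spacing while destroying spatial structure, so the null counts
measure how many candidates the level mixture alone would produce.

Time-point-specific regions are segments with zero same-type ≥ 1 bp
overlap at every other time point (a UMR overlapping only an LMR elsewhere
is still UMR-specific); the per-time-point status (UMR / LMR / neither) is
recorded for flow-diagram accounting.

## Differential methylation

Candidate windows slide over the CpGs covered in both conditions: 20
consecutive shared CpGs, step 5, maximum span 5 kb, minimum 5 shared CpGs
(trailing remainders are kept when not already covered).  The window width
of 20 is deliberate: the exact two-sided signed-rank p-value of an n-pair
window is floored at `2 / 2^n`, so 10-CpG windows (floor ≈ 2e-3) can never
survive Benjamini–Hochberg correction across genome-scale window counts,
whereas 20-CpG windows (floor ≈ 2e-6 after zero-dropping) retain power
while staying inside the exact-computation range.

The test of record is the exact two-sided Wilcoxon signed-rank test on
position-paired per-CpG level differences: zeros dropped before ranking
(the classical treatment), tied absolute differences mid-ranked, and the
null distribution over all 2^n sign assignments computed by subset-sum
convolution on doubled (integer) midranks — identical to brute-force
enumeration, used up to n = 25; beyond that a normal approximation with
continuity and tie correction takes over.  An unpaired rank-sum
(Mann–Whitney) variant is available (`variant="rank_sum"`).

A window is significant when |delta| strictly exceeds 30 percentage
points (absolute difference of window mean levels, later minus earlier)
and its BH-adjusted p across all windows of the transition is below 0.05.
Overlapping or book-ended significant windows of one direction are merged;
each merged region is re-tested on the union of its CpGs and must itself
pass both gates (BH re-applied across merged candidates).  Swapping the
two conditions flips every direction with identical |delta| and p.

## Region annotation

Overlap analysis is element-level: a query counts as overlapping when it
shares at least `min_bp` (default 1) bases with at least one track
element.  DHS-positive LMRs split into an insulator-like "CTCF-class"
(CTCF motif hit *and* CTCF site overlap), an "enhancer-class" (H3K4me1
overlap), and "DHS-other"; DHS-negative LMRs are "non-DHS".  Location
classes partition regions into promoter (within ±2 kb of a TSS — the
conventional complement of the > 5 kb "distal" definition, leaving a 2–5
kb band reported as "proximal"), exonic, intronic and intergenic, with
the signed distance to the nearest TSS and a CpG-island flag.

Liftover parses UCSC chain files exactly (header + block triplets,
forward- and reverse-strand query coordinates) and maps an interval when
at least `min_match` = 0.95 of its bases (the UCSC default) fall inside
the blocks of a single chain; the image is the span of the mapped bases.
Failures carry a reason: `no_chain`, `partial`, or `split` (coverage
sufficient only across several chains).  GWAS intersection takes index
SNPs plus LD proxies with r² ≥ 0.5 within 500 kb, locates them in lifted
LMRs, and attaches target genes through the interaction map.

## Motif analysis

PWMs are per-position base probabilities (JASPAR text input through
Bio.motifs, with a fallback parser for the letter-less four-row dialect;
pseudocount 0.8 split by background frequencies).  Scanning scores both
strands in log2 odds against the background; N scores zero; the default
hit threshold is 80% of the maximal achievable score (a JASPAR-style
relative score).  Enrichment of a foreground region set against a
length- and GC-matched background (±5 percentage points GC, foreground
excluded, deterministic under seed) uses the hypergeometric upper tail on
region-level hit counts with BH q-values across motifs.  Candidate
factors are filtered for expression: maximum RPKM above 1.  Two screen
gates are exposed: p < 1e-10 for the genome-wide LMR/UMR screens and
p < 0.01 for the per-transition DMR sets feeding network construction.

## Target assignment and networks

Interaction maps (curated "known" and computationally "predicted"
region–gene links, consumed as generic tables) assign a gene to every
region sharing ≥ 1 bp with the interaction's region interval; when both
evidence classes support one pair, "known" wins.  Summaries count unique
genes per region class and time point, with the deafness-gene subset
alongside.

A regulatory edge TF → gene for a transition requires four independently
checkable gates: (i) the TF's motif is enriched (p < 0.01) in the DMR set
of the supporting DMR's direction, (ii) the motif has an actual scan hit
inside that DMR (configurable down to set-level enrichment), (iii) an
interaction assigns the DMR to the gene, and (iv) expression
anti-correlation — hyper-DMRs pair only with down-regulated genes and
hypo-DMRs with up-regulated ones (adjusted p < 0.05 where available,
sign-only otherwise), with the TF itself expressed (RPKM > 1) at the
transition's time points.  Without an expression table the result is an
empty edge list, not an error.  Ego networks take all nodes within a
given undirected radius of a centre factor, with centre-touching edges
flagged as direct.

## Synthetic data

The generator emulates the study design the pipeline targets: three
time-point methylomes (embryonic / perinatal / mature) over a configurable
genome, with a "developmental" transition (DevTrans) and a "maturation"
transition (MatTrans).  Defaults, chosen once as the package's study
conditions: one 600 kb chromosome at GC 0.42; 10 UMRs (1.5 kb, at gene
promoters, 80% carrying a CG-dense island) at level 0.03; 20 LMRs
(800 bp, TSS-distal) at 0.30; background 0.85; 16 DMRs (800 bp, delta
0.40, four per transition × direction so that each DMR set is large
enough for the hypergeometric motif test to resolve); coverage
Poisson(15) per strand, floored at 1; flat non-CpG methylation rates
(0.002, 0.002, 0.012) with the mature stage elevated, mirroring the
maturation-stage rise of mCH seen in neural-lineage tissues.  The genome
spans 600 kb rather than less because planted regions must remain a small
minority of CpGs for the permutation-FDR gate to be informative.

Planted regions are non-overlapping, separated by background, with ≥ 6 kb
clearance around every TSS so distal regions stay unambiguously distal.
Tracks are wired to the truth: DHS covers 90% of LMRs, H3K4me1 the
non-CTCF DHS-positive LMRs, CTCF sites (with a planted CTCF-like motif
instance) 12% of them; enhancer-validation-like fragments overlap 80% of
their planted count.  Two synthetic TF motifs (10-bp consensus PFMs) are
planted: one into a subset of LMRs (the enrichment screen's signal) and
one per DMR according to the transition's assigned factor; each LMR/DMR
links to exactly one tail-placed target gene through an interaction map
split between "known" and "predicted".  Expression is anti-correlated
with planted DMR direction at a configurable compliance (default 0.9),
with planted TFs always expressed above RPKM 1.  An unmethylated spike-in
control (methylation = 1 − conversion rate, default error 0.005) supports
the conversion-rate QC.  A fixed seed yields byte-identical output files.

What the generator does *not* model — and hence what passing tests do not
establish about real data: read-level alignment artefacts, replicate
variance (one merged table per time point, matching a pooled-replicates
design), spatially structured non-CpG methylation, partially methylated
domains, copy-number or mappability biases, and realistic motif/GC
sequence composition beyond the planted structure.

## Numerical choices and degenerate inputs

Exact signed-rank p-values use float64 subset-sum tables (exact below
2^53; n ≤ 25 ⇒ 2^25 assignments).  All-zero difference vectors give
p = 1 and delta 0.  Empty call tables segment to an empty list with a
warning; a candidate set failing the FDR gate returns empty rather than
partially filtered.  Equal-coverage boundary cases are strict: region
mean exactly 0.10 classifies LMR, |delta| exactly 30.0 is not a DMR,
enrichment p exactly 1e-10 fails the screen, LD r² = 0.49 is excluded
(0.50 included).  Background matching doubles its GC tolerance with a
warning when placement fails repeatedly.  BH correction is
statsmodels' `multipletests(method="fdr_bh")` throughout.

## Problem sizes

The validation suite runs the segmentation recovery study on a 5 Mb
genome with 200 planted UMRs and 200 LMRs, DMR sensitivity on 2 Mb with
60 planted DMRs, null calibration on 10,000 simulated windows, and the
network study on the 600 kb default genome — sizes chosen so the full
suite completes in about a minute on one core while every statistic
retains enough events to be meaningful.

## Known limitations

The segmentation is a single-pass threshold scheme, not an HMM: region
boundaries are CpG-resolution and shoulders of strong UMRs occasionally
emit short flanking LMR calls (visible as a few extra LMR predictions in
the recovery scores).  The DMR caller assumes position-matched coverage
in both conditions and ignores within-window level trends.  Network
inference is deliberately conservative — every gate must pass — so its
recall on real data depends directly on the completeness of the
interaction map and expression table supplied.
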