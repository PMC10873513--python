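# Methods

This note documents the models, statistics and numerical choices behind
`polredist`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Coordinate conventions

All internal coordinates are 0-based, half-open (BED-native). Strands are
explicit; the TSS of a minus-strand gene is `end − 1` and all profile axes
run TSS → TES regardless of strand. GTF input (1-based, closed) is
converted on read and the conversion round-trips exactly. A read "overlaps"
a coverage bin if at least one base intersects it; with the default 10-bp
bins this matches pileup-then-bin behaviour closely and is exactly testable
against a brute-force per-base oracle.

## The elongation model

The nascent-read generator draws a read's 5′ end from a two-component,
per-base intensity that is **globally proportional across genes**:

* with weight `π · min(w, L)` the read falls uniformly in the
  promoter-proximal window `[TSS, TSS + w)` (default w = 500 bp), modelling
  the paused/promoter-proximal polymerase pool;
* with weight `(1 − π) · ∫₀ᴸ s^(d/1000) dd` it falls in the gene body with
  density ∝ `s^(d/1000)` at distance d bp from the TSS, i.e. a per-kb
  survival probability `s` for the elongating polymerase.

Reads are allocated to genes in proportion to each gene's total mass under
this intensity (times an optional per-gene initiation weight). This choice
matters: it makes the per-base body density of every gene proportional to
`(1 − π) · s^(d/1000)` with one global constant, so the expected body log2
fold change between a depleted and a control condition is

    log2FC(d) = C + (d / 1000) · log2(s_dep / s_ctrl)

with a *global* constant C and no gene-specific renormalization. Two
consequences are used throughout the tests: the per-kb log2FC slope is
known in closed form, and the mean body log2FC of a gene is `C + slope·L/2`
— linear in gene length, which is what produces the quartile-monotone
redistribution and the negative length–log2FC correlation. (The alternative
— fixed reads per gene with within-gene renormalization — cancels the
length trend to first order and makes the flat limit s = 1, π = 0 produce
1/L per-base densities rather than uniform coverage.) Under this
parameterization `π` is the promoter weighting of the intensity, not the
exact promoter read share of every gene; the realized share depends mildly
on gene length.

Defaults for the two study conditions: control `s = 0.999`/kb, `π = 0.3`;
depleted `s = 0.99`/kb, `π = 0.5` — a ten-fold drop in the per-kb loss rate
plus increased pausing, the regime where a 100-kb gene loses about
`100 · log2(0.99/0.999) ≈ −1.3` log2 units of far-body signal. Reads are
50 bp, single-end, strand-matched to the gene. Spike-in reads are a
binomial `spike_fraction` (default 5%) of the library, uniform over a
reserved geneless chromosome (`spike1`); labelling spike reads by
chromosome carries the same information as a second alignment pass without
bringing alignment into scope.

What the generator does **not** emulate: sequencing error, fragment-size
distributions, mappability, multi-mapping, expression heterogeneity beyond
the initiation weights, splicing dynamics, or condition-dependent library
composition other than the elongation parameters. Passing recovery tests
therefore demonstrate that the analysis code measures what the model
plants, not that real libraries satisfy the model.

## Screen statistics

z-scores standardize each well against the mean and sample standard
deviation (ddof = 1) of **all** wells of its readout, control wells
included (the readout-wide "all wells" reading; excluding controls is a
flag away). Hypothesis tests are unpaired equal-variance (Student) t-tests
of each target's replicates against the pooled non-targeting control
(NTC): the literal reading of an unqualified "unpaired t-test"; Welch is
available as a switch. The EdU readout is two-sided with hits additionally
required to *decrease* the mean (a delay in S-phase progression); the two
pKAP1 readouts are one-sided for an increase in percent-positive cells.
Hit thresholds are raw p-values — 0.05, except 0.15 for the +ATR-inhibitor
readout — with no multiple-testing correction at the screen stage. Under
the null the one-sided readouts call at their α and the EdU readout calls
at α/2 because of the direction requirement; the type-I calibration checks
are made on the t-test p-values themselves. Because all targets of a
screen share one NTC sample, their calls are correlated; calibration is
therefore assessed on screen-level fractions (the exchangeable unit), not
on pooled per-test counts.

The packaged reference screen (`simulate.reference_screen`) is a synthetic
stand-in for a focused 86-target screen: effects are planted so that 4
targets respond in all three readouts, 8 in exactly two, and per-readout
hit counts land between 8 and 56. Non-responding targets carry small
opposite-direction offsets so the planted structure is recoverable
essentially deterministically at the default noise level; the stochastic
null behaviour of the statistics is tested separately under a true null.

## Spike-in and read-count normalization

ChIP-Rx factors are `min_j(spike_j) / spike_i`, so the sample with the
fewest spike-in reads keeps factor 1.0 and all factors are ≤ 1. The factor
can be applied two ways, both provided because both are defensible
readings of common practice: seeded subsampling of the read list to
`round(factor × mapped)` (banker's rounding, for cross-platform
determinism), or scale-only multiplication of coverage values. Read-count
normalization subsamples every library to the smallest library's size.
Subsampling is hypergeometric, hence unbiased per bin; the binomial
thinning property (expected coverage = factor × original) is what the
tests check.

## BLISS break quantification

Demultiplexing assigns a read to the unique barcode within Hamming
distance 1; ties and distance > 1 go unassigned, and barcode sets with
pairwise distance ≤ 2 trigger a warning. UMI deduplication keys on the
exact tuple (chrom, position, strand, UMI) — mismatch tolerance is a
barcode property, not a UMI property here — and is a projection
(idempotent). In-silico digestion finds all exact motif occurrences; the
default AsiSI site `GCGATCGC` is its own reverse complement, so a
single-strand scan is complete (asserted at runtime); other motifs are
scanned on both strands and merged. Breaks are counted at a site if the
break position lies within `[site − w, site + len(motif) + w)` for any
site, each break once, with w = 250 bp by default (the counting window is
not dictated by anything in the data; it shifts calibration only, and the
window-invariance of the pipeline properties is part of the test suite).

Cross-sample normalization anchors on the restriction cuts: with equal
cutting efficiency everywhere, restriction-window counts are proportional
to library depth, so each sample is subsampled genome-wide to
`round(min_j(asisi_j)/asisi_i × total_dedup_i)` events. The relative break
burden (`relative_break_counts`) is then computed on the normalized
**non-restriction** events by default: the exogenous calibration cuts are
equalized across samples by construction, so including them would compress
any true biological difference toward 1 (a 2× planted background
difference would read as < 2×); the raw-total variant is available via
`exclude_asisi=False`.

The BLISS generator models fixed-efficiency cutting across a cell
population as Poisson(molecules × efficiency × depth) per site — not a
per-site Bernoulli, which at desk-scale site counts would add large
binomial noise to the anchor that population-scale cutting does not have.
PCR duplication emits each molecule Geometric(1 − duplication_rate) times
with the same UMI; barcode corruption is at most one substitution per
read.

## Profiles, metagenes and the redistribution statistic

Expressed genes default to ≥ 10 summed reads (profile gene universes);
the differential analysis removes genes with < 5 summed reads — both
thresholds are explicit parameters, applied to counts summed across
samples (the simplest auditable aggregation). Length stratification drops
genes shorter than 10 kb (intronic signal is unreliable below that), then
stably sorts by (length, gene_id) and cuts contiguous groups of size
⌊n/k⌋ with the remainder in the last group(s) — n = 8365 gives
2091/2091/2091/2092.

Gene bodies are rescaled by **mean density per equal-width segment**
(default 100 segments; mass-preserving and oracle-checkable against
per-base extraction), not by interpolation. Flanks use fixed-width bins.
CPM scaling (density × 10⁶ / mapped reads) precedes averaging, making
metagenes invariant to read duplication. Heatmaps append a fixed 10-kb
downstream extension past the TES so the end-of-gene boundary is visible
at every gene length; rows are sorted by ascending length and values are
`log2((t + ε)/(c + ε))` with ε = 1 CPM by default (bounded log ratios on
zero bins).

The redistribution statistic reports, per length quartile, the mean
log2FC in the promoter window `[TSS, TSS + 500)` and the mean over scaled
body segments of the per-segment log2FC. The body statistic deliberately
averages *positional* log2FC values rather than taking the log ratio of
body means: a 5′→3′ redistribution within the body leaves the body mean
almost unchanged (the survival model changes the shape, not the within-
gene mass, of the body under global allocation with fixed totals), so a
ratio of means is blind to exactly the effect of interest.

The per-kb slope estimator (`body_log2fc_slope`) fits an OLS line of
per-segment log2FC against TSS distance per gene and averages the
per-gene slopes — under the model the slope is shared while the intercept
is gene-specific, so pooling across genes without per-gene intercepts
would bias the fit. Defaults of 50 body segments and ε = 0.05 CPM balance
two opposing small-sample effects (pseudocount attenuation pulls the
slope toward zero; the concavity of log of noisy Poisson means pulls it
away); the first two segments are skipped to keep the promoter pool out
of the body fit. At the depths used in the recovery runs the estimator is
within a few percent of the analytic slope.

## Differential statistic and length–FC analytics

The differential stand-in is deliberately simple and fully specified
rather than a re-implementation of a negative-binomial GLM: counts are
normalized to the smallest library, `log2FC = log2((mean_t + 1)/(mean_c + 1))`,
p-values come from a two-sided equal-variance t on `log2(normalized + 1)`
replicate values, and FDR is Benjamini–Hochberg (step-up, clipped at 1;
implemented directly and cross-checked against an independent
implementation in the tests). The interface accepts externally computed
p-values so a negative-binomial test can be spliced in without changing
anything downstream. Counting modes: exonic (exon union), second-half
(strand-aware 3′ half by genomic midpoint) and intronic (intron union
after exon/blacklist filtering); reads overlapping regions of more than
one gene are discarded as ambiguous and reported.

The length–fold-change correlation defaults to log10(length) — fold
changes respond to order-of-magnitude length differences and the bp scale
lets a few 300-kb genes dominate the fit — with a `length_scale="bp"`
switch, and reports Pearson r with the two-sided t-transform p.

## Problem sizes used in the recovery runs

The packaged recovery runs use 300 genes × 600k reads per condition
(redistribution and slope), 2,000 genes × 60k reads × 3+3 replicates
(length–FC correlation), 2 × 10 Mb genomes with 10 vs 20 breaks/Mb at
1× vs 3× depth (BLISS), and 500 replicate screens (null calibration) —
sizes chosen so that sampling error is comfortably inside the recovery
tolerances while a full run stays in the minutes range on a single CPU.

## Known limitations

* No alignment, no BAM/bigWig binary I/O (SAM is read-only; bedGraph is
  the track format); paired-end fragments are not reconstructed.
* The differential stand-in has less power than a dispersion-sharing NB
  model at small replicate counts; its role is a specified, testable
  statistic, not a drop-in for edgeR/DESeq2.
* Plate-effect normalization (B-score, loess), SSMD and image
  segmentation are out of scope for the screen module.
* The restriction-anchored normalization assumes equal cutting efficiency
  across samples; if cutting differs, depth and biology are confounded by
  construction.
* Multi-mapped reads are passed through, not filtered; the coverage
  builder treats every supplied interval as one read.
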