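# Methods

This note documents the models implemented in ximosaic, the defaults and why
they were chosen, the statistical conventions, and what the synthetic data
do and do not capture.

## The mosaic reactivation model

A female cell silences one X chromosome; deleting Xist after silencing is
established perturbs maintenance rather than initiation, and single-gene
reporters show an all-or-none pattern: a few percent of cells express the
Xi allele fully, the rest not at all. ximosaic models this as a binary
indicator per (X gene, cell), drawn with probability

p(e) = p_max · e^h / (e^h + e50^h)

where e is the gene's expression rate (expected reads per active allele at
unit depth). The Hill form encodes the observation that stronger promoters
are more prone to losing silencing. Defaults: **p_max = 0.04, e50 = 1.5,
h = 1.2**, calibrated so that a gene at the top-tercile median expression of
the default fixture reactivates in ≈3.6% of cells (the few-percent regime
of a highly expressed neuronal gene) while a gene 100-fold lower sits at
≈0.14% (the order-of-magnitude-lower regime of low-activity cells).
`e50 = 0` is the uniform limit (every gene at p_max), used to inject an
exactly known reactivated fraction.

Two coupling modes are available because a single-reporter experiment cannot
distinguish them: `locus` (default) draws indicators independently across
genes within a cell; `chromosome` draws one chromosome-wide event per cell
and thins it by each gene's relative propensity, preserving the per-gene
marginals while making reactivation co-occur within cells. Both satisfy the
same expected-count contract, so all mean-level analyses are identical
between modes.

An optional `escape_fraction` adds a constant basal Xi output to every X
gene in both conditions (XCI escape); it defaults to 0 — the baseline Xi is
fully silent.

## Bulk RNA-seq counts

Expected counts are `2·e·depth` (autosomal, two active alleles) and
`(1 + f̄)·e·depth` (X-linked: the Xa plus the reactivated share of Xi
alleles, f̄ = mean indicator over the sample's cells). Counts are
gamma-Poisson (negative binomial) with variance `m + α·m²`; **α = 0.05**, a
single dispersion shared across genes — the simplest overdispersion
adequate for the rank-based and mean-based analyses used here. `α = 0`
gives exact Poisson sampling.

Defaults per sample: 10,000 cells, 3 replicates per condition (matching the
n=3 study design), **depth = 60**. The depth is chosen so that ~90% of X
genes clear the 20-read filter, i.e. a filtered universe of ≈540 of 600 X
genes — the size at which terciles of 180 and quartiles of 135 genes arise.
Expression rates are log-normal with **σ = 2.3**, putting the top tercile's
median expression roughly one order of magnitude above the middle and two
above the bottom tercile.

## The genome fixture

Chromosomes are 4 synthetic autosomes (19 real ones collapsed;
configurable) plus X, with 15,000 autosomal and 600 X genes on a regular
12-kb grid. Coordinates are 0-based half-open everywhere; BED is written
natively. TSS convention: interval start for `+` genes, `end − 1` for `-`
genes.

Each chromosome carries `n_islands_per_chrom` (default 600) CpG islands
attached to a seeded random subset of its genes — on X that is every gene.
An island sits with its midpoint within ±2.5 kb of the host TSS with
probability 0.9, otherwise mid-slot, 6 kb from any TSS (intergenic
background, unlinked). Islands have 15–35 CpG sites spaced 40–80 bp apart.
The spacing floor (≥ 2·cut_offset) means isolated-fragment geometry holds
for every site in generated fixtures, keeping expected island counts exactly
linear in methylation probability; truncation of closely spaced cuts is
still implemented and exercised on constructed inputs. Each site is
assayable by an independent Bernoulli(0.5) draw fixed for the fixture's
lifetime — an abstraction of the enzyme's sequence-context constraint that
leaves about half of all CpGs interrogatable.

## Methylome and its perturbation

Baseline per-site methylation probabilities: autosomal alleles 0.35, Xa
0.15, Xi 0.85 (the hypermethylated inactive X). The Cre- methylome is the
baseline. On the Cre+ Xi:

- islands linked to a gene are demethylated by a factor
  `d(e) = d_max · e^h/(e^h + e50^h)` of the linked gene's expression
  (**d_max = 0.2**, same Hill shape as reactivation), so demethylation
  tracks transcriptional propensity; this yields a tercile-1 vs
  terciles-2+3 methylation-ratio contrast of ≈0.025 — the observed scale;
- a random **10%** of X islands instead gain methylation
  (`p → p + 0.1·(1 − p)`), making the change bidirectional with a
  predominant hypomethylation shift;
- unlinked background islands are untouched.

## MeD-seq digestion model

The enzyme cuts at a fixed offset downstream of a methylated cytosine on
its own strand. We place a blunt double-strand break **cut_offset = 16** nt
downstream of each methylated C; for a CpG methylated on both strands the
two breaks fall at half-open boundaries `c − 15` and `c + 17`, releasing
exactly `2·cut_offset = 32` bp. The staggered nick pair (sticky ends) is
not modeled; 16 is used because it reproduces the canonical ~32-bp product.
Hemimethylated CpGs cut one strand only and release no sized fragment;
non-assayable sites never cut.

When methylated CpGs lie closer than a fragment length, breaks interleave:
fragments are the intervals between consecutive breaks that contain at
least one methylated CpG, so close pairs come out short and the size window
(**27–37 bp**, loose enough to tolerate moderately shortened products; the
physical gel window is not published) removes them — no special casing.
Fragments are assigned to the island containing their midpoint
(lower-median position for even lengths); midpoints outside every island go
to a background tally. Fragments extending past a chromosome end are
dropped with a logged warning.

Sampling: per sample, per cell (default 50; enough for per-island counts in
the hundreds at 2 replicates) and per allele copy (two autosomal copies,
Xa, Xi), symmetric methylation is drawn i.i.d. per site, the copy is
digested, size-selected, thinned by `capture_efficiency · depth_scale`, and
tallied. Expected island abundance is the summed per-allele site
probabilities × cells × thinning.

## Statistical conventions

- **Normalization**: each sample is scaled so its autosomal total (genes or
  islands) matches the across-sample geometric mean of autosomal totals; X
  features share the factor but never enter it, so an X-wide dosage or
  methylation change cannot distort the scaling. A sample with zero
  autosomal reads is an error.
- **Low-coverage filter**: a gene is retained iff its raw reads summed over
  all samples are ≥ 20 ("fewer than 20" excluded, so exactly 20 is kept).
  The filter defines the gene universe before any stratification.
- **Ratio**: per-condition means of normalized counts by default; a
  `pooled` mode sums raw reads instead. Zero-total genes have undefined
  ratios and are excluded downstream.
- **Stratification**: retained X genes are ranked by the mean normalized
  count over **all** samples, ties broken by gene_id, and cut into k
  contiguous blocks; remainders go to the lowest bins. The all-sample mean
  is used rather than the control-only mean deliberately: conditioning on
  the ratio's own denominator selects against genes whose control counts
  fluctuated low and biases the extreme bins (≈ +0.01 in the bottom
  quartile at these depths, enough to reverse the true ordering), while the
  all-sample mean is symmetric in the two conditions and exactly unbiased
  under the null.
- **Between-bin tests**: two-sided pooled-variance Student's t (a Welch
  option exists but is not the default, since the pooled test is the named
  convention this design follows); identical constant groups report t = 0,
  p = 1; zero pooled variance with unequal means reports p = 0. No
  multiple-testing correction — a handful of planned comparisons.
- **Dosage shift**: fc = (mean_mutant + c)/(mean_control + c) with
  pseudocount **c = 0.5** (keeps zero-control genes finite without moving
  high-count genes); the shift is computed on the fc scale, where an
  upshift of a fraction f appears as ≈ +f; log2 values are carried for
  plotting. Two-sided Wilcoxon rank-sum (`scipy.stats.ranksums`);
  direction is read from the sign of the mean shift. The reported mean
  shift is the difference of group means (an unweighted mean of per-gene
  differences is not defined across groups of different sizes; the output
  labels the convention).
- **TSS linkage**: island midpoint to nearest TSS, inclusive at 4,000 bp;
  equidistant ties go to the lexicographically smaller gene_id; each island
  links to at most one gene.
- **Tercile methylation contrast**: group A = islands of tercile-1 genes,
  group B = terciles 2+3 combined; the output reports both the absolute
  ratio difference and the relative reduction, since "percent reduction in
  methylation" is ambiguous between the two.
- **Seeds**: every stage derives its seed as
  `sha256(master|stage|index) mod 2^31`; identical configs reproduce every
  output byte-for-byte, and all tables carry a provenance header (config
  hash, master seed).

## Problem sizes in the test suite

The suite runs the analyses at the full default fixture scale (15,600
genes, 3,000 islands) for single runs, and uses 200-seed Monte Carlo for
the type-I/power checks, 60 seeds for the quartile-ordering check, and 12
simulation replicates per condition for the reactivated-fraction recovery
check — sizes at which the Monte-Carlo standard errors are comfortably
below the effects being asserted while the whole suite stays desk-scale.

## What the simulator does and does not capture

It emulates: gene-level count matrices with realistic overdispersion and
library-size variation, a mosaic all-or-none reactivation signal that
scales with expression, MeD-seq island counts with the correct digestion
geometry and assayability thinning, and the coupling of derepression and
demethylation through a shared expression response.

It does not capture: reads or alignment (no FASTQ/BAM), transcript
isoforms, explicit cell types (the neuron/astrocyte contrast is represented
only through expression rates), XCI escape genes (off by default),
enzyme sequence-context specificity beyond a site-level assayability flag,
chromatin state, or a real genome annotation. Passing tests therefore
demonstrate that the analyses behave correctly under the stated generative
model — not that real brain data meet that model's assumptions
(independent cells, shared dispersion, symmetric methylation, island-level
homogeneity).

## Known limitations

- Under the null, X and autosomal fold-change distributions are not
  perfectly exchangeable: X genes carry one active allele, so at equal
  expression they have half the counts and slightly heavier-tailed fold
  changes near the filter boundary. The Wilcoxon type-I error at α = 0.05
  measures ≈7–8% at default scale rather than exactly 5%.
- The per-gene fc of a single control against the mean of two others is
  heavy-tailed at low counts, so control-consistency *mean* shifts are
  noisy even when the rank test is null; the normalization-restoration
  property is exact and is what the tests assert.
- The inverted fraction estimator f̂ = (2r̄−1)/(1−r̄) is unbiased to second
  order at these depths but has Monte-Carlo error ≈0.009 per single
  3-replicate experiment at f ≤ 0.05; averaging over independent
  simulations (or more replicates) is needed for ±0.01 accuracy.
- `p_meth` values are island-homogeneous; within-island heterogeneity and
  gene-body vs promoter island classes are not modeled.
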