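# Methods

## Scope and model

The package implements the computational core of a derepression screen: a
repressive chromatin mark (H3K27me3, written by a PRC2 methyltransferase) is
profiled at transcription start sites in control cells, gene expression is
compared between control and methyltransferase-knockout cells, and genes
that are both marked and significantly upregulated on knockout are reported
as candidate direct targets of the repressor.  Inputs are per-gene fragment
counts with a two-condition replicate design, ChIP tag positions, and a gene
annotation; read alignment, peak calling and isoform quantification are out
of scope — tags and counts are taken as given.

Coordinates are 0-based half-open throughout (BED convention).  A gene's
TSS is its strand-aware 5' end; its exonic length is the length of the
union of its exon intervals.

## Expression scoring

FPKM is computed literally from its definition,
`count / ((exonic_length/1e3) · (library_size/1e6))`, with library sizes
supplied explicitly (they may exceed the column sums when the annotated
gene set does not cover every mapped fragment).  No expression filter is
applied; all-zero genes ride through with diffrat 0 and non-significant
status.

The effect/ranking statistic on condition means `a` (mutant) and `b`
(control) is

    diffrat(a, b) = |a − b| · log2((a + 1)/(b + 1)),

zero iff `a = b`, antisymmetric, sign following `a − b`.  It blends
absolute and relative change: strong on robustly expressed fold changes,
deliberately insensitive to ratios between near-zero values.

### Significance: two permutation schemes

`method="per-gene"` is the transparent reference scheme: a two-sided
permutation test on |diffrat| per gene over the distinct assignments of
samples to conditions — exhaustive when `C(n, n₁)` is within the
permutation budget (then `p = #{|d*| ≥ |d_obs|}/#splits`, the observed
assignment included), otherwise uniformly sampled without replacement with
add-one smoothing `p = (1+k)/(1+B)`.  Ties count as extreme (conservative);
Benjamini–Hochberg adjustment follows.  Its resolution is bounded by the
design: with three replicates per condition there are 20 balanced splits
and the sign symmetry of |diffrat| makes `p ≥ 2/20 = 0.1` for every gene,
before any multiple-testing adjustment.  No per-gene exchangeability
argument can do better — with six exchangeable samples, a single gene
simply does not contain evidence at the 0.01 level.  The scheme is kept
because it is exactly checkable against brute-force enumeration and
anchors the type-I behaviour of the pipeline.

`method="pooled"` (the default caller) earns genome-wide resolution the way
few-replicate designs must: by borrowing the null across genes.  The
observed statistic is a moderated standardized difference on
`y = log2(FPKM + 1)`:

    t_g = (ȳ_mut − ȳ_ctrl) / ((s_g + s0_g) · sqrt(1/n₁ + 1/n₀)),

where `s_g` is the pooled within-group standard deviation and `s0_g` a
moderation constant — the median `s` of the gene's expression stratum
(genes are split into 10 equal-occupancy strata by mean `y`; the constant
is computed once from the observed labels).  Stratified moderation makes
the statistic comparable across expression levels: low-count genes have
intrinsically noisier `y`, and a single global floor would let their lucky
splits dominate the pooled tail.  The statistic is recomputed for every
distinct relabelling except the two that reproduce the observed grouping
(which carry the full effect and would contaminate the null), and all
gene × split values form one pooled null; a gene's one-sided p is the
add-one-smoothed rank of its observed `t` in that pool — its expected rank
under label exchange.  Up- and down-regulation are each BH-adjusted at
level α (classic rank-based-caller practice); the reported `p_adj` is the
smaller of the two directional adjusted values, `p_raw` the doubled smaller
one-sided p capped at 1, and status requires `p_adj ≤ α` with the diffrat
sign setting the direction.

Design rationale, recorded because the design was genuinely open: a pooled
null on raw |diffrat| fails twice over — its tail is owned by the sampling
noise of the most expressed genes (the statistic has no variance
normalization) and, in data with real effects, by the attenuated effects
that balanced relabellings retain.  Rank-product-style pooling of pairwise
fold-change ranks removes the scale confound but is structurally
knife-edged: with k truly changed genes among n, a typical target cannot
rank above ~k/2, while the BH threshold is α·k/n — both scale with k.  The
moderated pooled statistic avoids both traps: standardization equalizes
genes across the expression range, recomputing `s_g` per split inflates the
denominator exactly for the relabellings that mix conditions, and the
Gaussian-like tail of a studentized mean difference separates a 4-fold
effect from noise far faster than a rank tail.  Under a global-null
simulation (no effects, 2000 genes, 3v3) both schemes call nothing at
adjusted p ≤ 0.01.

Degenerate inputs: an all-constant gene has `t = t* = 0` and receives
p = 1; a denominator of exactly zero yields statistic 0 rather than NaN.
Comparisons against the pool use a ±1e-12 guard so float noise cannot flip
a tie.

## Chromatin scoring

Raw score: the number of tags with `TSS − 2000 ≤ pos < TSS + 2000`
(half-open, clipped at 0; both tag strands counted — a histone mark has no
strand).  "Within 2 kb" is read as ±2 kb; genes on chromosomes absent from
the tag library count 0 with a logged warning.  One TSS per gene (the
annotation's canonical 5' end).

Scaling anchors 10 at the smallest raw count capturing 95% of genes — the
empirical quantile taken as a data value (`inverted_cdf`), so a gene at
exactly the anchor scores exactly 10:

    scaled = min(10, 10 · log2(raw + 1) / log2(anchor + 1)).

Counts above the anchor clip to 10 (a 0-to-10 scale is bounded); an
all-zero anchor maps everything to 0.  The base of the logarithm cancels in
the ratio; log2 is used for consistency with diffrat.  Classification:
scaled ≤ 2 → low, > 2 → high.  The quantile is computed on raw counts (not
log counts); with ≥ 5% of genes at or above the anchor, at most ~5% can sit
at the clip.

No input-chromatin normalization, no peak or domain calling, no
fragment-shift modelling: the score is deliberately the plain windowed tag
count the classification rule was defined on.

## Synthetic study generator

The generator emulates the *statistical structure* the analysis assumes,
not the sequence level: two genotypes with per-embryo replicate libraries
(3 per condition by default; the replicate number is a modelling choice,
configurable), ~18% of genes marked, a small marked subset truly
upregulated in the mutant (50 of 2000 at desk scale, echoing 231 of a
~20k-gene transcriptome), a smaller marked subset downregulated (6,
echoing 29), and an unmarked differentially expressed background (80,
proportional to the study-scale burden).

Defaults, with units and rationale:

- `n_genes = 2000`, two synthetic chromosomes, intergenic gaps 5–25 kb,
  exonic lengths log-normal around 1.5 kb (floor 200 bp), 1–8 exons.
- Baseline expression: FPKM ~ LogNormal(μ=1.0, σ=1.0) — median ≈ 2.7 FPKM
  with a realistic dynamic range.  Marked genes are depressed 4-fold
  (`marked_baseline_factor = 0.25`): repressed chromatin is lowly
  transcribed, and this is the depression the marked-vs-expression
  companion test is expected to detect.
- Direct targets' silenced baseline is redrawn to at least 1 FPKM
  (`min_target_baseline`): a derepression phenotype presupposes a
  detectably expressed transcript — the archetypal targets of such screens
  (matrix proteases and their transcriptional activators) are robustly
  expressed once the mark is lost.  Genes silenced below detection are not
  meaningful "derepressed targets" at any analysis' power.
- Counts: negative binomial, common dispersion 0.05 (typical inter-embryo
  biological variability for inbred material), mutant mean = baseline ·
  2^log2FC with |log2FC| ~ N(2.0, 0.25).  Library size 30 M fragments per
  sample: depth is kept realistic — the desk-scale reduction is in gene
  count, not in per-gene counting statistics, so a 0.7-FPKM gene still
  receives ~40 fragments and count shot noise does not masquerade as
  biology.
- ChIP tags: Poisson background at 5e-5 tags/bp (0.2 expected per 4-kb
  window) plus 200-fold enrichment inside marked TSS windows (~40 tags).
  At these rates the 2/10 boundary separates ≤1-tag from multi-tag windows,
  giving a high/low call with sensitivity ~1.0 and specificity ~0.98
  against truth — sparse desk-scale libraries where background at an
  unmarked promoter is a stray tag, as in a well-enriched immunoprecipitate.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: GC/length biases and library-size
imbalance between samples; gene-gene correlation and co-regulated modules;
batch structure across embryos; broad chromatin domains, mappability gaps
and input-dependent ChIP background; partial mark loss or heterogeneous
knockout efficiency; multi-TSS genes.  Recovery rates on the fixture
certify the pipeline's logic under its own assumptions, not field
performance.

Determinism: every stage draws from an independent, deterministically
derived RNG stream of the config seed; identical configs are
bit-reproducible, including written files (hash-checked in tests).

## Integration and association analyses

DE status × mark class yields six categories that partition the gene
universe (checked as a conservation law).  "Differentially expressed" in
the association test means status ≠ ns at the caller's α = 0.01.  The
marked-vs-expression comparison is a two-sided Mann–Whitney rank-sum on
per-gene mean FPKM within each condition (no distributional assumptions;
the assertable contract is the direction of the median shift plus
significance).  Mark-vs-DE independence is the two-sided Fisher's exact
test on the 2×2 table.

## Rescue genetics

Genotype fractions come from independent uniform gamete segregation: per
locus, the four sire × dam gamete combinations are enumerated and matched
against the (possibly wildcarded) target allele pair in either orientation;
loci multiply.  A Cre transgene is a hemizygous dominant locus
(`cre/0 × 0/0`), so conditional knockouts (`fl/fl` and Cre-positive) arise
at 25% pooled over a third locus and at 12.5% jointly with a homozygous
rescue genotype.  Expectations are conception-time fractions — embryonic
lethality is deliberately not modelled, since deviation of observed from
expected ratios is the phenotype being quantified.  Full genotype
distributions sum to 1 (conservation-tested).

Fisher's exact test sums hypergeometric probabilities not exceeding the
observed table's, with a 1e-7 relative tie guard against float noise (the
convention of standard implementations); the reported odds ratio is the
sample cross-product ratio, declared as such in the output.  Zero-margin
tables are flagged degenerate with NaN p.  The implementation is verified
against an exact integer-arithmetic enumeration oracle (exhaustively for
small tables, randomly up to N = 100) and against an independent library
implementation.

## Numerical conventions and limitations

- Pseudocount +1 appears in diffrat, in the pooled statistic's log
  transform, and in the chromatin scaling; it is part of each formula, not
  a tunable.
- BH adjustment is used everywhere a gene-wise family is tested; the pooled
  scheme controls each direction at α, hence ≤ 2α overall by union — the
  convention of directional rank-based callers.
- The per-gene scheme's p-values are exact but floor-limited; the pooled
  scheme's validity rests on cross-gene comparability after stratified
  standardization, which is approximate.  Both are permutation-based; both
  are checked for type-I control on global-null simulations, and the
  per-gene scheme against exhaustive enumeration.
- Problem sizes used in the shipped simulations (2000 genes, 3v3, 18
  usable splits pooled to a 36k-value null) keep any single analysis under
  a second; the generator and tests scale linearly if larger fixtures are
  wanted.
- Multi-TSS annotations are reduced to one canonical TSS per gene;
  per-transcript scoring is out of scope.
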