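# Methods

## Scope and data model

The package analyses three data layers around a knockout-vs-wild-type
contrast: (1) gene-level treatment-response counts for a genotype
(WT, DAXX_KO, ATRX_KO) × treatment (DMSO, etoposide) × replicate design;
(2) binding peaks with per-base signal tracks for two conditions; (3)
accessibility sites from replicated peak calls with per-site counts.
All coordinates are 0-based half-open (BED native), including bedGraph
steps and TSS positions, and chromosome names match by exact string —
one convention everywhere, no aliasing, no off-by-one between formats.
bedGraph is the reference signal dialect because it is text and
testable bit-exactly; bigWig input is out of scope.

## Differential stage

The differential stage is intentionally formula-level simple rather
than a count GLM: median-of-ratios size factors (factor_s = median over
genes of count/geometric-mean, restricted to genes positive in every
sample), log2(normalized + 1) transforms (pseudocount 1, zero-safe),
and t-tests. Per-replicate responses pair replicates by index across
treatments; unpaired designs are rejected rather than silently
averaged. The stage sits behind a small interface so a
dispersion-modelling alternative could be swapped in.

Two test variants are used, deliberately:

- **Welch's t** (unequal variances, Welch–Satterthwaite df) for the
  per-genotype etoposide-vs-DMSO call. Conventions for degenerate
  input: both groups zero-variance with equal means → t = 0, p = 1;
  zero variance with unequal means → p = 0. Calling requires BH-adjusted
  p strictly below the cut *and* a positive response estimate —
  "upregulated at FDR < 5%" implies direction.
- **Variance-moderated t** for contrasts with very few replicates: the
  per-row pooled variance (df = n₁+n₂−2) is shrunk toward the
  across-row mean variance with a prior of 20 pseudo-df, and the
  statistic referred to t with prior+pooled df. With two replicates per
  condition a plain Welch test has ~1 effective df and cannot detect
  even eightfold changes after multiple-testing correction; sharing
  variance across rows is how count-based differential tools make such
  designs workable. The moderated variant drives the accessibility-site
  change flags (two replicates) and, by default, the WT-vs-KO
  attenuation comparison (three or four replicates; pass
  `moderation_prior_df=None` for plain Welch). The moderated test is
  mildly conservative under the null when variances are homogeneous
  and can be anti-conservative if row variances differ strongly; in
  the count regimes simulated here (log-scale variances within ~2× of
  each other) its null rejection rate stays at or below nominal, which
  the test suite checks.

The attenuation rule gates on the WT upregulated set, then requires
two-sided p < 0.05 for the WT-vs-KO response comparison plus a lower KO
point estimate. Direction via the point estimate with a two-sided p is
conservative and symmetric with the response caller; a one-sided p
would roughly halve the p-values. The overlap universe for the
between-knockout enrichment defaults to all genes tested in both
comparisons and is configurable — the fold statistic |A∩B|·N/(|A||B|)
depends on N, which real analyses must choose explicitly.

Fisher's two-sided exact p is computed by summing hypergeometric
probabilities (at the observed margins) not exceeding the observed
table's, with a 1e−7 relative tie tolerance against float round-off —
the standard two-sided-by-probability-mass definition, vectorized via
log-gamma so exhaustive sweeps are cheap. Odds ratios are sample odds
ratios; in the factor-enrichment table a Haldane–Anscombe 0.5
correction is applied only when a cell is zero, and only to the odds
ratio — p-values stay exact and uncorrected.

## Signal quantification and classification

mean0 over an interval is Σ(step value × covered bases)/interval
length; bases with no step contribute zero. Querying a chromosome
absent from a track returns 0 with a logged warning rather than an
error, so sparse tracks behave like genome-wide zero tracks. Tracks are
depth-normalized by linear scaling to a fixed total signal (10⁹),
making between-track mean0 ratios independent of sequencing depth.

Classification uses fold = (mean0_WT + ε)/(mean0_KO + ε) with
ε = 5% × genome-wide mean of the WT track (total signal over the genome
span when chromosome sizes are supplied, else over the covered span).
The pseudocount is scale-free and guards division by ~0 at unbound
sites. The twofold threshold is inclusive ("at least twofold" → down at
fold = 2.0 exactly); the accessibility-site change threshold is strict
(fold > 2 → |log2 fold| > 1). These two boundary conventions differ on
purpose and each has a dedicated test.

Peak–gene association measures distance from the nearest peak edge
(zero inside the peak) to the TSS point, inclusive at the 3 kb window —
a peak ending exactly 3000 bp from a TSS associates; 3001 does not.
Context annotation instead uses the peak center (categories need a
single point): ≤1 kb → TSS±1kb, ≤10 kb → 1–10kb, else intragenic or
intergenic by whether the center falls in a gene body. Metaprofiles
average mean0 over fixed-width bins centered on peak midpoints,
dropping (and counting) peaks whose window crosses a chromosome edge.

## Factor enrichment and clustering

Overlap is ≥1 shared base between sorted interval lists (half-open:
touching intervals do not overlap), computed with a binary-search sweep
and checked against a quadratic oracle. Enrichment compares overlap
proportions between down and not-down peaks per factor (Fisher, BH
across factors, significant at FDR < 5%). Significant factors' overlap
indicator vectors are clustered with the asymmetric binary distance
1 − |u∧v|/|u∨v| (the conventional reading of "binary distance") under
average linkage; scipy's UPGMA provides the agglomeration, validated
against a naive oracle, and the dendrogram exports as Newick with
ultrametric branch lengths. The flat-cluster cut height (default 0.5)
is a presentation choice, not part of the statistics.

## Sites and domains

Accessibility sites are maximal union-merges of overlapping replicate
peaks — the construction is a package convention, as "unique sites" can
be built several ways. A site is significant when *every* supplied
replicate set contributes an overlapping FDR < 5% peak; when replicate
sets from several conditions are supplied (the pipeline default), that
reads as "consistent in all replicates of all conditions", the stricter
of the possible readings. Change-in-both requires both knockouts at
FDR < 5% and |log2 fold| > 1; direction-free by default (the domains
describe uniform *change*), with a loss-only mode available.

Domain detection enumerates windows of consecutive significant sites
per chromosome: a window qualifies when its footprint (first start to
running maximum end) spans strictly more than 100 kb, holds at least 5
sites, and at least 70% are changed-in-both. Overlapping qualifying
windows merge, and the merged footprint is reported once with its
statistics recomputed over the sites it contains. A merged footprint
can dilute slightly below the per-window 70% (two qualifying windows
overlapping on changed sites); the per-window threshold, not the merged
one, is the detection criterion. Consecutive-site windows realize "any
>100 kb region" without a step-size parameter and are exactly
checkable against an all-(i,j) enumeration oracle, which the tests do.

## Synthetic data

The generators produce every pipeline input with planted truth; their
defaults are the study conditions the pipeline is meant to face.

- **Counts**: NB(μ_g·2^effect, α) with Var = μ + αμ², α = 0.05 (a
  conventional bulk RNA-seq regime); baselines lognormal around 200.
  20% of genes respond to etoposide with log2 effects ~N(2, 0.5); 10%
  of genes (drawn from the responsive ones) are attenuated per
  knockout, retaining 25% of the effect — attenuation scales the
  treatment effect, not the baseline, matching a "less upregulated"
  phenotype. Half of each knockout's attenuated set is shared. Three
  replicates per cell by default (the assayed design's replicate count
  is not pinned down; recovery checks use four).
- **Peaks/tracks**: 200 non-overlapping 500 bp peaks in 2 kb slots over
  a 2×2 Mb toy genome; flat plateaus (making mean0 arithmetic exact in
  noise-free tests) emitted as 50 bp steps with truncated Gaussian
  noise (sd 0.1); planted classes 30% down / 60% unchanged / 10% up at
  fourfold.
- **Factors**: six factor sets, half enriched at overlap odds 6× the
  base rate 0.2 against down peaks, half null; factor peaks are
  sub-intervals of their target peaks.
- **Accessibility**: two planted 150 kb domains of eight equally spaced
  sites, all changed eightfold in both knockouts, on every chromosome
  except the last (kept unstructured for specificity checks); 40
  background sites changed at 5%; two replicates per condition,
  mirroring the assay design; ~5% of background sites appear in one
  replicate only so the consistency filter has work to do.

One seed drives everything; each generator draws from a sub-stream with
a fixed spawn key, so outputs are identical regardless of generator
call order, and identical configs reproduce byte-identical files.

What the generator does *not* emulate: read-level artefacts (GC bias,
duplicates, mappability), peak-shape structure, correlated
replicate batches, mean-dependent dispersion trends, or genome-scale
chromatin organization beyond the planted domains. Passing recovery
tests therefore demonstrates that the statistics find what they define,
at realistic effect sizes and noise — not that the pipeline is robust
to every artefact of real sequencing data.

## Problem sizes

The test suite and the acceptance script run everything at the sizes
above (2000 genes, 200 peaks, ~56 sites; domain specificity over
50–100 generator seeds; exhaustive Fisher enumeration over all 2×2
tables with N ≤ 60). These sizes give stable Monte-Carlo estimates
while keeping a full run in well under a minute per stage; the
implementation itself is vectorized and has no hard-coded sizes.

## Known limitations

- The differential stage is not a dispersion-modelling GLM; genes or
  sites with strongly outlying dispersion are handled less gracefully
  than DESeq2-style shrinkage would.
- The attenuation contrast is a direct two-sample comparison of
  response values, not an interaction test in a joint model.
- The domain scanner reports merged footprints whose recomputed changed
  fraction can fall marginally below the window-level threshold (see
  above).
- Factor enrichment treats peaks as exchangeable; spatial correlation
  between neighboring peaks is ignored, as in the underlying Fisher
  test.
- The gene universe for overlap enrichment, the UPGMA cut height and
  the significance-in-all-replicates site rule are explicit
  conventions; alternatives are configurable but change the numbers.
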