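# Methods

## Statistical model

Counts are modelled per gene as negative binomial with mean
μ<sub>gs</sub> = r<sub>gj</sub> · N<sub>s</sub> (group rate r, effective
library size N = raw library size × TMM factor) and variance
μ + φμ². A single common dispersion φ is shared across genes, estimated
by maximizing the Cox–Reid adjusted profile likelihood: for each
candidate φ the group rates are profiled out per gene (Newton steps on
log r; the score equation separates by group in the one-way layout) and
0.5·log of the Fisher information of each fitted rate is subtracted.
Brent search runs on log φ over [10⁻⁶, 10]; estimates at the lower bound
are reported as 0 (Poisson).

Two-group tests are quasi-likelihood F-tests: F = (deviance drop between
the pooled one-mean fit and the two-mean fit) / s², where s² is the
per-gene residual deviance divided by its residual degrees of freedom,
moderated toward the genome-wide mean scale with a prior weight w₀
(default 10 pseudo-df; w₀ = 0 gives the plain QL F-test), and the null
distribution is F(1, df + w₀). With 3 + 3 replicates this gives an
empirical type-I error of ~0.03–0.04 at nominal 0.05 on null NB
simulations (slightly conservative), which the test suite checks against
the [0.03, 0.07] band. Genes whose residual df is 0 fall back to a
likelihood-ratio χ²(1) test.

Decision rules follow the study design exactly: a gene is DE when
BH-FDR < 0.05, the fold change computed from average CPM with a 0.5
prior count exceeds 1.5 in either direction, and mean CPM > 1 in at
least one compared condition — comparisons failing that expression gate
are treated as nonsignificant regardless of p-value. The biotype call
additionally requires p < 0.05 in a pooled-variance Student t-test on
the three per-line mean CPMs of each biotype (df = 4). The line effect
within a biotype runs the three pairwise line contrasts (FDR within each
contrast) and flags genes DE in at least one pair.

## Normalization and QC

TMM follows the published trimmed-mean-of-M-values definition: reference
sample = the one whose upper-quartile count fraction is closest to the
mean; per sample, M- and A-values over genes positive in both sample and
reference; 30% two-sided trim on M and 5% on A by rank (upper bound
n+1−(⌊n·trim⌋+1), matching edgeR's indexing); inverse-delta-method-
variance weighting; factors rescaled to geometric mean 1. The
implementation reproduces edgeR 4.0 `calcNormFactors` to ~1e-10 on the
fixtures frozen in the test suite. CPM uses the TMM-effective library
size.

MDS is classical (Torgerson) scaling of pairwise distances defined as
the RMS of log2(CPM + 0.5) differences over each pair's 500 most
divergent genes (the "leading log-fold-change" idiom; the count is
configurable). The distance and gene subset the original analysis used
are not stated anywhere; this choice is ours and is declared, not
inferred. Outlier flagging formalizes the visual judgement "does not
cluster with its own biotype" without a tuning threshold: a sample is
flagged iff it lies strictly closer to another group's centroid than to
its own leave-one-out centroid; ties resolve as not flagged and
singleton groups are never flagged.

## Enrichment

The duplicated-gene test treats the candidate list as a finite
population: subsets of the observed class sizes are drawn without
replacement (10,000 draws by default), duplicated genes counted, and the
empirical 2.5/97.5 percentiles taken by the nearest-rank rule; the
verdict uses strict inequalities (above / within / below). Because
draws are without replacement the exact law is hypergeometric, which the
tests use as an oracle — at 100,000 draws the empirical CI equals the
exact quantiles on enumerable instances. Orthology tests are
Yates-corrected two-proportion χ² per category, each effector subset vs
the expressed-but-non-candidate background, with BH adjustment across
categories reported alongside raw p-values (the choice to report both is
ours; identical proportions short-circuit to p = 1).

## Copy number

Gene coverage is the length-weighted mean of per-exon mean depths,
Σ(depth·len)/Σ(len) — "summing exon coverages and dividing by total exon
size" is read this way because summing *mean* depths and dividing by
base pairs would be dimensionally inconsistent. Pool normalization
divides by the pool-wide mean gene coverage (per-gene self-division
would collapse everything to 1); the per-gene ratio is oriented
pea/alfalfa. 0/0 ratios are undefined (NaN), x/0 with x > 0 flagged
infinite, and both are excluded from rank tests. The absence call
requires ratio < 0.1 plus the expression gates in *all three* lines of
each biotype; the all-lines rule is the strict reading and is
configurable.

## Synthetic data generator

The generator emulates the study conditions, not arbitrary data: 6 lines
(3 per biotype, LSR1 and P123 as reference lines with SG/AT libraries),
2 host plants, 3 replicates per condition; NB counts with variance
μ + φμ² at φ = 0.1 by default; library sizes log-uniform in
[0.8M, 1.2M]; per-gene baseline abundances spanning 8 log2 units;
pool-seq exon depths at base 110× with multiplicative gamma noise
(CV 0.1 default); fecundity assays with 12 test plants per condition and
high/low NB means (80 vs 2 offspring) for matched/mismatched hosts.
Planted effect sizes default to log2FC 2 and planted set sizes mirror
the study's proportions at a 2,000-gene desk scale (~27% secreted, ~4%
of effectors per biotype-DE class, ~30% duplicated with 2× enrichment in
DE sets). Copy-number effects are planted in the pea pool and scale the
pea biotype's expression by the same ratio, coupling CNV and expression
the way the analysis assumes. Problem sizes throughout the tests and the
acceptance script (2,000–5,000 genes, 3 replicates) are chosen as the
smallest scales at which the statistical properties under test are
stable.

What the generator does **not** emulate: mapping artefacts and multi-
mapping bias, gene length effects, correlated gene–gene expression,
tagwise dispersion heterogeneity, GC/composition bias beyond what TMM
corrects, partial-exon CNV breakpoints, and real orthology structure.
Passing recovery tests therefore demonstrates correctness of the
inference chain under its own model assumptions, not robustness to every
artefact of real libraries.

## Numerical choices and edge cases

- BH q-values: step-up with NaN p-values excluded from ranking and
  reinserted as NaN.
- Fold change: (mean CPM + 0.5)/(mean CPM + 0.5); 0 vs 0 gives exactly 1.
- Zero-variance t-tests: p = 1 when means are equal, p = 0 otherwise
  (with a warning).
- All-zero genes: rate floored at 10⁻¹²; deviance terms with y = 0
  evaluate to their 0·log 0 = 0 limit.
- Percentages in summaries round half away from zero to integers.
- Determinism: every stochastic component takes an explicit seed;
  generator stages use independent, keyed substreams of one seed so the
  full pipeline is byte-reproducible (checked via sha256 manifests).

## Known limitations

- The common-dispersion model understates per-gene dispersion spread;
  the QL moderation absorbs some but not all of it (no tagwise trend).
- The nearest-centroid outlier rule assumes groups are roughly convex in
  the 2-D embedding; unusual geometries could flag valid samples.
- Absence calls depend on hard thresholds (0.1, CPM 1); genuine
  hemizygous + lowly-expressed genes near the boundaries are missed by
  design.
- The CLI exposes the pipeline at dataset granularity; partial reruns
  reuse no caching.
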