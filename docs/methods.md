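# Methods

## The problem

Microbiome sequencing experiments summarize each sample as a vector of
integer read counts per OTU (operational taxonomic unit).  Library sizes
— the per-sample column sums — are technical artifacts that vary by
orders of magnitude within one run, so counts must be placed on a common
scale before samples can be compared.  Two normalizations dominate
practice: dividing by the library size (proportions), and *rarefying* —
discarding samples below a minimum library size and subsampling the rest
without replacement to that common depth.  Both ignore that a count
carries depth-dependent uncertainty: for a binomial proportion estimate,
Var(p̂) = p(1−p)/n, so shrinking a 1000-read library to 100 reads
multiplies the variance of every proportion estimate by 10.  Proportions
further ignore *overdispersion*: among biological replicates the
variance of an OTU's counts exceeds the Poisson expectation.

`otubench` implements, from fully synthetic inputs, a benchmark that
quantifies what these choices cost.  The count model throughout is the
Negative Binomial (Gamma-Poisson),

    K_ij ~ NB(mean = s_j μ_i,  variance = s_j μ_i + φ_i (s_j μ_i)²),

with s_j a per-sample size factor, μ_i the OTU's mean proportion on a
common scale, and φ_i its dispersion; φ = 0 recovers the Poisson.

## Synthetic data generator

Real surveys supply the benchmark's raw material in the original
setting; here a generator replaces them:

- **Templates.**  Multinomial proportion profiles with geometric-series
  rank abundance, p_r ∝ decay^r, rank order shuffled by seed.  The decay
  parameter (default 0.99 over 200 OTUs) gives the heavy-tailed,
  dominance-structured profiles typical of community surveys while
  keeping closed forms for tests.  Pairs of environments with no shared
  taxa are built by concatenating two templates on disjoint halves of a
  common OTU universe.
- **Library sizes.**  Log-normal draws (default log-scale SD 1.0, a free
  parameter chosen to emulate order-of-magnitude spread), rescaled so
  the *realized* median equals the prescribed median, rounded, floored
  at 1.
- **Phylogeny.**  A random sequential-join binary tree with
  Exponential(1) branch lengths, purely to exercise UniFrac; it encodes
  no ecological signal.

What the generator does *not* emulate: taxon-taxon correlation,
phylogenetic signal in abundance, zero-inflation beyond multinomial
sampling, and empirical rank-abundance shapes.  Passing benchmarks here
demonstrate the statistical logic of the normalization comparison, not
performance on any particular real survey.

## The two simulation frameworks

**Simulation A (clustering).**  Two disjoint templates A and B are mixed
in both directions at an effect size ES: q ∝ ES·target + other.  ES is
therefore the ratio of target to non-target mass; ES = 1 makes the two
classes identical and ES → ∞ trivially separable.  An equal number of
samples (default 40 per class) is drawn multinomially at the drawn
library sizes.  Each normalization × distance combination is clustered
by PAM with k = 2 and scored by the fraction of all samples correctly
clustered (best of the two cluster↔class mappings); discarded samples
count as incorrect, so rarefying can score below the 50% floor of the
all-one-cluster solution, bounded by (n − n_discarded)/n.

**Simulation B (differential abundance).**  All samples are drawn from a
single template; a random 10% of OTUs (a configurable minority, so
false-positive rates remain interpretable) is multiplied by the effect
size in the test class only, after sampling — so test-class library
sizes inflate, as they would if a real perturbation added material.  An
option applies the perturbation to the template proportions instead
(renormalized, column sums preserved) for sensitivity analysis.
Per-OTU tests are BH-corrected; detection means adjusted p ≤ 0.05.

## Normalizations and the dispersion machinery

- Rarefying threshold: nearest-rank quantile of library sizes, default
  the 15th percentile within each experiment.  Subsampling is
  multivariate hypergeometric (exact sampling without replacement),
  always seeded.
- Common-scale rounding: round(target·k/s_j), half-to-even; the
  deterministic alternative to rarefying's random step.
- RLE (median-of-ratios) size factors over the OTUs present in all
  samples; sparse tables with no such OTU fall back to library-size
  proportionality with a warning.  Upper-quartile factors use the
  linear-interpolation 75th percentile of nonzero counts.
- Common-scale moments: mean and unbiased variance of k/s per OTU; a
  pooled variant pools within-class sums of squares so a real class
  effect is not booked as dispersion.
- Dispersion trend: v = μ + αμ² fitted by weighted least squares on
  (v−μ)/μ² with weights μ² (exact on noiseless quadratic moments),
  α clipped at 0.  Tests use the trend value for every OTU ("fit-only"
  sharing); the parametric closed form was chosen over a local
  regression because it admits an analytic VST and exact recovery tests.
- VST: u(x) = (2/√α)·asinh(√(αx)), continuously degenerating to 2√x at
  α = 0.

## Tests

- **NB exact test.**  Group sums are approximated as NB variables whose
  mean/variance aggregate the per-sample model; conditioning on the
  total T, the p value sums all splits no more probable than the
  observed one (ties included — conservative).  At φ = 0 with equal
  size factors and one sample per group this reduces exactly to the
  binomial conditional test, which the tests exploit as an oracle.  One
  implementation serves both RLE- and UQ-normalized variants.
- **NB Wald test.**  Per-OTU log-link NB GLM with class indicator and
  log size-factor offset; statistic β̂/SE, normal two-sided p.  No
  coefficient-shrinkage prior is applied by default (an optional ridge
  penalty exists); non-convergence is flagged with a warning and p = 1.
- **Welch t-test** on whatever values the condition dictates: raw
  counts, rarefied counts, or proportions.

The false-positive sign diagnostic reports, among detected-but-untrue
OTUs, the fraction whose direction says "more abundant in the null
class".  Under count perturbation the test class's libraries inflate, so
unperturbed OTUs' proportions shrink there — the diagnostic reads 1.0
when this artifact drives the false positives.

## Distances

Bray-Curtis and Euclidean are standard.  "PoissonDist" is defined here
as the size-factor-normalized Poisson deviance: per OTU, twice the
log-likelihood ratio of separate versus common means given the pair's
size factors (defaults: the pair's library sizes), summed over OTUs;
a pure depth difference scores 0.  top-MSD divides each sample by the
upper quartile of its nonzero counts (exactly scale invariant), adds a
pseudo-count of 0.5, and takes the RMS of the 500 largest absolute log2
fold changes; the pseudo-count and n_top are this package's fixed
constants.  Unweighted UniFrac delegates to scikit-bio (root edge
excluded, presence = count ≥ 1).  Weighted UniFrac is computed by a
direct branch-mass traversal (scikit-bio's implementation requires
integer counts and cannot take proportion vectors); the normalized
variant — the default — divides by Σ(x_j+y_j)·depth_j, the maximum
attainable for the pair.

## Numerical and design choices

- PAM: greedy BUILD then best strictly-improving SWAP; ties prefer the
  lowest sample index, making results deterministic without a seed.
  SWAP guarantees only a local optimum; on random 6-point problems it
  matches exhaustive enumeration in ≳85% of cases, comparable to other
  BUILD+SWAP implementations.
- ROC scores are raw p values (negated); BH is monotone, so adjusted
  values would give the same AUC, and they are used only for
  detection at the 0.05 threshold.
- Exact-test ties are included in the rejection sum with a 1e-7
  relative tolerance, which keeps symmetric splits at exactly p = 1 in
  floating point.
- Zero-sum OTUs are filtered before testing and reported as filtered;
  zero totals give p = 1 by convention.
- All randomness flows from explicit seeds; the suite driver derives
  per-replicate seeds as SHA-256(master, condition, replicate) mod 2³¹
  and writes them to a JSON-lines run log.

## Problem sizes

The shipped benchmark configurations are desk scale, chosen so the full
suite and the reproduction script each run in minutes on one core: 200
OTUs, 10–20 samples per class, 10 replicates per condition (20 for the
null-calibration run), median libraries 500–2000.  The directional
conclusions (mixture-model tests dominate; proportion/rarefied t-tests
accumulate systematically signed false positives as the effect grows;
rarefying caps and degrades clustering accuracy with an interior
threshold optimum near the 15th percentile under wide library-size
spread) are stable at this scale; absolute rates would shift with
larger panels.

## Known limitations

- The dispersion trend is a single quadratic coefficient; real data
  with mean-dependent dispersion would need the per-OTU φ estimates
  (also provided) or a local fit.
- The unsupervised ("blind") trend fit used before VST in clustering
  absorbs between-class differences into α.  At very small median
  libraries this makes the transform log-like and the zero pattern —
  which tracks library size — dominates Bray-Curtis on VST values, so
  VST-normalized clustering can trail proportion normalization there.
  This is a property of blind variance stabilization on sparse counts,
  and the benchmark reports it rather than hiding it.
- The NB Wald test without shrinkage is anti-conservative for OTUs with
  near-zero counts in one class; such fits are flagged.
- metagenomeSeq's zero-inflated Gaussian comparator is out of scope; the
  result schema leaves room for additional tests.
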