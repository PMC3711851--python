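# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that keep the pipeline
deterministic and well-behaved.

## Gaussian-mixture machinery

All 1-D mixture fits (signal noise models, SLR classification) share one
EM implementation (`gmm.py`). Parameters: convergence when the relative
log-likelihood change falls below 1e-8 or after 500 iterations; a
standard-deviation floor of 1e-3 log2 units to prevent singular
components; 5 seeded restarts per K with quantile-anchored, jittered mean
initialisation; K chosen by minimum BIC with 3K−1 free parameters. The
per-iteration log-likelihood trace is retained on the fit object so the
EM monotonicity guarantee is testable rather than assumed. Components are
always reported sorted by ascending mean. Multivariate profile clustering
uses scikit-learn's `GaussianMixture` (full covariance, 1e-6 ridge) —
a standard step, cross-checked in tests, with K scanned on a coarse
geometric grid and refined by ±1 around the winner because the BIC curve
is smooth in K at the scales involved.

The 1-D selector accepts K = 1 so that a null-only SLR distribution can
be described by a single component (and hence produce zero directional
calls); noise models require K ≥ 2 by construction, since a threshold
needs at least one signal component above the noise.

## Noise threshold

The threshold is the posterior-0.5 crossover of the lowest-mean
component against the union of all others, located by bracketed root
search (`brentq`, tolerance 1e-6) after a coarse march from the noise
mean. This definition is parameter-free, reduces to the equal-density
midpoint in the symmetric two-component case, and shifts exactly with
translations of the signal scale. Models in which the noise component
dominates everywhere (very heavy, very wide lowest component) have no
crossover; that is reported as an error rather than an arbitrary value.
Thresholds are fitted per experimental group (cell type × condition),
pooling that group's replicate arrays, which is the minimal reading of
per-dataset thresholds. A gene is expressed when its replicate-mean
signal exceeds the threshold in at least one group.

## Differential calling on SLR

SLR is a difference of replicate-mean log2 signals; no variance
moderation is applied because the statistic of interest is exactly this
difference of means. Components of the SLR mixture are mapped to classes
by their means against a ±0.1 log2 dead-band, and the component nearest
zero is always the null class — the dead-band prevents a slightly
off-centre null component from being read as directional, and 0.1 is
comfortably below the smallest defensible significant |SLR| (≈ 0.36 in
the motivating data). Genes are assigned by maximum posterior with ties
broken toward null (conservative). Reported tables round to 2 decimals
half-away-from-zero, matching the arithmetic of the published tables
(11.65 − 9.18 = 2.47); full precision is kept internally. Genes below
noise in both conditions are excluded from the fit and reported as "-";
below-noise in one condition only is a flag, not an exclusion.

## Conditional term enrichment

The unconditional kernel is the exact hypergeometric upper tail. The
conditional walk processes the DAG children-before-parents; a term is
significant at the child cutoff (default 0.05, the conventional
conditional-test default) and its *effective* gene set (direct plus all
descendants) is then removed from every ancestor's gene set and universe
copy before the ancestor is tested. Rows are emitted for every term that
overlaps the query at all. No multiple-testing correction is applied by
default — the report is a raw over-representation ranking — but a BH
column is available behind a flag. The gene universe is a required input
because the choice (all array genes vs expressed genes) materially
changes the margins and is a scientific decision, not a default.

## Binding calls

Preprocessing: quantile normalization uses the mean-of-order-statistics
reference with ties receiving the mean of the reference values their
positions span. Normalization is applied within channel — AB1 replicate
arrays to one reference, AB0 replicates to another — because the AB1
channel is genuinely enriched at bound promoters, and forcing both
channels onto a pooled reference measurably shrinks the enrichment being
tested (≈ 40% in simulation). The per-array 5th-percentile background
subtraction (linear interpolation percentile, floored at zero) aligns
the channel baselines afterwards. All ChIP arithmetic is on the
background-subtracted linear scale, consistent with binding scores in
the tens-to-hundreds of arbitrary units.

Scoring and testing: the promoter score is the mean over probes of the
replicate-averaged AB1−AB0 difference. Signal enhancement is a one-sided
Wilcoxon signed-rank test with zeros dropped; its null is computed
exactly for up to 25 probes by dynamic programming over attainable rank
sums (identical to enumerating all 2ⁿ sign assignments, and valid with
average ranks under ties), and by normal approximation with continuity
and tie corrections beyond. Nonuniformity is a permutation test of the
maximum window-mean of the differences (window 5 probes, B = 999
permutations, add-one p), which is sensitive to a positional peak and
blind to a flat offset — the complement of the enhancement test. The two
are combined as an intersection-union test, p = max, so a bound call
requires both overall enhancement and positional structure; BH is applied
to the combined p across promoters, and the bound flag additionally
requires score ≥ 15 (the published operating point). The permutation
seed is an explicit, logged parameter.

A practical note on the permutation statistic: with w-probe windows in an
n-probe region, the smallest attainable p against reshuffling is bounded
below by roughly (n−w+1)·w!·(n−w)!/n! — the probability that a random
permutation reassembles the top-w values contiguously. Regions much
smaller than ~25 probes therefore cannot reach the p ≈ 10⁻³ needed to
survive FDR control over hundreds of promoters, regardless of effect
size. This floor shaped the simulation defaults below and is worth
remembering when applying the caller to sparse probe maps.

## Integration

Crosstab percentages are 100·count/denominator rounded half away from
zero to 2 decimals, reported against both margins (share of the DE class
and share of all bound genes). Genes with several promoters take the
maximum binding score — the "any binding" reading. Spearman's rho uses
average ranks; its p-value is the t approximation for n > 10 and the
exact two-sided permutation tail (full enumeration of n! orderings) for
n ≤ 10. Correlations are reported separately for induced and repressed
genes, restricted to genes that are evaluated, have SLR ≠ 0 of the
requested sign, and positive binding score (AB1 > AB0).

## Synthetic-data generator

The generator emulates the *statistical* structure the pipeline assumes,
not the platform: no probe sequences, hybridisation thermodynamics, or
CEL-level artefacts.

Expression: baselines are drawn from a three-component log2 mixture —
weights (0.35, 0.40, 0.25), means (4.5, 7.0, 10.0), sds (0.6, 1.0, 1.2)
— chosen so the signal range matches published per-gene values (~4–13
log2); replicate noise sd 0.25 log2; n = 3 replicates per group
(triplicate arrays); 3% of expressed genes shifted up and 6% down in
heat-shock groups with |shift| ~ N(1.5, 0.4) log2, mirroring the
asymmetry of induction vs repression in the motivating contrast; signals
floored at 3.0 log2. Genes drawn from the noise component are never
differentially expressed. Each gene has its own deterministic child
stream of the call's seed, so enlarging a simulation never perturbs
existing genes.

ChIP: AB0 probe intensities are log-normal background; AB1 adds, at
bound promoters, amplitude × a Gaussian positional kernel centred on a
peak probe. Spec-level conditions: 500 promoters, 10% bound, amplitudes
~ U(20, 120) linear units (placing scores inside the published 10–160
range). Calibrated defaults: 28–32 probes per promoter, kernel sd 9.5
probes, background log-normal(3.0, 0.05), peak position drawn from the
central third of the region (promoter tiling is centred on the TSS
neighbourhood the factor occupies). These four were fixed jointly, once,
by a pilot so that the planted structure is recoverable at the published
operating point (score ≥ 15, FDR < 0.05): the score threshold requires
the kernel to cover ≥ ~70% of the region's probe mass at the lowest
amplitudes, while the permutation floor above requires ≥ ~25 probes —
the defaults are essentially the unique regime satisfying both. The
resulting probe-level noise (CV 5%) is cleaner than raw single-array
data; it should be read as post-normalization replicate-quality signal.

Annotation: a single-root DAG of depth ≤ 3 over n terms with random
direct gene sets, plus one designated term whose gene set overlaps a
designated query at a planted fraction.

What passing tests therefore do *not* show: robustness to probe-level
outliers and spatial artefacts, to mis-annotated probe maps, to
non-Gaussian expression noise, or to cross-hybridisation — real tiling
data is dirtier than this generator, and the binding caller's operating
characteristics there should be re-estimated on spike-ins or held-out
controls.

## Problem sizes and determinism

Default analysis sizes (15 000 genes × 2 groups × 3 replicates; 500
promoters × ~30 probes × 2 channels × 3 replicates; B = 999
permutations) keep a full end-to-end run with all tests in the
low minutes on one CPU. Every stochastic stage takes an explicit seed,
recorded in the pipeline manifest together with input checksums, and
reruns are bit-identical.

## Known limitations

* The enhancement and nonuniformity tests are reasonable but declared
  substitutes: the original analysis names the two tests without
  specifying them.
* The noise threshold's stability depends on how well-separated the
  noise and low-signal components are; with heavy overlap the fitted
  threshold (and hence the expressed-gene universe) can move by a few
  percent of genes between datasets.
* Percentages of "evaluated" genes depend on the universe convention;
  published totals that hinge on a specific array annotation are not
  reproducible from synthetic data and are not targeted.
* One SLR mixture is fitted per contrast; borrowing strength across
  contrasts (or across genes, empirical-Bayes style) is out of scope.
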