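# heatshock

Analysis of the heat-shock transcriptional response and HSF1 promoter
binding, for transcriptomics researchers comparing how somatic and germ
cells respond to hyperthermia. The package reimplements, as a tested and
reusable pipeline, the statistical workflow of a classic expression +
ChIP-on-chip study design: bulk microarray expression profiles of control
and heat-shocked cells (e.g. hepatocytes at 43&nbsp;°C, spermatocytes at
38/43&nbsp;°C) combined with promoter tiling-array ChIP of heat shock
transcription factor 1 (HSF1).

## What it computes

**Noise thresholding.** The distribution of log2 expression signals is
modelled as a 1-D Gaussian mixture fitted by EM (BIC selects the number of
components K); the lowest-mean component is the model of noise. The
expression threshold is the posterior crossover — the smallest signal *x*
at which

&nbsp;&nbsp;&nbsp;&nbsp;P(noise | x) = w₁ φ(x; μ₁, σ₁) / Σₖ wₖ φ(x; μₖ, σₖ) < ½.

Genes above threshold in at least one experimental group are "expressed";
the rest carry the below-noise (`nl`) flag.

**Differential calling.** For a contrast of heat shock (HS) against
control (C), each gene gets a signal log ratio, SLR = mean log2(HS) −
mean log2(C). A Gaussian mixture fitted to the SLR distribution maps
components to repressed / unchanged / induced classes by the sign of their
means; genes are assigned by maximum posterior, and the significant SLR
ranges are the observed min/max within each directional class (asymmetric
bounds are expected).

**Profile clustering.** Genes are clustered on multi-condition response
profiles with a full-covariance multivariate Gaussian mixture, K again by
BIC.

**Term enrichment.** Gene classes are tested for over-representation of
annotation terms with a conditional hypergeometric test on the term DAG:
children are tested first, and genes explained by an already-significant
descendant are removed from the ancestor's gene set and universe before
the ancestor is tested.

**Binding calls.** Probe-level tiling intensities from antibody (AB1) and
mock (AB0) ChIP samples are quantile normalized per channel and
background-subtracted at the per-array 5th percentile. Each promoter's
binding score is the mean over its probes of the replicate-averaged
AB1&nbsp;−&nbsp;AB0 difference (arbitrary linear units). Two tests must
both reject — a one-sided exact Wilcoxon signed-rank for overall signal
enhancement, and a max-sliding-window permutation test for positional
nonuniformity — combined as p = max(p_enh, p_nonunif), with
Benjamini–Hochberg FDR across promoters. A promoter is *bound* when
AB1−AB0 ≥ 15 and FDR < 0.05.

**Integration.** Bound genes are crosstabbed against induced/repressed
classes (counts and percentages of both margins), gene-set overlaps are
computed, and binding strength is correlated with SLR per direction using
Spearman's rho (exact permutation p for n ≤ 10).

A synthetic-data generator (`gen_expression`, `gen_chip`,
`gen_annotation`) emulates the statistical structure of all three inputs
with known planted truth, so every stage is testable end-to-end.

## Worked example

```python
from heatshock import (SimExprParams, SimChipParams, SignalNoiseModel,
                       SlrMixtureModel, gen_expression, gen_chip,
                       call_expressed, compute_slr, PromoterBindingModel)
from heatshock.noise import _group_samples

matrix, design, truth = gen_expression(SimExprParams(n_genes=4000, seed=11))
thresholds = {}
for group, samples in _group_samples(design).items():
    res = SignalNoiseModel(matrix[samples].to_numpy().ravel(), label=group) \
        .fit(k_range=(2, 4), seed=1)
    thresholds[group] = res.threshold
    print(f"{group}: K={res.k}, threshold={res.threshold:.2f} log2")

calls = call_expressed(matrix, design, thresholds)
table = compute_slr(matrix, design, calls, ("SC:C", "SC:HS"))
slr_res = SlrMixtureModel(table).fit(k_range=(1, 4), seed=2)
print(slr_res.summary().to_string(index=False))

signals, pmap, ctruth = gen_chip(SimChipParams(n_promoters=200, seed=12))
binding = PromoterBindingModel(signals, pmap).fit(seed=3)
print(binding.summary().to_string(index=False))
```

prints

```
SC:C: K=3, threshold=5.45 log2
SC:HS: K=3, threshold=5.43 log2
     class  slr_min  slr_max  n_genes  pct_of_evaluated
 induction     0.71     2.41       86              3.23
repression    -2.73    -0.65      162              6.09
 n_promoters  n_bound  mean_bound_score  sd_bound_score
         200       16         48.994461       17.126984
```

Reading the output: both groups' signal mixtures resolve three components
(noise / low / high) with a noise threshold near 5.4 log2 units. In the
simulated heat-shock contrast, 86 genes (3.2% of evaluated) are called
induced with significant SLRs from +0.71 to +2.41, and 162 (6.1%)
repressed down to −2.73 — recovering the planted 3% / 6% up/down
fractions. Of 200 simulated promoters, 16 pass both region tests at
AB1−AB0 ≥ 15 and FDR < 0.05, with bound scores averaging ≈ 49 arbitrary
units (the generator plants 10% bound).

The same stages are available from a shell:

```bash
heatshock simulate-expr --seed 11 --out-dir sim/
heatshock noise-fit --matrix sim/matrix.tsv --design sim/design.tsv --out thr.tsv
heatshock slr --matrix sim/matrix.tsv --design sim/design.tsv \
    --thresholds thr.tsv --control SC:C --heat-shock SC:HS --out contrast.tsv
heatshock run --config pipeline.yaml   # full pipeline with manifest
```

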