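# hcedecomp

Bayesian frequency–severity decomposition of end-of-life health care
expenditures (HCE) by disease group.

## The problem

In Japanese National Health Insurance claims, medical costs are billed as a
single monthly total per person — there is no breakdown by disease. Yet
end-of-life costs are known to be driven jointly by proximity to death
(PTD), age, sex and morbidity, and these effects differ sharply across
diseases. `hcedecomp` implements a two-part ("frequency–severity") pipeline
that decomposes the monthly totals of decedents into five ICD-10 disease
groups — circulatory (I00–I99), chronic kidney disease (N18), neoplasms
(C00–D48), respiratory (J00–J99) and others — over the 24 months before
death, stratified by sex and/or three age-at-death groups (65–75, 75–85,
85–95). It is aimed at health economists and biostatisticians studying
proximity-to-death cost dynamics, and ships a calibrated synthetic
decedent-panel generator so the whole method can be validated with known
ground truth.

## The model

For stratum *g*, months-before-death *t* ∈ {0,…,23} and disease group
*d* ∈ {1,…,5}, with I<sub>igtd</sub> the indicator that subject *i* incurred
a claim in group *d*:

**Frequency** — the occurrence proportion

&nbsp;&nbsp;&nbsp;&nbsp;F<sub>gtd</sub> = (1/N<sub>g</sub>) Σ<sub>i</sub> I<sub>igtd</sub>

**Severity** — latent disease-level costs behind the observed monthly total:

&nbsp;&nbsp;&nbsp;&nbsp;Y<sub>igt</sub> = Σ<sub>d</sub> Y<sub>igtd</sub> · I<sub>igtd</sub>,&nbsp;&nbsp;
Y<sub>igtd</sub> ~ Normal(μ<sub>gtd</sub>, σ²<sub>gtd</sub>)

with weakly informative priors μ<sub>gtd</sub> ~ Normal(0, 20²) and
σ²<sub>gtd</sub> ~ LogNormal(0, 10²) (costs in units of 100,000 JPY).
Because a sum of independent Normals is Normal, the latent components are
marginalized analytically and each cell's posterior over
(μ<sub>gtd</sub>, σ²<sub>gtd</sub>) is sampled by a self-contained adaptive
Metropolis-within-Gibbs sampler (4 chains × 6000 iterations, 2000 warm-up;
convergence declared when split-chain R̂ of every parameter and the
log-posterior is ≤ 1.05). A deterministic grid-quadrature oracle
cross-checks the sampler on small cells.

**Assembly** — per-capita average and cumulative average expenditures:

&nbsp;&nbsp;&nbsp;&nbsp;AHCE<sub>gtd</sub> = μ̂<sub>gtd</sub> · F<sub>gtd</sub>,&nbsp;&nbsp;
CAHCE<sub>gd</sub> = Σ<sub>t=0..23</sub> AHCE<sub>gtd</sub>

A reconstruction audit compares N<sub>g</sub>-weighted estimated totals with
the actual summed expenditure per month (error rate =
(actual − estimated)/actual × 100). Differences in μ between strata are
scored with directional Bayes factors (posterior odds of the favored
direction under the shared symmetric prior), binned on the conventional
scale: ≤3 not worth more than a bare mention, ≤20 positive, ≤150 strong,
>150 very strong. A descriptive battery (chi-square incurrence tests,
Kruskal–Wallis and Bonferroni-corrected Wilcoxon rank-sum on total incurred
cost, phi correlations of occurrence, admission ratios) rounds out the
pipeline.

## Worked example

```python
import hcedecomp as h

cfg = h.default_generator_config(scale=1000, seed=42)
panel, truth = h.generate_panel(cfg)
freq = h.frequency_table(panel, scheme="none")
post = h.fit_all_cells(panel, scheme="none",
                       mcmc=h.McmcConfig(n_chains=4, n_iter=2000, n_warmup=500, seed=0))
ahce = h.compute_ahce(post, freq)
cahce = h.compute_cahce(ahce)
rec = h.reconstruction_report(panel, ahce)

print(cahce.table.to_string(index=False))
print(rec[["ttd", "actual", "estimated", "error_rate_display"]].tail(3).to_string(index=False))
print("max R-hat:", round(max(cp.max_rhat for cp in post.values()), 4))
```

prints

```
stratum     disease     cahce
    all circulatory  9.254517
    all         ckd  6.370387
    all   neoplasms 11.732314
    all      others 19.223899
    all respiratory  6.675160

ttd       actual    estimated error_rate_display
 22  1774.810430  1774.995129             -0.01%
 23  1718.275923  1717.710542              0.03%
SUM 53254.736800 53256.278344              0.00%

max R-hat: 1.0109
```

The `cahce` column is the expected two-year per-capita cost attributed to
each disease group, in 100,000-JPY units — e.g. 19.2 means about 1.92
million JPY of the average decedent's final two years is attributed to the
"others" group. The reconstruction rows show the decomposition reassembles
the actual monthly totals to within a few hundredths of a percent, and the
R̂ line confirms every cell's chains mixed.

The same pipeline is scriptable from a shell:

```bash
hcedecomp synth --scale 3000 --seed 1 --out data/
hcedecomp pipeline --generate 3000 --seed 1 --out results/
```

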