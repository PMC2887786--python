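# arealrisk

Small-area disease-risk mapping for public-health surveillance: a tested,
reusable implementation of the standard neighbourhood-level pipeline —
indirect standardization of area case counts, spatial-autocorrelation
screening, Bayesian hierarchical smoothing, scan-statistic corroboration,
and choropleth-ready outputs.

## Who this is for

Epidemiologists and biostatisticians who need stable relative-risk
estimates over many small administrative areas (census dissemination
areas of ~400–700 residents, say), where raw rates are dominated by
Poisson noise: most areas observe a handful of cases, many observe zero,
and the most extreme raw ratios belong to the least populated areas.
Because registry and census microdata usually cannot be shared, the
package ships a synthetic study-region generator with the same
statistical structure, so every stage can be exercised, calibrated, and
regression-tested without any confidential data.

## The model

For areas *i* = 1..*n* with observed counts *Y<sub>i</sub>* and expected
counts *E<sub>i</sub>* = **P**<sub>i</sub>′**ψ** (stratified populations
times reference rates), the raw standardized incidence ratio is
θ̂<sub>i</sub> = *Y<sub>i</sub>*/*E<sub>i</sub>*. The Besag–York–Mollié
model smooths these:

```
Y_i | θ_i  ~  Poisson(E_i θ_i)
log θ_i    =  α + u_i + v_i
v_i        ~  Normal(0, σ_v²)                    (unstructured)
u          ~  ICAR(W, σ_u²)                      (spatially structured)
1/σ_u², 1/σ_v²  ~  Gamma(0.5, 0.0005),   α flat
```

where the intrinsic CAR prior penalises squared differences between
first-order contiguity neighbours and carries a sum-to-zero constraint.
Posterior summaries per area are the smoothed SIR (posterior mean of
θ<sub>i</sub>), a 95% credible interval, and the exceedance probability
P(θ<sub>i</sub> > 1 | data). The share of random-effect variation that
is spatial ("fracspatial") is summarised over draws.

Around the model sit the other pipeline stages:

- **Moran's I screen** on the SIR surface with a Poisson parametric
  bootstrap null (counts redrawn as Poisson(E<sub>i</sub>)), one-tailed
  for positive autocorrelation, Bonferroni-controlled across outcomes —
  only flagged outcomes proceed to the expensive MCMC.
- **Circular Kulldorff-style Poisson scan** with Monte-Carlo inference,
  corroborating clusters suggested by the smoothed map.
- **Choropleth outputs**: seven-class diverging classification centred
  on 1.0, significance/exceedance overlay flags, box-plot shrinkage
  summaries, annotated GeoJSON layers.

## Worked example

A 100-area synthetic region with a planted risk cluster (multiplier 2.0
over a seed area and its first-order neighbours), run end to end:

```python
import arealrisk as ar

cfg = ar.PipelineConfig(
    scenario=ar.ScenarioConfig(
        n_areas=100, sigma_v=0.05, base_rate=0.009,
        cluster_spec=ar.ClusterSpec("A0050", 1, 2.0),
    ),
    master_seed=7,
    mcmc=ar.MCMCConfig(n_chains=2, burn_in=2000, n_iter=8000, thin=8),
)
bundle = ar.run_pipeline(cfg)
```

which prints (via the snippets in `bundle`):

```
Moran's I = 0.305, bootstrap p = 0.001, flagged = True
planted cluster (7 areas): SIR vs remainder = 2.28 (95% CI 2.05-2.54, 333 observed)
exceedance >= 0.80 in 7 of 7 planted areas
fracspatial = 0.94 (95% CrI 0.60-1.00)
scan: most-likely zone of 9 areas, inside SIR = 1.83, p = 0.001
max R-hat = 1.078
```

Reading this: the screen detects strong positive spatial autocorrelation
(I = 0.305, the smallest attainable bootstrap p at B = 999), so the BYM
model runs; every planted area ends with posterior exceedance
probability ≥ 0.80; the combined cluster SIR relative to the remainder
of the region recovers the planted excess; the scan statistic
independently localises a significant 9-area zone over the same block;
and the chains pass the R̂ < 1.1 convergence gate. The same run from the
shell: `arealrisk run-all --config cfg.json --seed 7 --outdir out/`.

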