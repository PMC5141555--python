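# poismix

Finite Poisson mixture regression for model-based clustering of count
responses, built for heart-disease risk stratification and similar
epidemiological settings where a count outcome (such as an angiographic
disease stage coded 0–4) hides a heterogeneous population.

A single Poisson GLM assumes one coefficient vector for everyone and
`var(Y) = E(Y)`; real clinical counts routinely violate both. `poismix`
instead fits a K-component mixture of Poisson regressions

```
f(y_i | x_i, w_i) = Σ_k  π_k(w_i) · Pois(y_i; λ_ik),      log λ_ik = β_0k + x_iᵀ β_k
```

in three flavours:

- **standard** — fixed mixing weights π (a probability vector);
- **concomitant** — weights follow a multinomial-logit gate,
  `π_k(w) ∝ exp(γ_0k + wᵀ γ_k)`, so cluster membership itself depends on
  covariates;
- **zero-inflated (ZIPMR)** — an extra component degenerate at zero competes
  through the same gate, separating structural "no disease" zeros from
  sampled Poisson zeros.

Estimation is by EM with seeded multi-restarts: the E-step computes posterior
responsibilities τ_ik in log space, the M-step fits one responsibility-weighted
Poisson GLM per component (ridge-stabilised IRLS) and re-estimates the gate
(closed form / Newton). The number of components is chosen by scanning K and
comparing AIC, BIC and ICL (= BIC + 2 × posterior entropy). Mixture moments
satisfy `var(Y_i) = E(Y_i) + v_i` with `v_i ≥ 0` vanishing only when all
component rates coincide, which is why a well-fitting mixture explains extra
dispersion that no link change can.

The package also ships a synthetic-data generator that emulates the
Cleveland Clinic heart-disease table (13 mixed covariates plus a 0–4 count
response, `?` for missing), an end-to-end analysis pipeline with rootogram
and bootstrap-CI export, and a parameter-recovery harness.

## Worked example

Simulate a 600-row Cleveland-layout dataset from the built-in two-class
population and scan the concomitant model:

```bash
poismix simulate sim.csv --n 600 --seed 4
poismix scan sim.csv --kmin 1 --kmax 2 --seed 9 --restarts 5
```

```
     model_tag  K        mode  zero_inflated  df   loglik     AIC     BIC     ICL  converged
concomitant_K1  1 concomitant          False  14 -1095.13 2218.25 2279.81 2279.81       True
concomitant_K2  2 concomitant          False  42  -926.42 1936.84 2121.51 2357.00       True
best by BIC: concomitant_K2
```

BIC drops by ~158 from the single GLM to the two-component concomitant
model: the population is genuinely two-class. Fitting it and printing the
exponentiated coefficients (multiplicative rate ratios per unit covariate,
one column per component; `gate_*` columns are gate odds ratios):

```bash
poismix fit sim.csv --k 2 --seed 9 --restarts 5
```

```
loglik -926.418  df 42  AIC 1936.8  BIC 2121.5
sizes {1: 302, 2: 298}  priors [0.557, 0.443]
             comp_1   comp_2  gate_0  gate_1
(intercept)  0.2843   0.0000     1.0  1.9936
age          0.9987   0.9915     1.0  0.9950
sex          1.3632   5.2954     1.0  0.9752
cp           1.2271   1.9377     1.0  0.7735
...
exang        1.5201  23.5427     1.0  0.8838
ca           1.1882   1.6221     1.0  0.5951
```

Component 1 is always the high-mean-rate ("disease") group. Here its
diagnosis rate rises ~36% per unit of `sex` and ~23% per chest-pain level,
while component 2's baseline rate is essentially zero (intercept ratio
≈ 7e-5): the low-risk class. `poismix analyze FILE --out DIR` runs the whole
ladder (dispersion check, covariate-free / standard / concomitant / ZIP
scans, rootograms, optional bootstrap CIs) and writes a JSON report plus CSV
tables; on a 303-row input it appends a side-by-side block comparing this
run's criteria with the values originally published for that dataset.

From Python:

```python
import poismix as pm
spec = pm.two_component_recovery_spec(n=3000)
data, truth = pm.simulate_dataset(spec, seed=1)
model = pm.fit_em(data, K=2, mode="concomitant", config=pm.FitConfig(seed=1))
pm.rate_ratios(model, include_gate=True)
```

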