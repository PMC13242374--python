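# hospchoice

Gravity models of hospital choice for complex surgery.

Simulation studies of surgical regionalization usually assume patients are
treated at their nearest hospital. For operations like pancreaticoduodenectomy
that assumption is badly wrong — most patients bypass their closest center —
so redistribution models built on it understate real travel burdens.
`hospchoice` provides the machinery to test and improve on the distance-only
assumption: it estimates origin–destination patient-flow (gravity) models,
predicts each patient's hospital from the fitted coefficients, and measures
how often — and for whom — each model specification gets the observed
hospital right.

It is written for health-services researchers working with patient-level
discharge data (home ZIP, treating hospital, demographics) plus a hospital
attribute table and ZIP-centroid coordinates. Because such discharge data
are typically restricted, the package ships a seeded synthetic market
generator that emulates the same statistical structure with known true
parameters, so the whole pipeline is testable end to end.

## The model

Let `T_ij` be the number of patients from ZIP code `i` treated at hospital
`j`. The flow model is log-linear with origin and destination fixed effects:

```
log T_ij = α_i + δ_j + β_d · log d_ij + ε_ij
```

where `d_ij` is the great-circle distance in miles between the ZIP centroids
(floored at 0.5 mi so the log exists). Three specifications are compared:

1. **Model 1 — distance only**: prediction uses `β_d · log d_kj`.
2. **Model 2 — distance + volume**: adds `β_v · log V_j`, where `V_j` is the
   hospital's cohort volume.
3. **Model 3 — distance + volume + hospital characteristics**: adds four
   binary attributes (medical-school affiliation, rural location, cancer-
   program accreditation, centralized health system).

Estimation is two-stage. Stage 1 removes `α_i` and `δ_j` by double-demeaning
(alternating origin/destination weighted group means, iterated to
convergence on unbalanced panels) and estimates `β_d` from the demeaned
data, weighting each pair by `T_ij`; this equals explicit two-way
dummy-variable least squares. Stage 2 recovers the destination effects
`δ_j` and regresses them on the destination-invariant regressors (log
volume, hospital characteristics) by weighted least squares — these
regressors are annihilated by destination demeaning, so a fixed-effect
decomposition is the only way to assign them coefficients.

For prediction, every patient is scored against all in-state hospitals; the
linear predictor is softmax-transformed into choice probabilities, exact
score ties are broken by a seeded random permutation, and accuracy is the
fraction of patients whose observed hospital is in the top k (k = 1, 2, 3)
predictions. Evaluation also reports per-patient model-sufficiency classes,
descriptive subgroup comparisons (Welch t, Pearson χ²), and travel-distance
bias — the mean of observed minus predicted travel, positive when a model
underestimates how far patients really go.

## Worked example

```python
from hospchoice import SyntheticConfig, generate_market, analyze_market

market = generate_market(SyntheticConfig(seed=1))   # 2 states, 100 ZIPs,
bundle = analyze_market(market)                     # 15 hospitals, 20,000 patients

fit = bundle.fits["overall"][2]
print(f"beta_distance   {fit.beta_distance:.3f}")
print(f"beta_log_volume {fit.beta_log_volume:.3f}")
acc = bundle.accuracy.query("stratum == 'overall' and k == 1")
print(acc[["model_spec", "accuracy"]].to_string(index=False))
```

prints

```
beta_distance   -1.440
beta_log_volume 0.998
 model_spec  accuracy
          1  0.60000
          2  0.72620
          3  0.73080
```

The market was generated with a true distance coefficient of −1.5 and a
true attractiveness coefficient of 1.0, so the fit recovers both to within
a few percent (the residual gap in `β_d` reflects the log-linear
approximation of multinomial counts). The distance-only model predicts the
observed hospital for 60% of synthetic patients; adding volume raises this
by 12.6 percentage points — the same qualitative ordering reported for real
two-state pancreatectomy cohorts, where distance-only prediction is far
weaker than volume-aware prediction. The travel-bias report shows model 1
underestimating observed travel by 13.1 ± 24.5 miles versus 8.4 ± 23.9
miles for model 2.

A command-line interface mirrors the library:

```
hospchoice simulate --config sim.yaml --out market/
hospchoice run-all  --config run.yaml
hospchoice recovery --seed 1
```

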