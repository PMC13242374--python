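# Methods

## Problem and data model

The package models where surgical patients receive care as a spatial
interaction ("gravity") process. The unit of estimation is the
origin–destination pair: `T_ij`, the count of patients living in ZIP code
`i` treated at hospital `j`. Inputs are three delimited tables — patients
(one row per admission: home ZIP, treating hospital, demographics, payer,
area deprivation score, in-hospital death flag), hospitals (ZIP, state,
four binary characteristics), and ZIP centroids (latitude/longitude/state).
Records missing a resolvable patient or hospital ZIP are excluded first,
then records whose home ZIP lies outside the study states; the exclusion
log conserves the input count exactly. Hospital volume `V_j` is the number
of included cohort patients treated at `j` — including each index patient,
so volume is endogenous to the choices being modelled; this is deliberate
(see *Synthetic market*).

## Distance

Travel distance is the great-circle distance between ZIP centroids on a
sphere of radius 3958.7613 miles, floored at 0.5 miles (default) before
taking logs. The floor represents nonzero intra-ZIP travel and keeps
`log d` defined for same-ZIP pairs; the number of floored entries is
logged. Centroids are consumed as given; no polygon processing or
road-network routing is attempted, and ellipsoidal refinements are below
the positional precision of a ZIP centroid.

## Estimation

The flow model is `log T_ij = α_i + δ_j + β_d log d_ij + ε_ij` on the
positive flows (zero cells cannot enter a log-linear fit; prediction
nevertheless scores every patient–hospital pair).

**Stage 1 (within-estimation).** Origin and destination fixed effects are
removed by double-demeaning: alternately subtracting origin-group and
destination-group means of both `log T` and `log d` until the largest
group-mean adjustment falls below `tol` (default 1e−10). One pass suffices
on a complete balanced grid; unbalanced panels iterate, and the slope of
demeaned `log T` on demeaned `log d` is numerically identical to explicit
two-way dummy-variable least squares (verified to 1e−6 in the tests).
Each pair is weighted by its count `T_ij`. The weighting matters: the log
of a Poisson-like count has variance ≈ 1/E[T], so small distant cells are
the noisiest, and because `E[log T | T > 0]` exceeds `log E[T]` most at
small expectations, unweighted estimation systematically attenuates the
distance elasticity (by ≈ +0.2 on the reference market, versus ≈ +0.07
weighted). Count weights are the variance-stabilising generalised
least-squares choice for this error structure, implemented as weighted
group means in the demeaning sweep so the dummy-variable equivalence is
preserved exactly.

The iteration budget defaults to 100,000 sweeps. Alternating projections
converge geometrically at a rate governed by the connectivity of the
origin–destination incidence graph; panels that are nearly forests (e.g.
when choices are almost deterministic and each ZIP feeds one hospital)
converge at rates around 0.998, needing ~10⁴–10⁵ cheap O(cells) sweeps.
Non-convergence raises with diagnostics rather than returning a partial
transform.

**Stage 2 (fixed-effect decomposition).** Destination demeaning annihilates
destination-invariant regressors, so volume and hospital characteristics
cannot be estimated inside the within-transformation. Instead the
destination effects `δ_j` are recovered from the stage-1 residual surface
by the same alternating projections (normalised to mean zero, the shift
absorbed into the origin effects) and regressed on `log V_j` (model 2) or
`log V_j` plus the four binaries (model 3) by weighted least squares,
weights = number of positive-flow origins per destination (destinations
seen from more origins have better-estimated effects). A regressor that is
constant across the destinations in the sample, or a collinear set, raises
a degenerate-regressor error naming the offending columns. Stratified fits
(one per state, plus the pooled cohort) run the same two stages per
stratum; the pipeline skips and logs strata whose stage-2 design is
degenerate — with ~7 hospitals and 6 regressors this is common for model 3
at state level and is a statistical fact about small strata, not a failure
mode to hide.

Standard errors from stage 2 are reported descriptively only; the recovered
hospital effects minimise between-hospital variation and must not be read
causally.

## Prediction

For each patient `k`, all in-state cohort hospitals are scored:
model 1 `β_d log d_kj`; model 2 adds `β_v log V_j`; model 3 adds `γ'x_j`.
Origin effects are constant within a patient and omitted. By default the
stage-2 residuals of `δ_j` are *not* added back: including them would make
models 2 and 3 rank identically (both would reproduce the full destination
effects), collapsing the comparison between specifications; a flag exposes
the alternative. Scores map to choice probabilities by softmax over the
candidate set — only the rank order affects accuracy, so any strictly
monotone mapping is equivalent; softmax is used for interpretability and
its probabilities sum to one within 1e−12. Exact score ties are permuted
by a seeded generator; each patient consumes an independent stream keyed
by (seed, patient position), so predictions for one patient never depend
on `k` or on other patients. The default tie-break seed is 20160101 and is
recorded with every prediction run.

## Evaluation

Top-k accuracy is the fraction of patients whose observed hospital is among
the k highest-scoring predictions (k = 1 primary; 2, 3 as sensitivity),
reported overall, per state (state-specific fits), and for the Medicare
subset under the pooled fit. Per-patient correctness under the three
models is summarised both as exclusive classes ({all correct, models 2/3
only, model 1 but not all, none}) and as the model-1 margin, because
published sufficiency tables use the overlapping margin. Travel bias is
mean ± SD of (observed distance − distance to the top predicted hospital);
the sign convention makes "the model underestimates travel" positive.
Subgroup tables compare two classification groups with Welch t-tests
(continuous) and Pearson χ² without continuity correction (categorical);
expected cell counts below 1 attach a warning. No multiplicity adjustment
is applied, matching the descriptive style of the tables this machinery
reproduces.

## Synthetic market

The generator stands in for restricted discharge data. Defaults define the
reference study conditions: 2 states, 100 ZIPs, 15 hospitals, 20,000
patients, true distance coefficient −1.5, true attractiveness coefficient
1.0. ZIP centroids are uniform over a 2.5° square split into contiguous
state bands — sized so hospital spatial density (~1 per 1,900 sq mi) and
the resulting travel distances (median ≈ 20 miles) match a scaled-down
two-state surgical market rather than an artificially sparse one. ZIP
populations are Dirichlet(0.5), concentrating patients in a few metro-like
ZIPs. Hospitals occupy distinct ZIPs (so no two are exactly equidistant
from every patient), carry four Bernoulli characteristics, and have latent
log-normal attractiveness (SD 1.5, shifted by the characteristics) —
matching the heavy right skew of real complex-surgery volumes (median ~7,
IQR 2–26.5 per two years). Patient choices follow an in-state multinomial
logit with utility `θ_d log d + θ_v log A_j + θ_cov'x_j`; demographics,
payer, deprivation and rural-urban status are drawn from the marginals of
a published two-state pancreatectomy cohort, and in-hospital death is
Bernoulli with a logit decreasing in the chosen hospital's realized log
volume (intercept −3.5, slope −0.4 per log-volume unit → ~3% base rate),
so mortality–accuracy associations exist for the subgroup machinery.

Crucially, choices are driven by latent attractiveness `A_j` while
estimation uses realized volume `V_j`; the volume regressor is therefore
endogenous exactly as cohort-derived volume is in real analyses, and
recovery tolerances account for it. All stages are deterministic given the
configured seed (independent spawned streams per stage).

What the generator does *not* emulate: real ZIP geographies and population
rasters, cross-state choices, referral and insurance networks, hospital
entry/exit, and patient-level heterogeneity in preference weights. Passing
recovery tests therefore show that the estimator and prediction machinery
are correct under the model's own assumptions — not that the gravity model
captures real hospital choice, which is precisely the substantive question
the analysis leaves open.

## Numerical and design choices

- Demeaning tolerance 1e−10 (absolute, on log-count scale); iteration
  budget 100,000 sweeps; convergence failure is an error, never silent.
- Quartiles by linear interpolation between order statistics.
- Exclusion order fixed (missing/unresolvable ZIP before out-of-state) so
  logs are deterministic; "out-of-state" is judged from the home ZIP's
  state in the centroid table.
- Flow aggregation stores only positive counts; conservation (flows,
  volumes, exclusion log, sufficiency partition) is asserted exactly in
  the tests.
- Problem sizes in the test-suite: unit tests run a 30-ZIP / 8-hospital /
  3,000-patient market; recovery and ordering properties run the full
  reference market across 20 seeds, ~2–3 s per seed.

## Known limitations

- The log-linear estimator ignores zero flows; even count-weighted, a
  small residual attenuation of the distance elasticity (~5% on the
  reference market) remains. Poisson pseudo-maximum-likelihood would
  address it but is out of scope.
- Stage-2 coefficients inherit the endogeneity of cohort volume and the
  identification limits of few destinations; state-level model-3 fits are
  frequently degenerate by design of the market size.
- Geodesic centroid distance understates true travel effort and ignores
  drive time.
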