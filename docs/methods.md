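# Methods

`pexaudit` implements a group-fairness audit of a precision-medicine
algorithm that forecasts pulmonary exacerbations (PEx) in cystic fibrosis
from longitudinal FEV1 % predicted. This note records the models, the
conventions that had to be fixed for the pipeline to be testable, and what
the synthetic experiments do and do not demonstrate.

## Time and units

Time `t` is days since each patient's first encounter, stored as float.
One month is 30.4375 days, one year 365.25 days; the prediction horizons are
3, 6 and 12 months = 91.3125, 182.625 and 365.25 days. FEV1 is always in
% predicted points; "a 10% decline" is read as 10 absolute points (the
configurable `relative_fraction` mode implements the percent-of-baseline
reading instead).

## FIES labeling

At each encounter the rolling baseline is the mean of the two highest FEV1
values in the half-open window `[t − 365.25, t)` measured off IV
antibiotics and not inside an exclusion window; a single candidate is used
as-is; no candidate leaves the encounter unlabeled. The encounter is a PEx
when `fev1 ≤ baseline − 10` (non-strict). Measurements in `(p, p + 28]`
after a PEx at `p` are excluded from *future baseline candidate sets* only;
they still receive labels by default (`label_in_exclusion=True`), and a
positive label inside the window starts a new exclusion window. The PEx
measurement itself remains a candidate — only the post-event dip is
quarantined. The labeler is a strict one-pass algorithm: labels depend on
the past only, and tests verify equivalence with a from-scratch brute-force
recomputation.

The separate rapid-decline flag uses the strict comparison
(`fev1 < 12-month max − 10`) and does not filter by IV status, following
the definition's wording rather than FIES's.

## The lung-function model

Measured FEV1 of patient *i* at day *t*:

    y_i(t) = x_i(t)ᵀβ + b_{0i} + b_{1i} t + W_i(t) + ε_i(t)

* `x` — fixed effects; default design: intercept, age, F508del dummies
  (heterozygous, neither/unknown vs homozygous), male sex, Medicaid. The
  API accepts any boolean encounter column or numeric patient column as an
  extra term; the default is kept small so desk-scale parameter recovery is
  identifiable.
* `(b0, b1) ~ N(0, G)` — between-patient heterogeneity (intercept in
  points, slope in points/day).
* `W` — integrated Brownian motion, `cov(W(s), W(t)) = σ_w² min²(3max −
  min)/6` (units points²/day³ on σ_w²): smooth, nonstationary within-patient
  drift.
* `ε ~ N(0, σ_e²)` — measurement noise.

Estimation maximizes the marginal likelihood (REML optional). Internally β
is profiled out by GLS, `G` is parameterized by its Cholesky factor with the
slope in points/year, and `σ_w²`, `σ_e²` on log scales (per-year³ for
`σ_w²`) so all search directions are O(1); L-BFGS-B with numerical
gradients. Non-convergence returns the best-so-far parameters with
`converged=False`. When a covariance Cholesky fails, jitter
`1e-8·trace/n` is added once with a warning.

Forecasts are exact Gaussian conditioning of (history, future) on the
history; future fixed-effect covariates are frozen at their values at the
prediction time (no covariate forecasting, including age — over a 12-month
horizon the ≤1-point age effect is dwarfed by process variance). The
predictive covariance includes `σ_e²` because the FIES event operates on
*measured* FEV1.

The PEx probability at horizon `h` is the predictive probability that the
path dips to `baseline − 10` or below at some point of a monthly grid over
`(t, t+h]` (the endpoint is always on the grid), estimated by Monte Carlo
(default 500 joint samples). Samples are drawn as `mean + L z` with `z`
shaped `(grid, n_samples)`, so under a common seed nested horizons share
their leading draws and the estimate is exactly monotone in the horizon. A
Bonferroni union bound (`method="union_bound"`) is available as a cheap
upper bound; it is not the default because grid points are strongly
correlated.

## Fairness evaluation

One prediction record per scored encounter, pooled across patients. The
realized outcome is adjudicated against the FIES labels: positive iff at
least one labeled visit in `(t, t+h]` is a PEx, negative iff the window
contains labeled visits and none is a PEx, dropped (and counted) otherwise
— an outcome must be confirmable at an actual visit. The `exact_date_only`
variant adjudicates at the single next labeled visit.

Fixed conventions: `score ≥ cutoff` is predicted positive; the Youden
cutoff is the smallest threshold maximizing J; AUC is computed as the
Mann–Whitney statistic (midranks), which equals the trapezoidal area under
the tie-grouped ROC exactly. Confidence intervals are percentile bootstrap
over `B = 2000` replicates, resampling positives and negatives separately
within the evaluated group. CIs do not account for within-patient
clustering of records; this matches the stated evaluation design but will
be anti-conservative when many records share a patient.

## Synthetic registry

The generator emulates the structure the audit needs, not any particular
registry's marginals: categorical race/ethnicity/genotype with race-specific
genotype mixtures; log-normal road densities, distances and drive times
(5-minute binned) and logit-normal deprivation/greenspace with race-specific
locations; Bernoulli booleans; homogeneous-Poisson visit times over a
Gamma-distributed follow-up (mean 7.8 y) with a guaranteed visit at t = 0;
FEV1 trajectories from the model above; IV episodes triggered determin-
istically when FEV1 drops below a threshold (default 60), flagging visits in
the following 14 days. Trajectories are clipped to (1, 150] and clip counts
logged so tests can confirm they run in unclipped regimes.

Default group contrasts follow the published cohort's direction (Black
patients: higher road densities and deprivation, shorter distances, fewer
visits/year, less private insurance); all values are config entries. The
default noise sd of 6 points makes ~20% of labeled visits FIES-positive,
consistent with the published per-year visit and PEx rates. The Poisson
visit process and patient-constant infection/insurance flags are
simplifications: real registries have scheduled quarterly visits, seasonal
effects and time-varying covariates, so passing tests demonstrate correct
machinery, not real-world performance.

The `FairnessGapSpec` injects a controlled group distortion: noise sd ×m
(`noise_inflation`), covariate locations ×m (`covariate_shift`), or visit
rate ×m (`visit_sparsity`).

## Designed experiments (`pexaudit.studies`)

**Recovery study.** 300 patients, ~20 visits over ~5 years, generating
parameters chosen so every variance component carries signal (intercept sd
10, slope sd 4 pts/yr, IBM 16/yr³, noise sd 4). Across 20 seeded
replicates the median relative errors are ~1.5% (σ_e²), ~6% (G intercept),
~10% (G slope) and ~14% (σ_w²). σ_w² is intrinsically the hardest: IBM
variance grows as t³ and is partially confounded with the slope's t²
growth over finite follow-up.

**Audit study.** Three exchangeable racial groups (equal sizes, identical
covariate laws and visit rates), 2000 patients, 12-month horizon, two
interior encounters scored per patient (the first eligible encounter has an
uninformative history and end-of-follow-up encounters have no adjudicable
future), 300 MC samples per probability. The generating parameters use
stronger drift (IBM 16/yr³) and quieter noise (sd 3) than the registry-
mirroring defaults: when noise dominates, the FIES event at future visits
is essentially unpredictable (AUC ≈ 0.5 for everyone) and an audit has no
power by construction. Under this design the task is learnable (overall
AUC ≈ 0.77) and with no injected gap the inter-group AUC spread (~0.03)
stays within 3 bootstrap standard errors — the audit raises no false alarm.

With measurement-noise inflation ×2 on one group, that group's AUC drops by
~0.15 and its CI separates from both other groups'. Its sensitivity at the
shared cutoff is lower in point estimate but not CI-separated; the
direction of the sensitivity effect under noise inflation is
regime-dependent, because inflated noise also widens the predictive
distribution and can push the degraded group's scores upward. The audit's
reliable gap signal is the AUC (and specificity) separation.

## Pipeline and reproducibility

Stage seeds are derived from the master seed by SHA-256 hashing of the
stage name (all below 2³¹), so stages never share an RNG stream and reruns
are byte-identical for every CSV/YAML artifact. The manifest records the
config hash, stage seeds, versions and per-stage row/drop counts.

## Known limitations

* Visit times are Poisson by assumption; the real visit process is unknown.
* Bootstrap CIs ignore within-patient record clustering (see above).
* The full 11-covariate fixed-effect set of the original algorithm is
  API-supported but not exercised by default tests.
* Reproduction of registry-level operating characteristics is out of scope;
  the audit demonstrates calibration and power on synthetic cohorts only.
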