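# pexaudit

Group-fairness audit for pulmonary-exacerbation (PEx) prediction in cystic
fibrosis (CF), exercised end-to-end on synthetic registry data.

People with CF suffer recurring acute declines in lung function (pulmonary
exacerbations). Precision-medicine algorithms forecast these events from
longitudinal FEV1 % predicted so care can be directed early — but a model
trained on registry data can perform differently across racial and ethnic
groups, quietly widening health inequities. `pexaudit` packages the full
audit workflow for one such algorithm as a tested, reusable pipeline, for
biostatisticians and fairness researchers who want to study the audit's
statistical behaviour (calibration, power, bootstrap coverage) without
access to restricted registry data:

1. **Synthetic registry** — group-labeled patients, race-correlated
   covariates, irregular Poisson visit times, serially correlated FEV1
   trajectories, IV-antibiotic episodes, and controlled injectable fairness
   gaps.
2. **FIES labeling** — the FEV1-indicated exacerbation signal: a PEx is a
   drop of ≥ 10 points below a rolling baseline (mean of the two highest
   FEV1 in the past 12 months off IV antibiotics), with a 28-day
   post-event exclusion protecting the baseline.
3. **Forecasting model** — a Gaussian stochastic-process model of measured
   FEV1:

       y_i(t) = x_i(t)ᵀβ + b_{0i} + b_{1i} t + W_i(t) + ε_i(t)

   with fixed effects `β` (age, F508del genotype, sex, Medicaid, …), random
   intercept/slope `(b0, b1) ~ N(0, G)`, integrated Brownian motion `W`
   (`cov(W(s),W(t)) = σ_w² min²(3max−min)/6`) and noise `ε ~ N(0, σ_e²)`.
   Maximum-likelihood fitting, exact Gaussian conditional forecasting, and
   Monte-Carlo horizon probabilities
   `P(min over monthly grid of future FEV1 ≤ baseline − 10)` for 3-, 6- and
   12-month horizons.
4. **Fairness evaluation** — pooled ROC, Youden-optimal cutoff applied
   within each racial/ethnic group, per-group AUC / sensitivity /
   specificity with 2000-replicate stratified-bootstrap percentile CIs;
   sensitivity analyses with group-specific cutoffs and an exact-date
   outcome definition.
5. **Predictor screening** — per-group counts, means and proportions with
   95% CIs (Wilson / t), chi-square and ANOVA association tests, and
   per-patient encounter-rate statistics.

See `docs/methods.md` for the modeling details and `docs/schema.md` for the
CSV contracts.

## Worked example

Run the whole audit on a 200-patient synthetic cohort:

```sh
cat > demo.yaml <<'EOF'
simulation:
  n_patients: 200
bootstrap_B: 500
predictions_per_patient: 2
mc_samples: 300
fit_params: true
seed: 7
EOF
pexaudit -v run --config demo.yaml --out demo_run
```

The stages log their counts:

```
INFO pexaudit: stage simulate  done in 0.3s {'n_patients': 200, 'n_encounters': 8481, 'n_fev1_clipped': 17}
INFO pexaudit: stage label     done in 1.9s {'n_labeled': 8245, 'n_unlabeled': 236, 'n_pex': 1964}
INFO pexaudit: stage fit       done in 4.9s {'converged': True, 'log_likelihood': -28180.61, 'n_iter': 30}
INFO pexaudit: stage predict   done in 1.1s {'n_predictions': 1197}
INFO pexaudit: stage evaluate  done in 1.8s {'n_report_rows': 18, 'n_records_dropped': 107}
INFO pexaudit: stage screen    done in 0.1s {'n_predictors_screened': 14}
```

8,481 encounters are simulated, of which 8,245 receive a FIES label (the
rest have no baseline yet) and 1,964 are PEx events (~24% of labeled
visits). The model refits from the data (`converged: True`), two encounters
per patient are scored at each horizon, and 107 prediction records are
dropped because no future visit could confirm an outcome. The 3-month rows
of `demo_run/fairness_report.csv`:

```
 horizon_days  group_by   group   n   auc  auc_lo  auc_hi  sens  spec  cutoff
       91.312   overall Overall 292 0.659   0.598   0.723 0.705 0.556   0.520
       91.312      race   Black  12 0.625   0.188   1.000 0.250 0.875   0.520
       91.312      race   Other   2 1.000   1.000   1.000 1.000 1.000   0.520
       91.312      race   White 278 0.655   0.594   0.715 0.720 0.538   0.520
```

Reading: at the overall Youden cutoff of 0.520, the pooled 3-month AUC is
0.659; per-group rows apply that same cutoff within each group. At this
demo scale the registry-realistic race mix leaves only 12 Black records, so
their interval (0.19, 1.00) is essentially uninformative — exactly the
small-group uncertainty a real audit must confront; the designed audit
experiment in `pexaudit.studies` uses 2,000 patients with equal-size groups
instead. Stage-by-stage artifacts (`patients.csv`, `labels.csv`,
`predictions.csv`, `screening_table.csv`, ROC plot, manifest with config
hash and seeds) land in `demo_run/`; rerunning with the same config and
seed reproduces every CSV byte for byte.

The same stages are available individually (`pexaudit simulate`, `label`,
`fit`, `predict`, `evaluate`, `screen`) and as library functions.

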