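# CSV schemas

All artifacts are comma-separated UTF-8 with a header row; booleans are
serialized as `0`/`1`; missing values are the empty string. Times are days
since the patient's first encounter (float).

## patients.csv

| column | type | constraint |
|---|---|---|
| patient_id | string | unique |
| race | categorical | White, Black, Other |
| ethnicity | categorical | Hispanic, NonHispanic, Unknown |
| sex | categorical | female, male |
| f508del | categorical | homozygous, heterozygous, neither_unknown |
| baseline_age | float, years | ≥ 6 |
| insurance_private | bool | |
| smoker | bool | |
| smoking_household | bool | |
| secondhand_smoke | bool | |
| primary_road_density | float, m road / m² | ≥ 0 |
| secondary_road_density | float, m road / m² | ≥ 0 |
| deprivation_index | float | in [0, 1] |
| greenspace_fraction | float | in [0, 1] |
| distance_to_center | float, km | ≥ 0 |
| drive_time_to_center | float, min | ≥ 0, 5-minute bins |

## encounters.csv

| column | type | constraint |
|---|---|---|
| patient_id | string | must exist in patients.csv |
| t | float, days | ≥ 0, strictly increasing per patient |
| age | float, years | |
| fev1_pp | float, % predicted | in (0, 150] |
| on_iv | bool | on IV antibiotics at this visit |
| medicaid | bool | |
| cfrd | bool | CF-related diabetes |
| pa_positive | bool | Pseudomonas aeruginosa culture |
| mrsa_positive | bool | MRSA culture |

## labels.csv (output of `pexaudit label`)

patient_id, t, fev1_pp, baseline_pp (empty when undefined), is_pex
(0/1, empty when no baseline), in_exclusion_window (0/1), baseline_n
(0, 1 or 2).

## predictions.csv (output of `pexaudit predict`)

patient_id, t, horizon_days, pex_prob.

## fairness_report.csv (output of `pexaudit evaluate` / `run`)

horizon_days, group_by (overall | race | ethnicity), group, n, n_dropped,
auc, auc_lo, auc_hi, sens, sens_lo, sens_hi, spec, spec_lo, spec_hi,
cutoff, cutoff_mode, outcome_mode.
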