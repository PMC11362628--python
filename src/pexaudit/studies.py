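"""Canned simulation studies: the audit-calibration experiment and the
parameter-recovery experiment.

These are the package's designed experiments, with frozen generating
parameters chosen for identifiability rather than to mirror any particular
registry:

* The *audit study* uses three exchangeable racial groups (equal sizes,
  identical covariate laws and visit rates) so that, with no injected gap,
  any inter-group difference in audit metrics is pure sampling noise; its
  generating parameters emphasize forecastable systematic decline (strong
  integrated-Brownian-motion drift, quiet measurement noise) so the
  prediction task is genuinely learnable and a degradation of one group is
  visible against the calibrated background.

* The *recovery study* simulates a cohort from known parameters in a regime
  where every variance component carries signal (intercept sd 10, slope sd 4
  points/year, process drift sd 2.3 points at one year, noise sd 4) and
  refits the model to measure estimation error.
"""

from __future__ import annotations

import numpy as np

from pexaudit.fairness import auc, build_records, group_metrics, youden_cutoff
from pexaudit.fies import label_registry
from pexaudit.gp import ModelParams, fit_model
from pexaudit.pipeline import predict_registry, stage_seed
from pexaudit.registry import DAYS_PER_YEAR
from pexaudit.simulate import (FairnessGapSpec, SimulationConfig,
                               default_true_params, generate_registry)

#: generating parameters of the audit study: strong forecastable drift
AUDIT_PARAMS = ModelParams(
    beta=np.array([98.0, -1.0, 2.0, 4.0, 1.0, -3.0]),
    G=np.array([[100.0, 0.0], [0.0, (2.0 / DAYS_PER_YEAR) ** 2]]),
    sigma_w2=16.0 / DAYS_PER_YEAR ** 3,
    sigma_e2=9.0,
)

#: generating parameters of the recovery study: all components identifiable
RECOVERY_PARAMS = ModelParams(
    beta=np.array([98.0, -1.0, 2.0, 4.0, 1.0, -3.0]),
    G=np.array([[100.0, 0.0], [0.0, (4.0 / DAYS_PER_YEAR) ** 2]]),
    sigma_w2=16.0 / DAYS_PER_YEAR ** 3,
    sigma_e2=16.0,
)


def symmetric_audit_config(n_patients: int, seed: int) -> SimulationConfig:
    """Three exchangeable racial groups: equal probabilities, rates and
    covariate laws, so downstream group metrics differ only by noise."""
    eq = {"White": 1 / 3, "Black": 1 / 3, "Other": 1 / 3}
    base = SimulationConfig()
    return SimulationConfig(
        n_patients=n_patients, seed=seed, race_probs=eq,
        genotype_probs_by_race={r: dict(base.genotype_probs_by_race["White"]) for r in eq},
        encounter_rate_by_race={r: 5.25 for r in eq},
        covariate_means_by_race={k: {r: v["White"] for r in eq}
                                 for k, v in base.covariate_means_by_race.items()},
        covariate_event_probs_by_race={k: {r: v["White"] for r in eq}
                                       for k, v in base.covariate_event_probs_by_race.items()},
        followup_years_mean=4.0,
        true_params=AUDIT_PARAMS,
    )


def run_audit_study(
    gap: FairnessGapSpec | None = None,
    n_patients: int = 2000,
    seed: int = 1,
    horizon: float = DAYS_PER_YEAR,
    predictions_per_patient: int = 2,
    mc_samples: int = 300,
    B: int = 2000,
) -> dict:
    """Simulate, label, score with the generating parameters, and audit.

    Scoring with the true parameters isolates the fairness audit from
    estimation error.  Returns overall AUC, the shared Youden cutoff and the
    per-group :class:`~pexaudit.fairness.GroupMetrics`.
    """
    cfg = symmetric_audit_config(n_patients, stage_seed(seed, "simulate"))
    registry = generate_registry(cfg, gap)
    labels = label_registry(registry)
    preds = predict_registry(registry, labels, cfg.true_params, (horizon,),
                             predictions_per_patient, mc_samples,
                             seed=stage_seed(seed, "predict"))
    records, dropped = build_records(registry, labels, preds, horizon)
    cutoff = youden_cutoff(records)
    metrics = group_metrics(records, cutoff, "race", B=B,
                            seed=stage_seed(seed, "evaluate"))
    return {
        "overall_auc": auc(records),
        "cutoff": cutoff,
        "n_records": len(records),
        "n_dropped": dropped,
        "groups": {g.group: g for g in metrics},
    }


def recovery_config(seed: int, n_patients: int = 300) -> SimulationConfig:
    """One replicate of the recovery study: ~20 visits over ~5 years."""
    rate = {r: 4.0 for r in ("White", "Black", "Other")}
    return SimulationConfig(n_patients=n_patients, seed=seed,
                            followup_years_mean=5.0,
                            encounter_rate_by_race=rate,
                            true_params=RECOVERY_PARAMS)


def run_recovery_replicate(seed: int, n_patients: int = 300) -> dict:
    """Simulate from RECOVERY_PARAMS, refit, and report relative errors of
    the variance components plus beta z-scores (error / GLS standard error)."""
    cfg = recovery_config(seed, n_patients)
    registry = generate_registry(cfg)
    fit = fit_model(registry)
    true = cfg.true_params
    p = fit.params
    return {
        "converged": fit.converged,
        "rel_err": {
            "sigma_e2": abs(p.sigma_e2 - true.sigma_e2) / true.sigma_e2,
            "sigma_w2": abs(p.sigma_w2 - true.sigma_w2) / true.sigma_w2,
            "G_intercept": abs(p.G[0, 0] - true.G[0, 0]) / true.G[0, 0],
            "G_slope": abs(p.G[1, 1] - true.G[1, 1]) / true.G[1, 1],
        },
        "beta_z": np.abs(p.beta - true.beta) / fit.beta_se,
        "fit": fit,
    }


def published_cohort_registry():
    """Patient table reconstructed from the published 2003-2017 US CF
    registry cohort composition: 26,392 patients; race 24,490 White / 1,172
    Black / 730 Other; unknown ethnicity by race 691 / 58 / 206 (2,045
    Hispanic overall); F508del genotype 12,484 / 9,744 / 4,164.  Only the
    categorical partitions carry information; every other field is a
    placeholder constant and each patient gets one stub encounter."""
    import pandas as pd

    from pexaudit.registry import Registry

    race_counts = {"White": 24490, "Black": 1172, "Other": 730}
    unknown_by_race = {"White": 691, "Black": 58, "Other": 206}
    n_hispanic = 2045
    races, eths = [], []
    hisp_assigned = 0
    for race, n in race_counts.items():
        races.extend([race] * n)
        n_unk = unknown_by_race[race]
        n_known = n - n_unk
        # per-race Hispanic split is not published; the fill order does not
        # affect any marginal percentage
        n_h = min(n_known, n_hispanic - hisp_assigned)
        hisp_assigned += n_h
        eths.extend(["Hispanic"] * n_h + ["NonHispanic"] * (n_known - n_h)
                    + ["Unknown"] * n_unk)
    genotype_counts = {"homozygous": 12484, "heterozygous": 9744,
                       "neither_unknown": 4164}
    genotypes = [g for g, n in genotype_counts.items() for _ in range(n)]
    n = len(races)
    patients = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "race": races, "ethnicity": eths, "f508del": genotypes,
        "sex": "female", "baseline_age": 10.0, "insurance_private": False,
        "smoker": False, "smoking_household": False, "secondhand_smoke": False,
        "primary_road_density": 0.002, "secondary_road_density": 0.005,
        "deprivation_index": 0.35, "greenspace_fraction": 0.8,
        "distance_to_center": 50.0, "drive_time_to_center": 45.0,
    })
    encounters = pd.DataFrame({
        "patient_id": patients["patient_id"], "t": 0.0, "age": 10.0,
        "fev1_pp": 90.0, "on_iv": False, "medicaid": False, "cfrd": False,
        "pa_positive": False, "mrsa_positive": False})
    return Registry(patients=patients, encounters=encounters)


def bootstrap_se(ci: tuple[float, float], level: float = 0.95) -> float:
    """Normal-scale standard error implied by a percentile interval width."""
    from scipy.stats import norm
    return (ci[1] - ci[0]) / (2 * norm.ppf(1 - (1 - level) / 2))
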