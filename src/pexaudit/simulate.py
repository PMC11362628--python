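"""Synthetic CF registry generator.

Emulates the statistical structure of a national CF patient registry so the
whole audit pipeline is testable without access-restricted data: group-labeled
patients with race-correlated covariate distributions, irregular
Poisson-process visit times, FEV1 % predicted trajectories with
between-patient heterogeneity and integrated-Brownian-motion serial
correlation, and IV-antibiotic treatment episodes triggered by low FEV1.

Defaults mirror the published cohort qualitatively — e.g. Black patients have
higher road densities and deprivation, shorter distances and drive times to
the care center, and fewer visits per year — but every number is a config
entry, not a constant: the registry reports group summaries, not generative
laws, so the generator's laws are the package's own modeling choices.

A :class:`FairnessGapSpec` injects a controlled performance gap for one group
(extra measurement noise, shifted covariates, or sparser visits), giving the
fairness audit a known signal to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from pexaudit.gp import ModelParams, design_matrix, ibm_kernel_matrix
from pexaudit.registry import DAYS_PER_YEAR, RACE_LEVELS, Registry

_LOGNORMAL_COVARIATES = ("primary_road_density", "secondary_road_density",
                         "distance_to_center", "drive_time_to_center")
_LOGIT_COVARIATES = ("deprivation_index", "greenspace_fraction")


def default_true_params() -> ModelParams:
    """Generating parameters for simulation: mean FEV1 near 98 at age 0
    declining ~1 point/year of age, patient intercept sd 10, slope sd 1
    point/year, an integrated-Brownian-motion scale giving ~sd 9 points of
    accumulated within-patient drift after 8 years, and measurement noise
    sd 6.  The noise scale makes roughly a fifth of labeled visits FIES
    positive, matching the published per-year PEx-vs-visit rates; trajectories
    over a typical 8-year follow-up stay inside the physiologic range
    (clipping is rare and logged)."""
    slope_sd_per_day = 1.0 / DAYS_PER_YEAR
    return ModelParams(
        beta=np.array([98.0, -1.0, 2.0, 4.0, 1.0, -3.0]),
        G=np.array([[100.0, -0.1 * 10.0 * slope_sd_per_day],
                    [-0.1 * 10.0 * slope_sd_per_day, slope_sd_per_day ** 2]]),
        sigma_w2=1.0e-8,
        sigma_e2=36.0,
    )


@dataclass
class FairnessGapSpec:
    """Controlled group-level distortion injected into the simulation.

    gap_mode
        ``none`` | ``noise_inflation`` (measurement-noise sd of the target
        group multiplied by ``magnitude``) | ``covariate_shift`` (continuous
        covariate locations of the target group scaled by ``magnitude``) |
        ``visit_sparsity`` (visit rate of the target group multiplied by
        ``magnitude``).
    """

    gap_mode: str = "none"
    target_group: str = "Black"
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_mode not in ("none", "noise_inflation", "covariate_shift", "visit_sparsity"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")
        if self.gap_mode != "none" and self.magnitude <= 0:
            raise ValueError("magnitude must be positive")
        if self.target_group not in RACE_LEVELS:
            raise ValueError(f"target_group must be one of {RACE_LEVELS}")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic registry.

    Probability vectors must sum to 1 (checked to 1e-9); rates and durations
    must be positive.  Continuous covariates are drawn log-normally (road
    densities, distance, drive time; configured value = group median) or
    logit-normally (deprivation, greenspace; configured value = location on
    the probability scale); boolean covariates are Bernoulli.  Visit times
    follow a homogeneous Poisson process over each patient's follow-up, with
    a guaranteed first visit at t = 0.
    """

    n_patients: int = 500
    race_probs: dict = field(default_factory=lambda: {
        "White": 0.928, "Black": 0.044, "Other": 0.028})
    ethnicity_probs: dict = field(default_factory=lambda: {
        "Hispanic": 0.077, "NonHispanic": 0.886, "Unknown": 0.037})
    genotype_probs_by_race: dict = field(default_factory=lambda: {
        "White": {"homozygous": 0.492, "heterozygous": 0.367, "neither_unknown": 0.141},
        "Black": {"homozygous": 0.186, "heterozygous": 0.411, "neither_unknown": 0.403},
        "Other": {"homozygous": 0.308, "heterozygous": 0.375, "neither_unknown": 0.317},
    })
    followup_years_mean: float = 7.8
    encounter_rate_by_race: dict = field(default_factory=lambda: {
        "White": 5.25, "Black": 4.95, "Other": 5.30})
    covariate_means_by_race: dict = field(default_factory=lambda: {
        "primary_road_density": {"White": 0.0015, "Black": 0.0025, "Other": 0.0020},
        "secondary_road_density": {"White": 0.0040, "Black": 0.0060, "Other": 0.0050},
        "deprivation_index": {"White": 0.335, "Black": 0.404, "Other": 0.364},
        "greenspace_fraction": {"White": 0.828, "Black": 0.707, "Other": 0.723},
        "distance_to_center": {"White": 60.0, "Black": 40.0, "Other": 50.0},
        "drive_time_to_center": {"White": 50.0, "Black": 35.0, "Other": 45.0},
    })
    covariate_event_probs_by_race: dict = field(default_factory=lambda: {
        "female": {"White": 0.478, "Black": 0.485, "Other": 0.490},
        "insurance_private": {"White": 0.516, "Black": 0.282, "Other": 0.370},
        "smoker": {"White": 0.030, "Black": 0.030, "Other": 0.030},
        "smoking_household": {"White": 0.025, "Black": 0.039, "Other": 0.047},
        "secondhand_smoke": {"White": 0.057, "Black": 0.081, "Other": 0.064},
        "medicaid": {"White": 0.35, "Black": 0.60, "Other": 0.50},
        "cfrd": {"White": 0.20, "Black": 0.20, "Other": 0.20},
        "pa_positive": {"White": 0.50, "Black": 0.50, "Other": 0.50},
        "mrsa_positive": {"White": 0.25, "Black": 0.25, "Other": 0.25},
    })
    true_params: ModelParams = field(default_factory=default_true_params)
    iv_trigger_pp: float = 60.0
    iv_duration_days: float = 14.0
    lognormal_sigma: float = 0.4
    logit_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name, probs in (("race_probs", self.race_probs),
                            ("ethnicity_probs", self.ethnicity_probs),
                            *((f"genotype_probs_by_race[{r}]", g)
                              for r, g in self.genotype_probs_by_race.items())):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.followup_years_mean <= 0 or self.iv_duration_days < 0:
            raise ValueError("follow-up mean must be positive, IV duration nonnegative")
        if any(r <= 0 for r in self.encounter_rate_by_race.values()):
            raise ValueError("encounter rates must be positive")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["true_params"] = self.true_params.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "true_params" in d:
            d["true_params"] = ModelParams.from_dict(d["true_params"])
        return cls(**d)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def generate_patients(config: SimulationConfig, rng: np.random.Generator,
                      gap: FairnessGapSpec | None = None) -> pd.DataFrame:
    """Draw the static patient table (demographics, genotype, covariates)."""
    gap = gap or FairnessGapSpec()
    n = config.n_patients
    races = list(config.race_probs)
    race = rng.choice(races, size=n, p=[config.race_probs[r] for r in races])
    eths = list(config.ethnicity_probs)
    ethnicity = rng.choice(eths, size=n, p=[config.ethnicity_probs[e] for e in eths])

    genotype = np.empty(n, dtype=object)
    for r in races:
        mask = race == r
        levels = list(config.genotype_probs_by_race[r])
        genotype[mask] = rng.choice(
            levels, size=int(mask.sum()),
            p=[config.genotype_probs_by_race[r][g] for g in levels])

    # baseline age: 6 + log-normal, median ~10 y, right-skewed like the cohort
    baseline_age = 6.0 + rng.lognormal(mean=np.log(4.0), sigma=1.0, size=n)

    pat = pd.DataFrame({
        "patient_id": [f"P{i:06d}" for i in range(n)],
        "race": race, "ethnicity": ethnicity, "f508del": genotype,
        "baseline_age": baseline_age,
    })
    probs = config.covariate_event_probs_by_race
    p_female = np.array([probs["female"][r] for r in race])
    pat["sex"] = np.where(rng.random(n) < p_female, "female", "male")
    for cov in ("insurance_private", "smoker", "smoking_household", "secondhand_smoke"):
        p = np.array([probs[cov][r] for r in race])
        pat[cov] = rng.random(n) < p

    shift = np.where(
        (gap.gap_mode == "covariate_shift") & (race == gap.target_group),
        gap.magnitude, 1.0)
    for cov in _LOGNORMAL_COVARIATES:
        med = np.array([config.covariate_means_by_race[cov][r] for r in race]) * shift
        pat[cov] = np.exp(np.log(med) + config.lognormal_sigma * rng.standard_normal(n))
    for cov in _LOGIT_COVARIATES:
        loc = np.array([_logit(config.covariate_means_by_race[cov][r]) for r in race])
        loc = loc + np.log(shift)  # multiplicative shift on the odds scale
        z = loc + config.logit_sigma * rng.standard_normal(n)
        pat[cov] = 1.0 / (1.0 + np.exp(-z))
    # drive time is reported in 5-minute bins
    pat["drive_time_to_center"] = 5.0 * np.round(pat["drive_time_to_center"] / 5.0)
    return pat


def generate_encounter_times(patient: pd.Series, config: SimulationConfig,
                             rng: np.random.Generator,
                             rate_multiplier: float = 1.0) -> np.ndarray:
    """Visit days for one patient: t = 0 plus a homogeneous Poisson process.

    The per-year rate is the patient's race-specific configured rate times
    ``rate_multiplier`` (used by the visit-sparsity gap); follow-up length is
    Gamma(shape 4) with the configured mean.  Always returns >= 1 time.
    """
    rate = config.encounter_rate_by_race[patient["race"]] * rate_multiplier
    followup_days = rng.gamma(4.0, config.followup_years_mean / 4.0) * DAYS_PER_YEAR
    n_extra = rng.poisson(rate * followup_days / DAYS_PER_YEAR)
    extra = np.sort(rng.uniform(0.0, followup_days, size=n_extra))
    extra = extra[extra > 0]
    times = np.concatenate([[0.0], extra])
    # strictly increasing times (ties from uniform draws are measure-zero but
    # guard against duplicates after float rounding)
    keep = np.concatenate([[True], np.diff(times) > 1e-9])
    return times[keep]


def simulate_fev1(patient: pd.Series, times: np.ndarray, params: ModelParams,
                  rng: np.random.Generator,
                  encounter_covariates: pd.DataFrame | None = None,
                  ) -> tuple[np.ndarray, int]:
    """Draw one FEV1 % predicted trajectory at ``times``.

    y = X beta + b0 + b1 t + W(t) + eps with (b0, b1) ~ N(0, G), W integrated
    Brownian motion and iid noise.  Values are clipped to (1, 150]; the count
    of clipped values is returned so callers can log (and tests can verify
    they operate in unclipped regimes).

    ``encounter_covariates`` optionally supplies the encounter-level design
    columns (age, medicaid, ...); by default age advances deterministically
    from baseline_age and booleans are 0.
    """
    t = np.asarray(times, dtype=float)
    if len(t) and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if encounter_covariates is None:
        encounter_covariates = pd.DataFrame({
            "t": t, "age": float(patient["baseline_age"]) + t / DAYS_PER_YEAR,
            "medicaid": 0.0, "cfrd": 0.0, "pa_positive": 0.0, "mrsa_positive": 0.0,
        })
    X = design_matrix(patient, encounter_covariates, params.terms)
    mean = X @ params.beta

    b = rng.multivariate_normal(np.zeros(2), params.G, method="cholesky") \
        if np.any(params.G) else np.zeros(2)
    y = mean + b[0] + b[1] * t
    if params.sigma_w2 > 0:
        K = ibm_kernel_matrix(t, params.sigma_w2) + 1e-12 * np.eye(len(t))
        y = y + np.linalg.cholesky(K) @ rng.standard_normal(len(t))
    y = y + np.sqrt(params.sigma_e2) * rng.standard_normal(len(t))

    clipped = int(np.sum((y <= 1.0) | (y > 150.0)))
    return np.clip(y, 1.0 + 1e-6, 150.0), clipped


def simulate_iv_episodes(encounters: pd.DataFrame, config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """IV-antibiotic flags: a visit with FEV1 below the trigger starts an
    episode; subsequent visits within ``iv_duration_days`` after it are
    flagged on_iv (the triggering visit itself is not).  Deterministic given
    the trajectory; the rng argument is reserved for stochastic durations.
    """
    t = encounters["t"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("encounters must be ordered by t")
    fev = encounters["fev1_pp"].to_numpy(dtype=float)
    on_iv = np.zeros(len(t), dtype=bool)
    if config.iv_duration_days <= 0:
        return on_iv
    for i, (ti, fi) in enumerate(zip(t, fev)):
        if fi < config.iv_trigger_pp:
            on_iv |= (t > ti) & (t <= ti + config.iv_duration_days)
    return on_iv


def generate_registry(config: SimulationConfig,
                      gap: FairnessGapSpec | None = None) -> Registry:
    """Compose the full synthetic registry.

    Fully deterministic given ``config.seed``; the injected fairness gap (if
    any) is applied to the target racial group only.
    """
    gap = gap or FairnessGapSpec()
    rng = np.random.default_rng(config.seed)
    patients = generate_patients(config, rng, gap)
    probs = config.covariate_event_probs_by_race

    enc_frames = []
    total_clipped = 0
    for _, patient in patients.iterrows():
        race = patient["race"]
        targeted = race == gap.target_group
        rate_mult = gap.magnitude if (gap.gap_mode == "visit_sparsity" and targeted) else 1.0
        times = generate_encounter_times(patient, config, rng, rate_mult)

        params = config.true_params
        if gap.gap_mode == "noise_inflation" and targeted:
            params = ModelParams(beta=params.beta, G=params.G, sigma_w2=params.sigma_w2,
                                 sigma_e2=params.sigma_e2 * gap.magnitude ** 2,
                                 terms=params.terms)

        cov = pd.DataFrame({
            "t": times,
            "age": float(patient["baseline_age"]) + times / DAYS_PER_YEAR,
            "medicaid": float(rng.random() < probs["medicaid"][race]),
            "cfrd": float(rng.random() < probs["cfrd"][race]),
            "pa_positive": float(rng.random() < probs["pa_positive"][race]),
            "mrsa_positive": float(rng.random() < probs["mrsa_positive"][race]),
        })
        fev, clipped = simulate_fev1(patient, times, params, rng, cov)
        total_clipped += clipped
        frame = pd.DataFrame({
            "patient_id": patient["patient_id"], "t": times, "age": cov["age"],
            "fev1_pp": fev,
            "medicaid": cov["medicaid"].astype(bool),
            "cfrd": cov["cfrd"].astype(bool),
            "pa_positive": cov["pa_positive"].astype(bool),
            "mrsa_positive": cov["mrsa_positive"].astype(bool),
        })
        frame["on_iv"] = simulate_iv_episodes(frame, config)
        enc_frames.append(frame)

    encounters = pd.concat(enc_frames, ignore_index=True)
    cols = ["patient_id", "t", "age", "fev1_pp", "on_iv",
            "medicaid", "cfrd", "pa_positive", "mrsa_positive"]
    registry = Registry(patients=patients, encounters=encounters[cols])
    registry.n_clipped = total_clipped  # simulation log, not part of the schema
    return registry
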