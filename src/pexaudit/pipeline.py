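"""End-to-end orchestration: simulate -> label -> fit -> predict -> evaluate
-> screen, with per-stage seeds, a provenance manifest and CSV artifacts.

Every stage writes its output as a documented CSV so stages compose with
external tools; the manifest records the config hash, the derived stage
seeds, package versions and per-stage row/drop counts.  A rerun with the
same config and master seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pexaudit import __version__
from pexaudit.fairness import fairness_report, build_records, plot_roc_curves
from pexaudit.fies import FIESConfig, label_registry
from pexaudit.gp import ModelParams, fit_model, pex_probability
from pexaudit.registry import DAYS_PER_MONTH, DAYS_PER_YEAR, Registry, write_registry
from pexaudit.screening import encounter_rates, genotype_by_race, screening_table
from pexaudit.simulate import FairnessGapSpec, SimulationConfig, generate_registry

log = logging.getLogger("pexaudit")

#: default prediction horizons: 3, 6 and 12 months in days
DEFAULT_HORIZONS = (3 * DAYS_PER_MONTH, 6 * DAYS_PER_MONTH, DAYS_PER_YEAR)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed by stable hashing of the stage name, so stages
    never share an RNG stream and the master seed controls everything."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2 ** 31)


@dataclass
class PipelineConfig:
    """One config object for the whole audit run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    gap: FairnessGapSpec = field(default_factory=FairnessGapSpec)
    fies: FIESConfig = field(default_factory=FIESConfig)
    horizons: tuple[float, ...] = DEFAULT_HORIZONS
    group_by: tuple[str, ...] = ("race", "ethnicity")
    cutoff_mode: str = "shared"
    outcome_mode: str = "any_visit_in_horizon"
    bootstrap_B: int = 2000
    ci_level: float = 0.95
    fit_params: bool = True           # refit the model vs. use generating params
    predictions_per_patient: int = 3  # encounters per patient scored (0 = all)
    mc_samples: int = 500
    seed: int = 0

    def config_hash(self) -> str:
        d = asdict(self)
        d["simulation"]["true_params"] = self.simulation.true_params.to_dict()
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs = {}
        if "simulation" in d:
            sim = d["simulation"]
            if "true_params" in sim:
                sim["true_params"] = ModelParams.from_dict(sim["true_params"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "gap" in d:
            kwargs["gap"] = FairnessGapSpec(**d["gap"])
        if "fies" in d:
            kwargs["fies"] = FIESConfig(**d["fies"])
        for key in ("horizons", "group_by", "cutoff_mode", "outcome_mode",
                    "bootstrap_B", "ci_level", "fit_params",
                    "predictions_per_patient", "mc_samples", "seed"):
            if key in d:
                kwargs[key] = tuple(d[key]) if key in ("horizons", "group_by") else d[key]
        return cls(**kwargs)


def predict_registry(
    registry: Registry,
    labels: pd.DataFrame,
    params: ModelParams,
    horizons: tuple[float, ...] = DEFAULT_HORIZONS,
    predictions_per_patient: int = 0,
    mc_samples: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Score encounters with horizon PEx probabilities.

    For each selected encounter with a defined FIES baseline, the model is
    conditioned on the patient's history up to and including that encounter
    and the threshold-crossing probability is estimated per horizon with
    common random numbers across horizons (so longer horizons never score
    lower).  ``predictions_per_patient`` > 0 subsamples evenly spaced eligible
    encounters per patient to bound cost; 0 scores all of them.

    Returns columns patient_id, t, horizon_days, pex_prob.
    """
    pat = registry.patients.set_index("patient_id")
    enc = registry.sorted_encounters()
    lab_by_pid = dict(tuple(labels.groupby("patient_id")))
    rows = []
    for pid, grp in enc.groupby("patient_id", sort=False):
        grp = grp.reset_index(drop=True)
        lab = lab_by_pid.get(pid)
        if lab is None:
            continue
        lab = lab.sort_values("t").reset_index(drop=True)
        eligible = np.flatnonzero(lab["baseline_pp"].notna().to_numpy())
        if len(eligible) == 0:
            continue
        if predictions_per_patient and len(eligible) > predictions_per_patient:
            # interior quantiles: early encounters have uninformative histories
            # and end-of-follow-up encounters have no adjudicable future
            pick = np.linspace(0, len(eligible) - 1,
                               predictions_per_patient + 2)[1:-1].round().astype(int)
            eligible = eligible[np.unique(pick)]
        patient = pat.loc[pid]
        for i in eligible:
            t_i = float(lab.at[i, "t"])
            baseline = float(lab.at[i, "baseline_pp"])
            history = grp[grp["t"] <= t_i]
            enc_seed = stage_seed(seed, f"{pid}:{t_i:.6f}")
            for horizon in horizons:
                p = pex_probability(history, t_i, baseline, horizon, params, patient,
                                    n_samples=mc_samples, seed=enc_seed)
                rows.append((pid, t_i, horizon, p))
    return pd.DataFrame(rows, columns=["patient_id", "t", "horizon_days", "pex_prob"])


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full audit; returns the manifest (also written as YAML).

    Artifacts in ``out_dir``: patients.csv, encounters.csv, labels.csv,
    params.yaml, predictions.csv, fairness_report.csv, screening_table.csv,
    genotype_by_race.csv, encounter_rates.csv, roc_race.png, manifest.yaml.
    On a stage failure, artifacts of completed stages are preserved and the
    manifest marks the failing stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pexaudit_version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ("simulate", "fit", "predict", "evaluate")},
        "stages": {},
        "failed_stage": None,
    }

    def _finish(stage: str, t0: float, **counts):
        log.info("stage %-9s done in %.1fs %s", stage, time.perf_counter() - t0, counts)
        manifest["stages"][stage] = counts

    try:
        stage = "simulate"
        t0 = time.perf_counter()
        sim_cfg = SimulationConfig(**{**asdict(config.simulation),
                                      "true_params": config.simulation.true_params,
                                      "seed": stage_seed(config.seed, "simulate")})
        registry = generate_registry(sim_cfg, config.gap)
        write_registry(registry, out_dir)
        _finish(stage, t0, n_patients=registry.n_patients,
                n_encounters=registry.n_encounters,
                n_fev1_clipped=getattr(registry, "n_clipped", 0))

        stage = "label"
        t0 = time.perf_counter()
        labels = label_registry(registry, config.fies)
        out_labels = labels.copy()
        out_labels["is_pex"] = out_labels["is_pex"].map(
            lambda v: "" if pd.isna(v) else int(v))
        out_labels.to_csv(out_dir / "labels.csv", index=False)
        _finish(stage, t0, n_labeled=int(labels["is_pex"].notna().sum()),
                n_unlabeled=int(labels["is_pex"].isna().sum()),
                n_pex=int(labels["is_pex"].fillna(False).sum()))

        stage = "fit"
        t0 = time.perf_counter()
        if config.fit_params:
            fit = fit_model(registry)
            params = fit.params
            fit_info = {"converged": fit.converged, "log_likelihood": fit.log_likelihood,
                        "n_iter": fit.n_iter}
        else:
            params = config.simulation.true_params
            fit_info = {"converged": None, "note": "generating parameters used (no refit)"}
        with open(out_dir / "params.yaml", "w") as fh:
            yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
        _finish(stage, t0, **fit_info)

        stage = "predict"
        t0 = time.perf_counter()
        predictions = predict_registry(
            registry, labels, params, config.horizons,
            config.predictions_per_patient, config.mc_samples,
            seed=stage_seed(config.seed, "predict"))
        predictions.to_csv(out_dir / "predictions.csv", index=False)
        _finish(stage, t0, n_predictions=len(predictions))

        stage = "evaluate"
        t0 = time.perf_counter()
        report = fairness_report(
            registry, labels, predictions, config.horizons, config.group_by,
            config.cutoff_mode, config.outcome_mode, config.bootstrap_B,
            config.ci_level, seed=stage_seed(config.seed, "evaluate"))
        report.to_csv(out_dir / "fairness_report.csv", index=False)
        records, _ = build_records(registry, labels, predictions,
                                   config.horizons[-1], config.outcome_mode)
        by_race = {r: g for r, g in records.groupby("race")
                   if g["outcome"].nunique() == 2}
        if by_race:
            plot_roc_curves(by_race, out_dir / "roc_race.png")
        n_dropped = int(report["n_dropped"].iloc[0]) if len(report) else 0
        _finish(stage, t0, n_report_rows=len(report), n_records_dropped=n_dropped)

        stage = "screen"
        t0 = time.perf_counter()
        screening_table(registry).to_csv(out_dir / "screening_table.csv", index=False)
        genotype_by_race(registry).to_csv(out_dir / "genotype_by_race.csv", index=False)
        encounter_rates(registry, labels).to_csv(out_dir / "encounter_rates.csv", index=False)
        _finish(stage, t0, n_predictors_screened=len(
            pd.read_csv(out_dir / "screening_table.csv")["predictor"].unique()))
    except Exception as exc:  # preserve partial outputs, mark the failing stage
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        raise

    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
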