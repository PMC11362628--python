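"""Predictor-race association screening.

Reproduces the descriptive machinery of a registry cohort table: per-group
counts, proportions and means with 95% confidence intervals for every model
predictor, an overall association test of each predictor with the grouping
variable, and per-patient encounter-rate statistics.  These summaries are the
diagnostic layer of the fairness audit — a predictor strongly associated with
race is a candidate pathway for group-differential model performance.

Test choices: Pearson chi-square (no continuity correction) for categorical
and boolean predictors, one-way ANOVA for continuous ones, with
Kruskal-Wallis available as a robustness option; Wilson intervals for
proportions and t intervals for means.  Raw p-values are reported without
multiplicity adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from pexaudit.registry import DAYS_PER_YEAR, Registry

#: patient-table predictors by kind
BOOLEAN_PREDICTORS = ("insurance_private", "smoker", "smoking_household", "secondhand_smoke")
CONTINUOUS_PREDICTORS = ("baseline_age", "primary_road_density", "secondary_road_density",
                         "deprivation_index", "greenspace_fraction",
                         "distance_to_center", "drive_time_to_center")
CATEGORICAL_PREDICTORS = ("sex", "f508del", "ethnicity")


class ScreeningError(ValueError):
    pass


def _check_predictor(predictor: str) -> str:
    if predictor in BOOLEAN_PREDICTORS:
        return "boolean"
    if predictor in CONTINUOUS_PREDICTORS:
        return "continuous"
    if predictor in CATEGORICAL_PREDICTORS:
        return "categorical"
    valid = sorted(BOOLEAN_PREDICTORS + CONTINUOUS_PREDICTORS + CATEGORICAL_PREDICTORS)
    raise ScreeningError(f"unknown predictor {predictor!r}; valid names: {valid}")


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return float("nan"), float("nan")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, center - half)
    hi = 1.0 if k == n else min(1.0, center + half)
    return float(lo), float(hi)


def t_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """t-based interval for a mean; degenerate (zero-width) when var = 0."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return float("nan"), float("nan")
    m, se = float(x.mean()), float(x.std(ddof=1) / np.sqrt(n))
    half = stats.t.ppf(1 - (1 - level) / 2, n - 1) * se
    return m - half, m + half


def summarize_predictor(registry: Registry, predictor: str,
                        group_by: str = "race") -> pd.DataFrame:
    """Per-group summary of one predictor.

    Booleans: proportion with Wilson 95% CI.  Continuous: mean with t 95% CI.
    Categorical: one row per (group, level) with within-group proportion and
    Wilson CI.  Columns: predictor, group, level, n, estimate, ci_lo, ci_hi,
    kind.
    """
    kind = _check_predictor(predictor)
    pat = registry.patients
    groups = [(g, grp) for g, grp in pat.groupby(group_by, sort=True) if len(grp)]
    if len(groups) < 2:
        raise ScreeningError("need at least 2 non-empty groups")
    rows = []
    for g, grp in groups:
        if kind == "boolean":
            k, n = int(grp[predictor].sum()), len(grp)
            lo, hi = wilson_ci(k, n)
            rows.append((predictor, g, "", n, k / n, lo, hi, kind))
        elif kind == "continuous":
            x = grp[predictor].to_numpy(dtype=float)
            lo, hi = t_ci(x)
            rows.append((predictor, g, "", len(grp), float(x.mean()), lo, hi, kind))
        else:
            for level in sorted(grp[predictor].unique()):
                k, n = int((grp[predictor] == level).sum()), len(grp)
                lo, hi = wilson_ci(k, n)
                rows.append((predictor, g, level, n, k / n, lo, hi, kind))
    return pd.DataFrame(rows, columns=["predictor", "group", "level", "n",
                                       "estimate", "ci_lo", "ci_hi", "kind"])


def chi_square_independence(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square test of independence: sum (O - E)^2 / E with
    E = row_total * col_total / grand_total; no continuity correction.

    Returns (statistic, p_value, dof); raises if any expected count is 0.
    """
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected == 0).any():
        raise ScreeningError("expected cell count 0; collapse sparse levels before testing")
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if dof == 0:  # a constant predictor carries no association information
        return 0.0, 1.0, 0
    return stat, float(stats.chi2.sf(stat, dof)), dof


def test_association(registry: Registry, predictor: str, group_by: str = "race",
                     method: str = "default") -> dict:
    """Overall association of a predictor with the grouping variable.

    Boolean/categorical predictors: Pearson chi-square on the level x group
    contingency table.  Continuous: one-way ANOVA F test (``method='default'``)
    or Kruskal-Wallis (``method='kruskal'``).  Returns a dict with keys
    ``test``, ``statistic``, ``p_value``, ``dof`` (chi-square only).
    """
    kind = _check_predictor(predictor)
    pat = registry.patients
    if kind in ("boolean", "categorical"):
        col = pat[predictor].astype(int) if kind == "boolean" else pat[predictor]
        table = pd.crosstab(col, pat[group_by]).to_numpy()
        stat, p, dof = chi_square_independence(table)
        return {"test": "pearson_chi2", "statistic": stat, "p_value": p, "dof": dof}
    samples = [grp[predictor].to_numpy(dtype=float)
               for _, grp in pat.groupby(group_by, sort=True) if len(grp)]
    if len(samples) < 2:
        raise ScreeningError("need at least 2 non-empty groups")
    if method == "kruskal":
        stat, p = stats.kruskal(*samples)
        return {"test": "kruskal_wallis", "statistic": float(stat), "p_value": float(p)}
    if np.ptp(np.concatenate(samples)) == 0:  # constant predictor: no association
        return {"test": "anova_f", "statistic": 0.0, "p_value": 1.0}
    stat, p = stats.f_oneway(*samples)
    return {"test": "anova_f", "statistic": float(stat), "p_value": float(p)}


def encounter_rates(registry: Registry, labels: pd.DataFrame,
                    group_by: str = "race") -> pd.DataFrame:
    """Per-group means (with t 95% CIs) of per-patient encounter statistics:
    encounters/year, PEx encounters/year, non-PEx encounters/year, and total
    encounter count.

    Follow-up is last minus first encounter day, floored at 1 day; PEx/non-PEx
    counts come from the FIES labels (undefined labels count as neither).
    """
    enc = registry.sorted_encounters()
    lab = labels.copy()
    per_patient = []
    lab_groups = dict(tuple(lab.groupby("patient_id")))
    for pid, grp in enc.groupby("patient_id", sort=False):
        t = grp["t"].to_numpy(dtype=float)
        followup_years = max(t.max() - t.min(), 1.0) / DAYS_PER_YEAR
        lg = lab_groups.get(pid)
        n_pex = int(lg["is_pex"].fillna(False).sum()) if lg is not None else 0
        n_labeled = int(lg["is_pex"].notna().sum()) if lg is not None else 0
        per_patient.append({
            "patient_id": pid,
            "total_encounters": len(t),
            "encounters_per_year": len(t) / followup_years,
            "pex_per_year": n_pex / followup_years,
            "non_pex_per_year": (n_labeled - n_pex) / followup_years,
        })
    pp = pd.DataFrame(per_patient).merge(
        registry.patients[["patient_id", group_by]], on="patient_id")
    rows = []
    for g, grp in pp.groupby(group_by, sort=True):
        for measure in ("encounters_per_year", "pex_per_year",
                        "non_pex_per_year", "total_encounters"):
            x = grp[measure].to_numpy(dtype=float)
            lo, hi = t_ci(x)
            rows.append((g, measure, len(grp), float(x.mean()), lo, hi))
    return pd.DataFrame(rows, columns=["group", "measure", "n_patients",
                                       "mean", "ci_lo", "ci_hi"])


def screening_table(registry: Registry, group_by: str = "race") -> pd.DataFrame:
    """Full cohort-contrast table: every predictor's per-group summary plus
    its association p-value (the audit's analogue of a 'Table 1')."""
    parts = []
    for predictor in (*BOOLEAN_PREDICTORS, *CONTINUOUS_PREDICTORS, *CATEGORICAL_PREDICTORS):
        if predictor == group_by:
            continue
        summ = summarize_predictor(registry, predictor, group_by)
        res = test_association(registry, predictor, group_by)
        summ["p_value"] = res["p_value"]
        summ["test"] = res["test"]
        parts.append(summ)
    return pd.concat(parts, ignore_index=True)


def genotype_by_race(registry: Registry) -> pd.DataFrame:
    """Counts and within-race percentages of each F508del level."""
    from pexaudit.registry import round_half_up
    pat = registry.patients
    rows = []
    for race, grp in pat.groupby("race", sort=True):
        for level, k in grp["f508del"].value_counts().items():
            rows.append((race, level, int(k),
                         round_half_up(100.0 * k / len(grp), 1)))
    return pd.DataFrame(rows, columns=["race", "f508del", "n", "pct"])
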