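"""Group-fairness audit of PEx predictions: ROC curves, Youden-optimal
cutoffs, group-stratified sensitivity/specificity and bootstrap intervals.

The audit design: predicted PEx probabilities are compared with realized
outcomes (was at least one PEx confirmed at a clinical visit inside the
prediction horizon?) pooled over all encounters; an overall Youden-optimal
cutoff is chosen from the pooled ROC curve and then applied *within each
racial / ethnic group*, yielding group-specific sensitivity and specificity.
Equal performance across groups at the shared operating point is the
fairness criterion (equalized-odds style).  Two sensitivity analyses are
available: group-specific cutoffs, and an outcome adjudicated only at the
single next clinical visit.

Conventions fixed here so confusion matrices are reproducible: a record is
predicted positive when score >= cutoff; at a tied Youden maximum the
smallest maximizing threshold is returned; bootstrap intervals are percentile
intervals from resampling positives and negatives separately (2000
replicates by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pexaudit.registry import Registry


class EvaluationError(ValueError):
    pass


# -- record construction ----------------------------------------------------

def build_records(
    registry: Registry,
    labels: pd.DataFrame,
    probabilities: pd.DataFrame,
    horizon: float,
    outcome_mode: str = "any_visit_in_horizon",
) -> tuple[pd.DataFrame, int]:
    """Join predictions with realized outcomes into evaluation records.

    Parameters
    ----------
    labels : FIES labels (columns patient_id, t, is_pex) — the adjudication
        source.  Only encounters with a defined is_pex count as evaluated.
    probabilities : columns patient_id, t, horizon_days, pex_prob.
    outcome_mode : ``any_visit_in_horizon`` — outcome true iff at least one
        labeled visit in (t, t+horizon] is a PEx, false iff the window holds
        labeled visits and none is a PEx; ``exact_date_only`` — outcome read
        off the single next labeled visit, if it falls inside the window.

    Returns
    -------
    (records, n_dropped): records have columns patient_id, t, horizon, score,
    outcome, race, ethnicity; encounters whose outcome cannot be confirmed
    (no labeled visit in the window) are dropped and counted.
    """
    if horizon <= 0:
        raise EvaluationError("horizon must be positive")
    if outcome_mode not in ("any_visit_in_horizon", "exact_date_only"):
        raise EvaluationError(f"unknown outcome_mode {outcome_mode!r}")

    probs = probabilities[np.isclose(probabilities["horizon_days"], horizon)]
    lab = labels[labels["is_pex"].notna()]
    lab_by_pid = {pid: grp.sort_values("t") for pid, grp in lab.groupby("patient_id")}
    pat = registry.patients.set_index("patient_id")

    rows, dropped = [], 0
    for row in probs.itertuples(index=False):
        grp = lab_by_pid.get(row.patient_id)
        if grp is None:
            dropped += 1
            continue
        t_lab = grp["t"].to_numpy(dtype=float)
        pex = grp["is_pex"].to_numpy(dtype=bool)
        in_win = (t_lab > row.t) & (t_lab <= row.t + horizon)
        if outcome_mode == "any_visit_in_horizon":
            if not in_win.any():
                dropped += 1
                continue
            outcome = bool(pex[in_win].any())
        else:  # exact_date_only: adjudicate at the single next labeled visit
            after = np.flatnonzero(t_lab > row.t)
            if len(after) == 0 or t_lab[after[0]] > row.t + horizon:
                dropped += 1
                continue
            outcome = bool(pex[after[0]])
        p = pat.loc[row.patient_id]
        rows.append((row.patient_id, row.t, horizon, float(row.pex_prob),
                     outcome, p["race"], p["ethnicity"]))
    records = pd.DataFrame(
        rows, columns=["patient_id", "t", "horizon", "score", "outcome", "race", "ethnicity"])
    return records, dropped


# -- ROC machinery ----------------------------------------------------------

def _scores_outcomes(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    return (records["score"].to_numpy(dtype=float),
            records["outcome"].to_numpy(dtype=bool))


def roc_points(records: pd.DataFrame) -> pd.DataFrame:
    """ROC curve under the rule "score >= threshold is positive".

    Thresholds are every distinct score (ties grouped) plus a +inf sentinel
    where nothing is positive; returned in decreasing threshold order, so FPR
    and TPR are nondecreasing down the frame.
    """
    scores, outcomes = _scores_outcomes(records)
    n_pos, n_neg = int(outcomes.sum()), int((~outcomes).sum())
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise EvaluationError(f"ROC needs both classes; no {missing} records")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    pred = scores[None, :] >= thresholds[:, None]
    tpr = (pred & outcomes[None, :]).sum(axis=1) / n_pos
    fpr = (pred & ~outcomes[None, :]).sum(axis=1) / n_neg
    return pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})


def _auc_arrays(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 P(tie), via midranks."""
    n_pos = int(outcomes.sum())
    n_neg = len(outcomes) - n_pos
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise EvaluationError(f"ROC needs both classes; no {missing} records")
    from scipy.stats import rankdata
    ranks = rankdata(scores)
    u = ranks[outcomes].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc(records: pd.DataFrame) -> float:
    """Area under the ROC curve.

    Computed as the Mann-Whitney probability P(score+ > score-) + 0.5 P(tie),
    which equals the trapezoidal area under the tie-grouped ROC curve of
    :func:`roc_points` exactly.
    """
    return _auc_arrays(*_scores_outcomes(records))


def youden_cutoff(records: pd.DataFrame) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the smallest maximizing threshold (a fixed,
    documented convention); the +inf sentinel is never returned when a finite
    threshold attains the maximum.
    """
    pts = roc_points(records)
    j = pts["tpr"] - pts["fpr"]
    best = j.max()
    candidates = pts.loc[(j >= best - 1e-12) & np.isfinite(pts["threshold"]), "threshold"]
    if len(candidates) == 0:  # J maximized only by classifying nothing positive
        return float("inf")
    return float(candidates.min())


def confusion_at(records: pd.DataFrame, cutoff: float) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) under score >= cutoff -> predicted positive."""
    scores, outcomes = _scores_outcomes(records)
    pred = scores >= cutoff
    tp = int((pred & outcomes).sum())
    fp = int((pred & ~outcomes).sum())
    tn = int((~pred & ~outcomes).sum())
    fn = int((~pred & outcomes).sum())
    return tp, fp, tn, fn


def _sens_arrays(scores: np.ndarray, outcomes: np.ndarray, cutoff: float) -> float:
    n_pos = int(outcomes.sum())
    return float((scores[outcomes] >= cutoff).sum() / n_pos) if n_pos else float("nan")


def _spec_arrays(scores: np.ndarray, outcomes: np.ndarray, cutoff: float) -> float:
    n_neg = int((~outcomes).sum())
    return float((scores[~outcomes] < cutoff).sum() / n_neg) if n_neg else float("nan")


def sensitivity(records: pd.DataFrame, cutoff: float) -> float:
    tp, _, _, fn = confusion_at(records, cutoff)
    return tp / (tp + fn) if tp + fn else float("nan")


def specificity(records: pd.DataFrame, cutoff: float) -> float:
    _, fp, tn, _ = confusion_at(records, cutoff)
    return tn / (tn + fp) if tn + fp else float("nan")


def metric_fn(name: str, cutoff: float | None = None):
    """Standard metric callables for :func:`stratified_bootstrap_ci`.

    Returns an array-aware metric (fast path inside the bootstrap) for
    ``'auc'``, ``'sensitivity'`` or ``'specificity'``; the latter two require
    a cutoff.  The returned callable also accepts a records DataFrame.
    """
    if name == "auc":
        def fn(scores, outcomes=None):
            if outcomes is None:
                return auc(scores)
            return _auc_arrays(scores, outcomes)
    elif name in ("sensitivity", "specificity"):
        if cutoff is None:
            raise EvaluationError(f"{name} needs a cutoff")
        base = _sens_arrays if name == "sensitivity" else _spec_arrays

        def fn(scores, outcomes=None):
            if outcomes is None:
                return (sensitivity if name == "sensitivity" else specificity)(scores, cutoff)
            return base(scores, outcomes, cutoff)
    else:
        raise EvaluationError(f"unknown metric {name!r}")
    fn.takes_arrays = True
    fn.metric_name = name
    return fn


# -- bootstrap --------------------------------------------------------------

def stratified_bootstrap_ci(
    records: pd.DataFrame,
    metric,
    B: int = 2000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``metric(records) -> float``.

    Positives and negatives are resampled with replacement separately (the
    strata are the outcome classes within the evaluated record set), the
    metric is recomputed per replicate, and the (1-level)/2 percentiles are
    returned.  Raises if the metric is undefined in more than half of the
    replicates.
    """
    if B < 1:
        raise EvaluationError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores, outcomes = _scores_outcomes(records)
    pos_s, neg_s = scores[outcomes], scores[~outcomes]
    n_pos, n_neg = len(pos_s), len(neg_s)
    rep_outcomes = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    fast = getattr(metric, "takes_arrays", False)
    pos_df = records[records["outcome"].astype(bool)].reset_index(drop=True)
    neg_df = records[~records["outcome"].astype(bool)].reset_index(drop=True)
    vals = np.empty(B)
    for b in range(B):
        i_pos = rng.integers(0, n_pos, n_pos) if n_pos else np.empty(0, int)
        i_neg = rng.integers(0, n_neg, n_neg) if n_neg else np.empty(0, int)
        try:
            if fast:
                rep_scores = np.concatenate([pos_s[i_pos], neg_s[i_neg]])
                vals[b] = metric(rep_scores, rep_outcomes)
            else:
                rep = pd.concat([pos_df.iloc[i_pos], neg_df.iloc[i_neg]],
                                ignore_index=True)
                vals[b] = metric(rep)
        except EvaluationError:
            vals[b] = np.nan
    ok = np.isfinite(vals)
    if ok.sum() <= B / 2:
        raise EvaluationError("metric undefined in more than half of bootstrap replicates")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals[ok], [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


# -- group metrics ----------------------------------------------------------

@dataclass
class GroupMetrics:
    """Point estimates and intervals for one group at one operating point."""

    group: str
    n_records: int
    n_pos: int
    cutoff_used: float
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]


def group_metrics(
    records: pd.DataFrame,
    cutoff: float,
    group_by: str = "race",
    cutoff_mode: str = "shared",
    B: int = 2000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> list[GroupMetrics]:
    """Per-group AUC / sensitivity / specificity with bootstrap CIs.

    ``shared`` mode applies the supplied overall cutoff inside every group;
    ``group_specific`` recomputes the Youden-optimal cutoff within each group.
    Patients with unknown ethnicity are excluded from ethnicity-stratified
    evaluation.  A group with a single outcome class is reported with NaN
    metrics and a warning rather than raising.
    """
    if cutoff_mode not in ("shared", "group_specific"):
        raise EvaluationError(f"unknown cutoff_mode {cutoff_mode!r}")
    if group_by not in ("race", "ethnicity"):
        raise EvaluationError("group_by must be 'race' or 'ethnicity'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    recs = records
    if group_by == "ethnicity":
        recs = records[records["ethnicity"] != "Unknown"]

    out = []
    for level_name, grp in recs.groupby(group_by, sort=True):
        grp = grp.reset_index(drop=True)
        n_pos = int(grp["outcome"].astype(bool).sum())
        if n_pos == 0 or n_pos == len(grp):
            warnings.warn(f"group {level_name!r} has a single outcome class; metrics undefined",
                          RuntimeWarning, stacklevel=2)
            nan_ci = (float("nan"), float("nan"))
            out.append(GroupMetrics(str(level_name), len(grp), n_pos, float("nan"),
                                    float("nan"), nan_ci, float("nan"), nan_ci,
                                    float("nan"), nan_ci))
            continue
        cut = youden_cutoff(grp) if cutoff_mode == "group_specific" else cutoff
        out.append(GroupMetrics(
            group=str(level_name),
            n_records=len(grp),
            n_pos=n_pos,
            cutoff_used=float(cut),
            auc=auc(grp),
            auc_ci=stratified_bootstrap_ci(grp, metric_fn("auc"), B, level, rng),
            sensitivity=sensitivity(grp, cut),
            sensitivity_ci=stratified_bootstrap_ci(
                grp, metric_fn("sensitivity", cut), B, level, rng),
            specificity=specificity(grp, cut),
            specificity_ci=stratified_bootstrap_ci(
                grp, metric_fn("specificity", cut), B, level, rng),
        ))
    return out


# -- full report ------------------------------------------------------------

def fairness_report(
    registry: Registry,
    labels: pd.DataFrame,
    probabilities: pd.DataFrame,
    horizons: tuple[float, ...],
    group_by: tuple[str, ...] = ("race", "ethnicity"),
    cutoff_mode: str = "shared",
    outcome_mode: str = "any_visit_in_horizon",
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """The audit table: per horizon x grouping x group, AUC / sensitivity /
    specificity with CIs at the overall Youden-optimal cutoff.

    One row per (horizon, grouping, group) plus an ``Overall`` row per
    horizon.  Deterministic given ``seed``.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for horizon in horizons:
        records, dropped = build_records(registry, labels, probabilities,
                                         horizon, outcome_mode)
        if len(records) == 0:
            raise EvaluationError(f"no evaluable records at horizon {horizon}")
        overall_cut = youden_cutoff(records)
        rows.append({
            "horizon_days": horizon, "group_by": "overall", "group": "Overall",
            "n": len(records), "n_dropped": dropped,
            "auc": auc(records),
            "auc_ci": stratified_bootstrap_ci(records, metric_fn("auc"), B, level, rng),
            "sens": sensitivity(records, overall_cut),
            "sens_ci": stratified_bootstrap_ci(
                records, metric_fn("sensitivity", overall_cut), B, level, rng),
            "spec": specificity(records, overall_cut),
            "spec_ci": stratified_bootstrap_ci(
                records, metric_fn("specificity", overall_cut), B, level, rng),
            "cutoff": overall_cut,
        })
        for gb in group_by:
            for gm in group_metrics(records, overall_cut, gb, cutoff_mode,
                                    B, level, rng):
                rows.append({
                    "horizon_days": horizon, "group_by": gb, "group": gm.group,
                    "n": gm.n_records, "n_dropped": dropped,
                    "auc": gm.auc, "auc_ci": gm.auc_ci,
                    "sens": gm.sensitivity, "sens_ci": gm.sensitivity_ci,
                    "spec": gm.specificity, "spec_ci": gm.specificity_ci,
                    "cutoff": gm.cutoff_used,
                })
    report = pd.DataFrame(rows)
    for m in ("auc", "sens", "spec"):
        report[f"{m}_lo"] = report[f"{m}_ci"].map(lambda c: c[0])
        report[f"{m}_hi"] = report[f"{m}_ci"].map(lambda c: c[1])
        report = report.drop(columns=[f"{m}_ci"])
    report["cutoff_mode"] = cutoff_mode
    report["outcome_mode"] = outcome_mode
    cols = ["horizon_days", "group_by", "group", "n", "n_dropped",
            "auc", "auc_lo", "auc_hi", "sens", "sens_lo", "sens_hi",
            "spec", "spec_lo", "spec_hi", "cutoff", "cutoff_mode", "outcome_mode"]
    return report[cols]


def plot_roc_curves(records_by_group: dict[str, pd.DataFrame], out_path) -> None:
    """Save overlaid per-group ROC curves to ``out_path`` (png/pdf)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, recs in records_by_group.items():
        pts = roc_points(recs)
        ax.plot(pts["fpr"], pts["tpr"], label=f"{name} (AUC {auc(recs):.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
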