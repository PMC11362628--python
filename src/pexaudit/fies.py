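"""FEV1-indicated exacerbation signal (FIES) labeling and rapid-decline flags.

FIES is a data-driven pulmonary-exacerbation (PEx) definition: at each clinical
encounter a rolling baseline is computed as the mean of the two highest FEV1
% predicted values in the previous 12 months taken while the patient was not
on intravenous antibiotics; a PEx is flagged when the current FEV1 has dropped
at least 10 points (default; a relative-fraction mode is available) below that
baseline.  Measurements in the 28 days after a PEx are excluded from future
baseline candidate sets so that the acute dip does not drag the baseline down.

The labeler is a single chronological pass: each encounter's label depends
only on already-labeled history, never on the future.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pexaudit.registry import DAYS_PER_YEAR, Registry


@dataclass(frozen=True)
class FIESConfig:
    """Tunable parameters of the FIES rule.

    lookback_days
        Width of the rolling baseline window (default 12 months = 365.25 d).
    exclusion_days
        Measurements within this many days *after* a PEx are excluded from
        future baseline candidate sets (default 28 d).
    threshold_mode
        ``absolute_points``: PEx iff fev1 <= baseline - threshold_value.
        ``relative_fraction``: PEx iff fev1 <= baseline * (1 - threshold_value/100).
    threshold_value
        Drop size; percentage points in absolute mode, percent in relative mode.
    label_in_exclusion
        If True (default) encounters inside an exclusion window still receive
        a PEx label (and, if positive, start a new exclusion window); if False
        they are left unlabeled.
    """

    lookback_days: float = DAYS_PER_YEAR
    exclusion_days: float = 28.0
    threshold_mode: str = "absolute_points"
    threshold_value: float = 10.0
    label_in_exclusion: bool = True

    def __post_init__(self) -> None:
        if not (self.lookback_days > self.exclusion_days > 0):
            raise ValueError("need lookback_days > exclusion_days > 0")
        if self.threshold_value <= 0:
            raise ValueError("threshold_value must be positive")
        if self.threshold_mode not in ("absolute_points", "relative_fraction"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")

    def pex_threshold(self, baseline: float) -> float:
        """FEV1 value at or below which the encounter is a PEx."""
        if self.threshold_mode == "absolute_points":
            return baseline - self.threshold_value
        return baseline * (1.0 - self.threshold_value / 100.0)


def _in_exclusion(t: np.ndarray, pex_times: list[float], exclusion_days: float) -> np.ndarray:
    """True where t falls strictly after a PEx and within exclusion_days of it.

    The PEx measurement itself is not excluded (window is (p, p+exclusion]).
    """
    mask = np.zeros(len(t), dtype=bool)
    for p in pex_times:
        mask |= (t > p) & (t <= p + exclusion_days)
    return mask


def baseline_fev1(
    history: pd.DataFrame,
    t: float,
    prior_pex_times: list[float],
    config: FIESConfig = FIESConfig(),
) -> tuple[float, int]:
    """Rolling FIES baseline at time ``t`` from one patient's prior encounters.

    Candidates are history rows with time in ``[t - lookback, t)``, taken off
    IV antibiotics and not inside an exclusion window after a prior PEx.  The
    baseline is the mean of the two highest candidate values (ties are ranked
    by value, so equal values both enter the mean), the single value if only
    one candidate exists, and NaN with count 0 if none.

    Parameters
    ----------
    history : DataFrame with columns t, fev1_pp, on_iv, times strictly < t.
    prior_pex_times : times of PEx events already identified before ``t``.

    Returns
    -------
    (baseline_pp, baseline_n) where baseline_n in {0, 1, 2}.
    """
    ht = history["t"].to_numpy(dtype=float)
    if len(ht) and not np.all(np.diff(ht) > 0):
        raise ValueError("history must be sorted with strictly increasing t")
    if len(ht) and ht[-1] >= t:
        raise ValueError("history contains measurements at or after t")
    in_window = (ht >= t - config.lookback_days) & (ht < t)
    off_iv = ~history["on_iv"].to_numpy(dtype=bool)
    excluded = _in_exclusion(ht, prior_pex_times, config.exclusion_days)
    cand = history.loc[in_window & off_iv & ~excluded, "fev1_pp"].to_numpy(dtype=float)
    if len(cand) == 0:
        return float("nan"), 0
    if len(cand) == 1:
        return float(cand[0]), 1
    top2 = np.sort(cand)[-2:]
    return float(top2.mean()), 2


def label_encounters(encounters: pd.DataFrame, config: FIESConfig = FIESConfig()) -> pd.DataFrame:
    """Label one patient's encounters with FIES in a single chronological pass.

    Parameters
    ----------
    encounters : one patient's rows (columns patient_id, t, fev1_pp, on_iv),
        sorted by t.

    Returns
    -------
    DataFrame with columns ``patient_id, t, fev1_pp, baseline_pp, is_pex,
    in_exclusion_window, baseline_n``; ``baseline_pp`` is NaN and ``is_pex``
    pandas NA where no baseline could be formed.
    """
    t_arr = encounters["t"].to_numpy(dtype=float)
    if not np.all(np.diff(t_arr) > 0):
        raise ValueError("encounters must be sorted with strictly increasing t")
    fev = encounters["fev1_pp"].to_numpy(dtype=float)

    pex_times: list[float] = []
    base = np.full(len(t_arr), np.nan)
    base_n = np.zeros(len(t_arr), dtype=int)
    is_pex = np.full(len(t_arr), pd.NA, dtype=object)
    in_excl = np.zeros(len(t_arr), dtype=bool)

    for i, ti in enumerate(t_arr):
        in_excl[i] = bool(_in_exclusion(np.array([ti]), pex_times, config.exclusion_days)[0])
        if in_excl[i] and not config.label_in_exclusion:
            continue
        b, n = baseline_fev1(encounters.iloc[:i], ti, pex_times, config)
        base[i], base_n[i] = b, n
        if n > 0:
            flag = bool(fev[i] <= config.pex_threshold(b))
            is_pex[i] = flag
            if flag:
                pex_times.append(ti)

    return pd.DataFrame({
        "patient_id": encounters["patient_id"].to_numpy(),
        "t": t_arr,
        "fev1_pp": fev,
        "baseline_pp": base,
        "is_pex": pd.array(is_pex, dtype="boolean"),
        "in_exclusion_window": in_excl,
        "baseline_n": base_n,
    })


def label_registry(registry: Registry, config: FIESConfig = FIESConfig()) -> pd.DataFrame:
    """Apply :func:`label_encounters` to every patient; rows keep registry order."""
    enc = registry.sorted_encounters()
    parts = [
        label_encounters(grp.reset_index(drop=True), config)
        for _, grp in enc.groupby("patient_id", sort=False)
    ]
    return pd.concat(parts, ignore_index=True)


def rapid_decline_flag(
    history: pd.DataFrame,
    t: float,
    fev1_t: float,
    config: FIESConfig = FIESConfig(),
) -> bool | None:
    """Rapid lung-function decline: drop of *more than* 10 points from the
    12-month maximum observed FEV1 (all measurements, regardless of IV status).

    Returns None when the lookback window holds no measurements.  Note the
    strict inequality: a drop of exactly 10 points is not rapid decline,
    whereas the FIES PEx comparison is non-strict.
    """
    ht = history["t"].to_numpy(dtype=float)
    if len(ht) and not np.all(np.diff(ht) > 0):
        raise ValueError("history must be sorted with strictly increasing t")
    in_window = (ht >= t - config.lookback_days) & (ht < t)
    if not in_window.any():
        return None
    peak = float(history.loc[in_window, "fev1_pp"].max())
    return bool(fev1_t < peak - config.threshold_value)
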