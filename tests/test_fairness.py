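"""ROC/AUC/Youden machinery, bootstrap contracts, group metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_encounter, make_patient, make_registry
from pexaudit.fairness import (
    EvaluationError, auc, build_records, confusion_at, group_metrics,
    metric_fn, roc_points, sensitivity, specificity,
    stratified_bootstrap_ci, youden_cutoff,
)


def records_from(scores, outcomes, race=None, ethnicity=None):
    n = len(scores)
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "t": 0.0, "horizon": 91.3125,
        "score": list(scores), "outcome": [bool(o) for o in outcomes],
        "race": race or ["White"] * n,
        "ethnicity": ethnicity or ["NonHispanic"] * n,
    })


def brute_force_auc(scores, outcomes):
    """Pair counting: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, o in zip(scores, outcomes) if o]
    neg = [s for s, o in zip(scores, outcomes) if not o]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, outcomes):
    """Exhaustive J evaluation at every distinct score; smallest argmax."""
    recs = records_from(scores, outcomes)
    best_j, best_c = -np.inf, None
    for c in sorted(set(scores)):
        j = sensitivity(recs, c) + specificity(recs, c) - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return best_c


class TestRoc:
    def test_perfect_separation_passes_corner(self):
        pts = roc_points(records_from([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]))
        assert ((pts.fpr == 0) & (pts.tpr == 1)).any()

    def test_all_scores_equal_gives_diagonal_endpoints(self):
        pts = roc_points(records_from([0.5] * 6, [1, 1, 1, 0, 0, 0]))
        assert set(zip(pts.fpr, pts.tpr)) == {(0.0, 0.0), (1.0, 1.0)}

    def test_single_class_input_names_missing_class(self):
        with pytest.raises(EvaluationError, match="negative"):
            roc_points(records_from([0.4, 0.6], [1, 1]))

    def test_matches_sklearn(self):
        rng = np.random.default_rng(0)
        scores = np.round(rng.random(60), 2)
        outcomes = rng.random(60) < 0.4
        from sklearn.metrics import roc_curve
        fpr, tpr, _ = roc_curve(outcomes, scores, drop_intermediate=False)
        pts = roc_points(records_from(scores, outcomes))
        np.testing.assert_allclose(sorted(pts.fpr), sorted(fpr))
        np.testing.assert_allclose(sorted(pts.tpr), sorted(tpr))


class TestAuc:
    def test_perfect_separation_is_one(self):
        assert auc(records_from([0.9, 0.8, 0.1], [1, 1, 0])) == 1.0

    def test_hand_counted_pairs(self):
        # 0.8>0.6, 0.8>0.2, 0.4<0.6, 0.4>0.2 -> 3/4
        assert auc(records_from([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0])) == 0.75

    def test_all_ties_is_half(self):
        assert auc(records_from([0.3] * 4, [1, 1, 0, 0])) == 0.5

    def test_equals_trapezoid_of_roc_points(self):
        rng = np.random.default_rng(7)
        recs = records_from(np.round(rng.random(40), 1), rng.random(40) < 0.5)
        pts = roc_points(recs)
        assert auc(recs) == pytest.approx(
            float(np.trapezoid(pts.tpr, pts.fpr)), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 10), st.booleans()),
                    min_size=4, max_size=30))
    def test_mann_whitney_identity_property(self, items):
        scores = [s / 10 for s, _ in items]
        outcomes = [o for _, o in items]
        if not (any(outcomes) and not all(outcomes)):
            return
        assert auc(records_from(scores, outcomes)) == pytest.approx(
            brute_force_auc(scores, outcomes), abs=1e-12)


class TestYouden:
    def test_perfect_separation_returns_smallest_gap_threshold(self):
        # J = 1 for any cutoff in (0.4, 0.8]; smallest candidate score
        # attaining it is 0.8
        assert youden_cutoff(records_from([0.9, 0.8, 0.4, 0.1], [1, 1, 0, 0])) == 0.8

    def test_uninformative_scores_give_zero_J(self):
        recs = records_from([0.5] * 4, [1, 1, 0, 0])
        c = youden_cutoff(recs)
        assert sensitivity(recs, c) + specificity(recs, c) - 1 == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_exhaustive_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 40))
        scores = np.round(rng.random(n), 1)
        outcomes = rng.random(n) < 0.5
        if outcomes.all() or not outcomes.any():
            return
        assert youden_cutoff(records_from(scores, outcomes)) == pytest.approx(
            brute_force_youden(list(scores), list(outcomes)))


class TestBuildRecords:
    def _setup(self):
        patients = [make_patient("P1"), make_patient("P2", race="Black")]
        encounters = [make_encounter("P1", float(t), 90.0) for t in (0, 30, 80, 200)]
        encounters += [make_encounter("P2", float(t), 85.0) for t in (0, 400)]
        reg = make_registry(patients, encounters)
        labels = pd.DataFrame({
            "patient_id": ["P1"] * 4 + ["P2"] * 2,
            "t": [0.0, 30.0, 80.0, 200.0, 0.0, 400.0],
            "is_pex": pd.array([None, False, True, False, None, False], dtype="boolean"),
        })
        probs = pd.DataFrame({
            "patient_id": ["P1", "P2"], "t": [0.0, 0.0],
            "horizon_days": [91.3125] * 2, "pex_prob": [0.7, 0.2]})
        return reg, labels, probs

    def test_any_visit_positive_when_any_pex(self):
        reg, labels, probs = self._setup()
        recs, dropped = build_records(reg, labels, probs, 91.3125)
        # P1: visits at 30 (non-PEx) and 80 (PEx) in window -> outcome True
        assert recs.loc[recs.patient_id == "P1", "outcome"].iloc[0] == True
        # P2: no labeled visit within 91 days -> dropped
        assert "P2" not in set(recs.patient_id) and dropped == 1

    def test_exact_date_only_uses_next_visit(self):
        reg, labels, probs = self._setup()
        recs, _ = build_records(reg, labels, probs, 91.3125, "exact_date_only")
        # P1's next labeled visit after t=0 is t=30, non-PEx -> outcome False
        assert recs.loc[recs.patient_id == "P1", "outcome"].iloc[0] == False

    def test_nonpositive_horizon_rejected(self):
        reg, labels, probs = self._setup()
        with pytest.raises(EvaluationError):
            build_records(reg, labels, probs, 0.0)


class TestGroupMetrics:
    def test_identical_groups_get_identical_metrics(self):
        scores = [0.9, 0.7, 0.3, 0.1] * 2
        outcomes = [1, 1, 0, 0] * 2
        race = ["White"] * 4 + ["Black"] * 4
        recs = records_from(scores, outcomes, race=race)
        gms = group_metrics(recs, 0.5, "race", B=50, seed=0)
        by = {g.group: g for g in gms}
        assert by["White"].auc == by["Black"].auc
        assert by["White"].sensitivity == by["Black"].sensitivity

    def test_hand_tallied_confusion(self):
        # group A: scores .9 .6 .4 .2 outcomes 1 0 1 0, cutoff .5
        # -> TP=1 FN=1 FP=1 TN=1: sens .5 spec .5
        recs = records_from([0.9, 0.6, 0.4, 0.2, 0.9, 0.8, 0.3, 0.1],
                            [1, 0, 1, 0, 1, 1, 0, 0],
                            race=["White"] * 4 + ["Black"] * 4)
        gms = {g.group: g for g in group_metrics(recs, 0.5, "race", B=20, seed=0)}
        assert gms["White"].sensitivity == 0.5 and gms["White"].specificity == 0.5
        assert gms["Black"].sensitivity == 1.0 and gms["Black"].specificity == 1.0

    def test_group_specific_J_at_least_shared(self):
        rng = np.random.default_rng(4)
        recs = records_from(np.round(rng.random(60), 2), rng.random(60) < 0.5,
                            race=list(rng.choice(["White", "Black"], 60)))
        shared_cut = youden_cutoff(recs)
        shared = group_metrics(recs, shared_cut, "race", "shared", B=10, seed=0)
        specific = group_metrics(recs, shared_cut, "race", "group_specific", B=10, seed=0)
        for s, g in zip(shared, specific):
            j_s = s.sensitivity + s.specificity - 1
            j_g = g.sensitivity + g.specificity - 1
            assert j_g >= j_s - 1e-12

    def test_single_class_group_warns_not_crashes(self):
        recs = records_from([0.9, 0.8, 0.3, 0.2], [1, 1, 1, 0],
                            race=["White", "White", "Black", "Black"])
        with pytest.warns(RuntimeWarning, match="single outcome class"):
            gms = group_metrics(recs, 0.5, "race", B=10, seed=0)
        by = {g.group: g for g in gms}
        assert np.isnan(by["White"].auc)

    def test_pooled_sensitivity_is_weighted_mean_of_groups(self):
        rng = np.random.default_rng(9)
        recs = records_from(np.round(rng.random(80), 2), rng.random(80) < 0.4,
                            race=list(rng.choice(["White", "Black", "Other"], 80)))
        cutoff = youden_cutoff(recs)
        pooled = sensitivity(recs, cutoff)
        num = den = 0.0
        for _, grp in recs.groupby("race"):
            n_pos = grp.outcome.sum()
            if n_pos:
                num += n_pos * sensitivity(grp, cutoff)
                den += n_pos
        assert pooled == pytest.approx(num / den, abs=1e-12)

    def test_unknown_ethnicity_excluded(self):
        recs = records_from([0.9, 0.2, 0.8, 0.3], [1, 0, 1, 0],
                            ethnicity=["Hispanic", "Hispanic", "Unknown", "Unknown"])
        gms = group_metrics(recs, 0.5, "ethnicity", B=10, seed=0)
        assert {g.group for g in gms} == {"Hispanic"}


class TestBootstrap:
    def test_degenerate_metric_zero_width(self):
        recs = records_from([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0])
        lo, hi = stratified_bootstrap_ci(recs, metric_fn("auc"), B=100, seed=0)
        assert lo == hi == 1.0

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            scores = np.round(rng.random(50), 2)
            outcomes = rng.random(50) < 0.5
            recs = records_from(scores, outcomes)
            point = auc(recs)
            lo, hi = stratified_bootstrap_ci(recs, metric_fn("auc"), B=500, seed=seed)
            assert lo <= point + 1e-9 and point - 1e-9 <= hi

    def test_seed_contract(self):
        recs = records_from(np.linspace(0, 1, 30), [i % 2 for i in range(30)])
        a = stratified_bootstrap_ci(recs, metric_fn("auc"), B=200, seed=42)
        b = stratified_bootstrap_ci(recs, metric_fn("auc"), B=200, seed=42)
        c = stratified_bootstrap_ci(recs, metric_fn("auc"), B=200, seed=43)
        assert a == b and a != c

    def test_fast_and_generic_paths_agree(self):
        recs = records_from(np.linspace(0, 1, 24), [i % 3 == 0 for i in range(24)])
        fast = stratified_bootstrap_ci(recs, metric_fn("auc"), B=150, seed=7)
        slow = stratified_bootstrap_ci(recs, auc, B=150, seed=7)
        assert fast == slow
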