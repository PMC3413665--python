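"""Screening, risk scoring, ROC selection and sextile stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p53risk import screen
from p53risk.types import CoxFit, ExpressionMatrix, RiskThresholds, WeightedSignature
from conftest import make_annotation


class TestCensorAtHorizon:
    def test_boundary_conventions(self):
        ann = make_annotation([7.0, 3.0, 5.0], [1, 1, 1])
        out = screen.censor_at_horizon(ann, 5.0)
        assert out.loc["s0"].tolist() == [5.0, 0]  # event after horizon -> censored
        assert out.loc["s1"].tolist() == [3.0, 1]
        assert out.loc["s2"].tolist() == [5.0, 1]  # exactly at horizon kept as event
        # original untouched
        assert ann.df.loc["s0", "event"] == 1

    def test_rejects_bad_horizon(self):
        ann = make_annotation([1.0], [1])
        with pytest.raises(ValueError):
            screen.censor_at_horizon(ann, 0.0)


def _fit(pid, wald, p=1e-4, flagged=False):
    return CoxFit(pid, beta=wald * 0.1, se=0.1, p_value=p, flagged=flagged)


class TestWaldGroups:
    def test_threshold_membership_example(self):
        fits = [_fit("p1", 3.5), _fit("p2", -2.7), _fit("p3", 1.0), _fit("p4", 2.1)]
        gi, gii, giii = screen.select_wald_groups(fits)
        assert gi.probeset_ids == ["p1"]
        assert set(gii.probeset_ids) == {"p1", "p2"}
        assert set(giii.probeset_ids) == {"p1", "p2", "p4"}

    def test_nestedness_and_weight_identity(self):
        rng = np.random.default_rng(0)
        fits = [_fit(f"p{i}", w) for i, w in enumerate(rng.normal(0, 3, 50))]
        gi, gii, giii = screen.select_wald_groups(fits)
        assert set(gi.probeset_ids) <= set(gii.probeset_ids) <= set(giii.probeset_ids)
        for pid in gi.probeset_ids:
            assert gii.walds[pid] == gi.walds[pid] == giii.walds[pid]

    def test_insignificant_fits_excluded(self):
        fits = [_fit("p1", 3.5, p=0.5), _fit("p2", 3.0)]
        gi, _, _ = screen.select_wald_groups(fits)
        assert gi.probeset_ids == ["p2"]

    def test_all_below_threshold_yields_empty_groups(self, caplog):
        fits = [_fit("p1", 1.5), _fit("p2", -0.5)]
        with caplog.at_level("WARNING"):
            groups = screen.select_wald_groups(fits)
        assert all(len(g) == 0 for g in groups)

    def test_thresholds_must_decrease(self):
        with pytest.raises(ValueError):
            screen.select_wald_groups([], thresholds=(2.0, 2.5))


class TestP53RS:
    def test_weighted_sum_example(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 1.0], "s2": [0.0, 0.0]}, index=["a", "b"])
        )
        sig = WeightedSignature(walds=pd.Series({"a": 2.0, "b": -3.0}))
        scores = screen.compute_p53rs(expr, sig)
        assert scores["s1"] == pytest.approx(-1.0)
        assert scores["s2"] == pytest.approx(0.0)

    def test_homogeneity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(4, 5)), index=list("abcd"))
        sig = WeightedSignature(walds=pd.Series({"a": 2.0, "c": -1.5}))
        s1 = screen.compute_p53rs(ExpressionMatrix(df), sig)
        s2 = screen.compute_p53rs(ExpressionMatrix(2 * df), sig)
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-12)

    def test_coverage_floor(self):
        df = pd.DataFrame(np.ones((2, 3)), index=["a", "b"])
        sig = WeightedSignature(walds=pd.Series({"a": 1.0, "x": 1.0, "y": 1.0}))
        with pytest.raises(ValueError, match="coverage"):
            screen.compute_p53rs(ExpressionMatrix(df), sig)

    def test_missing_cells_use_probeset_mean(self):
        df = pd.DataFrame(
            {"s1": [1.0, np.nan], "s2": [3.0, 4.0], "s3": [2.0, 6.0]},
            index=["a", "b"],
        )
        sig = WeightedSignature(walds=pd.Series({"a": 1.0, "b": 1.0}))
        scores = screen.compute_p53rs(ExpressionMatrix(df), sig)
        assert scores["s1"] == pytest.approx(1.0 + 5.0)  # row-b mean = 5

    def test_monotonicity_in_positive_wald_probeset(self):
        df = pd.DataFrame({"s1": [1.0, 0.0], "s2": [1.0, 0.0]}, index=["a", "b"])
        sig = WeightedSignature(walds=pd.Series({"a": 2.0, "b": -1.0}))
        base = screen.compute_p53rs(ExpressionMatrix(df), sig)
        df2 = df.copy()
        df2.loc["a", "s1"] += 1.0
        bumped = screen.compute_p53rs(ExpressionMatrix(df2), sig)
        assert bumped["s1"] > base["s1"]
        assert bumped["s2"] == base["s2"]


class TestRoc:
    def _cohort(self, times, events):
        return pd.DataFrame(
            {"survival_time": times, "event": events},
            index=[f"s{i}" for i in range(len(times))],
        )

    def test_perfect_ranking(self):
        cohort = self._cohort([1, 2, 5, 5], [1, 1, 0, 0])
        scores = pd.Series([10.0, 9.0, 1.0, 2.0], index=cohort.index)
        roc = screen.roc_evaluate(scores, cohort, horizon=5.0)
        assert roc.auc == 1.0

    def test_specificity_at_full_sensitivity_example(self):
        # events score {5, 7}; non-events {1, 2, 3, 6, 8}
        cohort = self._cohort([1, 2, 5, 5, 5, 5, 5], [1, 1, 0, 0, 0, 0, 0])
        scores = pd.Series([5, 7, 1, 2, 3, 6, 8.0], index=cohort.index)
        roc = screen.roc_evaluate(scores, cohort, horizon=5.0, sensitivity_floor=1.0)
        assert roc.specificity_at_sensitivity == pytest.approx(60.0)

    def test_censored_before_horizon_excluded(self):
        cohort = self._cohort([1.0, 2.0, 3.0, 5.0], [1, 0, 1, 0])
        scores = pd.Series([4.0, 3.0, 2.0, 1.0], index=cohort.index)
        roc = screen.roc_evaluate(scores, cohort, horizon=5.0)
        assert roc.n_excluded == 1
        assert roc.n_positive == 2 and roc.n_negative == 1

    def test_single_class_errors(self):
        cohort = self._cohort([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            screen.roc_evaluate(pd.Series([1.0, 2.0], index=cohort.index), cohort, 5.0)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_auc_equals_pair_counting(self, data):
        n1 = data.draw(st.integers(1, 6))
        n0 = data.draw(st.integers(1, 6))
        vals = data.draw(
            st.lists(st.integers(0, 5), min_size=n1 + n0, max_size=n1 + n0)
        )
        events = [1] * n1 + [0] * n0
        cohort = self._cohort([1.0] * n1 + [5.0] * n0, events)
        scores = pd.Series([float(v) for v in vals], index=cohort.index)
        roc = screen.roc_evaluate(scores, cohort, horizon=5.0)
        pos, neg = vals[:n1], vals[n1:]
        pairs = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        assert roc.auc == pytest.approx(pairs / (n1 * n0), abs=1e-12)


class TestChooseOptimalGroup:
    def test_higher_auc_wins_and_size_breaks_exact_ties(self):
        rng = np.random.default_rng(2)
        n = 60
        risk = np.concatenate([np.zeros(30), np.ones(30)])
        times = np.where(risk == 1, 1.0, 6.0)
        events = np.where(risk == 1, 1, 0)
        cohort = pd.DataFrame(
            {"survival_time": times, "event": events},
            index=[f"s{i}" for i in range(n)],
        )
        informative = risk * 3 + rng.normal(0, 0.1, n)
        noise = rng.normal(size=n)
        df = pd.DataFrame(
            {"inf": informative, "noise": noise, "null": np.zeros(n)},
            index=cohort.index,
        ).T
        expr = ExpressionMatrix(df)
        good = WeightedSignature(pd.Series({"inf": 3.0}), group_label="good")
        bad = WeightedSignature(pd.Series({"noise": 3.0}), group_label="bad")
        best, roc = screen.choose_optimal_group(
            [good, bad], expr, cohort, horizon=5.0, sensitivity_floor=1.0
        )
        assert best.group_label == "good"
        assert roc.auc > 0.9

        # identical scores => AUC/specificity tie; the smaller group wins
        padded = WeightedSignature(
            pd.Series({"inf": 3.0, "null": 5.0}), group_label="padded"
        )
        best2, _ = screen.choose_optimal_group(
            [padded, good], expr, cohort, horizon=5.0, sensitivity_floor=1.0
        )
        assert best2.group_label == "good"

    def test_all_empty_errors(self, tiny_expr):
        empty = WeightedSignature(pd.Series(dtype=float))
        cohort = pd.DataFrame(
            {"survival_time": [1.0, 2.0], "event": [1, 0]}, index=["s1", "s2"]
        )
        with pytest.raises(ValueError, match="empty"):
            screen.choose_optimal_group([empty], tiny_expr, cohort, 5.0)


class TestSextilesAndAssignment:
    def test_type1_quantiles_on_1_to_12(self):
        scores = pd.Series(np.arange(1.0, 13.0), index=[f"s{i}" for i in range(12)])
        thr = screen.derive_sextile_thresholds(scores)
        assert thr.lower == 2.0
        assert thr.upper == 6.0

    def test_reorder_invariance_and_errors(self):
        scores = pd.Series(np.arange(1.0, 13.0), index=[f"s{i}" for i in range(12)])
        thr2 = screen.derive_sextile_thresholds(scores.sample(frac=1, random_state=0))
        assert (thr2.lower, thr2.upper) == (2.0, 6.0)
        with pytest.raises(ValueError):
            screen.derive_sextile_thresholds(scores.iloc[:5])
        with pytest.raises(ValueError, match="degenerate"):
            screen.derive_sextile_thresholds(
                pd.Series([1.0] * 12, index=[f"s{i}" for i in range(12)])
            )

    def test_printed_boundary_conventions(self):
        thr = RiskThresholds(-89.27, 25.33, "raw")
        scores = pd.Series(
            {"a": -90.0, "b": -89.27, "c": 0.0, "d": 25.33, "e": 100.0}
        )
        out = screen.assign_risk_groups(scores, thr)
        assert out["group"].tolist() == [
            "low", "intermediate", "intermediate", "high", "high",
        ]

    def test_scale_mismatch_rejected(self):
        thr = RiskThresholds(-1.0, 1.0, "z")
        with pytest.raises(ValueError, match="scale"):
            screen.assign_risk_groups(pd.Series({"a": 0.0, "b": 1.0}), thr, "raw")

    def test_self_assignment_proportions(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=120), index=[f"s{i}" for i in range(120)])
        thr = screen.derive_sextile_thresholds(scores)
        out = screen.assign_risk_groups(scores, thr)
        counts = out["group"].value_counts()
        # lower-closed boundaries put the threshold sample itself in the
        # upper group, so counts sit within one sample of n/6, 2n/6, 3n/6
        assert abs(counts["low"] - 20) <= 1
        assert abs(counts["intermediate"] - 40) <= 1
        assert abs(counts["high"] - 60) <= 1
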