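"""Centroid derivation and centroid-correlation behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p53risk import signature
from p53risk.types import CentroidTemplate, ExpressionMatrix
from conftest import make_annotation


def brute_pearson(x, y):
    """Textbook Pearson r and t-transform p, written independently."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (
        sum((a - mx) ** 2 for a in x) ** 0.5
        * sum((b - my) ** 2 for b in y) ** 0.5
    )
    r = num / den
    if abs(r) >= 1.0 - 1e-15:
        return r, 0.0
    from scipy import stats

    t = r * ((n - 2) / (1 - r * r)) ** 0.5
    return r, 2 * stats.t.sf(abs(t), n - 2)


def test_standardize_row_values(tiny_expr):
    z = signature.standardize(tiny_expr)
    np.testing.assert_allclose(z.values.loc["p1"], [-1.0, 0.0, 1.0])
    np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-12)


def test_standardize_drops_constant_rows(caplog):
    df = pd.DataFrame(
        [[5.0, 5.0, 5.0], [1.0, 2.0, 3.0], [0.0, 1.0, 4.0]],
        index=["const", "a", "b"],
        columns=["s1", "s2", "s3"],
    )
    with caplog.at_level("WARNING"):
        z = signature.standardize(ExpressionMatrix(df))
    assert "const" not in z.values.index
    assert any("const" in rec.message for rec in caplog.records)


class TestDeriveCentroid:
    def _planted(self, seed, d=3.0):
        rng = np.random.default_rng(seed)
        n_probes, n_sig = 120, 8
        x = rng.normal(0, 1.0, size=(n_probes, 40))
        x[:n_sig, 20:] += d
        expr = ExpressionMatrix(
            pd.DataFrame(
                x,
                index=[f"p{i}" for i in range(n_probes)],
                columns=[f"s{i}" for i in range(40)],
            )
        )
        ann = make_annotation(
            [np.nan] * 40, [np.nan] * 40, sample_ids=list(expr.sample_ids),
            class_label=["normal"] * 20 + ["carcinoma"] * 20,
        )
        return expr, ann, [f"p{i}" for i in range(n_sig)]

    def test_recovers_planted_set(self):
        expr, ann, planted = self._planted(0)
        cen = signature.derive_centroid(expr, ann, t_threshold=3.0, max_fdr=0.05)
        assert set(planted) <= set(cen.probeset_ids)
        false_pos = set(cen.probeset_ids) - set(planted)
        assert len(false_pos) <= 0.05 * 120

    def test_null_selects_nothing_or_raises(self):
        expr, ann, _ = self._planted(1, d=0.0)
        try:
            cen = signature.derive_centroid(expr, ann)
            assert len(cen) <= 0.05 * 120
        except ValueError as exc:
            assert "no probeset" in str(exc)

    def test_label_swap_negates_t_values(self):
        expr, ann, _ = self._planted(2)
        cen = signature.derive_centroid(expr, ann)
        swapped = signature.derive_centroid(
            expr, ann, tumour_label="normal", normal_label="carcinoma"
        )
        common = sorted(set(cen.probeset_ids) & set(swapped.probeset_ids))
        assert common == sorted(cen.probeset_ids)
        np.testing.assert_allclose(
            swapped.t_values[common], -cen.t_values[common], rtol=1e-12
        )

    def test_too_few_samples_per_class(self):
        expr, ann, _ = self._planted(3)
        ann.df["class_label"] = ["normal"] + ["carcinoma"] * 39
        with pytest.raises(ValueError, match=">=2"):
            signature.derive_centroid(expr, ann)


class TestCentroidCorrelation:
    centroid = CentroidTemplate(
        pd.Series({"p1": 2.0, "p2": -1.0, "p3": 3.0, "p4": -2.0})
    )

    def _matrix(self, cols):
        return ExpressionMatrix(
            pd.DataFrame(cols, index=["p1", "p2", "p3", "p4"]).astype(float)
        )

    def test_proportional_vector_gives_r_one(self):
        t = self.centroid.t_values
        m = self._matrix({"s1": 0.5 * t.values, "s2": -t.values})
        res = signature.centroid_correlation(m, self.centroid)
        assert res.loc["s1", "pearson_r"] == pytest.approx(1.0)
        assert res.loc["s2", "pearson_r"] == pytest.approx(-1.0)
        assert res.loc["s1", "p_value"] > 0

    def test_matches_brute_force_oracle(self):
        z = [1.0, 0.0, 2.0, -1.0]
        m = self._matrix({"s1": z, "s2": [0.3, 1.2, -0.7, 0.5]})
        res = signature.centroid_correlation(m, self.centroid)
        r, p = brute_pearson(z, list(self.centroid.t_values))
        assert res.loc["s1", "pearson_r"] == pytest.approx(r, abs=1e-12)
        assert res.loc["s1", "p_value"] == pytest.approx(p, rel=1e-10)
        assert res.loc["s1", "n_probesets_used"] == 4

    def test_missing_values_pairwise_excluded(self):
        m = self._matrix({"s1": [1.0, np.nan, 2.0, -1.0], "s2": [1.0, 0.0, 2.0, -1.0]})
        res = signature.centroid_correlation(m, self.centroid)
        assert res.loc["s1", "n_probesets_used"] == 3
        t = self.centroid.t_values
        r, _ = brute_pearson([1.0, 2.0, -1.0], [t["p1"], t["p3"], t["p4"]])
        assert res.loc["s1", "pearson_r"] == pytest.approx(r, abs=1e-12)

    def test_too_few_shared_probesets(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 1.0]}, index=["p1", "p2"])
        )
        with pytest.raises(ValueError, match=">=3"):
            signature.centroid_correlation(m, self.centroid)

    @given(
        z=st.lists(st.integers(-2, 2), min_size=4, max_size=4),
        t=st.lists(st.integers(-2, 2), min_size=4, max_size=4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_oracle_equivalence_on_integer_vectors(self, z, t):
        if len(set(z)) < 2 or len(set(t)) < 2:
            return
        cen = CentroidTemplate(pd.Series(dict(zip(["a", "b", "c", "d"], map(float, t)))))
        m = ExpressionMatrix(
            pd.DataFrame(
                {"s1": list(map(float, z)), "s2": [0.0, 1.0, 2.0, 3.0]},
                index=["a", "b", "c", "d"],
            )
        )
        res = signature.centroid_correlation(m, cen)
        r, p = brute_pearson(list(map(float, z)), list(map(float, t)))
        assert res.loc["s1", "pearson_r"] == pytest.approx(r, abs=1e-12)
        if abs(r) < 1:
            assert res.loc["s1", "p_value"] == pytest.approx(p, rel=1e-9)

    def test_centroid_negation_and_scale_invariance(self):
        m = self._matrix({"s1": [1.0, 0.4, -0.3, 2.0], "s2": [0.0, 1.0, -1.0, 0.5]})
        base = signature.centroid_correlation(m, self.centroid)
        neg = signature.centroid_correlation(
            m, CentroidTemplate(-self.centroid.t_values)
        )
        np.testing.assert_allclose(neg["pearson_r"], -base["pearson_r"], rtol=1e-12)
        scaled = signature.centroid_correlation(
            m, CentroidTemplate(7.5 * self.centroid.t_values)
        )
        np.testing.assert_allclose(scaled["pearson_r"], base["pearson_r"], rtol=1e-12)


def test_group_mean_correlation():
    res = pd.DataFrame(
        {"pearson_r": [0.2, 0.4, 0.9], "p_value": [0.1] * 3, "n_probesets_used": [5] * 3},
        index=pd.Index(["a", "b", "c"], name="sample_id"),
    )
    out = signature.group_mean_correlation(
        res, {"a": "wt", "b": "wt", "c": "mut"}
    )
    assert out.set_index("group").loc["wt", "mean_r"] == pytest.approx(0.3)
    assert out.set_index("group").loc["mut", "n"] == 1
    # permuting sample order leaves the result unchanged
    out2 = signature.group_mean_correlation(
        res.iloc[::-1], {"a": "wt", "b": "wt", "c": "mut"}
    )
    pd.testing.assert_frame_equal(out, out2)
    with pytest.raises(ValueError, match="without group"):
        signature.group_mean_correlation(res, {"a": "wt"})


def test_order_for_heatmap(tiny_expr):
    cen = CentroidTemplate(pd.Series({"p1": -1.0, "p2": 3.0, "p3": 0.5}))
    res = pd.DataFrame(
        {"pearson_r": [0.5, -0.2, 0.5]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    samples, probes = signature.order_for_heatmap(tiny_expr, cen, res)
    assert samples == ["s2", "s1", "s3"]  # ascending r; lexicographic tie-break
    assert probes == ["p2", "p3", "p1"]  # descending T


def test_rle_qc_flags_shifted_sample():
    rng = np.random.default_rng(0)
    x = rng.normal(8, 0.2, size=(50, 6))
    df = pd.DataFrame(x, index=[f"p{i}" for i in range(50)],
                      columns=[f"s{i}" for i in range(6)])
    df["s5"] += 5.0
    qc = signature.rle_qc(ExpressionMatrix(df))
    assert bool(qc.loc["s5", "flagged"])
    assert qc.loc["s5", "rle_median"] == pytest.approx(5.0, abs=0.5)
    assert not qc.loc[["s0", "s1", "s2", "s3"], "flagged"].any()
    # column order invariance
    qc2 = signature.rle_qc(ExpressionMatrix(df[df.columns[::-1]]))
    assert set(qc2.index[qc2.flagged]) == set(qc.index[qc.flagged])


def test_rle_identical_samples_unflagged():
    df = pd.DataFrame(
        np.tile(np.arange(10, dtype=float)[:, None], (1, 4)),
        index=[f"p{i}" for i in range(10)],
        columns=list("abcd"),
    )
    qc = signature.rle_qc(ExpressionMatrix(df))
    assert (qc["rle_median"] == 0).all()
    assert not qc["flagged"].any()
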