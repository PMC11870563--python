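"""Age-association statistics, BH-FDR, screening, ROI means, rank report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from petica.association import (
    REFERENCE_LINE,
    AgeAssociation,
    fdr_bh,
    rank_report,
    roi_means,
    screen,
    standardized_beta,
)
from petica.volumes import ValidationError, Volume


def _brute_force_bh(p):
    """Independent oracle: q_(i) = min_{j>=i} p_(j) * m / j, direct enumeration."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        tail = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(tail))
    return q


class TestStandardizedBeta:
    def test_self_correlation_is_one(self):
        ages = np.arange(10.0) + 50
        beta, p = standardized_beta(ages, ages)
        assert beta == pytest.approx(1.0)
        assert p < 1e-10

    def test_orthogonal_values_give_zero_beta(self):
        ages = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to centered ages
        beta, p = standardized_beta(values, ages)
        assert beta == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_closed_form_oracle_ten_points(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(55, 90, 10)
        values = 0.02 * ages + rng.normal(0, 0.5, 10)
        beta, p = standardized_beta(values, ages)
        # independent covariance / SD-product formula and t CDF evaluation
        r = float(
            np.mean((values - values.mean()) * (ages - ages.mean()))
            / (values.std() * ages.std())
        )
        t = r * np.sqrt(8) / np.sqrt(1 - r**2)
        p_expected = 2 * stats.t.sf(abs(t), df=8)
        assert beta == pytest.approx(r, rel=1e-10)
        assert p == pytest.approx(p_expected, rel=1e-8)

    def test_beta_equals_pearson_r(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=50)
        ages = rng.normal(size=50)
        beta, _ = standardized_beta(values, ages)
        assert beta == pytest.approx(stats.pearsonr(values, ages).statistic)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            standardized_beta(np.ones(5), np.arange(5.0))


class TestFDR:
    def test_single_p_passes_through(self):
        assert fdr_bh([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_ps_stay_equal(self):
        q = fdr_bh([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=8
        )
    )
    def test_matches_brute_force_min_over_tail(self, ps):
        assert np.allclose(fdr_bh(ps), _brute_force_bh(ps), atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=8))
    def test_q_never_below_p(self, ps):
        q = fdr_bh(ps)
        assert np.all(q >= np.asarray(ps) - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_bh([0.1, 1.2])


class TestScreening:
    def test_negative_beta_marked_x_neg(self):
        frame = pd.DataFrame(
            {"unit": ["a", "b", "c"], "beta": [0.3, -0.1, 0.0], "q": [0.01, 0.2, 0.5]}
        )
        out = screen(frame)
        assert list(out["status"]) == ["retained", "x-neg", "retained"]

    def test_metadata_flags_take_precedence(self):
        frame = pd.DataFrame(
            {"unit": ["ref", "wm", "ok"], "beta": [0.5, -0.5, 0.5], "q": [0.1] * 3}
        )
        out = screen(frame, {"ref": "reference", "wm": "x-non-gm"})
        assert list(out["status"]) == ["reference", "x-non-gm", "retained"]


class TestROIMeans:
    def _label_vol(self, labels):
        return Volume(np.asarray(labels, dtype=float), np.eye(4))

    def test_constant_volume_gives_constant_means(self):
        vol = Volume(np.full((4, 4, 4), 2.5), np.eye(4))
        labels = np.zeros((4, 4, 4))
        labels[:2] = 1
        labels[2:] = 2
        means = roi_means(vol, self._label_vol(labels))
        assert np.allclose(means.to_numpy(), 2.5)

    def test_two_label_hand_case(self):
        data = np.array([1.0, 1.0, 2.0, 2.0]).reshape(4, 1, 1)
        labels = np.array([1, 1, 2, 2]).reshape(4, 1, 1)
        means = roi_means(Volume(data, np.eye(4)), self._label_vol(labels))
        assert means.tolist() == [1.0, 2.0]

    def test_random_volume_matches_direct_per_label_average(self):
        rng = np.random.default_rng(0)
        data = rng.random((6, 6, 6))
        labels = rng.integers(0, 4, (6, 6, 6))
        means = roi_means(
            Volume(data, np.eye(4)), self._label_vol(labels)
        )
        for i, lab in enumerate((1, 2, 3)):
            assert means.iloc[i] == pytest.approx(data[labels == lab].mean())

    def test_missing_lut_label_warns_and_uses_id(self):
        data = np.ones((2, 2, 2))
        labels = np.ones((2, 2, 2))
        with pytest.warns(UserWarning):
            means = roi_means(
                Volume(data, np.eye(4)), self._label_vol(labels), lut={2: "x"}
            )
        assert list(means.index) == ["1"]


class TestModelAndRanking:
    def test_model_fits_all_columns_and_orders_q(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(55, 90, 80)
        z = (ages - ages.mean()) / ages.std()
        measures = pd.DataFrame(
            {
                "strong": 0.6 * z + rng.normal(0, 0.3, 80),
                "weak": 0.1 * z + rng.normal(0, 1.0, 80),
                "neg": -0.5 * z + rng.normal(0, 0.3, 80),
            }
        )
        res = AgeAssociation(measures, ages).fit()
        frame = res.frame.set_index("unit")
        assert frame.loc["neg", "status"] == "x-neg"
        assert (frame["q"] >= frame["p"] - 1e-15).all()
        assert frame.loc["strong", "q"] < frame.loc["weak", "q"]
        assert res.n_significant() >= 1
        assert "standardized beta" in res.summary()

    def test_rank_report_reference_line_and_sort(self):
        frame = pd.DataFrame(
            {
                "unit": ["a", "b", "c"],
                "beta": [0.5, 0.4, 0.3],
                "q": [0.05, 0.05, 0.05],
                "status": ["retained"] * 3,
            }
        )
        table = rank_report({"nets": frame})
        assert np.allclose(table["neg_log10_q"], REFERENCE_LINE)
        # ordering oracle: ranks follow an ascending-q sort
        rng = np.random.default_rng(3)
        qs = rng.uniform(0, 1, 6)
        frame2 = pd.DataFrame(
            {
                "unit": [f"u{i}" for i in range(6)],
                "beta": [0.1] * 6,
                "q": qs,
                "status": ["retained"] * 6,
            }
        )
        table2 = rank_report({"nets": frame2})
        assert list(table2["q"]) == sorted(qs)

    def test_rank_report_empty_retained_set(self):
        frame = pd.DataFrame(
            {"unit": ["a"], "beta": [-0.5], "q": [0.9], "status": ["x-neg"]}
        )
        table = rank_report({"nets": frame})
        assert len(table) == 0
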