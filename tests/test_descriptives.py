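"""Summary moments, Tukey hinges, smoothing, box-plot and notch interval."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pmroutes.descriptives import (
    boxplot_stats,
    empirical_median_ci,
    moving_average,
    relative_error_percent,
    summary_stats,
    tukey_hinges,
)
from pmroutes.series import RouteSeries

floats_list = st.lists(
    st.floats(min_value=0.0, max_value=1e3, allow_nan=False), min_size=1, max_size=40
)


class TestSummaryStats:
    def test_hand_computed_moments(self):
        s = summary_stats([0, 1, 2, 3, 4])
        assert s.mean == 2 and s.median == 2
        assert s.sd == pytest.approx(1.5811, abs=1e-4)
        assert s.skewness == pytest.approx(0.0)
        assert s.kurtosis == pytest.approx(1.7)

    def test_skewness_hand_oracle(self):
        # m2 = 18.75, m3 = 93.75 -> skew = 93.75 / 18.75**1.5
        s = summary_stats([0, 0, 0, 10])
        assert s.skewness == pytest.approx(1.1547, abs=1e-4)

    def test_constant_sample_has_undefined_shape(self):
        s = summary_stats([2, 2, 2, 2])
        assert (s.mean, s.median, s.sd) == (2, 2, 0)
        assert s.skewness is None and s.kurtosis is None

    @given(floats_list, st.floats(min_value=0, max_value=100))
    def test_location_shift_moves_location_only(self, xs, shift):
        a, b = summary_stats(xs), summary_stats([x + shift for x in xs])
        assert b.mean == pytest.approx(a.mean + shift, abs=1e-8)
        assert b.median == pytest.approx(a.median + shift, abs=1e-8)
        assert b.sd == pytest.approx(a.sd, abs=1e-8)
        if a.skewness is not None and b.skewness is not None:
            assert b.skewness == pytest.approx(a.skewness, abs=1e-6)
            assert b.kurtosis == pytest.approx(a.kurtosis, abs=1e-6)

    def test_normal_sample_shape_confirms_non_excess_convention(self, rng):
        x = rng.standard_normal(100_000)
        s = summary_stats(x)
        assert s.kurtosis == pytest.approx(3.0, abs=0.15)
        assert s.skewness == pytest.approx(0.0, abs=0.05)


class TestTukeyHinges:
    @pytest.mark.parametrize(
        "data, expected",
        [
            ([1, 2, 3, 4, 5], (2, 3, 4)),
            ([1, 2, 3, 4], (1.5, 2.5, 3.5)),
            ([5, 5, 5], (5, 5, 5)),
        ],
    )
    def test_hinge_rule(self, data, expected):
        q = tukey_hinges(data)
        assert (q.q1, q.q2, q.q3) == expected

    def test_matches_half_median_oracle_exhaustively(self, rng):
        for n in range(1, 13):
            for _ in range(20):
                x = np.sort(rng.uniform(0, 1, n))
                half = (n + 1) // 2
                q = tukey_hinges(x)
                assert q.q1 == np.median(x[:half])
                assert q.q3 == np.median(x[n - half:])
                assert q.q1 <= q.q2 <= q.q3


class TestMovingAverage:
    def test_truncated_centered_means(self):
        r = RouteSeries("t", np.array([1.0, 2, 3, 4, 5]))
        np.testing.assert_allclose(
            moving_average(r, 3).values, [1.5, 2, 3, 4, 4.5]
        )

    def test_window_one_is_identity_and_constant_unchanged(self, rng):
        x = rng.uniform(0, 1, 30)
        r = RouteSeries("t", x)
        np.testing.assert_array_equal(moving_average(r, 1).values, x)
        c = RouteSeries("c", np.full(10, 0.3))
        np.testing.assert_allclose(moving_average(c, 7).values, 0.3)

    def test_never_exceeds_input_range(self, rng):
        x = rng.uniform(0, 1, 50)
        for w in (2, 5, 10, 20):
            sm = moving_average(RouteSeries("t", x), w).values
            assert sm.min() >= x.min() - 1e-12
            assert sm.max() <= x.max() + 1e-12

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(RouteSeries("t", np.ones(3)), 0)


class TestBoxplot:
    def test_fence_outlier(self):
        b = boxplot_stats([1, 2, 3, 4, 100])
        assert list(b.outliers) == [100]
        assert b.whisker_high == 4

    def test_plain_and_constant_samples_have_no_outliers(self):
        assert boxplot_stats([1, 2, 3, 4, 5]).outliers.size == 0
        b = boxplot_stats([3, 3, 3])
        assert b.outliers.size == 0 and b.quartiles.iqr == 0


class TestEmpiricalMedianCI:
    def test_notch_formula(self):
        lo, hi = empirical_median_ci([1, 2, 3, 4])
        assert lo == pytest.approx(2.5 - 1.57)
        assert hi == pytest.approx(2.5 + 1.57)

    def test_constant_data_zero_width(self):
        lo, hi = empirical_median_ci([4, 4, 4, 4])
        assert lo == hi == 4

    @given(st.floats(min_value=0.1, max_value=50))
    def test_scale_equivariance(self, lam):
        base = np.array([1.0, 2, 3, 4, 10])
        lo, hi = empirical_median_ci(base)
        lo2, hi2 = empirical_median_ci(lam * base)
        assert lo2 == pytest.approx(lam * lo, rel=1e-9)
        assert hi2 == pytest.approx(lam * hi, rel=1e-9)


def test_relative_error_rounds_to_integer_percent():
    assert relative_error_percent(4.94, 4.91) == -1
    assert relative_error_percent(100.0, 115.0) == 15
    with pytest.raises(ValueError):
        relative_error_percent(0.0, 1.0)
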