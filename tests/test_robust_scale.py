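"""The seven scale estimators and their dispersion-estimate properties."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pmroutes.robust_scale import (
    biweight_midvariance,
    biweight_scale,
    lms_scale,
    mad,
    mean_abs_dev,
    sample_sd,
    scale_table,
    sir,
    subrange_scale,
)

SCALE_FNS = {
    "mad_mean": mean_abs_dev,
    "sd": sample_sd,
    "mad": mad,
    "sir": sir,
    "sbi": lambda x: biweight_scale(x, 9.0),
    "cn": lambda x: subrange_scale(x, 0.25),
    "lms": lms_scale,
}

sample = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False),
    min_size=8,
    max_size=40,
)


class TestPointEstimators:
    def test_hand_computed_values(self):
        assert mean_abs_dev([1, 2, 3, 4, 100]) == pytest.approx(31.2)
        assert mean_abs_dev([0, 4]) == 2
        assert sample_sd([0, 1, 2, 3, 4]) == pytest.approx(1.5811, abs=1e-4)
        assert sample_sd([0, 4]) == pytest.approx(2.8284, abs=1e-4)
        assert mad([1, 2, 3, 4, 100]) == 1
        assert mad([1, 1, 2, 2, 4, 7]) == 1
        assert sir([1, 2, 3, 4, 5]) == 1
        assert sir([1, 2, 3, 4]) == 1

    def test_constant_data_all_zero(self):
        x = [3.0] * 8
        for name, fn in SCALE_FNS.items():
            assert fn(x) == 0, name


class TestBiweight:
    def test_direct_evaluation_at_c_nine(self):
        # u = (x - M)/(9 * MAD) = 0, +-1/9, +-2/9 for [0,1,2,3,4]
        assert biweight_midvariance([0, 1, 2, 3, 4], 9.0) == pytest.approx(
            2.2971, abs=1e-3
        )

    def test_large_c_limit_is_mean_square_about_median(self, rng):
        for _ in range(10):
            x = rng.lognormal(0, 1, 30)
            limit = np.mean((x - np.median(x)) ** 2)
            assert biweight_midvariance(x, 1e6) == pytest.approx(limit, rel=1e-4)

    def test_scale_form_is_sqrt_of_midvariance(self):
        x = [0.0, 1, 2, 3, 4]
        assert biweight_scale(x, 9.0) == pytest.approx(
            np.sqrt(biweight_midvariance(x, 9.0))
        )

    def test_invalid_c(self):
        with pytest.raises(ValueError):
            biweight_midvariance([1, 2, 3], 0.0)


class TestSubrangeAndLMS:
    @pytest.mark.parametrize(
        "alpha, expected", [(0.2, 3.645), (0.45, 2.502)]
    )
    def test_normalised_minimum_subrange(self, alpha, expected):
        assert subrange_scale([1, 2, 3, 4, 100], alpha) == pytest.approx(
            expected, abs=2e-3
        )

    def test_raw_minimum_matches_brute_force_pair_enumeration(self, rng):
        from scipy import stats as ss

        for n in range(5, 31):
            x = np.sort(rng.lognormal(0, 1, n))
            for alpha in (0.1, 0.25, 0.4):
                h = int(np.floor(alpha * n)) + 1
                brute = min(
                    x[j] - x[i]
                    for i in range(n)
                    for j in range(n)
                    if j - i == h
                )
                norm = ss.norm.ppf(0.75) - ss.norm.ppf(0.75 - alpha)
                assert subrange_scale(x, alpha) == pytest.approx(
                    brute / norm, rel=1e-12
                )

    @pytest.mark.parametrize(
        "data, expected", [([1, 2, 3, 4, 100], 1.0), ([0, 10, 11, 12, 13, 100], 1.5)]
    )
    def test_lms_shortest_half_window(self, data, expected):
        assert lms_scale(data) == expected

    def test_subrange_rejects_bad_alpha_or_tiny_n(self):
        with pytest.raises(ValueError):
            subrange_scale([1, 2, 3, 4, 5], 0.6)
        with pytest.raises(ValueError):
            subrange_scale([1.0], 0.3)


class TestDispersionEstimateConditions:
    @given(sample, st.floats(min_value=-50, max_value=50),
           st.floats(min_value=-5, max_value=5))
    def test_shift_invariance_and_scale_equivariance(self, xs, shift, lam):
        x = np.array(xs)
        for name, fn in SCALE_FNS.items():
            s = fn(x)
            assert fn(x + shift) == pytest.approx(s, rel=1e-6, abs=1e-9), name
            assert fn(lam * x) == pytest.approx(
                abs(lam) * s, rel=1e-6, abs=1e-9
            ), name
            assert s >= 0, name


class TestNormalConsistencyAndBreakdown:
    def test_normal_consistency_of_robust_estimators(self, rng):
        x = rng.standard_normal(100_000)
        assert mad(x) == pytest.approx(0.6745, abs=0.02)
        assert sir(x) == pytest.approx(0.6745, abs=0.02)
        assert subrange_scale(x, 0.25) == pytest.approx(1.0, rel=0.10)
        # E[MAD] ~ (2/3) sigma for normal data, within 2%
        assert mad(x) == pytest.approx(2 / 3, rel=0.02)

    def test_high_breakdown_resists_heavy_corruption(self, rng):
        # 50%-breakdown estimators: moderate one-sided corruption moves
        # them a little, 40% corruption leaves them bounded (same order of
        # magnitude), while the classical SD explodes either way.
        x = rng.standard_normal(200)
        mild = x.copy()
        mild[:40] = 1e6  # 20% replaced
        assert abs(mad(mild) - mad(x)) / mad(x) < 0.5
        assert abs(lms_scale(mild) - lms_scale(x)) / lms_scale(x) < 0.5
        assert sample_sd(mild) / sample_sd(x) > 1e3
        heavy = x.copy()
        heavy[:80] = 1e6  # 40% replaced: bounded, not exploded
        assert mad(heavy) / mad(x) < 5
        assert lms_scale(heavy) / lms_scale(x) < 5
        assert sample_sd(heavy) / sample_sd(x) > 1e3


class TestScaleTable:
    def test_constant_series_all_zero(self):
        t = scale_table(np.full(20, 0.03))
        for est in (t.mad_mean, t.sd, t.mad, t.sir, t.lms):
            assert est == pytest.approx(0.0, abs=1e-12)

    def test_contaminated_sample_ordering(self, rng):
        # heavy contamination: classical SD > MADmean > robust estimates
        x = rng.lognormal(np.log(0.03), 0.4, 300)
        x[rng.random(300) < 0.08] *= 15
        t = scale_table(x)
        assert t.sd > t.mad_mean > max(t.mad, t.sir, t.lms)

    def test_sweep_grids_cover_stated_ranges(self, rng):
        t = scale_table(rng.lognormal(0, 1, 100))
        assert t.sbi_c[0] == pytest.approx(0.1) and t.sbi_c[-1] == pytest.approx(18.0)
        assert t.cn_alphas[0] == pytest.approx(0.005)
        assert t.cn_alphas[-1] == pytest.approx(0.495)
        assert np.all(t.sbi_estimates >= 0) and np.all(t.cn_estimates >= 0)
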