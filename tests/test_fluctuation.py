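import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import spikecascade as sc
from spikecascade._errors import (
    DegenerateSeriesError,
    InsufficientDataError,
    ParameterError,
)
from spikecascade.fluctuation import Profile, detrended_increments


class TestCumulate:
    def test_partial_sums(self):
        prof = sc.cumulate(sc.ISISeries(values=np.array([1.0, 2.0, 3.0])))
        np.testing.assert_allclose(prof.y, [1, 3, 6])

    def test_constant_rate_is_linear(self):
        prof = sc.cumulate(sc.ISISeries(values=np.full(100, 0.5)))
        np.testing.assert_allclose(np.diff(prof.y), 0.5)

    def test_single_isi(self):
        assert len(sc.cumulate(sc.ISISeries(values=np.array([2.0])))) == 1

    def test_empty_errors(self):
        with pytest.raises(InsufficientDataError):
            sc.cumulate(sc.ISISeries(values=np.empty(0)))


class TestMakeScales:
    def test_defaults(self):
        scales = sc.make_scales()
        assert scales[0] == 4 and scales[-1] == 582
        assert len(scales) == 10
        assert scales == sorted(set(scales))

    def test_small_grid(self):
        assert sc.make_scales(4, 8, 2) == [4, 8]

    def test_bad_ordering(self):
        with pytest.raises(ParameterError):
            sc.make_scales(8, 4, 3)


class TestDetrendedIncrements:
    @pytest.mark.parametrize("coeffs", [(2.0, 0.5, 0, 0), (1, 0.1, 1e-3, 1e-5)])
    def test_cubic_profile_is_annihilated(self, coeffs):
        i = np.arange(200, dtype=float)
        a, b, c, d = coeffs
        y = a + b * (i + 1) + c * (i + 1) ** 2 + d * (i + 1) ** 3
        with pytest.raises(DegenerateSeriesError):
            detrended_increments(Profile(y=y), s=16, order=3)

    def test_constant_isi_degenerate_for_any_order(self):
        prof = sc.cumulate(sc.ISISeries(values=np.full(300, 1.0)))
        for order in (1, 2, 3):
            with pytest.raises(DegenerateSeriesError):
                detrended_increments(prof, s=8, order=order)

    def test_standardized_has_unit_sd_and_small_mean(self, cascade_16k):
        fs = detrended_increments(sc.cumulate(cascade_16k), s=32)
        assert abs(np.std(fs.standardized) - 1.0) < 1e-12
        assert abs(np.mean(fs.standardized)) < 3 / np.sqrt(len(fs))

    def test_iid_increments_are_gaussian_at_moderate_scale(self):
        """CLT oracle: detrended sums of s iid ISIs match direct sums."""
        rng = np.random.default_rng(21)
        isi = sc.ISISeries(values=rng.gamma(4.0, 0.25, size=10 ** 4))
        fs = detrended_increments(sc.cumulate(isi), s=16)
        # direct oracle: sums of 16 iid gamma ISIs, centered and scaled
        sums = isi.values[: 16 * 600].reshape(-1, 16).sum(axis=1)
        z = (sums - sums.mean()) / sums.std()
        assert stats.kstest(fs.standardized, "norm").pvalue > 0.01
        assert stats.ks_2samp(fs.standardized, z).pvalue > 0.01

    def test_too_short_profile(self):
        with pytest.raises(InsufficientDataError):
            detrended_increments(Profile(y=np.arange(1, 10.0) ** 1.5), s=8)

    @given(st.tuples(*[st.floats(-2, 2) for _ in range(4)]))
    @settings(max_examples=30, deadline=None)
    def test_added_cubic_trend_never_changes_fluctuations(self, coeffs):
        """Any degree-<=3 trend added to the profile is removed exactly."""
        rng = np.random.default_rng(22)
        base = np.cumsum(rng.gamma(2.0, 0.5, size=600))
        i = np.arange(base.size, dtype=float)
        trend = sum(c * (i / 100) ** k for k, c in enumerate(coeffs))
        shifted = base + trend - trend.min() + 1.0
        if np.any(np.diff(shifted) <= 0):
            return  # profile invariant requires increasing y
        a = detrended_increments(Profile(y=base - base.min() + 1.0), s=16)
        b = detrended_increments(Profile(y=shifted), s=16)
        np.testing.assert_allclose(b.standardized, a.standardized,
                                   rtol=1e-8, atol=1e-8)


class TestFluctuationField:
    def test_short_series_skips_large_scales(self):
        n = 800
        isi = sc.ISISeries(values=np.random.default_rng(23).gamma(
            2.0, 0.5, size=n))
        field = sc.fluctuation_field(isi)
        # length rule: a scale needs one full 2s window, s <= (n - 1) / 2
        assert all(2 * fs.scale_s + 1 <= n for fs in field)
        assert 582 not in [fs.scale_s for fs in field]

    def test_scales_strictly_increasing(self, cascade_16k):
        field = sc.fluctuation_field(cascade_16k)
        out = [fs.scale_s for fs in field]
        assert out == sorted(set(out))

    def test_no_hidden_randomness(self, cascade_16k):
        a = sc.fluctuation_field(cascade_16k, scales=[8, 32])
        b = sc.fluctuation_field(cascade_16k, scales=[8, 32])
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.standardized, fb.standardized)

    def test_sigma_scales_like_sqrt_s_for_iid(self):
        """Brownian scaling of the profile of memoryless ISIs."""
        isi = sc.to_isi(sc.gen_poisson(1.0, 10 ** 5, seed=24))
        field = sc.fluctuation_field(isi)
        s = np.array([fs.scale_s for fs in field], dtype=float)
        sig = np.array([fs.sigma_s for fs in field])
        slope = np.polyfit(np.log(s), np.log(sig), 1)[0]
        assert abs(slope - 0.5) < 0.05

    def test_shuffling_preserves_smallest_scale_sigma(self):
        # for a renewal series the marginal fixes sigma at the smallest
        # scale, so a permutation changes it only by sampling noise
        # (linear detrending: a cubic on a 4-point window leaves no residual)
        isi = sc.gen_renewal(
            sc.RenewalParams(family="gamma", shape=2.0, scale=0.5),
            10 ** 5, seed=98)
        orig = detrended_increments(sc.cumulate(isi), s=2, order=1)
        shuf = detrended_increments(
            sc.cumulate(sc.shuffle_isi(isi, seed=25)), s=2, order=1)
        assert abs(shuf.sigma_s / orig.sigma_s - 1) < 0.05
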