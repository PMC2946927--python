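import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import spikecascade as sc
from spikecascade._errors import ParameterError


class TestPoisson:
    def test_mean_isi_matches_rate(self):
        # rate of the example cortical neuron; SE = mean/sqrt(n)
        rate, n = 2.3, 10 ** 5
        isi = sc.to_isi(sc.gen_poisson(rate, n, seed=1))
        se = (1 / rate) / np.sqrt(n)
        assert abs(isi.mean - 1 / rate) < 3 * se

    def test_cv_is_one(self):
        isi = sc.to_isi(sc.gen_poisson(1.0, 10 ** 5, seed=2))
        cv = np.std(isi.values) / np.mean(isi.values)
        assert abs(cv - 1.0) < 3 / np.sqrt(10 ** 5)

    def test_deterministic_under_seed(self):
        a = sc.gen_poisson(1.0, 100, seed=3)
        b = sc.gen_poisson(1.0, 100, seed=3)
        np.testing.assert_array_equal(a.times, b.times)

    def test_isi_distribution_is_exponential(self):
        isi = sc.to_isi(sc.gen_poisson(2.0, 10 ** 4, seed=4))
        stat = stats.kstest(isi.values, "expon", args=(0, 0.5))
        assert stat.pvalue > 0.01

    def test_invalid_rate(self):
        with pytest.raises(ParameterError):
            sc.gen_poisson(0.0, 100, seed=0)


class TestRenewal:
    def test_gamma_moments(self):
        p = sc.RenewalParams(family="gamma", shape=4.0, scale=0.25)
        isi = sc.gen_renewal(p, 10 ** 5, seed=5)
        n = 10 ** 5
        assert abs(isi.mean - 1.0) < 3 * 0.5 / np.sqrt(n)
        cv = np.std(isi.values) / isi.mean
        assert abs(cv - 0.5) < 0.02

    def test_exponential_equals_gamma_shape_one(self):
        a = sc.gen_renewal(sc.RenewalParams(family="exponential", rate=2.0),
                           10 ** 5, seed=6)
        b = sc.gen_renewal(sc.RenewalParams(family="gamma", shape=1.0,
                                            scale=0.5), 10 ** 5, seed=7)
        assert abs(a.mean - b.mean) < 3 * 0.5 * np.sqrt(2 / 10 ** 5)
        assert abs(np.var(a.values) - np.var(b.values)) < 0.02

    def test_powerlaw_tail_slope(self):
        # log-log histogram slope of the density ~ -alpha beyond the cutoff
        alpha = 2.5
        p = sc.RenewalParams(family="powerlaw_tail", alpha=alpha, cutoff=0.1)
        isi = sc.gen_renewal(p, 10 ** 6, seed=8)
        edges = np.geomspace(0.1, np.quantile(isi.values, 0.999), 30)
        counts, _ = np.histogram(isi.values, bins=edges)
        centers = np.sqrt(edges[:-1] * edges[1:])
        dens = counts / (np.diff(edges) * len(isi))
        good = dens > 0
        slope = np.polyfit(np.log(centers[good]), np.log(dens[good]), 1)[0]
        assert abs(slope + alpha) < 0.2

    def test_infinite_mean_rejected(self):
        with pytest.raises(ParameterError):
            sc.RenewalParams(family="powerlaw_tail", alpha=1.0, cutoff=0.1)


class TestCascade:
    def test_mean_isi_pinned(self, cascade_16k):
        assert np.isclose(cascade_16k.mean, 1.0)
        assert np.all(cascade_16k.values > 0)

    def test_degenerate_cascade_is_noise_only(self):
        p = sc.CascadeParams(depth=10, level_var=1e-12, mean_isi=2.0,
                             noise_eps=0.1)
        isi = sc.gen_cascade_isi(p, 1024, seed=9)
        # amplitudes collapse: ISIs ~ mean * |1 + eps*xi|, CV ~ eps
        cv = np.std(isi.values) / isi.mean
        assert cv < 0.15

    def test_depth_overflow_guard(self):
        with pytest.raises(ParameterError, match="depth"):
            sc.gen_cascade_isi(sc.CascadeParams(depth=3, level_var=0.1), 100,
                               seed=0)

    def test_bit_identical_under_seed(self):
        p = sc.CascadeParams(depth=8, level_var=0.05)
        a = sc.gen_cascade_isi(p, 256, seed=10)
        b = sc.gen_cascade_isi(p, 256, seed=10)
        np.testing.assert_array_equal(a.values, b.values)

    def test_lambda2_slope_matches_level_var(self, cascade_16k):
        """The per-octave lambda^2 decrement is the generator's level_var."""
        lc = sc.lambda_curve(cascade_16k, q=0.25, n_boot=0)
        m = (lc.scales >= 8) & (lc.scales <= 512)
        slope = np.polyfit(np.log2(lc.scales[m]), lc.lambda2[m], 1)[0]
        assert -0.05 * 1.4 < slope < -0.05 * 0.6


class TestShuffle:
    def test_multiset_conserved(self, cascade_16k):
        shuf = sc.shuffle_isi(cascade_16k, seed=11)
        np.testing.assert_array_equal(np.sort(shuf.values),
                                      np.sort(cascade_16k.values))
        assert len(shuf) == len(cascade_16k)

    def test_deterministic_permutation(self, cascade_16k):
        a = sc.shuffle_isi(cascade_16k, seed=12)
        b = sc.shuffle_isi(cascade_16k, seed=12)
        np.testing.assert_array_equal(a.values, b.values)

    @given(st.integers(0, 2 ** 20))
    @settings(max_examples=25, deadline=None)
    def test_conservation_any_seed(self, seed):
        isi = sc.ISISeries(values=np.array([0.5, 1.5, 2.5, 0.1, 0.9]))
        shuf = sc.shuffle_isi(isi, seed=seed)
        assert sorted(shuf.values) == sorted(isi.values)


class TestSplitTrain:
    def test_union_is_exact(self):
        train = sc.gen_poisson(1.0, 2000, seed=13)
        c1, c2 = sc.split_train(train, d=100.0, seed=14)
        merged = np.sort(np.concatenate([c1.times, c2.times]))
        np.testing.assert_array_equal(merged, train.times)

    def test_huge_d_degenerates_gracefully(self):
        train = sc.gen_poisson(1.0, 50, seed=15)
        c1, c2 = sc.split_train(train, d=10 * train.duration, seed=16)
        assert len(c1) + len(c2) == len(train)

    @pytest.mark.parametrize("d", [500.0, 1000.0, 2000.0])
    def test_reference_cut_scales_accepted(self, d):
        train = sc.gen_poisson(2.3, 20000, seed=17)
        c1, c2 = sc.split_train(train, d=d, seed=18)
        assert len(c1) > 0 and len(c2) > 0
        assert c1.meta["split_d"] == d

    def test_invalid_d(self):
        with pytest.raises(ParameterError):
            sc.split_train(sc.gen_poisson(1.0, 10, seed=0), d=0.0, seed=1)


class TestThinTrain:
    def test_partition_is_exact(self):
        train = sc.gen_poisson(1.0, 1000, seed=19)
        kids = sc.thin_train(train, 4, seed=20)
        merged = np.sort(np.concatenate([k.times for k in kids]))
        np.testing.assert_array_equal(merged, train.times)
        assert len(kids) == 4
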