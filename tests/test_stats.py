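"""Rank-sum tests, Storey q-values, CV profiles and condition comparisons."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import spikememd as sm
from spikememd.preprocess import TrialWindowSet
from spikememd.stats import (
    compare_rates,
    cv_profile,
    discriminability_spectrum,
    ranksum_p,
    storey_qvalues,
)


def _enumeration_ranksum_p(a, b):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    obs = ranks[:n_a].sum()
    mean = n_a * (len(pooled) + 1) / 2.0
    stats = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n_a)
    ]
    stats = np.array(stats)
    return np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12)


class TestRanksum:
    def test_identical_samples_p_one(self):
        assert ranksum_p([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_most_extreme_small_case(self):
        """{1,2,3} vs {4,5,6}: two-sided p = 2/C(6,3) = 0.1 exactly."""
        assert ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("n_a,n_b,seed", [(3, 4, 0), (5, 5, 1), (8, 6, 2), (4, 8, 3)])
    def test_exact_matches_enumeration(self, n_a, n_b, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n_a)
        b = rng.normal(0.5, size=n_b)
        assert ranksum_p(a, b) == pytest.approx(_enumeration_ranksum_p(a, b), abs=1e-12)

    def test_power_at_two_sd_shift(self):
        """n=15 vs 15 with a 2-SD shift: median p well under 0.01."""
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(500):
            a = rng.normal(0, 1, 15)
            b = rng.normal(2, 1, 15)
            ps.append(ranksum_p(a, b))
        assert np.median(ps) < 0.01

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            ranksum_p([1.0], [2.0, 3.0])


class TestStorey:
    def test_uniform_null_pi0_near_one(self):
        """pi0-hat close to 1 for uniform p-values, across seeds."""
        hits = 0
        for seed in range(100):
            p = np.random.default_rng(seed).uniform(size=1000)
            if 0.85 <= storey_qvalues(p).pi0 <= 1.0:
                hits += 1
        assert hits >= 95

    def test_all_signal_limit(self):
        res = storey_qvalues(np.full(1000, 1e-6))
        assert np.all(res.qvalues <= 1e-6 / (1 - 0.95) + 1e-12)

    def test_never_above_bh_by_more_than_pi0(self):
        """q equals pi0 times the BH-adjusted p, so q <= BH values."""
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.uniform(size=800), rng.beta(0.5, 10, size=200)])
        res = storey_qvalues(p)
        from statsmodels.stats.multitest import multipletests
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(res.qvalues <= bh + 1e-12)
        assert np.allclose(res.qvalues, res.pi0 * bh, atol=1e-12)

    def test_order_preserving(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        res = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(res.qvalues[order]) >= -1e-12)

    def test_small_family_reduces_to_bh(self):
        res = storey_qvalues([0.001, 0.2, 0.8])
        assert res.pi0 == 1.0
        assert res.qvalues[0] == pytest.approx(0.003)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.2])


def _windows(data, dt=0.001, window=(1.0, 0.5, 1.0), isi=None):
    return TrialWindowSet(data=np.asarray(data, float), bin_width=dt, window=window, isi_s=isi)


class TestCVProfile:
    def test_identical_trials_zero_cv(self):
        data = np.tile(np.random.default_rng(0).poisson(5, 2500), (6, 1))[:, :, None]
        prof = cv_profile(_windows(data))
        assert np.allclose(prof.cv, 0.0, atol=1e-12)

    def test_gain_noise_limit(self):
        """High-rate trials scaled by i.i.d. gains: CV -> gain SD."""
        rng = np.random.default_rng(1)
        base = np.full(2500, 5000.0)
        sigma = 0.2
        gains = rng.normal(1.0, sigma, size=200)
        data = (gains[:, None] * base)[:, :, None]
        prof = cv_profile(_windows(data))
        assert np.nanmedian(prof.cv) == pytest.approx(gains.std(ddof=1), rel=0.05)

    def test_common_scaling_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.poisson(4.0, size=(8, 2500, 1)).astype(float)
        p1 = cv_profile(_windows(data))
        p2 = cv_profile(_windows(7.0 * data))
        assert np.allclose(p1.cv, p2.cv, equal_nan=True)

    def test_zero_mean_bins_flagged(self):
        data = np.zeros((4, 2500, 1))
        prof = cv_profile(_windows(data))
        assert np.all(np.isnan(prof.cv))

    def test_restricted_to_stimulation_window(self):
        data = np.random.default_rng(3).poisson(3.0, size=(5, 2500, 1)).astype(float)
        prof = cv_profile(_windows(data))
        assert prof.times[0] >= 0.0
        assert prof.times[-1] < 0.5


class TestCompareRates:
    def _cond(self, rng, n_trials=10, shift=0.0, n=500):
        base = rng.normal(1.0, 0.05, size=(n_trials, n)) + shift
        return _windows(base[:, :, None], dt=0.005, window=(1.0, 0.5, 1.0))

    def test_null_window_p_uniform(self):
        """Identical conditions: window-level p is U(0,1) over replicates."""
        rng = np.random.default_rng(5)
        ps = [
            compare_rates(self._cond(rng), self._cond(rng)).window_p
            for _ in range(200)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_shift_detected(self):
        rng = np.random.default_rng(6)
        rc = compare_rates(self._cond(rng), self._cond(rng, shift=0.3))
        assert rc.window_p < 1e-4
        assert (rc.q < 0.05).mean() > 0.8

    def test_time_axis_passthrough(self):
        rng = np.random.default_rng(7)
        a = self._cond(rng)
        rc = compare_rates(a, self._cond(rng))
        t = a.times()
        expected = t[(t >= 0) & (t < 0.5)]
        assert np.allclose(rc.times, expected)

    def test_axis_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="time axes"):
            compare_rates(self._cond(rng), self._cond(rng, n=400))


class TestDiscriminabilityMap:
    def _ia(self, rng, n_trials=12, n_imfs=3, n_t=100, bump=0.0, imf=1, t_slice=slice(40, 70)):
        ia = rng.gamma(2.0, 1.0, size=(n_trials, n_imfs, n_t))
        if bump:
            ia[:, imf, t_slice] += bump
        return ia

    def test_dimensions(self):
        rng = np.random.default_rng(9)
        m = discriminability_spectrum(self._ia(rng), self._ia(rng))
        assert m.p.shape == (3, 100)
        assert m.q.shape == m.p.shape

    def test_null_discovery_fraction(self):
        rng = np.random.default_rng(10)
        m = discriminability_spectrum(self._ia(rng), self._ia(rng))
        assert m.significant().mean() <= 0.05

    def test_localized_difference_recovered(self):
        rng = np.random.default_rng(11)
        m = discriminability_spectrum(
            self._ia(rng), self._ia(rng, bump=3.0), time_decimate=1
        )
        sig = m.significant()
        assert sig[1, 40:70].mean() > 0.5
        off_target = np.delete(sig, 1, axis=0)
        assert off_target.mean() < 0.05

    def test_imf_count_mismatch_instructive_error(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError, match="jointly"):
            discriminability_spectrum(self._ia(rng), self._ia(rng, n_imfs=4))

    def test_monotone_in_effect_size(self):
        """More injected amplitude difference, never fewer discoveries."""
        counts = []
        for bump in (0.0, 1.0, 2.0, 4.0):
            rng = np.random.default_rng(13)  # same seed: same noise ladder
            m = discriminability_spectrum(self._ia(rng), self._ia(rng, bump=bump))
            counts.append(int(m.significant()[1].sum()))
        assert all(b >= a for a, b in zip(counts, counts[1:]))
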