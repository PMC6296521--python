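"""Generator correctness: thinning exactness, determinism, effect structure."""

import numpy as np
import pytest
from scipy import stats as sps

import spikememd as sm
from spikememd.protocol import GeneratorParams, ProtocolConfig
from spikememd.synthetic import thinning_sample, trial_intensity


class TestThinning:
    def test_constant_rate_counts_are_poisson(self):
        """Thinning a constant intensity reproduces the exact Poisson law."""
        rng = np.random.default_rng(42)
        counts = np.array(
            [
                len(thinning_sample(lambda t: np.full(np.shape(t), 5.0), 2.0, rng, 5.0))
                for _ in range(1000)
            ]
        )
        # goodness of fit against the exact Poisson(10) pmf, tails pooled so
        # every expected cell count is >= 5
        lo, hi = 4, 17
        edges = list(range(lo, hi + 1))
        obs = np.array(
            [np.sum(counts <= lo)]
            + [np.sum(counts == k) for k in range(lo + 1, hi)]
            + [np.sum(counts >= hi)]
        )
        pois = sps.poisson(10.0)
        exp = np.array(
            [pois.cdf(lo)]
            + [pois.pmf(k) for k in range(lo + 1, hi)]
            + [1 - pois.cdf(hi - 1)]
        ) * len(counts)
        chi2 = sps.chisquare(obs, exp)
        assert chi2.pvalue > 0.01

    def test_zero_intensity_empty(self):
        rng = np.random.default_rng(0)
        out = thinning_sample(lambda t: np.zeros(np.shape(t)), 2.0, rng, 1.0)
        assert len(out) == 0

    def test_support_respects_indicator(self):
        """lambda(t) = 20 * 1[t < 1] on [0, 2): no spikes after t = 1."""
        rng = np.random.default_rng(1)
        out = thinning_sample(
            lambda t: 20.0 * (np.asarray(t) < 1.0), 2.0, rng, 20.0
        )
        assert len(out) > 0
        assert out.max() < 1.0

    def test_negative_intensity_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="negative"):
            thinning_sample(lambda t: np.asarray(t) - 10.0, 2.0, rng, 5.0)

    def test_unbounded_intensity_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="bound"):
            thinning_sample(lambda t: np.full(np.shape(t), 10.0), 2.0, rng, 5.0)


class TestGenerateDataset:
    def test_homogeneous_limit(self):
        """All modulation off: homogeneous Poisson at the baseline rate."""
        proto = ProtocolConfig(
            isi_set=(1.0,), n_trials=99, n_electrodes=1, n_animals=1
        )
        params = GeneratorParams(
            baseline_rate=10.0,
            response_gain={1.0: 0.0},
            trial_gain_sd={1.0: 0.0},
            components=(),
            response_offset=0.0,
            onset_transient=(0.15, 0.05, 0.0),
            electrode_gamma_shape=1e9,  # degenerate: electrode rate == baseline
            seed=5,
        )
        ds = sm.generate_dataset(proto, params)
        period = proto.period(1.0)
        counts = ds.spikes.groupby("trial_index").size()
        counts = counts.reindex(range(proto.n_presentations()), fill_value=0)
        # presentation 0 also covers the 1 s lead-in; use presentations >= 1
        mean_expected = 10.0 * period
        obs = counts.iloc[1:].mean()
        se = np.sqrt(mean_expected / (len(counts) - 1))
        assert abs(obs - mean_expected) < 3 * se

    def test_seed_determinism(self, small_protocol):
        a = sm.generate_dataset(small_protocol, GeneratorParams(seed=1))
        b = sm.generate_dataset(small_protocol, GeneratorParams(seed=1))
        assert a.spikes.equals(b.spikes)

    def test_different_seeds_differ(self, small_protocol):
        a = sm.generate_dataset(small_protocol, GeneratorParams(seed=1))
        b = sm.generate_dataset(small_protocol, GeneratorParams(seed=2))
        assert not a.spikes.equals(b.spikes)

    def test_rate_calibration(self):
        """Empirical electrode rate matches the analytic mean of lambda(t)."""
        proto = ProtocolConfig(isi_set=(3.0,), n_trials=99, n_electrodes=1, n_animals=1)
        params = GeneratorParams(
            baseline_rate=20.0,
            trial_gain_sd={3.0: 0.0},
            electrode_gamma_shape=1e9,
            seed=11,
        )
        ds = sm.generate_dataset(proto, params)
        lam, _ = trial_intensity(proto, params, 3.0, 20.0, 1.0, np.zeros(4))
        tgrid = np.linspace(0, proto.period(3.0), 20001)
        analytic_mean = np.trapezoid(lam(tgrid), tgrid) / proto.period(3.0)
        sess = ds.session("A1", 3.0)
        t0, t1 = proto.lead_in, proto.lead_in + proto.n_presentations() * proto.period(3.0)
        n_obs = ((sess["session_time_s"] >= t0) & (sess["session_time_s"] < t1)).sum()
        emp = n_obs / (t1 - t0)
        assert abs(emp - analytic_mean) / analytic_mean < 0.05

    def test_psth_spectrum_peaks_at_grating_frequency(self):
        """Trial-averaged PSTH power during stimulation peaks near 6 Hz."""
        proto = ProtocolConfig(isi_set=(3.0,), n_trials=40, n_electrodes=8, n_animals=1)
        ds = sm.generate_dataset(proto, GeneratorParams(seed=3))
        rate = sm.bin_spikes(ds, 0.001, animal_id="A1", isi_s=3.0)
        win = sm.average_electrodes(
            sm.extract_windows(rate, proto.onsets(3.0), isi_s=3.0)
        )
        t = win.times()
        stim = (t >= 0) & (t < 0.5)
        psth = win.data.mean(axis=0)[stim, 0]
        psth = psth - psth.mean()
        freqs = np.fft.rfftfreq(len(psth), 0.001)
        power = np.abs(np.fft.rfft(psth)) ** 2
        band = (freqs >= 2) & (freqs <= 50)
        peak = freqs[band][np.argmax(power[band])]
        assert 5.0 <= peak <= 7.0

    def test_negative_intensity_configuration_rejected(self):
        proto = ProtocolConfig(isi_set=(1.0,), n_trials=2, n_electrodes=1, n_animals=1)
        params = GeneratorParams(
            components=((6.0, 2.0, True),), response_offset=0.0, seed=0
        )
        with pytest.raises(ValueError, match="negative"):
            sm.generate_dataset(proto, params)

    def test_spike_times_within_trial_bounds(self, small_dataset, small_protocol):
        for isi in small_protocol.isi_set:
            sel = small_dataset.spikes[small_dataset.spikes["isi_s"] == isi]
            assert sel["spike_time_s"].max() <= isi + small_protocol.stim_duration
            assert sel["spike_time_s"].min() >= -small_protocol.lead_in
            assert sel["trial_index"].between(0, small_protocol.n_trials).all()


@pytest.fixture(scope="module")
def default_windows():
    proto = ProtocolConfig(isi_set=(1.0, 3.0, 5.0), n_trials=15,
                           n_electrodes=16, n_animals=1)
    ds = sm.generate_dataset(proto, GeneratorParams(seed=21))
    out = {}
    for isi in proto.isi_set:
        rate = sm.filter_electrodes(sm.bin_spikes(ds, 0.001, "A1", isi), 0.5)
        out[isi] = sm.average_electrodes(
            sm.extract_windows(rate, proto.onsets(isi), isi_s=isi)
        )
    return out


class TestEffectDirections:
    """The generator encodes the qualitative orderings the analysis targets."""

    def test_stimulation_rate_ordering(self, default_windows):
        """Normalized stimulation-window rate: 3 s and 5 s above 1 s."""
        means = {}
        for isi, win in default_windows.items():
            norm = sm.normalize_rate(win)
            t = norm.times()
            stim = (t >= 0) & (t < 0.5)
            means[isi] = norm.data[:, stim, 0].mean()
        assert means[3.0] > means[1.0]
        assert means[5.0] > means[1.0]

    def test_cv_ordering(self, default_windows):
        """Across-trial CV during stimulation: lower for ISIs > 1 s."""
        cvs = {
            isi: np.nanmedian(sm.cv_profile(win).cv)
            for isi, win in default_windows.items()
        }
        assert cvs[3.0] < cvs[1.0]
        assert cvs[5.0] < cvs[1.0]
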