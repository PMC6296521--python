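import numpy as np
import pytest

import spikememd as sm


@pytest.fixture(scope="session")
def small_protocol() -> sm.ProtocolConfig:
    """Reduced protocol for fast end-to-end tests: 2 ISIs, 8 electrodes."""
    return sm.ProtocolConfig(
        isi_set=(1.0, 3.0), n_trials=10, n_electrodes=8, n_animals=1
    )


@pytest.fixture(scope="session")
def small_dataset(small_protocol) -> sm.SpikeDataset:
    return sm.generate_dataset(small_protocol, sm.GeneratorParams(seed=7))


@pytest.fixture(scope="session")
def wgn_filterbank_ratios():
    """Per-decomposition mean IF ratios of successive IMFs on pure WGN.

    20 seeds of a 4-channel white-noise signal; ratios over modes 2-6, the
    range where the dyadic filter-bank behavior of EMD-family decompositions
    is established.
    """
    from spikememd.hht import amplitude_weighted_if, analytic_signal, instantaneous
    from spikememd.namemd import add_wgn_channels, hammersley_directions, memd

    fs = 512.0
    dirs = sm.hammersley_directions(48, 4)
    ratios = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(384, 4))
        res = memd(add_wgn_channels(x, k=0), dirs)
        mf = []
        for m in range(res.n_imfs):
            vals = [
                amplitude_weighted_if(instantaneous(analytic_signal(res.imfs[c, m], fs)))
                for c in range(4)
            ]
            mf.append(np.nanmean(vals))
        mf = np.array(mf)
        r = mf[:-1] / mf[1:]
        ratios.extend(r[1:6])
    return np.asarray(ratios)


@pytest.fixture(scope="session")
def tone_decomposition():
    """NA-MEMD of a univariate 6 Hz tone with 4 WGN channels (shared)."""
    fs = 128.0
    t = np.arange(int(4 * fs)) / fs
    x = np.sin(2 * np.pi * 6 * t)[:, None]
    res = sm.namemd(x, n_dirs=64, k_noise=4, noise_sd=0.3, seed=0)
    return res, x[:, 0], fs
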