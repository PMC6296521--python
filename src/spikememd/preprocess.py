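"""Spike-time preprocessing: binning, electrode filtering, trial windows.

The analysis chain: bin each electrode's spikes at 1 ms resolution, keep only
electrodes whose whole-session mean rate exceeds 0.5 spikes/s, cut windows
from one second before to one second after each stimulus presentation
(discarding the first presentation of every recording), and average across
electrodes to obtain one population-rate channel per trial.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .synthetic import SpikeDataset

log = logging.getLogger(__name__)

__all__ = [
    "PopulationRate",
    "TrialWindowSet",
    "bin_spikes",
    "filter_electrodes",
    "extract_windows",
    "average_electrodes",
    "normalize_rate",
    "rebin_windows",
]


@dataclass
class PopulationRate:
    """Binned spike counts, time-bin x channel, half-open bins [t, t + dt)."""

    counts: np.ndarray  # (n_bins, n_channels)
    bin_width: float
    t0: float = 0.0
    channels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (time, channel)")
        if not self.channels:
            self.channels = list(range(self.counts.shape[1]))

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def times(self) -> np.ndarray:
        return self.t0 + self.bin_width * np.arange(self.n_bins)

    def mean_rates(self) -> np.ndarray:
        """Whole-session mean rate per channel, spikes/s."""
        return self.counts.sum(axis=0) / self.duration


@dataclass
class TrialWindowSet:
    """Stimulus-aligned windows: trial x time-bin x channel.

    ``window`` is (pre, stim, post) in seconds; bin 0 starts at t = -pre and
    stimulus onset falls on the first bin edge at t = 0.
    """

    data: np.ndarray  # (n_trials, n_bins, n_channels)
    bin_width: float
    window: tuple[float, float, float]
    isi_s: float | None = None
    animal_id: object = None
    channels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3:
            raise ValueError("data must be (trial, time, channel)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return -self.window[0] + self.bin_width * np.arange(self.n_bins)

    def onset_index(self) -> int:
        return int(round(self.window[0] / self.bin_width))

    def stim_slice(self) -> slice:
        i0 = self.onset_index()
        return slice(i0, i0 + int(round(self.window[1] / self.bin_width)))

    def rates(self) -> np.ndarray:
        """Counts converted to spikes/s."""
        return self.data / self.bin_width


def bin_spikes(
    dataset: SpikeDataset,
    bin_width: float,
    animal_id=None,
    isi_s: float | None = None,
) -> PopulationRate:
    """Bin one (animal, ISI) session into time x electrode spike counts.

    Half-open bins [t, t + dt): a spike exactly on an edge belongs to the bin
    it opens. The total count equals the number of in-range spikes.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if animal_id is None:
        if len(dataset.animals) != 1:
            raise ValueError("dataset has several animals; pass animal_id")
        animal_id = dataset.animals[0]
    if isi_s is None:
        if len(dataset.isis) != 1:
            raise ValueError("dataset has several ISI conditions; pass isi_s")
        isi_s = dataset.isis[0]

    sess = dataset.session(animal_id, isi_s)
    duration = dataset.protocol.session_duration(float(isi_s)) - dataset.protocol.tail
    n_bins = int(np.ceil(round(duration / bin_width, 9)))
    n_elec = dataset.protocol.n_electrodes
    counts = np.zeros((n_bins, n_elec), dtype=np.int64)
    if len(sess):
        t = sess["session_time_s"].to_numpy()
        e = sess["electrode_id"].to_numpy(dtype=int)
        # epsilon keeps edge spikes in the bin they open despite float division
        idx = np.floor(t / bin_width + 1e-9).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(counts, (idx[ok], e[ok]), 1)
    return PopulationRate(counts=counts, bin_width=bin_width, channels=list(range(n_elec)))


def filter_electrodes(rate: PopulationRate, min_rate: float = 0.5) -> PopulationRate:
    """Keep channels with whole-session mean rate strictly above ``min_rate``.

    Mirrors the analysis rule that only electrodes with activity higher than
    0.5 spikes/s enter the population signal.
    """
    rates = rate.mean_rates()
    keep = rates > min_rate
    if not keep.any():
        raise ValueError(f"no electrode exceeds {min_rate} spikes/s; dead dataset")
    return PopulationRate(
        counts=rate.counts[:, keep],
        bin_width=rate.bin_width,
        t0=rate.t0,
        channels=[c for c, k in zip(rate.channels, keep) if k],
    )


def extract_windows(
    rate: PopulationRate,
    onsets: Sequence[float],
    pre: float = 1.0,
    stim: float = 0.5,
    post: float = 1.0,
    drop_first: bool = True,
    isi_s: float | None = None,
    animal_id=None,
) -> TrialWindowSet:
    """Cut per-trial windows [onset - pre, onset + stim + post) from a session.

    The first stimulus of each recording is excluded. Windows that would
    overrun the recording are skipped with a warning rather than truncated, so
    all retained trials share an identical sample count.
    """
    dt = rate.bin_width
    n_bins = int(round((pre + stim + post) / dt))
    pre_bins = int(round(pre / dt))
    used = list(onsets[1:]) if drop_first else list(onsets)
    slabs = []
    for onset in used:
        i0 = int(round(onset / dt)) - pre_bins
        i1 = i0 + n_bins
        if i0 < 0 or i1 > rate.n_bins:
            warnings.warn(
                f"trial window at onset {onset:.3f}s exceeds the recording; skipped",
                stacklevel=2,
            )
            continue
        slabs.append(rate.counts[i0:i1, :])
    if not slabs:
        raise ValueError("no trial window fits inside the recording")
    return TrialWindowSet(
        data=np.stack(slabs).astype(float),
        bin_width=dt,
        window=(pre, stim, post),
        isi_s=isi_s,
        animal_id=animal_id,
        channels=list(rate.channels),
    )


def average_electrodes(windows: TrialWindowSet) -> TrialWindowSet:
    """Collapse the electrode axis to its mean: one population channel/trial."""
    if windows.data.shape[2] < 1:
        raise ValueError("no electrode channel to average")
    return replace(
        windows,
        data=windows.data.mean(axis=2, keepdims=True),
        channels=["population"],
    )


def rebin_windows(windows: TrialWindowSet, factor: int) -> TrialWindowSet:
    """Coarsen the time axis by summing counts over ``factor`` adjacent bins.

    Used to bound decomposition cost when full 1 ms resolution is not needed;
    trailing bins that do not fill a group are dropped.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return windows
    n = (windows.n_bins // factor) * factor
    data = windows.data[:, :n, :].reshape(windows.n_trials, n // factor, factor, -1).sum(axis=2)
    return replace(windows, data=data, bin_width=windows.bin_width * factor)


def normalize_rate(
    windows: TrialWindowSet,
    baseline: tuple[float, float] | None = None,
    method: str = "baseline",
) -> TrialWindowSet:
    """Normalize each trial against its own pre-stimulus statistics.

    ``baseline`` is (t_a, t_b) relative to onset, default the full
    pre-stimulus second. ``method``:

    - ``"baseline"`` (default): divide by the baseline mean — dimensionless,
      preserves multiplicative gain structure, comparable across animals;
    - ``"zscore"``: subtract the baseline mean and divide by the baseline SD;
    - ``"max"``: divide by the trial's maximum.

    A zero denominator is an error (no activity to scale by).
    """
    pre = windows.window[0]
    if baseline is None:
        baseline = (-pre, 0.0)
    t_a, t_b = baseline
    if t_a < -pre or t_b > 0 or t_b <= t_a:
        raise ValueError("baseline window must lie inside the pre-stimulus period")
    t = windows.times()
    mask = (t >= t_a) & (t < t_b)
    base = windows.data[:, mask, :].mean(axis=1, keepdims=True)
    if method == "baseline":
        if np.any(base == 0):
            raise ValueError("zero baseline mean in at least one trial/channel")
        return replace(windows, data=windows.data / base)
    if method == "zscore":
        sd = windows.data[:, mask, :].std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero baseline SD in at least one trial/channel")
        return replace(windows, data=(windows.data - base) / sd)
    if method == "max":
        peak = windows.data.max(axis=1, keepdims=True)
        if np.any(peak == 0):
            raise ValueError("all-zero trial cannot be max-scaled")
        return replace(windows, data=windows.data / peak)
    raise ValueError(f"unknown normalization method {method!r}")
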