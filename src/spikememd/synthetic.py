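"""Synthetic multi-electrode spike-train generator.

Emulates the statistical structure of population responses to a repeated
grating stimulus under different interstimulus intervals (ISIs): a
stimulus-locked oscillatory drive at the grating temporal frequency plus mid-
and high-frequency components, an ISI-dependent sustained response gain
(3/5 s > 1 s), ISI-dependent trial-to-trial variability (largest at 1 s), a
transient onset peak ~150 ms after stimulus onset, and per-electrode baseline
heterogeneity. Spikes are drawn from an inhomogeneous Poisson process by
Lewis-Shedler thinning, so the generator is exact given the intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .protocol import GeneratorParams, ProtocolConfig

__all__ = ["SpikeDataset", "thinning_sample", "generate_dataset", "trial_intensity"]

_COLUMNS = ["animal_id", "electrode_id", "isi_s", "trial_index", "spike_time_s"]


@dataclass
class SpikeDataset:
    """Spike times organised by animal / electrode / ISI condition / trial.

    ``spikes`` holds one row per spike with ``spike_time_s`` relative to the
    onset of the presentation it belongs to (presentation index 0 is the first
    stimulus of the recording, which preprocessing discards). Session-absolute
    times are reconstructed from the protocol's onset layout.
    """

    spikes: pd.DataFrame
    protocol: ProtocolConfig
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.spikes.columns]
        if missing:
            raise ValueError(f"spike table missing columns: {missing}")
        self.spikes = self.spikes[_COLUMNS].reset_index(drop=True)

    @property
    def animals(self) -> list:
        return sorted(self.spikes["animal_id"].unique().tolist())

    @property
    def isis(self) -> list[float]:
        return sorted(self.spikes["isi_s"].unique().tolist())

    def session(self, animal_id, isi_s: float) -> pd.DataFrame:
        """Spikes of one continuous recording, with session-absolute times."""
        sel = self.spikes[
            (self.spikes["animal_id"] == animal_id) & (self.spikes["isi_s"] == float(isi_s))
        ].copy()
        period = self.protocol.period(float(isi_s))
        sel["session_time_s"] = (
            self.protocol.lead_in + sel["trial_index"] * period + sel["spike_time_s"]
        )
        return sel.sort_values("session_time_s").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.spikes)


def thinning_sample(
    intensity_fn: Callable[[np.ndarray], np.ndarray],
    t_max: float,
    rng: np.random.Generator,
    rate_bound: float,
) -> np.ndarray:
    """Draw one realisation of an inhomogeneous Poisson process on [0, t_max).

    Lewis-Shedler thinning: candidate events from a homogeneous process at
    ``rate_bound`` are kept with probability ``intensity_fn(t) / rate_bound``.
    Exact provided ``intensity_fn`` is bounded by ``rate_bound`` on the
    interval, which is verified at every candidate point.
    """
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    if not np.isfinite(rate_bound) or rate_bound < 0:
        raise ValueError("rate_bound must be finite and >= 0")
    if rate_bound == 0 or t_max == 0:
        return np.empty(0)
    n_cand = rng.poisson(rate_bound * t_max)
    if n_cand == 0:
        return np.empty(0)
    t = np.sort(rng.uniform(0.0, t_max, size=n_cand))
    lam = np.asarray(intensity_fn(t), dtype=float)
    if np.any(lam < 0):
        raise ValueError("intensity is negative; component amplitudes/gain misconfigured")
    if np.any(lam > rate_bound * (1 + 1e-9)):
        raise ValueError("intensity exceeds the stated bound; thinning would be biased")
    keep = rng.uniform(size=n_cand) < lam / rate_bound
    return t[keep]


def trial_intensity(
    protocol: ProtocolConfig,
    params: GeneratorParams,
    isi_s: float,
    base_rate: float,
    trial_gain: float,
    phases: np.ndarray,
    next_trial_gain: float | None = None,
) -> tuple[Callable[[np.ndarray], np.ndarray], float]:
    """Intensity (spikes/s) of one presentation period, time relative to onset.

    The slow per-trial gain state is in place *before* its stimulus: the last
    second of each period (the next presentation's pre-stimulus baseline)
    already carries ``next_trial_gain``, so baseline normalization of a trial
    divides out that trial's own gain. ``next_trial_gain`` defaults to
    ``trial_gain`` (single-trial use).

    Returns the callable and a valid thinning bound. Negative intensity
    anywhere on the period raises ``ValueError`` (amplitude misconfiguration).
    """
    isi_s = float(isi_s)
    g_max = params.max_gain(isi_s)
    stim = protocol.stim_duration
    lat, width, on_amp = params.onset_transient
    comps = params.components
    r0 = params.response_offset
    period = protocol.period(isi_s)
    if next_trial_gain is None:
        next_trial_gain = trial_gain
    # gain-state switch one second before the next onset, never inside the
    # stimulus window
    switch = max(stim, period - 1.0)

    def modulation(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        s = (t >= 0) & (t < stim)
        osc = np.zeros_like(t)
        for (f, a, _locked), phi in zip(comps, phases):
            osc += a * np.cos(2 * math.pi * f * t + phi)
        gain_t = params.gain_profile(isi_s, np.clip(t, 0.0, None))
        out = 1.0 + gain_t * s * (r0 + osc)
        if on_amp != 0 and width > 0:
            out = out + on_amp * np.exp(-0.5 * ((t - lat) / width) ** 2)
        return out

    def lam(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        g = np.where(t < switch, trial_gain, next_trial_gain)
        return base_rate * g * modulation(t)

    # worst case: all components at -amplitude simultaneously, peak gain
    worst = 1.0 + g_max * min(0.0, r0 - params.amplitude_sum)
    if worst < 0:
        raise ValueError(
            "intensity can go negative (gain * (offset - sum amplitudes) < -1); "
            "reduce component amplitudes or raise response_offset"
        )
    g_big = max(trial_gain, next_trial_gain)
    bound = base_rate * g_big * (1.0 + g_max * (r0 + params.amplitude_sum) + abs(on_amp))
    return lam, bound


def _component_phases(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Per-trial phases: 0 for stimulus-locked components, random otherwise."""
    phases = np.zeros(len(params.components))
    for j, (_f, _a, locked) in enumerate(params.components):
        if not locked:
            phases[j] = rng.uniform(0.0, 2 * math.pi)
    return phases


def generate_dataset(protocol: ProtocolConfig, params: GeneratorParams) -> SpikeDataset:
    """Generate a full synthetic dataset (all animals, all ISI conditions).

    All randomness derives from ``params.seed``; identical configuration gives
    a bit-identical spike table. Per-animal electrode baselines are drawn once
    from a Gamma distribution with mean ``baseline_rate`` (shape
    ``electrode_gamma_shape``), so some electrodes can fall under the
    0.5 spikes/s analysis threshold.
    """
    root = np.random.SeedSequence(int(params.seed))
    animal_seqs = root.spawn(protocol.n_animals)
    records: list[tuple] = []

    for a_idx, a_seq in enumerate(animal_seqs):
        animal_id = f"A{a_idx + 1}"
        base_rng = np.random.Generator(np.random.PCG64(a_seq))
        shape = params.electrode_gamma_shape
        base_rates = base_rng.gamma(shape, params.baseline_rate / shape, size=protocol.n_electrodes)
        isi_seqs = a_seq.spawn(len(protocol.isi_set))
        for isi_s, i_seq in zip(protocol.isi_set, isi_seqs):
            rng = np.random.Generator(np.random.PCG64(i_seq))
            sd = params.gain_sd(isi_s)
            period = protocol.period(isi_s)
            n_pres = protocol.n_presentations()
            # one slow gain state per presentation, plus one for the tail of
            # the final period (the state switches 1 s before each onset)
            if sd > 0:
                gains = np.exp(rng.normal(0.0, sd, size=n_pres + 1))
            else:
                gains = np.ones(n_pres + 1)
            for k in range(n_pres):
                phases = _component_phases(params, rng)
                for e_idx in range(protocol.n_electrodes):
                    lam, bound = trial_intensity(
                        protocol,
                        params,
                        isi_s,
                        base_rates[e_idx],
                        float(gains[k]),
                        phases,
                        next_trial_gain=float(gains[k + 1]),
                    )
                    # lead-in before the first onset: spontaneous activity only,
                    # stored as negative times of presentation 0
                    if k == 0 and protocol.lead_in > 0:
                        rate0 = base_rates[e_idx] * float(gains[0])
                        t_pre = thinning_sample(
                            lambda t: np.full(np.shape(t), rate0),
                            protocol.lead_in,
                            rng,
                            rate0,
                        )
                        for t in t_pre - protocol.lead_in:
                            records.append((animal_id, e_idx, isi_s, k, t))
                    t_rel = thinning_sample(lam, period, rng, bound)
                    for t in t_rel:
                        records.append((animal_id, e_idx, isi_s, k, t))

    df = pd.DataFrame.from_records(records, columns=_COLUMNS)
    df["electrode_id"] = df["electrode_id"].astype(int)
    df["trial_index"] = df["trial_index"].astype(int)
    return SpikeDataset(
        spikes=df,
        protocol=protocol,
        provenance={"generator": params.to_dict(), "protocol": protocol.to_dict()},
    )
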