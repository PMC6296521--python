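"""Low-dimensional phase space for ISI discrimination.

Each ISI condition's mean population response is embedded as a trajectory in
three axes: normalized mean firing rate, instantaneous amplitude of the
low-frequency (~6 Hz, grating-band) IMF, and instantaneous amplitude of a
high-frequency (~18 Hz) IMF. After normalizing the axes to a common scale,
the pre-stimulus samples (400 to 200 ms before onset) of all trajectories
define a resting-state centroid (the fixed point); the per-time Euclidean
distance to it, the pairwise distances between trajectories over the
stimulation window, and an average-linkage tree over those distances
summarise how the conditions separate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.cluster.hierarchy import average, to_tree
from scipy.ndimage import uniform_filter1d
from scipy.spatial.distance import squareform

from .preprocess import TrialWindowSet

__all__ = [
    "PhaseSpaceTrajectory",
    "TrajectoryDistance",
    "assemble_trajectory",
    "build_trajectories",
    "normalize_axes",
    "resting_centroid",
    "distance_profiles",
    "select_imf_axes",
]

AXES = ("rate", "low_f_ia", "high_f_ia")
DEFAULT_RANGE = (-0.35, 1.5)  # canonical display/report range, seconds
CENTROID_WINDOW = (-0.4, -0.2)  # resting-state window, seconds before onset


@dataclass
class PhaseSpaceTrajectory:
    """Time-indexed 3-vectors (rate, low-f IA, high-f IA) for one ISI."""

    xyz: np.ndarray  # (n_times, 3)
    times: np.ndarray
    isi_s: float

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.xyz.shape != (len(self.times), 3):
            raise ValueError("xyz must be (n_times, 3)")

    def clip(self, t0: float, t1: float) -> "PhaseSpaceTrajectory":
        """Samples with t0 <= t <= t1 (inclusive ends, 1e-9 tolerance)."""
        m = (self.times >= t0 - 1e-9) & (self.times <= t1 + 1e-9)
        return replace(self, xyz=self.xyz[m], times=self.times[m])


def select_imf_axes(
    imf_freqs: np.ndarray, low_f: float = 6.0, high_f: float = 18.0
) -> tuple[int, int]:
    """Indices of the IMFs nearest (in log frequency) to the two target bands.

    Selection by measured mode frequency rather than ordinal index, because
    the ordinal position of the grating-band mode depends on the dataset.
    A target with no IMF within a factor of 2 is an error.
    """
    freqs = np.asarray(imf_freqs, dtype=float)
    picks = []
    for target in (low_f, high_f):
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.abs(np.log(freqs / target))
        dist = np.where(np.isfinite(dist), dist, np.inf)
        best = int(np.argmin(dist))
        if dist[best] > np.log(2.0):
            raise ValueError(
                f"no IMF within a factor 2 of {target} Hz; "
                f"available mode frequencies: {np.round(freqs, 2)}"
            )
        picks.append(best)
    return picks[0], picks[1]


def build_trajectories(
    norm_windows: dict[float, TrialWindowSet],
    trial_modes: dict[float, np.ndarray],
    imf_freqs: np.ndarray,
    low_f: float = 6.0,
    high_f: float = 18.0,
    smooth_s: float = 0.025,
    ia_smooth_s: float = 0.1,
) -> dict[float, PhaseSpaceTrajectory]:
    """Mean-population 3-axis trajectory per ISI condition.

    ``norm_windows`` maps ISI -> baseline-normalized rate windows and
    ``trial_modes`` maps ISI -> (n_trials, n_imfs, n_times) per-trial IMF
    channels on the same time axis. ``imf_freqs`` are per-IMF
    amplitude-weighted mean frequencies used to pick the two IA axes.

    The IA axes are the instantaneous amplitude of the *trial-averaged* mode:
    averaging the mode across trials first cancels trial-incoherent noise
    (whose amplitude would otherwise bias the axis upward) while the
    stimulus-locked oscillation survives. The rate axis is the trial-mean
    normalized rate, boxcar-smoothed (default 25 ms) because raw 1 ms bins
    are shot-noise dominated; the IA axes are smoothed over ``ia_smooth_s``
    (default 100 ms) since evoked amplitude dynamics are slow compared to the
    residual broadband envelope fluctuation.
    """
    if set(norm_windows) != set(trial_modes):
        raise ValueError("norm_windows and trial_modes must cover the same ISIs")
    low_idx, high_idx = select_imf_axes(imf_freqs, low_f, high_f)
    out: dict[float, PhaseSpaceTrajectory] = {}
    for isi, win in norm_windows.items():
        modes = np.asarray(trial_modes[isi], dtype=float)
        if modes.shape[2] != win.n_bins:
            raise ValueError(f"ISI {isi}: mode time axis does not match the rate windows")
        rate = win.data.mean(axis=2).mean(axis=0)  # mean over electrodes then trials
        out[isi] = assemble_trajectory(
            rate,
            modes[:, low_idx, :].mean(axis=0),
            modes[:, high_idx, :].mean(axis=0),
            times=win.times(),
            bin_width=win.bin_width,
            isi_s=isi,
            smooth_s=smooth_s,
            ia_smooth_s=ia_smooth_s,
        )
    return out


def assemble_trajectory(
    rate: np.ndarray,
    low_mode: np.ndarray,
    high_mode: np.ndarray,
    times: np.ndarray,
    bin_width: float,
    isi_s: float,
    smooth_s: float = 0.025,
    ia_smooth_s: float = 0.1,
) -> PhaseSpaceTrajectory:
    """Trajectory from a mean rate series and the two selected mean modes.

    Takes already-averaged components so callers can pool coherently (across
    trials, and across animals when their modes are stimulus-locked) before
    the amplitude nonlinearity is applied.
    """
    import scipy.signal

    size = max(1, int(round(smooth_s / bin_width)))
    if size > 1:
        rate = uniform_filter1d(np.asarray(rate, float), size=size, mode="nearest")
    ia_size = max(1, int(round(ia_smooth_s / bin_width)))
    cols = [rate]
    for mode in (low_mode, high_mode):
        ia = np.abs(scipy.signal.hilbert(np.asarray(mode, float)))
        if ia_size > 1:
            ia = uniform_filter1d(ia, size=ia_size, mode="nearest")
        cols.append(ia)
    return PhaseSpaceTrajectory(xyz=np.column_stack(cols), times=times, isi_s=isi_s)


def normalize_axes(
    trajs: dict[float, PhaseSpaceTrajectory],
    method: str = "sd",
) -> dict[float, PhaseSpaceTrajectory]:
    """Put the three axes on a common scale (pooled across all ISIs).

    ``method="sd"`` (default) divides each axis by its pooled standard
    deviation; ``method="minmax"`` maps each axis's pooled range onto [0, 1].
    Either way no axis dominates the Euclidean geometry, relative structure
    within an axis is preserved, and the operation is idempotent.
    """
    if not trajs:
        raise ValueError("no trajectories given")
    pooled = np.vstack([t.xyz for t in trajs.values()])
    if method == "sd":
        sd = pooled.std(axis=0)
        if np.any(sd == 0):
            dead = [AXES[i] for i in np.nonzero(sd == 0)[0]]
            raise ValueError(f"zero-variance axis: {dead}")
        return {isi: replace(t, xyz=t.xyz / sd) for isi, t in trajs.items()}
    if method == "minmax":
        lo, hi = pooled.min(axis=0), pooled.max(axis=0)
        if np.any(hi == lo):
            dead = [AXES[i] for i in np.nonzero(hi == lo)[0]]
            raise ValueError(f"zero-variance axis: {dead}")
        return {
            isi: replace(t, xyz=(t.xyz - lo) / (hi - lo)) for isi, t in trajs.items()
        }
    raise ValueError(f"unknown normalization method {method!r}")


def resting_centroid(
    trajs: dict[float, PhaseSpaceTrajectory],
    window: tuple[float, float] = CENTROID_WINDOW,
) -> np.ndarray:
    """Fixed-point estimate: mean over all trajectories' pre-stimulus samples.

    The window (default 400 to 200 ms before onset, inclusive) must contain
    pre-stimulus samples of every trajectory; every ISI contributes equally.
    """
    if window[1] > 0:
        raise ValueError("centroid window must be pre-stimulus")
    chunks = []
    for t in trajs.values():
        c = t.clip(*window)
        if len(c.times) == 0:
            raise ValueError("trajectory lacks samples in the centroid window")
        chunks.append(c.xyz.mean(axis=0))
    return np.mean(chunks, axis=0)


@dataclass
class TrajectoryDistance:
    """Distances to the resting centroid and between-trajectory structure."""

    isis: list[float]
    profiles: dict[float, np.ndarray]  # per-time ||traj - centroid||
    times: np.ndarray
    pairwise: np.ndarray  # (n_isi, n_isi) mean stimulation-window distance
    linkage: np.ndarray  # scipy average-linkage tree

    def stim_rms_distance(self, isi: float, window: tuple[float, float]) -> float:
        """RMS over window samples of the distance-to-centroid profile."""
        m = (self.times >= window[0] - 1e-9) & (self.times < window[1])
        return float(np.sqrt(np.mean(self.profiles[isi][m] ** 2)))

    def first_merge(self) -> tuple[float, float]:
        """The pair of ISIs that merges first in the tree."""
        i, j = int(self.linkage[0, 0]), int(self.linkage[0, 1])
        return tuple(sorted((self.isis[i], self.isis[j])))

    def to_newick(self) -> str:
        """Tree in Newick format with merge-height branch lengths."""
        root = to_tree(self.linkage)

        def fmt(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"isi_{self.isis[node.id]:g}s:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({fmt(root.left, root.dist)},{fmt(root.right, root.dist)});"


def distance_profiles(
    trajs: dict[float, PhaseSpaceTrajectory],
    centroid: np.ndarray,
    stim_window: tuple[float, float] = (0.0, 0.5),
) -> TrajectoryDistance:
    """Distance-to-centroid profiles, pairwise distances and linkage tree.

    The pairwise distance between two ISIs is the L2 distance between their
    trajectories over the stimulation window: the root of the time-averaged
    squared instantaneous Euclidean distance. Unlike a mean of instantaneous
    distances, whose rectified noise floor differs from pair to pair only
    through luck, the noise here enters as one additive variance term common
    to all pairs, so the ranking of pairwise distances reflects the true
    trajectory gaps. The tree uses average linkage.
    """
    isis = sorted(trajs)
    times = trajs[isis[0]].times
    for isi in isis:
        if len(trajs[isi].times) != len(times):
            raise ValueError("trajectories must share one time axis")
    profiles = {
        isi: np.linalg.norm(trajs[isi].xyz - np.asarray(centroid), axis=1) for isi in isis
    }
    m = (times >= stim_window[0] - 1e-9) & (times < stim_window[1])
    n = len(isis)
    pairwise = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            delta = trajs[isis[i]].xyz[m] - trajs[isis[j]].xyz[m]
            d = float(np.sqrt(np.mean(np.sum(delta**2, axis=1))))
            pairwise[i, j] = pairwise[j, i] = d
    link = average(squareform(pairwise, checks=False)) if n > 1 else np.empty((0, 4))
    return TrajectoryDistance(
        isis=isis, profiles=profiles, times=times, pairwise=pairwise, linkage=link
    )
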