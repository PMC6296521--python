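"""Noise-Assisted Multivariate Empirical Mode Decomposition (NA-MEMD).

Multivariate EMD decomposes a d-channel signal into a common set of intrinsic
mode functions (IMFs) by projecting it onto direction vectors drawn from a
low-discrepancy Hammersley sequence mapped to the unit (d-1)-sphere, locating
the extrema of every projection, interpolating d-variate envelopes through the
signal at those extrema, and iteratively subtracting the direction-averaged
mean envelope (sifting) until a two-threshold stopping criterion fires.

Noise assistance appends k white-Gaussian-noise channels to the n data
channels (d = n + k) before decomposition; the WGN drives the sifting to act
as a dyadic filter bank, which reduces mode mixing in intermittent signals.
Noise-channel IMFs are flagged and can be discarded afterwards.

The sifting stop test is the Rilling two-threshold criterion evaluated on the
ratio of the mean-envelope norm to the mean local envelope amplitude, the
criterion standard to the MEMD package lineage this decomposition follows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.special import ndtri

log = logging.getLogger(__name__)

__all__ = [
    "DirectionSet",
    "NoiseAugmentedSignal",
    "SiftConfig",
    "IMFSet",
    "hammersley_directions",
    "add_wgn_channels",
    "multivariate_mean_envelope",
    "sift_imf",
    "memd",
    "namemd",
    "discard_noise_imfs",
]


# ---------------------------------------------------------------------------
# direction vectors
# ---------------------------------------------------------------------------


def _first_primes(m: int) -> list[int]:
    primes: list[int] = []
    cand = 2
    while len(primes) < m:
        if all(cand % p for p in primes):
            primes.append(cand)
        cand += 1
    return primes


def _radical_inverse(base: int, i: int) -> float:
    inv, f = 0.0, 1.0 / base
    while i > 0:
        inv += f * (i % base)
        i //= base
        f /= base
    return inv


@dataclass(frozen=True)
class DirectionSet:
    """Unit direction vectors on the (d-1)-sphere, shape (n_dirs, d)."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("direction vectors must have unit norm")
        object.__setattr__(self, "vectors", v)

    @property
    def n_dirs(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


def hammersley_directions(n_dirs: int, d: int) -> DirectionSet:
    """Deterministic low-discrepancy direction vectors on the (d-1)-sphere.

    Hammersley points in the unit d-cube (first coordinate the centred
    van der Corput ramp, the rest radical inverses in the first d-1 prime
    bases) are pushed through the inverse normal CDF and normalised; since an
    isotropic Gaussian is spherically symmetric this yields a well-spread,
    bit-reproducible point set on the sphere.
    """
    if d < 2:
        raise ValueError("d must be >= 2")
    if n_dirs < 1:
        raise ValueError("n_dirs must be >= 1")
    bases = _first_primes(d - 1)
    u = np.empty((n_dirs, d))
    u[:, 0] = (2 * np.arange(n_dirs) + 1) / (2.0 * n_dirs)
    for j, b in enumerate(bases):
        u[:, j + 1] = [_radical_inverse(b, i + 1) for i in range(n_dirs)]
    z = ndtri(u)
    norms = np.linalg.norm(z, axis=1)
    # a point mapping exactly to the origin (all coords 0.5) has no direction;
    # assign the first axis unit vector
    degenerate = norms < 1e-12
    z[degenerate] = 0.0
    z[degenerate, 0] = 1.0
    norms[degenerate] = 1.0
    v = z / norms[:, None]
    return DirectionSet(vectors=v)


# ---------------------------------------------------------------------------
# noise augmentation
# ---------------------------------------------------------------------------


@dataclass
class NoiseAugmentedSignal:
    """d = n + k channel signal: n data channels then k WGN channels."""

    data: np.ndarray  # (time, d)
    n: int
    k: int
    noise_sd: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != self.n + self.k:
            raise ValueError("data must be (time, n + k)")

    @property
    def d(self) -> int:
        return self.n + self.k

    @property
    def noise_flags(self) -> np.ndarray:
        return np.arange(self.d) >= self.n


def add_wgn_channels(
    x: np.ndarray,
    k: int = 4,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> NoiseAugmentedSignal:
    """Append k i.i.d. white-Gaussian-noise channels to an n-channel signal.

    ``noise_sd`` defaults to the mean per-channel SD of the data (matched
    variance), which keeps the noise channels on the scale of the signal
    without dominating the projections.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    n_t, n = x.shape
    if k < 0:
        raise ValueError("k must be >= 0")
    if noise_sd is None:
        sds = x.std(axis=0)
        noise_sd = float(sds.mean()) if np.any(sds > 0) else 1.0
    if k == 0:
        return NoiseAugmentedSignal(data=x, n=n, k=0, noise_sd=noise_sd, seed=seed)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=(n_t, k))
    return NoiseAugmentedSignal(
        data=np.hstack([x, noise]), n=n, k=k, noise_sd=float(noise_sd), seed=seed
    )


# ---------------------------------------------------------------------------
# sifting machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiftConfig:
    """Sifting stop parameters (Rilling two-threshold test) and caps.

    Sifting stops when the envelope-symmetry ratio is below ``theta1`` on at
    least a fraction ``1 - alpha`` of samples and below ``theta2`` everywhere.
    ``max_iter`` bounds sifting per IMF and ``max_imfs`` bounds the
    decomposition depth on pathological inputs.
    """

    theta1: float = 0.05
    theta2: float = 0.5
    alpha: float = 0.05
    max_iter: int = 500
    max_imfs: int = 30

    def __post_init__(self) -> None:
        if self.theta1 <= 0 or self.theta2 <= 0 or not 0 < self.alpha < 1:
            raise ValueError("thresholds must be positive and 0 < alpha < 1")
        if self.max_iter < 1 or self.max_imfs < 1:
            raise ValueError("iteration caps must be >= 1")


def _local_extrema(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of a 1-D series.

    Plateau samples inherit the sign of the last non-flat difference so flat
    tops count once.
    """
    dp = np.diff(p)
    sign = np.sign(dp)
    zero = sign == 0
    if zero.any():
        # propagate the previous non-zero slope through flats
        idx = np.where(~zero, np.arange(sign.size), -1)
        np.maximum.accumulate(idx, out=idx)
        sign = np.where(idx >= 0, sign[np.clip(idx, 0, None)], 0.0)
    flips = np.diff(sign)
    maxima = np.where(flips < 0)[0] + 1
    minima = np.where(flips > 0)[0] + 1
    return maxima, minima


def _mirror_extend(
    p: np.ndarray, imax: np.ndarray, imin: np.ndarray, nbsym: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mirror-symmetric boundary extension of an extrema sequence.

    Reflects up to ``nbsym`` extrema of each kind about each end before
    envelope interpolation. The reflection point is the outermost extremum
    unless the signal starts (ends) beyond the first (last) opposite-kind
    extremum, in which case the endpoint itself anchors the mirror — the rule
    that keeps envelopes from collapsing or diverging at the edges.

    Returns (positions_max, source_rows_max, positions_min, source_rows_min):
    positions may lie outside [0, n-1]; source rows index the original signal.
    """
    n = len(p)
    # --- left end -------------------------------------------------------
    if imax[0] < imin[0]:
        if p[0] > p[imin[0]]:  # start above the first minimum: mirror on max
            lsym = imax[0]
            lmax = imax[1 : nbsym + 1][::-1]
            lmin = imin[:nbsym][::-1]
        else:  # mirror on the endpoint; endpoint acts as a minimum
            lsym = 0
            lmax = imax[:nbsym][::-1]
            lmin = np.r_[imin[: nbsym - 1][::-1], 0]
    else:
        if p[0] < p[imax[0]]:
            lsym = imin[0]
            lmin = imin[1 : nbsym + 1][::-1]
            lmax = imax[:nbsym][::-1]
        else:
            lsym = 0
            lmin = imin[:nbsym][::-1]
            lmax = np.r_[imax[: nbsym - 1][::-1], 0]
    tlmax = 2 * lsym - lmax
    tlmin = 2 * lsym - lmin
    if (len(tlmax) and tlmax[0] > 0) or (len(tlmin) and tlmin[0] > 0):
        # mirrored points do not reach past the start: anchor at the endpoint
        if imax[0] < imin[0]:
            lmax = imax[:nbsym][::-1]
            lmin = np.r_[imin[: nbsym - 1][::-1], 0]
        else:
            lmin = imin[:nbsym][::-1]
            lmax = np.r_[imax[: nbsym - 1][::-1], 0]
        tlmax = -lmax
        tlmin = -lmin
    # --- right end ------------------------------------------------------
    e = n - 1

    def _endpoint_right():
        if imax[-1] > imin[-1]:  # last extremum is a max: endpoint acts as min
            rmax_ = imax[-nbsym:][::-1]
            rmin_ = np.r_[e, imin[-(nbsym - 1) :][::-1]] if nbsym > 1 else np.array([e])
        else:
            rmin_ = imin[-nbsym:][::-1]
            rmax_ = np.r_[e, imax[-(nbsym - 1) :][::-1]] if nbsym > 1 else np.array([e])
        return rmax_, rmin_, e

    if imax[-1] < imin[-1]:  # last extremum is a minimum
        if p[-1] < p[imax[-1]]:  # ends below the last maximum: mirror on min
            rsym = imin[-1]
            rmax = imax[-nbsym:][::-1]
            rmin = imin[-nbsym - 1 : -1][::-1]
        else:
            rmax, rmin, rsym = _endpoint_right()
    else:  # last extremum is a maximum
        if p[-1] > p[imin[-1]]:  # ends above the last minimum: mirror on max
            rsym = imax[-1]
            rmin = imin[-nbsym:][::-1]
            rmax = imax[-nbsym - 1 : -1][::-1]
        else:
            rmax, rmin, rsym = _endpoint_right()
    trmax = 2 * rsym - rmax
    trmin = 2 * rsym - rmin
    if (len(trmax) and trmax.max() < e) or (len(trmin) and trmin.max() < e):
        # mirrored points do not reach past the end: anchor at the endpoint
        rmax, rmin, rsym = _endpoint_right()
        trmax = 2 * e - rmax
        trmin = 2 * e - rmin

    pos_max = np.r_[tlmax, imax, trmax]
    src_max = np.r_[lmax, imax, rmax]
    pos_min = np.r_[tlmin, imin, trmin]
    src_min = np.r_[lmin, imin, rmin]
    return pos_max, src_max, pos_min, src_min


def _envelope(x: np.ndarray, pos: np.ndarray, src: np.ndarray) -> np.ndarray:
    """Cubic d-variate interpolant through x[src] at positions ``pos``."""
    n_t = x.shape[0]
    order = np.argsort(pos, kind="mergesort")
    tt = pos[order].astype(float)
    yy = x[src[order]]
    keep = np.concatenate([[True], np.diff(tt) > 0])
    tt, yy = tt[keep], yy[keep]
    k = min(3, len(tt) - 1)
    spline = make_interp_spline(tt, yy, k=k)
    return spline(np.arange(n_t))


class MonotonicResidue(Exception):
    """No projection retains enough extrema: the residue is a trend."""


def multivariate_mean_envelope(
    x: np.ndarray, dirs: DirectionSet
) -> tuple[np.ndarray, np.ndarray]:
    """Direction-averaged mean envelope and local amplitude of a (T, d) signal.

    For each direction: project, find the projection's maxima and minima,
    interpolate d-variate max/min envelopes through the signal at those time
    points, and average (max + min) / 2 across directions. Also returns the
    mean envelope amplitude ||max - min|| / 2 used by the stopping criterion.

    Raises ``MonotonicResidue`` when fewer than three maxima or minima exist
    in every projection.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be (time, d)")
    if x.shape[0] < 4:
        raise ValueError("signal too short to envelope")
    proj = x @ dirs.vectors.T  # (T, n_dirs)
    env_sum = np.zeros_like(x)
    amp_sum = np.zeros(x.shape[0])
    n_used = 0
    for j in range(dirs.n_dirs):
        maxima, minima = _local_extrema(proj[:, j])
        if len(maxima) < 3 or len(minima) < 3:
            continue
        pos_max, src_max, pos_min, src_min = _mirror_extend(proj[:, j], maxima, minima)
        env_max = _envelope(x, pos_max, src_max)
        env_min = _envelope(x, pos_min, src_min)
        env_sum += (env_max + env_min) / 2.0
        amp_sum += np.linalg.norm(env_max - env_min, axis=1) / 2.0
        n_used += 1
    if n_used == 0:
        raise MonotonicResidue
    return env_sum / n_used, amp_sum / n_used


def sift_imf(
    x: np.ndarray, dirs: DirectionSet, cfg: SiftConfig = SiftConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Extract one IMF from a (T, d) signal by iterated envelope subtraction.

    Returns ``(imf, residue)`` with ``imf + residue == x`` exactly. If the
    stopping criterion never fires within ``cfg.max_iter`` iterations the
    current candidate is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    h = x.copy()
    for _ in range(cfg.max_iter):
        env_mean, amp = multivariate_mean_envelope(h, dirs)
        with np.errstate(divide="ignore", invalid="ignore"):
            sx = np.linalg.norm(env_mean, axis=1) / amp
        sx = np.where(np.isfinite(sx), sx, 0.0)
        if np.mean(sx > cfg.theta1) <= cfg.alpha and np.all(sx <= cfg.theta2):
            break
        h = h - env_mean
    else:
        warnings.warn("sifting did not converge within max_iter; returning candidate")
    return h, x - h


@dataclass
class IMFSet:
    """Aligned IMFs: array (channel, imf_index, time), index 0 = fastest mode.

    Mode alignment (one common IMF count across channels) holds by
    construction of multivariate sifting. ``noise_flags`` marks the appended
    WGN channels. The decomposition is complete: sum of IMFs plus residue
    reconstructs every channel.
    """

    imfs: np.ndarray  # (n_channels, n_imfs, T)
    residue: np.ndarray  # (n_channels, T)
    noise_flags: np.ndarray  # (n_channels,) bool
    config: SiftConfig = field(default_factory=SiftConfig)

    @property
    def n_channels(self) -> int:
        return self.imfs.shape[0]

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.imfs.shape[2]

    def reconstruct(self) -> np.ndarray:
        """(channel, time) sum of IMFs plus residue."""
        return self.imfs.sum(axis=1) + self.residue

    def data_channels(self) -> "IMFSet":
        return discard_noise_imfs(self)


def _decomposition_done(x: np.ndarray, dirs: DirectionSet) -> bool:
    """True when every projection of the residue has fewer than 3 extrema."""
    proj = x @ dirs.vectors.T
    for j in range(dirs.n_dirs):
        maxima, minima = _local_extrema(proj[:, j])
        if len(maxima) + len(minima) >= 3:
            return False
    return True


def memd(
    signal: NoiseAugmentedSignal,
    dirs: DirectionSet | None = None,
    cfg: SiftConfig = SiftConfig(),
    n_dirs: int = 300,
) -> IMFSet:
    """Full multivariate EMD of a noise-augmented signal.

    Sifts IMFs from successive residues until the residue is monotonic in all
    projections (or ``cfg.max_imfs`` is reached). Every channel receives the
    same number of IMFs; the reconstruction (sum of IMFs + residue) is exact
    up to floating-point rounding.
    """
    if dirs is None:
        dirs = hammersley_directions(n_dirs, signal.d)
    if dirs.d != signal.d:
        raise ValueError(f"direction dimension {dirs.d} != signal dimension {signal.d}")
    x = signal.data.copy()
    modes: list[np.ndarray] = []
    while len(modes) < cfg.max_imfs and not _decomposition_done(x, dirs):
        try:
            imf, residue = sift_imf(x, dirs, cfg)
        except MonotonicResidue:
            break
        modes.append(imf)
        x = residue
    if not modes:
        raise ValueError("input contains no oscillatory mode (monotonic in all projections)")
    imfs = np.stack(modes, axis=0).transpose(2, 0, 1)  # (channel, imf, time)
    return IMFSet(
        imfs=imfs,
        residue=x.T.copy(),
        noise_flags=signal.noise_flags.copy(),
        config=cfg,
    )


def namemd(
    x: np.ndarray,
    n_dirs: int = 300,
    k_noise: int = 4,
    noise_sd: float | None = None,
    seed: int | None = None,
    cfg: SiftConfig = SiftConfig(),
    keep_noise: bool = False,
) -> IMFSet:
    """Noise-assisted MEMD of an n-channel signal (time, n).

    Convenience wrapper: appends ``k_noise`` WGN channels, decomposes with
    ``n_dirs`` Hammersley directions, and (by default) drops the
    noise-channel IMFs from the result.
    """
    aug = add_wgn_channels(x, k=k_noise, noise_sd=noise_sd, seed=seed)
    dirs = hammersley_directions(n_dirs, aug.d)
    result = memd(aug, dirs, cfg)
    return result if keep_noise else discard_noise_imfs(result)


def discard_noise_imfs(imfs: IMFSet) -> IMFSet:
    """Drop the WGN-channel rows; IMF indices and data rows are untouched."""
    keep = ~imfs.noise_flags
    if keep.all():
        return imfs
    return IMFSet(
        imfs=imfs.imfs[keep],
        residue=imfs.residue[keep],
        noise_flags=imfs.noise_flags[keep],
        config=imfs.config,
    )
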