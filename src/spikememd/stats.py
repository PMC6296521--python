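"""Discriminability statistics: rank-sum maps, Storey q-values, CV profiles.

Every condition comparison uses the two-sided Wilcoxon rank-sum (Mann-Whitney)
test across trials; families of p-values are corrected for multiple testing
with Storey's positive-FDR q-values. Two significance tiers are carried
through the maps: q < 0.05 ("significant") and q < 0.1 ("statistically
relevant").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.ndimage import uniform_filter1d

from .preprocess import TrialWindowSet

__all__ = [
    "ranksum_p",
    "StoreyResult",
    "storey_qvalues",
    "DiscriminabilityMap",
    "discriminability_spectrum",
    "VariabilityProfile",
    "cv_profile",
    "RateComparison",
    "compare_rates",
]

SIGNIFICANT = 0.05
RELEVANT = 0.1

_EXACT_MAX_N = 25  # combined sample size up to which the exact null is used
_MIN_M_FOR_PI0 = 12  # below this the pi0 smoother is degenerate; use pi0 = 1


def ranksum_p(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when the combined sample is small (<= 25) and has
    no ties; otherwise the normal approximation with tie correction. Two
    samples with all values identical carry no ordering information: p = 1.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


@dataclass
class StoreyResult:
    pi0: float
    lambdas: np.ndarray
    pvalues: np.ndarray
    qvalues: np.ndarray


def storey_qvalues(p, lambdas: np.ndarray | None = None) -> StoreyResult:
    """Storey q-values with smoothed pi0 estimation.

    pi0(lambda) = #{p_i > lambda} / (m (1 - lambda)) on a lambda grid
    (default 0.05..0.95 step 0.05), smoothed with a cubic fit and evaluated at
    the largest lambda, clipped into (0, 1]. q_i is the usual step-up
    minimum of pi0 * m * p_(j) / j over j >= i, so q is monotone in p. For
    very small families the pi0 smoother has nothing to work with and pi0 is
    fixed at 1 (the Benjamini-Hochberg limit).
    """
    p = np.asarray(p, dtype=float).ravel()
    m = len(p)
    if m < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)

    if m < _MIN_M_FOR_PI0:
        pi0 = 1.0
    else:
        pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
        # precision weights: var of pi0(lambda) grows like 1/(1 - lambda)
        coef = np.polyfit(lambdas, pi0_l, 2, w=np.sqrt(1.0 - lambdas))
        pi0 = float(np.polyval(coef, lambdas.max()))
        pi0 = min(max(pi0, 1.0 / m), 1.0)

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return StoreyResult(pi0=pi0, lambdas=lambdas, pvalues=p, qvalues=q)


@dataclass
class DiscriminabilityMap:
    """IMF x time matrix of raw p and Storey q comparing two ISI conditions."""

    p: np.ndarray  # (n_imfs, n_times)
    q: np.ndarray
    times: np.ndarray
    labels: tuple[str, str]
    pi0: float
    thresholds: tuple[float, float] = (SIGNIFICANT, RELEVANT)

    def significant(self) -> np.ndarray:
        return self.q < self.thresholds[0]

    def relevant(self) -> np.ndarray:
        return self.q < self.thresholds[1]


def discriminability_spectrum(
    ia_a: np.ndarray,
    ia_b: np.ndarray,
    times: np.ndarray | None = None,
    labels: tuple[str, str] = ("A", "B"),
    time_decimate: int = 1,
) -> DiscriminabilityMap:
    """Per-IMF, per-time rank-sum map between two conditions' trial IA.

    ``ia_a`` and ``ia_b`` are (n_trials, n_imfs, n_times) instantaneous
    amplitudes of the per-trial IMF channels. Both conditions must carry the
    same IMF count and time axis (decompose them jointly if counts differ).
    Storey correction is applied jointly across all (IMF, time) cells of the
    map. ``time_decimate`` evaluates every k-th time bin.
    """
    ia_a = np.asarray(ia_a, dtype=float)
    ia_b = np.asarray(ia_b, dtype=float)
    if ia_a.ndim != 3 or ia_b.ndim != 3:
        raise ValueError("IA arrays must be (trial, imf, time)")
    if ia_a.shape[1] != ia_b.shape[1]:
        raise ValueError(
            f"IMF count mismatch ({ia_a.shape[1]} vs {ia_b.shape[1]}); "
            "decompose both conditions jointly to align modes"
        )
    if ia_a.shape[2] != ia_b.shape[2]:
        raise ValueError("conditions must share one time axis")
    n_imfs, n_t = ia_a.shape[1], ia_a.shape[2]
    t_idx = np.arange(0, n_t, time_decimate)
    if times is None:
        times = t_idx.astype(float)
    else:
        times = np.asarray(times)[t_idx]
    p = np.empty((n_imfs, len(t_idx)))
    for m in range(n_imfs):
        for j, t in enumerate(t_idx):
            p[m, j] = ranksum_p(ia_a[:, m, t], ia_b[:, m, t])
    res = storey_qvalues(p.ravel())
    q = res.qvalues.reshape(p.shape)
    return DiscriminabilityMap(p=p, q=q, times=times, labels=labels, pi0=res.pi0)


@dataclass
class VariabilityProfile:
    """Across-trial coefficient of variation per stimulation-window time bin.

    CV = SD / mean of the (boxcar-smoothed) trial rates across presentations;
    NaN where the mean rate is zero.
    """

    cv: np.ndarray
    times: np.ndarray
    smooth_s: float
    isi_s: float | None = None
    animal_id: object = None


def cv_profile(
    windows: TrialWindowSet,
    window: tuple[float, float] | None = None,
    smooth_s: float = 0.025,
) -> VariabilityProfile:
    """CV across trials of the smoothed population rate, per time bin.

    Raw 1 ms Poisson bins are mostly zeros and ones, which makes a raw CV
    degenerate, so trial rates are first smoothed with a boxcar
    (default 25 ms). ``window`` restricts the profile, defaulting to the
    stimulation window.
    """
    if windows.n_trials < 2:
        raise ValueError("CV needs at least 2 trials")
    x = windows.data.mean(axis=2)  # (trials, time); channel-collapsed
    size = max(1, int(round(smooth_s / windows.bin_width)))
    if size > 1:
        x = uniform_filter1d(x, size=size, axis=1, mode="nearest")
    t = windows.times()
    if window is None:
        window = (0.0, windows.window[1])
    mask = (t >= window[0]) & (t < window[1])
    sel = x[:, mask]
    mean = sel.mean(axis=0)
    sd = sel.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return VariabilityProfile(
        cv=cv, times=t[mask], smooth_s=smooth_s, isi_s=windows.isi_s, animal_id=windows.animal_id
    )


@dataclass
class RateComparison:
    """Per-timepoint and window-level rank-sum comparison of two conditions."""

    p: np.ndarray  # per time bin
    q: np.ndarray
    times: np.ndarray
    window_p: float  # single test on per-trial window means (uncorrected)
    labels: tuple[str, str] = ("A", "B")


def compare_rates(
    norm_a: TrialWindowSet,
    norm_b: TrialWindowSet,
    window: tuple[float, float] | None = None,
    labels: tuple[str, str] = ("A", "B"),
    time_decimate: int = 1,
) -> RateComparison:
    """Compare normalized rates of two conditions across trials.

    Rank-sum per time bin within ``window`` (default the stimulation window),
    Storey-corrected across the bins, plus one test on the per-trial window
    means. The output time axis equals the (restricted, decimated) input axis.
    """
    if norm_a.n_bins != norm_b.n_bins:
        raise ValueError(f"time axes differ: {norm_a.n_bins} vs {norm_b.n_bins} bins")
    t = norm_a.times()
    if window is None:
        window = (0.0, norm_a.window[1])
    mask = (t >= window[0]) & (t < window[1])
    a = norm_a.data.mean(axis=2)[:, mask]
    b = norm_b.data.mean(axis=2)[:, mask]
    t_sel = t[mask][::time_decimate]
    a_dec = a[:, ::time_decimate]
    b_dec = b[:, ::time_decimate]
    p = np.array([ranksum_p(a_dec[:, j], b_dec[:, j]) for j in range(a_dec.shape[1])])
    q = storey_qvalues(p).qvalues
    window_p = ranksum_p(a.mean(axis=1), b.mean(axis=1))
    return RateComparison(p=p, q=q, times=t_sel, window_p=window_p, labels=labels)
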