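"""Threshold choice and jump detection on the increment series.

Jumps are detected by thresholding the increments dX = X(t+dt) - X(t): a
maximal run of consecutive above-threshold increments is one detected event
(singlet, doublet, ... for run lengths 1, 2, ...), with amplitude
X(T_off) - X(T_on).  The threshold theta* itself is chosen from the asymmetry
between positive and negative increment statistics: the difference of
truncated means M+(theta) - M-(theta) rises where true jumps dominate, and
theta* is placed at the inflection point left of its maximum.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import GriddedDensity, kde_density
from .simulator import UniformTimeSeries


class ThresholdSelectionError(RuntimeError):
    """No jump asymmetry detected in the increment statistics."""


@dataclass
class ThresholdScan:
    """Truncated-mean curves over a threshold grid, plus the chosen theta*."""

    theta_grid: np.ndarray
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    count_pos: np.ndarray
    count_neg: np.ndarray
    se_diff: np.ndarray  # pooled standard error of the mean difference
    valid: np.ndarray
    theta_star: float | None = None
    max_index: int | None = None
    inflection_index: int | None = None

    @property
    def diff_curve(self) -> np.ndarray:
        return self.mean_pos - self.mean_neg

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "theta": self.theta_grid,
                "mean_pos": self.mean_pos,
                "mean_neg": self.mean_neg,
                "diff": self.diff_curve,
                "count_pos": self.count_pos,
                "count_neg": self.count_neg,
                "valid": self.valid,
            }
        )


@dataclass
class JumpPool:
    """Detected jump events and their empirical statistics Gamma_C, Q_C."""

    onsets: np.ndarray  # sample index at the start of the first above-threshold increment
    offsets: np.ndarray  # sample index at the end of the run
    durations: np.ndarray  # run length in steps
    amplitudes: np.ndarray  # X(T_off) - X(T_on)
    m: int  # number of above-threshold increments
    n_increments: int
    theta_star: float
    dt: float

    @property
    def gamma_C(self) -> float:
        return self.m / self.n_increments

    @property
    def n_events(self) -> int:
        return self.onsets.size

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "onset_time_s": self.onsets * self.dt,
                "offset_time_s": self.offsets * self.dt,
                "duration_steps": self.durations,
                "amplitude": self.amplitudes,
            }
        )


def _truncated_tail_stats(sorted_vals: np.ndarray, thetas: np.ndarray):
    """Mean, count and variance of {v in sorted_vals : v > theta} per theta."""
    csum = np.concatenate(([0.0], np.cumsum(sorted_vals)))
    csum2 = np.concatenate(([0.0], np.cumsum(sorted_vals**2)))
    idx = np.searchsorted(sorted_vals, thetas, side="right")
    counts = sorted_vals.size - idx
    sums = csum[-1] - csum[idx]
    sums2 = csum2[-1] - csum2[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(
            counts > 1,
            (sums2 - counts * means**2) / np.maximum(counts - 1, 1),
            np.nan,
        )
    return means, counts, var


def truncated_mean_curves(
    ts: UniformTimeSeries,
    theta_grid: np.ndarray | None = None,
    n_theta: int = 200,
    min_count: int = 50,
) -> ThresholdScan:
    """Sample means of the threshold-truncated positive and mirrored negative
    increment sets, per grid point.

    The default grid is uniform over the *usable* common range of the two
    sets: it stops where either truncated set would fall below ``min_count``
    members, so that all grid points resolve the statistically meaningful
    part of the curve (rare extreme increments would otherwise stretch the
    grid far past it).  Points below ``min_count`` are flagged invalid.
    """
    dx = ts.increments
    pos = np.sort(dx[dx > 0])
    neg = np.sort(-dx[dx < 0])
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            "increments are one-signed; input is degenerate or non-stationary"
        )
    if theta_grid is None:
        hi_pos = pos[-min(min_count, pos.size)]
        hi_neg = neg[-min(min_count, neg.size)]
        common_max = min(hi_pos, hi_neg, pos[-1], neg[-1])
        theta_grid = np.linspace(0.0, common_max, n_theta + 1)[1:]
    theta_grid = np.asarray(theta_grid, dtype=float)

    mean_pos, count_pos, var_pos = _truncated_tail_stats(pos, theta_grid)
    mean_neg, count_neg, var_neg = _truncated_tail_stats(neg, theta_grid)
    valid = (count_pos >= min_count) & (count_neg >= min_count)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(
            var_pos / np.maximum(count_pos, 1) + var_neg / np.maximum(count_neg, 1)
        )
    return ThresholdScan(
        theta_grid=theta_grid,
        mean_pos=mean_pos,
        mean_neg=mean_neg,
        count_pos=count_pos,
        count_neg=count_neg,
        se_diff=se,
        valid=valid,
    )


def select_threshold(
    scan: ThresholdScan, smooth_window: int = 5, significance: float = 3.0
) -> float:
    """Place theta* at the inflection point of M+ - M- left of its maximum.

    The difference curve is smoothed with a short moving average before
    differencing (the raw numeric second derivative is too noisy).  The
    inflection -- the zero of the second derivative left of the maximum -- is
    located as the steepest-ascent point of the smoothed curve (the maximum
    of its first difference below the argmax), refined by linearly
    interpolating the second-difference sign change around it.

    A curve whose maximum is not significant (below ``significance`` pooled
    standard errors, as on a pure-diffusion trace) or that has no convex
    rise below its maximum raises :class:`ThresholdSelectionError`; the
    caller may fall back to a user-supplied threshold.
    """
    idx = np.flatnonzero(scan.valid)
    if idx.size < max(5, smooth_window + 2):
        raise ThresholdSelectionError("too few valid threshold grid points")
    theta = scan.theta_grid[idx]
    diff = scan.diff_curve[idx]

    kernel = np.ones(smooth_window) / smooth_window
    pad = smooth_window // 2
    padded = np.concatenate((np.repeat(diff[0], pad), diff, np.repeat(diff[-1], pad)))
    smooth = np.convolve(padded, kernel, mode="valid")

    imax = int(np.argmax(smooth))
    if imax == 0:
        raise ThresholdSelectionError(
            "no interior maximum of the truncated-mean difference: "
            "no jump asymmetry detected"
        )
    if smooth[imax] < significance * scan.se_diff[idx][imax]:
        raise ThresholdSelectionError(
            "truncated-mean asymmetry is not statistically significant: "
            "no jump asymmetry detected"
        )
    d1 = np.gradient(smooth, theta)
    # the padded moving average distorts the first few points; exclude them
    # so a monotonically-decaying slope (concave curve) hits the boundary
    lo = pad + 1
    if imax <= lo + 1:
        raise ThresholdSelectionError(
            "maximum too close to the grid edge: no usable convex rise"
        )
    j = lo + int(np.argmax(d1[lo:imax]))
    if j == lo:
        raise ThresholdSelectionError(
            "no second-derivative sign change below the maximum: "
            "no jump asymmetry detected"
        )
    # refine: d2 crosses zero at the d1 maximum; interpolate between neighbors
    d2 = np.gradient(d1, theta)
    theta_star = float(theta[j])
    if j + 1 < d2.size and d2[j] > 0 >= d2[j + 1]:
        w = d2[j] / (d2[j] - d2[j + 1])
        theta_star = float(theta[j] + w * (theta[j + 1] - theta[j]))
    elif j >= 1 and d2[j - 1] > 0 >= d2[j]:
        w = d2[j - 1] / (d2[j - 1] - d2[j])
        theta_star = float(theta[j - 1] + w * (theta[j] - theta[j - 1]))

    scan.theta_star = theta_star
    scan.max_index = int(idx[imax])
    scan.inflection_index = int(idx[j])
    return theta_star


def detect_jumps(ts: UniformTimeSeries, theta_star: float) -> JumpPool:
    """Build the detected jump pool: maximal runs of increments > theta*.

    The offset is registered at the end of the above-threshold run even if
    the following increment is positive (but below threshold).  The per-step
    detection probability Gamma_C is m/(n-1) with m the total number of
    above-threshold increments.
    """
    if theta_star <= 0:
        raise ValueError("theta_star must be > 0")
    dx = ts.increments
    above = dx > theta_star
    edged = np.diff(above.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(edged == 1)
    ends = np.flatnonzero(edged == -1)  # exclusive increment index
    onsets = starts
    offsets = ends  # sample index of the last point of the run
    durations = ends - starts
    amplitudes = ts.values[offsets] - ts.values[onsets]
    return JumpPool(
        onsets=onsets,
        offsets=offsets,
        durations=durations,
        amplitudes=amplitudes,
        m=int(above.sum()),
        n_increments=dx.size,
        theta_star=float(theta_star),
        dt=ts.dt,
    )


def estimate_QC(
    pool: JumpPool,
    amplitude_grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    min_events: int = 30,
) -> GriddedDensity:
    """Kernel density estimate of the detected-jump amplitude distribution Q_C,
    renormalized on the positive amplitude grid."""
    if pool.n_events == 0:
        raise ValueError("cannot estimate Q_C from an empty jump pool")
    if pool.n_events < min_events:
        warnings.warn(
            f"only {pool.n_events} detected events; Q_C unreliable", stacklevel=2
        )
    if amplitude_grid is None:
        amplitude_grid = default_amplitude_grid(pool)
    return kde_density(pool.amplitudes, amplitude_grid, bandwidth=bandwidth)


def default_amplitude_grid(pool: JumpPool, n: int = 512) -> np.ndarray:
    """Uniform grid on (0, 1.2 * max detected amplitude]."""
    hi = 1.2 * float(np.max(pool.amplitudes))
    return np.linspace(0.0, hi, n + 1)[1:]
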