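"""Noise-intensity estimation and drift reconstruction.

D is estimated by realized variance (the sum of squared increments converges
to 2*D*T for additive diffusion) restricted to jump-free, post-transient
segments and to negative increments, which are unaffected by positive jumps;
the estimate is swept over detection thresholds and the minimum taken (the
estimator overshoots at both ends of the sweep).

F is recovered from the stationary differential Chapman-Kolmogorov balance:
integrating the stationary master equation once in y with vanishing flux at
the lower boundary gives

    F(y) = [ D P'(y) - lambda G(y) ] / P(y),
    G(y) = int_{-inf}^{y} [ P(u) - (Q_B * P)(u) ] du,

which reduces, for lambda = 0, to the stationary Fokker-Planck inversion
F(y) = D d/dy ln P(y) used as the initial guess F1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .detection import JumpPool, detect_jumps
from .grids import GriddedDensity, GriddedFunction
from .simulator import UniformTimeSeries


# ---------------------------------------------------------------------------
# noise intensity
# ---------------------------------------------------------------------------


def realized_variance_D(ts: UniformTimeSeries) -> float:
    """Whole-trace quadratic-variation estimator D = RV / (2T).

    Only valid on jump-free input (the caller's responsibility); positive
    jumps inflate the sum of squared increments.
    """
    dx = ts.increments
    return float(np.sum(dx * dx) / (2.0 * ts.duration))


@dataclass
class SegmentSet:
    """Jump-free index ranges between consecutive offsets and onsets."""

    starts: np.ndarray  # sample index of each segment start (a jump offset)
    stops: np.ndarray  # sample index of each segment end (the next onset)

    @property
    def durations_steps(self) -> np.ndarray:
        return self.stops - self.starts


def build_segments(pool: JumpPool, n_samples: int) -> SegmentSet:
    """Segments between T_off(i) and T_on(i+1), including the leading and
    trailing stretches of the trace."""
    starts = np.concatenate(([0], pool.offsets))
    stops = np.concatenate((pool.onsets, [n_samples - 1]))
    keep = stops > starts
    return SegmentSet(starts=starts[keep], stops=stops[keep])


def jump_triggered_average(
    ts: UniformTimeSeries,
    pool: JumpPool,
    top_fraction: float = 0.05,
    window_steps: int | None = None,
    deriv_threshold: float = 0.05,
    deriv_window: int = 500,
    persist: int = 3,
) -> tuple[np.ndarray, float]:
    """Average the post-offset windows of the largest detected jumps and read
    off the post-jump transient duration Phi.

    Phi is the first time the magnitude of the derivative of the average
    (state units per *second*, estimated over ``deriv_window`` steps because
    the averaged trace retains residual spread of order the stationary
    standard deviation over the event count) stays below ``deriv_threshold``
    for ``persist`` consecutive evaluations spaced half a window apart; if it
    never stabilizes, the window length is returned with a warning.
    """
    if pool.n_events < 5:
        raise ValueError("need at least 5 detected jumps for a triggered average")
    k = max(5, int(np.ceil(top_fraction * pool.n_events)))
    order = np.argsort(pool.amplitudes)[::-1][:k]
    offsets = pool.offsets[order]
    if window_steps is None:
        window_steps = min(10_000, ts.n // 10)
    windows = [
        ts.values[o : o + window_steps]
        for o in offsets
        if o + window_steps <= ts.n
    ]
    if not windows:
        raise ValueError("no full post-jump windows available")
    avg = np.mean(np.vstack(windows), axis=0)
    w = min(max(1, deriv_window), max(1, avg.size - 1))
    deriv = np.abs(avg[w:] - avg[:-w]) / (w * ts.dt)
    stride = max(1, w // 2)
    eval_idx = np.arange(0, deriv.size, stride)
    below = deriv[eval_idx] < deriv_threshold
    phi_step = None
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= persist:
            phi_step = int(eval_idx[i - persist + 1])
            break
    if phi_step is None:
        warnings.warn(
            "jump-triggered average never stabilizes; using the full window "
            "as the transient duration",
            stacklevel=2,
        )
        phi_step = window_steps
    return avg, phi_step * ts.dt


def _segment_estimate(
    ts: UniformTimeSeries, theta: float, Phi: float
) -> tuple[float, int]:
    """Duration-weighted segment estimate of D at one threshold, plus the
    number of negative increments it rests on (nan, 0 if none)."""
    pool = detect_jumps(ts, theta)
    segs = build_segments(pool, ts.n)
    phi_steps = int(np.ceil(Phi / ts.dt))
    dx = ts.increments
    d_vals = []
    weights = []
    total_used = 0
    for start, stop in zip(segs.starts, segs.stops):
        if stop - start <= phi_steps:
            continue
        seg_dx = dx[start + phi_steps : stop]
        neg = seg_dx[seg_dx < 0]
        if neg.size == 0:
            continue
        t_minus = neg.size * ts.dt
        d_vals.append(np.sum(neg * neg) / (2.0 * t_minus))
        weights.append((stop - start) * ts.dt)
        total_used += neg.size
    if not d_vals:
        return float("nan"), 0
    d_vals = np.asarray(d_vals)
    weights = np.asarray(weights)
    return float(np.sum(d_vals * weights) / np.sum(weights)), total_used


def segment_noise_intensity(
    ts: UniformTimeSeries, theta: float, Phi: float, min_increments: int = 1
) -> float:
    """Eq.-(22)/(23) style estimator at one threshold: detect jumps at
    ``theta``, form jump-free segments, keep negative increments occurring
    more than ``Phi`` after the segment start, and combine the per-segment
    estimates weighted by segment duration."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    d_hat, total_used = _segment_estimate(ts, theta, Phi)
    if total_used == 0:
        raise ValueError("no valid jump-free segments at this threshold")
    if total_used < min_increments:
        raise ValueError(
            f"only {total_used} post-transient negative increments at this "
            "threshold; estimate would be sampling-noise dominated"
        )
    return d_hat


@dataclass
class NoiseScan:
    """The D(theta) sweep and its minimum."""

    theta_values: np.ndarray
    D_hat_per_theta: np.ndarray
    Phi: float
    D_hat: float
    jump_triggered_average_trace: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"theta": self.theta_values, "D_hat": self.D_hat_per_theta}
        )


def noise_intensity_scan(
    ts: UniformTimeSeries,
    n_theta: int = 30,
    q_low: float = 0.90,
    q_high: float = 0.9999,
    top_fraction: float = 1.0,
    deriv_threshold: float = 0.05,
    min_valid: int = 3,
    min_increments: int = 10_000,
    jta_quantile: float = 0.999,
) -> NoiseScan:
    """Sweep the threshold, estimate D at each value, and take the minimum.

    The transient duration Phi comes from the jump-triggered average of the
    events above the ``jta_quantile`` of positive increments -- the largest
    few per-ten-thousand of increments, i.e. the biggest jumps, which carry
    the most prominent post-jump transient.  Sweep points whose segments
    contribute fewer than ``min_increments`` usable negative increments are
    dropped (their estimates would be dominated by sampling noise, corrupting
    the minimum selection).
    """
    dx = ts.increments
    pos = dx[dx > 0]
    if pos.size < 100:
        raise ValueError("too few positive increments for a threshold sweep")
    # tail fractions log-spaced: true jumps are a per-mille fraction of the
    # positive increments, so a linear quantile grid would put almost no
    # sweep points above the diffusive range
    tails = np.logspace(np.log10(1 - q_low), np.log10(1 - q_high), n_theta)
    thetas = np.unique(np.quantile(pos, 1.0 - tails))

    top_pool = detect_jumps(ts, float(np.quantile(pos, jta_quantile)))
    avg, Phi = jump_triggered_average(
        ts, top_pool, top_fraction=top_fraction, deriv_threshold=deriv_threshold
    )

    # a criterion-based Phi longer than the typical jump-free stretch would
    # starve the estimator: cap it at the median gap between the large events
    # of the triggered-average pool, so a sizeable share of the segments
    # always contributes
    top_segs = build_segments(top_pool, ts.n)
    if top_segs.durations_steps.size:
        cap = float(np.quantile(top_segs.durations_steps, 0.5)) * ts.dt
        Phi = min(Phi, cap)

    rows = [_segment_estimate(ts, float(th), Phi) for th in thetas]
    estimates = np.array([r[0] for r in rows])
    counts = np.array([r[1] for r in rows], dtype=float)
    # sampling-starved points only inject noise into the minimum selection
    keep = np.isfinite(estimates) & (counts >= min_increments)
    if keep.sum() < min_valid:
        raise ValueError(
            f"fewer than {min_valid} valid sweep points in the noise scan"
        )
    d_hats = estimates[keep]
    valid_thetas = thetas[keep]
    # a single noisy sweep point must not capture the minimum: take the
    # minimum of the 3-point median-filtered curve
    if d_hats.size >= 3:
        filt = np.array(
            [np.median(d_hats[max(0, i - 1) : i + 2]) for i in range(d_hats.size)]
        )
    else:
        filt = d_hats
    return NoiseScan(
        theta_values=np.asarray(valid_thetas),
        D_hat_per_theta=d_hats,
        Phi=Phi,
        D_hat=float(np.min(filt)),
        jump_triggered_average_trace=avg,
    )


# ---------------------------------------------------------------------------
# drift
# ---------------------------------------------------------------------------


def drift_from_chapman_kolmogorov(
    P_X: GriddedDensity,
    D_hat: float,
    lambda_hat: float,
    Q_B: GriddedDensity | None,
    floor: float = 1e-6,
) -> GriddedFunction:
    """Drift from the stationary jump-diffusion master-equation balance.

    One integration in y with zero probability flux at the lower boundary:
    F(y) = [D P'(y) - lambda G(y)] / P(y), with G the cumulative excess of
    probability over its jump-displaced image.  With ``lambda_hat`` = 0 this
    is exactly the stationary Fokker-Planck inversion D * d ln P / dy.
    Grid points where P falls below ``floor * max(P)`` are masked out.
    """
    y = P_X.x
    p = P_X.y
    dy = y[1] - y[0]
    dp = np.gradient(p, dy)

    if lambda_hat > 0 and Q_B is not None:
        # (Q_B * P)(u) = int_0^inf Q_B(s) P(u - s) ds on the state grid.
        # Q_B is rebinned mass-conservingly onto the state spacing (pointwise
        # resampling would lose narrow amplitude distributions entirely when
        # their scale is below dy).
        s_max = float(Q_B.x[-1])
        n_k = max(1, int(np.ceil((s_max + 0.5 * dy) / dy)) + 1)
        edges = np.clip(dy * (np.arange(n_k + 1) - 0.5), 0.0, None)
        cdf = np.interp(edges, Q_B.x, Q_B.cdf_values(), left=0.0, right=1.0)
        q_mass = np.diff(cdf)
        total = q_mass.sum()
        if total > 0:
            q_mass = q_mass / total
        conv = np.convolve(p, q_mass)[: p.size]
        G = np.concatenate(
            ([0.0], np.cumsum(0.5 * ((p - conv)[1:] + (p - conv)[:-1]) * dy))
        )
        numer = D_hat * dp - lambda_hat * G
    else:
        numer = D_hat * dp

    mask = p > floor * p.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(mask, numer / np.where(mask, p, 1.0), np.nan)
    valid = np.flatnonzero(mask)
    lo, hi = valid[0], valid[-1] + 1
    yy, ff = y[lo:hi], F[lo:hi]
    good = np.isfinite(ff)
    if not good.all():
        # interior dips below the floor (sparsely occupied stretches):
        # bridge them by interpolation so the drift is defined on the
        # whole occupied interval
        ff = np.interp(yy, yy[good], ff[good])
    return GriddedFunction(yy, ff)


def initial_drift(P_X: GriddedDensity, D_hat: float, floor: float = 1e-6) -> GriddedFunction:
    """Initial drift guess from the stationary Fokker-Planck inversion,
    F1(y) = D * d/dy ln P_X(y); necessarily flatter than the true drift when
    jumps widen P_X."""
    return drift_from_chapman_kolmogorov(P_X, D_hat, 0.0, None, floor=floor)


def local_slope(
    F: GriddedFunction, half_width: float
) -> tuple[float, float, tuple[float, float]]:
    """Linear fit of F around its stable fixed point.

    Returns (fixed_point, slope, 95% CI of the slope).  The stable fixed
    point is the zero crossing of F from positive to negative.
    """
    sign = np.sign(F.y)
    crossings = np.flatnonzero((sign[:-1] > 0) & (sign[1:] <= 0))
    if crossings.size == 0:
        raise ValueError("no stable (+ to -) zero crossing of the drift")
    i = int(crossings[0])
    # linear interpolation of the zero
    x0, x1 = F.x[i], F.x[i + 1]
    y0, y1 = F.y[i], F.y[i + 1]
    fixed_point = float(x0 - y0 * (x1 - x0) / (y1 - y0))

    lo, hi = fixed_point - half_width, fixed_point + half_width
    if lo < F.x[0] or hi > F.x[-1]:
        raise ValueError("half_width exceeds the drift grid")
    sel = (F.x >= lo) & (F.x <= hi) & np.isfinite(F.y)
    if sel.sum() < 3:
        raise ValueError("too few grid points inside the fit window")
    from scipy.stats import linregress, t as t_dist

    res = linregress(F.x[sel], F.y[sel])
    dof = int(sel.sum()) - 2
    half_ci = t_dist.ppf(0.975, dof) * res.stderr if dof > 0 else np.inf
    return fixed_point, float(res.slope), (res.slope - half_ci, res.slope + half_ci)
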