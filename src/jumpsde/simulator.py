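"""Euler-Maruyama simulation of stationary jump-diffusion processes.

The process is

    dY = F(Y) dt + sqrt(2 D) dW + dJ,

with drift F, diffusive noise intensity D (increment variance 2*D*dt per
step), and J a compound Poisson process of rate ``lambda`` whose i.i.d.
amplitudes are positive and drawn from Q_B.  Because the method assumes
``lambda * dt << 1``, jump occurrence per step is Bernoulli(lambda*dt) with at
most one jump per step, applied within the same step as the diffusive
increment (jumps and diffusion summate).

The simulator doubles as the validation workhorse: it records the ground
truth jump log (never consumed by the inference pipeline) and provides the
Monte Carlo oracle for the false-positive detection probability alpha(y).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numba import njit

from .grids import GriddedDensity, GriddedFunction

_CHUNK = 1 << 20


class DriftEvaluationError(RuntimeError):
    """Raised when the drift produces a non-finite value along a trajectory."""


# ---------------------------------------------------------------------------
# jump amplitude distributions
# ---------------------------------------------------------------------------


@dataclass
class LognormalJumps:
    """Parametric lognormal(mu, sigma^2) jump-amplitude family."""

    mu: float
    sigma: float

    def pdf(self, a):
        a = np.asarray(a, dtype=float)
        out = np.zeros_like(a)
        pos = a > 0
        out[pos] = np.exp(-((np.log(a[pos]) - self.mu) ** 2) / (2 * self.sigma**2)) / (
            a[pos] * self.sigma * math.sqrt(2 * math.pi)
        )
        return out

    def cdf(self, a):
        from scipy.stats import lognorm

        return lognorm(s=self.sigma, scale=math.exp(self.mu)).cdf(a)

    def mean(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.lognormal(self.mu, self.sigma, size=n)

    def to_gridded(self, n: int = 2048) -> GriddedDensity:
        hi = math.exp(self.mu + 5 * self.sigma)
        grid = np.linspace(hi / n, hi, n)
        return GriddedDensity(grid, self.pdf(grid)).normalize()


def _validate_jump_dist(dist) -> None:
    if dist is None:
        return
    if isinstance(dist, LognormalJumps):
        return
    if isinstance(dist, GriddedDensity):
        if dist.x[0] < 0 or (dist.x[0] == 0 and dist.y[0] > 0):
            raise ValueError("jump amplitude density must have positive support")
        if abs(dist.integral() - 1.0) > 1e-6:
            raise ValueError("jump amplitude density must integrate to 1 within 1e-6")
        return
    raise TypeError(f"unsupported jump distribution type: {type(dist)!r}")


def draw_jump_amplitudes(dist, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. positive jump amplitudes from ``dist``.

    ``dist`` is either a :class:`LognormalJumps` (direct parametric sampling)
    or a :class:`GriddedDensity` on positive support (inverse-CDF sampling on
    the grid).  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _validate_jump_dist(dist)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return dist.sample(n, rng)


# ---------------------------------------------------------------------------
# model and series containers
# ---------------------------------------------------------------------------


@dataclass
class JumpDiffusionModel:
    """The (F, D, lambda, Q_B, dt) tuple: ground truth for simulation and the
    fit result of the inference pipeline."""

    drift: Callable | GriddedFunction
    noise_intensity: float
    jump_rate: float
    jump_dist: LognormalJumps | GriddedDensity | None
    dt: float

    def __post_init__(self) -> None:
        if self.noise_intensity < 0:
            raise ValueError("noise intensity D must be >= 0")
        if self.jump_rate < 0:
            raise ValueError("jump rate lambda must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        gamma_b = self.jump_rate * self.dt
        if gamma_b >= 1.0:
            raise ValueError("lambda*dt must be < 1 (at most one jump per step)")
        if gamma_b > 0.1:
            warnings.warn(
                f"lambda*dt = {gamma_b:.3g} is not small; the per-step Bernoulli "
                "jump approximation assumes lambda*dt << 1",
                stacklevel=2,
            )
        if self.jump_rate > 0:
            _validate_jump_dist(self.jump_dist)

    @property
    def gamma_B(self) -> float:
        """Per-step true-jump probability lambda*dt."""
        return self.jump_rate * self.dt


@dataclass
class UniformTimeSeries:
    """A uniformly sampled scalar time series with sampling interval dt."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("need a 1-D series with at least two samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total duration T = (n-1)*dt."""
        return (self.n - 1) * self.dt

    @property
    def increments(self) -> np.ndarray:
        return np.diff(self.values)


@dataclass
class SimulatedSeries(UniformTimeSeries):
    """A simulated trace carrying its ground-truth jump log.

    ``jump_steps`` holds the increment index k of each injected jump (the
    jump happens within the step from sample k to sample k+1); the inference
    pipeline never reads these fields.
    """

    jump_steps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    jump_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def jump_times(self) -> np.ndarray:
        return self.jump_steps * self.dt


# ---------------------------------------------------------------------------
# Euler-Maruyama core
# ---------------------------------------------------------------------------


@njit(cache=True)
def _interp_scalar(v, xs, ys):
    if v <= xs[0]:
        return ys[0]
    if v >= xs[-1]:
        return ys[-1]
    j = np.searchsorted(xs, v)
    x0 = xs[j - 1]
    x1 = xs[j]
    w = (v - x0) / (x1 - x0)
    return ys[j - 1] * (1.0 - w) + ys[j] * w


@njit
def _em_chunk_fn(drift, x, out, dt, sig, z, jump_add):
    for i in range(z.size):
        f = drift(x)
        if not np.isfinite(f):
            return i
        x = x + f * dt + sig * z[i] + jump_add[i]
        out[i] = x
    return -1


@njit(cache=True)
def _em_chunk_grid(xs, ys, x, out, dt, sig, z, jump_add):
    for i in range(z.size):
        f = _interp_scalar(x, xs, ys)
        x = x + f * dt + sig * z[i] + jump_add[i]
        out[i] = x
    return -1


def _em_chunk_python(drift, x, out, dt, sig, z, jump_add):
    for i in range(z.size):
        f = drift(x)
        if not np.isfinite(f):
            return i
        x = x + f * dt + sig * z[i] + jump_add[i]
        out[i] = x
    return -1


def _jit_drift(drift):
    """Return an njit-compiled scalar drift, or None if not compilable."""
    cached = getattr(drift, "_jumpsde_jit", None)
    if cached is not None:
        return cached
    try:
        jitted = njit(drift)
        jitted(0.0)  # force compilation / catch unsupported constructs
    except Exception:
        return None
    try:
        drift._jumpsde_jit = jitted
    except (AttributeError, TypeError):
        pass
    return jitted


def simulate(
    model: JumpDiffusionModel,
    n_steps: int,
    x0: float,
    seed: int | np.random.Generator,
) -> SimulatedSeries:
    """Generate a realization of the jump-diffusion process.

    Per step: ``x += F(x)*dt + sqrt(2*D*dt)*z (+ B with prob lambda*dt)``.
    The same ``(model, n_steps, x0, seed)`` gives a bit-identical trace.
    Returns ``n_steps`` samples, the first being ``x0``.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    dt = model.dt
    sig = math.sqrt(2.0 * model.noise_intensity * dt)
    gamma_b = model.gamma_B

    drift = model.drift
    use_grid = isinstance(drift, GriddedFunction)
    jitted = None if use_grid else _jit_drift(drift)

    values = np.empty(n_steps)
    values[0] = x0
    jump_steps: list[np.ndarray] = []
    jump_amps: list[np.ndarray] = []

    x = float(x0)
    pos = 1
    while pos < n_steps:
        m = min(_CHUNK, n_steps - pos)
        z = rng.standard_normal(m)
        jump_add = np.zeros(m)
        if gamma_b > 0:
            mask = rng.random(m) < gamma_b
            k = int(mask.sum())
            if k:
                amps = draw_jump_amplitudes(model.jump_dist, k, rng)
                jump_add[mask] = amps
                jump_steps.append(np.flatnonzero(mask) + (pos - 1))
                jump_amps.append(amps)
        out = values[pos : pos + m]
        if use_grid:
            bad = _em_chunk_grid(drift.x, drift.y, x, out, dt, sig, z, jump_add)
        elif jitted is not None:
            bad = _em_chunk_fn(jitted, x, out, dt, sig, z, jump_add)
        else:
            bad = _em_chunk_python(drift, x, out, dt, sig, z, jump_add)
        if bad >= 0:
            raise DriftEvaluationError(
                f"drift evaluated to a non-finite value at step {pos + bad} "
                f"(state {x!r}); the drift must yield a stationary process"
            )
        x = float(out[-1])
        pos += m

    return SimulatedSeries(
        values=values,
        dt=dt,
        jump_steps=(
            np.concatenate(jump_steps) if jump_steps else np.empty(0, dtype=np.int64)
        ),
        jump_amplitudes=(np.concatenate(jump_amps) if jump_amps else np.empty(0)),
    )


# ---------------------------------------------------------------------------
# Monte Carlo oracle for the FP detection probability
# ---------------------------------------------------------------------------


@dataclass
class MonteCarloAlpha:
    """Monte Carlo estimate of the FP detection probability at one state."""

    probability: float
    standard_error: float
    n_reps: int

    def __float__(self) -> float:
        return self.probability


def monte_carlo_alpha(
    drift,
    D: float,
    y0: float,
    theta: float,
    dt: float,
    n_reps: int = 10_000,
    n_substeps: int = 1000,
    seed=None,
) -> MonteCarloAlpha:
    """Fraction of finely-integrated pure-diffusion paths of duration ``dt``
    whose net displacement exceeds ``theta``.

    This is the independent simulation oracle for the closed-form alpha(y):
    trajectories of Eq.-free pure diffusion are integrated at ``dt/n_substeps``
    and the exceedance fraction is returned with its binomial standard error.
    """
    if n_substeps < 100:
        raise ValueError("n_substeps must be >= 100 for a faithful fine-step oracle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h = dt / n_substeps
    sig = math.sqrt(2.0 * D * h)
    x = np.full(n_reps, float(y0))
    for _ in range(n_substeps):
        x += np.asarray(drift(x), dtype=float) * h + sig * rng.standard_normal(n_reps)
        if not np.all(np.isfinite(x)):
            raise DriftEvaluationError("drift produced non-finite values")
    p = float(np.mean(x - y0 > theta))
    se = math.sqrt(max(p * (1.0 - p), 0.0) / n_reps)
    return MonteCarloAlpha(probability=p, standard_error=se, n_reps=n_reps)
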