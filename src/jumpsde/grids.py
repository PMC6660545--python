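"""Non-parametric function and density containers on uniform grids.

The inference method represents the drift function F and every amplitude or
state density non-parametrically, as values on a finite grid.  These two small
containers are the common currency between modules: :class:`GriddedFunction`
is a piecewise-linear interpolant, :class:`GriddedDensity` adds probability
semantics (non-negativity, normalization, sampling).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GriddedFunction:
    """A real function of state known at grid points, linearly interpolated.

    Evaluation outside the grid clamps to the edge values (flat
    extrapolation), which is the conservative choice for drift functions
    estimated only on the occupied state range.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("grid and values must be 1-D arrays of equal length")
        if self.x.size < 2:
            raise ValueError("need at least two grid points")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("grid must be strictly increasing")

    def __call__(self, q):
        return np.interp(q, self.x, self.y)

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])


@dataclass
class GriddedDensity(GriddedFunction):
    """A probability density on a uniform grid.

    The density is trapezoid-integrable on its grid; :meth:`normalize`
    rescales it to unit mass.  Sampling uses the inverse CDF built from the
    cumulative trapezoid integral.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.y < -1e-12):
            raise ValueError("density values must be non-negative")
        self.y = np.clip(self.y, 0.0, None)

    def integral(self) -> float:
        return float(np.trapezoid(self.y, self.x))

    def normalize(self) -> "GriddedDensity":
        mass = self.integral()
        if mass <= 0.0:
            raise ValueError("cannot normalize a density with zero mass")
        return GriddedDensity(self.x, self.y / mass)

    def cdf_values(self) -> np.ndarray:
        c = np.concatenate(
            ([0.0], np.cumsum(0.5 * (self.y[1:] + self.y[:-1]) * np.diff(self.x)))
        )
        if c[-1] > 0:
            c = c / c[-1]
        return c

    def mean(self) -> float:
        return float(np.trapezoid(self.x * self.y, self.x) / self.integral())

    def variance(self) -> float:
        m = self.mean()
        return float(
            np.trapezoid((self.x - m) ** 2 * self.y, self.x) / self.integral()
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF sampling on the grid (piecewise-linear CDF)."""
        c = self.cdf_values()
        # break zero-mass plateaus with a vanishing monotone ramp so the
        # inversion never interpolates across them
        c = c + np.arange(c.size) * 1e-12
        c /= c[-1]
        u = rng.random(n)
        return np.interp(u, c, self.x)

    def l1_distance(self, other: "GriddedDensity") -> float:
        """Integrated absolute difference on the union of supports."""
        lo = min(self.x[0], other.x[0])
        hi = max(self.x[-1], other.x[-1])
        g = np.linspace(lo, hi, 4096)
        a = np.interp(g, self.x, self.y, left=0.0, right=0.0)
        b = np.interp(g, other.x, other.y, left=0.0, right=0.0)
        return float(np.trapezoid(np.abs(a - b), g))


def kde_density(
    samples: np.ndarray,
    grid: np.ndarray,
    bandwidth: float | None = None,
) -> GriddedDensity:
    """Gaussian kernel density estimate evaluated on ``grid``.

    Uses the FFT-based estimator so that million-sample traces are cheap.
    ``bandwidth`` is in data units; the default is Silverman's rule.  The
    result is renormalized to unit mass on the grid.
    """
    from statsmodels.nonparametric.kde import KDEUnivariate

    samples = np.asarray(samples, dtype=float)
    k = KDEUnivariate(samples)
    k.fit(bw=bandwidth if bandwidth is not None else "silverman", fft=True, gridsize=4096)
    vals = np.interp(grid, k.support, k.density, left=0.0, right=0.0)
    vals = np.clip(vals, 0.0, None)
    return GriddedDensity(np.asarray(grid, dtype=float), vals).normalize()
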