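"""False-positive detection statistics from the short-time propagator.

Large purely diffusive increments cross the detection threshold too; these
false positives (FPs) contaminate the detected jump pool.  Given the drift F,
noise intensity D and the empirical state density P_X, this module computes

* alpha(y): probability that a diffusive increment starting at y exceeds
  theta* within one step -- the upper tail of the Gaussian short-time
  propagator N(F(y)*dt, 2*D*dt);
* Gamma_A = int alpha(y) P_X(y) dy: the per-step FP detection probability;
* the FP amplitude distribution Q_A, by propagating the conditional laws of
  the state through successive above-threshold increments (rho_i, Xi_i, Z_i),
  forming the duration pmf P(tau = i*dt | Y0) and mixing the per-duration
  amplitude laws over the FP onset density P_Y0 ~ P_X * alpha.

All quadratures are trapezoidal on uniform grids.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .grids import GriddedDensity, GriddedFunction, kde_density


class GridCoverageError(RuntimeError):
    """The state grid cannot contain the propagated conditional laws."""


@dataclass
class StateGrid:
    """Uniform grid over the support where the state density is appreciable."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        d = np.diff(self.y)
        if not np.allclose(d, d[0], rtol=1e-8):
            raise ValueError("state grid must be uniform")

    @property
    def spacing(self) -> float:
        return float(self.y[1] - self.y[0])

    @classmethod
    def from_samples(
        cls,
        values: np.ndarray,
        n: int = 512,
        floor: float = 1e-6,
        bandwidth: float | None = None,
    ) -> tuple["StateGrid", GriddedDensity]:
        """Build the grid covering {P_X > floor * max(P_X)} and return it with
        the (renormalized) empirical state density on it."""
        values = np.asarray(values, dtype=float)
        span = values.max() - values.min()
        wide = np.linspace(values.min() - 0.1 * span, values.max() + 0.1 * span, 4096)
        dens = kde_density(values, wide, bandwidth=bandwidth)
        keep = np.flatnonzero(dens.y > floor * dens.y.max())
        lo, hi = wide[keep[0]], wide[keep[-1]]
        grid = cls(np.linspace(lo, hi, n))
        p = np.interp(grid.y, dens.x, dens.y)
        return grid, GriddedDensity(grid.y, p).normalize()


def empirical_state_density(
    values: np.ndarray, grid: StateGrid, bandwidth: float | None = None
) -> GriddedDensity:
    """FFT kernel density estimate of P_X on the state grid, unit mass."""
    return kde_density(values, grid.y, bandwidth=bandwidth)


# ---------------------------------------------------------------------------
# single-step quantities
# ---------------------------------------------------------------------------


def short_time_propagator(F_at_y: float, D: float, dt: float, xi):
    """Gaussian short-time transition density of the diffusive increment:
    mean F(y)*dt, variance 2*D*dt, evaluated at increment value(s) xi."""
    if D <= 0:
        raise ValueError("the method assumes diffusive noise: D must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    var = 2.0 * D * dt
    xi = np.asarray(xi, dtype=float)
    return np.exp(-((xi - F_at_y * dt) ** 2) / (2.0 * var)) / np.sqrt(
        2.0 * np.pi * var
    )


def _alpha_values(F_vals: np.ndarray, D: float, dt: float, theta_star: float):
    """Upper Gaussian tail: Prob(increment > theta* | F(y))."""
    sigma = np.sqrt(2.0 * D * dt)
    return ndtr(-(theta_star - np.asarray(F_vals, dtype=float) * dt) / sigma)


def alpha_of_y(
    F, D: float, dt: float, theta_star: float, grid: StateGrid
) -> GriddedFunction:
    """Conditional FP detection probability alpha(y) on the state grid
    (closed form of the propagator's upper-tail integral)."""
    if D <= 0:
        raise ValueError("the method assumes diffusive noise: D must be > 0")
    F_vals = np.asarray(F(grid.y), dtype=float)
    return GriddedFunction(grid.y, _alpha_values(F_vals, D, dt, theta_star))


def gamma_A(alpha: GriddedFunction, P_X: GriddedDensity) -> float:
    """Unconditional per-step FP detection probability: trapezoidal
    quadrature of alpha(y) * P_X(y)."""
    a = alpha(P_X.x)
    return float(np.clip(np.trapezoid(a * P_X.y, P_X.x), 0.0, 1.0))


def fp_onset_density(alpha: GriddedFunction, P_X: GriddedDensity) -> GriddedDensity:
    """Density of the state at FP onset, P_Y0(y) proportional to P_X(y)*alpha(y)."""
    prod = alpha(P_X.x) * P_X.y
    if not np.any(prod > 0):
        raise ValueError("alpha * P_X is identically zero; no FP onsets possible")
    return GriddedDensity(P_X.x, prod).normalize()


def truncated_increment_pdf(
    F_at_y: float, D: float, dt: float, theta_star: float, xi_grid: np.ndarray
) -> GriddedDensity:
    """The short-time propagator restricted to increments above theta* and
    renormalized; zero below the threshold."""
    xi_grid = np.asarray(xi_grid, dtype=float)
    vals = short_time_propagator(F_at_y, D, dt, xi_grid)
    vals = np.where(xi_grid > theta_star, vals, 0.0)
    mass = np.trapezoid(vals, xi_grid)
    if mass < 1e-300:
        raise ValueError(
            "truncated propagator has vanishing mass (alpha ~ 0 at this state)"
        )
    return GriddedDensity(xi_grid, vals / mass)


# ---------------------------------------------------------------------------
# conditional laws along an FP run
# ---------------------------------------------------------------------------


@dataclass
class ConditionalLaws:
    """rho_i, Z_i (and optionally Xi_i) for one FP starting value y0.

    ``rho`` has shape (i_max, len(y_ext)): rho[i-1] is the law of the state
    after i successive above-threshold increments.  ``Z[i-1]`` = Z_i is the
    probability that the i-th increment is above threshold given the previous
    ones were; Z_1 = alpha(y0).  ``Z`` has length i_max + 1 so the duration
    pmf can be evaluated up to i_max.
    """

    y0: float
    y_ext: np.ndarray
    rho: np.ndarray
    Z: np.ndarray

    def xi_density(self, i: int, xi_grid: np.ndarray, F, D, dt) -> GriddedDensity:
        """Xi_i: law of the i-th increment given the first i-1 were above
        threshold (marginalized over the state reached after i-1 steps)."""
        if i < 1 or i > self.rho.shape[0]:
            raise ValueError("i out of range")
        if i == 1:
            prev = None
        else:
            prev = self.rho[i - 2]
        xi_grid = np.asarray(xi_grid, dtype=float)
        F_vals = np.asarray(F(self.y_ext), dtype=float)
        var = 2.0 * D * dt
        if prev is None:
            f0 = float(np.asarray(F(self.y0), dtype=float))
            vals = np.exp(-((xi_grid - f0 * dt) ** 2) / (2 * var)) / np.sqrt(
                2 * np.pi * var
            )
        else:
            dy = self.y_ext[1] - self.y_ext[0]
            # Xi_i(xi) = int Gauss(xi; F(y)dt, 2Ddt) rho_{i-1}(y) dy
            gauss = np.exp(
                -((xi_grid[:, None] - F_vals[None, :] * dt) ** 2) / (2 * var)
            ) / np.sqrt(2 * np.pi * var)
            vals = gauss @ prev * dy
        return GriddedDensity(xi_grid, np.clip(vals, 0, None)).normalize()


def _extended_grid(grid: StateGrid, i_max_cap: int, D, dt, theta_star):
    """State grid extended upward so i_max successive above-threshold steps
    stay inside it (each conditioned step moves the state up by > theta*)."""
    dy = grid.spacing
    headroom = i_max_cap * (theta_star + 5.0 * np.sqrt(2.0 * D * dt))
    n_extra = int(np.ceil(headroom / dy))
    upper = grid.y[-1] + dy * np.arange(1, n_extra + 1)
    return np.concatenate((grid.y, upper))


def _cell_averaged_truncated_gaussian(
    grid: np.ndarray, mean, sigma: float, lower_cut
) -> np.ndarray:
    """Cell-averaged Gaussian density on a uniform grid, truncated below
    ``lower_cut`` (finite-volume discretization).

    Pointwise evaluation loses ~half a cell of mass at the sharp truncation
    edge; cell averages keep the discrete mass exact, which matters because
    the edge at theta* is a genuine discontinuity of the FP amplitude law.
    ``mean`` and ``lower_cut`` may be scalars or arrays broadcast along a
    second axis (one column per starting state).
    """
    d = grid[1] - grid[0]
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    lower_cut = np.broadcast_to(np.asarray(lower_cut, dtype=float), mean.shape)
    upper = grid[:, None] + 0.5 * d
    lower = np.maximum(grid[:, None] - 0.5 * d, lower_cut[None, :])
    hi = ndtr((upper - mean[None, :]) / sigma)
    lo = ndtr((lower - mean[None, :]) / sigma)
    cells = np.clip(hi - lo, 0.0, None) / d
    cells[upper <= lower_cut[None, :]] = 0.0
    return cells


def _truncated_transition_matrix(y_ext, F_vals, D, dt, theta_star):
    """M[j, k]: density of reaching y_j from y_k in one step conditioned on
    the increment exceeding theta*; each column integrates to one."""
    sigma = np.sqrt(2.0 * D * dt)
    M = _cell_averaged_truncated_gaussian(
        y_ext, y_ext + F_vals * dt, sigma, y_ext + theta_star
    )
    dy = y_ext[1] - y_ext[0]
    col_mass = M.sum(axis=0) * dy
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(col_mass[None, :] > 0, M / col_mass[None, :], 0.0)
    return M


def propagate_conditional_laws(
    F,
    D: float,
    dt: float,
    theta_star: float,
    y0: float,
    i_max: int,
    grid: StateGrid,
    mass_tol: float = 1e-3,
    _matrix_cache: dict | None = None,
) -> ConditionalLaws:
    """Propagate rho_1 .. rho_{i_max} and Z_1 .. Z_{i_max+1} from y0.

    rho_1 is the threshold-truncated propagator started at y0 (the law of the
    state after one above-threshold increment); subsequent rho_i apply the
    truncated one-step kernel.  Z_i is evaluated as the alpha-weighted mass of
    rho_{i-1}, which equals the upper-tail integral of Xi_i.
    """
    if i_max < 1:
        raise ValueError("i_max must be >= 1")
    if _matrix_cache is not None and "y_ext" in _matrix_cache:
        y_ext = _matrix_cache["y_ext"]
        F_vals = _matrix_cache["F_vals"]
        alpha_ext = _matrix_cache["alpha_ext"]
        M = _matrix_cache["M"]
    else:
        y_ext = _extended_grid(grid, i_max, D, dt, theta_star)
        F_vals = np.asarray(F(y_ext), dtype=float)
        alpha_ext = _alpha_values(F_vals, D, dt, theta_star)
        M = _truncated_transition_matrix(y_ext, F_vals, D, dt, theta_star)
        if _matrix_cache is not None:
            _matrix_cache.update(
                y_ext=y_ext, F_vals=F_vals, alpha_ext=alpha_ext, M=M
            )
    dy = y_ext[1] - y_ext[0]

    f0 = float(np.asarray(F(y0), dtype=float))
    sigma = np.sqrt(2.0 * D * dt)
    rho1 = _cell_averaged_truncated_gaussian(
        y_ext, y0 + f0 * dt, sigma, y0 + theta_star
    )[:, 0]
    mass = np.trapezoid(rho1, y_ext)
    if mass < 1e-300:
        raise ValueError("alpha ~ 0 at y0; no conditional law to propagate")
    rho1 /= mass

    rho = np.empty((i_max, y_ext.size))
    rho[0] = rho1
    Z = np.empty(i_max + 1)
    Z[0] = float(_alpha_values(np.array([f0]), D, dt, theta_star)[0])
    for i in range(1, i_max + 1):
        # Z_{i+1} = int alpha(y) rho_i(y) dy  (upper tail of Xi_{i+1})
        Z[i] = float(np.trapezoid(alpha_ext * rho[i - 1], y_ext))
        if i < i_max:
            nxt = M @ rho[i - 1] * dy
            m = np.trapezoid(nxt, y_ext)
            if m <= 0 or abs(m - 1.0) > mass_tol:
                raise GridCoverageError(
                    f"conditional-law mass leakage {abs(m - 1.0):.2e} at step "
                    f"{i + 1}; use a finer or wider state grid"
                )
            rho[i] = nxt / m
    return ConditionalLaws(y0=float(y0), y_ext=y_ext, rho=rho, Z=Z)


def duration_pmf(Z: np.ndarray) -> tuple[np.ndarray, float]:
    """FP duration pmf P(tau = i*dt | y0) = (1 - Z_{i+1}) prod_{n<=i} Z_n,
    for i = 1 .. len(Z)-1, plus the truncated tail mass.

    The pmf sums (with its tail) to Z_1 = alpha(y0): conditioned on the onset
    state, an FP of *some* duration occurs iff the first increment is above
    threshold.
    """
    Z = np.asarray(Z, dtype=float)
    cum = np.cumprod(Z[:-1])
    pmf = cum * (1.0 - Z[1:])
    tail = float(np.prod(Z))
    return pmf, tail


# ---------------------------------------------------------------------------
# the FP amplitude distribution
# ---------------------------------------------------------------------------


@dataclass
class FPStatistics:
    """All FP-related quantities for one (F, D, theta*) configuration."""

    grid: StateGrid
    alpha: GriddedFunction
    gamma_A: float
    P_Y0: GriddedDensity
    y0_grid: np.ndarray
    Z_table: np.ndarray  # shape (n_y0, i_max + 1)
    tau_pmf: np.ndarray  # shape (n_y0, i_max)
    tau_tail: np.ndarray  # shape (n_y0,)
    Q_components: list[GriddedDensity]
    component_masses: np.ndarray
    Q_A: GriddedDensity
    i_max: int
    raw_mass: float  # mass of sum_i Q_i before the final renormalization

    def to_dict(self) -> dict:
        return {
            "gamma_A": self.gamma_A,
            "i_max": self.i_max,
            "raw_mass": self.raw_mass,
            "component_masses": self.component_masses.tolist(),
            "normalization": "Q_A renormalized once; the duration mixture has "
            "total weight alpha(y0), not 1",
        }


def fp_amplitude_distribution(
    F,
    D: float,
    dt: float,
    theta_star: float,
    P_X: GriddedDensity,
    amplitude_grid: np.ndarray,
    i_max: int | None = None,
    n_y0: int = 64,
    i_max_cap: int = 10,
    tail_tol: float = 1e-3,
) -> FPStatistics:
    """Compute Q_A (and every conditional intermediate) by quadrature.

    For each onset state y0 on a coarsened sub-grid, the conditional laws are
    propagated to i_max above-threshold steps; the per-duration amplitude law
    is rho_i shifted to amplitude coordinates (a = y - y0), weighted by the
    duration pmf and averaged over the FP onset density P_Y0.  i_max is
    adaptive: the smallest i whose worst-case duration-pmf tail is below
    ``tail_tol`` relative to alpha(y0), capped at ``i_max_cap``.
    """
    grid = StateGrid(P_X.x)
    alpha = alpha_of_y(F, D, dt, theta_star, grid)
    g_A = gamma_A(alpha, P_X)
    P_Y0 = fp_onset_density(alpha, P_X)

    # coarse y0 sub-grid over the bulk of the onset density
    keep = np.flatnonzero(P_Y0.y > 1e-6 * P_Y0.y.max())
    y0_lo, y0_hi = P_Y0.x[keep[0]], P_Y0.x[keep[-1]]
    y0_grid = np.linspace(y0_lo, y0_hi, n_y0)
    p_y0 = np.interp(y0_grid, P_Y0.x, P_Y0.y)

    adaptively = i_max is None
    cur_i_max = 3 if adaptively else i_max
    # pre-build the shared truncated transition kernel with headroom for the
    # i_max cap, so the adaptive loop can deepen without re-gridding
    y_ext = _extended_grid(grid, max(cur_i_max, i_max_cap), D, dt, theta_star)
    F_vals = np.asarray(F(y_ext), dtype=float)
    cache: dict = {
        "y_ext": y_ext,
        "F_vals": F_vals,
        "alpha_ext": _alpha_values(F_vals, D, dt, theta_star),
        "M": _truncated_transition_matrix(y_ext, F_vals, D, dt, theta_star),
    }
    while True:
        laws = [
            propagate_conditional_laws(
                F, D, dt, theta_star, y0, cur_i_max, grid, _matrix_cache=cache
            )
            for y0 in y0_grid
        ]
        pmfs, tails = zip(*(duration_pmf(l.Z) for l in laws))
        rel_tail = max(
            t / max(l.Z[0], 1e-300) for t, l in zip(tails, laws)
        )
        if not adaptively or rel_tail < tail_tol or cur_i_max >= i_max_cap:
            if adaptively and rel_tail >= tail_tol:
                import warnings

                warnings.warn(
                    f"duration-pmf tail {rel_tail:.2e} above tolerance at the "
                    f"i_max cap {i_max_cap}",
                    stacklevel=2,
                )
            break
        cur_i_max += 1

    amplitude_grid = np.asarray(amplitude_grid, dtype=float)
    tau_pmf = np.vstack(pmfs)
    tau_tail = np.asarray(tails)
    Z_table = np.vstack([l.Z for l in laws])

    components = []
    sigma = np.sqrt(2.0 * D * dt)
    for i in range(1, cur_i_max + 1):
        # integrand over y0: rho_i(a + y0 | y0) * P(tau=i dt|y0) * P_Y0(y0)
        if i == 1:
            # singlet amplitude law in closed form (the state-grid detour
            # would smear the sharp edge at theta* over one state cell)
            f0 = np.asarray(F(y0_grid), dtype=float)
            dens = _cell_averaged_truncated_gaussian(
                amplitude_grid, f0 * dt, sigma, theta_star
            )
            norm_mass = ndtr(-(theta_star - f0 * dt) / sigma)
            vals = (dens / norm_mass[None, :]).T * (tau_pmf[:, 0] * p_y0)[:, None]
        else:
            vals = np.zeros((y0_grid.size, amplitude_grid.size))
            for k, law in enumerate(laws):
                shifted = np.interp(
                    amplitude_grid + y0_grid[k],
                    law.y_ext,
                    law.rho[i - 1],
                    left=0,
                    right=0,
                )
                vals[k] = shifted * tau_pmf[k, i - 1] * p_y0[k]
        components.append(np.trapezoid(vals, y0_grid, axis=0))

    comp_masses = np.array(
        [np.trapezoid(c, amplitude_grid) for c in components]
    )
    total = np.sum(components, axis=0)
    raw_mass = float(np.trapezoid(total, amplitude_grid))
    if raw_mass <= 0:
        raise ValueError("Q_A has zero mass; check theta* and the state grid")
    Q_A = GriddedDensity(amplitude_grid, total / raw_mass)
    Q_components = [
        GriddedDensity(amplitude_grid, c / raw_mass) for c in components
    ]

    return FPStatistics(
        grid=grid,
        alpha=alpha,
        gamma_A=g_A,
        P_Y0=P_Y0,
        y0_grid=y0_grid,
        Z_table=Z_table,
        tau_pmf=tau_pmf,
        tau_tail=tau_tail,
        Q_components=Q_components,
        component_masses=comp_masses / raw_mass,
        Q_A=Q_A,
        i_max=cur_i_max,
        raw_mass=raw_mass,
    )
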