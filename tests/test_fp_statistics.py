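import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import jumpsde as j
from jumpsde import presets
from jumpsde.fp_statistics import (
    StateGrid,
    _alpha_values,
    alpha_of_y,
    duration_pmf,
    fp_amplitude_distribution,
    fp_onset_density,
    gamma_A,
    propagate_conditional_laws,
    short_time_propagator,
    truncated_increment_pdf,
)

D, DT, THETA = 0.15, 0.01, 0.1


def flat(y):
    return 0.0 * y


def make_grid(lo=-3.0, hi=3.0, n=801):
    return StateGrid(np.linspace(lo, hi, n))


# ---------------------------------------------------------------------------
# propagator and alpha
# ---------------------------------------------------------------------------


def test_propagator_peak_and_shift():
    assert short_time_propagator(0.0, D, DT, 0.0) == pytest.approx(
        1.0 / np.sqrt(4 * np.pi * D * DT)
    )
    xi = np.linspace(-0.2, 0.2, 2001)
    vals = short_time_propagator(3.0, D, DT, xi)
    assert xi[np.argmax(vals)] == pytest.approx(3.0 * DT, abs=1e-3)


def test_propagator_requires_diffusion():
    with pytest.raises(ValueError):
        short_time_propagator(0.0, 0.0, DT, 0.0)


def test_alpha_trivial_limits():
    grid = make_grid()
    a_inf = alpha_of_y(flat, D, DT, 1e6, grid)
    assert np.all(a_inf.y == pytest.approx(0.0, abs=1e-300))
    a_zero = alpha_of_y(flat, D, DT, 0.0, grid)
    np.testing.assert_allclose(a_zero.y, 0.5, atol=1e-12)


def test_alpha_closed_form_equals_quadrature():
    grid = make_grid()
    a = alpha_of_y(presets.cubic_drift, D, DT, THETA, grid)
    for y in grid.y[[100, 300, 500, 700]]:  # grid nodes: no interpolation
        f = float(presets.cubic_drift(y))
        numeric, _ = quad(
            lambda xi: short_time_propagator(f, D, DT, xi),
            THETA, THETA + 2.0, epsabs=1e-12,
        )
        assert float(a(y)) == pytest.approx(numeric, abs=1e-8)


def test_gamma_A_constant_alpha_is_identity():
    grid = make_grid()
    P = j.GriddedDensity(grid.y, np.exp(-(grid.y**2))).normalize()
    alpha = j.GriddedFunction(grid.y, np.full(grid.y.size, 0.3))
    assert gamma_A(alpha, P) == pytest.approx(0.3, abs=1e-9)


def test_gamma_A_indicator_above_median_is_half():
    grid = make_grid()
    P = j.GriddedDensity(grid.y, np.exp(-(grid.y**2))).normalize()
    alpha = j.GriddedFunction(grid.y, (grid.y > 0).astype(float))
    assert gamma_A(alpha, P) == pytest.approx(0.5, abs=5e-3)


def test_onset_density_closed_forms():
    grid = StateGrid(np.linspace(0.0, 1.0, 501))
    P_uniform = j.GriddedDensity(grid.y, np.ones(grid.y.size)).normalize()
    alpha_lin = j.GriddedFunction(grid.y, grid.y)
    p = fp_onset_density(alpha_lin, P_uniform)
    np.testing.assert_allclose(p.y, 2 * grid.y, atol=5e-3)

    alpha_const = j.GriddedFunction(grid.y, np.full(grid.y.size, 0.2))
    P_tri = j.GriddedDensity(grid.y, 1.0 - np.abs(grid.y - 0.5)).normalize()
    p2 = fp_onset_density(alpha_const, P_tri)
    np.testing.assert_allclose(p2.y, P_tri.y, atol=1e-9)


def test_truncated_increment_pdf_properties():
    xi = np.linspace(-0.5, 0.8, 4001)
    d = truncated_increment_pdf(0.0, D, DT, THETA, xi)
    assert d.integral() == pytest.approx(1.0, abs=1e-6)
    assert np.all(d.y[xi <= THETA - 1e-3] == 0.0)
    assert d.mean() > THETA  # upper-truncated Gaussian sits above its cut


# ---------------------------------------------------------------------------
# conditional laws along an FP run
# ---------------------------------------------------------------------------


def test_rho_without_truncation_is_gaussian_sum():
    """With the threshold far below the increment range, conditioning is
    void and rho_i is the i-step Gaussian: variance i * 2 D dt."""
    grid = StateGrid(np.linspace(-2.0, 2.0, 2001))
    laws = propagate_conditional_laws(flat, D, DT, -10.0, 0.0, 3, grid)
    for i in range(3):
        rho = laws.rho[i]
        mass = np.trapezoid(rho, laws.y_ext)
        mean = np.trapezoid(laws.y_ext * rho, laws.y_ext) / mass
        var = np.trapezoid((laws.y_ext - mean) ** 2 * rho, laws.y_ext) / mass
        assert mass == pytest.approx(1.0, abs=1e-6)
        assert var == pytest.approx((i + 1) * 2 * D * DT, rel=1e-3)
        assert laws.Z[i] == pytest.approx(1.0, abs=1e-9)


def _rejection_sampled_Z(F, y0, i_max, n0=400_000, seed=17):
    """Monte Carlo oracle: propagate one-step Gaussian increments and keep
    the paths whose increments all exceed the threshold."""
    rng = np.random.default_rng(seed)
    sig = np.sqrt(2 * D * DT)
    y = np.full(n0, float(y0))
    Z = []
    for _ in range(i_max):
        xi = np.asarray(F(y)) * DT + sig * rng.standard_normal(y.size)
        keep = xi > THETA
        Z.append((keep.sum(), y.size))
        y = (y + xi)[keep]
        if y.size < 200:
            break
    return Z


def test_Z_matches_rejection_sampling_oracle():
    grid = StateGrid(np.linspace(-3.5, 3.0, 1601))
    y0 = -0.6
    laws = propagate_conditional_laws(presets.cubic_drift, D, DT, THETA, y0, 3, grid)
    oracle = _rejection_sampled_Z(presets.cubic_drift, y0, 3)
    for i, (k, n) in enumerate(oracle):
        p = k / n
        se = np.sqrt(max(p * (1 - p), 1e-12) / n)
        assert abs(laws.Z[i] - p) < 3 * se + 1e-4


def test_duration_pmf_degenerate_and_telescoping():
    pmf, tail = duration_pmf(np.array([0.3, 0.0, 0.0]))
    assert pmf[0] == pytest.approx(0.3)
    assert np.all(pmf[1:] == 0.0) and tail == 0.0


@settings(deadline=None, max_examples=50)
@given(
    st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=2, max_size=12)
)
def test_duration_pmf_telescopes_to_Z1(zs):
    """sum_i P(tau = i dt) + tail = Z_1 = alpha(y0), an algebraic identity."""
    Z = np.asarray(zs)
    pmf, tail = duration_pmf(Z)
    assert pmf.sum() + tail == pytest.approx(Z[0], abs=1e-12)


# ---------------------------------------------------------------------------
# the full FP amplitude distribution
# ---------------------------------------------------------------------------


def test_qa_imax1_reduces_to_truncated_propagator():
    """With a single duration term and flat drift, Q_A is exactly the
    upper-truncated one-step Gaussian; compare CDFs against the closed
    form."""
    from scipy.stats import norm

    grid_y = np.linspace(-1.0, 1.0, 801)
    P = j.GriddedDensity(grid_y, np.exp(-(grid_y**2) * 3)).normalize()
    amp = np.linspace(1e-4, 0.6, 3000)
    fp = fp_amplitude_distribution(flat, D, DT, THETA, P, amp, i_max=1)
    sig = np.sqrt(2 * D * DT)
    analytic = np.clip(norm.cdf(amp / sig) - norm.cdf(THETA / sig), 0, None) / norm.sf(
        THETA / sig
    )
    assert np.abs(fp.Q_A.cdf_values() - analytic).max() < 0.01
    assert fp.i_max == 1


def test_fp_statistics_normalizations(purediff_trace):
    grid, P_X = StateGrid.from_samples(purediff_trace.values, n=768)
    amp = np.linspace(1e-3, 0.8, 800)
    fp = fp_amplitude_distribution(presets.cubic_drift, D, DT, THETA, P_X, amp)
    assert fp.Q_A.integral() == pytest.approx(1.0, abs=1e-6)
    assert np.all(fp.Q_A.y >= 0)
    assert 0 <= fp.gamma_A <= 1
    assert fp.P_Y0.integral() == pytest.approx(1.0, abs=1e-6)
    assert np.all((fp.alpha.y >= 0) & (fp.alpha.y <= 1))
    # component masses are the duration mix and decrease with run length
    assert fp.component_masses.sum() == pytest.approx(1.0, abs=1e-6)
    assert np.all(np.diff(fp.component_masses) < 0)
    # pure-diffusion runs are singlets, doublets or triplets only
    assert fp.i_max <= 4


def test_qa_matches_empirical_fp_amplitudes(purediff_trace):
    """On a jump-free trace every detected event is an FP, so the calculated
    Q_A must reproduce the pooled amplitude distribution (KS < 0.02)."""
    pool = j.detect_jumps(purediff_trace, THETA)
    grid, P_X = StateGrid.from_samples(purediff_trace.values, n=1024)
    amp = np.linspace(1e-3, 1.2 * pool.amplitudes.max(), 1024)
    fp = fp_amplitude_distribution(presets.cubic_drift, D, DT, THETA, P_X, amp)
    cdf = fp.Q_A.cdf_values()
    emp = np.sort(pool.amplitudes)
    theory = np.interp(emp, fp.Q_A.x, cdf)
    ecdf = np.arange(1, emp.size + 1) / emp.size
    assert np.abs(ecdf - theory).max() < 0.02


def test_state_grid_requires_uniform_spacing():
    with pytest.raises(ValueError):
        StateGrid(np.array([0.0, 0.1, 0.3]))
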