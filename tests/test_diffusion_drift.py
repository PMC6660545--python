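import numpy as np
import pytest

import jumpsde as j
from jumpsde import presets
from jumpsde.diffusion_drift import (
    build_segments,
    drift_from_chapman_kolmogorov,
    initial_drift,
    jump_triggered_average,
    local_slope,
    noise_intensity_scan,
    realized_variance_D,
    segment_noise_intensity,
)
from jumpsde.fp_statistics import StateGrid

from conftest import series_from_increments


# ---------------------------------------------------------------------------
# realized variance
# ---------------------------------------------------------------------------


def test_rv_constant_trace_is_zero():
    ts = j.UniformTimeSeries(np.full(100, 2.5), dt=0.01)
    assert realized_variance_D(ts) == 0.0


def test_rv_equal_increments_closed_form():
    c = 0.03
    ts = series_from_increments(np.full(999, c), dt=0.01)
    assert realized_variance_D(ts) == pytest.approx(c**2 / (2 * 0.01))


def test_rv_on_ou_trace_is_accurate(ou_trace):
    """The quadratic-variation estimator on a pure diffusion: the error sits
    at its statistical floor sqrt(2/n) plus the O(k dt) discretization term,
    well below half a percent at n = 1e6."""
    d = realized_variance_D(ou_trace)
    assert abs(d - 0.15) / 0.15 < 5e-3


def test_rv_shift_invariant_and_quadratic_scaling(ou_trace):
    sub = j.UniformTimeSeries(ou_trace.values[:50_000], dt=0.01)
    base = realized_variance_D(sub)
    shifted = j.UniformTimeSeries(sub.values + 7.0, dt=0.01)
    scaled = j.UniformTimeSeries(3.0 * sub.values, dt=0.01)
    assert realized_variance_D(shifted) == pytest.approx(base, rel=1e-12)
    assert realized_variance_D(scaled) == pytest.approx(9 * base, rel=1e-12)


# ---------------------------------------------------------------------------
# jump-triggered average and Phi
# ---------------------------------------------------------------------------


def _planted_decay_trace(A=2.0, tau_c=0.5, dt=0.01, n_jumps=10, gap=4000):
    values = np.zeros(n_jumps * gap + 6000)
    t = np.arange(6000) * dt
    decay = A * np.exp(-t / tau_c)
    for k in range(n_jumps):
        start = k * gap + 100
        values[start + 1 : start + 1 + decay.size] = decay
        values[start + 1 + decay.size :] = 0.0  # reset tail; next jump re-plants
    # rebuild cleanly: zero baseline with planted decays
    values = np.zeros(n_jumps * gap + 6000)
    for k in range(n_jumps):
        start = k * gap + 100
        seg = decay[: min(decay.size, values.size - start - 1)]
        values[start + 1 : start + 1 + seg.size] = seg
    return j.UniformTimeSeries(values, dt=dt)


def test_phi_from_planted_exponential_decay():
    """Deterministic exponential transients after each jump: the windowed
    derivative of the triggered average crosses the 0.05/s criterion at a
    time computable in closed form."""
    A, tau_c, dt = 2.0, 0.5, 0.01
    ts = _planted_decay_trace(A=A, tau_c=tau_c, dt=dt)
    pool = j.detect_jumps(ts, 1.0)
    assert pool.n_events == 10
    w = 500
    avg, Phi = jump_triggered_average(ts, pool, deriv_window=w)
    # windowed derivative |x(t) - x(t+w dt)| / (w dt) for x = A exp(-t/tau):
    # crossing when A exp(-t/tau)(1 - exp(-w dt/tau)) = 0.05 * w * dt
    t_cross = tau_c * np.log(A * (1 - np.exp(-w * dt / tau_c)) / (0.05 * w * dt))
    stride = (w // 2) * dt
    expected = np.ceil(t_cross / stride) * stride  # first evaluation past the crossing
    assert Phi == pytest.approx(expected, abs=stride / 2)


def test_phi_zero_for_flat_post_jump_traces():
    values = np.zeros(50_000)
    for k in range(10):
        values[k * 5000 + 100 :] += 1.0  # pure steps, flat afterwards
    ts = j.UniformTimeSeries(values, dt=0.01)
    pool = j.detect_jumps(ts, 0.5)
    _, Phi = jump_triggered_average(ts, pool)
    assert Phi == 0.0


def test_jta_requires_events():
    ts = j.UniformTimeSeries(np.zeros(1000), dt=0.01)
    pool = j.detect_jumps(ts, 0.5)
    with pytest.raises(ValueError):
        jump_triggered_average(ts, pool)


# ---------------------------------------------------------------------------
# segment estimator
# ---------------------------------------------------------------------------


def test_alternating_increments_closed_form():
    c = 0.04
    inc = np.tile([c, -c], 2000)
    ts = series_from_increments(inc, dt=0.01)
    d = segment_noise_intensity(ts, theta=2 * c, Phi=0.0)
    assert d == pytest.approx(c**2 / (2 * 0.01))


def test_segment_estimator_unbiased_on_pure_diffusion(ou_trace):
    """With the threshold above every increment there is one segment and the
    estimator reduces to the negative-increment realized variance, unbiased
    because E[xi^2 | xi < 0] = 2 D dt for centered Gaussian increments."""
    sub = j.UniformTimeSeries(ou_trace.values[:500_000], dt=0.01)
    theta = float(sub.increments.max()) + 1.0
    d = segment_noise_intensity(sub, theta, Phi=0.0)
    assert abs(d - 0.15) / 0.15 < 0.01


def test_segments_exclude_detected_runs():
    rng = np.random.default_rng(2)
    ts = j.UniformTimeSeries(np.cumsum(rng.normal(0, 0.05, 20_000)), dt=0.01)
    pool = j.detect_jumps(ts, 0.12)
    segs = build_segments(pool, ts.n)
    assert np.all(segs.stops > segs.starts)
    for on, off in zip(pool.onsets, pool.offsets):
        inside = (segs.starts < off) & (segs.stops > on)
        # a segment never spans a detected run
        assert not np.any((segs.starts < on) & (segs.stops > off))


def test_noise_scan_recovers_case1_D(case1_fit):
    assert abs(case1_fit.D_hat - 0.13) / 0.13 < 0.03


def test_noise_scan_matches_rv_without_jumps(purediff_trace):
    scan = noise_intensity_scan(purediff_trace)
    rv = realized_variance_D(purediff_trace)
    assert abs(scan.D_hat - rv) / rv < 0.02


# ---------------------------------------------------------------------------
# drift estimation
# ---------------------------------------------------------------------------


def test_initial_drift_gaussian_density_is_linear():
    y = np.linspace(-2, 2, 1001)
    sigma2 = 0.4
    P = j.GriddedDensity(y, np.exp(-(y**2) / (2 * sigma2))).normalize()
    F1 = initial_drift(P, D_hat=0.2)
    expected = -0.2 * F1.x / sigma2
    interior = slice(20, -20)
    np.testing.assert_allclose(F1.y[interior], expected[interior], atol=5e-3)


def test_initial_drift_recovers_ou_slope(ou_trace):
    from statsmodels.nonparametric.bandwidths import bw_silverman

    bw = float(bw_silverman(ou_trace.values)) * ou_trace.n ** (2 / 35)
    grid, P_X = StateGrid.from_samples(ou_trace.values, n=512, bandwidth=bw)
    F1 = initial_drift(P_X, D_hat=0.15)
    fp, slope, ci = local_slope(F1, half_width=0.5)
    assert abs(fp) < 0.1
    assert abs(slope - (-0.2)) / 0.2 < 0.05


def test_ck_drift_reduces_to_initial_drift_without_jumps():
    y = np.linspace(-2, 2, 801)
    P = j.GriddedDensity(y, np.exp(-(y**2))).normalize()
    a = initial_drift(P, 0.1)
    b = drift_from_chapman_kolmogorov(P, 0.1, 0.0, None)
    np.testing.assert_array_equal(a.y, b.y)


def test_ck_drift_point_mass_jump_limit():
    """Q_B concentrated at vanishing amplitude displaces nothing: the jump
    correction G vanishes and the pure-diffusion inversion is recovered."""
    y = np.linspace(-2, 2, 801)
    P = j.GriddedDensity(y, np.exp(-(y**2))).normalize()
    s = np.linspace(1e-6, 2e-3, 50)
    qb = j.GriddedDensity(s, np.exp(-((s - 1e-3) ** 2) / (2 * 2e-4**2))).normalize()
    a = initial_drift(P, 0.1)
    b = drift_from_chapman_kolmogorov(P, 0.1, 0.5, qb)
    np.testing.assert_allclose(a.y, b.y, atol=5e-3)


def test_ck_drift_recovers_cubic_from_jumpy_density(case1_trace):
    """Feeding the stationary balance the true (D, lambda, Q_B) and the
    empirical density of a jump-diffusion trace returns the cubic drift on
    the occupied range."""
    from statsmodels.nonparametric.bandwidths import bw_silverman

    bw = float(bw_silverman(case1_trace.values)) * case1_trace.n ** (2 / 35)
    grid, P_X = StateGrid.from_samples(case1_trace.values, n=1024, bandwidth=bw)
    qb = j.LognormalJumps(-1.2, 0.2).to_gridded()
    F = drift_from_chapman_kolmogorov(P_X, 0.13, 0.1, qb)
    truth = presets.cubic_drift(F.x)
    occupied = np.interp(F.x, P_X.x, P_X.y) > 1e-3 * P_X.y.max()
    sup = np.max(np.abs(F.y[occupied] - truth[occupied]))
    rng_f = truth[occupied].max() - truth[occupied].min()
    assert sup / rng_f < 0.15


def test_local_slope_linear_exact():
    y = np.linspace(-1, 1, 201)
    F = j.GriddedFunction(y, -0.7 * (y - 0.1))
    fp, slope, (lo, hi) = local_slope(F, half_width=0.3)
    assert fp == pytest.approx(0.1, abs=1e-9)
    assert slope == pytest.approx(-0.7, abs=1e-9)
    assert lo <= slope <= hi


def test_local_slope_cubic_matches_symbolic_derivative():
    y = np.linspace(-2.5, 1.5, 2001)
    F = j.GriddedFunction(y, presets.cubic_drift(y))
    fp, slope, _ = local_slope(F, half_width=0.05)
    # dF/dy = -(0.6 (y-0.5)^2 + 0.2 (y-0.7)) at the stable zero
    expected = -(0.6 * (fp - 0.5) ** 2 + 0.2 * (fp - 0.7))
    assert slope == pytest.approx(expected, rel=5e-3)


def test_local_slope_window_exceeding_grid_errors():
    y = np.linspace(-1, 1, 101)
    F = j.GriddedFunction(y, -y)
    with pytest.raises(ValueError):
        local_slope(F, half_width=5.0)


def test_local_slope_requires_stable_zero():
    y = np.linspace(-1, 1, 101)
    F = j.GriddedFunction(y, y + 2.0)  # no + to - crossing
    with pytest.raises(ValueError):
        local_slope(F, half_width=0.2)
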