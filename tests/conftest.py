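"""Shared fixtures: simulated validation traces and full pipeline fits.

Heavy objects (million-step traces and their fits) are session-scoped so the
parameter-recovery, drift, amplitude and diagnostics tests all share one
computation.
"""
from __future__ import annotations

import warnings

import numpy as np
import pytest

import jumpsde as j
from jumpsde import presets


@pytest.fixture(scope="session")
def x0() -> float:
    return presets.default_x0()


@pytest.fixture(scope="session")
def ou_model() -> j.JumpDiffusionModel:
    return j.JumpDiffusionModel(
        drift=lambda y: -0.2 * y,
        noise_intensity=0.15,
        jump_rate=0.0,
        jump_dist=None,
        dt=0.01,
    )


@pytest.fixture(scope="session")
def ou_trace(ou_model) -> j.SimulatedSeries:
    return j.simulate(ou_model, 1_000_000, 0.0, seed=4)


@pytest.fixture(scope="session")
def case1_trace(x0) -> j.SimulatedSeries:
    return j.simulate(presets.case1(), 1_000_000, x0, seed=1)


@pytest.fixture(scope="session")
def case2_trace(x0) -> j.SimulatedSeries:
    return j.simulate(presets.case2(), 1_000_000, x0, seed=2)


@pytest.fixture(scope="session")
def purediff_trace(x0) -> j.SimulatedSeries:
    return j.simulate(presets.pure_diffusion(), 1_000_000, x0, seed=3)


@pytest.fixture(scope="session")
def case1_fit(case1_trace) -> j.FitResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return j.fit(case1_trace)


@pytest.fixture(scope="session")
def case2_fit(case2_trace) -> j.FitResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return j.fit(case2_trace)


def series_from_increments(increments, dt: float = 0.01) -> j.UniformTimeSeries:
    """A series whose np.diff equals the given increments exactly."""
    values = np.concatenate(([0.0], np.cumsum(increments)))
    return j.UniformTimeSeries(values=values, dt=dt)
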