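"""Validation-case presets: cubic drift with additive noise and lognormal jumps.

All three presets share the drift

    F(y) = -( a (y - 0.5)^3 + 0.5 a (y - 0.7)^2 + 0.1 ),  a = 0.2,

a mostly-decreasing nonlinearity with a single stable fixed point near
y = -0.6, sampled at dt = 0.01 s.  Case 1 pairs a low jump rate and small
amplitudes with strong diffusive noise; Case 2 pairs a doubled rate and much
larger amplitudes with weak noise; the pure-diffusion preset has no jumps and
is used to validate the false-positive calculus at theta* = 0.1.
"""
from __future__ import annotations

import numpy as np

from .simulator import JumpDiffusionModel, LognormalJumps

DT = 0.01
DRIFT_A = 0.2

#: thresholds the increment-asymmetry rule lands on for each case
THETA_STAR = {"case1": 0.125, "case2": 0.07, "purediff": 0.1}

#: default trace length for validation runs (the total duration is then 1e4 s)
N_STEPS = 1_000_000


def cubic_drift(y):
    return -(0.2 * (y - 0.5) ** 3 + 0.1 * (y - 0.7) ** 2 + 0.1)


def case1() -> JumpDiffusionModel:
    """Sparse, small jumps in strong noise: lambda=0.1/s, D=0.13,
    lognormal(-1.2, 0.2^2) amplitudes (mean ~0.31)."""
    return JumpDiffusionModel(
        drift=cubic_drift,
        noise_intensity=0.13,
        jump_rate=0.1,
        jump_dist=LognormalJumps(mu=-1.2, sigma=0.2),
        dt=DT,
    )


def case2() -> JumpDiffusionModel:
    """Frequent, large jumps in weak noise: lambda=0.2/s, D=0.05,
    lognormal(1, 0.5^2) amplitudes (mean ~3.1)."""
    return JumpDiffusionModel(
        drift=cubic_drift,
        noise_intensity=0.05,
        jump_rate=0.2,
        jump_dist=LognormalJumps(mu=1.0, sigma=0.5),
        dt=DT,
    )


def pure_diffusion() -> JumpDiffusionModel:
    """No jumps, D=0.15; every detected event is a false positive."""
    return JumpDiffusionModel(
        drift=cubic_drift,
        noise_intensity=0.15,
        jump_rate=0.0,
        jump_dist=None,
        dt=DT,
    )


PRESETS = {"case1": case1, "case2": case2, "purediff": pure_diffusion}


def drift_fixed_point() -> float:
    """Stable zero of the preset drift (numerical root)."""
    from scipy.optimize import brentq

    return float(brentq(cubic_drift, -2.0, 0.0))


def default_x0() -> float:
    return drift_fixed_point()
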