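"""Long-trace validation utilities.

The false-positive calculus is validated by comparing the calculated per-step
FP detection probability Gamma_A with the measured threshold-crossing rate
Gamma_C on a jump-free simulation.  Both quantities carry sampling floors of
order sqrt(alpha/n), so the comparison needs traces far longer than fit-scale
ones; this module streams the simulation in chunks so the trace never has to
be held in memory.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fp_statistics import _alpha_values
from .simulator import JumpDiffusionModel, simulate


@dataclass
class ThresholdCrossingComparison:
    """Measured vs calculated per-step detection probability on one trace."""

    gamma_C: float
    gamma_A: float
    m: int
    n_increments: int

    @property
    def relative_difference_pct(self) -> float:
        return 100.0 * abs(self.gamma_A - self.gamma_C) / self.gamma_C


def threshold_crossing_comparison(
    model: JumpDiffusionModel,
    theta: float,
    n_steps: int,
    x0: float,
    seed,
    chunk: int = 5_000_000,
) -> ThresholdCrossingComparison:
    """Stream a pure-diffusion simulation and accumulate Gamma_C = m/n and
    Gamma_A = mean of alpha(X_t) over the trace.

    The empirical mean of alpha over the samples is the exact quadrature of
    the Gamma_A integral against the empirical state distribution; no density
    estimate enters.  Requires a jump-free model (the comparison is an FP
    statement).
    """
    if model.jump_rate != 0:
        raise ValueError("the Gamma_A/Gamma_C comparison requires lambda = 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = 0
    n_inc = 0
    alpha_sum = 0.0
    n_alpha = 0
    x = float(x0)
    remaining = n_steps
    first = True
    while remaining > 0:
        size = min(chunk, remaining if first else remaining + 1)
        s = simulate(model, max(size, 2), x, rng)
        dx = s.increments
        m += int(np.count_nonzero(dx > theta))
        n_inc += dx.size
        F_vals = np.asarray(model.drift(s.values[:-1]), dtype=float)
        alpha_sum += float(
            _alpha_values(F_vals, model.noise_intensity, model.dt, theta).sum()
        )
        n_alpha += s.n - 1
        x = float(s.values[-1])
        remaining -= s.n if first else s.n - 1
        first = False
    return ThresholdCrossingComparison(
        gamma_C=m / n_inc,
        gamma_A=alpha_sum / n_alpha,
        m=m,
        n_increments=n_inc,
    )
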