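"""Leaky integrate-and-fire blink generator with an oscillating threshold.

The generator's potential V integrates a binomially arriving input and
leaks with rate c,

    dV/dt = -c V + I + xi,      xi ~ N(0, sigma^2),

where I delivers amplitude ``b`` with probability ``p_input`` at each
time step.  A blink is elicited the moment V reaches the sinusoidal
threshold

    theta(t) = a + k sin(2 pi t / tau),

after which V resets to ``v0``.  The oscillating threshold stands for
slow physiological fluctuations of the blink generator's excitability;
it is what lets this model produce bimodal and trimodal inter-blink
interval distributions that a constant threshold cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import lif_first_passage_steps
from .clock import SimulationClock
from .sample import IBISample


@dataclass(frozen=True)
class LIFParams:
    """Parameters of the variable-threshold LIF blink generator.

    Parameters
    ----------
    c : float
        Leak (decay) rate, 1/s, >= 0.
    b : float
        Input amplitude (potential per second, default 1).
    p_input : float
        Per-step probability of an input event (default 0.5, the
        binomial input convention under which reaching a unit threshold
        with b*dt = 0.001 takes 2000 steps on average).
    sigma : float
        Standard deviation of the Gaussian noise term (default 0).
    a : float
        Threshold baseline (default 1).
    k : float
        Threshold oscillation amplitude (>= 0).
    tau : float
        Threshold oscillation period, s (> 0).
    v0 : float
        Initial and post-blink reset potential (default 0).
    sqrt_dt_noise : bool
        If True (default) the noise enters with diffusion scaling
        sigma*sqrt(dt)*N(0,1) per step; if False, with literal Euler
        scaling sigma*dt*N(0,1).
    """

    c: float
    b: float = 1.0
    p_input: float = 0.5
    sigma: float = 0.0
    a: float = 1.0
    k: float = 0.0
    tau: float = 1.0
    v0: float = 0.0
    sqrt_dt_noise: bool = True

    def __post_init__(self) -> None:
        for name in ("c", "b", "p_input", "sigma", "a", "k", "tau", "v0"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not 0.0 <= self.p_input <= 1.0:
            raise ValueError(f"p_input must lie in [0, 1], got {self.p_input}")
        if self.a - self.k <= self.v0:
            raise ValueError(
                "threshold trough a - k must stay above the reset level v0 "
                f"(a - k = {self.a - self.k}, v0 = {self.v0})"
            )


def threshold_value(params: LIFParams, t):
    """Threshold theta(t) = a + k sin(2 pi t / tau) at time(s) ``t``.

    Accepts a scalar or an array of times; with k = 0 the threshold is
    the constant ``a``.
    """
    t = np.asarray(t, dtype=float)
    theta = params.a + params.k * np.sin(2.0 * np.pi * t / params.tau)
    return float(theta) if theta.ndim == 0 else theta


def threshold_trace(params: LIFParams, clock: SimulationClock):
    """Threshold evaluated on the clock's time grid.

    Returns ``(times, theta)``; theta is periodic with period tau and
    bounded by a - k and a + k.
    """
    times = np.arange(1, clock.n_steps + 1) * clock.dt
    return times, threshold_value(params, times)


def simulate_lif(params: LIFParams, clock: SimulationClock) -> IBISample:
    """Simulate the variable-threshold LIF model and return its IBIs.

    Per step: an input event is drawn (probability ``p_input``,
    amplitude ``b``), the potential is updated, and the updated V is
    compared against theta evaluated at the step's time; on crossing, a
    blink is recorded and V resets to ``v0``.  The pre-first-blink
    segment is excluded from the intervals.  Seed-deterministic.
    """
    steps = lif_first_passage_steps(
        params.c,
        params.b,
        params.p_input,
        params.sigma,
        params.a,
        params.k,
        params.tau,
        params.v0,
        clock.dt,
        clock.n_steps,
        clock.seed,
        params.sqrt_dt_noise,
    )
    return IBISample.from_blink_steps(steps, clock.dt)
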