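"""One-dimensional stochastic diffusion (OSD) blink generator.

The blink generator's potential follows an Ornstein-Uhlenbeck process

    dX = (-beta X + mu) dt + phi dW,    X(0) = x0,

with mean reversion toward ``mu / beta``.  A blink is the first passage
of X to a constant threshold; the potential then resets to ``x0`` and
the passage times between consecutive blinks are the inter-blink
intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._kernels import ou_first_passage_steps
from .clock import SimulationClock
from .sample import IBISample


@dataclass(frozen=True)
class OSDParams:
    """Parameters of the OU blink generator.

    Parameters
    ----------
    beta : float
        Spontaneous decay rate (1/s, > 0).
    mu : float
        Average input (drift of the potential, 1/s).
    phi : float
        Noise intensity (>= 0; 0 gives the deterministic relaxation
        used in closed-form checks).
    x0 : float
        Initial and post-blink reset potential (dimensionless).
    threshold : float
        Constant firing threshold (dimensionless, default 1.0).
    """

    beta: float
    mu: float
    phi: float
    x0: float = 0.0
    threshold: float = 1.0

    def __post_init__(self) -> None:
        for name in ("beta", "mu", "phi", "x0", "threshold"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.phi < 0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")
        if self.threshold <= self.x0:
            raise ValueError(
                f"threshold ({self.threshold}) must exceed x0 ({self.x0})"
            )

    def noiseless_passage_time(self) -> float:
        """Closed-form first-passage time of the phi = 0 relaxation.

        The noiseless potential is X(t) = mu/beta + (x0 - mu/beta)
        exp(-beta t), which reaches the threshold at
        t* = (1/beta) * ln((mu/beta - x0) / (mu/beta - threshold))
        provided the fixed point mu/beta lies above the threshold;
        otherwise the threshold is never reached and the passage time is
        infinite.
        """
        fp = self.mu / self.beta
        if fp <= self.threshold:
            return math.inf
        return math.log((fp - self.x0) / (fp - self.threshold)) / self.beta


def simulate_osd(params: OSDParams, clock: SimulationClock) -> IBISample:
    """Simulate the OSD model and return its inter-blink intervals.

    Euler-Maruyama integration on the clock's grid; a blink is recorded
    at the first step where X >= threshold and X resets to ``x0`` at
    that step.  The segment before the first blink is excluded, so a run
    with ``n`` crossings yields ``n - 1`` intervals.  Zero blinks within
    the horizon yield an empty sample.
    """
    steps = ou_first_passage_steps(
        params.beta,
        params.mu,
        params.phi,
        params.x0,
        params.threshold,
        clock.dt,
        clock.n_steps,
        clock.seed,
    )
    return IBISample.from_blink_steps(steps, clock.dt)
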