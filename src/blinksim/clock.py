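"""Simulation clock shared by both blink generators."""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class SimulationClock:
    """Integration step, horizon and seed conventions for a simulation run.

    Parameters
    ----------
    dt : float
        Integration time step in seconds (default 0.001 s).
    horizon : float
        Total simulated time in seconds (default 3000 s, i.e. 50 min of
        observation).
    seed : int
        Seed for the run's random number stream.  Identical (parameters,
        clock) pairs produce bit-identical output.
    """

    dt: float = 0.001
    horizon: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be finite and > 0, got {self.dt}")
        if not (math.isfinite(self.horizon) and self.horizon >= self.dt):
            raise ValueError(f"horizon must be finite and >= dt, got {self.horizon}")
        n = self.horizon / self.dt
        if abs(n - round(n)) > 1e-6 * max(1.0, n):
            raise ValueError(
                f"horizon ({self.horizon}) must be an integer multiple of dt ({self.dt})"
            )
        if int(round(n)) < 1:
            raise ValueError("clock must cover at least one step")
        if not isinstance(self.seed, (int,)) or self.seed < 0:
            raise ValueError(f"seed must be a non-negative integer, got {self.seed}")

    @property
    def n_steps(self) -> int:
        """Number of integration steps covered by the horizon."""
        return int(round(self.horizon / self.dt))

    def with_seed(self, seed: int) -> "SimulationClock":
        """Return a copy of this clock with a different seed."""
        return SimulationClock(dt=self.dt, horizon=self.horizon, seed=seed)
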