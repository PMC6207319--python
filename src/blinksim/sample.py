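"""Container for inter-blink-interval samples."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class IBISample:
    """An ordered sequence of inter-blink intervals in seconds.

    ``intervals`` holds the times between consecutive blinks; the segment
    from the start of observation to the first blink is not an
    inter-blink interval and is excluded, so with ``n_blinks`` threshold
    crossings there are ``n_blinks - 1`` intervals.

    Attributes
    ----------
    intervals : numpy.ndarray
        Strictly positive intervals, in temporal order, seconds.
    n_blinks : int
        Number of threshold crossings observed (``len(intervals) + 1``
        when at least one blink occurred, 0 otherwise).
    """

    intervals: np.ndarray
    n_blinks: int = field(default=-1)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
            raise ValueError("intervals must be finite and > 0")
        object.__setattr__(self, "intervals", arr)
        if self.n_blinks < 0:
            object.__setattr__(self, "n_blinks", arr.size + 1 if arr.size else 0)
        if self.n_blinks > 0 and arr.size != self.n_blinks - 1:
            raise ValueError(
                f"expected n_blinks - 1 = {self.n_blinks - 1} intervals, got {arr.size}"
            )
        if self.n_blinks == 0 and arr.size:
            raise ValueError("n_blinks == 0 is inconsistent with non-empty intervals")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def mean(self) -> float:
        """Sample mean IBI (s); NaN for an empty sample."""
        return float(np.mean(self.intervals)) if len(self) else float("nan")

    @property
    def median(self) -> float:
        """Sample median IBI (s); NaN for an empty sample."""
        return float(np.median(self.intervals)) if len(self) else float("nan")

    @classmethod
    def from_blink_steps(cls, steps: np.ndarray, dt: float) -> "IBISample":
        """Build a sample from the step indices at which blinks occurred."""
        steps = np.asarray(steps, dtype=np.int64)
        if steps.size == 0:
            return cls(intervals=np.empty(0), n_blinks=0)
        return cls(intervals=np.diff(steps) * dt, n_blinks=int(steps.size))
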