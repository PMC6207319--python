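"""File formats, fixture generation and the shared RNG policy.

IBI files are plain text: one interval in seconds per line, ``#`` lines
ignored.  Files written by this package carry a header comment with the
package version, the full parameter set and the seed, so any output can
be regenerated from its own header.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .sample import IBISample

logger = logging.getLogger(__name__)

#: Ground-truth component means (s) and weights of the test fixtures.
FIXTURE_COMPONENTS: Dict[str, Tuple[Tuple[float, ...], Tuple[float, ...], float]] = {
    # kind: (means, weights, component sd)
    "unimodal": ((5.0,), (1.0,), 1.0),
    "bimodal": ((2.0, 7.0), (0.5, 0.5), 0.4),
    "trimodal": ((2.0, 8.0, 14.0), (0.4, 0.35, 0.25), 0.5),
}


def read_ibis(path: Union[str, Path]) -> IBISample:
    """Read an IBI sample from a plain-text file.

    One decimal value (seconds) per line; blank lines and lines starting
    with ``#`` are ignored.  Negative, zero or non-finite entries raise
    a parse error naming the offending line.  An empty file yields an
    empty sample with a logged warning.
    """
    path = Path(path)
    values = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                value = float(line)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: not a decimal value: {line!r}"
                ) from exc
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"{path}:{lineno}: intervals must be finite and > 0, got {line!r}"
                )
            values.append(value)
    if not values:
        logger.warning("%s: empty IBI file", path)
        return IBISample(intervals=np.empty(0), n_blinks=0)
    return IBISample(intervals=np.asarray(values))


def _atomic_write(path: Path, text: str) -> None:
    """Write via a temp file in the same directory, then rename."""
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_ibis(
    sample: IBISample,
    path: Union[str, Path],
    *,
    params: Optional[dict] = None,
) -> None:
    """Write a sample to a plain-text IBI file (6 decimal places).

    The header comment records the package version and, when given, the
    generating parameter set and seed, making the file self-describing.
    """
    from . import __version__

    lines = [f"# blinksim {__version__}"]
    if params:
        lines.append(
            "# " + " ".join(f"{key}={value}" for key, value in sorted(params.items()))
        )
    lines.append(f"# n_blinks={sample.n_blinks} n_intervals={len(sample)}")
    lines.extend(f"{x:.6f}" for x in sample.intervals)
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def make_fixture(kind: str, n: int, seed: int) -> Tuple[IBISample, Tuple[float, ...]]:
    """Synthetic IBI sample with known ground-truth modes, for testing.

    ``unimodal``, ``bimodal`` and ``trimodal`` draw from truncated
    Gaussian mixtures inside [0, 20] s with the component means of
    :data:`FIXTURE_COMPONENTS`; ``flat`` draws uniformly on (0, 20],
    whose density 0.05 sits below the 0.1 peak-admission floor.  Returns
    ``(sample, ground_truth_peaks)``; identical ``(kind, n, seed)``
    yield identical samples.
    """
    if n < 10:
        raise ValueError(f"n must be >= 10, got {n}")
    rng = np.random.default_rng(seed)
    if kind == "flat":
        xs = rng.uniform(0.0, 20.0, size=n)
        xs = np.where(xs <= 0, 0.001, xs)
        return IBISample(intervals=xs), ()
    if kind not in FIXTURE_COMPONENTS:
        raise ValueError(
            f"unknown fixture kind {kind!r}; expected one of "
            f"{sorted(FIXTURE_COMPONENTS)} or 'flat'"
        )
    means, weights, sd = FIXTURE_COMPONENTS[kind]
    comps = rng.choice(len(means), size=n, p=weights)
    xs = rng.normal(np.asarray(means)[comps], sd)
    # rejection-resample the few draws outside (0, 20]
    bad = (xs <= 0) | (xs > 20.0)
    while bad.any():
        xs[bad] = rng.normal(np.asarray(means)[comps[bad]], sd)
        bad = (xs <= 0) | (xs > 20.0)
    return IBISample(intervals=xs), means
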