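"""Parameter-grid sweeps and matching against published bimodal IBIs.

A sweep enumerates a rectangular parameter grid (optionally
stride-subsampled), simulates one run per combination, classifies each
run's IBI density and tallies modality classes.  The reference matcher
searches LIF parameter combinations whose bimodal peak pair reproduces,
within a +/-0.025 s tolerance, one of the six bimodal inter-blink
distributions reported by Ponder & Kennedy.
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clock import SimulationClock
from .density import MODALITY_LABELS, classify, match_peaks
from .lif import LIFParams, simulate_lif
from .osd import OSDParams, simulate_osd

#: Fixed parameters used in the published grids: the OSD threshold is
#: 1.0; the LIF runs use a unit threshold baseline and no input noise.
OSD_FIXED = {"x0": 0.0, "threshold": 1.0}
LIF_FIXED = {"a": 1.0, "sigma": 0.0, "b": 1.0, "p_input": 0.5, "v0": 0.0}

#: Published sweep grids: (name, min, max, increment) per axis.
OSD_REFERENCE_AXES = (("beta", 0.01, 10.0, 0.01), ("mu", 0.1, 10.0, 0.1), ("phi", 0.5, 1.0, 0.05))
LIF_REFERENCE_AXES = (("c", 0.0, 1.0, 0.01), ("k", 0.0, 0.9, 0.01), ("tau", 0.5, 10.0, 0.5))


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic per-combination seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class GridSpec:
    """A rectangular parameter grid with inclusive endpoints.

    Each axis is a ``(name, min, max, increment)`` tuple; grid values
    are built as ``min + i * increment`` (integer index times increment,
    avoiding floating-point accumulation) with
    ``floor((max - min)/increment) + 1`` points per axis.
    """

    axes: Tuple[Tuple[str, float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.axes:
            raise ValueError("grid must have at least one axis")
        for name, lo, hi, inc in self.axes:
            if inc <= 0:
                raise ValueError(f"{name}: increment must be > 0, got {inc}")
            if lo > hi:
                raise ValueError(f"{name}: min {lo} exceeds max {hi}")

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(a[0] for a in self.axes)

    def axis_values(self, name: str, stride: int = 1) -> np.ndarray:
        for ax_name, lo, hi, inc in self.axes:
            if ax_name == name:
                n = int(math.floor((hi - lo) / inc + 1e-9)) + 1
                vals = lo + np.arange(n) * inc
                return np.round(vals, 12)[::stride]
        raise KeyError(name)

    def _strides(self, stride) -> Tuple[int, ...]:
        """Normalise an int or per-axis sequence of strides."""
        if np.isscalar(stride):
            strides = (int(stride),) * len(self.axes)
        else:
            strides = tuple(int(s) for s in stride)
            if len(strides) != len(self.axes):
                raise ValueError(
                    f"expected {len(self.axes)} per-axis strides, got {len(strides)}"
                )
        if any(s < 1 for s in strides):
            raise ValueError(f"strides must be >= 1, got {strides}")
        return strides

    def shape(self, stride=1) -> Tuple[int, ...]:
        strides = self._strides(stride)
        return tuple(
            self.axis_values(name, s).size for name, s in zip(self.names, strides)
        )

    @property
    def n_combinations(self) -> int:
        return int(np.prod(self.shape()))

    def combinations(self, stride=1) -> Iterable[Tuple[int, Dict[str, float]]]:
        """Yield ``(full_grid_index, {name: value})`` per kept combination.

        ``stride`` is an int applied to every axis or a per-axis
        sequence.  The index is the combination's flat position in the
        *full* (stride-1) grid, so a combination keeps the same derived
        seed at any stride.
        """
        strides = self._strides(stride)
        full_sizes = self.shape(1)
        index_axes = [
            np.arange(0, size, s) for size, s in zip(full_sizes, strides)
        ]
        value_axes = [
            self.axis_values(name, s) for name, s in zip(self.names, strides)
        ]
        for idxs, vals in zip(
            itertools.product(*index_axes), itertools.product(*value_axes)
        ):
            flat = 0
            for i, size in zip(idxs, full_sizes):
                flat = flat * size + i
            yield flat, dict(zip(self.names, vals))


#: Grid objects for the published sweeps.
def osd_reference_grid() -> GridSpec:
    """The published OSD sweep grid (1000 beta x 100 mu x 11 phi)."""
    return GridSpec(OSD_REFERENCE_AXES)


def lif_reference_grid() -> GridSpec:
    """The published LIF sweep grid (101 c x 91 k x 20 tau)."""
    return GridSpec(LIF_REFERENCE_AXES)


@dataclass
class SweepResult:
    """Per-combination classifications and aggregate modality tallies."""

    model: str
    records: pd.DataFrame
    n_combinations: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_combinations = len(self.records)

    @property
    def counts(self) -> Dict[str, int]:
        c = self.records["modality"].value_counts().to_dict()
        return {label: int(c.get(label, 0)) for label in MODALITY_LABELS}

    @property
    def fractions(self) -> Dict[str, float]:
        """Modality fractions over all combinations (they sum to 1)."""
        n = max(self.n_combinations, 1)
        return {label: count / n for label, count in self.counts.items()}

    @property
    def n_computable(self) -> int:
        """Combinations whose density could be estimated."""
        return self.n_combinations - self.counts["not_computable"]

    def peaked_fraction(self, of_computable: bool = False) -> float:
        """Fraction of runs with at least one admitted peak.

        By default the denominator is all swept combinations;
        ``of_computable`` restricts it to the runs that produced enough
        blinks for a density estimate.
        """
        peaked = int((self.records["n_peaks"] >= 1).sum())
        denom = self.n_computable if of_computable else self.n_combinations
        return peaked / denom if denom else float("nan")

    def summary(self) -> dict:
        return {
            "model": self.model,
            "n_combinations": self.n_combinations,
            "n_computable": self.n_computable,
            "counts": self.counts,
            "fractions": self.fractions,
            "peaked_fraction": self.peaked_fraction(False),
            "peaked_fraction_of_computable": self.peaked_fraction(True),
        }


def _simulate_one(model: str, combo: Dict[str, float], clock: SimulationClock):
    if model == "osd":
        params = OSDParams(**OSD_FIXED, **combo)
        return simulate_osd(params, clock)
    if model == "lif":
        params = LIFParams(**LIF_FIXED, **combo)
        return simulate_lif(params, clock)
    raise ValueError(f"unknown model {model!r}; expected 'osd' or 'lif'")


def run_sweep(
    model: str,
    grid: GridSpec,
    clock: SimulationClock,
    stride=1,
    *,
    out_path: Optional[str] = None,
    n_min: int = 10,
    progress: bool = False,
) -> SweepResult:
    """Simulate and classify every kept grid combination.

    One 3000 s run is simulated per combination with a seed derived
    deterministically from the clock's base seed and the combination's
    full-grid index, then classified.  ``stride`` keeps every
    ``stride``-th grid point per axis (an int, or one int per axis).  If ``out_path`` is given, rows
    stream to a TSV as they are produced, so an aborted sweep retains
    its completed rows.
    """
    if model not in ("osd", "lif"):
        raise ValueError(f"unknown model {model!r}; expected 'osd' or 'lif'")
    combos = list(grid.combinations(stride))
    if not combos:
        raise ValueError("empty grid")
    rows: List[dict] = []
    sink = open(out_path, "w") if out_path else None
    header_written = False
    try:
        iterator = combos
        if progress:
            from tqdm import tqdm

            iterator = tqdm(combos, desc=f"{model} sweep")
        for flat_index, combo in iterator:
            run_clock = clock.with_seed(derive_seed(clock.seed, flat_index))
            sample = _simulate_one(model, combo, run_clock)
            report = classify(sample, n_min=n_min)
            row = {
                **combo,
                "index": flat_index,
                "seed": run_clock.seed,
                "n_blinks": sample.n_blinks,
                "n_peaks": report.n_peaks,
                "peaks": ";".join(f"{p:.3f}" for p in report.peaks),
                "modality": report.modality,
                "median_ibi": report.median_ibi,
                "mean_ibi": report.mean_ibi,
            }
            rows.append(row)
            if sink is not None:
                if not header_written:
                    sink.write("\t".join(row) + "\n")
                    header_written = True
                sink.write("\t".join(str(v) for v in row.values()) + "\n")
                sink.flush()
    finally:
        if sink is not None:
            sink.close()
    return SweepResult(model=model, records=pd.DataFrame(rows))


def modality_map(
    result: SweepResult, *, tau: float, atol: float = 1e-9
) -> pd.DataFrame:
    """Peak-count table over (c, k) at a fixed threshold period tau.

    Rows are decay values c, columns threshold amplitudes k, cells the
    number of admitted peaks; not-computable cells are NaN.  Raises
    KeyError when the sweep does not cover the requested tau slice.
    """
    if result.model != "lif":
        raise ValueError("modality maps are defined for LIF sweeps")
    rec = result.records
    mask = np.isclose(rec["tau"].to_numpy(dtype=float), tau, atol=atol)
    if not mask.any():
        raise KeyError(f"sweep contains no slice at tau = {tau}")
    sl = rec.loc[mask].copy()
    sl.loc[sl["modality"] == "not_computable", "n_peaks"] = np.nan
    return sl.pivot(index="c", columns="k", values="n_peaks")


@dataclass(frozen=True)
class ReferenceBimodal:
    """One published bimodal IBI distribution and its matching ranges."""

    case: int
    first_peak: float
    second_peak: float
    mean: float
    a_minus_k_range: Tuple[float, float]
    tau_range: Tuple[float, float]
    freq_range: Tuple[float, float]
    median_range: Tuple[float, float]

    def __post_init__(self) -> None:
        if not self.first_peak < self.second_peak:
            raise ValueError("first_peak must precede second_peak")

    @property
    def peaks(self) -> Tuple[float, float]:
        return (self.first_peak, self.second_peak)


def load_reference_table() -> List[ReferenceBimodal]:
    """The bundled table of published bimodal IBI distributions."""
    with importlib.resources.files("blinksim.data").joinpath(
        "ponder_kennedy_table3.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return [
        ReferenceBimodal(
            case=int(r.case),
            first_peak=float(r.first_peak),
            second_peak=float(r.second_peak),
            mean=float(r.mean),
            a_minus_k_range=(float(r.a_minus_k_min), float(r.a_minus_k_max)),
            tau_range=(float(r.tau_min), float(r.tau_max)),
            freq_range=(float(r.freq_min), float(r.freq_max)),
            median_range=(float(r.median_min), float(r.median_max)),
        )
        for r in df.itertuples()
    ]


def get_reference_case(case: int) -> ReferenceBimodal:
    for ref in load_reference_table():
        if ref.case == case:
            return ref
    raise KeyError(f"no reference case {case}")


def _range_values(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    return np.round(lo + np.arange(n) * step, 12)


def match_reference(
    case: ReferenceBimodal,
    clock: SimulationClock,
    *,
    a_minus_k_values: Optional[Sequence[float]] = None,
    tau_values: Optional[Sequence[float]] = None,
    c_values: Optional[Sequence[float]] = None,
    tolerance: float = 0.025,
    n_min: int = 10,
) -> pd.DataFrame:
    """LIF parameter combinations reproducing a reference peak pair.

    For every (a - k, tau, c) combination the LIF model is simulated
    with a = 1, k = 1 - (a - k) and sigma = 0, classified, and kept when
    it is bimodal with both peaks within ``tolerance`` of the reference
    pair.  The search covers the case's published (a - k, tau) ranges
    and, because the published table omits the decay, all c in [0, 1]
    step 0.01; matches at any c count.  Returns a DataFrame of matches
    (possibly empty) with each match's peaks and sample median.
    """
    if a_minus_k_values is None:
        a_minus_k_values = _range_values(*case.a_minus_k_range, 0.01)
    if tau_values is None:
        tau_values = _range_values(*case.tau_range, 0.5)
    if c_values is None:
        c_values = _range_values(0.0, 1.0, 0.01)
    rows = []
    index = 0
    for a_minus_k in a_minus_k_values:
        for tau in tau_values:
            for c in c_values:
                params = LIFParams(
                    c=float(c),
                    k=float(np.round(1.0 - a_minus_k, 12)),
                    tau=float(tau),
                    **LIF_FIXED,
                )
                run_clock = clock.with_seed(derive_seed(clock.seed, index))
                index += 1
                sample = simulate_lif(params, run_clock)
                report = classify(sample, n_min=n_min)
                if report.modality != "bimodal":
                    continue
                if not match_peaks(report, case.peaks, tolerance=tolerance):
                    continue
                rows.append(
                    {
                        "case": case.case,
                        "a_minus_k": float(a_minus_k),
                        "k": params.k,
                        "tau": float(tau),
                        "c": float(c),
                        "seed": run_clock.seed,
                        "first_peak": float(report.peaks[0]),
                        "second_peak": float(report.peaks[1]),
                        "median_ibi": report.median_ibi,
                        "mean_ibi": report.mean_ibi,
                        "n_blinks": report.n_blinks,
                    }
                )
    columns = [
        "case", "a_minus_k", "k", "tau", "c", "seed",
        "first_peak", "second_peak", "median_ibi", "mean_ibi", "n_blinks",
    ]
    return pd.DataFrame(rows, columns=columns)
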