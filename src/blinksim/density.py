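"""Kernel density estimation and modality classification of IBI samples.

The density of inter-blink intervals is estimated on a fixed grid over
the usual 0-20 s IBI range with a Gaussian kernel,

    f_h(x) = 1/(n h) sum_i K((x - x_i)/h),   K(u) = exp(-u^2/2)/sqrt(2 pi).

Peaks are the grid locations where the finite-difference derivative of
f_h changes sign from positive to negative, admitted only when the
density value there exceeds 0.1 and exceeds the minimum by a quarter of
the max-min spread.  The peak count classifies the distribution as
peak-less, unimodal, bimodal, trimodal or multimodal; unimodal
distributions with a peak below the centre of the evaluation range are
labelled positively skewed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator

from ._kernels import gaussian_kde_grid
from .sample import IBISample

logger = logging.getLogger(__name__)

#: Gaussian-kernel roughness, R(K) = integral of K(u)^2 du = 1/(2 sqrt(pi)).
GAUSSIAN_KERNEL_ROUGHNESS = 1.0 / (2.0 * math.sqrt(math.pi))

MODALITY_LABELS = (
    "not_computable",
    "peak_less",
    "unimodal",
    "bimodal",
    "trimodal",
    "multimodal",
)


@dataclass(frozen=True)
class DensityEstimate:
    """A KDE evaluated on a uniform grid over [0, t_max] seconds."""

    grid: np.ndarray
    values: np.ndarray
    bandwidth: float
    n: int

    def integral(self) -> float:
        """Trapezoidal integral of the density over its grid."""
        return float(np.trapezoid(self.values, self.grid))


@dataclass(frozen=True)
class DistributionReport:
    """Peaks, modality and summary statistics of one IBI distribution."""

    peaks: np.ndarray
    modality: str
    skew_label: str
    median_ibi: float
    mean_ibi: float
    n_blinks: int
    bandwidth: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", np.asarray(self.peaks, dtype=float))
        if self.modality not in MODALITY_LABELS:
            raise ValueError(f"unknown modality label {self.modality!r}")

    @property
    def n_peaks(self) -> int:
        return int(self.peaks.size)

    def to_dict(self) -> dict:
        return {
            "peaks": [float(p) for p in self.peaks],
            "n_peaks": self.n_peaks,
            "modality": self.modality,
            "skew_label": self.skew_label,
            "median_ibi": self.median_ibi,
            "mean_ibi": self.mean_ibi,
            "n_blinks": self.n_blinks,
            "bandwidth": self.bandwidth,
        }


def _as_intervals(sample: Union[IBISample, Sequence[float], np.ndarray]) -> np.ndarray:
    if isinstance(sample, IBISample):
        return np.asarray(sample.intervals, dtype=float)
    return np.asarray(sample, dtype=float).ravel()


def select_bandwidth(
    sample,
    *,
    method: str = "normal_reference",
    grid_step: float = 0.005,
    t_max: float = 20.0,
    fallback_bandwidth: float = 0.05,
) -> float:
    """Plug-in bandwidth for the Gaussian KDE.

    Both variants return the asymptotically optimal

        h = [ R(K) / (n R(f'')) ]^(1/5)

    with Gaussian-kernel roughness R(K) = 1/(2 sqrt(pi)); they differ in
    how the curvature roughness R(f'') = integral of f''(x)^2 dx is
    obtained:

    ``normal_reference`` (default)
        R(f'') is the curvature integral of a Gaussian reference density
        with the sample's standard deviation, 3 / (8 sqrt(pi) sd^5)
        (the closed form of the trapezoidal integral over the squared
        reference curvature), which reduces h to Silverman's rule
        (4/3)^(1/5) sd n^(-1/5) ~ 1.06 sd n^(-1/5).  This is the
        selector under which the package reproduces the published
        peak-location matches.
    ``curvature``
        R(f'') is estimated from the data: a pilot KDE with the
        normal-reference bandwidth supplies f'' on the evaluation grid
        and the integral is taken by the trapezoidal rule.  Adaptive to
        multimodality, hence systematically smaller h on strongly
        bimodal samples.

    ``fallback_bandwidth`` doubles as a lower bound: a zero-variance (or
    otherwise degenerate) sample falls back to it with a logged warning,
    and a selected bandwidth below it is clamped up to it.  Without the
    clamp, very sharp interval distributions (sample sd of a few tens of
    milliseconds) select bandwidths at which Monte-Carlo jitter in the
    density produces spurious admitted peaks.
    """
    xs = _as_intervals(sample)
    n = xs.size
    if n < 2:
        raise ValueError("bandwidth selection requires at least 2 intervals")
    if method not in ("normal_reference", "curvature"):
        raise ValueError(f"unknown bandwidth method {method!r}")
    sd = float(np.std(xs, ddof=1))
    if sd == 0.0 or not math.isfinite(sd):
        logger.warning(
            "degenerate sample (sd = %s); falling back to bandwidth %.3f s",
            sd,
            fallback_bandwidth,
        )
        return fallback_bandwidth
    h0 = 1.06 * sd * n ** (-0.2)
    if method == "normal_reference":
        roughness = 3.0 / (8.0 * math.sqrt(math.pi) * sd**5)
    else:
        grid = _make_grid(grid_step, t_max)
        curvature = gaussian_kde_grid(np.sort(xs), grid, h0, True)
        roughness = float(np.trapezoid(curvature**2, grid))
    if roughness <= 0.0 or not math.isfinite(roughness):
        logger.warning(
            "curvature roughness not positive (%s); falling back to bandwidth %.3f s",
            roughness,
            fallback_bandwidth,
        )
        return fallback_bandwidth
    h = float((GAUSSIAN_KERNEL_ROUGHNESS / (n * roughness)) ** 0.2)
    return max(h, fallback_bandwidth)


def _make_grid(grid_step: float, t_max: float) -> np.ndarray:
    if grid_step <= 0 or grid_step > 0.005:
        raise ValueError(
            f"grid_step must lie in (0, 0.005] s to resolve the 0.025 s "
            f"peak-matching tolerance, got {grid_step}"
        )
    n_cells = int(round(t_max / grid_step))
    return np.linspace(0.0, t_max, n_cells + 1)


def estimate_density(
    sample,
    *,
    grid_step: float = 0.005,
    bandwidth: Optional[float] = None,
    bandwidth_method: str = "normal_reference",
    t_max: float = 20.0,
    fallback_bandwidth: float = 0.05,
) -> DensityEstimate:
    """Gaussian KDE of an IBI sample on the [0, t_max] grid.

    If ``bandwidth`` is omitted it is chosen by :func:`select_bandwidth`.
    """
    xs = _as_intervals(sample)
    if xs.size < 2:
        raise ValueError("density estimation requires at least 2 intervals")
    if bandwidth is None:
        bandwidth = select_bandwidth(
            xs,
            method=bandwidth_method,
            grid_step=grid_step,
            t_max=t_max,
            fallback_bandwidth=fallback_bandwidth,
        )
    if not (math.isfinite(bandwidth) and bandwidth > 0):
        raise ValueError(f"bandwidth must be finite and > 0, got {bandwidth}")
    grid = _make_grid(grid_step, t_max)
    values = gaussian_kde_grid(np.sort(xs), grid, float(bandwidth), False)
    return DensityEstimate(grid=grid, values=values, bandwidth=float(bandwidth), n=xs.size)


def find_peaks(density: DensityEstimate, *, min_height: float = 0.1) -> np.ndarray:
    """Locations of admitted density peaks, sorted ascending.

    A candidate peak is a grid point where the finite-difference
    derivative changes sign from positive to negative (the leftmost
    point of a flat maximum).  It is admitted when the density value
    there exceeds ``min_height`` and exceeds the grid minimum by one
    quarter of the max-min spread.  An empty array means peak-less.
    """
    v = density.values
    d = np.diff(v)
    sgn = np.sign(d)
    nonzero = np.flatnonzero(sgn)
    vmin = float(v.min())
    vmax = float(v.max())
    relative_floor = vmin + (vmax - vmin) / 4.0
    locations = []
    for left, right in zip(nonzero[:-1], nonzero[1:]):
        if sgn[left] > 0 and sgn[right] < 0:
            p = left + 1
            if v[p] > min_height and v[p] > relative_floor:
                locations.append(density.grid[p])
    return np.asarray(locations, dtype=float)


def _modality_from_count(n_peaks: int) -> str:
    if n_peaks == 0:
        return "peak_less"
    if n_peaks == 1:
        return "unimodal"
    if n_peaks == 2:
        return "bimodal"
    if n_peaks == 3:
        return "trimodal"
    return "multimodal"


def classify(
    sample,
    *,
    grid_step: float = 0.005,
    bandwidth: Optional[float] = None,
    bandwidth_method: str = "normal_reference",
    t_max: float = 20.0,
    n_min: int = 10,
    fallback_bandwidth: float = 0.05,
    min_peak_height: float = 0.1,
    use_sample_skewness: bool = False,
) -> DistributionReport:
    """Classify the modality of an IBI sample's kernel-estimated density.

    Samples with fewer than ``n_min`` blinks are declared
    ``not_computable`` and no peak finding is attempted.  A unimodal
    distribution is labelled ``positively_skewed`` when its peak lies
    below the centre of the evaluation range (t_max / 2); with
    ``use_sample_skewness`` the label additionally requires the sample
    skewness g1 to exceed 0.5.  Median and mean are computed from the
    raw intervals.  The function is pure: identical inputs yield an
    identical report.
    """
    xs = _as_intervals(sample)
    if isinstance(sample, IBISample):
        n_blinks = sample.n_blinks
    else:
        n_blinks = xs.size + 1 if xs.size else 0
    median = float(np.median(xs)) if xs.size else float("nan")
    mean = float(np.mean(xs)) if xs.size else float("nan")
    if n_blinks < n_min:
        return DistributionReport(
            peaks=np.empty(0),
            modality="not_computable",
            skew_label="n/a",
            median_ibi=median,
            mean_ibi=mean,
            n_blinks=n_blinks,
        )
    density = estimate_density(
        xs,
        grid_step=grid_step,
        bandwidth=bandwidth,
        bandwidth_method=bandwidth_method,
        t_max=t_max,
        fallback_bandwidth=fallback_bandwidth,
    )
    peaks = find_peaks(density, min_height=min_peak_height)
    modality = _modality_from_count(peaks.size)
    if modality == "unimodal":
        skewed = peaks[0] < t_max / 2.0
        if use_sample_skewness and skewed:
            from scipy.stats import skew

            skewed = bool(skew(xs) > 0.5)
        skew_label = "positively_skewed" if skewed else "not_positively_skewed"
    else:
        skew_label = "n/a"
    return DistributionReport(
        peaks=peaks,
        modality=modality,
        skew_label=skew_label,
        median_ibi=median,
        mean_ibi=mean,
        n_blinks=n_blinks,
        bandwidth=density.bandwidth,
    )


def match_peaks(
    report: Union[DistributionReport, Sequence[float], np.ndarray],
    reference_peaks: Sequence[float],
    *,
    tolerance: float = 0.025,
) -> bool:
    """True iff the detected peaks match the reference within tolerance.

    Peaks are matched in sorted order (first to first, second to
    second); a cardinality mismatch returns False.  The default
    tolerance of +/-0.025 s is half the 0.5 s histogram bin width of the
    reference distributions, e.g. a reference peak at 0.5 s accepts
    detections in 0.475-0.525 s.
    """
    peaks = report.peaks if isinstance(report, DistributionReport) else np.asarray(
        report, dtype=float
    )
    ref = np.asarray(reference_peaks, dtype=float)
    if peaks.size != ref.size:
        return False
    return bool(
        np.all(np.abs(np.sort(peaks) - np.sort(ref)) <= tolerance + 1e-12)
    )


class IBIDensityClassifier(BaseEstimator):
    """Modality classifier for inter-blink-interval samples.

    A scikit-learn-style estimator: ``fit`` takes the sample of
    intervals (1-d array-like or :class:`IBISample`), estimates the
    Gaussian-kernel density over [0, ``t_max``] s, finds admitted peaks
    and exposes the classification through fitted attributes.

    Parameters
    ----------
    grid_step : float
        Evaluation grid step, s (<= 0.005 so the 0.025 s peak-matching
        tolerance stays resolvable).
    bandwidth : float or None
        Fixed KDE bandwidth in s; None selects the plug-in bandwidth.
    t_max : float
        Upper edge of the evaluation range, s.
    n_min : int
        Minimum blink count below which the density is declared not
        computable.
    fallback_bandwidth : float
        Bandwidth used for zero-variance samples.
    min_peak_height : float
        Absolute density value a peak must exceed.
    use_sample_skewness : bool
        Require sample skewness g1 > 0.5 in addition to the
        centre-of-range rule for the positively-skewed label.

    Attributes
    ----------
    density_ : DensityEstimate
        The fitted KDE (absent when not computable).
    bandwidth_ : float
        Bandwidth actually used.
    peaks_ : numpy.ndarray
        Admitted peak locations, s.
    n_peaks_ : int
    modality_ : str
        One of ``not_computable, peak_less, unimodal, bimodal, trimodal,
        multimodal``.
    skew_label_ : str
    median_ : float
    mean_ : float
    report_ : DistributionReport
    """

    def __init__(
        self,
        grid_step: float = 0.005,
        bandwidth: Optional[float] = None,
        bandwidth_method: str = "normal_reference",
        t_max: float = 20.0,
        n_min: int = 10,
        fallback_bandwidth: float = 0.05,
        min_peak_height: float = 0.1,
        use_sample_skewness: bool = False,
    ):
        self.grid_step = grid_step
        self.bandwidth = bandwidth
        self.bandwidth_method = bandwidth_method
        self.t_max = t_max
        self.n_min = n_min
        self.fallback_bandwidth = fallback_bandwidth
        self.min_peak_height = min_peak_height
        self.use_sample_skewness = use_sample_skewness

    def fit(self, X, y=None):
        """Estimate the density of the intervals in ``X`` and classify it."""
        report = classify(
            X,
            grid_step=self.grid_step,
            bandwidth=self.bandwidth,
            bandwidth_method=self.bandwidth_method,
            t_max=self.t_max,
            n_min=self.n_min,
            fallback_bandwidth=self.fallback_bandwidth,
            min_peak_height=self.min_peak_height,
            use_sample_skewness=self.use_sample_skewness,
        )
        self.report_ = report
        self.peaks_ = report.peaks
        self.n_peaks_ = report.n_peaks
        self.modality_ = report.modality
        self.skew_label_ = report.skew_label
        self.median_ = report.median_ibi
        self.mean_ = report.mean_ibi
        self.bandwidth_ = report.bandwidth
        if report.modality != "not_computable":
            self.density_ = estimate_density(
                X,
                grid_step=self.grid_step,
                bandwidth=report.bandwidth,
                t_max=self.t_max,
                fallback_bandwidth=self.fallback_bandwidth,
            )
        return self

    def matches(self, reference_peaks, tolerance: float = 0.025) -> bool:
        """Order-matched peak comparison against ``reference_peaks``."""
        return match_peaks(self.report_, reference_peaks, tolerance=tolerance)
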