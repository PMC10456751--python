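"""Rotational-bias statistics and angular-displacement distributions.

Given an ensemble of twist (chi) trajectories, this module

* classifies each trajectory as clockwise / counterclockwise by the sign
  of its net angular displacement (sign convention: positive chi = CCW as
  viewed from the cytoplasmic side, configurable),
* summarises the CW/CCW split with per-direction MSD slopes and a
  bootstrap confidence interval on the CCW fraction,
* builds unit-area histograms of the displacement distribution and fits a
  single Gaussian (location, FWHM, peak area) to them, and
* subtracts two such histograms (treatment minus control) and locates the
  signed extrema of the difference — the "subtraction map" summarising a
  ligand-induced shift of the distribution.

Angular excursions here are a few mrad, far below a radian, so linear
(non-circular) statistics are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .exceptions import DataError, EmptyEnsembleError, FitError
from .msd import compute_msd, linear_slope
from .trajectories import Trajectory, TrajectoryEnsemble

__all__ = [
    "BiasResult",
    "AngularHistogram",
    "GaussianFit",
    "SubtractionMap",
    "FWHM_FACTOR",
    "net_displacement",
    "classify_rotation",
    "rotational_bias",
    "displacement_histogram",
    "fit_gaussian",
    "subtract_histograms",
]

#: FWHM of a Gaussian in units of sigma: 2*sqrt(2*ln 2).
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Integral tolerance for "unit-normalized".
NORM_TOL = 1e-9


@dataclass
class BiasResult:
    """CW/CCW classification of an ensemble with per-direction MSD slopes."""

    n_ccw: int
    n_cw: int
    n_null: int
    ccw_fraction: float
    ci_low: float
    ci_high: float
    msd_slope_ccw: float | None  # mrad^2/ms; None if class too small
    msd_slope_cw: float | None
    n_bootstrap: int
    sign_convention: str = "+chi = CCW viewed from the cytoplasmic side"
    flags: tuple[str, ...] = ()

    @property
    def n_total(self) -> int:
        return self.n_ccw + self.n_cw + self.n_null


@dataclass
class AngularHistogram:
    """Angular-displacement histogram; density has units 1/mrad."""

    bin_edges: np.ndarray  # mrad, length n_bins + 1
    density: np.ndarray
    counts: np.ndarray
    axis: str
    normalized: bool
    statistic: str = "net"  # "net" or "lag:<n>"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        self.counts = np.asarray(self.counts)
        if np.any(self.density < 0):
            raise DataError("histogram density must be non-negative")
        if self.normalized and abs(self.integral() - 1.0) > NORM_TOL:
            raise DataError(
                f"histogram flagged normalized but integrates to "
                f"{self.integral()!r}"
            )

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))


@dataclass
class GaussianFit:
    """Single-Gaussian fit of a displacement histogram.

    ``peak_area`` is the free amplitude A of
    A/(sigma sqrt(2 pi)) * exp(-(x-loc)^2 / 2 sigma^2); it may be < 1 when
    the Gaussian captures only the core of a heavier-tailed distribution.
    """

    location: float  # mrad
    location_se: float
    fwhm: float  # mrad
    fwhm_se: float
    peak_area: float
    peak_area_se: float
    sigma: float
    sigma_se: float
    residual_norm: float
    n_bins: int

    def __post_init__(self) -> None:
        # FWHM is derived from sigma via the exact Gaussian identity
        assert self.fwhm == FWHM_FACTOR * self.sigma


@dataclass
class SubtractionMap:
    """Bin-wise difference of two unit-normalized histograms."""

    bin_edges: np.ndarray
    difference: np.ndarray  # treatment - control density, 1/mrad
    extrema: list = field(default_factory=list)  # (position mrad, amplitude)
    smoothing_bins: int = 3
    threshold: float = 0.0

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def integral(self) -> float:
        return float(np.sum(self.difference * np.diff(self.bin_edges)))


def net_displacement(trajectory: Trajectory, axis: str = "chi") -> float:
    """Net angular displacement (last minus first value) on an axis."""
    x = trajectory.axis_values(axis)
    return float(x[-1] - x[0])


def classify_rotation(
    ensemble: TrajectoryEnsemble, sign: int = +1
) -> tuple[int, int, int]:
    """Count (n_ccw, n_cw, n_null) by the sign of net twist displacement.

    ``sign=+1`` is the default convention (positive chi displacement =
    CCW from the cytoplasmic side); ``sign=-1`` flips to the
    extracellular-side view.
    """
    if sign not in (+1, -1):
        raise DataError("sign must be +1 or -1")
    d = np.array([net_displacement(t, "chi") for t in ensemble]) * sign
    return int(np.sum(d > 0)), int(np.sum(d < 0)), int(np.sum(d == 0))


def rotational_bias(
    ensemble: TrajectoryEnsemble,
    n_bootstrap: int = 1000,
    seed: int = 0,
    sign: int = +1,
    max_lag_frames: int | None = None,
    min_class_size: int = 5,
) -> BiasResult:
    """Full rotational-bias summary of an ensemble.

    Counts CW/CCW/null trajectories, estimates the CCW fraction among
    directed trajectories with a 95% trajectory-level percentile-bootstrap
    CI, and reports the linear MSD slope of the CCW and CW sub-ensembles
    separately (``None`` when a direction has fewer than
    ``min_class_size`` members).
    """
    if len(ensemble) == 0:
        raise EmptyEnsembleError("rotational bias needs a non-empty ensemble")
    d = np.array([net_displacement(t, "chi") for t in ensemble]) * sign
    n_ccw = int(np.sum(d > 0))
    n_cw = int(np.sum(d < 0))
    n_null = int(np.sum(d == 0))
    directed = d[d != 0]
    flags: list[str] = []
    if directed.size == 0:
        frac = math.nan
        lo, hi = 0.0, 1.0
        flags.append("no_directed_trajectories")
    else:
        frac = n_ccw / directed.size
        if len(ensemble) < 2:
            lo, hi = 0.0, 1.0
            flags.append("degenerate_ci_single_trajectory")
        else:
            rng = np.random.Generator(np.random.PCG64(seed))
            idx = rng.integers(0, len(d), size=(n_bootstrap, len(d)))
            samples = d[idx]
            pos = np.sum(samples > 0, axis=1).astype(float)
            neg = np.sum(samples < 0, axis=1).astype(float)
            denom = pos + neg
            with np.errstate(invalid="ignore"):
                fracs = np.where(denom > 0, pos / denom, np.nan)
            fracs = fracs[~np.isnan(fracs)]
            lo, hi = (float(v) for v in np.percentile(fracs, [2.5, 97.5]))

    def class_slope(mask: np.ndarray) -> float | None:
        members = [t for t, keep in zip(ensemble, mask) if keep]
        if len(members) < min_class_size:
            return None
        sub = ensemble.replace(members)
        ml = max_lag_frames
        if ml is None:
            ml = max(2, min(ensemble.n_frames_nominal // 4, 100))
        return linear_slope(compute_msd(sub, "chi", ml)).slope

    return BiasResult(
        n_ccw=n_ccw, n_cw=n_cw, n_null=n_null,
        ccw_fraction=frac, ci_low=lo, ci_high=hi,
        msd_slope_ccw=class_slope(d > 0),
        msd_slope_cw=class_slope(d < 0),
        n_bootstrap=n_bootstrap,
        sign_convention=(
            "+chi = CCW viewed from the cytoplasmic side"
            if sign == +1 else
            "-chi = CCW (extracellular-side view)"
        ),
        flags=tuple(flags),
    )


def _displacements(
    ensemble: TrajectoryEnsemble, axis: str, lag_frames: int | None
) -> tuple[np.ndarray, str]:
    if lag_frames is None:
        return (
            np.array([net_displacement(t, axis) for t in ensemble]),
            "net",
        )
    vals = []
    for t in ensemble:
        x = t.axis_values(axis)
        if len(x) > lag_frames:
            vals.append(x[lag_frames:] - x[:-lag_frames])
    if not vals:
        raise EmptyEnsembleError(
            f"no trajectory long enough for lag {lag_frames} frames"
        )
    return np.concatenate(vals), f"lag:{lag_frames}"


def displacement_histogram(
    ensemble: TrajectoryEnsemble,
    axis: str = "chi",
    bin_width: float = 0.25,
    lag_frames: int | None = None,
) -> AngularHistogram:
    """Unit-area histogram of angular displacements.

    By default the statistic is the per-trajectory *net* displacement
    (matching the direction classification); ``lag_frames`` switches to
    pooled fixed-lag displacements.  Bins have the given width (default
    0.25 mrad) on a grid *centred on zero* (zero is a bin centre, so the
    edge set is symmetric and mirroring the data mirrors the histogram
    exactly), extended to cover all data.
    """
    if len(ensemble) == 0:
        raise EmptyEnsembleError("histogram needs a non-empty ensemble")
    if bin_width <= 0:
        raise DataError("bin_width must be > 0")
    data, statistic = _displacements(ensemble, axis, lag_frames)
    amax = float(np.max(np.abs(data))) if data.size else 0.0
    # centers at j*w for j = -k..k, so edges are +-(j + 1/2)*w and the
    # grid is exactly mirror-symmetric about zero
    k = max(1, int(np.floor(amax / bin_width + 0.5)))
    edges = (np.arange(-k, k + 2) - 0.5) * bin_width
    counts, _ = np.histogram(data, bins=edges)
    density = counts / (data.size * bin_width)
    return AngularHistogram(
        bin_edges=edges, density=density, counts=counts,
        axis=axis, normalized=True, statistic=statistic,
    )


def _gauss(x, area, loc, sigma):
    return area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
        -((x - loc) ** 2) / (2 * sigma**2)
    )


def fit_gaussian(histogram: AngularHistogram) -> GaussianFit:
    """Least-squares single-Gaussian fit to bin-centre densities.

    Reports location, FWHM = 2*sqrt(2 ln 2)*sigma and the free amplitude
    ("peak area"); standard errors come from the fit covariance, with the
    FWHM error propagated exactly from sigma's.
    """
    x = histogram.centers
    y = histogram.density
    occupied = int(np.sum(y > 0))
    if occupied < 5:
        raise FitError(
            f"Gaussian fit needs >= 5 occupied bins, got {occupied}"
        )
    w = histogram.bin_width
    total = float(np.sum(y) * w)
    mean0 = float(np.sum(x * y) * w / total)
    var0 = float(np.sum((x - mean0) ** 2 * y) * w / total)
    sigma0 = max(math.sqrt(var0), w / 2)
    p0 = [total, mean0, sigma0]
    try:
        popt, pcov = optimize.curve_fit(
            _gauss, x, y, p0=p0,
            bounds=([0.0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    area, loc, sigma = (float(v) for v in popt)
    area_se, loc_se, sigma_se = (float(v) for v in perr)
    resid = float(np.linalg.norm(_gauss(x, *popt) - y))
    return GaussianFit(
        location=loc, location_se=loc_se,
        fwhm=FWHM_FACTOR * sigma, fwhm_se=FWHM_FACTOR * sigma_se,
        peak_area=area, peak_area_se=area_se,
        sigma=sigma, sigma_se=sigma_se,
        residual_norm=resid, n_bins=len(x),
    )


def _rebin_density(
    edges: np.ndarray, density: np.ndarray, target_edges: np.ndarray
) -> np.ndarray:
    """Exact piecewise-constant rebinning of a density onto target edges.

    Mass in each source bin is distributed over target bins in proportion
    to interval overlap, so the integral is conserved to rounding.
    """
    target = np.zeros(len(target_edges) - 1)
    widths = np.diff(target_edges)
    for lo, hi, d in zip(edges[:-1], edges[1:], density):
        if d == 0.0:
            continue
        # overlap of [lo, hi) with each target bin
        left = np.clip(target_edges[:-1], lo, hi)
        right = np.clip(target_edges[1:], lo, hi)
        overlap = np.clip(right - left, 0.0, None)
        target += d * overlap / widths
    return target


def subtract_histograms(
    h_treatment: AngularHistogram, h_control: AngularHistogram,
    smoothing_bins: int = 3,
    tail_fraction: float = 0.2,
    threshold_factor: float = 2.0,
) -> SubtractionMap:
    """Subtraction map: treatment density minus control density.

    Both inputs must be unit-normalized with the same bin width.  Grids
    that share edges are differenced directly on the union range (missing
    bins are zero); offset grids are rebinned (exact piecewise-constant
    overlap weighting) onto the treatment grid first.  The integral of
    the difference is zero by conservation of probability mass.

    Extrema are located on a ``smoothing_bins``-point moving average of
    the difference: each maximal run of constant sign contributes its
    largest-|value| bin, kept when it exceeds
    ``threshold_factor x RMS`` of the map's outer ``tail_fraction`` of
    bins (where no real structure is expected).  Reported amplitudes are
    the raw (unsmoothed) differences at the peak bins; exact ties are
    averaged, which keeps peak picking mirror-equivariant.
    """
    for h, name in ((h_treatment, "treatment"), (h_control, "control")):
        if abs(h.integral() - 1.0) > NORM_TOL:
            raise DataError(f"{name} histogram is not unit-normalized")
    w = h_treatment.bin_width
    if abs(h_control.bin_width - w) > 1e-12:
        raise DataError(
            f"incompatible bin widths ({w} vs {h_control.bin_width} mrad): "
            "rebuild both histograms with a common bin width before "
            "subtracting"
        )
    # common grid with the treatment's phase, covering both ranges
    lo = min(h_treatment.bin_edges[0], h_control.bin_edges[0])
    hi = max(h_treatment.bin_edges[-1], h_control.bin_edges[-1])
    n_lo = int(np.ceil((h_treatment.bin_edges[0] - lo) / w - 1e-9))
    n_hi = int(np.ceil((hi - h_treatment.bin_edges[-1]) / w - 1e-9))
    edges = np.concatenate([
        h_treatment.bin_edges[0] - w * np.arange(n_lo, 0, -1),
        h_treatment.bin_edges,
        h_treatment.bin_edges[-1] + w * np.arange(1, n_hi + 1),
    ])

    def on_grid(h: AngularHistogram) -> np.ndarray:
        offset = (h.bin_edges[0] - edges[0]) / w
        if abs(offset - round(offset)) < 1e-9:  # phase-aligned: exact insert
            out = np.zeros(len(edges) - 1)
            i0 = int(round(offset))
            out[i0:i0 + len(h.density)] = h.density
            return out
        return _rebin_density(h.bin_edges, h.density, edges)

    diff = on_grid(h_treatment) - on_grid(h_control)

    if smoothing_bins < 1 or smoothing_bins % 2 == 0:
        raise DataError("smoothing_bins must be a positive odd number")
    # moving average built from symmetric pairs (x[i-k] + x[i+k]) so the
    # result is bitwise identical under grid reversal (out-of-range = 0)
    n = len(diff)
    half = smoothing_bins // 2
    padded = np.concatenate([np.zeros(half), diff, np.zeros(half)])
    smoothed = padded[half:half + n].copy()
    for k in range(1, half + 1):
        smoothed += padded[half - k:half - k + n] + \
            padded[half + k:half + k + n]
    smoothed /= smoothing_bins
    n_tail = max(1, int(round(tail_fraction / 2 * n)))
    tails = np.concatenate([smoothed[:n_tail], smoothed[-n_tail:]])
    threshold = threshold_factor * float(np.sqrt(np.mean(tails**2)))

    centers = 0.5 * (edges[:-1] + edges[1:])
    extrema: list[tuple[float, float]] = []
    sign = np.sign(smoothed)
    run_start = 0
    for i in range(1, n + 1):
        if i == n or sign[i] != sign[run_start]:
            if sign[run_start] != 0:
                seg_abs = np.abs(smoothed[run_start:i])
                peak_val = float(seg_abs.max())
                if peak_val > threshold:
                    # ties (possible in quantized tails) are resolved by
                    # averaging the tied bins, which keeps peak picking
                    # exactly mirror-equivariant
                    tied = np.flatnonzero(seg_abs == peak_val) + run_start
                    extrema.append(
                        (float(np.mean(centers[tied])),
                         float(np.mean(diff[tied])))
                    )
            run_start = i
    return SubtractionMap(
        bin_edges=edges, difference=diff, extrema=extrema,
        smoothing_bins=smoothing_bins, threshold=threshold,
    )
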