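"""Mean squared angular displacement (MSD) estimation and model fitting.

The MSD at lag t is modelled as

    MSD(t) = D_alpha * t**alpha + 2 * beta**2

with ``D_alpha`` the anomalous diffusion coefficient (mrad^2/ms^alpha),
``alpha`` the anomalous exponent (alpha < 1 subdiffusion, alpha > 1
superdiffusion) and ``beta`` (mrad) the per-frame measurement error, which
contributes a constant offset of twice its variance.  Alongside the
nonlinear fit a plain linear slope (mrad^2/ms) over the short-lag region is
reported, which is the single number usually quoted for a recording.

The estimator is the standard single-particle-tracking time-averaged MSD
with overlapping windows, pooled over trajectories with pair-count
weighting — at short spot lifetimes this uses every available displacement
pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import DataError, EmptyEnsembleError, FitError
from .trajectories import TrajectoryEnsemble, split_by_acquisition_half

__all__ = [
    "MSDCurve",
    "MSDFit",
    "LinearSlope",
    "DamageCheck",
    "compute_msd",
    "fit_msd_anomalous",
    "linear_slope",
    "default_linear_fit_range",
    "radiation_damage_check",
]


@dataclass
class MSDCurve:
    """Pooled time-averaged MSD: lag (ms), msd (mrad^2), pair counts."""

    lag: np.ndarray
    msd: np.ndarray
    pair_count: np.ndarray
    axis: str
    n_trajectories: int = 0

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=np.float64)
        self.msd = np.asarray(self.msd, dtype=np.float64)
        self.pair_count = np.asarray(self.pair_count, dtype=np.int64)
        if np.any(self.msd < 0):
            raise DataError("MSD values must be non-negative")
        if np.any(np.diff(self.lag) <= 0):
            raise DataError("lags must be strictly increasing")

    def select(self, fit_range: tuple[float, float] | None) -> np.ndarray:
        """Boolean mask of lags inside [lo, hi] (inclusive); None = all."""
        if fit_range is None:
            return np.ones(len(self.lag), dtype=bool)
        lo, hi = fit_range
        return (self.lag >= lo) & (self.lag <= hi)


@dataclass
class MSDFit:
    """Result of the anomalous-diffusion fit MSD(t) = D t^alpha + 2 beta^2."""

    d_alpha: float
    alpha: float
    beta: float
    d_alpha_se: float
    alpha_se: float
    beta_se: float
    fit_range: tuple[float, float]
    residual_norm: float
    n_points: int
    n_trajectories: int
    success: bool = True
    flags: tuple[str, ...] = ()
    message: str = ""


@dataclass
class LinearSlope:
    """OLS slope of MSD vs lag with free intercept."""

    slope: float  # mrad^2/ms
    slope_se: float
    intercept: float
    fit_range: tuple[float, float]
    n_points: int


@dataclass
class DamageCheck:
    """Radiation-damage diagnostic: MSD slope ratio second/first half."""

    ratio: float
    ci_low: float
    ci_high: float
    slope_first: float
    slope_second: float
    n_first: int
    n_second: int
    n_bootstrap: int


def compute_msd(
    ensemble: TrajectoryEnsemble, axis: str, max_lag_frames: int
) -> MSDCurve:
    """Pooled time-averaged MSD of one angular axis.

    For lag n*dt the estimate is the mean of ``(x(t + n*dt) - x(t))**2``
    over all trajectories and all overlapping start frames, i.e. per-lag
    displacement-pair sums pooled across trajectories and divided by the
    total pair count.  Lags with no pairs are omitted.

    Raises
    ------
    EmptyEnsembleError
        If no trajectory contributes at least one displacement pair.
    """
    if max_lag_frames < 1:
        raise DataError("max_lag_frames must be >= 1")
    if len(ensemble) == 0:
        raise EmptyEnsembleError("cannot compute MSD of an empty ensemble")
    sums = np.zeros(max_lag_frames)
    counts = np.zeros(max_lag_frames, dtype=np.int64)
    for traj in ensemble:
        x = traj.axis_values(axis)
        top = min(max_lag_frames, len(x) - 1)
        for n in range(1, top + 1):
            d = x[n:] - x[:-n]
            sums[n - 1] += np.dot(d, d)
            counts[n - 1] += d.size
    if counts[0] == 0:
        raise EmptyEnsembleError(
            "no displacement pairs: all trajectories shorter than 2 frames"
        )
    keep = counts > 0
    lags = np.arange(1, max_lag_frames + 1) * ensemble.frame_interval
    return MSDCurve(
        lag=lags[keep],
        msd=sums[keep] / counts[keep],
        pair_count=counts[keep],
        axis=axis,
        n_trajectories=len(ensemble),
    )


def _msd_model(t, d_alpha, alpha, beta):
    return d_alpha * t**alpha + 2.0 * beta**2


def fit_msd_anomalous(
    curve: MSDCurve, fit_range: tuple[float, float] | None = None
) -> MSDFit:
    """Weighted nonlinear least-squares fit of the anomalous MSD model.

    Weights are the per-lag pair counts (sigma ~ 1/sqrt(count)).  Bounds:
    D_alpha >= 0, 0 < alpha <= 2, beta >= 0.  Initialisation: beta from
    the short-lag extrapolated intercept ``2*msd[0] - msd[1]``, then
    (D_alpha, alpha) from ordinary least squares of log(msd - 2 beta0^2)
    against log(lag).  On non-convergence the fit is retried from three
    multiplicatively jittered starts; a persistent failure is returned as
    an ``MSDFit`` with ``success=False`` and diagnostics, never as silent
    zeros.
    """
    mask = curve.select(fit_range)
    t = curve.lag[mask]
    y = curve.msd[mask]
    w = curve.pair_count[mask].astype(float)
    if len(t) < 4:
        raise FitError(
            f"anomalous fit needs >= 4 points in range, got {len(t)}"
        )
    rng_used = (float(t[0]), float(t[-1]))

    if np.all(y == 0):
        # motionless, noiseless input: amplitude parameters are zero and
        # the exponent is unidentifiable
        return MSDFit(
            d_alpha=0.0, alpha=1.0, beta=0.0,
            d_alpha_se=0.0, alpha_se=np.inf, beta_se=0.0,
            fit_range=rng_used, residual_norm=0.0,
            n_points=len(t), n_trajectories=curve.n_trajectories,
            success=True, flags=("alpha_unidentifiable",),
            message="all-zero MSD curve: alpha unidentifiable",
        )

    beta0_sq = max(0.0, (2.0 * y[0] - y[1]) / 2.0)
    resid = np.clip(y - 2.0 * beta0_sq, np.max(y) * 1e-9, None)
    slope, intercept = np.polyfit(np.log(t), np.log(resid), 1)
    alpha0 = float(np.clip(slope, 0.05, 2.0))
    d0 = float(np.exp(intercept))
    p0 = np.array([d0, alpha0, np.sqrt(beta0_sq)])

    sigma = 1.0 / np.sqrt(w)
    bounds = ([0.0, 1e-6, 0.0], [np.inf, 2.0, np.inf])
    last_err: Exception | None = None
    jitter_rng = np.random.Generator(np.random.PCG64(0))
    for attempt in range(4):
        start = p0 if attempt == 0 else p0 * np.exp(
            jitter_rng.normal(0.0, 0.3, size=3)
        )
        start = np.clip(start, [0.0, 1e-6, 0.0], [np.inf, 2.0, np.inf])
        try:
            popt, pcov = optimize.curve_fit(
                _msd_model, t, y, p0=start, sigma=sigma,
                bounds=bounds, maxfev=20000,
            )
            perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
            resid_norm = float(
                np.linalg.norm((_msd_model(t, *popt) - y) / sigma)
            )
            return MSDFit(
                d_alpha=float(popt[0]), alpha=float(popt[1]),
                beta=float(popt[2]),
                d_alpha_se=float(perr[0]), alpha_se=float(perr[1]),
                beta_se=float(perr[2]),
                fit_range=rng_used, residual_norm=resid_norm,
                n_points=len(t), n_trajectories=curve.n_trajectories,
            )
        except RuntimeError as exc:  # no convergence; jitter and retry
            last_err = exc
    return MSDFit(
        d_alpha=np.nan, alpha=np.nan, beta=np.nan,
        d_alpha_se=np.nan, alpha_se=np.nan, beta_se=np.nan,
        fit_range=rng_used, residual_norm=np.nan,
        n_points=len(t), n_trajectories=curve.n_trajectories,
        success=False, flags=("no_convergence",),
        message=f"fit failed after 3 jittered restarts: {last_err}",
    )


def default_linear_fit_range(curve: MSDCurve) -> tuple[float, float]:
    """Default short-lag window for the linear slope: lags up to 25% of the
    longest available lag (at least the two shortest lags)."""
    hi = max(0.25 * curve.lag[-1], curve.lag[min(1, len(curve.lag) - 1)])
    return (float(curve.lag[0]), float(hi))


def linear_slope(
    curve: MSDCurve, fit_range: tuple[float, float] | None = None
) -> LinearSlope:
    """Ordinary least-squares slope of MSD vs lag with free intercept.

    This is the plain "slope of the MSD curve" in mrad^2/ms quoted for a
    recording; by construction it is invariant under adding a constant
    (e.g. the noise floor 2 beta^2) to the curve.
    """
    if fit_range is None:
        fit_range = default_linear_fit_range(curve)
    mask = curve.select(fit_range)
    t = curve.lag[mask]
    y = curve.msd[mask]
    if len(t) < 2:
        raise FitError(
            f"linear slope needs >= 2 points in range {fit_range}, "
            f"got {len(t)}"
        )
    res = stats.linregress(t, y)
    return LinearSlope(
        slope=float(res.slope),
        slope_se=float(res.stderr) if len(t) > 2 else np.nan,
        intercept=float(res.intercept),
        fit_range=(float(t[0]), float(t[-1])),
        n_points=len(t),
    )


def radiation_damage_check(
    ensemble: TrajectoryEnsemble,
    axis: str = "chi",
    max_lag_frames: int | None = None,
    fit_range: tuple[float, float] | None = None,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> DamageCheck:
    """Compare MSD slopes of the first and second acquisition halves.

    Accumulating X-ray damage would inflate (or deaden) motion over the
    recording; a slope ratio second/first compatible with 1 is the
    no-damage diagnostic.  The 95% confidence interval is a percentile
    bootstrap over trajectories, resampled within each half.
    """
    first, second = split_by_acquisition_half(ensemble)
    if len(first) == 0 or len(second) == 0:
        raise EmptyEnsembleError(
            "radiation damage check needs trajectories in both halves"
        )
    if max_lag_frames is None:
        max_lag_frames = max(
            2, min(ensemble.n_frames_nominal // 4, 100)
        )

    def half_slope(half: TrajectoryEnsemble) -> float:
        curve = compute_msd(half, axis, max_lag_frames)
        return linear_slope(curve, fit_range).slope

    s1 = half_slope(first)
    s2 = half_slope(second)
    rng = np.random.Generator(np.random.PCG64(seed))
    ratios = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        f_res = first.replace(
            _resample(first.trajectories, rng), bootstrap=b
        )
        s_res = second.replace(
            _resample(second.trajectories, rng), bootstrap=b
        )
        ratios[b] = half_slope(s_res) / half_slope(f_res)
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return DamageCheck(
        ratio=s2 / s1, ci_low=float(lo), ci_high=float(hi),
        slope_first=s1, slope_second=s2,
        n_first=len(first), n_second=len(second),
        n_bootstrap=n_bootstrap,
    )


def _resample(trajectories: list, rng: np.random.Generator) -> list:
    idx = rng.integers(0, len(trajectories), size=len(trajectories))
    out = []
    for k, i in enumerate(idx):
        t = trajectories[i]
        # clone with a unique id to satisfy ensemble invariants
        out.append(
            type(t)(
                id=f"b{k}:{t.id}",
                frame_index=t.frame_index,
                time=t.time,
                theta=t.theta,
                chi=t.chi,
                source_ring=t.source_ring,
            )
        )
    return out
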