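"""Synthetic angular-trajectory generator.

Emulates the statistical structure a DXT analysis assumes: each labelled
nanocrystal performs rotational (fractional) Brownian motion in tilt
``theta`` and twist ``chi``, the twist optionally carrying a constant
angular drift (a rotational bias), and the spot stays visible only while
the tilt remains inside the Bragg acceptance window — so faster particles
produce shorter-lived spots, which is the premise behind lifetime
filtering.

The latent path per axis satisfies ``Var[x(t) - x(0)] = m * t**alpha``
where ``m`` (mrad^2/ms) is the *observable* MSD coefficient — the quantity
an MSD analysis reports as a slope — rather than a bare diffusion
constant; this keeps simulation settings directly comparable with
analysis output and sidesteps factor-of-two conventions.  ``alpha = 1``
gives ordinary Brownian motion (iid Gaussian increments); ``alpha != 1``
gives fractional Gaussian noise with Hurst exponent ``H = alpha/2``,
generated with the exact increment covariance via Cholesky factorisation.
Measurement noise N(0, beta^2) is added per frame per axis, producing the
``2*beta**2`` intercept of the MSD model.

Determinism: a ``(config, seed)`` pair fully determines the output; every
particle draws from its own spawned substream, so the ensemble is
reproducible bit-exactly and independent of evaluation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import ConfigError
from .trajectories import Trajectory, TrajectoryEnsemble

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_latent_path",
    "apply_observation_model",
    "simulate_ensemble",
    "DEFAULT_WINDOW_HALFWIDTH_MRAD",
]

#: Default Bragg-acceptance halfwidth (mrad) applied to the tilt axis.
#: Calibrated (scripts/calibrate_window.py) so that at m_theta = 10
#: mrad^2/ms and 0.1 ms/frame the median spot lifetime falls in the
#: 2.5-4.0 ms medium class.  A modelling choice, not an instrument claim.
DEFAULT_WINDOW_HALFWIDTH_MRAD = 6.0


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated recording.

    ``msd_slope_theta`` / ``msd_slope_chi`` are the per-axis MSD
    coefficients m in mrad^2/ms^alpha; ``drift_chi`` is a signed constant
    twist rate in mrad/ms (positive = counterclockwise as seen from the
    cytoplasmic side); ``beta`` is the per-frame measurement noise sigma
    in mrad; ``theta_window_halfwidth`` is the Bragg acceptance halfwidth
    in mrad (``inf`` disables spot loss).
    """

    n_particles: int = 1000
    frame_interval: float = 0.1  # ms
    n_frames: int = 450
    msd_slope_theta: float = 10.0  # mrad^2/ms^alpha
    msd_slope_chi: float = 10.0
    alpha: float = 1.0
    beta: float = 0.5  # mrad
    drift_chi: float = 0.0  # mrad/ms, + = CCW
    theta_window_halfwidth: float = DEFAULT_WINDOW_HALFWIDTH_MRAD  # mrad
    seed: int = 0
    condition_label: str = "simulated"

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ConfigError("n_particles must be >= 1")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0")
        if self.msd_slope_theta < 0 or self.msd_slope_chi < 0:
            raise ConfigError("MSD slopes must be >= 0")
        if self.beta < 0:
            raise ConfigError("beta must be >= 0")
        if not 0 < self.alpha <= 2:
            raise ConfigError("alpha must be in (0, 2]")
        if self.theta_window_halfwidth <= 0:
            raise ConfigError("theta_window_halfwidth must be > 0")


@dataclass
class GroundTruth:
    """Per-particle truth accompanying a simulated ensemble."""

    config: SimulationConfig
    true_lifetime_frames: np.ndarray  # visible run length, all particles
    observed_ids: list[str]  # ids that survived the >= 2 frame cut
    drift_label: str = ""  # "ccw" / "cw" / "none"

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "true_lifetime_frames": self.true_lifetime_frames.tolist(),
            "observed_ids": list(self.observed_ids),
            "drift_label": self.drift_label,
        }


# Cholesky factors of the fGn increment correlation are expensive for long
# recordings; cache by (n_increments, alpha).
_FGN_CHOLESKY_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _fgn_cholesky(n: int, alpha: float) -> np.ndarray:
    """Lower Cholesky factor of the unit-fGn autocovariance (n increments).

    gamma(k) = 0.5 * (|k+1|^a - 2|k|^a + |k-1|^a) with a = alpha = 2H is
    the autocovariance of unit-variance fractional Gaussian noise.
    """
    key = (n, float(alpha))
    cached = _FGN_CHOLESKY_CACHE.get(key)
    if cached is not None:
        return cached
    k = np.arange(n, dtype=np.float64)
    gamma = 0.5 * (
        np.abs(k + 1) ** alpha - 2 * np.abs(k) ** alpha + np.abs(k - 1) ** alpha
    )
    from scipy.linalg import toeplitz, cholesky

    cov = toeplitz(gamma)
    L = cholesky(cov, lower=True)
    _FGN_CHOLESKY_CACHE[key] = L
    return L


def _increments(
    rng: np.random.Generator, config: SimulationConfig, slope: float
) -> np.ndarray:
    """Draw n_frames-1 latent increments with Var[sum over t] = slope*t^alpha."""
    n = config.n_frames - 1
    z = rng.standard_normal(n)
    if slope == 0.0:
        return np.zeros(n)
    scale = np.sqrt(slope) * config.frame_interval ** (config.alpha / 2.0)
    if config.alpha == 1.0:
        return scale * z
    return scale * (_fgn_cholesky(n, config.alpha) @ z)


def simulate_latent_path(
    config: SimulationConfig, particle_rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Latent (noise-free) theta(t), chi(t) for one particle.

    Both start at 0; chi additionally accumulates ``drift_chi * t``.
    Draw order (theta increments, then chi increments) is part of the
    reproducibility contract.
    """
    t = np.arange(config.n_frames) * config.frame_interval
    theta = np.concatenate(
        ([0.0], np.cumsum(_increments(particle_rng, config, config.msd_slope_theta)))
    )
    chi = np.concatenate(
        ([0.0], np.cumsum(_increments(particle_rng, config, config.msd_slope_chi)))
    )
    chi = chi + config.drift_chi * t
    return theta, chi


def apply_observation_model(
    theta: np.ndarray,
    chi: np.ndarray,
    config: SimulationConfig,
    particle_rng: np.random.Generator,
    particle_id: str = "p0",
) -> tuple[Trajectory | None, int]:
    """Turn a latent path into the observed spot trajectory.

    The spot is visible while the latent tilt stays within
    ``theta_window_halfwidth`` of its initial value (the window is centred
    on each particle's own starting tilt: spots are by construction visible
    when they appear; twist motion never terminates a spot).  The first
    contiguous visible run becomes the observed trajectory; measurement
    noise N(0, beta^2) is added per frame per axis.  Runs shorter than two
    frames are discarded (a single-frame blink cannot be tracked).

    Returns ``(trajectory_or_None, visible_run_length_in_frames)``.
    """
    n = len(theta)
    if n < 2:
        raise ConfigError("latent path must be longer than 1 frame")
    outside = np.abs(theta - theta[0]) > config.theta_window_halfwidth
    exits = np.flatnonzero(outside)
    n_visible = int(exits[0]) if exits.size else n
    # noise drawn for the full nominal length keeps the particle stream
    # layout independent of the window setting
    noise_theta = particle_rng.standard_normal(n) * config.beta
    noise_chi = particle_rng.standard_normal(n) * config.beta
    if n_visible < 2:
        return None, n_visible
    sl = slice(0, n_visible)
    time = np.arange(n_visible) * config.frame_interval
    traj = Trajectory(
        id=particle_id,
        frame_index=np.arange(n_visible),
        time=time,
        theta=theta[sl] + noise_theta[sl],
        chi=chi[sl] + noise_chi[sl],
    )
    return traj, n_visible


def simulate_ensemble(
    config: SimulationConfig,
) -> tuple[TrajectoryEnsemble, GroundTruth]:
    """Simulate a full recording: n_particles latent paths, observed spots.

    Each particle uses its own substream spawned from ``config.seed``.
    Emits a warning (and an empty ensemble) if no particle survives the
    two-frame visibility cut.
    """
    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(config.n_particles)
    width = max(4, len(str(config.n_particles - 1)))
    trajectories: list[Trajectory] = []
    lifetimes = np.empty(config.n_particles, dtype=np.int64)
    observed_ids: list[str] = []
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        theta, chi = simulate_latent_path(config, rng)
        pid = f"p{i:0{width}d}"
        traj, n_visible = apply_observation_model(theta, chi, config, rng, pid)
        lifetimes[i] = n_visible
        if traj is not None:
            trajectories.append(traj)
            observed_ids.append(pid)
    if not trajectories:
        warnings.warn(
            "simulate_ensemble: no trajectory survived the visibility "
            "window; returning an empty ensemble",
            stacklevel=2,
        )
    if config.drift_chi > 0:
        drift_label = "ccw"
    elif config.drift_chi < 0:
        drift_label = "cw"
    else:
        drift_label = "none"
    ensemble = TrajectoryEnsemble(
        trajectories=trajectories,
        frame_interval=config.frame_interval,
        n_frames_nominal=config.n_frames,
        condition_label=config.condition_label,
        meta={"simulated": True, "seed": config.seed},
    )
    truth = GroundTruth(
        config=config,
        true_lifetime_frames=lifetimes,
        observed_ids=observed_ids,
        drift_label=drift_label,
    )
    return ensemble, truth
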