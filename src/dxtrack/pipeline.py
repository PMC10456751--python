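"""Run orchestration: simulate/load -> lifetime-filter -> analyze -> report.

A run is described by a :class:`RunConfig` (usually loaded from YAML):
named conditions (each an input trajectory table or an inline simulation
block), the lifetime classes to analyze, fit and histogram settings, and
the condition pairs to subtract.  ``run_pipeline`` executes every
condition x lifetime-class cell — MSD curve, anomalous fit, linear slope,
rotational bias, displacement histogram with Gaussian fit — plus the
per-condition radiation-damage check and the configured subtraction maps,
and writes every artifact with provenance (resolved config, its hash, the
seed, package version).

Stage failures are recorded per cell and do not abort the rest of the run;
partial results are preserved and the error report names the failing
stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .directional import (
    displacement_histogram,
    fit_gaussian,
    rotational_bias,
    subtract_histograms,
)
from .exceptions import ConfigError, DXTError
from .lifetime import STANDARD_CLASSES, LifetimeClass, filter_by_lifetime
from .msd import (
    compute_msd,
    fit_msd_anomalous,
    linear_slope,
    radiation_damage_check,
)
from .simulate import SimulationConfig, simulate_ensemble
from .trajectories import (
    TrajectoryEnsemble,
    read_trajectories,
    write_trajectories,
)

__all__ = [
    "RunConfig",
    "ConditionSpec",
    "run_pipeline",
    "make_fixtures",
    "load_config",
]

logger = logging.getLogger(__name__)


@dataclass
class ConditionSpec:
    """One experimental condition: a table on disk or a simulation block."""

    name: str
    table: str | None = None
    simulation: dict | None = None

    def __post_init__(self) -> None:
        if (self.table is None) == (self.simulation is None):
            raise ConfigError(
                f"condition {self.name!r}: exactly one of 'table' or "
                "'simulation' must be given"
            )


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    conditions: list[ConditionSpec]
    frame_interval: float = 0.1  # ms; applies to table inputs
    axis: str = "chi"
    lifetime_classes: list[LifetimeClass] = field(
        default_factory=lambda: list(STANDARD_CLASSES)
    )
    max_lag_frames: int | None = None
    linear_fit_range: tuple[float, float] | None = None
    anomalous_fit_range: tuple[float, float] | None = None
    histogram_bin_width: float = 0.25  # mrad
    n_bootstrap: int = 1000
    seed: int = 0
    subtraction_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigError("at least one condition is required")
        names = [c.name for c in self.conditions]
        if len(names) != len(set(names)):
            raise ConfigError("condition names must be unique")
        if self.axis not in ("theta", "chi"):
            raise ConfigError("axis must be 'theta' or 'chi'")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0")
        if self.histogram_bin_width <= 0:
            raise ConfigError("histogram_bin_width must be > 0")
        for a, b in self.subtraction_pairs:
            for name in (a, b):
                if name not in names:
                    raise ConfigError(
                        f"subtraction pair references unknown condition "
                        f"{name!r}"
                    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    conditions = [
        ConditionSpec(name=name, **spec)
        for name, spec in raw.get("conditions", {}).items()
    ]
    classes = [
        LifetimeClass(
            label=c["label"],
            min_ms=float(c["min_ms"]),
            max_ms=float(c.get("max_ms", math.inf)),
        )
        for c in raw.get("lifetime_classes", [])
    ] or list(STANDARD_CLASSES)
    pairs = [tuple(p) for p in raw.get("subtraction_pairs", [])]

    def _range(key):
        v = raw.get(key)
        return None if v is None else (float(v[0]), float(v[1]))

    return RunConfig(
        conditions=conditions,
        frame_interval=float(raw.get("frame_interval_ms", 0.1)),
        axis=raw.get("axis", "chi"),
        lifetime_classes=classes,
        max_lag_frames=raw.get("max_lag_frames"),
        linear_fit_range=_range("linear_fit_range_ms"),
        anomalous_fit_range=_range("anomalous_fit_range_ms"),
        histogram_bin_width=float(raw.get("histogram_bin_width_mrad", 0.25)),
        n_bootstrap=int(raw.get("n_bootstrap", 1000)),
        seed=int(raw.get("seed", 0)),
        subtraction_pairs=pairs,
    )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(_as_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: _as_jsonable(v)
            for k, v in dataclasses.asdict(obj).items()
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


def _load_condition(
    spec: ConditionSpec, config: RunConfig
) -> TrajectoryEnsemble:
    if spec.table is not None:
        return read_trajectories(
            spec.table, config.frame_interval, condition_label=spec.name
        )
    sim_kwargs = dict(spec.simulation or {})
    sim_kwargs.setdefault("seed", config.seed)
    sim_kwargs.setdefault("condition_label", spec.name)
    ensemble, _ = simulate_ensemble(SimulationConfig(**sim_kwargs))
    return ensemble


def _analyze_cell(
    ensemble: TrajectoryEnsemble, config: RunConfig, cell_seed: int
) -> dict:
    """All statistics of one condition x lifetime-class cell."""
    max_lag = config.max_lag_frames
    if max_lag is None:
        max_lag = max(2, min(ensemble.n_frames_nominal // 4, 100))
    curve = compute_msd(ensemble, config.axis, max_lag)
    fit = fit_msd_anomalous(curve, config.anomalous_fit_range)
    slope = linear_slope(curve, config.linear_fit_range)
    bias = rotational_bias(
        ensemble, n_bootstrap=config.n_bootstrap, seed=cell_seed,
        max_lag_frames=max_lag,
    )
    hist = displacement_histogram(
        ensemble, axis=config.axis, bin_width=config.histogram_bin_width
    )
    try:
        gauss = _as_jsonable(fit_gaussian(hist))
    except DXTError as exc:
        gauss = {"error": str(exc)}
    return {
        "n_trajectories": len(ensemble),
        "lifetime_meta": _as_jsonable(ensemble.meta),
        "msd_curve": {
            "lag_ms": curve.lag.tolist(),
            "msd_mrad2": curve.msd.tolist(),
            "pair_count": curve.pair_count.tolist(),
        },
        "anomalous_fit": _as_jsonable(fit),
        "linear_slope_mrad2_per_ms": _as_jsonable(slope),
        "bias": _as_jsonable(bias),
        "histogram": {
            "bin_edges_mrad": hist.bin_edges.tolist(),
            "density_per_mrad": hist.density.tolist(),
            "statistic": hist.statistic,
        },
        "gaussian_fit": gauss,
        "_histogram_obj": hist,  # stripped before serialization
    }


def run_pipeline(
    config: RunConfig, out_dir, force: bool = False
) -> dict:
    """Execute a full run and write the artifact bundle to ``out_dir``.

    Refuses to write into a directory that already holds a run unless
    ``force`` is set.  Returns the in-memory bundle (conditions x classes
    -> statistics, subtraction maps, damage checks, provenance, errors).
    """
    out = Path(out_dir)
    marker = out / "provenance.json"
    if marker.exists() and not force:
        raise ConfigError(
            f"{out} already contains a run; pass force=True (--force) to "
            "overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)

    bundle: dict = {"conditions": {}, "subtractions": {}, "damage": {},
                    "errors": []}
    histograms: dict[tuple[str, str], object] = {}
    for ci, spec in enumerate(config.conditions):
        try:
            ensemble = _load_condition(spec, config)
        except DXTError as exc:
            bundle["errors"].append(
                {"stage": "load", "condition": spec.name, "error": str(exc)}
            )
            continue
        logger.info("condition %s: %d trajectories", spec.name, len(ensemble))
        cond_res: dict = {}
        for ki, cls in enumerate(config.lifetime_classes):
            cell = f"{spec.name}/{cls.label}"
            try:
                sub = filter_by_lifetime(ensemble, cls)
                logger.info(
                    "cell %s: retained %d/%d", cell, len(sub), len(ensemble)
                )
                res = _analyze_cell(
                    sub, config, cell_seed=(config.seed + 1000 * ci + ki)
                )
                histograms[(spec.name, cls.label)] = res.pop("_histogram_obj")
                cond_res[cls.label] = res
            except DXTError as exc:
                bundle["errors"].append(
                    {"stage": "analyze", "cell": cell, "error": str(exc)}
                )
        try:
            dmg = radiation_damage_check(
                ensemble, axis=config.axis,
                n_bootstrap=min(config.n_bootstrap, 200),
                seed=config.seed + ci,
            )
            bundle["damage"][spec.name] = _as_jsonable(dmg)
        except DXTError as exc:
            bundle["errors"].append(
                {"stage": "damage_check", "condition": spec.name,
                 "error": str(exc)}
            )
        bundle["conditions"][spec.name] = cond_res

    for treat, ctrl in config.subtraction_pairs:
        for cls in config.lifetime_classes:
            key = f"{treat}-{ctrl}/{cls.label}"
            h_t = histograms.get((treat, cls.label))
            h_c = histograms.get((ctrl, cls.label))
            if h_t is None or h_c is None:
                bundle["errors"].append(
                    {"stage": "subtraction", "cell": key,
                     "error": "missing histogram for one side"}
                )
                continue
            try:
                smap = subtract_histograms(h_t, h_c)
                bundle["subtractions"][key] = {
                    "bin_edges_mrad": smap.bin_edges.tolist(),
                    "difference_per_mrad": smap.difference.tolist(),
                    "extrema": [
                        {"position_mrad": p, "amplitude_per_mrad": a}
                        for p, a in smap.extrema
                    ],
                    "threshold_per_mrad": smap.threshold,
                }
            except DXTError as exc:
                bundle["errors"].append(
                    {"stage": "subtraction", "cell": key, "error": str(exc)}
                )

    bundle["provenance"] = {
        "config": _as_jsonable(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    with open(out / "results.json", "w") as fh:
        json.dump(
            {k: v for k, v in bundle.items() if k != "provenance"},
            fh, indent=2,
        )
    with open(marker, "w") as fh:
        json.dump(bundle["provenance"], fh, indent=2)
    return bundle


# --------------------------------------------------------------------------
# documented fixture set


def _derived_seed(seed: int, k: int) -> int:
    """Independent child seed below 2**31, stable in (seed, k)."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31)


def _merge(
    parts: list[tuple[str, TrajectoryEnsemble]], label: str
) -> TrajectoryEnsemble:
    base = parts[0][1]
    trajectories = []
    for prefix, ens in parts:
        for t in ens:
            trajectories.append(
                dataclasses.replace(t, id=f"{prefix}_{t.id}")
            )
    return TrajectoryEnsemble(
        trajectories=trajectories,
        frame_interval=base.frame_interval,
        n_frames_nominal=base.n_frames_nominal,
        condition_label=label,
    )


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Generate the documented synthetic fixture set.

    Four ensembles, each a trajectory table plus a ground-truth JSON:

    * ``null`` — no drift, homogeneous speed (bias null calibration),
    * ``biased`` — +0.2 mrad/ms twist drift (bias detection),
    * ``heterogeneous`` — equal mix of slow (5) and fast (40 mrad^2/ms)
      particles (lifetime-filtering tests),
    * ``slow_recording`` — 12.5 ms/frame x 5000 frames at 0.04 mrad^2/ms
      (slow-motion recording geometry).

    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "fixtures": {}}

    def emit(name: str, ensemble: TrajectoryEnsemble, truth: dict) -> None:
        table = out / f"{name}.csv"
        write_trajectories(ensemble, table)
        truth_path = out / f"{name}.truth.json"
        with open(truth_path, "w") as fh:
            json.dump(_as_jsonable(truth), fh, indent=2)
        manifest["fixtures"][name] = {
            "table": table.name,
            "ground_truth": truth_path.name,
            "n_trajectories": len(ensemble),
            "frame_interval_ms": ensemble.frame_interval,
        }

    null_cfg = SimulationConfig(
        n_particles=500, seed=_derived_seed(seed, 0), condition_label="null"
    )
    ens, truth = simulate_ensemble(null_cfg)
    emit("null", ens, truth.to_dict())

    biased_cfg = dataclasses.replace(
        null_cfg, drift_chi=0.2, seed=_derived_seed(seed, 1),
        condition_label="biased",
    )
    ens, truth = simulate_ensemble(biased_cfg)
    emit("biased", ens, truth.to_dict())

    slow_part = SimulationConfig(
        n_particles=250, msd_slope_theta=5.0, msd_slope_chi=5.0,
        seed=_derived_seed(seed, 2), condition_label="heterogeneous",
    )
    fast_part = dataclasses.replace(
        slow_part, msd_slope_theta=40.0, msd_slope_chi=40.0,
        seed=_derived_seed(seed, 3),
    )
    ens_slow, truth_slow = simulate_ensemble(slow_part)
    ens_fast, truth_fast = simulate_ensemble(fast_part)
    merged = _merge(
        [("slow", ens_slow), ("fast", ens_fast)], "heterogeneous"
    )
    emit("heterogeneous", merged, {
        "components": {
            "slow": truth_slow.to_dict(),
            "fast": truth_fast.to_dict(),
        },
        "speed_label_by_prefix": {"slow": 5.0, "fast": 40.0},
    })

    slow_rec_cfg = SimulationConfig(
        n_particles=100, frame_interval=12.5, n_frames=5000,
        msd_slope_theta=0.04, msd_slope_chi=0.04, beta=0.5,
        seed=_derived_seed(seed, 4), condition_label="slow_recording",
    )
    ens, truth = simulate_ensemble(slow_rec_cfg)
    emit("slow_recording", ens, truth.to_dict())

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
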