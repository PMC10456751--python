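"""Angular-trajectory data model and tabular I/O.

A DXT recording yields, per diffraction spot, a short time series of the
nanocrystal orientation expressed as two angles: tilt ``theta`` and twist
``chi``, both in milliradians.  A :class:`Trajectory` holds one such series;
a :class:`TrajectoryEnsemble` holds every trajectory of one experimental
condition together with the acquisition metadata (frame interval, nominal
recording length).

The on-disk format is a delimited UTF-8 text table (comma or tab,
auto-detected) with header

    ``id,frame,time_ms,theta_mrad,chi_mrad[,ring]``

Frame indices are 0-based and consecutive within a trajectory.  A gap in the
frame sequence terminates the trajectory at read time and the remainder is
re-emitted as a new trajectory (suffix ``#1``, ``#2`` ...): a diffraction
spot that disappears and re-appears is, for lifetime purposes, a new spot,
because the lifetime is the duration of *uninterrupted* visibility.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError

__all__ = [
    "Trajectory",
    "TrajectoryEnsemble",
    "read_trajectories",
    "write_trajectories",
    "split_by_acquisition_half",
]

_REQUIRED_COLUMNS = ("id", "frame", "time_ms", "theta_mrad", "chi_mrad")

#: Absolute tolerance (ms) when checking that successive sample times differ
#: by exactly one frame interval.
TIME_STEP_TOL_MS = 1e-9


@dataclass
class Trajectory:
    """Angular time series of a single diffraction spot.

    Parameters
    ----------
    id
        Unique identifier within its ensemble.
    frame_index
        0-based, consecutive integer frame numbers.
    time
        Sample times in ms, strictly increasing with a constant step.
    theta, chi
        Tilt and twist angles in mrad, same length as ``time``.
    source_ring
        Optional label of the powder ring the spot was assigned to,
        e.g. ``"Au(111)"``.
    """

    id: str
    frame_index: np.ndarray
    time: np.ndarray
    theta: np.ndarray
    chi: np.ndarray
    source_ring: str | None = None

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=np.float64)
        self.theta = np.asarray(self.theta, dtype=np.float64)
        self.chi = np.asarray(self.chi, dtype=np.float64)
        n = len(self.time)
        if n < 2:
            raise DataError(f"trajectory {self.id!r}: length {n} < 2")
        for name in ("frame_index", "theta", "chi"):
            if len(getattr(self, name)) != n:
                raise DataError(
                    f"trajectory {self.id!r}: field {name} has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )
        if np.any(np.diff(self.frame_index) != 1):
            raise DataError(
                f"trajectory {self.id!r}: frame indices not consecutive"
            )
        if np.any(np.diff(self.time) <= 0):
            raise DataError(
                f"trajectory {self.id!r}: time not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def axis_values(self, axis: str) -> np.ndarray:
        """Return the angular series of the requested axis ('theta'|'chi')."""
        if axis == "theta":
            return self.theta
        if axis == "chi":
            return self.chi
        raise ValueError(f"axis must be 'theta' or 'chi', got {axis!r}")

    def mirrored(self, axis: str = "chi") -> "Trajectory":
        """Copy with the chosen angular axis sign-flipped (handedness flip)."""
        theta = -self.theta if axis == "theta" else self.theta.copy()
        chi = -self.chi if axis == "chi" else self.chi.copy()
        return Trajectory(
            id=self.id,
            frame_index=self.frame_index.copy(),
            time=self.time.copy(),
            theta=theta,
            chi=chi,
            source_ring=self.source_ring,
        )


@dataclass
class TrajectoryEnsemble:
    """All trajectories of one condition plus acquisition metadata.

    ``meta`` is free-form provenance (e.g. lifetime-class label and
    retained/total counts after filtering); analysis code only reads it.
    """

    trajectories: list[Trajectory]
    frame_interval: float  # ms
    n_frames_nominal: int
    condition_label: str = ""
    axis_info: str = "theta=tilt, chi=twist, mrad"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise DataError("frame_interval must be > 0")
        ids = [t.id for t in self.trajectories]
        if len(ids) != len(set(ids)):
            raise DataError("trajectory ids are not unique")
        for t in self.trajectories:
            if len(t) > self.n_frames_nominal:
                raise DataError(
                    f"trajectory {t.id!r} longer ({len(t)}) than nominal "
                    f"recording length ({self.n_frames_nominal})"
                )
            step = np.diff(t.time)
            if np.any(np.abs(step - self.frame_interval) > TIME_STEP_TOL_MS):
                raise DataError(
                    f"trajectory {t.id!r}: time step deviates from the "
                    f"frame interval {self.frame_interval} ms"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def replace(self, trajectories: list[Trajectory], **meta) -> "TrajectoryEnsemble":
        """New ensemble with the same acquisition metadata, new trajectories."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return TrajectoryEnsemble(
            trajectories=trajectories,
            frame_interval=self.frame_interval,
            n_frames_nominal=self.n_frames_nominal,
            condition_label=self.condition_label,
            axis_info=self.axis_info,
            meta=new_meta,
        )

    def mirrored(self, axis: str = "chi") -> "TrajectoryEnsemble":
        return self.replace([t.mirrored(axis) for t in self.trajectories],
                            mirrored_axis=axis)


def read_trajectories(
    path,
    frame_interval: float,
    n_frames_nominal: int | None = None,
    condition_label: str = "",
) -> TrajectoryEnsemble:
    """Read a trajectory table into an ensemble.

    The table must have a header with at least the columns
    ``id, frame, time_ms, theta_mrad, chi_mrad``; an optional ``ring``
    column carries the powder-ring assignment.  Comma and tab delimiters
    are auto-detected.  Rows are grouped by ``id`` (file order of first
    appearance preserved) and sorted by frame within each id.  Rows with
    missing required values are rejected with row-numbered diagnostics.

    Parameters
    ----------
    frame_interval
        Acquisition frame interval in ms; every within-trajectory time step
        must equal it to within ``TIME_STEP_TOL_MS``.
    n_frames_nominal
        Nominal recording length in frames.  Defaults to the longest
        trajectory found.

    Raises
    ------
    FormatError
        Missing required columns.
    DataError
        Non-monotonic or inconsistent times within an id (the message
        names the id), or no valid trajectory in the file.
    """
    if frame_interval <= 0:
        raise DataError("frame_interval must be > 0")
    try:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        table = pd.read_csv(
            path, sep=sep, dtype={"id": str},
            float_precision="round_trip",
        )
    except (pd.errors.EmptyDataError, StopIteration) as exc:
        raise FormatError(f"{path}: empty file or no header") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )

    bad = table.index[
        table[list(_REQUIRED_COLUMNS)].isna().any(axis=1)
    ].tolist()
    if bad:
        rows = ", ".join(str(i + 2) for i in bad)  # +2: header + 1-based
        warnings.warn(
            f"{path}: rejected {len(bad)} malformed row(s) at line(s) {rows}",
            stacklevel=2,
        )
        table = table.drop(index=bad)

    has_ring = "ring" in table.columns
    trajectories: list[Trajectory] = []
    for spot_id, group in table.groupby("id", sort=False):
        group = group.sort_values("frame")
        frames = group["frame"].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) == 0):
            raise DataError(f"id {spot_id!r}: duplicate frame index")
        times = group["time_ms"].to_numpy(dtype=np.float64)
        if np.any(np.diff(times) <= 0):
            raise DataError(f"id {spot_id!r}: time not strictly increasing")
        # a frame gap ends the visibility run: split into segments
        cut = np.flatnonzero(np.diff(frames) != 1) + 1
        segments = np.split(np.arange(len(frames)), cut)
        for k, seg in enumerate(segments):
            if len(seg) < 2:
                continue
            seg_id = spot_id if k == 0 else f"{spot_id}#{k}"
            seg_times = times[seg]
            if np.any(
                np.abs(np.diff(seg_times) - frame_interval) > TIME_STEP_TOL_MS
            ):
                raise DataError(
                    f"id {seg_id!r}: time step inconsistent with frame "
                    f"interval {frame_interval} ms"
                )
            ring = None
            if has_ring:
                ring_vals = group["ring"].iloc[seg]
                if not ring_vals.isna().all():
                    ring = str(ring_vals.iloc[0])
            trajectories.append(
                Trajectory(
                    id=str(seg_id),
                    frame_index=np.arange(len(seg), dtype=np.int64),
                    time=seg_times,
                    theta=group["theta_mrad"].to_numpy(dtype=np.float64)[seg],
                    chi=group["chi_mrad"].to_numpy(dtype=np.float64)[seg],
                    source_ring=ring,
                )
            )
    if n_frames_nominal is None:
        n_frames_nominal = max((len(t) for t in trajectories), default=2)
    return TrajectoryEnsemble(
        trajectories=trajectories,
        frame_interval=frame_interval,
        n_frames_nominal=n_frames_nominal,
        condition_label=condition_label,
    )


def write_trajectories(ensemble: TrajectoryEnsemble, path) -> None:
    """Write an ensemble as a CSV trajectory table.

    Floats are written with shortest round-tripping repr, so
    ``read_trajectories(write_trajectories(e))`` reproduces every numeric
    field bit-exactly.  The optional ``ring`` column is emitted only when
    at least one trajectory carries a ring label.  An empty ensemble
    produces a header-only file.
    """
    any_ring = any(t.source_ring is not None for t in ensemble)
    columns = ["id", "frame", "time_ms", "theta_mrad", "chi_mrad"]
    if any_ring:
        columns.append("ring")
    frames_out = []
    for t in ensemble:
        data = {
            "id": t.id,
            "frame": t.frame_index,
            "time_ms": t.time,
            "theta_mrad": t.theta,
            "chi_mrad": t.chi,
        }
        if any_ring:
            data["ring"] = t.source_ring if t.source_ring is not None else ""
        frames_out.append(pd.DataFrame(data))
    if frames_out:
        out = pd.concat(frames_out, ignore_index=True)
    else:
        out = pd.DataFrame(columns=columns)
    out.to_csv(path, index=False, columns=columns)


def split_by_acquisition_half(
    ensemble: TrajectoryEnsemble,
) -> tuple[TrajectoryEnsemble, TrajectoryEnsemble]:
    """Partition an ensemble into first and second acquisition halves.

    Used by the radiation-damage check: a slope change between the halves
    flags beam damage accumulating over the recording.  Acquisition order
    is the stored trajectory order (file order for read ensembles, since
    per-spot wall clocks are not recorded).  For odd counts the first half
    receives the extra trajectory.
    """
    n = len(ensemble)
    n_first = math.ceil(n / 2)
    first = ensemble.replace(ensemble.trajectories[:n_first],
                             acquisition_half="first")
    second = ensemble.replace(ensemble.trajectories[n_first:],
                              acquisition_half="second")
    return first, second
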