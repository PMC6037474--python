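"""Domain types and delimited-text I/O for single-particle trajectory data.

The on-disk dialect is a comma-delimited UTF-8 table with the mandatory
header ``track_id,frame,t_s,x_um,y_um``.  Coordinates are planar positions
in micrometres in image space; frame indices are 0-based.  There is no
universal SPT interchange format, so :func:`from_dataframe` acts as an
import shim: any table with recognisable track/frame/position columns can
be mapped onto this dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionSettings",
    "Localization",
    "Trajectory",
    "TrajectoryDataset",
    "TrajectoryFormatError",
    "read_trajectory_table",
    "write_trajectory_table",
    "split_on_gaps",
    "from_dataframe",
]

#: Sentinel for "no gap limit" in :func:`split_on_gaps`.
NO_GAP_LIMIT = math.inf

TABLE_COLUMNS = ("track_id", "frame", "t_s", "x_um", "y_um")


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory table violates the format contract."""


@dataclass(frozen=True)
class AcquisitionSettings:
    """Imaging and tracking parameters attached to a trajectory dataset.

    Parameters
    ----------
    frame_interval_s
        Time between successive frames (camera cycle time), seconds.
    exposure_s
        Camera exposure per frame, seconds; at most ``frame_interval_s``.
    localization_error_um
        One-dimensional localization precision sigma, micrometres.
    detection_depth_um
        Axial extent dz of the detection slab (molecules further than
        dz/2 from focus are not detected), micrometres.
    gaps_allowed
        Maximum number of consecutive missed frames tolerated inside one
        track before it is split.
    jumps_considered
        Number of frame-lag multiples used when pooling displacements.
    d_max_um2s
        Maximal expected diffusion coefficient, µm²/s (tracking-search
        radius parameter; carried as metadata).
    """

    frame_interval_s: float
    exposure_s: float
    localization_error_um: float = 0.045
    detection_depth_um: float = 0.7
    gaps_allowed: int = 1
    jumps_considered: int = 4
    d_max_um2s: float = 20.0

    def __post_init__(self) -> None:
        for name in ("frame_interval_s", "exposure_s", "detection_depth_um",
                     "d_max_um2s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        # zero is the noiseless limit, useful for degenerate simulations
        if self.localization_error_um < 0:
            raise ValueError("localization_error_um must be >= 0")
        if self.exposure_s > self.frame_interval_s:
            raise ValueError("exposure_s cannot exceed frame_interval_s")
        if self.gaps_allowed < 0:
            raise ValueError("gaps_allowed must be >= 0")
        if self.jumps_considered < 1:
            raise ValueError("jumps_considered must be >= 1")


@dataclass(frozen=True)
class Localization:
    """A single detection: one molecule in one frame."""

    track_id: str
    frame: int
    t_s: float
    x_um: float
    y_um: float

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise TrajectoryFormatError(f"negative frame index {self.frame}")
        if not (math.isfinite(self.x_um) and math.isfinite(self.y_um)):
            raise TrajectoryFormatError(
                f"non-finite coordinate in track {self.track_id!r} frame {self.frame}")


@dataclass(frozen=True)
class Trajectory:
    """An ordered run of localizations sharing one track id."""

    track_id: str
    localizations: tuple[Localization, ...]

    def __post_init__(self) -> None:
        if not self.localizations:
            raise TrajectoryFormatError("empty trajectory")
        frames = [loc.frame for loc in self.localizations]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise TrajectoryFormatError(
                f"track {self.track_id!r}: frames not strictly increasing: {frames}")
        if any(loc.track_id != self.track_id for loc in self.localizations):
            raise TrajectoryFormatError(
                f"track {self.track_id!r}: inconsistent track ids")

    def __len__(self) -> int:
        return len(self.localizations)

    @property
    def frames(self) -> np.ndarray:
        return np.array([loc.frame for loc in self.localizations], dtype=np.int64)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of planar positions in µm."""
        return np.array([[loc.x_um, loc.y_um] for loc in self.localizations])

    def max_frame_increment(self) -> int:
        f = self.frames
        return int(np.max(np.diff(f))) if len(f) > 1 else 0


@dataclass(frozen=True)
class TrajectoryDataset:
    """Trajectories plus acquisition settings and condition metadata.

    ``metadata`` carries free-form condition labels; conventional keys are
    ``condition``, ``cell_id``, ``cell_cycle_stage`` ("interphase" or
    "mitosis") and ``timepoint_min`` (minutes post mitotic release).
    """

    settings: AcquisitionSettings
    trajectories: tuple[Trajectory, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise TrajectoryFormatError("dataset contains no trajectories")
        limit = self.settings.gaps_allowed + 1
        for traj in self.trajectories:
            if traj.max_frame_increment() > limit:
                raise TrajectoryFormatError(
                    f"track {traj.track_id!r} has a frame increment of "
                    f"{traj.max_frame_increment()} but gaps_allowed="
                    f"{self.settings.gaps_allowed} permits at most {limit}")

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def n_localizations(self) -> int:
        return sum(len(t) for t in self.trajectories)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (loc.track_id, loc.frame, loc.t_s, loc.x_um, loc.y_um)
            for traj in self.trajectories
            for loc in traj.localizations
        ]
        return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def _check_time_consistency(df: pd.DataFrame, settings: AcquisitionSettings) -> None:
    expected = df["frame"].to_numpy(dtype=float) * settings.frame_interval_s
    if not np.allclose(df["t_s"].to_numpy(dtype=float), expected, atol=1e-6):
        bad = int(np.argmax(np.abs(df["t_s"].to_numpy(float) - expected)))
        raise TrajectoryFormatError(
            f"t_s inconsistent with frame * frame_interval_s at row {bad} "
            f"(t_s={df['t_s'].iloc[bad]}, frame={df['frame'].iloc[bad]})")


def from_dataframe(
    df: pd.DataFrame,
    settings: AcquisitionSettings,
    metadata: Optional[Mapping[str, object]] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> TrajectoryDataset:
    """Build a dataset from an in-memory table.

    ``column_map`` maps this package's column names to the names used in
    ``df`` (the import shim for other trackers' exports, e.g.
    ``{"track_id": "TRACK_ID", "frame": "FRAME", ...}``).  A missing
    ``t_s`` column is reconstructed from ``frame`` and the frame interval.
    """
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns and c != "t_s"]
    if missing:
        raise TrajectoryFormatError(f"missing required columns: {missing}")
    df = df.copy()
    if "t_s" not in df.columns:
        df["t_s"] = df["frame"].astype(float) * settings.frame_interval_s

    frames = pd.to_numeric(df["frame"], errors="coerce")
    if frames.isna().any() or (frames < 0).any() or (frames % 1 != 0).any():
        raise TrajectoryFormatError("frame column must contain nonnegative integers")
    df["frame"] = frames.astype(np.int64)
    for col in ("t_s", "x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            raise TrajectoryFormatError(f"non-finite value in column {col!r}")
        df[col] = vals.astype(float)
    if df.duplicated(subset=["track_id", "frame"]).any():
        dup = df[df.duplicated(subset=["track_id", "frame"])].iloc[0]
        raise TrajectoryFormatError(
            f"duplicate (track_id, frame) pair: ({dup['track_id']!r}, {dup['frame']})")
    _check_time_consistency(df, settings)

    df = df.sort_values(["track_id", "frame"], kind="stable")
    trajectories: list[Trajectory] = []
    for tid, group in df.groupby("track_id", sort=True):
        locs = tuple(
            Localization(str(tid), int(r.frame), float(r.t_s),
                         float(r.x_um), float(r.y_um))
            for r in group.itertuples(index=False)
        )
        frames = np.array([loc.frame for loc in locs], dtype=np.int64)
        # validation step: a run of missing frames longer than gaps_allowed
        # ends the track, so such input is split rather than rejected
        pieces = list(_split_frames(frames, settings.gaps_allowed))
        if len(pieces) == 1:
            trajectories.append(Trajectory(str(tid), locs))
        else:
            for k, sl in enumerate(pieces):
                sub_id = f"{tid}.{k}"
                trajectories.append(Trajectory(
                    sub_id,
                    tuple(replace(loc, track_id=sub_id) for loc in locs[sl])))
    dataset = TrajectoryDataset(settings, tuple(trajectories), dict(metadata or {}))
    return dataset


def read_trajectory_table(
    path: Union[str, Path],
    settings: AcquisitionSettings,
    metadata: Optional[Mapping[str, object]] = None,
) -> TrajectoryDataset:
    """Read a comma-delimited trajectory table into a validated dataset.

    Rows are grouped by ``track_id`` and sorted by ``frame``.  Duplicate
    (track, frame) pairs, negative frames or non-finite coordinates raise
    :class:`TrajectoryFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"track_id": str}, float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(
            f"{path}: header must declare {list(TABLE_COLUMNS)}; missing {missing}")
    return from_dataframe(df, settings, metadata)


def write_trajectory_table(dataset: TrajectoryDataset, path: Union[str, Path]) -> None:
    """Write a dataset to the canonical comma-delimited table format."""
    df = dataset.to_dataframe()
    # shortest-round-trip float formatting so read(write(x)) == x exactly
    df.to_csv(Path(path), index=False,
              float_format=lambda v: repr(float(v)))


def _split_frames(frames: np.ndarray, max_gap: float) -> Iterator[slice]:
    """Yield slices of maximal runs whose frame increments are <= max_gap + 1."""
    if math.isinf(max_gap):
        yield slice(0, len(frames))
        return
    breaks = np.flatnonzero(np.diff(frames) > max_gap + 1)
    start = 0
    for b in breaks:
        yield slice(start, b + 1)
        start = b + 1
    yield slice(start, len(frames))


def split_on_gaps(dataset: TrajectoryDataset, max_gap: float) -> TrajectoryDataset:
    """Split trajectories wherever more than ``max_gap`` consecutive frames
    are missing, conserving every localization.

    ``max_gap`` may be ``math.inf`` (sentinel: no splitting).  Sub-tracks
    are renamed ``"<track_id>.<k>"`` so track ids stay unique.
    """
    if max_gap != NO_GAP_LIMIT and max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[Trajectory] = []
    for traj in dataset.trajectories:
        pieces = list(_split_frames(traj.frames, max_gap))
        if len(pieces) == 1:
            out.append(traj)
            continue
        for k, sl in enumerate(pieces):
            tid = f"{traj.track_id}.{k}"
            locs = tuple(replace(loc, track_id=tid)
                         for loc in traj.localizations[sl])
            out.append(Trajectory(tid, locs))
    gaps = int(max_gap) if not math.isinf(max_gap) else dataset.settings.gaps_allowed
    settings = replace(dataset.settings, gaps_allowed=gaps)
    return TrajectoryDataset(settings, tuple(out), dict(dataset.metadata))
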