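"""Reading, validation, filtering and writing of cell-track tables.

The pipeline starts from extracted nucleus-centroid tracks: delimited text
with one row per (track, frame) carrying a track id, time and x/y position.
Column names, delimiter and unit conversion factors are configurable so that
exports from different tracking tools can be ingested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TableConfig",
    "Track",
    "TrackSet",
    "TrackIOError",
    "ConfigurationError",
    "TrackValidationError",
    "read_tracks",
    "write_tracks",
    "filter_tracks",
]

#: uniform frame spacing tolerance, hours
_SPACING_TOL = 1e-6


class TrackIOError(Exception):
    """Base class for track I/O problems."""


class ConfigurationError(TrackIOError):
    """File/column layout does not match the configuration."""


class TrackValidationError(TrackIOError):
    """A track violates its invariants (time ordering, spacing, length)."""


@dataclass(frozen=True)
class TableConfig:
    """Column mapping and unit conversion for track tables.

    ``time_to_hours`` and ``length_to_um`` multiply raw file values; e.g. a
    file with time in minutes uses ``time_to_hours=1/60``.
    """

    track_id: str = "track_id"
    time: str = "t_h"
    x: str = "x_um"
    y: str = "y_um"
    delimiter: str = ","
    time_to_hours: float = 1.0
    length_to_um: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "TableConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class Track:
    """Time-ordered nucleus-centroid positions of one cell.

    Invariants: strictly increasing time, uniform frame spacing (within
    1e-6 h), at least two frames.  Times in hours, positions in um.
    """

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise TrackValidationError(f"track {self.track_id}: ragged columns")
        if len(self.t) < 2:
            raise TrackValidationError(f"track {self.track_id}: fewer than 2 frames")
        steps = np.diff(self.t)
        if np.any(steps <= 0):
            raise TrackValidationError(
                f"track {self.track_id}: time not strictly increasing "
                "(duplicated or out-of-order timestamps)"
            )
        if np.max(steps) - np.min(steps) > _SPACING_TOL:
            raise TrackValidationError(
                f"track {self.track_id}: non-uniform frame spacing "
                f"(range {np.max(steps) - np.min(steps):.3g} h)"
            )

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def path_length(self) -> float:
        """Total Euclidean path length along the track, um."""
        return float(np.sum(np.hypot(np.diff(self.x), np.diff(self.y))))


@dataclass
class TrackSet:
    """A collection of tracks recorded under one experimental condition."""

    tracks: list
    condition_label: str = ""
    geometry_hint: object | None = None  # RingGeometry
    barrier_hint: object | None = None  # BarrierSpec

    def __post_init__(self) -> None:
        ids = [tr.track_id for tr in self.tracks]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise TrackValidationError(f"duplicate track ids: {dup}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


def read_tracks(path, config: TableConfig | None = None, condition_label: str = "") -> TrackSet:
    """Read a delimited track table into a :class:`TrackSet`.

    Rows are sorted by time within each track; duplicated (id, time) rows
    raise a :class:`TrackValidationError` naming the track.  Units are
    converted to hours / um via the config factors.
    """
    config = config or TableConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=config.delimiter)
    needed = {config.track_id, config.time, config.x, config.y}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"{path.name}: missing columns {sorted(missing)}; found {list(df.columns)}"
        )
    tracks = []
    for tid, g in df.groupby(config.track_id, sort=False):
        g = g.sort_values(config.time, kind="stable")
        t = g[config.time].to_numpy(dtype=float) * config.time_to_hours
        if np.any(np.diff(t) <= 0):
            raise TrackValidationError(
                f"track {tid}: duplicated or non-monotone timestamps"
            )
        tracks.append(
            Track(
                track_id=str(tid),
                t=t,
                x=g[config.x].to_numpy(dtype=float) * config.length_to_um,
                y=g[config.y].to_numpy(dtype=float) * config.length_to_um,
            )
        )
    return TrackSet(tracks=tracks, condition_label=condition_label)


def write_tracks(ts: TrackSet, path, config: TableConfig | None = None) -> None:
    """Write a TrackSet as a delimited table (inverse of :func:`read_tracks`)."""
    config = config or TableConfig()
    frames = []
    for tr in ts:
        frames.append(
            pd.DataFrame(
                {
                    config.track_id: tr.track_id,
                    config.time: tr.t / config.time_to_hours,
                    config.x: tr.x / config.length_to_um,
                    config.y: tr.y / config.length_to_um,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=[config.track_id, config.time, config.x, config.y]
    )
    out.to_csv(path, sep=config.delimiter, index=False)


def filter_tracks(
    ts: TrackSet,
    min_duration: float = 18.0,
    min_path_length: float = 50.0,
) -> tuple[TrackSet, pd.DataFrame]:
    """Drop short and non-moving tracks.

    A track is retained when its total duration is at least ``min_duration``
    hours (default 18 h) and its total path length is at least
    ``min_path_length`` um.  The path-length cut operationalizes the
    exclusion of dead or non-moving cells; the default of 50 um over the
    whole track is configurable.

    Returns the retained TrackSet and an exclusion report with one row per
    excluded track (columns ``track_id``, ``reason``); reason is ``duration``
    or ``non-moving``.
    """
    if min_duration < 0:
        raise ValueError("min_duration must be >= 0")
    kept, rows = [], []
    for tr in ts:
        if tr.duration < min_duration:
            rows.append({"track_id": tr.track_id, "reason": "duration"})
        elif tr.path_length < min_path_length:
            rows.append({"track_id": tr.track_id, "reason": "non-moving"})
        else:
            kept.append(tr)
    if ts.tracks and not kept:
        warnings.warn("all tracks excluded by filter_tracks", stacklevel=2)
    report = pd.DataFrame(rows, columns=["track_id", "reason"])
    out = TrackSet(
        tracks=kept,
        condition_label=ts.condition_label,
        geometry_hint=ts.geometry_hint,
        barrier_hint=ts.barrier_hint,
    )
    return out, report
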