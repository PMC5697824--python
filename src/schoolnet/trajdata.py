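"""Trajectory data model, tabular I/O and preprocessing.

The experimental setting is a ring-shaped (annular) tank filmed from above
at a fixed frame rate; every fish contributes a 2D position time series on a
common clock.  This module defines the in-memory containers
(:class:`RingGeometry`, :class:`FishTrack`, :class:`TrajectorySet`), reads
and writes the delimited-text trajectory format, interpolates short tracking
gaps, and converts between Cartesian and polar coordinates relative to the
tank center.

Conventions
-----------
* units: millimetres and seconds internally (``units="m"`` converts on read);
* origin at the tank center, x rightward, y upward;
* angles in radians, anticlockwise positive, wrapped to (-pi, pi];
* frames indexed from 0; timestamps are authoritative, frame numbers are
  informational.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._angles import wrap_angle
from .errors import DegeneratePointError, MalformedInputError

__all__ = [
    "RingGeometry",
    "FishTrack",
    "TrajectorySet",
    "read_trajectories",
    "write_trajectories",
    "interpolate_gaps",
    "to_polar",
    "from_polar",
]

#: relative tolerance on the uniform time step
_DT_RTOL = 1e-4


@dataclass(frozen=True)
class RingGeometry:
    """Annular tank geometry: center and inner/outer wall radii in mm.

    Defaults follow a corridor with a 35 cm outer wall and a 25 cm
    inner wall, i.e. a 10 cm wide swimming channel.
    """

    center: tuple[float, float] = (0.0, 0.0)
    outer_radius: float = 350.0
    inner_radius: float = 250.0

    def __post_init__(self):
        if not (self.outer_radius > self.inner_radius > 0):
            raise ValueError("require outer_radius > inner_radius > 0")

    @property
    def midline_radius(self) -> float:
        return 0.5 * (self.outer_radius + self.inner_radius)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.outer_radius - self.inner_radius)


@dataclass
class FishTrack:
    """One fish's position time series on a uniform clock.

    ``valid_mask`` flags frames where the tracker produced a position;
    positions at invalid frames are NaN.
    """

    fish_id: int
    times: np.ndarray
    positions: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.all(np.isfinite(self.positions), axis=1)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if len(self.times) != len(self.positions) or len(self.times) != len(self.valid_mask):
            raise ValueError("times, positions and valid_mask lengths differ")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            dt = steps[0]
            if np.any(np.abs(steps - dt) > _DT_RTOL * dt):
                raise MalformedInputError(
                    f"fish {self.fish_id}: non-uniform time step"
                )
        if np.any(~np.isfinite(self.positions[self.valid_mask])):
            raise ValueError("non-finite position at a frame marked valid")

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("track too short to define a time step")
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class TrajectorySet:
    """N fish tracks on a shared clock inside one tank geometry."""

    tracks: list[FishTrack]
    geometry: RingGeometry
    dt: float

    def __post_init__(self):
        if len(self.tracks) < 1:
            raise ValueError("need at least one track")
        t0 = self.tracks[0].times
        for tr in self.tracks[1:]:
            if len(tr.times) != len(t0) or np.any(np.abs(tr.times - t0) > _DT_RTOL * self.dt):
                raise MalformedInputError("tracks do not share a common clock")

    @property
    def n_fish(self) -> int:
        return len(self.tracks)

    @property
    def n_frames(self) -> int:
        return len(self.tracks[0])

    @property
    def times(self) -> np.ndarray:
        return self.tracks[0].times

    @property
    def fish_ids(self) -> list[int]:
        return [tr.fish_id for tr in self.tracks]

    @property
    def positions(self) -> np.ndarray:
        """(N, T, 2) array of positions, NaN at invalid frames."""
        pos = np.stack([tr.positions for tr in self.tracks])
        for k, tr in enumerate(self.tracks):
            pos[k, ~tr.valid_mask] = np.nan
        return pos


def _sniff_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if "\t" in head else ","


def read_trajectories(path, geometry: RingGeometry, units: str = "mm") -> TrajectorySet:
    """Read a delimited trajectory table into a :class:`TrajectorySet`.

    The file must have a header row with columns ``frame,time,id,x,y``
    (an optional ``orientation`` column is carried through but unused here);
    CSV vs TSV is autodetected.  Missing positions may be encoded as blank
    cells or NaN.  Rows are sorted by time; every distinct id becomes one
    :class:`FishTrack`, with ``valid_mask`` false at frames where that fish
    has no (finite) position.

    Raises
    ------
    MalformedInputError
        On duplicate ``(time, id)`` rows or a non-uniform time step.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"frame", "time", "id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedInputError(f"missing columns: {sorted(missing)}")
    if units == "m":
        df["x"] = df["x"] * 1000.0
        df["y"] = df["y"] * 1000.0
    elif units != "mm":
        raise MalformedInputError(f"unknown units {units!r}")

    df = df.sort_values(["time", "id"], kind="mergesort")
    if df.duplicated(subset=["time", "id"]).any():
        raise MalformedInputError("duplicate (time, id) rows")

    grid = np.unique(df["time"].to_numpy(dtype=float))
    if len(grid) >= 2:
        steps = np.diff(grid)
        dt = np.min(steps)
        if np.any(np.abs(steps - dt) > _DT_RTOL * dt):
            raise MalformedInputError("time column is not a uniform grid")
    else:
        dt = np.nan
    index = pd.Index(grid, name="time")

    tracks = []
    for fid, sub in df.groupby("id"):
        sub = sub.set_index("time").reindex(index)
        pos = sub[["x", "y"]].to_numpy(dtype=float)
        tracks.append(FishTrack(int(fid), grid.copy(), pos))
    return TrajectorySet(tracks, geometry, float(dt))


def write_trajectories(ts: TrajectorySet, path, sep: str = ",") -> None:
    """Write a :class:`TrajectorySet` back to the tabular text format."""
    rows = []
    for tr in ts.tracks:
        for k in range(len(tr)):
            x, y = tr.positions[k]
            rows.append(
                (k, tr.times[k], tr.fish_id,
                 x if tr.valid_mask[k] else np.nan,
                 y if tr.valid_mask[k] else np.nan)
            )
    df = pd.DataFrame(rows, columns=["frame", "time", "id", "x", "y"])
    df = df.sort_values(["time", "id"], kind="mergesort")
    df.to_csv(path, sep=sep, index=False, float_format="%.6f")


def interpolate_gaps(ts: TrajectorySet, max_gap: int = 50):
    """Linearly interpolate interior tracking gaps of at most ``max_gap`` frames.

    Runs of consecutive invalid frames bounded by valid frames on both sides
    and no longer than ``max_gap`` are filled linearly in x and y and marked
    valid.  Longer runs, and runs touching either end of the series, are never
    extrapolated: they stay invalid and are listed in the report.

    Returns
    -------
    (TrajectorySet, list of dict)
        The new set and a gap report with entries
        ``{fish_id, start_frame, length, action}`` where action is one of
        ``"interpolated"``, ``"left"`` (too long) or ``"boundary"``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    report: list[dict] = []
    new_tracks = []
    for tr in ts.tracks:
        pos = tr.positions.copy()
        mask = tr.valid_mask.copy()
        n = len(tr)
        k = 0
        while k < n:
            if mask[k]:
                k += 1
                continue
            start = k
            while k < n and not mask[k]:
                k += 1
            length = k - start
            at_boundary = start == 0 or k == n
            if at_boundary:
                action = "boundary"
            elif length <= max_gap:
                lo, hi = start - 1, k  # valid anchors
                frac = (np.arange(start, k) - lo) / (hi - lo)
                pos[start:k] = pos[lo] + frac[:, None] * (pos[hi] - pos[lo])
                mask[start:k] = True
                action = "interpolated"
            else:
                action = "left"
            report.append(
                {"fish_id": tr.fish_id, "start_frame": int(start),
                 "length": int(length), "action": action}
            )
        new_tracks.append(FishTrack(tr.fish_id, tr.times.copy(), pos, mask))
    return TrajectorySet(new_tracks, ts.geometry, ts.dt), report


def gap_report_json(report: list[dict]) -> str:
    return json.dumps(report, indent=2)


def to_polar(ts: TrajectorySet):
    """Polar coordinates of every fish relative to the tank center.

    Returns ``(rho, psi)`` arrays of shape (N, T): ``rho`` is the distance
    from the center in mm, ``psi`` the angle of the position vector from the
    horizontal, anticlockwise positive, in (-pi, pi].  Invalid frames are NaN.

    Raises
    ------
    DegeneratePointError
        If a valid position coincides exactly with the tank center.
    """
    cx, cy = ts.geometry.center
    pos = ts.positions
    dx = pos[..., 0] - cx
    dy = pos[..., 1] - cy
    rho = np.hypot(dx, dy)
    if np.any(rho[np.isfinite(rho)] == 0.0):
        raise DegeneratePointError("position exactly at tank center")
    psi = wrap_angle(np.arctan2(dy, dx))
    psi[~np.isfinite(rho)] = np.nan
    return rho, psi


def from_polar(rho: np.ndarray, psi: np.ndarray, geometry: RingGeometry) -> np.ndarray:
    """Inverse of :func:`to_polar`; returns positions shaped like rho + (2,)."""
    cx, cy = geometry.center
    return np.stack([cx + rho * np.cos(psi), cy + rho * np.sin(psi)], axis=-1)
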