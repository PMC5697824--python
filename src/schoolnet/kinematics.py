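"""Per-frame kinematics: velocity, heading, wall incidence, pairwise geometry,
group polarization and burst/coast segmentation.

Headings are defined from the velocity vector, ``v_i = ||v_i|| (cos phi_i,
sin phi_i)``; the wall-incidence angle ``theta_w = wrap(phi - psi)`` measures
the heading relative to the local radial direction (psi is the angular
position in the tank).  A fish gliding along the wall has |theta_w| near
90 degrees, and the sign of sin(theta_w) encodes the circulation direction
(positive = anticlockwise).  Undefined quantities are propagated as NaN
markers, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._angles import moving_average, wrap_angle
from .errors import TooShortError, UndefinedHeadingError
from .trajdata import TrajectorySet, to_polar

__all__ = [
    "KinematicState",
    "PairGeometry",
    "BurstSegmentation",
    "compute_kinematics",
    "polarization",
    "pair_geometry",
    "pair_geometry_series",
    "detect_bursts",
    "burst_influence_overlap",
]


@dataclass
class KinematicState:
    """Per-fish per-frame kinematic quantities on the common clock.

    All arrays are (N, T) or (N, T, 2); NaN marks undefined values.
    """

    fish_ids: list[int]
    times: np.ndarray
    dt: float
    vel: np.ndarray       # (N, T, 2) mm/s
    speed: np.ndarray     # (N, T) mm/s
    phi: np.ndarray       # (N, T) heading, rad
    e: np.ndarray         # (N, T, 2) unit heading
    rho: np.ndarray       # (N, T) mm
    psi: np.ndarray       # (N, T) rad
    theta_w: np.ndarray   # (N, T) rad, wall incidence
    positions: np.ndarray  # (N, T, 2) mm

    def index_of(self, fish_id: int) -> int:
        return self.fish_ids.index(fish_id)

    @property
    def n_fish(self) -> int:
        return len(self.fish_ids)

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class PairGeometry:
    """Relative state of neighbor j with respect to focal fish i at one frame."""

    d_ij: float
    theta_ij: float   # viewing angle: bearing of j minus heading of i
    phi_ij: float     # heading difference phi_j - phi_i
    u_ij: np.ndarray  # relative position (2,)
    v_ij: np.ndarray  # relative velocity (2,)


@dataclass
class BurstSegmentation:
    """Burst intervals (onset, offset frames) and a per-frame bursting flag."""

    intervals: list[tuple[int, int]]
    bursting: np.ndarray

    @property
    def burst_fraction(self) -> float:
        return float(np.mean(self.bursting))


def compute_kinematics(ts: TrajectorySet, speed_floor: float = 1.0) -> KinematicState:
    """Differentiate trajectories into velocities, headings and wall incidence.

    Velocity is a central finite difference over one frame (forward/backward
    differences at the series ends).  The heading is ``atan2(vy, vx)`` where
    the speed is at least ``speed_floor`` (mm/s); below the floor the last
    defined heading is carried forward, which avoids atan2 noise at near-zero
    speed.  Frames before the first defined heading stay NaN.

    Raises
    ------
    UndefinedHeadingError
        If some track never reaches the speed floor.
    """
    if speed_floor < 0:
        raise ValueError("speed_floor must be >= 0")
    pos = ts.positions
    n, t = pos.shape[:2]
    if t < 2:
        raise TooShortError("need at least two frames to differentiate")
    vel = np.gradient(pos, ts.dt, axis=1)
    speed = np.linalg.norm(vel, axis=2)
    phi = np.arctan2(vel[..., 1], vel[..., 0])
    defined = np.isfinite(speed) & (speed >= speed_floor)
    phi = np.where(defined, phi, np.nan)
    # carry the last defined heading forward
    for i in range(n):
        if not defined[i].any():
            raise UndefinedHeadingError(
                f"fish {ts.fish_ids[i]}: speed never reaches the floor"
            )
        idx = np.where(defined[i], np.arange(t), -1)
        idx = np.maximum.accumulate(idx)
        filled = np.where(idx >= 0, phi[i, np.maximum(idx, 0)], np.nan)
        phi[i] = filled
    e = np.stack([np.cos(phi), np.sin(phi)], axis=-1)
    rho, psi = to_polar(ts)
    theta_w = wrap_angle(phi - psi)
    theta_w[np.isnan(phi) | np.isnan(psi)] = np.nan
    return KinematicState(
        fish_ids=list(ts.fish_ids), times=ts.times.copy(), dt=ts.dt,
        vel=vel, speed=speed, phi=phi, e=e, rho=rho, psi=psi,
        theta_w=theta_w, positions=pos,
    )


def polarization(e: np.ndarray) -> np.ndarray | float:
    """Group polarization P = ||sum_i e_i|| / N of unit headings.

    Accepts (N, 2) for a single frame (returns a scalar) or (N, T, 2) for a
    series (returns (T,)).  Any undefined heading at a frame makes that
    frame's polarization NaN.
    """
    e = np.asarray(e, dtype=float)
    single = e.ndim == 2
    if single:
        e = e[:, None, :]
    n = e.shape[0]
    p = np.linalg.norm(np.sum(e, axis=0), axis=-1) / n
    p[np.any(np.isnan(e), axis=(0, 2))] = np.nan
    return float(p[0]) if single else p


def pair_geometry(kin: KinematicState, i: int, j: int, t_idx: int) -> PairGeometry:
    """Relative geometry of neighbor ``j`` seen from focal ``i`` at one frame.

    ``i`` and ``j`` are fish ids.  Coincident positions give d_ij = 0 with a
    NaN viewing angle.
    """
    a, b = kin.index_of(i), kin.index_of(j)
    u_ij = kin.positions[b, t_idx] - kin.positions[a, t_idx]
    d = float(np.hypot(*u_ij))
    if d == 0.0:
        theta = np.nan
    else:
        theta = float(wrap_angle(np.arctan2(u_ij[1], u_ij[0]) - kin.phi[a, t_idx]))
    phi_ij = float(wrap_angle(kin.phi[b, t_idx] - kin.phi[a, t_idx]))
    v_ij = kin.vel[b, t_idx] - kin.vel[a, t_idx]
    return PairGeometry(d_ij=d, theta_ij=theta, phi_ij=phi_ij, u_ij=u_ij, v_ij=v_ij)


def pair_geometry_series(kin: KinematicState, i: int, j: int,
                         frames: np.ndarray | None = None) -> dict:
    """Vectorized :func:`pair_geometry` over ``frames`` (default: all).

    Returns a dict of arrays ``d_ij, theta_ij, phi_ij, u_ij, v_ij``.
    """
    a, b = kin.index_of(i), kin.index_of(j)
    sl = slice(None) if frames is None else frames
    u_ij = kin.positions[b, sl] - kin.positions[a, sl]
    d = np.hypot(u_ij[..., 0], u_ij[..., 1])
    bearing = np.arctan2(u_ij[..., 1], u_ij[..., 0])
    theta = wrap_angle(bearing - kin.phi[a, sl])
    theta = np.where(d == 0.0, np.nan, theta)
    phi_ij = wrap_angle(kin.phi[b, sl] - kin.phi[a, sl])
    v_ij = kin.vel[b, sl] - kin.vel[a, sl]
    return {"d_ij": d, "theta_ij": theta, "phi_ij": phi_ij, "u_ij": u_ij, "v_ij": v_ij}


def detect_bursts(speed: np.ndarray, dt: float,
                  accel_threshold: float = 300.0,
                  smooth_window: int = 5) -> BurstSegmentation:
    """Segment a speed series into burst intervals.

    Burst-and-coast swimmers alternate brief accelerations with passive
    glides.  Operationally here: the speed is smoothed by a centered moving
    average of ``smooth_window`` frames; a burst core is a maximal run where
    the smoothed acceleration exceeds ``accel_threshold`` (mm/s^2), extended
    backward to the preceding local speed minimum and forward to the next
    local speed maximum.  This operational rule is this package's own.
    """
    speed = np.asarray(speed, dtype=float)
    if accel_threshold <= 0:
        raise ValueError("accel_threshold must be > 0")
    n = speed.size
    if n < max(2, smooth_window):
        raise TooShortError("speed series shorter than the smoothing window")
    sm = moving_average(speed, smooth_window)
    accel = np.gradient(sm, dt)
    core = accel > accel_threshold
    intervals: list[tuple[int, int]] = []
    k = 0
    while k < n:
        if not core[k]:
            k += 1
            continue
        a = k
        while k < n and core[k]:
            k += 1
        b = k - 1
        while a > 0 and sm[a - 1] < sm[a]:
            a -= 1
        while b < n - 1 and sm[b + 1] > sm[b]:
            b += 1
        if b > a:
            if intervals and a <= intervals[-1][1]:
                intervals[-1] = (intervals[-1][0], max(intervals[-1][1], b))
            else:
                intervals.append((a, b))
    bursting = np.zeros(n, dtype=bool)
    for a, b in intervals:
        bursting[a:b + 1] = True
    return BurstSegmentation(intervals=intervals, bursting=bursting)


@dataclass
class BurstOverlap:
    """Association between bursting and being an influential neighbor.

    ``statistic[j]`` is P(j bursting at t - tau | j influences someone at t)
    divided by j's overall burst fraction: 1 means bursting carries no extra
    information about influence.  ``raster`` holds, per focal fish, the
    influencer id at frames where the influencer was bursting at t - tau
    (0 elsewhere; the largest influencer id wins ties), alongside each fish's
    own bursting flags, mirroring the raster-figure construction.
    """

    statistic: dict[int, float]
    skipped: int
    raster_own: dict[int, np.ndarray] = field(default_factory=dict)
    raster_influencer: dict[int, np.ndarray] = field(default_factory=dict)


def burst_influence_overlap(bursts: dict[int, BurstSegmentation],
                            records, dt: float,
                            n_frames: int | None = None) -> BurstOverlap:
    """Overlap statistic between bursting activity and influence records.

    ``records`` is the influence-record table (columns ``frame``, ``focal``,
    ``neighbor``, ``tau_frames``).  Records whose look-back frame ``t - tau``
    precedes the series start are skipped and counted.
    """
    if n_frames is None:
        n_frames = len(next(iter(bursts.values())).bursting)
    flags: dict[int, list[bool]] = {j: [] for j in bursts}
    raster_infl = {i: np.zeros(n_frames, dtype=int) for i in bursts}
    skipped = 0
    for row in records.itertuples(index=False):
        src = int(row.frame) - int(row.tau_frames)
        if src < 0:
            skipped += 1
            continue
        j = int(row.neighbor)
        was_bursting = bool(bursts[j].bursting[src])
        flags[j].append(was_bursting)
        if was_bursting:
            i = int(row.focal)
            row_i = raster_infl.setdefault(i, np.zeros(n_frames, dtype=int))
            row_i[int(row.frame)] = max(row_i[int(row.frame)], j)
    stat = {}
    for j, fl in flags.items():
        if not fl:
            stat[j] = np.nan
            continue
        frac = bursts[j].burst_fraction
        stat[j] = float(np.mean(fl) / frac) if frac > 0 else np.nan
    return BurstOverlap(
        statistic=stat, skipped=skipped,
        raster_own={i: b.bursting.copy() for i, b in bursts.items()},
        raster_influencer=raster_infl,
    )
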