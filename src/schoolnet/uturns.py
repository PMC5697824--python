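"""Individual and collective U-turn detection, normalized event time, and
position/distance/turning ranks.

In an annular tank the school circulates clockwise or anticlockwise and
spontaneously reverses in collective U-turn events.  An individual U-turn is
located by a persistent sign change of sin(theta_w) (theta_w is the
wall-incidence angle); its start and end are bounded by threshold crossings
of |theta_w|, with thresholds taken as the maximum absolute moving average
of theta_w over a span before/after the turn instant.  The collective event
runs from the earliest individual start to the latest individual end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._angles import moving_average
from .errors import IncompleteEventError, TooShortError, UnboundedTurnError, ZeroDurationError
from .kinematics import KinematicState

__all__ = [
    "UTurnConfig",
    "IndividualUTurn",
    "UTurnEvent",
    "detect_individual_uturns",
    "uturn_bounds",
    "collective_uturn",
    "detect_collective_uturns",
    "normalized_time",
    "position_rank",
    "distance_rank",
    "turning_rank",
]


@dataclass(frozen=True)
class UTurnConfig:
    """Tunable parameters of the U-turn detector.

    persistence : frames of coherent circulation required on each side of a
        candidate sign change (filters jitter around sin(theta_w) = 0);
    min_abs_sin : minimum mean |sin theta_w| on each side of the candidate;
    assoc_window : seconds within which individual turn instants are grouped
        into one collective event;
    bound_span / ma_window : frames over which the bounding thresholds are
        computed, and the moving-average width, respectively.
    """

    persistence: int = 25
    min_abs_sin: float = 0.5
    assoc_window: float = 3.0
    bound_span: int = 50
    ma_window: int = 5


@dataclass
class IndividualUTurn:
    fish_id: int
    s_idx: int
    m_idx: int
    e_idx: int
    thr_s: float
    thr_e: float
    t_s: float
    t_m: float
    t_e: float
    direction_before: str  # "anticlockwise" | "clockwise"
    direction_after: str


@dataclass
class UTurnEvent:
    """One collective U-turn: per-fish individual turns plus global bounds."""

    individuals: dict[int, IndividualUTurn]
    t_s: float
    t_e: float
    s_idx: int
    e_idx: int
    direction_before: str
    direction_after: str

    @property
    def duration(self) -> float:
        return self.t_e - self.t_s

    def to_dict(self) -> dict:
        return {
            "direction_before": self.direction_before,
            "direction_after": self.direction_after,
            "t_s": self.t_s,
            "t_e": self.t_e,
            "fish": {
                str(f): {
                    "t_s_i": iu.t_s, "t_m_i": iu.t_m, "t_e_i": iu.t_e,
                    "thresholds": [iu.thr_s, iu.thr_e],
                }
                for f, iu in self.individuals.items()
            },
        }


def detect_individual_uturns(theta_w: np.ndarray,
                             persistence: int = 25,
                             min_abs_sin: float = 0.5) -> list[int]:
    """Candidate turn instants: persistent sign changes of sin(theta_w).

    A candidate is a frame where sin(theta_w) changes sign such that the mean
    of sin(theta_w) over the ``persistence`` frames on each side exceeds
    ``min_abs_sin`` in absolute value with opposite signs.  Of the two frames
    adjacent to the crossing, the one with the smaller |sin| is reported.
    Candidates closer than ``persistence`` frames are the same physical turn
    (zero-crossing jitter); the one with the smallest |sin| is kept.
    """
    s = np.sin(np.asarray(theta_w, dtype=float))
    n = s.size
    out: list[int] = []
    cross = np.where(s[:-1] * s[1:] < 0)[0]
    for k in cross:
        lo, hi = k - persistence + 1, k + 1 + persistence
        if lo < 0 or hi > n:
            continue
        before = np.mean(s[lo:k + 1])
        after = np.mean(s[k + 1:hi])
        if (np.abs(before) > min_abs_sin and np.abs(after) > min_abs_sin
                and before * after < 0):
            cand = int(k if np.abs(s[k]) <= np.abs(s[k + 1]) else k + 1)
            if out and cand - out[-1] < persistence:
                if np.abs(s[cand]) < np.abs(s[out[-1]]):
                    out[-1] = cand
            else:
                out.append(cand)
    return out


def uturn_bounds(theta_w: np.ndarray, m_idx: int,
                 span: int = 50, ma_window: int = 5):
    """Bound an individual U-turn around the turn instant ``m_idx``.

    The start threshold is the maximum |moving average of theta_w| over the
    ``span`` frames before ``m_idx`` (the end threshold uses the span after);
    the start (end) frame is found by stepping backward (forward) from
    ``m_idx`` to the first frame where |theta_w| reaches the threshold.

    Returns ``(s_idx, e_idx, thr_s, thr_e)``.

    Raises
    ------
    TooShortError
        If fewer than ``span`` frames are available on either side.
    UnboundedTurnError
        If a threshold is never reached within the record.
    """
    theta_w = np.asarray(theta_w, dtype=float)
    n = theta_w.size
    if m_idx < span or m_idx + span >= n:
        raise TooShortError(f"need {span} frames on each side of the turn instant")
    ma = np.abs(moving_average(theta_w, ma_window))
    before = ma[m_idx - span:m_idx]
    after = ma[m_idx + 1:m_idx + span + 1]
    if np.all(np.isnan(before)) or np.all(np.isnan(after)):
        raise UnboundedTurnError("no defined incidence around the turn instant")
    thr_s = float(np.nanmax(before))
    thr_e = float(np.nanmax(after))
    abs_t = np.abs(theta_w)
    tol = 1e-9  # absorbs rounding between a flat plateau and its own average
    s_idx = None
    for k in range(m_idx - 1, -1, -1):
        if abs_t[k] >= thr_s - tol:
            s_idx = k
            break
    if s_idx is None:
        raise UnboundedTurnError("start threshold never reached")
    e_idx = None
    for k in range(m_idx + 1, n):
        if abs_t[k] >= thr_e - tol:
            e_idx = k
            break
    if e_idx is None:
        raise UnboundedTurnError("end threshold never reached")
    return s_idx, e_idx, thr_s, thr_e


def collective_uturn(turns: list[IndividualUTurn],
                     fish_ids: list[int] | None = None):
    """Collective bounds: earliest individual start, latest individual end.

    If ``fish_ids`` is given, every listed fish must contribute exactly one
    matched individual turn, otherwise an :class:`IncompleteEventError` is
    raised.
    """
    if fish_ids is not None:
        have = {t.fish_id for t in turns}
        missing = set(fish_ids) - have
        if missing or len(turns) != len(fish_ids):
            raise IncompleteEventError(f"missing individual turns for fish {sorted(missing)}")
    if not turns:
        raise IncompleteEventError("no individual turns")
    t_s = min(t.t_s for t in turns)
    t_e = max(t.t_e for t in turns)
    return t_s, t_e


def _direction(sign: float) -> str:
    return "anticlockwise" if sign > 0 else "clockwise"


def _individual_turn(kin: KinematicState, fish_idx: int, m_idx: int,
                     config: UTurnConfig) -> IndividualUTurn:
    th = kin.theta_w[fish_idx]
    s_idx, e_idx, thr_s, thr_e = uturn_bounds(
        th, m_idx, span=config.bound_span, ma_window=config.ma_window)
    s = np.sin(th)
    before = np.mean(s[m_idx - config.persistence:m_idx])
    return IndividualUTurn(
        fish_id=kin.fish_ids[fish_idx],
        s_idx=s_idx, m_idx=m_idx, e_idx=e_idx, thr_s=thr_s, thr_e=thr_e,
        t_s=float(kin.times[s_idx]), t_m=float(kin.times[m_idx]),
        t_e=float(kin.times[e_idx]),
        direction_before=_direction(before), direction_after=_direction(-before),
    )


def detect_collective_uturns(kin: KinematicState,
                             config: UTurnConfig = UTurnConfig()):
    """Detect all complete collective U-turns in a recording.

    Individual turn candidates of the N fish are grouped greedily in time:
    candidates whose turn instants fall within ``assoc_window`` seconds of the
    cluster's first candidate and share the same direction change are merged.
    A cluster with exactly one matched turn per fish becomes a
    :class:`UTurnEvent`; incomplete clusters are skipped and counted.

    Returns ``(events, n_incomplete)``.
    """
    cand: list[IndividualUTurn] = []
    for i in range(kin.n_fish):
        for m in detect_individual_uturns(
                kin.theta_w[i], config.persistence, config.min_abs_sin):
            try:
                cand.append(_individual_turn(kin, i, m, config))
            except (TooShortError, UnboundedTurnError):
                continue
    cand.sort(key=lambda u: u.t_m)
    events: list[UTurnEvent] = []
    n_incomplete = 0
    k = 0
    while k < len(cand):
        anchor = cand[k]
        cluster = [anchor]
        k += 1
        while (k < len(cand)
               and cand[k].t_m - anchor.t_m <= config.assoc_window
               and cand[k].direction_before == anchor.direction_before):
            cluster.append(cand[k])
            k += 1
        try:
            t_s, t_e = collective_uturn(cluster, kin.fish_ids)
        except IncompleteEventError:
            n_incomplete += 1
            continue
        s_idx = min(u.s_idx for u in cluster)
        e_idx = max(u.e_idx for u in cluster)
        events.append(UTurnEvent(
            individuals={u.fish_id: u for u in cluster},
            t_s=t_s, t_e=t_e, s_idx=s_idx, e_idx=e_idx,
            direction_before=anchor.direction_before,
            direction_after=anchor.direction_after,
        ))
    return events, n_incomplete


def normalized_time(t, t_s: float, t_e: float):
    """Normalized event time (t - t_s)/(t_e - t_s); 0 at start, 1 at end."""
    if t_e <= t_s:
        raise ZeroDurationError("event has zero (or negative) duration")
    return (np.asarray(t, dtype=float) - t_s) / (t_e - t_s)


def position_rank(positions: np.ndarray, velocities: np.ndarray,
                  fish_ids: list[int] | None = None,
                  tol: float = 1e-9) -> np.ndarray | None:
    """Rank fish by advancement along the mean group velocity.

    Rank 1 is the most advanced projection on the unit mean-velocity vector;
    relative distances are ignored.  Ties break by ascending fish id.
    Returns None (undefined-rank marker) when the mean velocity is below
    ``tol``.
    """
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    n = len(positions)
    ids = np.asarray(fish_ids if fish_ids is not None else range(n))
    z = velocities.mean(axis=0)
    nz = np.linalg.norm(z)
    if not np.isfinite(nz) or nz < tol:
        return None
    proj = positions @ (z / nz)
    order = np.lexsort((ids, -proj))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def distance_rank(distances: np.ndarray,
                  neighbor_ids: list[int] | None = None) -> np.ndarray:
    """Rank the N-1 neighbors of a focal fish by distance (1 = nearest).

    Ties break by ascending neighbor id.
    """
    d = np.asarray(distances, dtype=float)
    ids = np.asarray(neighbor_ids if neighbor_ids is not None else range(len(d)))
    order = np.lexsort((ids, d))
    ranks = np.empty(len(d), dtype=int)
    ranks[order] = np.arange(1, len(d) + 1)
    return ranks


def turning_rank(event: UTurnEvent) -> dict[int, int]:
    """Rank fish by individual U-turn start time (1 = first; ties by id)."""
    items = sorted(event.individuals.values(), key=lambda u: (u.t_s, u.fish_id))
    return {u.fish_id: r for r, u in enumerate(items, start=1)}
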