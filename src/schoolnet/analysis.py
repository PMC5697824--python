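"""High-level pipeline: from a trajectory set to per-event influence records.

This layer composes the modules: kinematics -> U-turn detection -> delay
extraction -> influential-neighbor identification -> per-record geometry and
ranks.  The result of one collective U-turn is an :class:`EventAnalysis`,
the unit that the aggregation, null-model and sensitivity machinery consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .influence import (AnalysisConfig, CorrelationField, count_influential,
                        eta, extract_delays, identify_influential,
                        remove_influence_chains)
from .kinematics import KinematicState, compute_kinematics, pair_geometry_series, polarization
from .trajdata import TrajectorySet
from .uturns import UTurnConfig, UTurnEvent, detect_collective_uturns, distance_rank, position_rank, turning_rank

__all__ = ["EventAnalysis", "extract_all_delays", "analyze_event", "analyze_trajectories"]


@dataclass
class EventAnalysis:
    """Influence analysis of one collective U-turn.

    ``frames`` are the analyzed frame indices (the configured span in
    normalized event time, clipped to the record); ``records`` is the
    time-resolved influence edge list with per-record geometry and ranks;
    ``nif``/``eta_`` are (N, F) arrays over the analyzed frames; ``speed``
    and ``pol`` support the normalized-time courses.
    """

    event: UTurnEvent
    config: AnalysisConfig
    fish_ids: list[int]
    frames: np.ndarray
    tbar: np.ndarray
    records: pd.DataFrame
    nif: np.ndarray
    eta_: np.ndarray
    speed: np.ndarray
    pol: np.ndarray
    n_removed: int
    kin: KinematicState

    @property
    def in_uturn(self) -> np.ndarray:
        """Boolean mask over ``frames``: within [t_s, t_e]."""
        t = self.kin.times[self.frames]
        return (t >= self.event.t_s) & (t <= self.event.t_e)


def extract_all_delays(kin: KinematicState, config: AnalysisConfig,
                       start: int | None = None, stop: int | None = None):
    """Delay tracks for every ordered pair of fish.

    Returns ``{focal_id: {neighbor_id: DelayTrack}}``.
    """
    tracks: dict[int, dict] = {}
    for a, i in enumerate(kin.fish_ids):
        tracks[i] = {}
        for b, j in enumerate(kin.fish_ids):
            if i == j:
                continue
            field = CorrelationField(kin.e[a], kin.e[b], config.w)
            tracks[i][j] = extract_delays(
                kin.e[a], kin.e[b], config, start=start, stop=stop,
                focal=i, neighbor=j, field=field)
    return tracks


def _attach_geometry_and_ranks(records: pd.DataFrame, kin: KinematicState,
                               event: UTurnEvent) -> pd.DataFrame:
    """Add d_ij, theta_ij, phi_ij, focal-frame coordinates and ranks."""
    n = len(records)
    cols = {c: np.full(n, np.nan) for c in
            ("d_ij", "theta_ij", "phi_ij", "rel_x", "rel_y",
             "relv_x", "relv_y")}
    ranks = {c: np.full(n, -1, dtype=int) for c in
             ("dist_rank", "pos_rank", "turn_rank")}
    if n == 0:
        return records.assign(**cols, **ranks)
    turn_ranks = turning_rank(event)
    fidx = {f: k for k, f in enumerate(kin.fish_ids)}
    foc = records["focal"].to_numpy(dtype=int)
    nbr = records["neighbor"].to_numpy(dtype=int)
    frm = records["frame"].to_numpy(dtype=int)

    geo_cache: dict[tuple[int, int], dict] = {}

    def geo(i, j):
        g = geo_cache.get((i, j))
        if g is None:
            g = pair_geometry_series(kin, i, j)
            geo_cache[(i, j)] = g
        return g

    for (i, j), rows in records.groupby(["focal", "neighbor"]).groups.items():
        rows = np.asarray(rows)
        t = frm[rows]
        g = geo(int(i), int(j))
        cols["d_ij"][rows] = g["d_ij"][t]
        cols["theta_ij"][rows] = g["theta_ij"][t]
        cols["phi_ij"][rows] = g["phi_ij"][t]
        # neighbor position/velocity in the focal frame (heading along +y)
        a = np.pi / 2 - kin.phi[fidx[int(i)], t]
        ca, sa = np.cos(a), np.sin(a)
        ux, uy = g["u_ij"][t, 0], g["u_ij"][t, 1]
        vx, vy = g["v_ij"][t, 0], g["v_ij"][t, 1]
        cols["rel_x"][rows] = ca * ux - sa * uy
        cols["rel_y"][rows] = sa * ux + ca * uy
        cols["relv_x"][rows] = ca * vx - sa * vy
        cols["relv_y"][rows] = sa * vx + ca * vy
        ranks["turn_rank"][rows] = turn_ranks.get(int(j), -1)

    # distance and position ranks per needed frame
    needed = np.unique(frm)
    dist_rank_tab = np.full((kin.n_fish, kin.n_fish, len(needed)), -1, dtype=int)
    pos_rank_tab = np.full((kin.n_fish, len(needed)), -1, dtype=int)
    for i in kin.fish_ids:
        others = [f for f in kin.fish_ids if f != i]
        d_mat = np.stack([geo(i, f)["d_ij"][needed] for f in others])  # (N-1, F)
        for c in range(len(needed)):
            dr = distance_rank(d_mat[:, c], others)
            for oi, f in enumerate(others):
                dist_rank_tab[fidx[i], fidx[f], c] = dr[oi]
    for c, t in enumerate(needed):
        pr = position_rank(kin.positions[:, t], kin.vel[:, t], kin.fish_ids)
        if pr is not None:
            pos_rank_tab[:, c] = pr
    col_of = {t: c for c, t in enumerate(needed)}
    cidx = np.array([col_of[t] for t in frm])
    fi = np.array([fidx[f] for f in foc])
    ni = np.array([fidx[f] for f in nbr])
    ranks["dist_rank"] = dist_rank_tab[fi, ni, cidx]
    ranks["pos_rank"] = pos_rank_tab[ni, cidx]
    return records.assign(**cols, **ranks)


def analyze_event(kin: KinematicState, event: UTurnEvent,
                  config: AnalysisConfig,
                  tracks: dict | None = None) -> EventAnalysis:
    """Run the influential-neighbor analysis over one collective U-turn.

    The analysis span is ``config.span`` in normalized event time (default
    [-1, 2]: one duration before the start to one after the end), clipped to
    the record.  ``tracks`` may supply precomputed delay tracks (used by the
    sensitivity sweep, whose combos share them across thresholds).
    """
    dur = event.duration
    t0 = event.t_s + config.span[0] * dur
    t1 = event.t_s + config.span[1] * dur
    times = kin.times
    start = int(np.searchsorted(times, t0 - 1e-9))
    stop = int(np.searchsorted(times, t1 + 1e-9))
    start = max(start, 0)
    stop = min(stop, kin.n_frames)
    frames = np.arange(start, stop)

    if tracks is None:
        tracks = extract_all_delays(kin, config, start=start, stop=stop)

    recs = []
    for i in kin.fish_ids:
        recs.append(identify_influential(tracks[i], i, config, times, frames=frames))
    records = pd.concat(recs, ignore_index=True) if recs else pd.DataFrame()
    n_removed = 0
    if config.chain_removal:
        records, n_removed = remove_influence_chains(records)
    records = _attach_geometry_and_ranks(records, kin, event)

    nif = count_influential(records, kin.fish_ids, frames)
    idxs = [kin.index_of(f) for f in kin.fish_ids]
    speed = kin.speed[idxs][:, frames]
    pol = polarization(kin.e[idxs][:, frames])
    tbar = (times[frames] - event.t_s) / dur
    return EventAnalysis(
        event=event, config=config, fish_ids=list(kin.fish_ids),
        frames=frames, tbar=tbar, records=records, nif=nif,
        eta_=eta(nif), speed=speed, pol=pol, n_removed=n_removed, kin=kin,
    )


def analyze_trajectories(ts: TrajectorySet, config: AnalysisConfig = AnalysisConfig(),
                         uconfig: UTurnConfig = UTurnConfig(),
                         speed_floor: float = 1.0):
    """Full pipeline on a trajectory set: one :class:`EventAnalysis` per
    detected collective U-turn.  Returns ``(analyses, n_incomplete)``."""
    kin = compute_kinematics(ts, speed_floor=speed_floor)
    events, n_incomplete = detect_collective_uturns(kin, uconfig)
    return [analyze_event(kin, ev, config) for ev in events], n_incomplete
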