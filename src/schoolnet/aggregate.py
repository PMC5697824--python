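"""Cross-event aggregation: rank/count histograms, normalized-time courses,
spatial density and relative-velocity maps, and delay maps.

All aggregates operate on lists of :class:`~schoolnet.analysis.EventAnalysis`
and report proportions or per-bin means; empty bins carry NaN markers, never
zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import EventAnalysis
from .kinematics import pair_geometry_series

__all__ = [
    "RankHistograms",
    "TimeCourse",
    "SpatialMap",
    "rank_histograms",
    "time_course",
    "spatial_map",
    "angle_distance_distributions",
    "delay_map",
]


@dataclass
class RankHistograms:
    """Proportions of U-turn time by influential-neighbor class.

    ``nif`` has N bins (N_if = 0..N-1 over focal-fish frames); ``dist_rank``
    has N-1 bins; ``pos_rank`` and ``turn_rank`` have N bins, all over
    influence records.  ``empty`` flags blocks with no contributing samples
    (their entries are zeros).
    """

    nif: np.ndarray
    dist_rank: np.ndarray
    pos_rank: np.ndarray
    turn_rank: np.ndarray
    empty: dict[str, bool] = field(default_factory=dict)


def rank_histograms(analyses: list[EventAnalysis], n_fish: int,
                    within_uturn: bool = True) -> RankHistograms:
    """Pool the four influential-neighbor histograms across events.

    Each focal-fish frame contributes one sample to the N_if histogram; each
    influence record contributes one sample to the rank histograms.  With
    ``within_uturn`` (default) only frames inside [t_s, t_e] count, matching
    the proportion-of-U-turn-time reading.
    """
    nif_counts = np.zeros(n_fish)
    dist_counts = np.zeros(n_fish - 1) if n_fish > 1 else np.zeros(0)
    pos_counts = np.zeros(n_fish)
    turn_counts = np.zeros(n_fish)
    for an in analyses:
        mask = an.in_uturn if within_uturn else np.ones(len(an.frames), bool)
        vals = an.nif[:, mask].ravel()
        vals = np.clip(vals, 0, n_fish - 1)
        nif_counts += np.bincount(vals, minlength=n_fish)
        rec = an.records
        if within_uturn and len(rec):
            t = an.kin.times[rec["frame"].to_numpy()]
            rec = rec[(t >= an.event.t_s) & (t <= an.event.t_e)]
        for col, counts, max_rank in (("dist_rank", dist_counts, n_fish - 1),
                                      ("pos_rank", pos_counts, n_fish),
                                      ("turn_rank", turn_counts, n_fish)):
            if len(rec):
                r = rec[col].to_numpy()
                r = r[(r >= 1) & (r <= max_rank)]
                counts += np.bincount(r - 1, minlength=max_rank)

    def norm(c):
        s = c.sum()
        return (c / s if s > 0 else c), s == 0

    nif_h, e1 = norm(nif_counts)
    d_h, e2 = norm(dist_counts)
    p_h, e3 = norm(pos_counts)
    t_h, e4 = norm(turn_counts)
    return RankHistograms(nif=nif_h, dist_rank=d_h, pos_rank=p_h, turn_rank=t_h,
                          empty={"nif": bool(e1), "dist_rank": bool(e2),
                                 "pos_rank": bool(e3), "turn_rank": bool(e4)})


@dataclass
class TimeCourse:
    """Cross-event averages on the normalized-time grid t-bar in [-1, 2]."""

    grid: np.ndarray
    speed: np.ndarray
    pol: np.ndarray
    nif: np.ndarray
    eta: np.ndarray
    counts: dict[str, np.ndarray] = field(default_factory=dict)


def _accumulate(grid, x, y, total, count):
    """Add linear interpolation of (x, y) onto grid points inside x's span."""
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return
    xs, ys = x[ok], y[ok]
    inside = (grid >= xs[0]) & (grid <= xs[-1])
    total[inside] += np.interp(grid[inside], xs, ys)
    count[inside] += 1


def time_course(analyses: list[EventAnalysis], step: float = 0.05) -> TimeCourse:
    """Average speed, polarization, N_if and eta in normalized event time.

    Per event and fish, series are linearly interpolated onto the grid over
    the event's own t-bar span and averaged with per-point counts; eta is
    averaged over defined frames only (its NaN zero-denominator frames are
    sampled at the nearest frame rather than interpolated across).
    """
    grid = np.round(np.arange(-1.0, 2.0 + step / 2, step), 10)
    g = len(grid)
    tot = {k: np.zeros(g) for k in ("speed", "pol", "nif", "eta")}
    cnt = {k: np.zeros(g) for k in ("speed", "pol", "nif", "eta")}
    for an in analyses:
        x = an.tbar
        for i in range(len(an.fish_ids)):
            _accumulate(grid, x, an.speed[i], tot["speed"], cnt["speed"])
            _accumulate(grid, x, an.nif[i].astype(float), tot["nif"], cnt["nif"])
            # eta: nearest-frame sampling over defined frames only
            e = an.eta_[i]
            if len(x):
                inside = (grid >= x[0]) & (grid <= x[-1])
                nearest = np.searchsorted(x, grid[inside])
                nearest = np.clip(nearest, 0, len(x) - 1)
                vals = e[nearest]
                okv = np.isfinite(vals)
                idxs = np.where(inside)[0][okv]
                tot["eta"][idxs] += vals[okv]
                cnt["eta"][idxs] += 1
        _accumulate(grid, x, an.pol, tot["pol"], cnt["pol"])
    out = {}
    for k in tot:
        with np.errstate(invalid="ignore", divide="ignore"):
            out[k] = np.where(cnt[k] > 0, tot[k] / np.maximum(cnt[k], 1), np.nan)
    return TimeCourse(grid=grid, speed=out["speed"], pol=out["pol"],
                      nif=out["nif"], eta=out["eta"], counts=cnt)


@dataclass
class SpatialMap:
    """Focal-frame maps of influential-neighbor locations.

    The focal fish sits at the origin heading along +y, so "ahead" is up.
    ``occupancy`` counts records per square cell; ``mean_vel`` is the mean
    relative velocity per cell (NaN where empty).  ``polar_hist`` is the
    companion (angle x radius) histogram of (theta_ij, d_ij).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy: np.ndarray
    mean_vel: np.ndarray
    angle_edges: np.ndarray
    radius_edges: np.ndarray
    polar_hist: np.ndarray


def spatial_map(analyses: list[EventAnalysis], cell: float = 20.0,
                extent: float = 200.0, angle_bin_deg: float = 30.0,
                radius_bin: float = 20.0) -> SpatialMap:
    """Density and mean-relative-velocity map of influential neighbors."""
    nb = int(np.ceil(extent / cell))
    edges = np.arange(-nb, nb + 1) * cell
    occ = np.zeros((len(edges) - 1, len(edges) - 1))
    vsum = np.zeros((len(edges) - 1, len(edges) - 1, 2))
    a_edges = np.radians(np.arange(-180.0, 180.0 + angle_bin_deg / 2, angle_bin_deg))
    r_edges = np.arange(0.0, extent + radius_bin / 2, radius_bin)
    ph = np.zeros((len(a_edges) - 1, len(r_edges) - 1))
    for an in analyses:
        rec = an.records
        if not len(rec):
            continue
        x = rec["rel_x"].to_numpy()
        y = rec["rel_y"].to_numpy()
        vx = rec["relv_x"].to_numpy()
        vy = rec["relv_y"].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        h, _, _ = np.histogram2d(x[ok], y[ok], bins=(edges, edges))
        occ += h
        ix = np.clip(np.digitize(x[ok], edges) - 1, 0, len(edges) - 2)
        iy = np.clip(np.digitize(y[ok], edges) - 1, 0, len(edges) - 2)
        np.add.at(vsum, (ix, iy, 0), vx[ok])
        np.add.at(vsum, (ix, iy, 1), vy[ok])
        th = rec["theta_ij"].to_numpy()
        d = rec["d_ij"].to_numpy()
        okp = np.isfinite(th) & np.isfinite(d)
        hp, _, _ = np.histogram2d(th[okp], d[okp], bins=(a_edges, r_edges))
        ph += hp
    with np.errstate(invalid="ignore"):
        mean_vel = np.where(occ[..., None] > 0, vsum / np.maximum(occ[..., None], 1), np.nan)
    return SpatialMap(x_edges=edges, y_edges=edges, occupancy=occ,
                      mean_vel=mean_vel, angle_edges=a_edges,
                      radius_edges=r_edges, polar_hist=ph)


def angle_distance_distributions(analyses: list[EventAnalysis],
                                 d_bin: float = 10.0, d_max: float = 300.0,
                                 angle_bin_deg: float = 15.0,
                                 within_uturn: bool = True) -> dict:
    """Distance and viewing-angle distributions: influential vs all pairs.

    Returns a dict with histogram arrays and (mean, sd) for ``d_ij`` and
    ``theta_ij`` of (i) influential pairs (one sample per record) and
    (ii) all ordered pairs at the analyzed frames.
    """
    d_edges = np.arange(0.0, d_max + d_bin / 2, d_bin)
    a_edges = np.radians(np.arange(-180.0, 180.0 + angle_bin_deg / 2, angle_bin_deg))
    infl_d, infl_a, all_d, all_a = [], [], [], []
    for an in analyses:
        rec = an.records
        mask = an.in_uturn if within_uturn else np.ones(len(an.frames), bool)
        sel_frames = an.frames[mask]
        if len(rec):
            t = an.kin.times[rec["frame"].to_numpy()]
            rmask = ((t >= an.event.t_s) & (t <= an.event.t_e)) if within_uturn \
                else np.ones(len(rec), bool)
            infl_d.append(rec["d_ij"].to_numpy()[rmask])
            infl_a.append(rec["theta_ij"].to_numpy()[rmask])
        for i in an.fish_ids:
            for j in an.fish_ids:
                if i == j:
                    continue
                g = pair_geometry_series(an.kin, i, j, sel_frames)
                all_d.append(g["d_ij"])
                all_a.append(g["theta_ij"])

    def summarize(vals, edges):
        v = np.concatenate(vals) if vals else np.array([])
        v = v[np.isfinite(v)]
        hist, _ = np.histogram(v, bins=edges)
        total = hist.sum()
        return {
            "hist": hist / total if total else hist.astype(float),
            "edges": edges,
            "mean": float(np.mean(v)) if v.size else np.nan,
            "sd": float(np.std(v)) if v.size else np.nan,
            "n": int(v.size),
        }

    return {
        "influential_distance": summarize(infl_d, d_edges),
        "influential_angle": summarize(infl_a, a_edges),
        "all_distance": summarize(all_d, d_edges),
        "all_angle": summarize(all_a, a_edges),
    }


def delay_map(analyses: list[EventAnalysis], phi_bin_deg: float = 20.0,
              d_bin: float = 20.0, d_max: float = 300.0) -> dict:
    """Mean extracted delay per (heading-difference, distance) bin.

    Empty bins are NaN, never zero.  Returns ``{phi_edges, d_edges, mean_tau,
    counts}``.
    """
    p_edges = np.radians(np.arange(-180.0, 180.0 + phi_bin_deg / 2, phi_bin_deg))
    d_edges = np.arange(0.0, d_max + d_bin / 2, d_bin)
    tsum = np.zeros((len(p_edges) - 1, len(d_edges) - 1))
    cnt = np.zeros_like(tsum)
    for an in analyses:
        rec = an.records
        if not len(rec):
            continue
        phi = rec["phi_ij"].to_numpy()
        d = rec["d_ij"].to_numpy()
        tau = rec["tau_s"].to_numpy()
        ok = np.isfinite(phi) & np.isfinite(d) & (d < d_max)
        ip = np.clip(np.digitize(phi[ok], p_edges) - 1, 0, len(p_edges) - 2)
        idd = np.clip(np.digitize(d[ok], d_edges) - 1, 0, len(d_edges) - 2)
        np.add.at(tsum, (ip, idd), tau[ok])
        np.add.at(cnt, (ip, idd), 1)
    with np.errstate(invalid="ignore"):
        mean_tau = np.where(cnt > 0, tsum / np.maximum(cnt, 1), np.nan)
    return {"phi_edges": p_edges, "d_edges": d_edges,
            "mean_tau": mean_tau, "counts": cnt}
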