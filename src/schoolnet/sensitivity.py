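"""Parameter-selection machinery: the 40-combination sweep, 19-dimensional
summary vectors, the cosine-similarity matrix, and C_min retention curves.

The identification depends on three global parameters (window half-width w,
threshold C_min, multi-influencer tolerance eps).  Each combination is
summarized by concatenating the four influential-neighbor histograms of a
5-fish analysis into a 19-vector (5 N_if proportions, 4 distance-rank, 5
position-rank, 5 turning-rank proportions); combinations are compared by
cosine similarity.  Delay tracks depend only on w, so the sweep caches them
across the threshold combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregate import RankHistograms, rank_histograms
from .analysis import analyze_event, extract_all_delays
from .errors import SchoolnetError, UndefinedSimilarityError
from .influence import AnalysisConfig

__all__ = [
    "SWEEP_W", "SWEEP_EPS", "SWEEP_CMIN",
    "sweep_grid", "summary_vector", "cosine_similarity",
    "run_sweep", "similarity_matrix", "retention_curve", "SweepResult",
]

SWEEP_W = (0, 1, 2, 3, 4)
SWEEP_EPS = (3.0, 5.0)
SWEEP_CMIN = (0.995, 0.99, 0.95, 0.5)


def sweep_grid() -> list[tuple[float, float, int]]:
    """The 40 (eps, C_min, w) combinations, ordered lexicographically."""
    return [(e, c, w)
            for e in sorted(SWEEP_EPS)
            for c in sorted(SWEEP_CMIN)
            for w in sorted(SWEEP_W)]


def summary_vector(hists: RankHistograms):
    """Concatenate the four histogram blocks into the 19-dim summary.

    Block order: N_if proportions (5), distance rank (4), position rank (5),
    turning rank (5).  Empty blocks contribute zeros and are flagged.
    """
    vec = np.concatenate([hists.nif, hists.dist_rank, hists.pos_rank,
                          hists.turn_rank])
    return vec, dict(hists.empty)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos of the angle between two vectors; 1 iff proportion vectors agree."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError("zero-norm summary vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class SweepResult:
    combos: list[tuple[float, float, int]]
    vectors: np.ndarray          # (40, 19), NaN rows where a combo failed
    matrix: np.ndarray           # (40, 40) cosine similarities, NaN missing
    flags: list[dict] = field(default_factory=list)


def run_sweep(datasets: list[tuple], base: AnalysisConfig,
              n_fish: int = 5) -> SweepResult:
    """Run the full pipeline for all 40 combinations over the datasets.

    ``datasets`` is a list of ``(kin, event)`` pairs (one per collective
    U-turn).  Delay tracks are extracted once per w and reused for every
    (C_min, eps) pair; a failing combo leaves a NaN row/column, and the sweep
    continues.
    """
    combos = sweep_grid()
    vectors = np.full((len(combos), 4 * n_fish - 1), np.nan)
    flags: list[dict] = [{} for _ in combos]
    track_cache: dict[int, list] = {}
    for ci, (eps_v, cmin_v, w_v) in enumerate(combos):
        cfg = base.with_(w=w_v, c_min=cmin_v, eps=eps_v)
        try:
            if w_v not in track_cache:
                per_event = []
                for kin, ev in datasets:
                    dur = ev.duration
                    t0 = ev.t_s + cfg.span[0] * dur
                    t1 = ev.t_s + cfg.span[1] * dur
                    start = max(0, int(np.searchsorted(kin.times, t0 - 1e-9)))
                    stop = min(kin.n_frames, int(np.searchsorted(kin.times, t1 + 1e-9)))
                    per_event.append(extract_all_delays(kin, cfg, start, stop))
                track_cache[w_v] = per_event
            analyses = [
                analyze_event(kin, ev, cfg, tracks=track_cache[w_v][k])
                for k, (kin, ev) in enumerate(datasets)
            ]
            hists = rank_histograms(analyses, n_fish)
            vec, fl = summary_vector(hists)
            vectors[ci] = vec
            flags[ci] = fl
        except SchoolnetError as err:
            flags[ci] = {"failed": str(err)}
    matrix = similarity_matrix(vectors)
    return SweepResult(combos=combos, vectors=vectors, matrix=matrix, flags=flags)


def similarity_matrix(vectors: np.ndarray) -> np.ndarray:
    """Symmetric cosine-similarity matrix with unit diagonal.

    Rows that are all-NaN (failed combos) leave NaN cells; zero-norm vectors
    likewise yield NaN cells rather than aborting the sweep.
    """
    n = len(vectors)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            a, b = vectors[i], vectors[j]
            if np.any(np.isnan(a)) or np.any(np.isnan(b)):
                continue
            try:
                s = cosine_similarity(a, b)
            except UndefinedSimilarityError:
                continue
            mat[i, j] = mat[j, i] = s
    return mat


def retention_curve(datasets: list[tuple], config: AnalysisConfig,
                    c_min_values=SWEEP_CMIN) -> pd.DataFrame:
    """Data retention as a function of C_min.

    For each threshold, counts the (focal, frame) pairs keeping at least one
    candidate that passes both the correlation and the reaction-time gates;
    retention depends only on thresholding, so delay tracks are extracted
    once.  Fractions are relative to the count at C_min = 0.5.

    ``datasets`` is a list of ``(kin, event)`` pairs as in :func:`run_sweep`.
    """
    best_gammas = []
    for kin, ev in datasets:
        dur = ev.duration
        t0 = ev.t_s + config.span[0] * dur
        t1 = ev.t_s + config.span[1] * dur
        start = max(0, int(np.searchsorted(kin.times, t0 - 1e-9)))
        stop = min(kin.n_frames, int(np.searchsorted(kin.times, t1 + 1e-9)))
        tracks = extract_all_delays(kin, config, start, stop)
        for i in kin.fish_ids:
            per = tracks[i]
            gam = np.stack([per[j].gamma for j in per])
            tau = np.stack([per[j].tau_frames for j in per])
            ok = (tau >= 0) & (tau * config.dt > config.tau_r)
            masked = np.where(ok, gam, -np.inf)
            best = masked.max(axis=0)[start:stop]
            best_gammas.append(best[np.isfinite(best) | (best == -np.inf)])
    best_all = np.concatenate(best_gammas) if best_gammas else np.array([])
    ref = int(np.sum(best_all > 0.5))
    rows = []
    for c in sorted(c_min_values, reverse=True):
        cnt = int(np.sum(best_all > c))
        rows.append({"c_min": c, "count": cnt,
                     "fraction": cnt / ref if ref else np.nan})
    return pd.DataFrame(rows)
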