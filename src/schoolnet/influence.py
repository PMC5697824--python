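"""Time-delayed directional correlation and influential-neighbor inference.

The core quantity is the directional correlation

    H_ij(t, tau) = e_i(t) . e_j(t - tau),

the cosine of the angle between the focal fish's unit heading now and a
neighbor's unit heading ``tau`` seconds earlier, and its average C_ij(t, tau,
w) over a centered window of 2w+1 frames.  Per frame, the delay tau*_k that
maximizes C is extracted recursively: the search range at frame k is
[0, tau*_{k-1} + 1] frames, encoding the assumption that once a fish copies
a neighbor's past heading it will not later copy an even older one.  A
neighbor is influential at a frame when its windowed correlation at the
extracted delay exceeds C_min and the delay exceeds the reaction-time floor
tau_R; when several neighbors pass, those within eps percent of the best
score all qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import TooShortError

__all__ = [
    "AnalysisConfig",
    "CorrelationField",
    "DelayTrack",
    "directional_correlation",
    "windowed_correlation",
    "extract_delays",
    "identify_influential",
    "count_influential",
    "eta",
    "remove_influence_chains",
    "global_delay",
    "RECORD_COLUMNS",
]

#: columns of the influence-record table (the time-resolved edge list)
RECORD_COLUMNS = ["frame", "t", "focal", "neighbor", "tau_frames", "tau_s", "C"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the influential-neighbor identification.

    w : half-window (frames) of the correlation average (window = 2w+1);
    c_min : correlation threshold a neighbor must exceed;
    eps : multi-influencer tolerance, percent of the top passing score;
    tau_r : reaction-time floor (s) below which a delay is not biologically
        attributable to influence;
    tau0 : initial delay bound (frames) of the extraction recursion;
    dt : frame period (s);
    span : analysis window in normalized event time (t-bar units);
    chain_removal : drop records explained by chains of influence.
    """

    w: int = 2
    c_min: float = 0.95
    eps: float = 3.0
    tau_r: float = 0.04
    tau0: int = 50
    dt: float = 0.02
    span: tuple[float, float] = (-1.0, 2.0)
    chain_removal: bool = False

    def __post_init__(self):
        if self.w < 0 or self.eps < 0 or self.tau_r < 0 or self.tau0 < 0:
            raise ValueError("w, eps, tau_r, tau0 must be >= 0")
        if not -1.0 <= self.c_min <= 1.0:
            raise ValueError("c_min must lie in [-1, 1]")

    def with_(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


def directional_correlation(e_i: np.ndarray, e_j: np.ndarray) -> float:
    """Dot product of two unit headings; NaN components give a NaN marker."""
    return float(np.dot(np.asarray(e_i, float), np.asarray(e_j, float)))


class CorrelationField:
    """Lazy grid of windowed correlations C_ij(t, tau, w) for one ordered pair.

    Columns (fixed tau) are computed on demand and cached.  A cell is NaN
    (masked) when the window is incomplete at either end of the record or any
    contributing heading is undefined: history must reach back to
    ``t - tau - w`` frames.
    """

    def __init__(self, e_i: np.ndarray, e_j: np.ndarray, w: int):
        self.e_i = np.asarray(e_i, dtype=float)
        self.e_j = np.asarray(e_j, dtype=float)
        if self.e_i.shape != self.e_j.shape or self.e_i.ndim != 2:
            raise ValueError("headings must be (T, 2) arrays of equal shape")
        self.w = int(w)
        self.n_frames = self.e_i.shape[0]
        self._cols: dict[int, np.ndarray] = {}

    def h_column(self, tau: int) -> np.ndarray:
        """H_ij(t, tau) for all t; NaN where t - tau precedes the record."""
        t = self.n_frames
        h = np.full(t, np.nan)
        if tau < t:
            a = self.e_i[tau:]
            b = self.e_j[:t - tau] if tau else self.e_j
            h[tau:] = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
        return h

    def column(self, tau: int) -> np.ndarray:
        col = self._cols.get(tau)
        if col is None:
            h = self.h_column(tau)
            w = self.w
            col = np.full(self.n_frames, np.nan)
            if self.n_frames >= 2 * w + 1:
                win = np.lib.stride_tricks.sliding_window_view(h, 2 * w + 1)
                col[w:self.n_frames - w] = win.mean(axis=-1)
            self._cols[tau] = col
        return col

    def value(self, t_idx: int, tau: int) -> float:
        return float(self.column(tau)[t_idx])

    def row(self, t_idx: int, tau_max: int) -> np.ndarray:
        """C(t_idx, tau) for tau = 0..tau_max inclusive."""
        return np.array([self.column(tau)[t_idx] for tau in range(tau_max + 1)])


def windowed_correlation(e_i: np.ndarray, e_j: np.ndarray,
                         t_idx: int, tau: int, w: int) -> float:
    """C_ij(t, tau, w): mean of H over the 2w+1 frames centered on t.

    Returns NaN when any term is unavailable.
    """
    return CorrelationField(e_i, e_j, w).value(t_idx, tau)


@dataclass
class DelayTrack:
    """Extracted per-frame delays for one ordered pair (focal, neighbor).

    ``tau_frames[t] = -1`` and ``gamma[t] = NaN`` mark frames where the
    extraction is undefined (window unavailable or headings missing).
    """

    focal: int
    neighbor: int
    w: int
    tau_frames: np.ndarray  # (T,) int
    gamma: np.ndarray       # (T,) float

    @property
    def defined(self) -> np.ndarray:
        return self.tau_frames >= 0


def extract_delays(e_i: np.ndarray, e_j: np.ndarray, config: AnalysisConfig,
                   start: int | None = None, stop: int | None = None,
                   focal: int = -1, neighbor: int = -1,
                   field: CorrelationField | None = None) -> DelayTrack:
    """Recursive per-frame delay extraction for one ordered pair.

    At each analyzed frame the windowed correlation is maximized over delays
    in [0, tau*_{prev} + 1] frames; the smallest delay attaining the maximum
    is kept.  The first search range is [0, tau0] (tau0 clipped to the
    largest delay the record can ever host), and extraction begins at the
    first frame where that full initial range is available -- a narrower
    start would pin the recursion to small delays and strand it at local
    correlation maxima, defeating the purpose of the wide initial bound.
    Earlier frames are reported undefined.  ``start``/``stop`` restrict the
    analyzed frames; the correlation window may still reach into history
    before ``start``.

    Raises
    ------
    TooShortError
        If the series cannot host a single full correlation window.
    """
    if field is None:
        field = CorrelationField(e_i, e_j, config.w)
    t_total = field.n_frames
    w = config.w
    if t_total < 2 * w + 1:
        raise TooShortError("series shorter than the correlation window")
    tau0_eff = min(int(config.tau0), t_total - 2 * w - 1)
    first = max(w, tau0_eff + w, 0 if start is None else int(start))
    last = min(t_total - w, t_total if stop is None else int(stop))
    tau = np.full(t_total, -1, dtype=int)
    gamma = np.full(t_total, np.nan)
    prev = tau0_eff - 1  # so the first range is [0, tau0_eff]
    for t in range(first, last):
        hi = min(prev + 1, t - w)
        if hi < 0:
            continue
        vals = field.row(t, hi)
        if np.all(np.isnan(vals)):
            continue
        k = int(np.nanargmax(vals))  # first occurrence = smallest tau on ties
        tau[t] = k
        gamma[t] = vals[k]
        prev = k
    return DelayTrack(focal=focal, neighbor=neighbor, w=w,
                      tau_frames=tau, gamma=gamma)


def identify_influential(tracks: dict[int, DelayTrack], focal: int,
                         config: AnalysisConfig, times: np.ndarray,
                         frames: np.ndarray | None = None) -> pd.DataFrame:
    """Influential neighbors of one focal fish, frame by frame.

    A candidate neighbor passes when its correlation at the extracted delay
    exceeds ``c_min`` and the delay exceeds ``tau_r`` seconds; among passing
    candidates, all with scores within ``eps`` percent of the maximum are
    emitted as influence records.
    """
    neighbors = sorted(tracks)
    if not neighbors:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    gam = np.stack([tracks[j].gamma for j in neighbors])        # (M, T)
    tau = np.stack([tracks[j].tau_frames for j in neighbors])   # (M, T)
    passing = (gam > config.c_min) & (tau * config.dt > config.tau_r) & (tau >= 0)
    masked = np.where(passing, gam, -np.inf)
    gmax = masked.max(axis=0)
    keep = passing & (gam >= (1.0 - config.eps / 100.0) * gmax[None, :])
    if frames is not None:
        sel = np.zeros(gam.shape[1], dtype=bool)
        sel[frames] = True
        keep &= sel[None, :]
    m_idx, t_idx = np.where(keep)
    return pd.DataFrame({
        "frame": t_idx,
        "t": times[t_idx],
        "focal": focal,
        "neighbor": np.asarray(neighbors)[m_idx],
        "tau_frames": tau[m_idx, t_idx],
        "tau_s": tau[m_idx, t_idx] * config.dt,
        "C": gam[m_idx, t_idx],
    }).sort_values(["frame", "neighbor"], kind="mergesort").reset_index(drop=True)


def count_influential(records: pd.DataFrame, fish_ids: list[int],
                      frames: np.ndarray) -> np.ndarray:
    """Number of distinct influential neighbors N_if per (fish, frame).

    Returns an (N, len(frames)) integer array aligned with ``fish_ids`` and
    the (sorted, contiguous or not) ``frames`` index array.
    """
    frames = np.asarray(frames)
    pos = {f: k for k, f in enumerate(frames)}
    fidx = {f: k for k, f in enumerate(fish_ids)}
    nif = np.zeros((len(fish_ids), len(frames)), dtype=int)
    if len(records):
        for row in records.itertuples(index=False):
            k = pos.get(int(row.frame))
            if k is not None:
                nif[fidx[int(row.focal)], k] += 1
    return nif


def eta(nif: np.ndarray) -> np.ndarray:
    """Relative variation |N_if(t+dt) - N_if(t)| / N_if(t) of one fish.

    Frames with N_if = 0 (and the final frame) are NaN markers, excluded
    from any downstream average.
    """
    nif = np.asarray(nif, dtype=float)
    out = np.full(nif.shape, np.nan)
    denom = nif[..., :-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.abs(nif[..., 1:] - denom) / denom
    out[..., :-1] = np.where(denom > 0, val, np.nan)
    return out


def remove_influence_chains(records: pd.DataFrame):
    """Drop pairwise records explained by a simultaneous chain of influence.

    If focal F1 is influenced by both F2 and F3 at a frame and F2 is itself
    influenced by F3 there, the (F1, F2) record is dropped (and symmetrically
    (F1, F3) when F3 is influenced by F2).  Conditions are evaluated on the
    input set and removals applied in one pass, which makes the operation
    idempotent.  Returns ``(filtered records, number removed)``.
    """
    if not len(records):
        return records.copy(), 0
    present = set(zip(records["frame"].astype(int),
                      records["focal"].astype(int),
                      records["neighbor"].astype(int)))
    drop: set[tuple[int, int, int]] = set()
    by_focal: dict[tuple[int, int], list[int]] = {}
    for f, foc, nb in present:
        by_focal.setdefault((f, foc), []).append(nb)
    for (f, foc), nbs in by_focal.items():
        if len(nbs) < 2:
            continue
        for a, b in combinations(sorted(nbs), 2):
            if (f, a, b) in present:   # a influenced by b -> drop (focal, a)
                drop.add((f, foc, a))
            if (f, b, a) in present:
                drop.add((f, foc, b))
    if not drop:
        return records.copy(), 0
    key = list(zip(records["frame"].astype(int), records["focal"].astype(int),
                   records["neighbor"].astype(int)))
    mask = np.array([k not in drop for k in key])
    return records[mask].reset_index(drop=True), int((~mask).sum())


def global_delay(e_i: np.ndarray, e_j: np.ndarray,
                 max_tau: int | None = None) -> int:
    """Single dataset-wide delay: argmax over tau of the time-averaged H.

    This is the classic constant-delay leadership measure; the per-frame
    recursion above generalizes it.  Delays whose overlap with the record is
    empty are excluded; ties resolve to the smallest delay.
    """
    e_i = np.asarray(e_i, dtype=float)
    e_j = np.asarray(e_j, dtype=float)
    t = e_i.shape[0]
    if t < 2:
        raise TooShortError("need at least two frames")
    if max_tau is None:
        max_tau = t - 1
    best_tau, best = None, -np.inf
    for tau in range(min(max_tau, t - 1) + 1):
        a = e_i[tau:]
        b = e_j[:t - tau] if tau else e_j
        h = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
        if np.all(np.isnan(h)):
            continue
        m = np.nanmean(h)
        if m > best:
            best, best_tau = m, tau
    if best_tau is None:
        raise TooShortError("no delay with a non-empty overlap")
    return best_tau
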