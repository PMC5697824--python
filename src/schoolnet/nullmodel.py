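"""Bootstrap null model: artificial collective U-turns from independent
individual turns.

To show that detected influence does not arise from chance or from the
channeled motion in the annular corridor, artificial groups are assembled
from individual U-turn trajectories sampled from *different* real (here:
source) collective events.  Each sampled trajectory is rigidly rotated so
its turning point lands in the upper part of the tank (angular position
pi/2 +- xi), time-shifted so it turns near time zero (+- zeta), and mirrored
if needed so all group members circulate in the same direction as a randomly
chosen reference fish.  The identical analysis pipeline is then run on the
artificial events: any influence it reports is spurious by construction.

Random draws consume a single seeded generator in a fixed order per event
(source events, fish within events, reference, xi's, zeta's) so ensembles
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._angles import wrap_angle
from .analysis import EventAnalysis, analyze_event
from .errors import InsufficientPoolError, SchoolnetError
from .influence import AnalysisConfig
from .kinematics import compute_kinematics
from .trajdata import FishTrack, RingGeometry, TrajectorySet, from_polar
from .uturns import UTurnConfig, UTurnEvent, detect_collective_uturns

__all__ = [
    "NullConfig",
    "TurnTrack",
    "ArtificialUTurn",
    "extract_turn_tracks",
    "rotate_track",
    "shift_track",
    "mirror_track",
    "build_artificial_uturn",
    "generate_null_ensemble",
]


@dataclass(frozen=True)
class NullConfig:
    """Null-ensemble parameters: rotation range xi (rad), time-shift range
    zeta (s), group size, ensemble size and seed."""

    xi_range: float = np.pi / 12
    zeta_range: float = 1.0
    group_size: int = 5
    n_events: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.xi_range < np.pi:
            raise ValueError("xi_range must lie in (0, pi)")
        if self.zeta_range <= 0 or self.group_size < 2:
            raise ValueError("zeta_range > 0 and group_size >= 2 required")


@dataclass
class TurnTrack:
    """One individual U-turn trajectory in polar form.

    ``turn_idx`` is the frame of the turn instant (sin(theta_w) sign change);
    ``direction_before`` is +1 for anticlockwise circulation before the turn.
    """

    times: np.ndarray
    rho: np.ndarray
    psi: np.ndarray
    turn_idx: int
    dt: float
    source_event: int
    source_fish: int
    direction_before: int

    def __len__(self):
        return len(self.times)


def extract_turn_tracks(kin, events: list[UTurnEvent],
                        source_event_offset: int = 0,
                        pad: int = 150) -> list[TurnTrack]:
    """Cut each fish's individual U-turn window out of a recording.

    The window spans ``pad`` frames on each side of the turn instant (clipped
    to the record), wide enough for the downstream bounding and correlation
    windows.  ``source_event_offset`` keeps event ids unique when pooling
    several recordings.
    """
    out = []
    for e_num, ev in enumerate(events):
        for fish_id, iu in ev.individuals.items():
            k = kin.index_of(fish_id)
            lo = max(0, iu.m_idx - pad)
            hi = min(kin.n_frames, iu.m_idx + pad + 1)
            d = 1 if iu.direction_before == "anticlockwise" else -1
            out.append(TurnTrack(
                times=kin.times[lo:hi].copy(),
                rho=kin.rho[k, lo:hi].copy(),
                psi=kin.psi[k, lo:hi].copy(),
                turn_idx=iu.m_idx - lo,
                dt=kin.dt,
                source_event=source_event_offset + e_num,
                source_fish=fish_id,
                direction_before=d,
            ))
    return out


def rotate_track(track: TurnTrack, xi: float) -> TurnTrack:
    """Rotate so the turning point's angular position becomes pi/2 + xi."""
    if not 0 <= track.turn_idx < len(track):
        raise SchoolnetError("turn instant outside the track")
    delta = -track.psi[track.turn_idx] + np.pi / 2 + xi
    return replace(track, psi=wrap_angle(track.psi + delta), rho=track.rho.copy(),
                   times=track.times.copy())


def shift_track(track: TurnTrack, zeta: float) -> TurnTrack:
    """Shift the clock so the turn happens at time ``zeta``.

    ``zeta`` is snapped to the frame grid so shifted tracks from different
    sources still share a common clock.
    """
    zeta_snapped = round(zeta / track.dt) * track.dt
    new_times = (np.arange(len(track)) - track.turn_idx) * track.dt + zeta_snapped
    return replace(track, times=new_times, rho=track.rho.copy(), psi=track.psi.copy())


def mirror_track(track: TurnTrack) -> TurnTrack:
    """Reflect across the vertical axis through the tank center.

    psi maps to pi - psi, which keeps the relocated turning region (upper
    tank) in place while reversing the circulation direction; applying it
    twice is the identity.
    """
    return replace(track, psi=wrap_angle(np.pi - track.psi),
                   rho=track.rho.copy(), times=track.times.copy(),
                   direction_before=-track.direction_before)


@dataclass
class ArtificialUTurn:
    """A recombined artificial collective U-turn plus its provenance."""

    ts: TrajectorySet
    provenance: list[dict] = field(default_factory=list)


def build_artificial_uturn(pool: list[TurnTrack], config: NullConfig,
                           rng: np.random.Generator,
                           geometry: RingGeometry) -> ArtificialUTurn:
    """Assemble one artificial collective U-turn from the pool.

    Samples ``group_size`` distinct source events (one random track each),
    picks a random reference fish, rotates/time-shifts every track, mirrors
    those circulating against the reference, and truncates all tracks to the
    intersection of their shifted spans.
    """
    events = sorted({t.source_event for t in pool})
    if len(events) < config.group_size:
        raise InsufficientPoolError(
            f"pool covers {len(events)} events < group size {config.group_size}")
    chosen_events = rng.choice(len(events), size=config.group_size, replace=False)
    chosen_events = [events[k] for k in chosen_events]
    tracks = []
    for ev in chosen_events:
        cand = [t for t in pool if t.source_event == ev]
        tracks.append(cand[rng.integers(len(cand))])
    ref = int(rng.integers(config.group_size))
    xis = rng.uniform(-config.xi_range, config.xi_range, size=config.group_size)
    zetas = rng.uniform(-config.zeta_range, config.zeta_range, size=config.group_size)

    ref_dir = tracks[ref].direction_before
    prov = []
    shifted = []
    for k, tr in enumerate(tracks):
        mirrored = tr.direction_before != ref_dir
        t2 = rotate_track(tr, xis[k])
        if mirrored:
            t2 = mirror_track(t2)
        t2 = shift_track(t2, zetas[k])
        shifted.append(t2)
        prov.append({"source_event": tr.source_event, "source_fish": tr.source_fish,
                     "xi": float(xis[k]), "zeta": float(zetas[k]),
                     "mirrored": bool(mirrored)})

    dt = shifted[0].dt
    lo = max(t.times[0] for t in shifted)
    hi = min(t.times[-1] for t in shifted)
    if hi <= lo:
        raise InsufficientPoolError("shifted tracks have no common time span")
    n = int(round((hi - lo) / dt)) + 1
    common = lo + np.arange(n) * dt
    fish_tracks = []
    for k, t2 in enumerate(shifted):
        i0 = int(round((lo - t2.times[0]) / dt))
        rho = t2.rho[i0:i0 + n]
        psi = t2.psi[i0:i0 + n]
        pos = from_polar(rho, psi, geometry)
        fish_tracks.append(FishTrack(k + 1, common.copy(), pos))
    return ArtificialUTurn(ts=TrajectorySet(fish_tracks, geometry, dt),
                           provenance=prov)


def generate_null_ensemble(pool: list[TurnTrack], config: NullConfig,
                           aconfig: AnalysisConfig, geometry: RingGeometry,
                           uconfig: UTurnConfig = UTurnConfig()):
    """Build ``n_events`` artificial U-turns and run the identical pipeline.

    Events where the pipeline fails (no complete collective U-turn detected,
    short record, ...) are skipped and counted.  Returns
    ``(artificial_uturns, analyses, n_failed)``.
    """
    rng = np.random.default_rng(config.seed)
    arts: list[ArtificialUTurn] = []
    analyses: list[EventAnalysis] = []
    n_failed = 0
    for _ in range(config.n_events):
        art = build_artificial_uturn(pool, config, rng, geometry)
        arts.append(art)
        try:
            kin = compute_kinematics(art.ts)
            events, _ = detect_collective_uturns(kin, uconfig)
            if not events:
                n_failed += 1
                continue
            # the event nearest time zero is the assembled one
            ev = min(events, key=lambda e: abs(0.5 * (e.t_s + e.t_e)))
            analyses.append(analyze_event(kin, ev, aconfig))
        except SchoolnetError:
            n_failed += 1
    return arts, analyses, n_failed
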