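"""Ground-truth simulator: ring-constrained fish groups performing collective
U-turns with a known influence structure.

The generator deliberately implants exactly the statistical structure the
inference assumes: each follower reproduces a designated influencer's
realized displacement with a fixed integer-frame lag (heading noise rotates
the copied step), so its heading series is the influencer's delayed by
exactly the configured lag plus its own von Mises jitter.  Initiators (fish
without an influencer) swim tangentially along a preferred radius with a
persistent Ornstein-Uhlenbeck heading wiggle (the burst-and-coast zigzag)
and execute scripted U-turns: over a turn of duration D the heading offset
from the local wall tangent ramps smoothly from +90 deg through 0 (pointing
at the wall) to -90 deg, while the speed dips, mimicking the observed
slow-down at mid-turn.  Positions are integrated with an explicit Euler
step and confined to the corridor by wall steering plus a radial clip.

Because noise enters only the step directions, ground-truth delays are
exact by construction, which is what makes the generator a
parameter-recovery oracle for the inference pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._angles import wrap_angle
from .errors import InvalidGraphError
from .trajdata import FishTrack, RingGeometry, TrajectorySet, write_trajectories

__all__ = [
    "UTurnSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_school",
    "preset_config",
    "make_fixture_suite",
    "PRESETS",
]


@dataclass(frozen=True)
class UTurnSpec:
    """One scripted U-turn: which fish initiates, when, and how long it takes.

    ``duration=None`` falls back to the config-wide turn duration.
    """

    fish_id: int
    time: float
    duration: float | None = None


@dataclass
class SimConfig:
    """Study conditions of the simulator.

    Defaults emulate the experimental setting: 50 Hz sampling (dt = 0.02 s),
    an annular corridor of radii 250/350 mm, cruising speeds around
    150 mm/s that dip to roughly 40% at mid-turn, and individual turns
    lasting about half a second.  ``influence_graph`` maps follower id ->
    (influencer id, delay in frames >= 1); fish absent from the graph are
    initiators driven by ``uturn_schedule``.
    """

    n_fish: int = 5
    dt: float = 0.02
    duration: float = 8.0
    geometry: RingGeometry = field(default_factory=RingGeometry)
    influence_graph: dict[int, tuple[int, int]] = field(default_factory=dict)
    heading_noise_kappa: float | None = 400.0
    wiggle_sd: float = 0.4           # rad, sd of the OU heading wiggle
    wiggle_tau: float = 0.1          # s, correlation time of the wiggle
    cruise_speed: float = 150.0
    speed_jitter: float = 0.0        # sd of per-fish cruise speed (mm/s)
    speed_dip: float = 0.7           # fractional dip at mid-turn
    turn_duration: float = 0.4       # s
    uturn_schedule: list[UTurnSpec] = field(default_factory=list)
    radial_spread: float = 25.0      # per-fish preferred-radius spread (mm)
    radial_relax: float = 0.3        # s, relaxation time toward preferred radius
    burst_amplitude: float = 0.0     # optional square-wave speed envelope
    burst_period: float = 0.5        # s
    spacing: float = 60.0            # arc spacing between initiators (mm)
    seed: int = 0

    def __post_init__(self):
        if self.cruise_speed <= 0:
            raise ValueError("cruise speed must be positive")
        for spec in self.uturn_schedule:
            if not 0 <= spec.time <= self.duration:
                raise ValueError("scheduled turn outside the simulation span")
        for f, (g, lag) in self.influence_graph.items():
            if lag < 1:
                raise InvalidGraphError("delays must be at least one frame")
            if f == g:
                raise InvalidGraphError("a fish cannot influence itself")
            if g not in range(1, self.n_fish + 1) or f not in range(1, self.n_fish + 1):
                raise InvalidGraphError("influence graph references unknown fish")


@dataclass
class GroundTruth:
    """Labels the simulator guarantees about its own output."""

    influencer: np.ndarray     # (N, T) int, 0 = none
    delay_frames: np.ndarray   # (N, T) int, 0 = none
    turn_times: dict[int, float]   # true mid-turn instants per fish
    schedule: list[UTurnSpec]
    influence_graph: dict[int, tuple[int, int]]


def _smoothstep(x: np.ndarray | float):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _resolve_turn_times(config: SimConfig) -> dict[int, float]:
    """True mid-turn instants: scripted for initiators, propagated by lags."""
    times: dict[int, float] = {}
    for spec in config.uturn_schedule:
        d = spec.duration if spec.duration is not None else config.turn_duration
        times[spec.fish_id] = spec.time + 0.5 * d
    # breadth-first propagation through the follower graph
    changed = True
    while changed:
        changed = False
        for f, (g, lag) in config.influence_graph.items():
            if f not in times and g in times:
                times[f] = times[g] + lag * config.dt
                changed = True
    return times


def simulate_school(config: SimConfig):
    """Run the simulator; returns ``(TrajectorySet, GroundTruth)``.

    The output is fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_fish
    dt = config.dt
    t_frames = int(round(config.duration / dt)) + 1
    geom = config.geometry
    r_mid = geom.midline_radius
    ids = list(range(1, n + 1))
    idx = {f: k for k, f in enumerate(ids)}

    cruise = config.cruise_speed + config.speed_jitter * rng.standard_normal(n)
    cruise = np.clip(cruise, 0.2 * config.cruise_speed, None)

    # preferred radii spread across the corridor, order shuffled; the band is
    # biased inward because a U-turn swings the fish toward the outer wall
    band_lo = geom.inner_radius + 35.0
    band_hi = geom.outer_radius - 50.0
    band_mid = 0.5 * (band_lo + band_hi)
    half = min(config.radial_spread, 0.5 * (band_hi - band_lo))
    if n > 1 and half > 0:
        offsets = np.linspace(-half, half, n)
        rng.shuffle(offsets)
    else:
        offsets = np.zeros(n)
    pref_r = band_mid + offsets

    # scripted turns per fish, sorted by time
    turns: dict[int, list[tuple[float, float]]] = {f: [] for f in ids}
    for spec in config.uturn_schedule:
        d = spec.duration if spec.duration is not None else config.turn_duration
        turns[spec.fish_id].append((spec.time, d))
    for f in ids:
        turns[f].sort()

    # cumulative lag from the root initiator decides the arc offset so each
    # follower starts where its influencer was lag frames earlier -- i.e. on
    # the root's own path.  An exact-copy follower integrates a rigid copy
    # of its influencer's path from its starting point, so starting on that
    # path keeps it there (and inside the corridor); starting on a different
    # radius would translate the whole copied path toward a wall.
    depth_lag: dict[int, int] = {}
    root_of: dict[int, int] = {}
    for f in ids:
        total, g = 0, f
        seen = set()
        while g in config.influence_graph and g not in seen:
            seen.add(g)
            g2, lag = config.influence_graph[g]
            total += lag
            g = g2
        depth_lag[f] = total
        root_of[f] = g

    pos = np.zeros((n, t_frames, 2))
    phi = np.zeros((n, t_frames))
    spd = np.zeros((n, t_frames))
    rank = 0
    psi0 = np.zeros(n)
    r0 = np.zeros(n)
    for k, f in enumerate(ids):
        if f in config.influence_graph:
            r0[k] = pref_r[idx[root_of[f]]]
            arc = depth_lag[f] * dt * config.cruise_speed
        else:
            r0[k] = pref_r[k]
            arc = rank * config.spacing
            rank += 1
        psi0[k] = -arc / r0[k]
    cx, cy = geom.center
    for k in range(n):
        pos[k, 0] = (cx + r0[k] * np.cos(psi0[k]),
                     cy + r0[k] * np.sin(psi0[k]))

    lo = geom.inner_radius + 5.0
    hi = geom.outer_radius - 5.0
    kappa = config.heading_noise_kappa

    # persistent heading wiggle (OU process) of self-driven fish: the zigzag
    # of burst-and-coast swimming; followers inherit it through copying
    a_ou = np.exp(-dt / config.wiggle_tau) if config.wiggle_tau > 0 else 0.0
    sig_ou = config.wiggle_sd * np.sqrt(max(0.0, 1.0 - a_ou * a_ou))
    wiggle = np.zeros(n)

    direction = np.ones(n)  # +1 anticlockwise
    for t in range(t_frames):
        now = t * dt
        if config.wiggle_sd > 0:
            wiggle = a_ou * wiggle + sig_ou * rng.standard_normal(n)
        for k, f in enumerate(ids):
            graph = config.influence_graph.get(f)
            if graph is not None and t >= graph[1]:
                # follower: copy the influencer's realized displacement with
                # the configured lag (heading noise rotates the step).  The
                # realized step rather than the commanded heading is copied
                # so a noiseless follower's path is an exact translate of
                # the influencer's path, wall interactions included.
                g, lag = graph
                delta = pos[idx[g], t - lag + 1] - pos[idx[g], t - lag]
                heading = np.arctan2(delta[1], delta[0])
                speed_k = float(np.hypot(*delta)) / dt
            else:
                x, y = pos[k, t]
                rho = np.hypot(x - cx, y - cy)
                psi = np.arctan2(y - cy, x - cx)
                active = None
                for (t0, d) in turns[f]:
                    if t0 <= now < t0 + d:
                        active = (t0, d)
                        break
                # direction after all completed turns
                s = 1.0 if len([1 for (t0, d) in turns[f] if now >= t0 + d]) % 2 == 0 else -1.0
                if active is not None:
                    t0, d = active
                    h = _smoothstep((now - t0) / d)
                    heading = psi + s * (np.pi / 2 - np.pi * h)
                    speed_k = cruise[k] * (1.0 - config.speed_dip
                                           * np.sin(np.pi * (now - t0) / d))
                else:
                    steer = np.arcsin(np.clip(
                        s * (rho - pref_r[k]) / (cruise[k] * config.radial_relax),
                        -0.6, 0.6))
                    heading = psi + s * np.pi / 2 + steer
                    speed_k = cruise[k]
                heading = heading + wiggle[k]
                direction[k] = s
            if config.burst_amplitude > 0 and graph is None:
                phase = (now % config.burst_period) / config.burst_period
                speed_k *= 1.0 + config.burst_amplitude * (1.0 if phase < 0.5 else -1.0)
            if kappa is not None:
                heading = heading + rng.vonmises(0.0, kappa)
            phi[k, t] = wrap_angle(heading)
            spd[k, t] = speed_k
            if t + 1 < t_frames:
                step = spd[k, t] * dt
                nxt = pos[k, t] + step * np.array([np.cos(phi[k, t]),
                                                  np.sin(phi[k, t])])
                rho_n = np.hypot(nxt[0] - cx, nxt[1] - cy)
                if rho_n < lo or rho_n > hi:
                    scale = np.clip(rho_n, lo, hi) / rho_n
                    nxt = (cx + (nxt[0] - cx) * scale, cy + (nxt[1] - cy) * scale)
                pos[k, t + 1] = nxt

    times = np.arange(t_frames) * dt
    tracks = [FishTrack(f, times.copy(), pos[idx[f]].copy()) for f in ids]
    ts = TrajectorySet(tracks, geom, dt)

    influencer = np.zeros((n, t_frames), dtype=int)
    delay = np.zeros((n, t_frames), dtype=int)
    for f, (g, lag) in config.influence_graph.items():
        influencer[idx[f], lag:] = g
        delay[idx[f], lag:] = lag
    gt = GroundTruth(
        influencer=influencer, delay_frames=delay,
        turn_times=_resolve_turn_times(config),
        schedule=list(config.uturn_schedule),
        influence_graph=dict(config.influence_graph),
    )
    return ts, gt


# ---------------------------------------------------------------------------
# canonical fixtures

def preset_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named study-condition presets used throughout the test suite.

    ``pair_lag20``          noiseless 2-fish pair, follower lag 20 frames;
    ``pair_lag20_noisy``    the same with von Mises kappa = 100 heading noise;
    ``chain5``              5-fish chain 2<-1, 3<-2, 4<-3, 5<-4 (lag 10 each);
    ``star5``               fish 2..5 all copy fish 1 (lags 10, 15, 20, 25);
    ``independent5``        5 independent turners: staggered turn times within
                            +-1 s, per-fish turn durations in [0.4, 1.0] s and
                            per-fish cruising speeds -- a no-influence control.
    """
    rng = np.random.default_rng(seed)
    base = dict(duration=8.0, seed=seed)
    mid_turn = 4.0
    if name == "pair_lag20":
        cfg = SimConfig(n_fish=2, heading_noise_kappa=None,
                        influence_graph={2: (1, 20)},
                        uturn_schedule=[UTurnSpec(1, mid_turn)], **base)
    elif name == "pair_lag20_noisy":
        cfg = SimConfig(n_fish=2, heading_noise_kappa=100.0,
                        influence_graph={2: (1, 20)},
                        uturn_schedule=[UTurnSpec(1, mid_turn)], **base)
    elif name == "chain5":
        cfg = SimConfig(n_fish=5, heading_noise_kappa=100.0,
                        influence_graph={2: (1, 10), 3: (2, 10),
                                         4: (3, 10), 5: (4, 10)},
                        uturn_schedule=[UTurnSpec(1, mid_turn)], **base)
    elif name == "star5":
        cfg = SimConfig(n_fish=5, heading_noise_kappa=100.0,
                        influence_graph={2: (1, 10), 3: (1, 15),
                                         4: (1, 20), 5: (1, 25)},
                        uturn_schedule=[UTurnSpec(1, mid_turn)], **base)
    elif name == "independent5":
        sched = [UTurnSpec(f, mid_turn + rng.uniform(-1.0, 1.0),
                           rng.uniform(0.4, 1.0)) for f in range(1, 6)]
        cfg = SimConfig(n_fish=5, heading_noise_kappa=100.0,
                        speed_jitter=15.0, uturn_schedule=sched, **base)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(cfg, **overrides) if overrides else cfg


PRESETS = ("pair_lag20", "pair_lag20_noisy", "chain5", "star5", "independent5")


def make_fixture_suite(out_dir) -> dict:
    """Write the canonical labeled fixtures to ``out_dir``.

    Each fixture consists of a trajectory CSV plus a ``*_truth.json`` with
    the influence graph, delays and scripted turn schedule; a manifest lists
    them all.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name in PRESETS:
        cfg = preset_config(name)
        ts, gt = simulate_school(cfg)
        traj = out / f"{name}.csv"
        write_trajectories(ts, traj)
        truth = out / f"{name}_truth.json"
        truth.write_text(json.dumps({
            "influence_graph": {str(f): list(v) for f, v in gt.influence_graph.items()},
            "turn_times": {str(f): t for f, t in gt.turn_times.items()},
            "uturn_schedule": [
                {"fish_id": s.fish_id, "time": s.time, "duration": s.duration}
                for s in gt.schedule],
        }, indent=2))
        manifest[name] = {"trajectories": traj.name, "ground_truth": truth.name}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
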