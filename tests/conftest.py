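"""Shared fixtures: synthetic study conditions and cached heavy ensembles.

Heavy ensembles (structured vs null, sensitivity dataset) are session-scoped
so the acceptance checks share one computation.
"""

from __future__ import annotations

import pytest

from schoolnet.analysis import analyze_event
from schoolnet.influence import AnalysisConfig
from schoolnet.kinematics import compute_kinematics
from schoolnet.nullmodel import NullConfig, extract_turn_tracks, generate_null_ensemble
from schoolnet.synthdata import preset_config, simulate_school
from schoolnet.trajdata import RingGeometry
from schoolnet.uturns import detect_collective_uturns


def analyze_preset(name: str, seed: int = 0, **cfg_kw):
    """Simulate one preset, detect its collective U-turn and analyze it.

    Returns ``(ts, gt, kin, event, analysis)`` or None if no complete event
    was detected (rare under heavy noise seeds).
    """
    ts, gt = simulate_school(preset_config(name, seed=seed))
    kin = compute_kinematics(ts)
    events, _ = detect_collective_uturns(kin)
    if not events:
        return None
    an = analyze_event(kin, events[0], AnalysisConfig(dt=ts.dt, **cfg_kw))
    return ts, gt, kin, events[0], an


@pytest.fixture(scope="session")
def pair_noiseless():
    out = analyze_preset("pair_lag20")
    assert out is not None
    return out


@pytest.fixture(scope="session")
def star_run():
    out = analyze_preset("star5", chain_removal=True)
    assert out is not None
    return out


@pytest.fixture(scope="session")
def chain_run():
    out = analyze_preset("chain5")
    assert out is not None
    return out


def build_structured_ensemble(n_events: int, base_seed: int = 0,
                              preset: str = "chain5"):
    """Structured 5-fish ensemble: one collective U-turn per simulation.

    Returns ``(analyses, pool)`` where pool holds the individual turn tracks
    feeding the null model.
    """
    analyses, pool = [], []
    offset = 0
    seed = base_seed
    while len(analyses) < n_events:
        ts, _ = simulate_school(preset_config(preset, seed=seed))
        seed += 1
        kin = compute_kinematics(ts)
        events, _ = detect_collective_uturns(kin)
        if not events:
            continue
        an = analyze_event(kin, events[0], AnalysisConfig(dt=ts.dt))
        analyses.append(an)
        pool.extend(extract_turn_tracks(kin, events[:1], source_event_offset=offset))
        offset += 1
    return analyses, pool


@pytest.fixture(scope="session")
def ensembles_200():
    """200 structured events and a 200-event null built from their turns."""
    structured, pool = build_structured_ensemble(200, base_seed=0)
    _, nulls, n_failed = generate_null_ensemble(
        pool, NullConfig(n_events=200, seed=42), AnalysisConfig(), RingGeometry())
    assert n_failed < 40  # the pipeline must handle the vast majority
    return structured, nulls


@pytest.fixture(scope="session")
def sweep_datasets():
    """20 collective U-turns as (kin, event) pairs for the parameter sweep."""
    datasets = []
    seed = 300
    while len(datasets) < 20:
        ts, _ = simulate_school(preset_config("chain5", seed=seed))
        seed += 1
        kin = compute_kinematics(ts)
        events, _ = detect_collective_uturns(kin)
        if events:
            datasets.append((kin, events[0]))
    return datasets
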