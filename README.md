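# schoolnet

Influence-network inference for schooling fish from time-delayed
directional correlations during collective U-turns.

## The problem

Groups of strongly schooling fish (e.g. rummy-nose tetras) swimming in an
annular tank circulate together and spontaneously reverse direction in
*collective U-turns*.  During such an event every fish must copy, with some
reaction delay, the heading of one or a few neighbors — its **influential
neighbors**.  Identifying who copies whom, when, and with what delay turns
raw trajectories into a time-resolved interaction network, without assuming
anything about the sensory channel or a fixed neighborhood rule (metric,
topological or visual).

`schoolnet` implements the full analysis chain for this problem, for
researchers in collective animal behavior who have per-fish 2D trajectories
at a fixed frame rate:

- trajectory I/O, gap interpolation and polar conversion (`trajdata`),
- headings, wall incidence, polarization, burst/coast segmentation
  (`kinematics`),
- individual and collective U-turn detection and ranking (`uturns`),
- the core delay-correlation inference (`influence`, `analysis`),
- cross-event aggregation: histograms, time courses, spatial and delay
  maps (`aggregate`),
- a bootstrap null model of artificial U-turns (`nullmodel`),
- parameter-sensitivity machinery (`sensitivity`),
- a ground-truth simulator of delayed heading copying (`synthdata`).

## The method

For fish *i* and *j* with unit headings **e**, the directional correlation
and its window average are

    H_ij(t, τ) = e_i(t) · e_j(t − τ)
    C_ij(t, τ, w) = (2w+1)⁻¹ Σ_{k=−w..w} H_ij(t + kΔt, τ)

Per frame, the delay τ*_k maximizing C is extracted recursively with the
search range [0, τ*_{k−1} + 1] frames (a fish never copies an *older*
snapshot of a neighbor than it just did), initialized with a wide bound
τ*_0 = 50 frames.  Neighbor *j* is an **influential neighbor** of *i* at
frame *k* when C_ij(t_k, τ*_k, w) > C_min and τ*_k Δt > τ_R (a reaction-time
floor); when several neighbors pass, those within ε% of the best score all
qualify.  Defaults: w = 2, C_min = 0.95, ε = 3, τ_R = 0.04 s, Δt = 0.02 s.

Collective U-turns are segmented from the wall-incidence angle
θ_w = φ − ψ (heading minus angular position): an individual turn is a
persistent sign change of sin θ_w, bounded by threshold crossings of
|θ_w|; the collective event runs from the earliest individual start to the
latest individual end, and results are reported in normalized event time
t̄ = (t − t_s)/(t_e − t_s).

Because correlation is not causation, a **null model** rebuilds artificial
collective U-turns from individual turns sampled from *different* events
(rotated to a common sector, time-shifted, mirrored to one circulation
direction) and runs the identical analysis: influence it reports is
spurious by construction and calibrates the structured results.

## Worked example

Simulate a 5-fish school in which fish 2–5 copy fish 1 with lags of 10, 15,
20 and 25 frames, then recover that structure from the trajectories alone:

```python
import numpy as np
from schoolnet import (AnalysisConfig, analyze_event, compute_kinematics,
                       detect_collective_uturns, preset_config,
                       simulate_school)

ts, truth = simulate_school(preset_config("star5"))
kin = compute_kinematics(ts)
events, _ = detect_collective_uturns(kin)
an = analyze_event(kin, events[0],
                   AnalysisConfig(dt=ts.dt, chain_removal=True))

counts = np.bincount(an.nif[:, an.in_uturn].ravel(), minlength=5)
print("collective U-turn:", round(events[0].t_s, 2), "->",
      round(events[0].t_e, 2), "s")
print("N_if histogram over U-turn frames:", counts)
for focal in (2, 3, 4, 5):
    sub = an.records[an.records.focal == focal]
    top = sub.neighbor.value_counts().idxmax()
    med = sub[sub.neighbor == top].tau_s.median()
    print(f"fish {focal}: top influencer {top}, median delay {med:.2f} s "
          f"(true {truth.influence_graph[focal][1] * ts.dt:.2f} s)")
```

Output:

```
collective U-turn: 4.0 -> 5.36 s
N_if histogram over U-turn frames: [130 183  31   1   0]
fish 2: top influencer 1, median delay 0.20 s (true 0.20 s)
fish 3: top influencer 1, median delay 0.30 s (true 0.30 s)
fish 4: top influencer 1, median delay 0.40 s (true 0.40 s)
fish 5: top influencer 1, median delay 0.49 s (true 0.50 s)
```

The event is found where it was scripted, the modal number of influential
neighbors per fish-frame is 1, fish 1 is identified as everyone's dominant
influencer, and each follower's implanted reaction delay is recovered from
the influence records.

A command-line interface mirrors the pipeline (`schoolnet simulate`,
`detect-uturns`, `influence`, `null-model`, `sensitivity`); see
`schoolnet --help`.

## Documentation

`docs/methods.md` describes the model, the estimator choices, the
synthetic-data generator and its limitations, and all numerical decisions.
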