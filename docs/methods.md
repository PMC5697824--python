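# Methods

This note documents the model and estimator implemented in `schoolnet`, the
assumptions behind them, the synthetic study conditions used for testing,
and the numerical choices made where the design was genuinely open.

## Setting and data model

The package analyzes groups of N fish (typically 2 or 5) swimming in an
annular corridor (outer wall radius 350 mm, inner 250 mm by default),
tracked at 50 Hz (Δt = 0.02 s).  Positions are handled in millimetres with
the origin at the tank center, x rightward, y upward, angles anticlockwise
positive in (−π, π].  Tracking gaps of at most 50 consecutive frames,
bounded by valid frames, are filled by linear interpolation; longer or
boundary-touching gaps are never extrapolated, only reported.

Per frame, velocity is a central finite difference over one frame
(one-sided at the ends); the heading φ is the velocity direction where the
speed is at least 1 mm/s, else carried forward from the last defined frame
(atan2 of a near-zero velocity is noise, not heading).  The wall-incidence
angle θ_w = wrap(φ − ψ), with ψ the angular position, is ±90° for
wall-following motion, and the sign of sin θ_w encodes circulation
direction.  Group polarization is P(t) = ‖Σ e_i‖/N for unit headings e_i.
Undefined quantities propagate as NaN markers and are excluded from
averages; they are never silently zeroed.

## U-turn segmentation

An individual U-turn instant t_m is a sign change of sin θ_w that is
*persistent*: the mean of sin θ_w over 25 frames on each side must exceed
0.5 in absolute value with opposite signs.  Crossings closer than the
persistence window are zero-crossing jitter of one physical turn and are
merged (keeping the frame with the smallest |sin θ_w|).  The turn is then
bounded: the start (end) threshold is the maximum |5-frame moving average
of θ_w| over the 50 frames before (after) t_m, and the start (end) frame is
the first frame, stepping backward (forward) from t_m, whose |θ_w| reaches
that threshold.  The comparison is ≥ with a 1e-9 tolerance: thresholds are
moving-average maxima, and on a noiseless plateau the raw series never
*strictly* exceeds its own average.  Moving averages use truncated
(shrinking) windows at the series edges.  On an analytic dip profile the
bounds land exactly on the dip shoulders, and doubling either the 50-frame
span or the 5-frame window moves them by less than 2 frames; on strongly
wiggling synthetic data the thresholds are extreme-value statistics of the
plateau noise and this robustness degrades — a property of plateau noise,
not of real near-wall swimming, where incidence is tightly constrained.

Individual turns are associated into one collective event when their turn
instants fall within 3 s and share the direction change; the collective
event spans min over fish of individual starts to max of individual ends.
A cluster missing any fish is rejected and counted.  Event time is reported
as t̄ = (t − t_s)/(t_e − t_s).

Ranks: position rank orders fish by the projection of position on the unit
mean-velocity vector of the group (undefined when that mean is ~0);
distance rank orders a focal fish's neighbors by distance; turning rank
orders fish by individual turn start.  All ties break by ascending fish id.

## Influence inference

For each ordered pair, H_ij(t, τ) = e_i(t)·e_j(t−τ) and C_ij(t, τ, w) is
its mean over the 2w+1 frames centered on t.  C cells whose window reaches
before the record or touches an undefined heading are masked, never
zero-filled.

The per-frame delay is extracted recursively: the search range at frame k
is [0, τ*_{k−1} + 1] frames, and τ*_k is the *smallest* delay attaining the
range maximum of C.  The first range is [0, τ0] with τ0 = 50 frames,
clipped to the largest delay the record can host, and extraction begins at
the first frame where that full initial range is available; earlier frames
are reported undefined.  Starting earlier would pin the recursion to
availability-truncated small delays and strand it at local correlation
maxima (observed directly: truncated starts cost up to 40% of frames on a
noiseless exact-lag pair), defeating the purpose of the wide initial bound.

A neighbor is influential at a frame when C at the extracted delay exceeds
C_min = 0.95 **and** the delay exceeds the reaction-time floor τ_R = 0.04 s
(smaller delays are not biologically attributable to influence; they arise
generically in polarized phases where every delay correlates).  Among
passing neighbors, all with scores within ε = 3 percent of the best also
qualify — ε is defined here as a percent-of-maximum tolerance, the one
reading consistent with its stated magnitude and role; the predicate is a
single isolated expression so alternatives are one-line swaps.  Each gate
is applied per neighbor independently.

N_if(i, t) counts a fish's distinct influential neighbors; its relative
variation η(t) = |N_if(t+Δt) − N_if(t)|/N_if(t) is undefined (and excluded
from averages) where N_if = 0.  Chain removal drops records explained by
simultaneous chains: if the focal fish is influenced by both A and B while
A is influenced by B, the (focal, A) record is removed — influence is
attributed to the upstream neighbor.  Conditions are evaluated on the input
set and removals applied in one pass, making the operation idempotent.  A
dataset-wide constant delay (argmax over τ of time-averaged H) is provided
as the classical single-delay comparator; its instability across data
subsets is what motivates the per-frame recursion.

Influence is evaluated over a configurable span of normalized event time,
default t̄ ∈ [−1, 2], clipped to the record.

## Aggregation

Histograms (N_if value, distance/position/turning rank of influential
neighbors) count one sample per focal-fish frame (N_if) or per record
(ranks), restricted by default to frames inside [t_s, t_e]; each block is
normalized to 1, with explicit empty markers.  Normalized-time courses of
speed, polarization, N_if and η use linear interpolation onto a t̄ grid of
step 0.05 over [−1, 2] with per-point sample counts (η uses nearest-frame
sampling over its defined frames only, since interpolating across undefined
frames would manufacture values).  Spatial maps bin each record's neighbor
position in the focal frame (focal at origin, heading along +y) into 20 mm
cells with per-cell mean relative velocity, plus a polar histogram in 30° ×
20 mm bins; delay maps bin mean extracted delay over (heading difference,
distance) in 20° × 20 mm bins.  Empty bins are NaN.

## Null model

Artificial collective U-turns are assembled from individual turn windows
pooled across events: sample `group_size` distinct source events (one
random track each), pick a random reference, rotate each track so its turn
lands at angular position π/2 + ξ (ξ uniform in ±π/12), shift its clock so
the turn lands at ζ (uniform in ±1 s, snapped to the frame grid so tracks
share a clock), and mirror tracks circulating against the reference (ψ ↦
π − ψ, an involution that keeps the relocated turn sector in place).
Tracks are truncated to the intersection of shifted spans, and the
identical pipeline is run.  Draws consume one seeded generator in a fixed
order (events, fish, reference, ξ's, ζ's), so ensembles are reproducible
bit-for-bit.  Group members are independent by construction, so any
influence detected calibrates the method's spurious-correlation floor —
which is substantial in a corridor, where co-circulating fish correlate at
their geometric separation delay.

## Synthetic study conditions

The generator implants exactly the statistical structure the inference
assumes, because parameter recovery — not biological realism — is its
purpose.  Initiators swim tangentially along a preferred radius with (i) a
persistent Ornstein–Uhlenbeck heading wiggle (sd 0.4 rad, correlation time
0.1 s) standing in for the burst-and-coast zigzag, and (ii) white von Mises
jitter (κ = 400 by default).  The wiggle is essential twice over: it makes
the copied heading signal identifiable at the true lag (white noise alone
has no temporal structure for a 5-frame window to lock onto), and its
amplitude keeps *independent* fish below the C_min gate on average
(E cos Δφ ≈ exp(−σ²) < 0.95 for σ = 0.4).  Scripted U-turns ramp the
wall-tangent offset smoothly from +90° through 0 (pointing at the wall) to
−90° over 0.4 s while the speed dips by 70% from a 150 mm/s cruise —
speeds, dip and durations in the range reported for tetras in this
geometry.

Followers reproduce their influencer's *realized displacement* with a fixed
integer-frame lag (≥ 1), heading noise rotating the copied step, and start
on the root initiator's path, arc-shifted by the cumulative lag.  A
heading-copying follower integrates a translated copy of its influencer's
path; unless it starts on that path, the translation eventually meets a
wall and silently breaks the implanted delay.  Step-copying with an on-path
start makes the noiseless follower an exact translate of the influencer's
realized path, wall interactions included, so ground-truth delays are exact
and the central-difference heading estimate inherits the shift frame-for-
frame.  Preferred radii are drawn from a band biased away from both walls
([inner+35, outer−50] mm): the wall-ward turn swings fish ~20 mm outward,
and the wiggle diffuses them radially ~7 mm (sd), so the band plus a
steering term (relaxation 0.3 s, cap 0.6 rad) keeps self-driven fish clear
of the hard radial clip that would otherwise corrupt the copy construction.

Named presets fix the study conditions: a lag-20 pair (noiseless and with
κ = 100 follower jitter), a 5-fish chain (lag 10 per link), a 5-fish star
(lags 10/15/20/25 onto fish 1), and a no-influence control of five
independent turners with staggered turn times (±1 s), per-fish turn
durations (0.4–1 s) and per-fish cruise speeds (sd 15 mm/s).

What the generator does *not* emulate: hydrodynamics, body shape and
occlusion, attraction/repulsion forces, speed copying beyond the influencer
relation, 3D motion, and tracking artifacts other than gaps.  Passing tests
therefore show that the estimator recovers the structure it assumes when
that structure is present, and reports little structure when it is absent —
not that real fish follow this model.

## Sensitivity machinery

The sweep evaluates all 40 combinations of w ∈ {0..4}, ε ∈ {3, 5}, C_min ∈
{0.995, 0.99, 0.95, 0.5}; each run is summarized by a 19-vector (5 N_if
proportions, 4 distance-rank, 5 position-rank, 5 turning-rank proportions)
and combinations are compared by cosine similarity (40×40 symmetric matrix,
unit diagonal; failed combos leave NaN cells and the sweep continues).
Delay tracks depend only on w and are cached across threshold combinations,
with no effect on outputs.  Retention curves count, per C_min, the (focal,
frame) pairs keeping at least one candidate that passes both gates,
normalized to the count at C_min = 0.5; retention is a pointwise monotone
step function of C_min by construction.

## Problem sizes and determinism

The test suite exercises the ensemble machinery at 200 structured + 200
null events (5 fish, 8 s at 50 Hz each) and the sweep at 20 events; the
reproduction script uses 100 + 100 events and a 10-event sweep.  These
sizes put multinomial sampling error well below the effect sizes asserted
(e.g. structured-vs-null mean influential-neighbor count differs by a
factor ~2).  All randomness flows from explicit integer seeds through
`numpy.random.Generator`; reruns are bit-identical.

## Known limitations

- In an annular corridor, relative positions between fish concentrate along
  the ring, so spatial distributions of (null) influential neighbors are
  ahead/behind-biased; statistical isotropy at large n is unattainable in
  this geometry, for any generator parameterization.
- The delay recursion is only locally greedy: entering a heading-sweep
  phase from a wrong delay, it re-converges downward instantly but climbs
  upward at one frame per frame.  Delays are therefore trustworthy at
  frames passing the correlation gates (influence records), not as a raw
  per-frame series through polarized phases.
- The burst detector (smoothed-acceleration threshold 300 mm/s², window 5,
  extended to the surrounding speed minimum/maximum) is an operational
  stand-in; the literature's burst-and-coast segmentation is model-based.
- ε's operational rule (percent-of-maximum) is an interpretation; it is
  isolated behind a single predicate for easy replacement.
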