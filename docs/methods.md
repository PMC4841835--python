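# Methods

This note records what `gdlkit` computes, the assumptions behind it, the
defaults that matter and why, and what the synthetic data does and does not
establish.

## Data model and formats

A skeleton stream is a strictly time-ordered sequence of frames, each
holding one 3-D position (metres, right-handed, +y vertical — the Kinect
convention) per joint of a fixed topology.  Two presets ship: the 20-joint
Kinect v1 layout (`K1`) and the 25-joint Kinect v2 layout (`K2`); any
user-defined single-rooted tree is accepted.  The native file format is a
plain-text CSV-like table (`time,<joint>.x,<joint>.y,<joint>.z,...`, `#`
comments) chosen because it is diff-able and trivially produced by other
tools; floats are written with `repr` (shortest round-trip form), which
makes write → read → write byte-identical.  BVH files are imported by a
purpose-built parser with forward kinematics: per joint, the local
transform is the offset (plus root translation channels) and the Euler
rotations applied in the file's declared channel order; world rotations
and positions accumulate down the hierarchy.  End Sites are ignored.
Orientation channels beyond positions are not retained — all features are
built from positions.

## Features

Features are declarative expressions (a small typed language with vector
literals, `joint()` references, vector algebra, arithmetic, comparisons,
boolean connectives and trigonometric functions) evaluated per frame in
definition order.  Three kinds exist: numeric, vector and logical; logical
features that are true on a frame form the frame's conclusions.  Forward
references are rejected — earlier features only — and `prev(F)` gives the
previous frame's value of an earlier feature (falling back to the current
value on the first frame, so finite-difference features start at zero).
Expressions are serialized from their ASTs in a canonical form, which makes
every definition document byte-stable through a load/save cycle.

The angle operation is contractually arccos(a·b/|a||b|), clamped to
[0°, 180°], but computed as atan2(|a×b|, a·b): mathematically identical and
well-conditioned near 0° and 180°.  It is exactly symmetric, exactly
invariant under power-of-two rescaling of either argument, invariant to
about 1e-12° under arbitrary positive rescaling, and raises a
degenerate-vector error (naming the offending operand, and the feature and
timestamp when inside stream evaluation) on zero-length input.

The built-in six-angle set (A1–A6, degrees) relates right thigh, right
shin and left thigh to the torso axis and to the global vertical.  The
concrete joint assignments (thigh = hip→knee, torso = spine-base→
spine-shoulder, shin = knee→ankle) are this package's documented choice of
the body vectors for a knee kick.  A1–A3 (body-vector pairs) are invariant
under arbitrary rigid transforms of the skeleton; A4–A6 reference the
world vertical and are invariant under the physically relevant viewpoint
changes, rotations about the vertical plus translations.  The test suite
checks both classes at 1e-9°.

## Classification engine

Key-frame rules are boolean expressions over the current feature vector,
evaluated independently per rule (one frame may satisfy several).  An
action lists rule names in order plus two mandatory time restrictions:
`max_gap`, the largest allowed time between consecutive key-frame
satisfactions, and `max_span`, the largest first-to-last time.  Either can
be set large to effectively disable it.

Frames flow through feature evaluation → rule evaluation → a memory stack
(time-bounded buffer of timestamp, feature vector, satisfied rules and
emitted classes; eviction from the oldest end only; default capacity =
largest `max_span` + 1 s so no witness is evicted early).  Matching is
attempted when the newest entry satisfies an action's final key frame: a
feasibility pass per key-frame level (tracking the latest feasible
predecessor, O(k·n)) decides existence, and a greedy backward walk reports
the latest-possible earlier key-frame times.  By default one frame may
satisfy two consecutive key frames simultaneously (non-decreasing witness
times); `strict_order=True` requires distinct frames.  The engine is
strictly causal: frame-by-frame and batch classification are identical by
construction (the batch path wraps the incremental classifier).

Duplicate suppression: a new event for an action is dropped while its
trigger time is within `max_gap` of the previously emitted one.  With
interval rules and held poses this yields one event per performed
repetition: later final-key-frame frames either fall in the refractory
window or fail the gap constraint to the previous key frame.  Degenerate
frames (zero-length vector in an angle) never abort a stream: they are
labelled `N`, logged, and counted.

Per action, the engine also emits a timeline: each frame labelled with the
highest-index satisfied key frame of that action's sequence, or `N` —
matching the convention that later phases supersede earlier ones when a
frame satisfies several.

## R-GDL training

Exemplar frames are pooled (one row per frame over the numeric features;
each row carries its exemplar id, timestamp and normalized phase
(t − t_first)/(t_last − t_first), 0 for single-frame exemplars).  Columns
are standardized (zero mean, unit variance) before clustering and PCA
because features can have different scales.  k-means (scikit-learn, fixed
seed, 10 restarts, squared-Euclidean objective) finds the k key frames; k
is a user input defaulting to 3, with an optional silhouette sweep over
k ∈ [2, 8] provided for inspection but never applied silently.  Clusters
are ordered by the mean phase of their members.  Tolerances are
3 × the per-feature member standard deviation — a ≈3σ interval covers a
cluster without ballooning into its neighbours — floored at 5° so that
razor-thin or single-member clusters still produce satisfiable rules.

Rule synthesis turns key frame i into the conjunction
|feature − centroid_i| ≤ tolerance_i over all features, and the action
sequences the k rules.  When time restrictions are not supplied they are
estimated from training data: per exemplar, each key frame occurs at the
mean timestamp of its member rows; `max_gap` is the 95th percentile of
consecutive gaps and `max_span` of spans, each times a 1.5 safety factor.
Pooled (not per-exemplar) clustering is used; percentile-based tolerances
would be a reasonable alternative to σ-based ones, σ was chosen for
robustness at small sample sizes.  Only numeric features train; logical
features are outputs of synthesized rules, not inputs.

The PCA projection (2-D or 3-D) runs on the standardized columns, drops
constant columns with a warning, and fixes component signs so the
largest-magnitude loading of each component is positive (deterministic
output).

## Synthetic motion

The generator renders a key-pose script — full-body poses with per-pose
hold times, inter-pose transition times, repetitions, rate and noise — by
linear interpolation of joint positions, sampling at the stated rate and
adding i.i.d. Gaussian noise per joint coordinate.  Each repetition plays
the poses in order and transitions back to the first pose; the trailing
return transition after the last repetition is omitted so streams end on
the final key pose.  Ground truth records every pose's hold interval per
repetition.  Position interpolation (rather than joint-angle interpolation)
was chosen for simplicity; tests compare against the generator's own
analytic geometry, not against human realism.

The built-in Hiza-Geri script has three explicit key poses (slightly
flexed neutral stance, chamber with the thigh horizontal, strike with the
shin driven forward) on the K2 skeleton, 1 s holds, 0.1 s transitions
(a fast knee strike), 30 Hz (Kinect-class rate).  The geometry keeps every
built-in angle well inside (0°, 180°): unsigned angles fold at the
boundaries, so a pose angle at exactly 180° would bias noisy means
downward by roughly the angular noise scale — the flexion in the neutral
stance is there to avoid that degeneracy, as real joints also never sit at
a mathematically exact 180°.  Noise defaults to the positional equivalent
of 3° of angular noise on a 0.45 m limb (s = radians(3°)·L/2 ≈ 0.012 m,
from the small-angle relation between endpoint noise and direction
wobble).  The single-pose Kiba-Dachi script provides a static wide-stance
technique.

`action_from_poses` builds the reference hand-written action for a script:
±15° interval rules around each pose's noiseless feature values with
`max_gap` = 1.0 s and `max_span` = 3.0 s.  These defaults are tied to the
script timing: a witness must bridge the middle hold (≥ ~0.7 s between
satisfactions), while chains spanning repetitions are at least 1.2 s apart,
so 1.0 s admits exactly one match per repetition and rejects out-of-order
sequences.  Time restrictions are always tunable per action; there are no
universally correct values.

## What the tests establish (and what they do not)

The synthetic generator produces exactly the structure the rules assume:
piecewise-held poses, stationary Gaussian noise, a fixed skeleton with no
occlusion, jitter in timing only through sampling.  Passing the recovery
and closed-loop tests therefore shows the algorithmic chain is correct and
well-calibrated under its stated noise model; it does not show robustness
to real-sensor artefacts (joint swaps, occlusion dropouts, tracking drift,
tempo variation between performers).  Time-scaling measurements show the
engine's cost is linear in the frame count with a bounded stack; absolute
per-frame milliseconds are hardware-dependent and reported, never
asserted.

Problem sizes used throughout: 1000 random vector pairs for angle checks;
100 random rigid transforms; 1000 random matcher instances with stacks up
to 50 entries and sequences up to 5 key frames (full exhaustive
enumeration on small stacks also validates the recursive oracle used for
large ones); 10-repetition detection streams; 20 training runs × 20
exemplars with 10 held-out positives and 4 order-permuted negatives each;
timing over {100, 200, 500, 1000, 2000, 5000, 10000, 20000} frames.

## Numerical and degenerate-input conventions

- Timestamps must strictly increase within a stream (equal timestamps are
  permitted in the raw memory stack, which only requires non-decrease).
- `norm` of the zero vector is 0; only `angle` treats zero-length input as
  an error.
- Phase of a single-frame exemplar is defined as 0.
- Constant feature columns are dropped from PCA (with a warning) and give
  unit scale in standardization.
- k-means with k = 1 reduces exactly to the column mean.
- Canonical serialization: expressions are printed from ASTs with
  deterministic parenthesization; YAML mappings keep insertion order;
  floats use shortest round-trip representation.

## Known limitations

- No forward-referencing rule conclusions (by design, mirroring their
  removal from the paradigm) and no probabilistic scoring — matching is
  exact rule satisfaction.
- The duplicate-suppression contract (refractory window equal to
  `max_gap`) is this package's own; with actions whose final key frame
  stays satisfiable much longer than `max_gap` while earlier key frames
  also remain within reach, a long performance could re-trigger.
- BVH import supports the standard hierarchy/motion dialect with Euler
  channels; exotic dialects (scale channels, non-standard keywords) are
  rejected rather than guessed.
- Kinetics (forces) are out of scope; the toolkit analyses kinematics
  only.
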