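"""Memory stack, sequence matcher (vs brute force) and stream classifier."""

import itertools

import numpy as np
import pytest

import gdlkit as g
from gdlkit.engine import MemoryStack, evaluate_keyframes, match_sequence
from gdlkit.errors import OrderingError, ValidationError
from gdlkit.features import FeatureVector


def fv(t, **values):
    return FeatureVector(t, values)


def make_stack(times, satisfied, capacity=1e9):
    st = MemoryStack(capacity)
    for t, s in zip(times, satisfied):
        st.push(t, fv(t), s)
    return st


# --------------------------------------------------------------------------
# rules
# --------------------------------------------------------------------------

def test_rule_evaluation_direct():
    rule = g.KeyFrameRule("r", "A1 < 30.0 and A2 > 150.0")
    assert rule.satisfied(fv(0, A1=10.0, A2=170.0))
    assert not rule.satisfied(fv(0, A1=10.0, A2=10.0))


def test_rules_independent_per_frame():
    rules = [g.KeyFrameRule("lo", "A1 < 50.0"), g.KeyFrameRule("hi", "A1 > 20.0")]
    assert evaluate_keyframes(fv(0, A1=30.0), rules) == {"lo", "hi"}
    assert evaluate_keyframes(fv(0, A1=10.0), rules) == {"lo"}


def test_rule_referencing_unknown_feature_rejected():
    aset = g.ActionSet([g.KeyFrameRule("r", "Nope > 1.0")],
                       [g.ActionDefinition("c", ("r",), 1.0, 2.0)])
    with pytest.raises(ValidationError):
        aset.validate({"A1": "number"})


def test_action_definition_invariants():
    with pytest.raises(ValidationError):
        g.ActionDefinition("c", (), 1.0, 2.0)
    with pytest.raises(ValidationError):
        g.ActionDefinition("c", ("r",), 0.0, 2.0)
    with pytest.raises(ValidationError):
        g.ActionDefinition("c", ("r",), 2.0, 1.0)
    with pytest.raises(ValidationError):
        g.ActionSet([], [g.ActionDefinition("c", ("r",), 1.0, 2.0)])


# --------------------------------------------------------------------------
# memory stack
# --------------------------------------------------------------------------

def test_push_and_evict():
    st = MemoryStack(10.0)
    st.push(0.0, fv(0.0), set())
    assert len(st) == 1
    for t in (1.0, 3.0, 5.0):
        st.push(t, fv(t), set())
    st.push(100.0, fv(100.0), set())
    assert len(st) == 1
    assert st.newest.timestamp == 100.0


def test_push_time_regression_raises():
    st = make_stack([0.0, 1.0], [set(), set()])
    with pytest.raises(OrderingError):
        st.push(0.5, fv(0.5), set())


def test_eviction_matches_filter_oracle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        times = np.sort(rng.uniform(0, 30, size=rng.integers(1, 40)))
        cap = float(rng.uniform(0.5, 10))
        st = MemoryStack(cap)
        for t in times:
            st.push(float(t), fv(float(t)), set())
        expected = [t for t in times if times[-1] - t <= cap]
        assert [e.timestamp for e in st.view()] == pytest.approx(expected)


# --------------------------------------------------------------------------
# sequence matching
# --------------------------------------------------------------------------

def test_match_constructed_witness():
    action = g.ActionDefinition("kick", ("KF1", "KF2", "KF3"), 0.5, 2.0)
    st = make_stack([0.0, 0.4, 0.8], [{"KF1"}, {"KF2"}, {"KF3"}])
    ev = match_sequence(st, action)
    assert ev is not None
    assert ev.class_name == "kick"
    assert ev.keyframe_times == (0.0, 0.4, 0.8)
    assert ev.trigger_time == 0.8
    assert "kick" in st.newest.emitted


def test_match_order_violation_returns_none():
    action = g.ActionDefinition("kick", ("KF1", "KF2", "KF3"), 0.5, 2.0)
    st = make_stack([0.0, 0.4, 0.8], [{"KF2"}, {"KF1"}, {"KF3"}])
    assert match_sequence(st, action) is None


def test_match_gap_and_span_limits():
    action = g.ActionDefinition("a", ("KF1", "KF2"), 0.3, 1.0)
    st = make_stack([0.0, 0.5], [{"KF1"}, {"KF2"}])     # gap 0.5 > 0.3
    assert match_sequence(st, action) is None
    action2 = g.ActionDefinition("a", ("KF1", "KF2", "KF3"), 0.6, 1.0)
    st = make_stack([0.0, 0.6, 1.2], [{"KF1"}, {"KF2"}, {"KF3"}])  # span 1.2 > 1.0
    assert match_sequence(st, action2) is None


def test_same_frame_may_satisfy_consecutive_keyframes():
    action = g.ActionDefinition("a", ("KF1", "KF2"), 0.5, 1.0)
    st = make_stack([0.0], [{"KF1", "KF2"}])
    ev = match_sequence(st, action)
    assert ev is not None and ev.keyframe_times == (0.0, 0.0)
    strict = g.ActionDefinition("a", ("KF1", "KF2"), 0.5, 1.0, strict_order=True)
    st = make_stack([0.0], [{"KF1", "KF2"}])
    assert match_sequence(st, strict) is None


def brute_force_match(times, satisfied, action):
    """Exhaustive enumeration over all index tuples (oracle).

    Returns the witness with latest-possible earlier key-frame times, or
    None.  Independent of the engine's DP/greedy implementation.
    """
    k = len(action.keyframe_sequence)
    n = len(times)
    last = n - 1
    if action.keyframe_sequence[-1] not in satisfied[last]:
        return None
    combos = (itertools.combinations_with_replacement(range(n), k)
              if not action.strict_order else itertools.combinations(range(n), k))
    best = None
    for idx in combos:
        if idx[-1] != last:
            continue
        if any(action.keyframe_sequence[j] not in satisfied[idx[j]] for j in range(k)):
            continue
        if any(times[idx[j + 1]] - times[idx[j]] > action.max_gap for j in range(k - 1)):
            continue
        if times[idx[-1]] - times[idx[0]] > action.max_span:
            continue
        # greedy-backward semantics: maximize the later key-frame indices
        # first, i.e. reversed-lexicographic maximum over valid witnesses
        if best is None or idx[::-1] > best[::-1]:
            best = idx
    if best is None:
        return None
    return tuple(times[i] for i in best)


def random_instance(rng, max_n=10, max_k=4):
    n = int(rng.integers(1, max_n + 1))
    k = int(rng.integers(1, max_k + 1))
    times = np.round(np.cumsum(rng.uniform(0.05, 0.5, size=n)), 6).tolist()
    kf_names = [f"K{j}" for j in range(k)]
    satisfied = [frozenset(nm for nm in kf_names if rng.random() < 0.45)
                 for _ in range(n)]
    action = g.ActionDefinition(
        "c", tuple(kf_names),
        max_gap=float(rng.uniform(0.1, 1.5)),
        max_span=float(rng.uniform(1.5, 4.0)),
        strict_order=bool(rng.random() < 0.3))
    return times, satisfied, action


def test_match_agrees_with_exhaustive_enumeration():
    rng = np.random.default_rng(2024)
    hits = 0
    for _ in range(600):
        times, satisfied, action = random_instance(rng)
        st = make_stack(times, satisfied)
        ev = match_sequence(st, action)
        expected = brute_force_match(times, satisfied, action)
        if expected is None:
            assert ev is None
        else:
            hits += 1
            assert ev is not None
            assert ev.keyframe_times == pytest.approx(expected)
    assert hits > 50  # the sampler must actually produce matches


def test_monotone_robustness_extra_unassigned_frames():
    """Interleaving non-satisfying frames never changes the outcome while
    the time restrictions still hold."""
    action = g.ActionDefinition("kick", ("KF1", "KF2", "KF3"), 0.5, 2.0)
    times = [0.0, 0.4, 0.8]
    sats = [{"KF1"}, {"KF2"}, {"KF3"}]
    base = match_sequence(make_stack(times, sats), action)
    dense_times, dense_sats = [], []
    for i, (t, s) in enumerate(zip(times, sats)):
        dense_times.append(t)
        dense_sats.append(s)
        if i < 2:
            for dt in (0.1, 0.2, 0.3):
                dense_times.append(t + dt)
                dense_sats.append(set())
    ev = match_sequence(make_stack(dense_times, dense_sats), action)
    assert ev is not None and base is not None
    assert ev.keyframe_times == base.keyframe_times


# --------------------------------------------------------------------------
# stream classification
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def kick_setup():
    script = g.builtin_kick_script(seed=3, repetitions=3)
    seq, gt = g.generate(script)
    defs = g.builtin_hiza_geri_features()
    aset = g.action_from_poses(script, defs, "kick")
    return script, seq, gt, defs, aset


def test_no_rules_satisfied_gives_all_unassigned(k2, hiza_defs):
    script = g.builtin_kick_script(seed=1, repetitions=1, noise_sigma_pos=0.0)
    seq, _ = g.generate(script)
    aset = g.ActionSet([g.KeyFrameRule("never", "A1 > 999.0")],
                       [g.ActionDefinition("c", ("never",), 1.0, 2.0)])
    res = g.classify_stream(seq, hiza_defs, aset)
    assert res.events == []
    assert set(res.timelines["c"].labels) == {g.UNASSIGNED}


def test_single_kick_detected_once(hiza_defs):
    script = g.builtin_kick_script(seed=5, repetitions=1)
    seq, _ = g.generate(script)
    aset = g.action_from_poses(script, hiza_defs, "kick")
    res = g.classify_stream(seq, hiza_defs, aset)
    assert len(res.events) == 1
    ev = res.events[0]
    assert ev.keyframe_times == tuple(sorted(ev.keyframe_times))


def test_three_repetitions_three_events(kick_setup):
    script, seq, gt, defs, aset = kick_setup
    res = g.classify_stream(seq, defs, aset)
    assert len(res.events) == 3
    # each trigger falls inside the corresponding final-pose hold interval
    for ev, rep in zip(res.events, gt.intervals):
        t0, t1 = rep[-1]
        assert t0 - 1e-9 <= ev.trigger_time <= t1 + 1e-9


def test_timeline_labels_match_ground_truth_holds(hiza_defs):
    script = g.builtin_kick_script(seed=2, repetitions=2, noise_sigma_pos=0.0)
    seq, gt = g.generate(script)
    aset = g.action_from_poses(script, hiza_defs, "kick")
    res = g.classify_stream(seq, hiza_defs, aset)
    tl = res.timelines["kick"]
    for rep in gt.intervals:
        for pi, (a, b) in enumerate(rep):
            for t, lab in zip(tl.times, tl.labels):
                if a + 1e-9 < t < b - 1e-9:
                    assert lab == f"kick_kf{pi + 1}"


def test_online_equals_offline(kick_setup):
    script, seq, gt, defs, aset = kick_setup
    batch = g.classify_stream(seq, defs, aset)
    clf = g.StreamClassifier(defs, aset, topology=seq.topology)
    streamed = []
    for frame in seq.frames:
        streamed.extend(clf.process_frame(frame))
    assert streamed == batch.events
    assert clf.result().timelines["kick"].labels == batch.timelines["kick"].labels


def test_classification_is_deterministic(kick_setup):
    script, seq, gt, defs, aset = kick_setup
    r1 = g.classify_stream(seq, defs, aset)
    r2 = g.classify_stream(seq, defs, aset)
    assert r1.events == r2.events
    assert r1.timelines["kick"].labels == r2.timelines["kick"].labels
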