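"""The GDL classifier core.

An *action* is an ordered sequence of key frames; a *key frame* is a
boolean rule over the current frame's feature values.  Frames flow through
feature evaluation, rule evaluation and a time-bounded memory stack; an
action fires when its key frames appear in order in the stack with every
consecutive gap at most ``max_gap`` seconds and the first-to-last span at
most ``max_span`` seconds.  The engine is strictly causal: classifying a
stream frame by frame gives bit-identical results to batch classification.

Alongside the event list the engine produces, per action, a key-frame
timeline: for every frame the highest-index satisfied key frame of that
action, or ``"N"`` when none is satisfied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import expressions as ex
from .errors import DegenerateVectorError, OrderingError, ValidationError
from .features import FeatureDefinition, FeatureVector, evaluate_features, validate_features
from .skeleton import MotionSequence, SkeletonFrame

__all__ = [
    "KeyFrameRule", "ActionDefinition", "ActionSet", "MemoryStack", "StackEntry",
    "ClassificationEvent", "KeyFrameTimeline", "StreamResult",
    "evaluate_keyframes", "match_sequence", "classify_stream", "StreamClassifier",
    "UNASSIGNED",
]

log = logging.getLogger("gdlkit")

#: Timeline label for frames not assigned to any key frame.
UNASSIGNED = "N"


# --------------------------------------------------------------------------
# definitions
# --------------------------------------------------------------------------

@dataclass
class KeyFrameRule:
    """A named boolean constraint over the current feature vector."""

    name: str
    expression: "str | ex.Node"
    expr: ex.Node = field(init=False, repr=False)
    _compiled: object = field(init=False, default=None, repr=False)

    def __post_init__(self):
        self.expr = (ex.parse(self.expression)
                     if isinstance(self.expression, str) else self.expression)

    @property
    def source(self) -> str:
        return ex.to_source(self.expr)

    def validate(self, feature_kinds: Mapping[str, str]) -> None:
        t = ex.infer_type(self.expr, feature_kinds, joints=None)
        if t != ex.BOOLEAN:
            raise ValidationError(f"rule {self.name!r} must be boolean, got {t}")

    def satisfied(self, fv: FeatureVector) -> bool:
        if self._compiled is None:
            self._compiled = ex.compile_expr(self.expr)
        ctx = ex.EvalContext(positions=None, values=fv.values, timestamp=fv.timestamp)
        return bool(self._compiled(ctx))


@dataclass
class ActionDefinition:
    """An action class: ordered key frames plus time restrictions.

    ``max_gap`` bounds the time between consecutive key-frame
    satisfactions, ``max_span`` the time from first to last.  With
    ``strict_order=False`` (default) one frame may satisfy two consecutive
    key frames simultaneously (non-decreasing key-frame times); set it to
    require strictly increasing times on distinct frames.
    """

    class_name: str
    keyframe_sequence: tuple[str, ...]
    max_gap: float
    max_span: float
    strict_order: bool = False

    def __post_init__(self):
        self.keyframe_sequence = tuple(self.keyframe_sequence)
        if len(self.keyframe_sequence) < 1:
            raise ValidationError(f"action {self.class_name!r}: empty key-frame sequence")
        if not self.max_gap > 0:
            raise ValidationError(f"action {self.class_name!r}: max_gap must be > 0")
        if self.max_span < self.max_gap:
            raise ValidationError(
                f"action {self.class_name!r}: max_span must be >= max_gap")


@dataclass
class ActionSet:
    """A rule library plus the actions built from it (one loadable document)."""

    rules: list[KeyFrameRule]
    actions: list[ActionDefinition]

    def __post_init__(self):
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate key-frame rule names")
        byname = set(names)
        for a in self.actions:
            missing = [k for k in a.keyframe_sequence if k not in byname]
            if missing:
                raise ValidationError(
                    f"action {a.class_name!r} references undefined key frames {missing}")

    def validate(self, feature_kinds: Mapping[str, str]) -> None:
        for r in self.rules:
            r.validate(feature_kinds)


# --------------------------------------------------------------------------
# memory stack
# --------------------------------------------------------------------------

@dataclass
class StackEntry:
    timestamp: float
    fv: FeatureVector
    satisfied: frozenset
    emitted: set = field(default_factory=set)


class MemoryStack:
    """Time-bounded, time-ordered buffer of frames, features and conclusions.

    Retains every entry within ``capacity`` seconds of the newest one;
    eviction happens only from the oldest end.
    """

    def __init__(self, capacity: float):
        if not capacity > 0:
            raise ValueError("capacity must be positive (seconds)")
        self.capacity = float(capacity)
        self.entries: list[StackEntry] = []
        self._start = 0  # logical head; compacted lazily

    def __len__(self) -> int:
        return len(self.entries) - self._start

    def view(self) -> list[StackEntry]:
        return self.entries[self._start:]

    @property
    def newest(self) -> StackEntry | None:
        return self.entries[-1] if len(self) else None

    def push(self, timestamp: float, fv: FeatureVector,
             satisfied: Iterable[str]) -> StackEntry:
        """Append an entry; evict entries older than the capacity window."""
        if len(self) and timestamp < self.entries[-1].timestamp:
            raise OrderingError(
                f"push at t={timestamp} before newest t={self.entries[-1].timestamp}")
        entry = StackEntry(timestamp, fv, frozenset(satisfied))
        self.entries.append(entry)
        cutoff = timestamp - self.capacity
        while self.entries[self._start].timestamp < cutoff:
            self._start += 1
        if self._start > 256 and self._start * 2 > len(self.entries):
            del self.entries[: self._start]
            self._start = 0
        return entry


def evaluate_keyframes(fv: FeatureVector,
                       rules: Sequence[KeyFrameRule]) -> set[str]:
    """Names of the rules satisfied by this feature vector (independent per rule)."""
    return {r.name for r in rules if r.satisfied(fv)}


# --------------------------------------------------------------------------
# sequence matching
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationEvent:
    """One recognized action occurrence.

    ``trigger_time`` is the timestamp of the final key frame;
    ``keyframe_times`` reports one timestamp per key frame, the
    latest-possible witness (greedy backward match).
    """

    class_name: str
    trigger_time: float
    keyframe_times: tuple[float, ...]


def match_sequence(stack: MemoryStack,
                   action: ActionDefinition) -> ClassificationEvent | None:
    """Try to complete ``action`` at the newest stack entry.

    Returns an event iff the newest entry satisfies the last key frame and
    entries e1 <= ... <= ek exist (ek = newest; '<' under
    ``strict_order``) satisfying the key frames in order with every
    consecutive gap <= max_gap and total span <= max_span.  Among multiple
    witnesses the latest-possible earlier key-frame times are reported.
    Emitting an event records the class on the newest entry.
    """
    entries = stack.view()
    if not entries:
        raise OrderingError("match_sequence on an empty stack")
    newest = entries[-1]
    seq = action.keyframe_sequence
    k = len(seq)
    if seq[-1] not in newest.satisfied:
        return None
    t_last = newest.timestamp
    # feasible[j][i] == True iff key frames 0..j can be matched with key
    # frame j at entry i (span handled by restricting level 0 to the window)
    n = len(entries)
    min_t = t_last - action.max_span
    prev_level: list[bool] = [
        (seq[0] in e.satisfied and e.timestamp >= min_t) for e in entries]
    levels = [prev_level]
    for j in range(1, k):
        cur: list[bool] = [False] * n
        # one forward pass tracking the latest feasible predecessor index;
        # the latest predecessor maximizes t_pred, so it is the best witness
        # for the gap constraint
        latest = -1
        ptr = 0
        for i in range(n):
            limit = i if not action.strict_order else i - 1
            while ptr <= limit:
                if prev_level[ptr]:
                    latest = ptr
                ptr += 1
            if (seq[j] in entries[i].satisfied and latest >= 0
                    and entries[i].timestamp - entries[latest].timestamp <= action.max_gap):
                cur[i] = True
        levels.append(cur)
        prev_level = cur
    if not prev_level[n - 1]:
        return None
    # greedy backward witness: latest-possible earlier key-frame entries
    witness = [n - 1]
    for j in range(k - 2, -1, -1):
        nxt = witness[-1]
        limit = nxt if not action.strict_order else nxt - 1
        t_next = entries[nxt].timestamp
        found = -1
        for i in range(limit, -1, -1):
            if levels[j][i] and t_next - entries[i].timestamp <= action.max_gap:
                found = i
                break
        assert found >= 0, "DP feasibility guarantees a witness"
        witness.append(found)
    witness.reverse()
    event = ClassificationEvent(
        action.class_name, t_last,
        tuple(entries[i].timestamp for i in witness))
    newest.emitted.add(action.class_name)
    return event


# --------------------------------------------------------------------------
# stream classification
# --------------------------------------------------------------------------

@dataclass
class KeyFrameTimeline:
    """Per-frame key-frame assignment for one action (Fig.-4-style bar)."""

    class_name: str
    times: list[float]
    labels: list[str]  # key-frame rule name or UNASSIGNED


@dataclass
class StreamResult:
    timelines: dict[str, KeyFrameTimeline]
    events: list[ClassificationEvent]
    n_degenerate: int = 0


class StreamClassifier:
    """Causal, frame-by-frame GDL classifier.

    Feed frames in time order with :meth:`process_frame`; events are
    returned as soon as they fire.  ``classify_stream`` is a thin batch
    wrapper over this class, so online and offline use are equivalent by
    construction.

    Duplicate suppression: after an action fires, new events for the same
    action are suppressed while the new trigger time is within ``max_gap``
    of the previous one (a refractory period); an event with the same class
    and trigger time is never emitted twice.
    """

    def __init__(self, feature_defs: Sequence[FeatureDefinition],
                 action_set: ActionSet,
                 topology=None,
                 capacity: float | None = None):
        self.feature_defs = list(feature_defs)
        self.action_set = action_set
        if topology is not None:
            kinds = validate_features(self.feature_defs, topology)
        else:
            kinds = {d.name: {"logical": ex.BOOLEAN, "numeric": ex.NUMBER,
                              "vector": ex.VECTOR}[d.kind] for d in self.feature_defs}
        action_set.validate(kinds)
        if capacity is None:
            capacity = max((a.max_span for a in action_set.actions), default=2.0) + 1.0
        self.stack = MemoryStack(capacity)
        self._history: FeatureVector | None = None
        self._last_trigger: dict[str, float] = {}
        self._kf_index = {
            a.class_name: {name: i for i, name in enumerate(a.keyframe_sequence)}
            for a in action_set.actions}
        self.timelines = {a.class_name: KeyFrameTimeline(a.class_name, [], [])
                          for a in action_set.actions}
        self.events: list[ClassificationEvent] = []
        self.n_degenerate = 0

    def process_frame(self, frame: SkeletonFrame) -> list[ClassificationEvent]:
        """Process one frame; returns the events fired on this frame."""
        t = frame.timestamp
        try:
            fv = evaluate_features(frame, self.feature_defs, self._history)
        except DegenerateVectorError as err:
            log.warning("degenerate frame skipped: %s", err)
            self.n_degenerate += 1
            for tl in self.timelines.values():
                tl.times.append(t)
                tl.labels.append(UNASSIGNED)
            return []
        self._history = fv
        satisfied = evaluate_keyframes(fv, self.action_set.rules)
        self.stack.push(t, fv, satisfied)
        fired: list[ClassificationEvent] = []
        for action in self.action_set.actions:
            idx = self._kf_index[action.class_name]
            hits = [idx[name] for name in satisfied if name in idx]
            tl = self.timelines[action.class_name]
            tl.times.append(t)
            tl.labels.append(action.keyframe_sequence[max(hits)] if hits else UNASSIGNED)
            event = match_sequence(self.stack, action)
            if event is None:
                continue
            last = self._last_trigger.get(action.class_name)
            if last is not None and event.trigger_time - last < action.max_gap:
                continue  # refractory window
            self._last_trigger[action.class_name] = event.trigger_time
            fired.append(event)
        self.events.extend(fired)
        return fired

    def result(self) -> StreamResult:
        return StreamResult(self.timelines, self.events, self.n_degenerate)


def classify_stream(seq: MotionSequence,
                    feature_defs: Sequence[FeatureDefinition],
                    action_set: ActionSet,
                    capacity: float | None = None) -> StreamResult:
    """Classify a whole motion sequence.

    Frames are processed strictly in time order through feature evaluation,
    rule evaluation, the memory stack and the per-action sequence matcher.
    Returns per-action key-frame timelines and the fired events.
    """
    clf = StreamClassifier(feature_defs, action_set, topology=seq.topology,
                           capacity=capacity)
    for frame in seq.frames:
        clf.process_frame(frame)
    return clf.result()
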