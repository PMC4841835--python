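"""Typed kinematic features evaluated per skeleton frame.

Features come in three kinds — ``logical`` (boolean), ``numeric`` (float)
and ``vector`` (3-D) — and are defined declaratively as expressions over
joint positions, constants and earlier features (forward references are
rejected).  Logical features that evaluate to ``true`` on a frame are the
frame's *conclusions*.

The module also ships the built-in six-angle feature set used for the
Hiza-Geri knee kick: five body vectors (right thigh, torso axis, right
shin, left thigh, global vertical) and the six pairwise angles

    A1 = angle(thigh_R, torso)      A4 = angle(thigh_R, vertical)
    A2 = angle(shin_R,  torso)      A5 = angle(shin_R,  vertical)
    A3 = angle(thigh_L, torso)      A6 = angle(thigh_L, vertical)

reported in degrees in [0, 180].  A1-A3 relate pairs of body vectors and
are invariant under arbitrary rigid transforms of the skeleton; A4-A6
relate body vectors to the global vertical and are invariant under the
physically relevant class of viewpoint changes — rotations about the
vertical axis plus arbitrary translations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import expressions as ex
from .errors import DegenerateVectorError, ValidationError
from .skeleton import JointTopology, SkeletonFrame, k2_topology

__all__ = [
    "vec3", "add", "scale", "dot", "cross", "norm", "angle",
    "FeatureDefinition", "FeatureVector",
    "validate_features", "evaluate_features",
    "builtin_hiza_geri_features", "HIZA_GERI_VECTORS",
]


# --------------------------------------------------------------------------
# vector algebra (Euclidean 3-space)
# --------------------------------------------------------------------------

def vec3(x: float, y: float, z: float) -> np.ndarray:
    """Construct a 3-D vector (float64 array)."""
    return np.array([x, y, z], dtype=float)


def add(a, b) -> np.ndarray:
    return np.asarray(a, float) + np.asarray(b, float)


def scale(a, s: float) -> np.ndarray:
    return np.asarray(a, float) * float(s)


def dot(a, b) -> float:
    return float(np.dot(np.asarray(a, float), np.asarray(b, float)))


def cross(a, b) -> np.ndarray:
    return np.cross(np.asarray(a, float), np.asarray(b, float))


def norm(a) -> float:
    return float(np.linalg.norm(np.asarray(a, float)))


def angle(a, b) -> float:
    """Unsigned angle between two vectors, in degrees, in [0, 180].

    Contractually arccos(dot/(|a||b|)); computed as atan2(|a x b|, a.b),
    which is the same quantity but numerically stable near 0 and 180
    degrees.  Symmetric in its arguments and invariant under positive
    scaling of either.  Raises :class:`DegenerateVectorError` on a
    zero-length operand.
    """
    return ex._angle_deg(np.asarray(a, float), np.asarray(b, float))


# --------------------------------------------------------------------------
# feature definitions
# --------------------------------------------------------------------------

_KIND_TO_TYPE = {"logical": ex.BOOLEAN, "numeric": ex.NUMBER, "vector": ex.VECTOR}


@dataclass
class FeatureDefinition:
    """One named, typed feature given by an expression.

    ``expression`` may be source text or a pre-built AST; the canonical
    source form is available as :attr:`source`.
    """

    name: str
    kind: str  # 'logical' | 'numeric' | 'vector'
    expression: "str | ex.Node"
    expr: ex.Node = field(init=False, repr=False)
    _compiled: object = field(init=False, default=None, repr=False)

    def __post_init__(self):
        if self.kind not in _KIND_TO_TYPE:
            raise ValidationError(
                f"feature {self.name!r}: kind must be logical/numeric/vector, got {self.kind!r}")
        self.expr = (ex.parse(self.expression)
                     if isinstance(self.expression, str) else self.expression)

    @property
    def source(self) -> str:
        return ex.to_source(self.expr)

    def compiled(self):
        if self._compiled is None:
            self._compiled = ex.compile_expr(self.expr)
        return self._compiled


@dataclass
class FeatureVector:
    """The evaluated feature values of one frame."""

    timestamp: float
    values: dict[str, object]

    @property
    def conclusions(self) -> set[str]:
        """Names of logical features that are true on this frame."""
        return {k for k, v in self.values.items() if v is True}

    def __getitem__(self, name: str):
        return self.values[name]


def validate_features(defs: Sequence[FeatureDefinition],
                      topology: JointTopology) -> dict[str, str]:
    """Check a definition list against a topology.

    Enforces unique names, no forward references, joint existence and that
    each expression's result type matches its declared kind.  Returns the
    name -> type mapping (useful for validating rules downstream).
    """
    kinds: dict[str, str] = {}
    for d in defs:
        if d.name in kinds:
            raise ValidationError(f"duplicate feature name {d.name!r}")
        t = ex.infer_type(d.expr, kinds, topology.joint_names)
        if t != _KIND_TO_TYPE[d.kind]:
            raise ValidationError(
                f"feature {d.name!r} declared {d.kind} but expression has type {t}")
        kinds[d.name] = t
    return kinds


def evaluate_features(frame: SkeletonFrame,
                      defs: Sequence[FeatureDefinition],
                      history: FeatureVector | None = None) -> FeatureVector:
    """Evaluate all features on one frame, in definition order.

    ``history`` is the previous frame's FeatureVector; ``prev(F)`` reads
    from it (falling back to the current frame's value when absent, so
    finite-difference features start at zero).  A zero-length vector inside
    ``angle`` raises :class:`DegenerateVectorError` tagged with the frame
    timestamp and feature name.
    """
    ctx = ex.EvalContext(positions=frame.positions, values={},
                         prev_values=history.values if history is not None else None,
                         timestamp=frame.timestamp)
    for d in defs:
        try:
            ctx.values[d.name] = d.compiled()(ctx)
        except DegenerateVectorError as err:
            raise DegenerateVectorError(err.operand, timestamp=frame.timestamp,
                                        feature=d.name) from None
    return FeatureVector(frame.timestamp, ctx.values)


# --------------------------------------------------------------------------
# built-in Hiza-Geri angle set (K2 topology)
# --------------------------------------------------------------------------

#: The five body vectors behind the six built-in angles, as (name, source).
HIZA_GERI_VECTORS: tuple[tuple[str, str], ...] = (
    ("v1", "sub(joint(KneeRight), joint(HipRight))"),      # right thigh
    ("v2", "sub(joint(SpineShoulder), joint(SpineBase))"),  # torso axis
    ("v3", "sub(joint(AnkleRight), joint(KneeRight))"),    # right shin
    ("v4", "sub(joint(KneeLeft), joint(HipLeft))"),        # left thigh
    ("v5", "vec(0.0, 1.0, 0.0)"),                           # global vertical
)

_HIZA_GERI_ANGLES = (
    ("A1", "v1", "v2"), ("A2", "v3", "v2"), ("A3", "v4", "v2"),
    ("A4", "v1", "v5"), ("A5", "v3", "v5"), ("A6", "v4", "v5"),
)


def builtin_hiza_geri_features(topology: JointTopology | None = None,
                               include_vectors: bool = False,
                               ) -> list[FeatureDefinition]:
    """The six-angle knee-kick feature set on the K2 topology.

    Returns six numeric features A1..A6 (degrees).  With
    ``include_vectors=True`` the five underlying vector features v1..v5 are
    prepended (the angles then reference them by name; the default inlines
    the vector expressions so that only the six numeric features exist).
    Raises :class:`ValidationError` if the topology lacks the needed joints.
    """
    topo = topology if topology is not None else k2_topology()
    vec_src = dict(HIZA_GERI_VECTORS)
    defs: list[FeatureDefinition] = []
    if include_vectors:
        defs.extend(FeatureDefinition(n, "vector", s) for n, s in HIZA_GERI_VECTORS)
        defs.extend(FeatureDefinition(a, "numeric", f"angle({u}, {v})")
                    for a, u, v in _HIZA_GERI_ANGLES)
    else:
        defs.extend(FeatureDefinition(a, "numeric",
                                      f"angle({vec_src[u]}, {vec_src[v]})")
                    for a, u, v in _HIZA_GERI_ANGLES)
    validate_features(defs, topo)
    return defs
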