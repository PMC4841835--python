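"""Skeleton topologies, frame data model, and motion-stream I/O.

A skeleton stream is a time-ordered sequence of frames; each frame holds one
3-D position per joint of a fixed topology.  Coordinates are metres in a
right-handed Cartesian frame with the vertical axis along +y (the Kinect
convention).  Two topology presets are built in: the 20-joint Kinect v1
layout ("K1") and the 25-joint Kinect v2 layout ("K2"); arbitrary
user-defined topologies are supported as long as the parent graph is a
single rooted tree.

The native on-disk format is a plain-text table: a header line
``time,<joint>.x,<joint>.y,<joint>.z,...`` followed by one comma-separated
row per frame, ``#`` starting a comment line.  BVH files (hierarchy +
Euler-angle motion) can be imported; world joint positions are recovered by
forward kinematics.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FormatError, OrderingError, StreamParseError, TopologyError

__all__ = [
    "JointTopology",
    "SkeletonFrame",
    "MotionSequence",
    "k1_topology",
    "k2_topology",
    "topology_by_name",
    "read_stream",
    "write_stream",
    "import_bvh",
]


# --------------------------------------------------------------------------
# topologies
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class JointTopology:
    """A named, ordered joint set with a rooted parent tree.

    ``parent_of`` maps each non-root joint to its parent; the root is absent
    from the mapping (or maps to ``None``).
    """

    name: str
    joint_names: tuple[str, ...]
    parent_of: Mapping[str, str | None]

    def __post_init__(self):
        names = self.joint_names
        if len(set(names)) != len(names):
            raise TopologyError(f"duplicate joint names in topology {self.name!r}")
        object.__setattr__(self, "joint_names", tuple(names))
        parents = {c: p for c, p in self.parent_of.items() if p is not None}
        roots = [j for j in names if parents.get(j) is None]
        if len(roots) != 1:
            raise TopologyError(
                f"topology {self.name!r} must have exactly one root, found {roots}")
        for child, parent in parents.items():
            if child not in names or parent not in names:
                raise TopologyError(
                    f"parent link {child!r}->{parent!r} references unknown joint")
        # reject cycles / forests: every joint must reach the root
        root = roots[0]
        for j in names:
            seen, cur = set(), j
            while cur != root:
                if cur in seen:
                    raise TopologyError(f"cycle at joint {cur!r} in {self.name!r}")
                seen.add(cur)
                cur = parents.get(cur)
                if cur is None:
                    raise TopologyError(f"joint {j!r} is disconnected from the root")
        object.__setattr__(self, "parent_of", dict(parents))

    @property
    def root(self) -> str:
        parents = self.parent_of
        return next(j for j in self.joint_names if j not in parents)

    def __len__(self) -> int:
        return len(self.joint_names)


def _chain(parent_map: dict, pairs: Iterable[tuple[str, str]]) -> None:
    for child, parent in pairs:
        parent_map[child] = parent


_K1_JOINTS = (
    "HipCenter", "Spine", "ShoulderCenter", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
)

_K2_JOINTS = (
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
)


def k1_topology() -> JointTopology:
    """The 20-joint Kinect v1 skeleton."""
    p: dict[str, str | None] = {}
    _chain(p, [
        ("Spine", "HipCenter"), ("ShoulderCenter", "Spine"), ("Head", "ShoulderCenter"),
        ("ShoulderLeft", "ShoulderCenter"), ("ElbowLeft", "ShoulderLeft"),
        ("WristLeft", "ElbowLeft"), ("HandLeft", "WristLeft"),
        ("ShoulderRight", "ShoulderCenter"), ("ElbowRight", "ShoulderRight"),
        ("WristRight", "ElbowRight"), ("HandRight", "WristRight"),
        ("HipLeft", "HipCenter"), ("KneeLeft", "HipLeft"),
        ("AnkleLeft", "KneeLeft"), ("FootLeft", "AnkleLeft"),
        ("HipRight", "HipCenter"), ("KneeRight", "HipRight"),
        ("AnkleRight", "KneeRight"), ("FootRight", "AnkleRight"),
    ])
    return JointTopology("K1", _K1_JOINTS, p)


def k2_topology() -> JointTopology:
    """The 25-joint Kinect v2 skeleton."""
    p: dict[str, str | None] = {}
    _chain(p, [
        ("SpineMid", "SpineBase"), ("SpineShoulder", "SpineMid"),
        ("Neck", "SpineShoulder"), ("Head", "Neck"),
        ("ShoulderLeft", "SpineShoulder"), ("ElbowLeft", "ShoulderLeft"),
        ("WristLeft", "ElbowLeft"), ("HandLeft", "WristLeft"),
        ("HandTipLeft", "HandLeft"), ("ThumbLeft", "HandLeft"),
        ("ShoulderRight", "SpineShoulder"), ("ElbowRight", "ShoulderRight"),
        ("WristRight", "ElbowRight"), ("HandRight", "WristRight"),
        ("HandTipRight", "HandRight"), ("ThumbRight", "HandRight"),
        ("HipLeft", "SpineBase"), ("KneeLeft", "HipLeft"),
        ("AnkleLeft", "KneeLeft"), ("FootLeft", "AnkleLeft"),
        ("HipRight", "SpineBase"), ("KneeRight", "HipRight"),
        ("AnkleRight", "KneeRight"), ("FootRight", "AnkleRight"),
    ])
    return JointTopology("K2", _K2_JOINTS, p)


def topology_by_name(name: str) -> JointTopology:
    low = name.lower()
    if low == "k1":
        return k1_topology()
    if low == "k2":
        return k2_topology()
    raise TopologyError(f"unknown topology preset {name!r} (expected 'K1' or 'K2')")


# --------------------------------------------------------------------------
# frames and sequences
# --------------------------------------------------------------------------

@dataclass
class SkeletonFrame:
    """One timestamped set of joint positions.

    ``positions`` maps joint name to a length-3 float array (metres).
    """

    timestamp: float
    positions: dict[str, np.ndarray]

    def __post_init__(self):
        if not math.isfinite(self.timestamp) or self.timestamp < 0:
            raise OrderingError(f"timestamp must be finite and >= 0, got {self.timestamp}")
        self.positions = {k: np.asarray(v, dtype=float) for k, v in self.positions.items()}
        for name, p in self.positions.items():
            if p.shape != (3,):
                raise TopologyError(f"joint {name!r} position must be 3-D, got shape {p.shape}")
            if not np.all(np.isfinite(p)):
                raise TopologyError(f"joint {name!r} has non-finite coordinates")

    def validate(self, topology: JointTopology) -> None:
        missing = [j for j in topology.joint_names if j not in self.positions]
        if missing:
            raise TopologyError(f"frame at t={self.timestamp} missing joints {missing}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SkeletonFrame":
        """Return a copy with every joint mapped through ``R @ p + t``."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return SkeletonFrame(self.timestamp,
                             {k: R @ v + t for k, v in self.positions.items()})


@dataclass
class MotionSequence:
    """A time-ordered skeleton stream over one topology."""

    topology: JointTopology
    frames: list[SkeletonFrame] = field(default_factory=list)
    nominal_rate: float | None = None

    def __post_init__(self):
        last = -math.inf
        for i, f in enumerate(self.frames):
            f.validate(self.topology)
            if f.timestamp <= last:
                raise OrderingError(
                    f"timestamps must strictly increase: frame {i} at t={f.timestamp} "
                    f"follows t={last}")
            last = f.timestamp

    def __len__(self) -> int:
        return len(self.frames)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MotionSequence):
            return NotImplemented
        if self.topology.joint_names != other.topology.joint_names:
            return False
        if len(self.frames) != len(other.frames):
            return False
        for a, b in zip(self.frames, other.frames):
            if a.timestamp != b.timestamp:
                return False
            for j in self.topology.joint_names:
                if not np.array_equal(a.positions[j], b.positions[j]):
                    return False
        return True

    def slice(self, n: int) -> "MotionSequence":
        """First ``n`` frames (cheap prefix view used for benchmarking)."""
        return MotionSequence(self.topology, self.frames[:n], self.nominal_rate)


# --------------------------------------------------------------------------
# frame-stream format
# --------------------------------------------------------------------------

def _fmt(x: float) -> str:
    # repr() is the shortest string that round-trips the float exactly
    return repr(float(x))


def write_stream(seq: MotionSequence, path: str | Path) -> None:
    """Write a MotionSequence in the native frame-stream format.

    The output is canonical: re-reading and re-writing reproduces the bytes.
    """
    cols = ["time"]
    for j in seq.topology.joint_names:
        cols += [f"{j}.x", f"{j}.y", f"{j}.z"]
    lines = [",".join(cols)]
    for f in seq.frames:
        row = [_fmt(f.timestamp)]
        for j in seq.topology.joint_names:
            row.extend(_fmt(c) for c in f.positions[j])
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_stream(path: str | Path, topology: JointTopology) -> MotionSequence:
    """Read a frame-stream file against a declared topology.

    Raises :class:`StreamParseError` (with line number) on malformed records
    and :class:`TopologyError` when the header does not cover the topology.
    """
    text = Path(path).read_text(encoding="utf-8")
    header: list[str] | None = None
    frames: list[SkeletonFrame] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split(",")
        if header is None:
            header = [h.strip() for h in fields]
            if header[0] != "time":
                raise StreamParseError("header must start with 'time'", lineno)
            expected = ["time"]
            for j in topology.joint_names:
                expected += [f"{j}.x", f"{j}.y", f"{j}.z"]
            if header != expected:
                raise TopologyError(
                    f"header columns do not match topology {topology.name!r} "
                    f"({len(header)} columns, expected {len(expected)})")
            continue
        if len(fields) != 1 + 3 * len(topology):
            raise StreamParseError(
                f"expected {1 + 3 * len(topology)} fields, got {len(fields)}", lineno)
        try:
            values = [float(v) for v in fields]
        except ValueError as exc:
            raise StreamParseError(str(exc), lineno) from None
        positions = {}
        for k, j in enumerate(topology.joint_names):
            positions[j] = np.array(values[1 + 3 * k: 4 + 3 * k], dtype=float)
        try:
            frames.append(SkeletonFrame(values[0], positions))
        except (OrderingError, TopologyError) as exc:
            raise StreamParseError(str(exc), lineno) from None
    if header is None:
        raise StreamParseError("empty file: missing header")
    return MotionSequence(topology, frames)


# --------------------------------------------------------------------------
# BVH import (forward kinematics)
# --------------------------------------------------------------------------

_ROT = {
    "Xrotation": lambda c, s: np.array([[1, 0, 0], [0, c, -s], [0, s, c]]),
    "Yrotation": lambda c, s: np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]]),
    "Zrotation": lambda c, s: np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]]),
}


@dataclass
class _BvhNode:
    name: str
    parent: "_BvhNode | None"
    offset: np.ndarray
    channels: list[str]


def _tokenize_bvh(text: str) -> list[str]:
    return re.findall(r"[^\s]+", text)


def import_bvh(path: str | Path) -> MotionSequence:
    """Import a BVH file, computing world joint positions per frame.

    Rotations are applied in the channel order declared in the file
    (each listed channel multiplies on the right of the joint's local
    rotation, the standard BVH convention).  End Sites are ignored; the
    topology is built from the named joints.
    """
    tokens = _tokenize_bvh(Path(path).read_text(encoding="utf-8"))
    pos = 0

    def peek() -> str:
        if pos >= len(tokens):
            raise FormatError("unexpected end of BVH file")
        return tokens[pos]

    def take(expected: str | None = None) -> str:
        nonlocal pos
        tok = peek()
        if expected is not None and tok.upper() != expected.upper():
            raise FormatError(f"expected {expected!r}, got {tok!r}")
        pos += 1
        return tok

    if take().upper() != "HIERARCHY":
        raise FormatError("BVH must start with HIERARCHY")

    nodes: list[_BvhNode] = []

    def parse_joint(parent: "_BvhNode | None") -> None:
        kw = take()  # ROOT / JOINT / End
        if kw.upper() == "END":
            take("Site")
            take("{")
            take("OFFSET")
            for _ in range(3):
                take()
            take("}")
            return
        name = take()
        take("{")
        take("OFFSET")
        offset = np.array([float(take()) for _ in range(3)])
        channels: list[str] = []
        if peek().upper() == "CHANNELS":
            take()
            n = int(take())
            channels = [take() for _ in range(n)]
        node = _BvhNode(name, parent, offset, channels)
        nodes.append(node)
        while peek() != "}":
            up = peek().upper()
            if up in ("JOINT", "END"):
                parse_joint(node)
            else:
                raise FormatError(f"unexpected token {peek()!r} in hierarchy")
        take("}")

    parse_joint(None)

    if pos >= len(tokens) or take().upper() != "MOTION":
        raise FormatError("BVH missing MOTION section")
    take("Frames:")
    n_frames = int(take())
    t1 = take()
    if t1.upper() == "FRAME":
        take("Time:")
    frame_time = float(take())

    names = [n.name for n in nodes]
    if len(set(names)) != len(names):
        raise FormatError("duplicate joint names in BVH hierarchy")
    parent_of = {n.name: (n.parent.name if n.parent else None) for n in nodes}
    topology = JointTopology(Path(path).stem, tuple(names), parent_of)

    n_channels = sum(len(n.channels) for n in nodes)
    data = tokens[pos:]
    if len(data) < n_frames * n_channels:
        raise FormatError(
            f"MOTION data truncated: need {n_frames * n_channels} values, "
            f"got {len(data)}")
    try:
        values = np.array([float(v) for v in data[: n_frames * n_channels]])
    except ValueError as exc:
        raise FormatError(f"bad MOTION value: {exc}") from None
    values = values.reshape(n_frames, n_channels)

    frames: list[SkeletonFrame] = []
    for fi in range(n_frames):
        row = values[fi]
        ci = 0
        world_R: dict[str, np.ndarray] = {}
        world_p: dict[str, np.ndarray] = {}
        positions: dict[str, np.ndarray] = {}
        for node in nodes:
            trans = node.offset.copy()
            R = np.eye(3)
            for ch in node.channels:
                v = row[ci]
                ci += 1
                if ch.endswith("position"):
                    axis = "XYZ".index(ch[0].upper())
                    trans[axis] += v
                elif ch in _ROT:
                    a = math.radians(v)
                    R = R @ _ROT[ch](math.cos(a), math.sin(a))
                else:
                    raise FormatError(f"unknown channel {ch!r}")
            if node.parent is None:
                world_p[node.name] = trans
                world_R[node.name] = R
            else:
                pR = world_R[node.parent.name]
                world_p[node.name] = world_p[node.parent.name] + pR @ trans
                world_R[node.name] = pR @ R
            positions[node.name] = world_p[node.name]
        frames.append(SkeletonFrame(fi * frame_time, positions))
    return MotionSequence(topology, frames, nominal_rate=(1.0 / frame_time if frame_time > 0 else None))
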