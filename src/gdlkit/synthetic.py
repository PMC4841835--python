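"""Synthetic labelled skeleton streams: key-pose interpolation plus noise.

A :class:`KeyPoseScript` lists full-body key poses with per-pose hold times
and inter-pose transition times; :func:`generate` renders it into a motion
stream at a fixed rate by linear interpolation of joint positions, adding
i.i.d. Gaussian positional noise, and returns ground truth — the hold
interval of every key pose in every repetition.  Everything is
deterministic given the script's seed.

Built-in scripts emulate two karate techniques on the 25-joint K2 skeleton:
a Hiza-Geri knee kick (three key poses: slightly flexed neutral stance,
knee chambered with the thigh horizontal, and the strike with the shin
driven forward) and a Kiba-Dachi horse stance (a single held wide-legged
pose).  Joint geometry is written out explicitly so pose angles can be
computed in closed form by tests.

Timing layout: each repetition plays pose 1 .. pose n with its holds and
transitions, then transitions back to pose 1 before the next repetition;
the trailing return transition after the final repetition is omitted, so
the stream ends on the last key pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .features import FeatureDefinition, evaluate_features
from .engine import ActionDefinition, ActionSet, KeyFrameRule
from .skeleton import JointTopology, MotionSequence, SkeletonFrame, k2_topology

__all__ = [
    "KeyPoseScript", "GroundTruth", "generate",
    "builtin_kick_script", "builtin_stance_script",
    "standing_pose", "kick_key_poses", "with_pose_order",
    "positional_noise_for_angle_sigma", "action_from_poses",
]


# --------------------------------------------------------------------------
# script and ground truth
# --------------------------------------------------------------------------

@dataclass
class KeyPoseScript:
    """A repeatable scripted motion built from held key poses.

    ``transition_times[i]`` is the transition from pose i to pose i+1; the
    last element is the return transition from the final pose back to pose
    0, used between repetitions.  ``noise_sigma_pos`` is the standard
    deviation (metres) of the Gaussian noise added independently to every
    joint coordinate of every frame.
    """

    topology: JointTopology
    key_poses: list[dict[str, np.ndarray]]
    hold_times: list[float]
    transition_times: list[float]
    repetitions: int = 1
    noise_sigma_pos: float = 0.0
    rate: float = 30.0
    seed: int = 0

    def __post_init__(self):
        n = len(self.key_poses)
        if n < 1:
            raise ValidationError("script needs at least one key pose")
        if len(self.hold_times) != n or len(self.transition_times) != n:
            raise ValidationError(
                "hold_times and transition_times must both have one entry per pose "
                "(the last transition is the return to pose 0)")
        if any(not d > 0 for d in self.hold_times + self.transition_times):
            raise ValidationError("all durations must be > 0")
        if not self.rate > 0:
            raise ValidationError("rate must be > 0")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")
        self.key_poses = [
            {k: np.asarray(v, float) for k, v in pose.items()} for pose in self.key_poses]
        for pose in self.key_poses:
            missing = [j for j in self.topology.joint_names if j not in pose]
            if missing:
                raise ValidationError(f"key pose missing joints {missing}")

    @property
    def rep_duration(self) -> float:
        return sum(self.hold_times) + sum(self.transition_times)

    @property
    def total_duration(self) -> float:
        # trailing return transition omitted
        return self.repetitions * self.rep_duration - self.transition_times[-1]


@dataclass
class GroundTruth:
    """Hold intervals per repetition: ``intervals[rep][pose] == (t0, t1)``."""

    intervals: list[list[tuple[float, float]]]

    @property
    def n_repetitions(self) -> int:
        return len(self.intervals)


def _segments(script: KeyPoseScript):
    """Yield (t_start, duration, pose_a_index, pose_b_index) pieces in order."""
    t = 0.0
    n = len(script.key_poses)
    for rep in range(script.repetitions):
        for i in range(n):
            yield t, script.hold_times[i], i, i
            t += script.hold_times[i]
            last_piece = (rep == script.repetitions - 1) and (i == n - 1)
            if not last_piece:
                yield t, script.transition_times[i], i, (i + 1) % n
                t += script.transition_times[i]


def generate(script: KeyPoseScript) -> tuple[MotionSequence, GroundTruth]:
    """Render a script into a noisy motion stream plus ground truth.

    Frames are sampled at ``script.rate`` Hz from t = 0 up to (excluding)
    the total scripted duration; within a hold the pose is constant, within
    a transition joint positions are linearly interpolated.
    """
    topo = script.topology
    joints = topo.joint_names
    n_joints = len(joints)
    poses = np.stack([
        np.stack([pose[j] for j in joints]) for pose in script.key_poses])  # (P, J, 3)

    total = script.total_duration
    n_frames = int(round(total * script.rate))
    times = np.arange(n_frames) / script.rate

    segs = list(_segments(script))
    starts = np.array([s[0] for s in segs])
    positions = np.empty((n_frames, n_joints, 3))
    seg_idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(segs) - 1)
    for si, (t0, dur, a, b) in enumerate(segs):
        mask = seg_idx == si
        if not mask.any():
            continue
        if a == b:
            positions[mask] = poses[a]
        else:
            frac = ((times[mask] - t0) / dur)[:, None, None]
            positions[mask] = (1.0 - frac) * poses[a] + frac * poses[b]

    if script.noise_sigma_pos > 0:
        rng = np.random.default_rng(script.seed)
        positions = positions + rng.normal(
            0.0, script.noise_sigma_pos, size=positions.shape)

    frames = [
        SkeletonFrame(float(times[i]),
                      {j: positions[i, k] for k, j in enumerate(joints)})
        for i in range(n_frames)]
    seq = MotionSequence(topo, frames, nominal_rate=script.rate)

    intervals: list[list[tuple[float, float]]] = []
    for rep in range(script.repetitions):
        rep_start = rep * script.rep_duration
        rows: list[tuple[float, float]] = []
        t = rep_start
        for i in range(len(script.key_poses)):
            rows.append((t, t + script.hold_times[i]))
            t += script.hold_times[i] + script.transition_times[i]
        intervals.append(rows)
    return seq, GroundTruth(intervals)


def with_pose_order(script: KeyPoseScript, order: Sequence[int],
                    seed: int | None = None) -> KeyPoseScript:
    """A copy of the script with its key poses permuted (negative examples).

    A non-identity order destroys the temporal key-frame sequence, so a
    correctly trained action definition must not fire on the result.
    """
    order = list(order)
    if sorted(order) != list(range(len(script.key_poses))):
        raise ValidationError(f"order must be a permutation, got {order}")
    return KeyPoseScript(
        topology=script.topology,
        key_poses=[script.key_poses[i] for i in order],
        hold_times=[script.hold_times[i] for i in order],
        transition_times=[script.transition_times[i] for i in order],
        repetitions=script.repetitions,
        noise_sigma_pos=script.noise_sigma_pos,
        rate=script.rate,
        seed=script.seed if seed is None else seed)


# --------------------------------------------------------------------------
# built-in K2 geometry
# --------------------------------------------------------------------------

def positional_noise_for_angle_sigma(sigma_deg: float, limb_length: float = 0.45) -> float:
    """Positional noise (metres) giving roughly the requested angular noise.

    For a limb vector of length L whose two endpoints each receive i.i.d.
    noise of std s per coordinate, the direction wobbles by about 2 s / L
    radians (two endpoints, two transverse components), so
    ``s = radians(sigma_deg) * L / 2``.
    """
    return math.radians(sigma_deg) * limb_length / 2.0


def standing_pose() -> dict[str, np.ndarray]:
    """A slightly flexed neutral K2 stance with explicit joint coordinates.

    x is lateral (left negative), y vertical, z forward; metres.  Knees and
    torso carry a small natural flexion so that no built-in angle sits at
    exactly 0 or 180 degrees (where unsigned angles fold).
    """
    p = {
        "SpineBase": (0.0, 1.00, 0.0),
        "SpineMid": (0.0, 1.22, -0.01),
        "SpineShoulder": (0.0, 1.44, -0.03),
        "Neck": (0.0, 1.50, -0.03),
        "Head": (0.0, 1.65, -0.01),
        "ShoulderLeft": (-0.20, 1.42, -0.03),
        "ElbowLeft": (-0.25, 1.15, -0.02),
        "WristLeft": (-0.27, 0.92, 0.02),
        "HandLeft": (-0.28, 0.85, 0.03),
        "HandTipLeft": (-0.28, 0.78, 0.04),
        "ThumbLeft": (-0.24, 0.84, 0.05),
        "ShoulderRight": (0.20, 1.42, -0.03),
        "ElbowRight": (0.25, 1.15, -0.02),
        "WristRight": (0.27, 0.92, 0.02),
        "HandRight": (0.28, 0.85, 0.03),
        "HandTipRight": (0.28, 0.78, 0.04),
        "ThumbRight": (0.24, 0.84, 0.05),
        "HipLeft": (-0.10, 0.95, 0.0),
        "KneeLeft": (-0.15, 0.52, 0.12),
        "AnkleLeft": (-0.11, 0.11, -0.02),
        "FootLeft": (-0.11, 0.03, 0.10),
        "HipRight": (0.10, 0.95, 0.0),
        "KneeRight": (0.15, 0.52, 0.12),
        "AnkleRight": (0.11, 0.11, -0.02),
        "FootRight": (0.11, 0.03, 0.10),
    }
    return {k: np.array(v, float) for k, v in p.items()}


def kick_key_poses() -> list[dict[str, np.ndarray]]:
    """The three Hiza-Geri key poses: neutral, chamber, strike."""
    neutral = standing_pose()

    chamber = {k: v.copy() for k, v in neutral.items()}
    # right thigh swings to horizontal, shin hangs down
    chamber["KneeRight"] = np.array([0.13, 0.93, 0.45])
    chamber["AnkleRight"] = np.array([0.10, 0.55, 0.36])
    chamber["FootRight"] = np.array([0.10, 0.50, 0.46])

    strike = {k: v.copy() for k, v in chamber.items()}
    # shin drives forward, slightly above horizontal
    strike["AnkleRight"] = np.array([0.10, 0.85, 0.86])
    strike["FootRight"] = np.array([0.10, 0.88, 0.97])
    return [neutral, chamber, strike]


def builtin_kick_script(seed: int = 0, repetitions: int = 1,
                        noise_sigma_pos: float | None = None,
                        rate: float = 30.0) -> KeyPoseScript:
    """A scripted Hiza-Geri kick on the K2 skeleton.

    Defaults: 1 s holds at each of the three key poses, 0.1 s transitions
    (a fast knee strike), 30 Hz sampling, and positional noise equivalent
    to about 3 degrees of angular noise on a 0.45 m limb.
    """
    if noise_sigma_pos is None:
        noise_sigma_pos = positional_noise_for_angle_sigma(3.0)
    return KeyPoseScript(
        topology=k2_topology(),
        key_poses=kick_key_poses(),
        hold_times=[1.0, 1.0, 1.0],
        transition_times=[0.1, 0.1, 0.1],
        repetitions=repetitions,
        noise_sigma_pos=noise_sigma_pos,
        rate=rate,
        seed=seed)


def builtin_stance_script(seed: int = 0, hold: float = 2.0,
                          noise_sigma_pos: float | None = None,
                          rate: float = 30.0) -> KeyPoseScript:
    """A held Kiba-Dachi horse stance (single key pose) on the K2 skeleton."""
    if noise_sigma_pos is None:
        noise_sigma_pos = positional_noise_for_angle_sigma(3.0)
    pose = standing_pose()
    for side, sx in (("Left", -1.0), ("Right", 1.0)):
        pose[f"Hip{side}"] = np.array([sx * 0.16, 0.88, 0.0])
        pose[f"Knee{side}"] = np.array([sx * 0.32, 0.50, 0.08])
        pose[f"Ankle{side}"] = np.array([sx * 0.38, 0.10, 0.0])
        pose[f"Foot{side}"] = np.array([sx * 0.40, 0.03, 0.12])
    pose["SpineBase"] = np.array([0.0, 0.93, 0.0])
    pose["SpineMid"] = np.array([0.0, 1.15, -0.02])
    pose["SpineShoulder"] = np.array([0.0, 1.37, -0.05])
    return KeyPoseScript(
        topology=k2_topology(),
        key_poses=[pose],
        hold_times=[hold],
        transition_times=[0.1],
        repetitions=1,
        noise_sigma_pos=noise_sigma_pos,
        rate=rate,
        seed=seed)


# --------------------------------------------------------------------------
# reference rules straight from script poses
# --------------------------------------------------------------------------

def action_from_poses(script: KeyPoseScript,
                      feature_defs: Sequence[FeatureDefinition],
                      class_name: str,
                      tolerance_deg: float = 15.0,
                      max_gap: float = 1.0,
                      max_span: float = 3.0) -> ActionSet:
    """Hand-style action definition built from a script's own key poses.

    Each key pose becomes one key-frame rule: every numeric feature must
    lie within ``tolerance_deg`` of its value on the noiseless pose.  This
    is the reference (ground-truth) definition against which the generator
    and the trained models are checked.

    The default time restrictions suit the built-in scripts' timing: with
    1 s holds and 0.1 s transitions a witness needs consecutive gaps of at
    least about 0.7 s (the middle hold must be bridged), while gaps across
    repetitions are at least 1.2 s, so ``max_gap=1.0`` admits exactly one
    match per repetition and rejects out-of-order chains.
    """
    numeric = [d for d in feature_defs if d.kind == "numeric"]
    rules: list[KeyFrameRule] = []
    names: list[str] = []
    for i, pose in enumerate(script.key_poses):
        frame = SkeletonFrame(0.0, pose)
        fv = evaluate_features(frame, feature_defs)
        terms = []
        for d in numeric:
            v = float(fv[d.name])
            terms.append(f"{d.name} >= {v - tolerance_deg!r} and "
                         f"{d.name} <= {v + tolerance_deg!r}")
        name = f"{class_name}_kf{i + 1}"
        names.append(name)
        rules.append(KeyFrameRule(name, " and ".join(terms)))
    action = ActionDefinition(class_name, tuple(names), max_gap, max_span)
    return ActionSet(rules, [action])
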