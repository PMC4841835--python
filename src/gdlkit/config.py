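"""Reading and writing the declarative configuration documents.

All definition documents are YAML: feature sets, key-frame rule / action
sets, trained models, synthetic-motion scripts and ground truth.  Output
is canonical — expressions are re-serialized from their ASTs and floats
printed with round-trip precision — so a write/read/write cycle is
byte-identical.

Tabular outputs (per-frame feature tables, event lists, timelines) are
plain CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import (ActionDefinition, ActionSet, ClassificationEvent,
                     KeyFrameRule, StreamResult)
from .errors import ValidationError
from .features import FeatureDefinition
from .skeleton import JointTopology, topology_by_name
from .synthetic import GroundTruth, KeyPoseScript
from .trainer import TrainedModel

__all__ = [
    "save_feature_defs", "load_feature_defs",
    "save_action_set", "load_action_set",
    "save_model", "load_model",
    "save_script", "load_script",
    "save_ground_truth", "load_ground_truth",
    "save_events", "load_events",
    "save_timelines", "save_feature_table",
]


def _dump(data, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(data, sort_keys=False, default_flow_style=False),
        encoding="utf-8")


def _load(path: str | Path):
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping document")
    return data


# -- feature definitions ----------------------------------------------------

def save_feature_defs(defs: Sequence[FeatureDefinition], path: str | Path) -> None:
    _dump({"features": [
        {"name": d.name, "kind": d.kind, "expr": d.source} for d in defs]}, path)


def load_feature_defs(path: str | Path) -> list[FeatureDefinition]:
    data = _load(path)
    try:
        return [FeatureDefinition(f["name"], f["kind"], f["expr"])
                for f in data["features"]]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed feature document ({exc})") from None


# -- rules and actions ------------------------------------------------------

def save_action_set(aset: ActionSet, path: str | Path) -> None:
    doc = {
        "rules": [{"name": r.name, "expr": r.source} for r in aset.rules],
        "actions": [
            {"class": a.class_name,
             "sequence": list(a.keyframe_sequence),
             "max_gap": float(a.max_gap),
             "max_span": float(a.max_span),
             **({"strict_order": True} if a.strict_order else {})}
            for a in aset.actions],
    }
    _dump(doc, path)


def load_action_set(path: str | Path) -> ActionSet:
    data = _load(path)
    try:
        rules = [KeyFrameRule(r["name"], r["expr"]) for r in data.get("rules", [])]
        actions = [ActionDefinition(a["class"], tuple(a["sequence"]),
                                    float(a["max_gap"]), float(a["max_span"]),
                                    bool(a.get("strict_order", False)))
                   for a in data.get("actions", [])]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed action document ({exc})") from None
    return ActionSet(rules, actions)


# -- trained models ---------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    doc = {
        "k": int(model.k),
        "features": list(model.feature_names),
        "centroids": [[float(v) for v in row] for row in model.centroids],
        "tolerances": [[float(v) for v in row] for row in model.tolerances],
        "temporal_order": [int(c) for c in model.temporal_order],
        "scaler_mean": [float(v) for v in model.scaler_mean],
        "scaler_scale": [float(v) for v in model.scaler_scale],
        "inertia": float(model.inertia),
    }
    if model.generated_action is not None:
        a = model.generated_action.actions[0]
        doc["time_params"] = {"max_gap": float(a.max_gap), "max_span": float(a.max_span)}
        doc["class"] = a.class_name
    _dump(doc, path)


def load_model(path: str | Path) -> TrainedModel:
    data = _load(path)
    model = TrainedModel(
        k=int(data["k"]),
        feature_names=list(data["features"]),
        centroids=np.asarray(data["centroids"], float),
        tolerances=np.asarray(data["tolerances"], float),
        temporal_order=np.asarray(data["temporal_order"], int),
        assignments=np.array([], int),
        scaler_mean=np.asarray(data["scaler_mean"], float),
        scaler_scale=np.asarray(data["scaler_scale"], float),
        inertia=float(data.get("inertia", 0.0)))
    if "time_params" in data and "class" in data:
        from .trainer import synthesize_rules
        tp = (data["time_params"]["max_gap"], data["time_params"]["max_span"])
        synthesize_rules(model, data["class"], tp)
    return model


# -- synthetic scripts and ground truth -------------------------------------

def save_script(script: KeyPoseScript, path: str | Path) -> None:
    doc = {
        "topology": script.topology.name,
        "key_poses": [
            {j: [float(c) for c in pose[j]] for j in script.topology.joint_names}
            for pose in script.key_poses],
        "hold_times": [float(t) for t in script.hold_times],
        "transition_times": [float(t) for t in script.transition_times],
        "repetitions": int(script.repetitions),
        "noise_sigma_pos": float(script.noise_sigma_pos),
        "rate": float(script.rate),
        "seed": int(script.seed),
    }
    _dump(doc, path)


def load_script(path: str | Path,
                topology: JointTopology | None = None) -> KeyPoseScript:
    data = _load(path)
    topo = topology if topology is not None else topology_by_name(data["topology"])
    return KeyPoseScript(
        topology=topo,
        key_poses=[{j: np.asarray(p, float) for j, p in pose.items()}
                   for pose in data["key_poses"]],
        hold_times=[float(t) for t in data["hold_times"]],
        transition_times=[float(t) for t in data["transition_times"]],
        repetitions=int(data.get("repetitions", 1)),
        noise_sigma_pos=float(data.get("noise_sigma_pos", 0.0)),
        rate=float(data.get("rate", 30.0)),
        seed=int(data.get("seed", 0)))


def save_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    _dump({"intervals": [
        [[float(a), float(b)] for a, b in rep] for rep in gt.intervals]}, path)


def load_ground_truth(path: str | Path) -> GroundTruth:
    data = _load(path)
    return GroundTruth([[(float(a), float(b)) for a, b in rep]
                        for rep in data["intervals"]])


# -- tabular outputs --------------------------------------------------------

def save_events(events: Sequence[ClassificationEvent], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "trigger_time", "keyframe_times"])
        for e in events:
            w.writerow([e.class_name, repr(e.trigger_time),
                        ";".join(repr(t) for t in e.keyframe_times)])


def load_events(path: str | Path) -> list[ClassificationEvent]:
    out: list[ClassificationEvent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(ClassificationEvent(
                row["class"], float(row["trigger_time"]),
                tuple(float(t) for t in row["keyframe_times"].split(";") if t)))
    return out


def save_timelines(result: StreamResult, path: str | Path) -> None:
    """One CSV with time plus one label column per action."""
    names = list(result.timelines)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["time"] + names)
        if names:
            n = len(result.timelines[names[0]].times)
            for i in range(n):
                row = [repr(result.timelines[names[0]].times[i])]
                row += [result.timelines[c].labels[i] for c in names]
                w.writerow(row)


def save_feature_table(fvs, path: str | Path) -> None:
    """Per-frame feature values as CSV (vector features expand to .x/.y/.z)."""
    rows = []
    for fv in fvs:
        row: dict[str, object] = {"time": fv.timestamp}
        for name, value in fv.values.items():
            if isinstance(value, np.ndarray):
                row[f"{name}.x"], row[f"{name}.y"], row[f"{name}.z"] = (
                    float(value[0]), float(value[1]), float(value[2]))
            elif isinstance(value, bool):
                row[name] = value
            else:
                row[name] = float(value)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
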