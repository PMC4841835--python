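"""Automatic key-frame discovery and rule synthesis (R-GDL).

Exemplar recordings are mapped into feature space (one row per frame over
the numeric features), pooled, standardized and clustered with k-means;
each cluster is a candidate key frame.  Clusters are ordered by the mean
normalized phase of their member frames, per-feature tolerances are taken
from member spread, and an executable action definition — interval rules
plus estimated time restrictions — is emitted for the rule engine.  A PCA
projection of the pooled cloud is provided for visual inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .engine import ActionDefinition, ActionSet, KeyFrameRule
from .errors import DegenerateVectorError, InsufficientDataError, ValidationError
from .features import FeatureDefinition, evaluate_features
from .skeleton import MotionSequence

__all__ = [
    "FeatureMatrix", "TrainedModel",
    "build_feature_matrix", "cluster_keyframes", "synthesize_rules",
    "train", "pca_project", "silhouette_sweep",
]

log = logging.getLogger("gdlkit")


# --------------------------------------------------------------------------
# feature matrix
# --------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Frames pooled from exemplars, one row per frame, numeric features only.

    Row metadata: source exemplar id, timestamp, and normalized phase
    (t - t_first) / (t_last - t_first) within the exemplar (0 for a
    single-frame exemplar).
    """

    values: np.ndarray          # (n_rows, n_features)
    feature_names: list[str]
    exemplar_ids: np.ndarray    # (n_rows,) int
    timestamps: np.ndarray      # (n_rows,) float
    phases: np.ndarray          # (n_rows,) float in [0, 1]
    n_dropped: int = 0

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def build_feature_matrix(exemplars: Sequence[MotionSequence],
                         defs: Sequence[FeatureDefinition]) -> FeatureMatrix:
    """Evaluate numeric features on every frame of every exemplar.

    Degenerate frames (zero-length vector inside an angle) are dropped with
    a logged warning; the count is reported on the matrix.
    """
    if len(exemplars) < 1:
        raise InsufficientDataError("need at least one exemplar")
    numeric = [d for d in defs if d.kind == "numeric"]
    if not numeric:
        raise ValidationError("no numeric features to train on")
    names = [d.name for d in numeric]
    rows, ex_ids, times, phases = [], [], [], []
    dropped = 0
    for ei, seq in enumerate(exemplars):
        if len(seq) == 0:
            continue
        t0 = seq.frames[0].timestamp
        t1 = seq.frames[-1].timestamp
        span = t1 - t0
        history = None
        for f in seq.frames:
            try:
                fv = evaluate_features(f, defs, history)
            except DegenerateVectorError as err:
                dropped += 1
                log.warning("dropping degenerate frame: %s", err)
                continue
            history = fv
            rows.append([float(fv[n]) for n in names])
            ex_ids.append(ei)
            times.append(f.timestamp)
            phases.append((f.timestamp - t0) / span if span > 0 else 0.0)
    if dropped:
        log.warning("dropped %d degenerate frames while building feature matrix", dropped)
    if not rows:
        raise InsufficientDataError("no evaluable frames in exemplars")
    return FeatureMatrix(np.asarray(rows, float), names,
                         np.asarray(ex_ids), np.asarray(times), np.asarray(phases),
                         n_dropped=dropped)


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """R-GDL training output.

    ``centroids``/``tolerances`` are in original feature units (degrees for
    the built-in angle set), one row per cluster.  ``temporal_order[i]`` is
    the cluster id of the i-th key frame in time (clusters sorted by mean
    member phase).  ``generated_action`` is filled by
    :func:`synthesize_rules`.
    """

    k: int
    feature_names: list[str]
    centroids: np.ndarray        # (k, f), original units
    tolerances: np.ndarray       # (k, f), > 0
    temporal_order: np.ndarray   # (k,) permutation of cluster ids
    assignments: np.ndarray      # (n_rows,) cluster id per matrix row
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    inertia: float               # k-means objective in standardized space
    exemplar_ids: np.ndarray | None = None
    timestamps: np.ndarray | None = None
    generated_action: ActionSet | None = None


def cluster_keyframes(m: FeatureMatrix, k: int, seed: int,
                      n_init: int = 10,
                      tolerance_factor: float = 3.0,
                      tolerance_floor: float = 5.0) -> TrainedModel:
    """Discover ``k`` key frames by k-means over standardized features.

    Tolerances are ``tolerance_factor`` times the per-feature standard
    deviation of each cluster's members, floored at ``tolerance_floor``
    (degrees for angle features) so single-member or razor-thin clusters
    still yield satisfiable rules.  Deterministic given ``seed``.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if m.n_rows < k:
        raise InsufficientDataError(f"{m.n_rows} rows < k={k}")
    scaler = StandardScaler()
    X = scaler.fit_transform(m.values)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    centroids = scaler.inverse_transform(km.cluster_centers_)
    tolerances = np.empty_like(centroids)
    mean_phase = np.empty(k)
    for c in range(k):
        members = m.values[labels == c]
        std = members.std(axis=0, ddof=0) if len(members) else np.zeros(centroids.shape[1])
        tolerances[c] = np.maximum(tolerance_factor * std, tolerance_floor)
        mean_phase[c] = m.phases[labels == c].mean() if (labels == c).any() else np.inf
    order = np.argsort(mean_phase, kind="stable")
    return TrainedModel(
        k=k, feature_names=list(m.feature_names),
        centroids=centroids, tolerances=tolerances,
        temporal_order=order, assignments=labels,
        scaler_mean=scaler.mean_.copy(), scaler_scale=scaler.scale_.copy(),
        inertia=float(km.inertia_),
        exemplar_ids=m.exemplar_ids.copy(), timestamps=m.timestamps.copy())


# --------------------------------------------------------------------------
# rule synthesis
# --------------------------------------------------------------------------

def _estimate_time_params(model: TrainedModel, safety: float = 1.5,
                          ) -> tuple[float, float]:
    """Estimate (max_gap, max_span) from exemplar key-frame timing.

    Per exemplar, each key frame's occurrence time is the mean timestamp of
    its member rows; gaps are differences between consecutive key frames in
    temporal order, the span is last minus first.  The 95th percentile over
    exemplars, times a safety factor, becomes the restriction.
    """
    gaps: list[float] = []
    spans: list[float] = []
    for ei in np.unique(model.exemplar_ids):
        sel = model.exemplar_ids == ei
        times = []
        for c in model.temporal_order:
            member_t = model.timestamps[sel & (model.assignments == c)]
            if len(member_t) == 0:
                break
            times.append(member_t.mean())
        if len(times) != model.k:
            continue
        diffs = np.diff(times)
        if np.any(diffs < 0):
            continue
        gaps.extend(diffs)
        spans.append(times[-1] - times[0])
    if model.k == 1 or not gaps:
        return 1.0, 1.0  # single key frame: restrictions are vacuous
    max_gap = float(np.percentile(gaps, 95) * safety)
    max_span = float(np.percentile(spans, 95) * safety) if spans else max_gap
    return max_gap, max(max_span, max_gap)


def synthesize_rules(model: TrainedModel, class_name: str,
                     time_params: tuple[float, float] | None = None,
                     safety: float = 1.5) -> ActionSet:
    """Emit an executable action definition from a trained model.

    Key frame i (temporal order) becomes a rule requiring every feature to
    lie within its tolerance of the cluster centroid; the action sequences
    the rules with ``time_params = (max_gap, max_span)`` (estimated from
    exemplar timing when not given).  The result is stored on
    ``model.generated_action`` and returned.
    """
    if time_params is None:
        max_gap, max_span = _estimate_time_params(model, safety)
    else:
        max_gap, max_span = float(time_params[0]), float(time_params[1])
    rules: list[KeyFrameRule] = []
    names: list[str] = []
    for i, c in enumerate(model.temporal_order):
        terms = []
        for fi, fname in enumerate(model.feature_names):
            lo = float(model.centroids[c, fi] - model.tolerances[c, fi])
            hi = float(model.centroids[c, fi] + model.tolerances[c, fi])
            terms.append(f"{fname} >= {lo!r} and {fname} <= {hi!r}")
        name = f"{class_name}_kf{i + 1}"
        names.append(name)
        rules.append(KeyFrameRule(name, " and ".join(terms)))
    action = ActionDefinition(class_name, tuple(names), max_gap, max_span)
    out = ActionSet(rules, [action])
    model.generated_action = out
    return out


def train(exemplars: Sequence[MotionSequence],
          defs: Sequence[FeatureDefinition],
          k: int, seed: int, class_name: str = "action",
          time_params: tuple[float, float] | None = None,
          **cluster_kwargs) -> TrainedModel:
    """Convenience pipeline: feature matrix -> clustering -> rule synthesis."""
    m = build_feature_matrix(exemplars, defs)
    model = cluster_keyframes(m, k, seed, **cluster_kwargs)
    synthesize_rules(model, class_name, time_params)
    return model


# --------------------------------------------------------------------------
# PCA inspection
# --------------------------------------------------------------------------

def pca_project(m: FeatureMatrix, dims: int = 3,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """PCA of the standardized feature cloud.

    Returns ``(coords, explained_variance_ratio, components, kept_names)``.
    Constant columns are dropped with a warning; component signs follow a
    deterministic convention (the largest-magnitude loading of each
    component is positive).
    """
    if m.n_rows <= dims:
        raise InsufficientDataError(f"need more than {dims} rows, got {m.n_rows}")
    std = m.values.std(axis=0)
    keep = std > 0
    if not keep.all():
        dropped = [n for n, k_ in zip(m.feature_names, keep) if not k_]
        log.warning("dropping constant feature columns: %s", dropped)
    X = m.values[:, keep]
    kept_names = [n for n, k_ in zip(m.feature_names, keep) if k_]
    X = StandardScaler().fit_transform(X)
    p = PCA(n_components=min(dims, X.shape[1]))
    coords = p.fit_transform(X)
    comps = p.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            coords[:, i] = -coords[:, i]
    return coords, p.explained_variance_ratio_.copy(), comps, kept_names


def silhouette_sweep(m: FeatureMatrix, seed: int,
                     k_range: Sequence[int] = range(2, 9)) -> dict[int, float]:
    """Silhouette score per candidate k (inspection aid; never auto-applied)."""
    from sklearn.metrics import silhouette_score
    X = StandardScaler().fit_transform(m.values)
    out: dict[int, float] = {}
    for k in k_range:
        if m.n_rows <= k:
            continue
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        out[k] = float(silhouette_score(X, labels))
    return out
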