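"""R-GDL training: feature matrix, clustering, rule synthesis, PCA."""

import itertools

import numpy as np
import pytest

import gdlkit as g
from gdlkit.errors import InsufficientDataError
from gdlkit.trainer import (FeatureMatrix, build_feature_matrix,
                            cluster_keyframes, pca_project, synthesize_rules)

from conftest import FEATURE_NAMES


@pytest.fixture(scope="module")
def exemplars(hiza_defs):
    return [g.generate(g.builtin_kick_script(seed=100 + i, repetitions=1))[0]
            for i in range(12)]


@pytest.fixture(scope="module")
def matrix(exemplars, hiza_defs):
    return build_feature_matrix(exemplars, hiza_defs)


# --------------------------------------------------------------------------
# feature matrix
# --------------------------------------------------------------------------

def test_matrix_shape_one_row_per_frame(hiza_defs):
    seq, _ = g.generate(g.builtin_kick_script(seed=0, repetitions=1))
    m = build_feature_matrix([seq], hiza_defs)
    assert m.values.shape == (len(seq), 6)
    assert m.feature_names == FEATURE_NAMES
    assert m.phases[0] == 0.0 and m.phases[-1] == 1.0
    assert np.all(np.diff(m.phases) >= 0)


def test_matrix_rows_equal_per_frame_evaluation(hiza_defs):
    seq, _ = g.generate(g.builtin_kick_script(seed=1, repetitions=1))
    m = build_feature_matrix([seq], hiza_defs)
    history = None
    for i, frame in enumerate(seq.frames):
        history = g.evaluate_features(frame, hiza_defs, history)
        expected = [float(history[n]) for n in FEATURE_NAMES]
        np.testing.assert_allclose(m.values[i], expected)


def test_single_frame_exemplar_phase_zero(k2, hiza_defs):
    pose = g.standing_pose()
    seq = g.MotionSequence(k2, [g.SkeletonFrame(4.0, pose)])
    m = build_feature_matrix([seq], hiza_defs)
    assert m.n_rows == 1
    assert m.phases[0] == 0.0


def test_degenerate_rows_dropped_with_count(k2, hiza_defs):
    pose = g.standing_pose()
    bad = {k: v.copy() for k, v in pose.items()}
    bad["KneeRight"] = bad["HipRight"].copy()  # zero-length thigh vector
    seq = g.MotionSequence(k2, [g.SkeletonFrame(0.0, pose),
                                g.SkeletonFrame(1.0, bad),
                                g.SkeletonFrame(2.0, pose)])
    m = build_feature_matrix([seq], hiza_defs)
    assert m.n_rows == 2
    assert m.n_dropped == 1


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def test_k1_centroid_is_column_mean(matrix):
    model = cluster_keyframes(matrix, k=1, seed=0)
    np.testing.assert_allclose(model.centroids[0], matrix.values.mean(axis=0),
                               rtol=1e-9, atol=1e-9)
    assert list(model.temporal_order) == [0]


def test_insufficient_rows_raises(k2, hiza_defs):
    seq = g.MotionSequence(k2, [g.SkeletonFrame(0.0, g.standing_pose())])
    m = build_feature_matrix([seq], hiza_defs)
    with pytest.raises(InsufficientDataError):
        cluster_keyframes(m, k=2, seed=0)


def test_two_planted_poses_recovered_within_one_degree(hiza_defs):
    """Two well-separated held poses, long holds, noise far below the
    separation: k=2 centroids land on the planted pose angles."""
    poses = g.kick_key_poses()
    script = g.KeyPoseScript(
        topology=g.k2_topology(), key_poses=[poses[0], poses[2]],
        hold_times=[2.0, 2.0], transition_times=[0.1, 0.1],
        repetitions=1, noise_sigma_pos=g.positional_noise_for_angle_sigma(3.0),
        rate=30.0, seed=17)
    exems = [g.KeyPoseScript(**{**script.__dict__, "seed": 17 + i})
             for i in range(10)]
    streams = [g.generate(s)[0] for s in exems]
    m = build_feature_matrix(streams, hiza_defs)
    model = cluster_keyframes(m, k=2, seed=0)
    planted = np.array([
        [float(g.evaluate_features(g.SkeletonFrame(0.0, p), hiza_defs)[n])
         for n in FEATURE_NAMES] for p in (poses[0], poses[2])])
    recovered = model.centroids[model.temporal_order]
    assert np.abs(recovered - planted).max() < 1.0


def test_small_instance_matches_exhaustive_partition_optimum():
    """On tiny instances the k-means objective equals the global optimum
    found by enumerating every assignment."""
    rng = np.random.default_rng(0)
    for trial in range(5):
        n, k = 8, 3
        X = rng.normal(size=(n, 2)) + rng.choice([0, 4, 8], size=(n, 1))
        m = FeatureMatrix(X, ["f1", "f2"], np.zeros(n, int),
                          np.arange(n, dtype=float), np.linspace(0, 1, n))
        model = cluster_keyframes(m, k=k, seed=trial)
        # oracle on the same standardized matrix
        Z = (X - X.mean(0)) / X.std(0)
        best = np.inf
        for assign in itertools.product(range(k), repeat=n):
            sse = 0.0
            for c in range(k):
                pts = Z[np.array(assign) == c]
                if len(pts):
                    sse += ((pts - pts.mean(0)) ** 2).sum()
            best = min(best, sse)
        assert model.inertia == pytest.approx(best, rel=1e-7, abs=1e-9)


def test_temporal_order_sorted_by_phase(matrix, planted_pose_angles):
    model = cluster_keyframes(matrix, k=3, seed=0)
    phases = [matrix.phases[model.assignments == c].mean()
              for c in model.temporal_order]
    assert phases == sorted(phases)
    # ordered centroids should correspond to the planted pose sequence
    recovered = model.centroids[model.temporal_order]
    assert np.abs(recovered - planted_pose_angles).max() < 2.0


def test_tolerances_positive_and_floored(matrix):
    model = cluster_keyframes(matrix, k=3, seed=0)
    assert np.all(model.tolerances >= 5.0)


def test_training_deterministic_given_seed(matrix):
    m1 = cluster_keyframes(matrix, k=3, seed=9)
    m2 = cluster_keyframes(matrix, k=3, seed=9)
    np.testing.assert_array_equal(m1.centroids, m2.centroids)
    np.testing.assert_array_equal(m1.assignments, m2.assignments)
    np.testing.assert_array_equal(m1.temporal_order, m2.temporal_order)


# --------------------------------------------------------------------------
# rule synthesis
# --------------------------------------------------------------------------

def test_synthesized_structure_three_rules_six_intervals(matrix):
    model = cluster_keyframes(matrix, k=3, seed=0)
    aset = synthesize_rules(model, "kick")
    assert len(aset.rules) == 3
    assert aset.actions[0].keyframe_sequence == ("kick_kf1", "kick_kf2", "kick_kf3")
    for r in aset.rules:
        # conjunction of 6 interval constraints = 12 comparisons
        assert r.source.count(">=") == 6 and r.source.count("<=") == 6


def test_closed_loop_training_exemplars_redetected(exemplars, hiza_defs, matrix):
    model = cluster_keyframes(matrix, k=3, seed=0)
    aset = synthesize_rules(model, "kick")
    ok = sum(1 for seq in exemplars
             if len(g.classify_stream(seq, hiza_defs, aset).events) == 1)
    assert ok >= 0.95 * len(exemplars)


def test_widening_tolerances_never_removes_detection(exemplars, hiza_defs, matrix):
    model = cluster_keyframes(matrix, k=3, seed=0)
    narrow = synthesize_rules(model, "kick")
    detected_narrow = [len(g.classify_stream(s, hiza_defs, narrow).events) > 0
                       for s in exemplars[:6]]
    model.tolerances = model.tolerances * 1.5
    wide = synthesize_rules(model, "kick",
                            time_params=(narrow.actions[0].max_gap,
                                         narrow.actions[0].max_span))
    detected_wide = [len(g.classify_stream(s, hiza_defs, wide).events) > 0
                     for s in exemplars[:6]]
    for a, b in zip(detected_narrow, detected_wide):
        assert b or not a


def test_estimated_time_params_allow_detection(matrix, exemplars, hiza_defs):
    model = cluster_keyframes(matrix, k=3, seed=0)
    aset = synthesize_rules(model, "kick")
    a = aset.actions[0]
    assert a.max_gap > 0 and a.max_span >= a.max_gap


# --------------------------------------------------------------------------
# PCA projection
# --------------------------------------------------------------------------

def test_planar_data_fully_explained_by_two_components():
    rng = np.random.default_rng(1)
    basis = rng.normal(size=(2, 6))
    coefs = rng.normal(size=(40, 2))
    X = coefs @ basis  # rank-2 cloud embedded in 6-D
    m = FeatureMatrix(X, [f"f{i}" for i in range(6)], np.zeros(40, int),
                      np.arange(40, dtype=float), np.linspace(0, 1, 40))
    coords, evr, comps, names = pca_project(m, dims=3)
    assert evr[:2].sum() == pytest.approx(1.0, abs=1e-9)
    assert len(names) == 6


def test_projected_centroids_are_member_means(matrix):
    model = cluster_keyframes(matrix, k=3, seed=0)
    coords, evr, comps, names = pca_project(matrix, dims=3)
    Z = (matrix.values - matrix.values.mean(0)) / matrix.values.std(0)
    for c in range(3):
        sel = model.assignments == c
        centroid_z = Z[sel].mean(axis=0)
        projected_centroid = (centroid_z - Z.mean(0)) @ comps.T
        np.testing.assert_allclose(projected_centroid, coords[sel].mean(axis=0),
                                   atol=1e-8)


def test_retained_variance_matches_eigendecomposition_oracle(matrix):
    coords, evr, comps, names = pca_project(matrix, dims=2)
    Z = (matrix.values - matrix.values.mean(0)) / matrix.values.std(0)
    cov = np.cov(Z, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    np.testing.assert_allclose(evr[:2], eig[:2] / eig.sum(), rtol=1e-9)
    # reconstruction error == total variance - retained variance
    recon = coords @ comps
    resid = ((Z - Z.mean(0)) - recon) ** 2
    n = Z.shape[0]
    total_var = eig.sum()
    retained = eig[:2].sum()
    assert resid.sum() / (n - 1) == pytest.approx(total_var - retained, rel=1e-6)


def test_constant_column_dropped_with_warning(caplog):
    rng = np.random.default_rng(2)
    X = rng.normal(size=(30, 3))
    X[:, 1] = 7.0
    m = FeatureMatrix(X, ["a", "const", "b"], np.zeros(30, int),
                      np.arange(30, dtype=float), np.linspace(0, 1, 30))
    with caplog.at_level("WARNING", logger="gdlkit"):
        coords, evr, comps, names = pca_project(m, dims=2)
    assert names == ["a", "b"]
    assert "const" in caplog.text


def test_pca_needs_more_rows_than_dims(matrix):
    tiny = FeatureMatrix(matrix.values[:2], matrix.feature_names,
                         matrix.exemplar_ids[:2], matrix.timestamps[:2],
                         matrix.phases[:2])
    with pytest.raises(InsufficientDataError):
        pca_project(tiny, dims=3)
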