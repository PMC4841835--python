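import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gdlkit as g

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

FEATURE_NAMES = ["A1", "A2", "A3", "A4", "A5", "A6"]


@pytest.fixture(scope="session")
def k2():
    return g.k2_topology()


@pytest.fixture(scope="session")
def k1():
    return g.k1_topology()


@pytest.fixture(scope="session")
def hiza_defs():
    return g.builtin_hiza_geri_features()


@pytest.fixture(scope="session")
def kick_script_clean():
    """Noiseless single kick."""
    return g.builtin_kick_script(seed=0, repetitions=1, noise_sigma_pos=0.0)


@pytest.fixture(scope="session")
def planted_pose_angles(kick_script_clean, hiza_defs):
    """Analytic (noiseless) feature values of the three kick key poses."""
    rows = []
    for pose in kick_script_clean.key_poses:
        fv = g.evaluate_features(g.SkeletonFrame(0.0, pose), hiza_defs)
        rows.append([float(fv[n]) for n in FEATURE_NAMES])
    return np.array(rows)


def random_k2_frame(rng, timestamp=0.0):
    topo = g.k2_topology()
    return g.SkeletonFrame(
        timestamp,
        {j: rng.uniform(-1.0, 2.0, size=3) for j in topo.joint_names})
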