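import numpy as np
import pytest

import sinusid as sd


def random_rigid_transform(rng, max_angle_deg=30.0, max_translation=20.0):
    """Uniform-axis rotation up to max_angle_deg plus a bounded translation."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rotation = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
    translation = rng.uniform(-max_translation, max_translation, 3)
    return sd.RigidTransform(rotation, translation)


@pytest.fixture(scope="session")
def small_config():
    """Tiny cohort settings for fast unit tests (coarse meshes)."""
    return sd.CohortConfig(n_per_sex=2, seed=11, mesh_subdivisions=2)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sd.generate_cohort(small_config)


@pytest.fixture(scope="session")
def sinus_mesh(small_cohort):
    """One representative deformed sinus surface (162 vertices)."""
    return small_cohort.models[0].mesh


@pytest.fixture(scope="session")
def default_experiment():
    """Full match/mismatch experiment under the default generator regime.

    n_per_sex=10 keeps the run around a minute while preserving the
    statistical structure (default deformation and repeat-noise sds).
    """
    config = sd.CohortConfig(n_per_sex=10, seed=0)
    cohort = sd.generate_cohort(config)
    table = sd.run_experiment(sd.build_pairs(cohort))
    return table
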