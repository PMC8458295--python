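"""Shared fixtures: small meshes and cohorts reused across the suite."""

import numpy as np
import pytest
import trimesh

from mandssm.synthetic import CohortSpec, generate_base_mandible, generate_cohort


@pytest.fixture(scope="session")
def base_mesh():
    return generate_base_mandible(700, seed=2)


@pytest.fixture(scope="session")
def sphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=10.0)


@pytest.fixture(scope="session")
def small_cohort():
    """25 samples, 500 base points, default amplitudes and noise."""
    return generate_cohort(CohortSpec(n_samples=25, n_points_base=500, seed=5))


@pytest.fixture(scope="session")
def recovery_cohort():
    """200 samples at the default study conditions (3 modes, 5% noise)."""
    return generate_cohort(CohortSpec(n_samples=200, n_points_base=900, seed=7))


def principal_angles_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Principal angles (degrees) between the column spans of u and v."""
    qu, _ = np.linalg.qr(u)
    qv, _ = np.linalg.qr(v)
    s = np.linalg.svd(qu.T @ qv, compute_uv=False)
    return np.degrees(np.arccos(np.clip(s, -1.0, 1.0)))
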