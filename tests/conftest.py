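import numpy as np
import pytest

from facemorph import GeneratorConfig, sample_cohort
from facemorph.mesh_core import TriMesh


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same stream regardless of run order
    return np.random.default_rng(20250901)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small noisy cohort with jitter: 10 volunteers + 5 paired patients."""
    cfg = GeneratorConfig(
        resolution=12, n_volunteers=10, n_patients=5, rank=4,
        variances=(1.6, 1.0, 0.6, 0.4), noise_sd=0.2, seed=7,
    )
    return sample_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise- and jitter-free cohort for exact-recovery checks."""
    cfg = GeneratorConfig(
        resolution=12, n_volunteers=12, n_patients=10, rank=4,
        variances=(1.6, 1.0, 0.6, 0.4), noise_sd=0.0,
        rotation_jitter_deg=0.0, translation_jitter_mm=0.0, scale_jitter=(1.0, 1.0),
        seed=11,
    )
    return sample_cohort(cfg)


def random_mesh(rng, n=50) -> TriMesh:
    """Arbitrary corresponded test mesh: random vertices on a fixed fan triangulation."""
    vertices = rng.normal(size=(n, 3)) * 10.0
    faces = np.column_stack(
        [np.zeros(n - 2, dtype=int), np.arange(1, n - 1), np.arange(2, n)]
    )
    return TriMesh(vertices, faces)
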