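"""Non-rigid ICP registration and batch dense correspondence."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from facemorph.alignment import SimilarityTransform
from facemorph.correspondence import (
    NicpConfig,
    build_correspondence,
    closest_points_on_surface,
    nicp_register,
)
from facemorph.mesh_core import TriMesh, average_euclidean_distance, unflatten
from facemorph.synthetic_faces import (
    GeneratorConfig,
    make_bent_target,
    make_template,
    sample_cohort,
)


class _Fixture:
    """Template + smoothly bent target with exactly known per-vertex truth."""

    def __init__(self):
        cfg = GeneratorConfig(
            resolution=16, n_volunteers=1, n_patients=0, rank=4,
            variances=(1.6, 1.0, 0.6, 0.4), seed=3,
        )
        (self.template, self.template_landmarks,
         self.target, self.target_landmarks) = make_bent_target(cfg, amplitude=5.0, seed=3)


@pytest.fixture(scope="module")
def deform_fixture():
    f = _Fixture()
    return f, f.target, f.target_landmarks


class TestNicpConfig:
    def test_increasing_stiffness_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            NicpConfig(stiffness_schedule=(1.0, 2.0), landmark_weight_schedule=(1.0, 0.0))

    def test_schedule_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            NicpConfig(stiffness_schedule=(2.0, 1.0), landmark_weight_schedule=(1.0,))


class TestClosestPoint:
    def test_matches_brute_force_over_all_triangles(self, rng):
        cfg = GeneratorConfig(resolution=10, n_volunteers=0, n_patients=0,
                              rank=4, variances=(1.6, 1.0, 0.6, 0.4), seed=0)
        mesh, _ = make_template(cfg)
        queries = mesh.vertices[rng.choice(len(mesh.vertices), 20)] + rng.normal(
            scale=5.0, size=(20, 3)
        )
        _, dist, _ = closest_points_on_surface(mesh, queries)
        # brute force: distance to every triangle via dense sampling of barycentres
        tri = mesh.vertices[mesh.faces]
        w = np.array(
            [[a, b, 1 - a - b] for a in np.linspace(0, 1, 25)
             for b in np.linspace(0, 1, 25) if a + b <= 1.0]
        )
        samples = np.einsum("kj,mjc->mkc", w, tri).reshape(-1, 3)
        brute = np.sqrt(((queries[:, None] - samples[None]) ** 2).sum(-1)).min(1)
        assert np.all(dist <= brute + 1e-9)
        assert np.allclose(dist, brute, atol=0.05)  # sampling resolution of the oracle


class TestNicpRegister:
    def test_fixed_point(self, deform_fixture):
        c, _, _ = deform_fixture
        shape, residual = nicp_register(
            c.template, c.template, c.template_landmarks, c.template_landmarks
        )
        assert residual < 1e-6
        aed = average_euclidean_distance(
            unflatten(shape, c.template.faces), c.template
        )
        assert aed < 1e-6

    def test_known_smooth_deformation_recovered(self, deform_fixture):
        """AED to the ground-truth deformed vertices stays below 0.5 mm at 5 mm amplitude."""
        c, target, target_lms = deform_fixture
        disp = np.linalg.norm(target.vertices - c.template.vertices, axis=1)
        assert disp.max() == pytest.approx(5.0, abs=1e-9)
        shape, residual = nicp_register(
            c.template, target, c.template_landmarks, target_lms
        )
        aed = average_euclidean_distance(unflatten(shape, c.template.faces), target)
        assert aed < 0.5
        assert residual >= 0.0 and np.isfinite(residual)

    def test_target_with_hole_completes(self, deform_fixture):
        c, target, target_lms = deform_fixture
        # delete ~20% of the surface: all faces touching the lowest-y fifth
        cut = np.quantile(target.vertices[:, 1], 0.2)
        keep_faces = ~np.any(target.vertices[target.faces][:, :, 1] < cut, axis=1)
        used = np.unique(target.faces[keep_faces])
        remap = -np.ones(target.n_vertices, dtype=int)
        remap[used] = np.arange(len(used))
        holed = TriMesh(target.vertices[used], remap[target.faces[keep_faces]], "holed")
        shape, residual = nicp_register(
            c.template, holed, c.template_landmarks, target_lms
        )
        assert np.isfinite(residual) and residual >= 0.0
        assert shape.n_vertices == c.template.n_vertices

    def test_rigid_equivariance_after_prealignment(self, deform_fixture):
        """Registering a rigidly moved target (after pre-alignment) matches the original."""
        c, target, target_lms = deform_fixture
        ref = build_correspondence(
            c.template, [target], [target_lms], c.template_landmarks
        ).shapes[0]

        T = SimilarityTransform(
            Rotation.from_euler("xyz", [20, -10, 30], degrees=True).as_matrix(),
            1.0, np.array([15.0, -8.0, 4.0]),
        )
        moved = target.with_vertices(T.apply(target.vertices), "moved")
        moved_lms = type(target_lms)(
            "moved", T.apply(target_lms.points), list(target_lms.names)
        )
        out = build_correspondence(
            c.template, [moved], [moved_lms], c.template_landmarks
        )
        aed = np.linalg.norm(
            (out.shapes[0].x - ref.x).reshape(-1, 3), axis=1
        ).mean()
        assert aed < 0.1

    def test_disconnected_template_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                      [10, 10, 10], [11, 10, 10], [10, 11, 10]], dtype=float)
        f = np.array([[0, 1, 2], [3, 4, 5]])
        tpl = TriMesh(v, f)
        with pytest.raises(ValueError, match="disconnected"):
            nicp_register(tpl, tpl)

    def test_landmark_name_mismatch_rejected(self, deform_fixture):
        c, _, _ = deform_fixture
        bad = type(c.template_landmarks)(
            "bad", c.template_landmarks.points,
            [n + "_x" for n in c.template_landmarks.names],
        )
        with pytest.raises(ValueError, match="landmark names"):
            nicp_register(c.template, c.template, c.template_landmarks, bad)

    def test_residual_nonincreasing_over_stiffness_steps(self, deform_fixture):
        """Coarse-to-fine: a looser stiffness tail never fits worse than the stiff head."""
        c, target, target_lms = deform_fixture
        residuals = []
        schedule = (50.0, 20.0, 5.0, 2.0, 0.8, 0.5)
        for cut in range(1, len(schedule) + 1):
            cfg = NicpConfig(
                stiffness_schedule=schedule[:cut],
                landmark_weight_schedule=tuple(np.linspace(5, 0, cut)),
            )
            _, r = nicp_register(c.template, target, c.template_landmarks,
                                 target_lms, cfg)
            residuals.append(r)
        assert np.all(np.diff(residuals) <= 1e-6)


class TestBuildCorrespondence:
    def test_batch_shape_contract(self):
        cfg5 = GeneratorConfig(
            resolution=16, n_volunteers=5, n_patients=0, rank=4,
            variances=(1.6, 1.0, 0.6, 0.4), noise_sd=0.0,
            rotation_jitter_deg=5.0, translation_jitter_mm=10.0, seed=9,
        )
        cc = sample_cohort(cfg5)
        out = build_correspondence(
            cc.template, cc.meshes, cc.landmarks, cc.template_landmarks
        )
        assert len(out) == 5 and not out.failures
        assert all(s.n_vertices == cc.template.n_vertices for s in out.shapes)
        assert out.scan_ids == [m.id for m in cc.meshes]

    def test_empty_scan_list(self, deform_fixture):
        c, _, _ = deform_fixture
        out = build_correspondence(c.template, [], [], c.template_landmarks)
        assert len(out) == 0 and not out.failures

    def test_one_corrupt_scan_recorded(self, deform_fixture):
        c, target, target_lms = deform_fixture
        good = target.with_vertices(target.vertices, "good")
        corrupt_lms = type(c.template_landmarks)(
            "bad", c.template_landmarks.points,
            [n + "_z" for n in c.template_landmarks.names],
        )
        out = build_correspondence(
            c.template, [good, good], [target_lms, corrupt_lms],
            c.template_landmarks,
        )
        assert len(out) == 1
        assert len(out.failures) == 1 and out.failures[0][0] == "good"
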