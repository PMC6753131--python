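"""Synthetic face-like cohorts with known ground truth.

Real clinical face databases are proprietary, so every pipeline stage is
exercised on generated data instead.  The generator produces:

* a smooth parametric **template** — an ellipsoidal facial patch with a nose
  and chin protrusion on a regular grid, with named landmarks at analytically
  known vertices;
* **volunteers** — template + a random low-rank smooth deformation
  (``B @ beta`` with an orthonormal basis of low-frequency fields and a
  descending variance spectrum) + sensor noise;
* **preoperative patients** — additionally displaced by a localised jaw
  dipole field (maxilla pushed in, mandible pushed out — the class-2
  malocclusion signature), amplitude ``patient_effect_size`` mm;
* **postoperative patients** — the *same* subject coefficients pushed through
  a known linear surgical operator that removes most of the jaw displacement
  and leaves a small residual on the nose;
* a random per-scan **similarity corruption** (rotation/translation/scale)
  standing in for arbitrary scanner poses.

Everything the pipeline should recover — generative coefficients, clean
corresponded shapes, the jaw vertex mask, the surgical operator — is retained
in the returned :class:`SyntheticCohort`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import SimilarityTransform
from .clinical_ml import CohortTable
from .mesh_core import (
    FlatShape,
    LandmarkSet,
    TriMesh,
    write_landmarks,
    write_mesh,
)

__all__ = ["GeneratorConfig", "SyntheticCohort", "make_template", "sample_cohort", "write_cohort"]

# landmark name -> (u, v) parametric position on the template grid
_LANDMARKS_UV = {
    "pronasale": (0.0, 0.0),
    "glabella": (0.0, 0.35),
    "pogonion": (0.0, -0.7),
    "exocanthion_r": (0.45, 0.4),
    "exocanthion_l": (-0.45, 0.4),
    "cheilion_r": (0.3, -0.45),
    "cheilion_l": (-0.3, -0.45),
}


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohorts.

    Defaults mirror the emulated study where it states sizes (113 paired
    patient scans; the volunteer pool scaled to 500 for desk-scale work) and
    otherwise use values a face scanner and an orthognathic cohort would
    plausibly produce: identity variation of ~2 mm RMS across the surface
    (consistent with sub-millimetre nearest-neighbour distances in dense face
    databases), a jaw effect large against half-millimetre sensor noise.
    """

    resolution: int = 20                 # vertices per grid side
    n_volunteers: int = 500
    n_patients: int = 113                # paired preop/postop subjects
    rank: int = 8                        # generative basis rank
    variances: tuple[float, ...] = (1.6, 1.0, 0.6, 0.4, 0.25, 0.15, 0.1, 0.05)  # mm^2
    patient_effect_size: float = 8.0     # mm peak jaw displacement
    effect_size_sd_fraction: float = 0.15
    jaw_correction: float = 0.9          # fraction of jaw displacement removed by surgery
    nose_residual_gain: float = 0.25     # residual nose amplitude per mm of jaw amplitude
    noise_sd: float = 0.5                # mm isotropic sensor noise per vertex
    rotation_jitter_deg: float = 10.0
    translation_jitter_mm: float = 20.0
    scale_jitter: tuple[float, float] = (0.95, 1.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution < 8:
            raise ValueError("resolution must be >= 8")
        v = np.asarray(self.variances, dtype=float)
        if len(v) != self.rank:
            raise ValueError("one variance per basis component required")
        if np.any(v <= 0) or np.any(np.diff(v) > 0):
            raise ValueError("variance spectrum must be positive and descending")
        if self.patient_effect_size < 0:
            raise ValueError("patient_effect_size must be >= 0")


@dataclass
class SyntheticCohort:
    """A generated cohort plus everything needed to check recovery."""

    template: TriMesh
    template_landmarks: LandmarkSet
    meshes: list[TriMesh]
    landmarks: list[LandmarkSet]
    cohort: CohortTable
    clean_shapes: dict[str, FlatShape]        # template-frame, noise- and jitter-free
    noisy_clean_shapes: dict[str, FlatShape]  # template-frame with noise, jitter-free
    true_coefficients: pd.DataFrame           # beta0..beta{r-1}, jaw_amp, nose_amp per scan
    surgical_operator: np.ndarray             # linear map on (beta, jaw, nose)
    jaw_mask: np.ndarray                      # boolean vertex mask of the jaw effect
    basis_fields: np.ndarray                  # (3n, r) orthonormal generative basis
    jaw_field: np.ndarray                     # (3n,), unit peak amplitude
    nose_field: np.ndarray                    # (3n,), unit peak amplitude
    transforms: dict[str, SimilarityTransform] = field(default_factory=dict)

    def ground_truth_corresponded(self, noisy: bool = True) -> "CorrespondedSet":
        """The cohort as a template-frame corresponded set, bypassing registration.

        Useful when a downstream stage (model fitting, metrics, classification,
        regression) is under study and registration is not the question.
        """
        from .correspondence import CorrespondedSet

        source = self.noisy_clean_shapes if noisy else self.clean_shapes
        ids = self.cohort.table["scan_id"].tolist()
        return CorrespondedSet(
            template_faces=self.template.faces.copy(),
            shapes=[source[i] for i in ids],
            residuals=[0.0] * len(ids),
            scan_ids=ids,
        )


def _grid(resolution: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u = np.linspace(-1.0, 1.0, resolution)
    v = np.linspace(-1.0, 1.0, resolution)
    uu, vv = np.meshgrid(u, v, indexing="xy")
    return u, uu.ravel(), vv.ravel()


def _height(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Template z (mm) at parametric (u, v): facial dome + nose + chin."""
    dome = 40.0 * np.sqrt(np.clip(1.0 - 0.55 * u ** 2 - 0.35 * v ** 2, 0.0, None))
    nose = 12.0 * np.exp(-((u / 0.18) ** 2 + (v / 0.22) ** 2))
    chin = 4.0 * np.exp(-((u / 0.35) ** 2 + ((v + 0.62) / 0.18) ** 2))
    return dome + nose + chin


def make_template(config: GeneratorConfig) -> tuple[TriMesh, LandmarkSet]:
    """Deterministic face-like grid surface with named landmarks."""
    r = config.resolution
    _, uu, vv = _grid(r)
    x = 60.0 * uu
    y = 80.0 * vv
    z = _height(uu, vv)
    vertices = np.column_stack([x, y, z])
    faces = []
    for row in range(r - 1):
        for col in range(r - 1):
            a = row * r + col
            b = a + 1
            c = a + r
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    mesh = TriMesh(vertices, np.array(faces), id="template")
    names, points = [], []
    for name, (lu, lv) in _LANDMARKS_UV.items():
        idx = np.argmin((uu - lu) ** 2 + (vv - lv) ** 2)
        names.append(name)
        points.append(vertices[idx])
    return mesh, LandmarkSet("template", np.array(points), names)


def _landmark_indices(template: TriMesh, landmarks: LandmarkSet) -> np.ndarray:
    d = np.linalg.norm(template.vertices[None] - landmarks.points[:, None], axis=2)
    return d.argmin(axis=1)


def _similarity_tangent(template: TriMesh) -> np.ndarray:
    """Orthonormal basis (3n, 7) of the similarity orbit's tangent space at the
    template: 3 translations, 3 infinitesimal rotations, 1 scaling."""
    v = template.vertices - template.vertices.mean(axis=0)
    n = len(v)
    cols = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = 1.0
        cols.append(t.reshape(-1))
    for omega in np.eye(3):
        cols.append(np.cross(np.broadcast_to(omega, (n, 3)), v).reshape(-1))
    cols.append(v.reshape(-1))
    Q, _ = np.linalg.qr(np.column_stack(cols))
    return Q


def _basis_fields(template: TriMesh, uu: np.ndarray, vv: np.ndarray, rank: int) -> np.ndarray:
    """Orthogonal (3n, rank) basis of smooth normal-direction deformation fields.

    Fields are projected orthogonal to the similarity orbit (translation /
    rotation / scale directions) — variation along that orbit is removed by
    alignment and would be unrecoverable ground truth — and scaled to unit
    per-vertex RMS so a coefficient of c mm displaces the surface by c mm RMS
    at any mesh resolution.
    """
    freqs = [(1, 0), (0, 1), (1, 1), (2, 0), (0, 2), (2, 1), (1, 2), (2, 2),
             (3, 0), (0, 3), (3, 1), (1, 3)]
    if rank > len(freqs):
        raise ValueError(f"rank must be <= {len(freqs)}")
    normals = template.vertex_normals()
    cols = []
    for a, b in freqs[:rank]:
        f = np.cos(0.5 * np.pi * a * uu) * np.cos(0.5 * np.pi * b * vv)
        cols.append((f[:, None] * normals).reshape(-1))
    B = np.column_stack(cols)
    S = _similarity_tangent(template)
    B = B - S @ (S.T @ B)
    Q, _ = np.linalg.qr(B)
    return Q * np.sqrt(template.n_vertices)


def _jaw_field(template: TriMesh, uu: np.ndarray, vv: np.ndarray) -> np.ndarray:
    """Unit-peak dipole along +z: maxilla pushed back (-), mandible forward (+)."""
    lateral = np.exp(-((uu / 0.65) ** 2))
    maxilla = -np.exp(-(((vv + 0.28) / 0.18) ** 2))
    mandible = np.exp(-(((vv + 0.62) / 0.18) ** 2))
    f = lateral * (maxilla + mandible)
    f = f / np.abs(f).max()
    disp = np.zeros_like(template.vertices)
    disp[:, 2] = f
    return disp.reshape(-1)


def _nose_field(template: TriMesh, uu: np.ndarray, vv: np.ndarray) -> np.ndarray:
    """Unit-peak nose protrusion along +z."""
    f = np.exp(-((uu / 0.2) ** 2 + (vv / 0.22) ** 2))
    f = f / f.max()
    disp = np.zeros_like(template.vertices)
    disp[:, 2] = f
    return disp.reshape(-1)


def make_bent_target(
    config: GeneratorConfig, amplitude: float = 5.0, seed: int = 0
) -> tuple[TriMesh, LandmarkSet, TriMesh, LandmarkSet]:
    """Template plus a smooth normal-direction bending of known peak amplitude.

    Returns ``(template, template_landmarks, target, target_landmarks)`` where
    the target's per-vertex ground truth is exactly known.  The displacement is
    purely along vertex normals: tangential sliding is unobservable to
    closest-point registration (any tangential field leaves the surface
    unchanged), so normal-direction bending is the meaningful recovery fixture.
    """
    template, lms = make_template(config)
    _, uu, vv = _grid(config.resolution)
    normals = template.vertex_normals()
    rng = np.random.default_rng(seed)
    f = np.zeros_like(uu)
    for a, b in [(1, 0), (0, 1), (1, 1), (2, 0), (0, 2)]:
        f += rng.standard_normal() * np.cos(0.5 * np.pi * a * uu) * np.cos(0.5 * np.pi * b * vv)
    f *= amplitude / np.abs(f).max()
    target_pts = template.vertices + f[:, None] * normals
    target = TriMesh(target_pts, template.faces, "bent")
    lm_idx = _landmark_indices(template, lms)
    target_lms = LandmarkSet("bent", target_pts[lm_idx], list(lms.names))
    return template, lms, target, target_lms


def _random_similarity(rng: np.random.Generator, config: GeneratorConfig) -> SimilarityTransform:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-config.rotation_jitter_deg, config.rotation_jitter_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    s = rng.uniform(*config.scale_jitter)
    t = rng.uniform(-config.translation_jitter_mm, config.translation_jitter_mm, size=3)
    return SimilarityTransform(R, float(s), t)


def surgical_operator_matrix(config: GeneratorConfig) -> np.ndarray:
    """Linear map on extended coefficients (beta_1..beta_r, jaw_amp, nose_amp)."""
    r = config.rank
    A = np.eye(r + 2)
    A[r, r] = 1.0 - config.jaw_correction       # most jaw displacement removed
    A[r + 1, r] = config.nose_residual_gain      # residual nose effect driven by jaw amp
    A[r + 1, r + 1] = 1.0
    return A


def sample_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a full cohort; all randomness flows from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    template, template_lms = make_template(config)
    _, uu, vv = _grid(config.resolution)
    B = _basis_fields(template, uu, vv, config.rank)
    jaw = _jaw_field(template, uu, vv)
    nose = _nose_field(template, uu, vv)
    jaw_mask = np.abs(jaw.reshape(-1, 3)[:, 2]) > 0.1
    lm_idx = _landmark_indices(template, template_lms)
    operator = surgical_operator_matrix(config)
    sd = np.sqrt(np.asarray(config.variances))

    meshes: list[TriMesh] = []
    landmark_sets: list[LandmarkSet] = []
    rows: list[dict] = []
    clean: dict[str, FlatShape] = {}
    noisy_clean: dict[str, FlatShape] = {}
    coeff_rows: list[dict] = []
    transforms: dict[str, SimilarityTransform] = {}

    def emit(scan_id: str, subject_id: str, group: str, ext_coeffs: np.ndarray,
             pair_id: str | None) -> None:
        beta, jaw_amp, nose_amp = ext_coeffs[:-2], ext_coeffs[-2], ext_coeffs[-1]
        disp = B @ beta + jaw_amp * jaw + nose_amp * nose
        pts = template.vertices + disp.reshape(-1, 3)
        clean[scan_id] = FlatShape(pts.reshape(-1).copy())
        if config.noise_sd > 0:
            pts = pts + rng.normal(0.0, config.noise_sd, size=pts.shape)
        noisy_clean[scan_id] = FlatShape(pts.reshape(-1).copy())
        T = _random_similarity(rng, config)
        transforms[scan_id] = T
        meshes.append(TriMesh(T.apply(pts), template.faces, scan_id))
        landmark_sets.append(
            LandmarkSet(scan_id, T.apply(pts[lm_idx]), list(template_lms.names))
        )
        rows.append({"scan_id": scan_id, "subject_id": subject_id, "group": group,
                     "pair_id": pair_id})
        coeff_rows.append(
            {"scan_id": scan_id,
             **{f"beta{i}": beta[i] for i in range(config.rank)},
             "jaw_amp": jaw_amp, "nose_amp": nose_amp}
        )

    for i in range(config.n_volunteers):
        beta = rng.standard_normal(config.rank) * sd
        ext = np.concatenate([beta, [0.0, 0.0]])
        emit(f"vol{i:04d}", f"V{i:04d}", "volunteer", ext, None)

    for i in range(config.n_patients):
        beta = rng.standard_normal(config.rank) * sd
        jaw_amp = config.patient_effect_size
        if config.patient_effect_size > 0:
            jaw_amp = abs(rng.normal(
                config.patient_effect_size,
                config.effect_size_sd_fraction * config.patient_effect_size,
            ))
        pre = np.concatenate([beta, [jaw_amp, 0.0]])
        post = operator @ pre
        emit(f"pat{i:04d}_pre", f"P{i:04d}", "preop", pre, f"P{i:04d}")
        emit(f"pat{i:04d}_post", f"P{i:04d}", "postop", post, f"P{i:04d}")

    return SyntheticCohort(
        template=template,
        template_landmarks=template_lms,
        meshes=meshes,
        landmarks=landmark_sets,
        cohort=CohortTable(pd.DataFrame(rows)),
        clean_shapes=clean,
        noisy_clean_shapes=noisy_clean,
        true_coefficients=pd.DataFrame(coeff_rows),
        surgical_operator=operator,
        jaw_mask=jaw_mask,
        basis_fields=B,
        jaw_field=jaw,
        nose_field=nose,
        transforms=transforms,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path, format: str = "ply") -> Path:
    """Write meshes, landmark files and the cohort table to *directory*."""
    directory = Path(directory)
    (directory / "meshes").mkdir(parents=True, exist_ok=True)
    (directory / "landmarks").mkdir(parents=True, exist_ok=True)
    write_mesh(cohort.template, directory / f"template.{format}")
    write_landmarks(cohort.template_landmarks, directory / "template_landmarks.txt")
    for mesh, lms in zip(cohort.meshes, cohort.landmarks):
        write_mesh(mesh, directory / "meshes" / f"{mesh.id}.{format}")
        write_landmarks(lms, directory / "landmarks" / f"{mesh.id}.txt")
    cohort.cohort.table.to_csv(directory / "cohort.csv", index=False)
    cohort.true_coefficients.to_csv(directory / "true_coefficients.csv", index=False)
    return directory
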