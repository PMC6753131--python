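"""The PCA shape model ("3D morphable model") and its two core identities.

A morphable model consists of a mean shape ``M`` (length 3n), an orthonormal
basis ``U`` (3n x d, columns ordered by decreasing sample variance) and the
per-component variances.  Any face in the model's span is synthesised as

    X* = M + U @ alpha                      (synthesis)

and any corresponded face is embedded by the orthogonal projection

    alpha = U.T @ (X - M),  P(X) = M + U @ U.T @ (X - M)   (projection)

which is the least-squares optimal reconstruction with d components.  The
coefficient vector ``alpha`` is the feature vector used for diagnosis and
surgery simulation downstream.

PCA is computed by SVD of the centred data matrix (never the 3n x 3n
covariance); component signs are fixed by forcing each column's
largest-magnitude entry positive, which makes model builds bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .correspondence import CorrespondedSet
from .mesh_core import FlatShape, TriMesh, unflatten

__all__ = ["MorphableModel", "ShapeVector", "fit_pca", "save_model", "load_model"]


@dataclass
class MorphableModel:
    """Mean + orthonormal shape basis + per-component sample variances (mm^2)."""

    mean: FlatShape
    basis: np.ndarray            # (3n, d), orthonormal columns
    variances: np.ndarray        # (d,), descending
    template_faces: np.ndarray
    n_training: int
    id: str = "model"

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        d = self.basis.shape[1]
        if self.variances.shape != (d,):
            raise ValueError("one variance per basis column required")
        if d > 0:
            if not np.allclose(self.basis.T @ self.basis, np.eye(d), atol=1e-8):
                raise ValueError("basis columns are not orthonormal")
            if np.any(self.variances <= 0) or np.any(np.diff(self.variances) > 0):
                raise ValueError("variances must be positive and descending")
        if d > max(self.n_training - 1, 0):
            raise ValueError("more components than training shapes allow")

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.mean.n_vertices

    # -- Eq. 1: synthesis ---------------------------------------------------

    def synthesise(self, alpha: "ShapeVector | np.ndarray", id: str = "synth") -> TriMesh:
        """Mesh for coefficient vector *alpha*; zero coefficients give the mean face."""
        a = alpha.alpha if isinstance(alpha, ShapeVector) else np.asarray(alpha, dtype=float)
        if a.ndim != 1 or len(a) > self.n_components:
            raise ValueError(f"alpha must be a vector of length <= {self.n_components}")
        x = self.mean.x + self.basis[:, : len(a)] @ a
        return unflatten(FlatShape(x), self.template_faces, id)

    # -- Eq. 2: projection --------------------------------------------------

    def project(
        self, x: FlatShape | TriMesh, n_components: int | None = None
    ) -> tuple["ShapeVector", FlatShape]:
        """Optimal coefficients and reconstruction of *x* in the model subspace."""
        flat = x.x if isinstance(x, FlatShape) else x.vertices.reshape(-1)
        if flat.size != self.mean.x.size:
            raise ValueError(
                f"shape has {flat.size // 3} vertices, model expects {self.n_vertices}"
            )
        k = self.n_components if n_components is None else min(n_components, self.n_components)
        U = self.basis[:, :k]
        alpha = U.T @ (flat - self.mean.x)
        recon = FlatShape(self.mean.x + U @ alpha)
        return ShapeVector(alpha, self.id), recon

    def sample_faces(
        self, m: int, seed: int, truncate_sigma: float | None = None
    ) -> list[TriMesh]:
        """Draw *m* random faces, alpha_i ~ N(0, variance_i) independently.

        ``truncate_sigma`` optionally clips each coefficient at +-that many
        standard deviations.
        """
        if m < 1:
            raise ValueError("m must be >= 1")
        rng = np.random.default_rng(seed)
        sd = np.sqrt(self.variances)
        out = []
        for i in range(m):
            a = rng.standard_normal(self.n_components)
            if truncate_sigma is not None:
                a = np.clip(a, -truncate_sigma, truncate_sigma)
            out.append(self.synthesise(a * sd, id=f"synth{i}"))
        return out

    def mean_mesh(self, id: str = "mean") -> TriMesh:
        return unflatten(self.mean, self.template_faces, id)


@dataclass
class ShapeVector:
    """Coefficients of one face in a model's subspace."""

    alpha: np.ndarray
    model_id: str = "model"

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("shape vector must be finite")

    def __len__(self) -> int:
        return len(self.alpha)


def fit_pca(
    data: CorrespondedSet | np.ndarray,
    n_components: int | None = None,
    template_faces: np.ndarray | None = None,
    id: str = "model",
) -> MorphableModel:
    """Build a morphable model from an aligned, corresponded shape set.

    *data* is either a :class:`CorrespondedSet` or an (m, 3n) array of flat
    shapes.  Components are the principal directions of the centred data, with
    sample variances (divide by m-1).  Requests for more than m-1 components
    are clipped with a warning; directions with numerically zero variance are
    dropped.
    """
    if isinstance(data, CorrespondedSet):
        X = data.data_matrix()
        template_faces = data.template_faces if template_faces is None else template_faces
    else:
        X = np.asarray(data, dtype=np.float64)
    if template_faces is None:
        raise ValueError("template_faces required when fitting from a raw array")
    m = X.shape[0]
    if m < 2:
        raise ValueError("PCA needs at least 2 shapes")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centred data matrix; thin factors only
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = S ** 2 / (m - 1)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size and S[0] > 0 else 0
    d_max = min(m - 1, rank)
    d = d_max if n_components is None else n_components
    if d > d_max:
        warnings.warn(
            f"requested {d} components but only {d_max} available; clipping", RuntimeWarning
        )
        d = d_max
    basis = Vt[:d].T.copy()
    # deterministic sign: largest-magnitude entry of each column positive
    if d > 0:
        flips = np.sign(basis[np.abs(basis).argmax(axis=0), np.arange(d)])
        flips[flips == 0] = 1.0
        basis *= flips
    return MorphableModel(
        mean=FlatShape(mean),
        basis=basis,
        variances=variances[:d],
        template_faces=np.asarray(template_faces, dtype=np.int64),
        n_training=m,
        id=id,
    )


# ---------------------------------------------------------------------------
# persistence: one directory of .npy arrays + a JSON meta file.  np.save is
# timestamp-free, so identical models serialise to byte-identical files.


def save_model(model: MorphableModel, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "mean.npy", model.mean.x)
    np.save(directory / "basis.npy", model.basis)
    np.save(directory / "variances.npy", model.variances)
    np.save(directory / "faces.npy", model.template_faces)
    meta = {"id": model.id, "n_training": model.n_training}
    (directory / "meta.json").write_text(json.dumps(meta, sort_keys=True) + "\n")
    return directory


def load_model(directory: str | Path) -> MorphableModel:
    directory = Path(directory)
    if not (directory / "meta.json").exists():
        raise FileNotFoundError(f"no model found at {directory} (expected meta.json)")
    meta = json.loads((directory / "meta.json").read_text())
    return MorphableModel(
        mean=FlatShape(np.load(directory / "mean.npy")),
        basis=np.load(directory / "basis.npy"),
        variances=np.load(directory / "variances.npy"),
        template_faces=np.load(directory / "faces.npy"),
        n_training=int(meta["n_training"]),
        id=str(meta["id"]),
    )
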