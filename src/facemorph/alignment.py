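"""Similarity alignment of shape collections via generalised Procrustes analysis.

GPA removes rotation, translation and scale from a collection of corresponded
shapes, leaving only shape information.  Each shape is normalised to unit
centroid size during the iteration; afterwards the cohort's mean centroid size
is restored so the aligned shapes (and everything built on them) stay in mm.
The rotational gauge freedom of GPA is removed by aligning the converged mean
to the first input shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh_core import FlatShape

__all__ = ["SimilarityTransform", "AlignedSet", "procrustes_pair", "generalised_procrustes"]


@dataclass
class SimilarityTransform:
    """x -> scale * rotation @ x + translation."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).ravel()
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-10):
            raise ValueError("rotation must be proper (det = +1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), 1.0, np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, inner: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying *inner* first, then *self*."""
        return SimilarityTransform(
            self.rotation @ inner.rotation,
            self.scale * inner.scale,
            self.scale * self.rotation @ inner.translation + self.translation,
        )


@dataclass
class AlignedSet:
    """GPA output: aligned shapes plus the per-input transforms that produced them."""

    shapes: list[FlatShape]
    transforms: list[SimilarityTransform]
    mean: FlatShape = None  # type: ignore[assignment]
    iterations_run: int = 0
    converged: bool = True
    history: list[float] = field(default_factory=list)


def procrustes_pair(
    source: np.ndarray, target: np.ndarray, with_scale: bool = True
) -> SimilarityTransform:
    """Least-squares similarity transform mapping *source* points onto *target*.

    Closed-form orthogonal-Procrustes solution: SVD of the cross-covariance of
    the centred point sets, determinant-corrected so the rotation is proper.
    Minimises ``sum_i || s R source_i + t - target_i ||^2``.
    """
    src = np.asarray(source, dtype=np.float64)
    tgt = np.asarray(target, dtype=np.float64)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be matching (k, 3) point sets")
    if len(src) < 3:
        raise ValueError("need at least 3 point pairs")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    sc, tc = src - mu_s, tgt - mu_t
    cov = tc.T @ sc / len(src)
    U, S, Vt = np.linalg.svd(cov)
    if np.linalg.matrix_rank(cov, tol=1e-12 * max(S[0], 1e-300)) < 2:
        raise ValueError("degenerate (rank < 2) point configuration")
    D = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        D[2, 2] = -1.0
    R = U @ D @ Vt
    if with_scale:
        var_s = (sc ** 2).sum() / len(src)
        s = float(np.trace(np.diag(S) @ D) / var_s)
    else:
        s = 1.0
    t = mu_t - s * R @ mu_s
    return SimilarityTransform(R, s, t)


def _centroid_size(points: np.ndarray) -> float:
    return float(np.linalg.norm(points - points.mean(axis=0)))


def generalised_procrustes(
    shapes: list[FlatShape],
    max_iter: int = 100,
    tol: float = 1e-6,
    keep_mm_scale: bool = True,
) -> AlignedSet:
    """Iteratively align a corresponded shape collection, removing similarity effects.

    Scheme: centre and unit-size-normalise every shape, take the first as the
    initial reference, then repeat (align all to current mean; recompute mean;
    renormalise mean) until the mean moves less than *tol* (AED between
    successive means, mm) or *max_iter* is hit.  With ``keep_mm_scale`` the
    cohort's mean centroid size is restored at the end so results stay in mm.
    """
    if len(shapes) < 2:
        raise ValueError("GPA needs at least 2 shapes")
    n = shapes[0].n_vertices
    if any(s.n_vertices != n for s in shapes):
        counts = sorted({s.n_vertices for s in shapes})
        raise ValueError(f"all shapes must share one vertex count, got {counts}")

    pts = [s.as_points().copy() for s in shapes]
    sizes = np.array([_centroid_size(p) for p in pts])
    if np.any(sizes <= 0):
        raise ValueError("degenerate shape with zero centroid size")
    normed = [(p - p.mean(axis=0)) / s for p, s in zip(pts, sizes)]

    mean = normed[0].copy()
    aligned = [p.copy() for p in normed]
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i, p in enumerate(normed):
            T = procrustes_pair(p, mean, with_scale=True)
            aligned[i] = T.apply(p)
        new_mean = np.mean(aligned, axis=0)
        new_mean = (new_mean - new_mean.mean(axis=0)) / _centroid_size(new_mean)
        change = float(np.linalg.norm(new_mean - mean, axis=1).mean())
        history.append(change)
        mean = new_mean
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last change {history[-1]:.3g})",
            RuntimeWarning,
        )

    # gauge fixing: orient the mean (and with it the whole set) to the first input,
    # and restore the cohort's physical scale so coordinates remain in mm
    out_scale = float(sizes.mean()) if keep_mm_scale else 1.0
    gauge = procrustes_pair(mean, normed[0], with_scale=False)
    gauge = SimilarityTransform(gauge.rotation, out_scale, np.zeros(3))

    final_shapes: list[FlatShape] = []
    transforms: list[SimilarityTransform] = []
    for i, p in enumerate(pts):
        T = procrustes_pair(p, gauge.apply(mean), with_scale=True)
        final_shapes.append(FlatShape(T.apply(p).reshape(-1)))
        transforms.append(T)
    mean_flat = FlatShape(gauge.apply(mean).reshape(-1))
    return AlignedSet(
        shapes=final_shapes,
        transforms=transforms,
        mean=mean_flat,
        iterations_run=it,
        converged=converged,
        history=history,
    )
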