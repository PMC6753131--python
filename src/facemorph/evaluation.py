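"""Intrinsic validation metrics for morphable models, plus manifold embedding.

Three standard statistical-shape-model metrics:

* **compactness** — cumulative fraction of total sample variance captured by
  the first k components; high compactness means few components describe the
  cohort.
* **generalisation** — leave-one-out reconstruction error (AED, mm): a model
  built without one face is asked to reconstruct it with k components; large
  errors mean the model cannot represent unseen faces.
* **specificity** — faces are drawn at random from the model and each is
  compared to its nearest real face (exact, exhaustive search); small values
  mean synthetic faces look like real ones.

t-SNE embedding of shape coefficients is a thin, seeded wrapper around
scikit-learn with a hyper-parameter sweep driver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .correspondence import CorrespondedSet
from .morphable_model import MorphableModel, ShapeVector, fit_pca

__all__ = [
    "MetricsReport",
    "compactness",
    "generalisation",
    "specificity",
    "tsne_embed",
    "tsne_sweep",
]


@dataclass
class MetricsReport:
    """Per-model metric curves, one row per component count in ``k_grid``."""

    k_grid: np.ndarray
    compactness: np.ndarray
    generalisation_mean: np.ndarray
    generalisation_sd: np.ndarray
    specificity_mean: float
    specificity_sd: float
    n_synth: int
    seed: int
    model_id: str = "model"
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_components": self.k_grid,
                "compactness": self.compactness,
                "generalisation_mean_mm": self.generalisation_mean,
                "generalisation_sd_mm": self.generalisation_sd,
            }
        )


def _flat_aed(a: np.ndarray, b: np.ndarray) -> float:
    """AED between two flat length-3n shape vectors."""
    return float(np.linalg.norm((a - b).reshape(-1, 3), axis=1).mean())


def compactness(model: MorphableModel) -> np.ndarray:
    """c(k) = sum_{i<=k} var_i / sum_i var_i for k = 1..d.

    Build the model full-rank if the curve should end at 1.0.
    """
    v = model.variances
    return np.cumsum(v) / v.sum()


def generalisation(
    shapes: CorrespondedSet,
    k_grid: list[int] | np.ndarray,
    eval_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Leave-one-out reconstruction error per component count.

    For every held-out shape (all of them, or the subset named by *eval_ids*),
    a model is fitted to the remainder and the held-out face is projected with
    k components; the AED between face and reconstruction is recorded.
    Returns a tidy frame with columns (n_components, scan_id, aed_mm).
    """
    if len(shapes) < 3:
        raise ValueError("generalisation needs at least 3 shapes")
    ids = shapes.scan_ids or [str(i) for i in range(len(shapes))]
    if eval_ids is None:
        eval_idx = list(range(len(shapes)))
    else:
        missing = set(eval_ids) - set(ids)
        if missing:
            raise ValueError(f"eval_ids not in the corresponded set: {sorted(missing)}")
        eval_idx = [ids.index(e) for e in eval_ids]
    X = shapes.data_matrix()
    k_grid = np.asarray(k_grid, dtype=int)
    rows = []
    for i in eval_idx:
        rest = np.delete(X, i, axis=0)
        model = fit_pca(rest, template_faces=shapes.template_faces)
        held = X[i]
        centred = held - model.mean.x
        for k in k_grid:
            kk = min(int(k), model.n_components)
            if kk < k:
                warnings.warn(
                    f"fold {ids[i]}: only {model.n_components} components available "
                    f"for requested k={k}; clipping",
                    RuntimeWarning,
                )
            U = model.basis[:, :kk]
            recon = model.mean.x + U @ (U.T @ centred)
            rows.append({"n_components": int(k), "scan_id": ids[i],
                         "aed_mm": _flat_aed(held, recon)})
    return pd.DataFrame(rows)


def generalisation_summary(folds: pd.DataFrame) -> pd.DataFrame:
    g = folds.groupby("n_components")["aed_mm"]
    return pd.DataFrame(
        {"mean_mm": g.mean(), "sd_mm": g.std(ddof=1).fillna(0.0)}
    ).reset_index()


def specificity(
    model: MorphableModel,
    real_shapes: CorrespondedSet,
    n_synth: int = 1000,
    seed: int = 0,
    truncate_sigma: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Mean +- sd of the distance from random synthetic faces to real faces.

    For each of *n_synth* randomly synthesised faces the AED to every real
    shape is computed and the minimum taken (exact exhaustive neighbour
    search).  Returns ``(mean, sd, minima)``.
    """
    if len(real_shapes) == 0:
        raise ValueError("specificity needs a non-empty real shape set")
    if real_shapes.shapes[0].n_vertices != model.n_vertices:
        raise ValueError("model and real shapes disagree on vertex count")
    real = real_shapes.data_matrix()  # (m, 3n)
    synth = model.sample_faces(n_synth, seed=seed, truncate_sigma=truncate_sigma)
    minima = np.empty(n_synth)
    for i, mesh in enumerate(synth):
        diffs = real.reshape(len(real), -1, 3) - mesh.vertices[None]
        aeds = np.linalg.norm(diffs, axis=2).mean(axis=1)
        minima[i] = aeds.min()
    sd = float(minima.std(ddof=1)) if n_synth > 1 else 0.0
    return float(minima.mean()), sd, minima


def tsne_embed(
    alphas: list[ShapeVector] | np.ndarray,
    labels: list[str],
    perplexity: float = 30.0,
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D t-SNE embedding of shape coefficients, labelled for plotting.

    Deterministic under a fixed seed.  Requires at least ``3 * perplexity``
    points for the embedding to be well posed.
    """
    A = np.stack([a.alpha for a in alphas]) if not isinstance(alphas, np.ndarray) else alphas
    if len(A) != len(labels):
        raise ValueError("one label per shape vector required")
    if len(A) < 3 * perplexity:
        raise ValueError(
            f"{len(A)} points is too few for perplexity {perplexity} (need >= {3 * perplexity:g})"
        )
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=int(n_iter),
        random_state=seed,
        init="pca",
    ).fit_transform(A)
    return pd.DataFrame({"x": emb[:, 0], "y": emb[:, 1], "label": labels})


def tsne_sweep(
    alphas: list[ShapeVector] | np.ndarray,
    labels: list[str],
    perplexities: tuple[float, ...] = (2.0, 30.0, 100.0),
    n_iters: tuple[int, ...] = (1000,),
    seed: int = 0,
) -> dict[tuple[float, int], pd.DataFrame]:
    """Hyper-parameter sweep over (perplexity, iteration-count) grids."""
    out = {}
    for p in perplexities:
        for it in n_iters:
            out[(p, it)] = tsne_embed(alphas, labels, perplexity=p, n_iter=it, seed=seed)
    return out
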