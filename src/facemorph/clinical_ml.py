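"""Diagnosis and surgery simulation in morphable-model coefficient space.

Two clinical applications operate on the shape coefficients (``alpha`` from
the model projection):

* **Diagnosis** — a linear support-vector machine separates patient from
  non-patient faces.  Performance is estimated by Monte-Carlo cross-validation:
  the cohort is split into stratified train/test partitions many times and the
  confusion matrix averaged over iterations, together with per-scan
  misclassification tallies (which scans are *repeatedly* misclassified).
* **Surgery simulation** — a multivariate linear map ("design matrix") from
  preoperative to postoperative coefficients is learnt with ordinary least
  squares (LR), ridge (RR), LASSO, or least-angle regression with a one-
  predictor budget per output (LARS).  Applying the map to a new preoperative
  projection and synthesising yields the predicted postoperative face.

Coefficients are used raw (not whitened), matching their role as coordinates
in the model subspace; whitening is available via a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from sklearn.linear_model import Lars, Lasso, LinearRegression, Ridge
from sklearn.svm import SVC

from .mesh_core import FlatShape, TriMesh, unflatten
from .morphable_model import MorphableModel

__all__ = [
    "CohortTable",
    "SplitSpec",
    "ClassifierReport",
    "RegressionReport",
    "SurgeryRegressor",
    "make_splits",
    "classify_diagnosis",
    "classification_component_sweep",
    "fit_surgery_regressor",
    "simulate_postop",
    "evaluate_regression",
]

GROUPS = ("volunteer", "preop", "postop")


@dataclass
class CohortTable:
    """Per-scan metadata: ids, group labels and preop/postop pairing."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"scan_id", "subject_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        if self.table["scan_id"].duplicated().any():
            dup = self.table.loc[self.table["scan_id"].duplicated(), "scan_id"].tolist()
            raise ValueError(f"duplicate scan_id values: {dup}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        if "pair_id" in self.table.columns:
            post = self.table[(self.table.group == "postop") & self.table.pair_id.notna()]
            pre_pairs = set(
                self.table.loc[(self.table.group == "preop") & self.table.pair_id.notna(),
                               "pair_id"]
            )
            orphans = sorted(set(post.pair_id) - pre_pairs)
            if orphans:
                raise ValueError(f"postop scans without a matching preop pair_id: {orphans}")

    def scan_ids(self, group: str | None = None) -> list[str]:
        t = self.table if group is None else self.table[self.table.group == group]
        return t["scan_id"].tolist()

    def pairs(self) -> pd.DataFrame:
        """One row per preop/postop pair: (pair_id, preop_scan, postop_scan)."""
        if "pair_id" not in self.table.columns:
            return pd.DataFrame(columns=["pair_id", "preop_scan", "postop_scan"])
        pre = self.table[(self.table.group == "preop") & self.table.pair_id.notna()]
        post = self.table[(self.table.group == "postop") & self.table.pair_id.notna()]
        merged = pre.merge(post, on="pair_id", suffixes=("_pre", "_post"))
        return pd.DataFrame(
            {
                "pair_id": merged["pair_id"],
                "preop_scan": merged["scan_id_pre"],
                "postop_scan": merged["scan_id_post"],
            }
        )


@dataclass
class SplitSpec:
    """Monte-Carlo cross-validation scheme: repeated stratified random splits."""

    train_fraction: float = 0.8
    n_iterations: int = 1000
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def train_counts(class_sizes: dict[str, int], fraction: float) -> dict[str, int]:
    """Per-class training-set sizes: round(fraction * class size)."""
    return {c: int(np.round(fraction * n)) for c, n in class_sizes.items()}


def make_splits(
    labels: np.ndarray, spec: SplitSpec
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (train_indices, test_indices) for each Monte-Carlo iteration.

    Stratified: each class contributes exactly ``round(fraction * class_size)``
    scans to training, every iteration.  Reproducible under ``spec.seed``.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to split")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members")
    n_train = train_counts(dict(zip(classes, counts)), spec.train_fraction)
    for c, n in zip(classes, counts):
        if n_train[c] in (0, n):
            raise ValueError(
                f"class {c!r}: train fraction {spec.train_fraction} leaves an empty "
                "train or test partition"
            )
    rng = np.random.default_rng(spec.seed)
    class_idx = {c: np.flatnonzero(labels == c) for c in classes}
    for _ in range(spec.n_iterations):
        train, test = [], []
        if spec.stratified:
            for c in classes:
                perm = rng.permutation(class_idx[c])
                train.append(perm[: n_train[c]])
                test.append(perm[n_train[c]:])
        else:
            perm = rng.permutation(len(labels))
            k = int(np.round(spec.train_fraction * len(labels)))
            train, test = [perm[:k]], [perm[k:]]
        yield np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


@dataclass
class ClassifierReport:
    """Average confusion matrix and derived metrics over Monte-Carlo iterations.

    Patients (preop) are the positive class.  ``misclassification`` counts, per
    scan, how often it landed on the wrong side over all iterations in which it
    was in the test partition.
    """

    tp: float
    fp: float
    fn: float
    tn: float
    n_iterations: int
    n_components: int
    misclassification: pd.DataFrame = field(default_factory=pd.DataFrame)
    skipped_iterations: int = 0

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    def summary(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
        }


def _binary_labels(cohort: CohortTable, scan_ids: list[str]) -> np.ndarray:
    groups = cohort.table.set_index("scan_id").loc[scan_ids, "group"]
    if "postop" in set(groups):
        raise ValueError("diagnosis is preop-vs-volunteer; drop postop scans first")
    return (groups == "preop").to_numpy().astype(int)


def classify_diagnosis(
    cohort: CohortTable,
    alphas: np.ndarray,
    scan_ids: list[str],
    spec: SplitSpec,
    n_components: int | None = None,
    C: float = 1.0,
    whiten: bool = False,
) -> ClassifierReport:
    """Monte-Carlo cross-validated linear-SVM diagnosis of patient vs volunteer.

    *alphas* is the (n_scans, d) coefficient matrix from one shared model, row
    order matching *scan_ids*.  Each iteration trains ``SVC(kernel='linear',
    C=C)`` on a fresh stratified split truncated to *n_components* and
    accumulates the confusion counts on the test partition.
    """
    alphas = np.asarray(alphas, dtype=np.float64)
    y = _binary_labels(cohort, scan_ids)
    k = alphas.shape[1] if n_components is None else min(n_components, alphas.shape[1])
    X = alphas[:, :k]
    if whiten:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    tp = fp = fn = tn = 0.0
    miss = np.zeros(len(scan_ids), dtype=int)
    tested = np.zeros(len(scan_ids), dtype=int)
    used = skipped = 0
    for train, test in make_splits(y, spec):
        if len(np.unique(y[train])) < 2:
            skipped += 1
            continue
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        truth = y[test]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        wrong = test[pred != truth]
        miss[wrong] += 1
        tested[test] += 1
        used += 1
    if used == 0:
        raise ValueError("all Monte-Carlo iterations were degenerate")
    mis = pd.DataFrame(
        {
            "scan_id": scan_ids,
            "group": cohort.table.set_index("scan_id").loc[scan_ids, "group"].to_numpy(),
            "times_tested": tested,
            "times_misclassified": miss,
        }
    )
    return ClassifierReport(
        tp=tp / used, fp=fp / used, fn=fn / used, tn=tn / used,
        n_iterations=used, n_components=k,
        misclassification=mis, skipped_iterations=skipped,
    )


def classification_component_sweep(
    cohort: CohortTable,
    alphas: np.ndarray,
    scan_ids: list[str],
    spec: SplitSpec,
    k_grid: list[int],
    C: float = 1.0,
) -> pd.DataFrame:
    """Accuracy (and companions) as a function of the number of components."""
    rows = []
    for k in k_grid:
        rep = classify_diagnosis(cohort, alphas, scan_ids, spec, n_components=k, C=C)
        rows.append({"n_components": rep.n_components, **rep.summary()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# surgery simulation


@dataclass
class SurgeryRegressor:
    """A learnt linear map from preoperative to postoperative coefficients."""

    method: str
    k: int
    coef: np.ndarray       # (k, k): postop = preop @ coef.T + intercept
    intercept: np.ndarray  # (k,)

    def predict(self, preop_alpha: np.ndarray) -> np.ndarray:
        a = np.asarray(preop_alpha, dtype=np.float64)
        if a.shape[-1] != self.k:
            raise ValueError(f"expected {self.k} components, got {a.shape[-1]}")
        return a @ self.coef.T + self.intercept


_METHODS = ("LR", "RR", "LASSO", "LARS")


def fit_surgery_regressor(
    method: str,
    preop_alphas: np.ndarray,
    postop_alphas: np.ndarray,
    k: int | None = None,
    hyper: dict | None = None,
) -> SurgeryRegressor:
    """Fit the design matrix mapping preop to postop coefficients.

    Methods and default penalties: LR (ordinary least squares), RR (ridge,
    alpha=0.5), LASSO (alpha=0.1), LARS (one nonzero coefficient per output
    component — each postop component is explained by its single best preop
    predictor).  Rows of the two coefficient matrices must be aligned pairs.
    """
    method = method.upper()
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    pre = np.asarray(preop_alphas, dtype=np.float64)
    post = np.asarray(postop_alphas, dtype=np.float64)
    if pre.shape != post.shape:
        raise ValueError("preop and postop coefficient matrices must be aligned")
    if len(pre) < 2:
        raise ValueError("need at least 2 preop/postop pairs")
    k = pre.shape[1] if k is None else min(k, pre.shape[1])
    pre, post = pre[:, :k], post[:, :k]
    hyper = hyper or {}
    if method == "LR":
        est = LinearRegression().fit(pre, post)
        coef, intercept = est.coef_, est.intercept_
    elif method == "RR":
        est = Ridge(alpha=hyper.get("alpha", 0.5)).fit(pre, post)
        coef, intercept = est.coef_, est.intercept_
    elif method == "LASSO":
        est = Lasso(alpha=hyper.get("alpha", 0.1), max_iter=50_000).fit(pre, post)
        coef, intercept = est.coef_, est.intercept_
    else:  # LARS, one nonzero predictor per output component
        budget = hyper.get("n_nonzero_coefs", 1)
        coef = np.zeros((k, k))
        intercept = np.zeros(k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # Lars warns when it exhausts small problems
            for j in range(k):
                est = Lars(n_nonzero_coefs=budget).fit(pre, post[:, j])
                coef[j] = est.coef_
                intercept[j] = est.intercept_
    return SurgeryRegressor(method=method, k=k, coef=np.atleast_2d(coef),
                            intercept=np.atleast_1d(intercept))


def simulate_postop(
    model: MorphableModel,
    regressor: SurgeryRegressor,
    preop: FlatShape | TriMesh,
    k: int | None = None,
) -> TriMesh:
    """Predict the postoperative face for a preoperative scan.

    Pipeline: project the preop shape onto the model, truncate to k
    components, push through the design matrix, synthesise the result.
    """
    k = regressor.k if k is None else k
    if k != regressor.k:
        raise ValueError(f"regressor was fitted with k={regressor.k}, got k={k}")
    alpha, _ = model.project(preop, n_components=k)
    pred = regressor.predict(alpha.alpha[:k])
    return model.synthesise(pred, id="simulated_postop")


@dataclass
class RegressionReport:
    """Leave-one-out surgery-simulation errors, one row per (method, k, pair)."""

    folds: pd.DataFrame
    k_grid: list[int]
    methods: list[str]

    def summary(self) -> pd.DataFrame:
        g = self.folds.groupby(["method", "n_components"])
        out = g.agg(
            mean_mm=("aed_truth_mm", "mean"),
            sd_mm=("aed_truth_mm", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
            mean_vs_global_mean_mm=("aed_mean_global_mm", "mean"),
            mean_vs_postop_mean_mm=("aed_mean_postop_mm", "mean"),
        ).reset_index()
        return out

    def best_and_worst(self, method: str, k: int) -> tuple[pd.Series, pd.Series]:
        sel = self.folds[(self.folds.method == method) & (self.folds.n_components == k)]
        if sel.empty:
            raise ValueError(f"no folds for method={method}, k={k}")
        return sel.loc[sel.aed_truth_mm.idxmin()], sel.loc[sel.aed_truth_mm.idxmax()]


def _aed_flat(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm((a - b).reshape(-1, 3), axis=1).mean())


def evaluate_regression(
    model: MorphableModel,
    preop_flats: np.ndarray,
    postop_flats: np.ndarray,
    pair_ids: list[str],
    methods: tuple[str, ...] = _METHODS,
    k_grid: tuple[int, ...] = (10,),
    hyper: dict | None = None,
) -> RegressionReport:
    """Leave-one-out evaluation of surgery simulation.

    For every held-out pair, every method and every component count k: fit the
    design matrix on the remaining pairs, predict the held-out postoperative
    face, and record the AED against (i) the ground-truth postoperative scan,
    (ii) the model's mean face, and (iii) the mean postoperative face of the
    cohort — the last two are population baselines a patient-specific
    prediction must beat.
    """
    pre = np.asarray(preop_flats, dtype=np.float64)
    post = np.asarray(postop_flats, dtype=np.float64)
    if pre.shape != post.shape or len(pre) != len(pair_ids):
        raise ValueError("preop/postop stacks and pair_ids must be aligned")
    if len(pre) < 3:
        raise ValueError("need at least 3 pairs for leave-one-out evaluation")
    d = model.n_components
    pre_a = np.stack([model.project(FlatShape(x))[0].alpha for x in pre])
    post_a = np.stack([model.project(FlatShape(x))[0].alpha for x in post])
    mean_global = model.mean.x
    mean_postop = post.mean(axis=0)
    rows = []
    for k in k_grid:
        kk = min(int(k), d)
        for method in methods:
            for i in range(len(pre)):
                rest = np.delete(np.arange(len(pre)), i)
                reg = fit_surgery_regressor(
                    method, pre_a[rest, :kk], post_a[rest, :kk], hyper=hyper
                )
                pred_alpha = reg.predict(pre_a[i, :kk])
                pred = model.mean.x + model.basis[:, :kk] @ pred_alpha
                rows.append(
                    {
                        "method": method,
                        "n_components": int(k),
                        "pair_id": pair_ids[i],
                        "aed_truth_mm": _aed_flat(pred, post[i]),
                        "aed_mean_global_mm": _aed_flat(pred, mean_global),
                        "aed_mean_postop_mm": _aed_flat(pred, mean_postop),
                    }
                )
    return RegressionReport(
        folds=pd.DataFrame(rows), k_grid=[int(k) for k in k_grid], methods=list(methods)
    )
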