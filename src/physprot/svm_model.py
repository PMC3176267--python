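"""Gaussian-kernel soft-margin SVM with cross-validated grid search.

The decision function is

    f(x) = sum_i  y_i alpha_i K(x_i, x) + b,      K(u, v) = exp(-gamma ||u - v||^2)

with the class given by the sign of f (f = 0 maps to -1).  The quadratic
program behind training is delegated to scikit-learn's libsvm backbone;
the stored model keeps the support vectors, dual coefficients y_i*alpha_i,
bias, kernel width, feature subset and scaling parameters, and is fully
self-sufficient: decision values are recomputed here from those fields
alone, never by calling back into the trainer.

Hyperparameters (C, gamma) are tuned by grid search over a log2 lattice
with stratified 5-fold cross-validation, selecting the cell with the
highest mean fold accuracy; ties prefer the smallest C (lowest model
complexity), then the smallest gamma.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .encoder import ScalingParams
from .io_formats import FeatureMatrix

#: Default search lattice (the customary libsvm-guide grid).
DEFAULT_C_GRID = tuple(2.0**p for p in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**p for p in range(-15, 4, 2))


def rbf_kernel(a: np.ndarray, b: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||a - b||^2); symmetric, in (0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    d = a - b
    return float(np.exp(-gamma * np.dot(d, d)))


@dataclass
class SvmModel:
    """A trained RBF-SVM, self-sufficient for computing decision values.

    ``dual_coef[i]`` is y_i * alpha_i for support vector i, so
    0 < |dual_coef[i]| <= C.
    """

    gamma: float
    C: float
    support_vectors: np.ndarray  # m x d
    dual_coef: np.ndarray  # length m, values y_i * alpha_i
    bias: float
    feature_ids: tuple[str, ...] = ()
    scaling: ScalingParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_coef = np.asarray(self.dual_coef, dtype=float)
        if self.support_vectors.ndim != 2:
            raise ValueError("support_vectors must be an m x d matrix")
        m = self.support_vectors.shape[0]
        if m == 0:
            raise ValueError("model must have at least one support vector")
        if self.dual_coef.shape != (m,):
            raise ValueError("dual_coef must align with support vectors")
        if np.any(self.dual_coef == 0):
            raise ValueError("stored support vectors must have alpha > 0")
        if np.any(np.abs(self.dual_coef) > self.C * (1 + 1e-9)):
            raise ValueError("alpha must satisfy 0 < alpha <= C")

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]


def train_svm(matrix: FeatureMatrix, C: float, gamma: float) -> SvmModel:
    """Solve the soft-margin RBF dual on a labeled, standardized matrix."""
    if matrix.y is None:
        raise ValueError("training requires labels")
    if len(np.unique(matrix.y)) < 2:
        raise ValueError("training requires both classes present")
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")
    clf = SVC(kernel="rbf", C=C, gamma=gamma)
    clf.fit(matrix.X, matrix.y)
    return SvmModel(
        gamma=gamma,
        C=C,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        feature_ids=tuple(matrix.feature_ids),
    )


def decision_value(model: SvmModel, x: np.ndarray) -> float:
    """f(x) = sum_i y_i alpha_i exp(-gamma ||x_i - x||^2) + b."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.support_vectors.shape[1],):
        raise ValueError(
            f"dimension mismatch: x has shape {x.shape}, model expects "
            f"({model.support_vectors.shape[1]},)"
        )
    diff = model.support_vectors - x
    k = np.exp(-model.gamma * (diff * diff).sum(axis=1))
    return float(model.dual_coef @ k + model.bias)


def predict(model: SvmModel, x: np.ndarray) -> int:
    """+1 if the decision value is strictly positive, else -1."""
    return 1 if decision_value(model, x) > 0 else -1


def decision_values(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """Vectorized decision values for an n x d matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError("X must be n x d with the model's dimension")
    sq = (
        (X * X).sum(axis=1)[:, None]
        + (model.support_vectors**2).sum(axis=1)[None, :]
        - 2.0 * X @ model.support_vectors.T
    )
    return np.exp(-model.gamma * np.maximum(sq, 0.0)) @ model.dual_coef + model.bias


def predict_matrix(model: SvmModel, X: np.ndarray) -> np.ndarray:
    f = decision_values(model, X)
    return np.where(f > 0, 1, -1)


def stratified_kfold(labels: Sequence[int], k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold assignment (length n, values 0..k-1), class-balanced.

    Per-class counts differ by at most one across folds; the shuffle is
    reproducible from the seed.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    for c in np.unique(y):
        if (y == c).sum() < k:
            raise ValueError(f"class {c} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


@dataclass(frozen=True)
class GridSearchResult:
    """All (C, gamma) cells with their CV accuracies and the chosen pair."""

    grid: tuple[tuple[float, float], ...]
    cv_accuracy: tuple[float, ...]  # percentages, aligned with grid
    best_C: float
    best_gamma: float
    k: int
    seed: int

    @property
    def best_accuracy(self) -> float:
        return max(self.cv_accuracy)


def grid_search_cv(
    matrix: FeatureMatrix,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    k: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Stratified k-fold CV accuracy for every (C, gamma) cell.

    Each cell's score is the mean held-out-fold accuracy (percent).  The
    best cell maximizes that score; ties prefer smaller C, then smaller
    gamma.  The fold assignment is shared across cells so scores are
    comparable.
    """
    if matrix.y is None:
        raise ValueError("grid search requires labels")
    if not len(C_grid) or not len(gamma_grid):
        raise ValueError("grids must be non-empty")
    folds = stratified_kfold(matrix.y, k=k, seed=seed)
    cells = []
    accs = []
    for C in C_grid:
        for gamma in gamma_grid:
            fold_accs = []
            for f in range(k):
                train = folds != f
                sub = FeatureMatrix(
                    sample_ids=[matrix.sample_ids[i] for i in np.flatnonzero(train)],
                    feature_ids=list(matrix.feature_ids),
                    X=matrix.X[train],
                    y=matrix.y[train],
                )
                model = train_svm(sub, C=C, gamma=gamma)
                pred = predict_matrix(model, matrix.X[~train])
                fold_accs.append(100.0 * float(np.mean(pred == matrix.y[~train])))
            cells.append((float(C), float(gamma)))
            accs.append(float(np.mean(fold_accs)))
    # best: max accuracy; ties -> smallest C, then smallest gamma
    best_i = min(
        range(len(cells)), key=lambda i: (-accs[i], cells[i][0], cells[i][1])
    )
    return GridSearchResult(
        grid=tuple(cells),
        cv_accuracy=tuple(accs),
        best_C=cells[best_i][0],
        best_gamma=cells[best_i][1],
        k=k,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# JSON persistence


def save_model(model: SvmModel, path: str | Path) -> None:
    """Serialize a model to JSON; floats keep full round-trip precision."""
    payload = {
        "format": "physprot-svm-model",
        "version": 1,
        "gamma": model.gamma,
        "C": model.C,
        "bias": model.bias,
        "dual_coef": model.dual_coef.tolist(),
        "support_vectors": model.support_vectors.tolist(),
        "feature_ids": list(model.feature_ids),
        "scaling": None
        if model.scaling is None
        else {
            "feature_ids": list(model.scaling.feature_ids),
            "center": model.scaling.center.tolist(),
            "scale": model.scaling.scale.tolist(),
        },
        "meta": model.meta,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def load_model(path: str | Path) -> SvmModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "physprot-svm-model":
        raise ValueError(f"{path}: not a model file")
    scaling = None
    if payload["scaling"] is not None:
        s = payload["scaling"]
        scaling = ScalingParams(
            feature_ids=tuple(s["feature_ids"]),
            center=np.array(s["center"]),
            scale=np.array(s["scale"]),
        )
    return SvmModel(
        gamma=payload["gamma"],
        C=payload["C"],
        support_vectors=np.array(payload["support_vectors"]),
        dual_coef=np.array(payload["dual_coef"]),
        bias=payload["bias"],
        feature_ids=tuple(payload["feature_ids"]),
        scaling=scaling,
        meta=payload.get("meta", {}),
    )
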