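"""End-to-end workflow: encode -> standardize -> select -> tune -> train -> test.

`run_train` executes the training protocol: encode the sequences under the
property tables, z-score the features on the training data, rank features
with the chosen filter method on the full training set (the subset is then
frozen), grid-search (C, gamma) with stratified k-fold CV on the selected
subset, and refit on all training data at the best cell.  `run_predict`
applies a stored model to new sequences; `run_experiment_table` repeats
train+test across selector methods and subset sizes, mirroring the usual
"performance by feature subset" result tables.

A `--nested` style re-selection inside each CV fold (honest error
estimates) is available via ``nested=True``; the default keeps selection
outside CV, matching the simpler protocol the selector+SVM literature
commonly reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import __version__
from .encoder import apply_standardizer, encode_dataset, fit_standardizer
from .evalmetrics import confusion, evaluate, metrics
from .featselect import (
    FeatureRanking,
    infogain_scores,
    mrmr_order,
    relieff_weights,
    top_k,
)
from .io_formats import FeatureMatrix, PropertyTable, SequenceRecord
from .svm_model import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    GridSearchResult,
    SvmModel,
    decision_values,
    grid_search_cv,
    predict_matrix,
    train_svm,
)

SELECTORS = ("relieff", "infogain", "mrmr")


@dataclass(frozen=True)
class PipelineConfig:
    """One canonical record of a training run."""

    selector: str = "relieff"
    n_features: int | None = 100  # None = all features
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    k_folds: int = 5
    seed: int = 0
    standardize: bool = True
    nested: bool = False  # re-run selection inside each CV fold
    relieff_k: int = 10

    def __post_init__(self) -> None:
        if self.selector not in SELECTORS:
            raise ValueError(
                f"selector must be one of {SELECTORS}, got {self.selector!r}"
            )
        if self.n_features is not None and self.n_features < 1:
            raise ValueError("n_features must be >= 1 or None")

    def digest(self) -> str:
        blob = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v
             for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def rank_features(matrix: FeatureMatrix, config: PipelineConfig) -> FeatureRanking:
    """Rank all features of a labeled matrix with the configured method."""
    if config.selector == "relieff":
        return relieff_weights(matrix, k_neighbors=config.relieff_k,
                               seed=config.seed)
    if config.selector == "infogain":
        return infogain_scores(matrix)
    n = matrix.n_features if config.n_features is None else config.n_features
    return mrmr_order(matrix, n_select=min(n, matrix.n_features))


def _nested_grid_search(
    work: FeatureMatrix, config: PipelineConfig, k_features: int
) -> GridSearchResult:
    """Grid search with feature selection re-run inside every CV fold.

    The ranking is recomputed on each fold's training part, so held-out
    accuracies are not contaminated by selection; costs one extra ranking
    per fold.  The best (C, gamma) is then used for the final refit on the
    externally selected subset.
    """
    from .svm_model import stratified_kfold

    folds = stratified_kfold(work.y, k=config.k_folds, seed=config.seed)
    fold_subs = []
    for f in range(config.k_folds):
        train_idx = np.flatnonzero(folds != f)
        test_idx = np.flatnonzero(folds == f)
        fold_train = FeatureMatrix(
            sample_ids=[work.sample_ids[i] for i in train_idx],
            feature_ids=list(work.feature_ids),
            X=work.X[train_idx], y=work.y[train_idx],
        )
        ranking = rank_features(fold_train, config)
        feats = top_k(ranking, min(k_features, work.n_features))
        fold_subs.append((fold_train.subset_features(feats), test_idx, feats))
    cells, accs = [], []
    for C in config.C_grid:
        for gamma in config.gamma_grid:
            fold_accs = []
            for fold_train_sub, test_idx, feats in fold_subs:
                model = train_svm(fold_train_sub, C=C, gamma=gamma)
                X_te = work.subset_features(feats).X[test_idx]
                pred = predict_matrix(model, X_te)
                fold_accs.append(100.0 * float(np.mean(pred == work.y[test_idx])))
            cells.append((float(C), float(gamma)))
            accs.append(float(np.mean(fold_accs)))
    best_i = min(range(len(cells)),
                 key=lambda i: (-accs[i], cells[i][0], cells[i][1]))
    return GridSearchResult(
        grid=tuple(cells), cv_accuracy=tuple(accs),
        best_C=cells[best_i][0], best_gamma=cells[best_i][1],
        k=config.k_folds, seed=config.seed,
    )


@dataclass
class TrainResult:
    model: SvmModel
    grid: GridSearchResult
    ranking: FeatureRanking
    selected: list[str]
    cv_report: dict
    config: PipelineConfig


def run_train(matrix: FeatureMatrix, config: PipelineConfig) -> TrainResult:
    """Full training protocol on a labeled feature matrix.

    Returns the refit model (carrying its scaling parameters and frozen
    feature subset), the grid-search surface, the feature ranking, and a
    CV report at the chosen (C, gamma).
    """
    if matrix.y is None:
        raise ValueError("training requires a labeled matrix")
    if config.standardize:
        scaling = fit_standardizer(matrix)
        work = apply_standardizer(matrix, scaling)
    else:
        scaling = None
        work = matrix

    ranking = rank_features(work, config)
    k = (
        min(config.n_features, work.n_features)
        if config.n_features is not None
        else work.n_features
    )
    selected = top_k(ranking, k)
    sub = work.subset_features(selected)

    if config.nested:
        grid = _nested_grid_search(work, config, k)
    else:
        grid = grid_search_cv(
            sub, C_grid=config.C_grid, gamma_grid=config.gamma_grid,
            k=config.k_folds, seed=config.seed,
        )
    model = train_svm(sub, C=grid.best_C, gamma=grid.best_gamma)
    model.scaling = scaling
    model.meta = {
        "selector": config.selector,
        "n_features": k,
        "seed": config.seed,
        "config_digest": config.digest(),
        "cv_accuracy": grid.best_accuracy,
        "package_version": __version__,
    }
    train_pred = predict_matrix(model, sub.X)
    cv_report = metrics(confusion(sub.y, train_pred)).as_dict()
    cv_report["cv_accuracy"] = grid.best_accuracy
    return TrainResult(
        model=model, grid=grid, ranking=ranking, selected=selected,
        cv_report=cv_report, config=config,
    )


def _prepare_features(model: SvmModel, matrix: FeatureMatrix) -> np.ndarray:
    """Standardize with the model's stored params and subset its features."""
    if model.scaling is not None:
        missing = [f for f in model.scaling.feature_ids
                   if f not in matrix.feature_ids]
        if missing:
            raise KeyError(f"matrix lacks features the model expects: {missing}")
        full = matrix.subset_features(list(model.scaling.feature_ids))
        full = apply_standardizer(full, model.scaling)
        return full.subset_features(list(model.feature_ids)).X
    return matrix.subset_features(list(model.feature_ids)).X


def run_predict(
    model: SvmModel,
    records: Sequence[SequenceRecord],
    tables: Sequence[PropertyTable],
    labels: Sequence[int] | None = None,
) -> dict:
    """Apply a stored model to sequences; evaluate when labels are given.

    Returns {"predictions": [(id, decision_value, label), ...]} plus an
    "evaluation" entry when true labels are supplied.
    """
    accessions = {t.accession for t in tables}
    needed = (
        model.scaling.feature_ids if model.scaling is not None
        else model.feature_ids
    )
    missing = [f for f in needed if f not in accessions]
    if missing:
        raise KeyError(
            f"property file lacks accessions the model expects: {missing}"
        )
    table_by_acc = {t.accession: t for t in tables}
    used = [table_by_acc[f] for f in needed]
    matrix = encode_dataset(records, used)
    X = _prepare_features(model, matrix)
    f = decision_values(model, X)
    pred = np.where(f > 0, 1, -1)
    out = {
        "predictions": [
            (rec.id, float(fv), int(p))
            for rec, fv, p in zip(records, f, pred)
        ]
    }
    if labels is not None:
        out["evaluation"] = evaluate(np.asarray(labels), pred, f)
    return out


def run_experiment_table(
    train: FeatureMatrix,
    test: FeatureMatrix,
    subset_sizes: Sequence[int],
    config: PipelineConfig,
    selectors: Sequence[str] = SELECTORS,
) -> list[dict]:
    """Train+test for each selector and subset size.

    Each row carries (method, n_features, sensitivity, specificity, MCC,
    test accuracy, CV accuracy), the columns of the familiar
    feature-subset performance tables; a size equal to the full feature
    count is reported as "all".
    """
    from dataclasses import replace

    rows = []
    for method in selectors:
        for size in subset_sizes:
            if size > train.n_features:
                raise ValueError(
                    f"subset size {size} exceeds d={train.n_features}"
                )
            cfg = replace(config, selector=method, n_features=size)
            result = run_train(train, cfg)
            X_test = _prepare_features(result.model, test)
            f = decision_values(result.model, X_test)
            pred = np.where(f > 0, 1, -1)
            rep = metrics(confusion(test.y, pred))
            rows.append({
                "method": method,
                "n_features": size,
                "subset": "all" if size == train.n_features else str(size),
                "sensitivity": round(rep.sensitivity, 2),
                "specificity": round(rep.specificity, 2),
                "mcc": round(rep.mcc, 4),
                "test_accuracy": round(rep.accuracy, 2),
                "cv_accuracy": round(result.grid.best_accuracy, 2),
            })
    return rows


def experiment_table_tsv(rows: list[dict]) -> str:
    """Serialize experiment rows as a TSV table."""
    cols = ["method", "subset", "sensitivity", "specificity", "mcc",
            "test_accuracy", "cv_accuracy"]
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in cols))
    return "\n".join(lines) + "\n"
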