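"""Filter feature selection: ReliefF, information gain, and mRMR.

Three classifier-independent rankings of the physicochemical features:

* **ReliefF** — instance-based weighting: each sample's feature values are
  compared against its k nearest hits (same class) and k nearest misses
  (other class); features whose values separate the classes locally gain
  weight, features that vary within a class lose it.
* **Information gain** — H(class) - H(class | feature) in bits, after
  discretizing each continuous feature with the Fayyad-Irani MDL recursive
  binary-split method; a feature the MDL criterion refuses to split at all
  scores 0.
* **mRMR** — greedy forward selection maximizing mutual information with
  the class while penalizing the average mutual information with already
  selected features (the MID "difference" criterion of Peng et al.), on
  features discretized into 3 states at mean +/- one standard deviation.

Scores are sorted descending with ties broken by ascending original feature
index; for mRMR the order is the greedy selection order itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import FeatureMatrix


@dataclass(frozen=True)
class FeatureRanking:
    """An ordered list of feature ids with scores and the params used."""

    method: str
    feature_ids: tuple[str, ...]
    scores: tuple[float, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.scores):
            raise ValueError("feature_ids and scores must align")
        if not all(math.isfinite(s) for s in self.scores):
            raise ValueError("scores must be finite")


def _check_two_classes(matrix: FeatureMatrix) -> None:
    if matrix.y is None:
        raise ValueError("feature selection requires a labeled matrix")
    if len(np.unique(matrix.y)) < 2:
        raise ValueError("feature selection requires both classes present")


def _ranked(method: str, matrix: FeatureMatrix, scores: np.ndarray,
            params: dict) -> FeatureRanking:
    """Order features by descending score, ties by ascending input index."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    return FeatureRanking(
        method=method,
        feature_ids=tuple(matrix.feature_ids[j] for j in order),
        scores=tuple(float(scores[j]) for j in order),
        params=params,
    )


# ---------------------------------------------------------------------------
# ReliefF


def relieff_weights(
    matrix: FeatureMatrix, k_neighbors: int = 10, n_samplings: int | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """ReliefF weights for continuous features on a two-class matrix.

    With ``n_samplings=None`` (the default) every instance is used exactly
    once in a fixed order, so the result is deterministic and invariant to
    row order; a smaller ``n_samplings`` subsamples instances with the given
    seed.  Per-feature differences are normalized by the feature's observed
    range, and nearest neighbors are found under the Manhattan distance on
    those normalized differences.  Miss contributions carry the standard
    class-prior weighting P(miss class) / (1 - P(class of the sample)),
    which is identically 1 for two classes with priors estimated from the
    data.
    """
    _check_two_classes(matrix)
    X, y = matrix.X, matrix.y
    n, d = X.shape
    class_sizes = {c: int((y == c).sum()) for c in np.unique(y)}
    smallest = min(class_sizes.values())
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k_neighbors >= smallest:
        raise ValueError(
            f"k_neighbors={k_neighbors} must be smaller than the smallest "
            f"class ({smallest} samples)"
        )
    rng = np.random.default_rng(seed)
    if n_samplings is None or n_samplings >= n:
        sampled = np.arange(n)
    else:
        sampled = rng.choice(n, size=n_samplings, replace=False)
    m = len(sampled)

    ranges = X.max(axis=0) - X.min(axis=0)
    inv_range = np.where(ranges > 0, 1.0 / np.where(ranges > 0, ranges, 1.0), 0.0)
    Xs = X * inv_range  # constant features collapse to 0 => diff 0 everywhere
    D = cdist(Xs, Xs, metric="cityblock")

    priors = {c: class_sizes[c] / n for c in class_sizes}
    W = np.zeros(d)
    for i in sampled:
        same = y == y[i]
        for is_hit in (True, False):
            cand = np.flatnonzero(same if is_hit else ~same)
            cand = cand[cand != i]
            # stable sort => distance ties broken by ascending row index
            nearest = cand[np.argsort(D[i, cand], kind="stable")[:k_neighbors]]
            diffs = np.abs(Xs[nearest] - Xs[i]).sum(axis=0)
            if is_hit:
                W -= diffs / (m * k_neighbors)
            else:
                miss_class = y[nearest[0]]
                w_prior = priors[miss_class] / (1.0 - priors[y[i]])
                W += w_prior * diffs / (m * k_neighbors)
    return _ranked(
        "relieff", matrix, W,
        {"k_neighbors": k_neighbors, "n_samplings": m, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Information gain with Fayyad-Irani MDL discretization


def _entropy(y: np.ndarray) -> float:
    """Shannon entropy of a label vector, in bits."""
    if len(y) == 0:
        return 0.0
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _mdl_cuts(x: np.ndarray, y: np.ndarray) -> list[float]:
    """Accepted cut points of the Fayyad-Irani recursive MDL partition."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    def recurse(lo: int, hi: int) -> list[float]:
        n = hi - lo
        if n < 2:
            return []
        xv, yv = xs[lo:hi], ys[lo:hi]
        ent_s = _entropy(yv)
        if ent_s == 0.0:
            return []
        best_gain, best_cut, best_split = -1.0, None, None
        for i in range(1, n):
            if xv[i] == xv[i - 1]:
                continue
            left, right = yv[:i], yv[i:]
            cond = (i * _entropy(left) + (n - i) * _entropy(right)) / n
            gain = ent_s - cond
            if gain > best_gain + 1e-12:
                best_gain = gain
                best_cut = (xv[i - 1] + xv[i]) / 2.0
                best_split = i
        if best_cut is None:
            return []
        left, right = yv[:best_split], yv[best_split:]
        k = len(np.unique(yv))
        k1, k2 = len(np.unique(left)), len(np.unique(right))
        delta = math.log2(3**k - 2) - (
            k * ent_s - k1 * _entropy(left) - k2 * _entropy(right)
        )
        threshold = (math.log2(n - 1) + delta) / n
        if best_gain <= threshold:
            return []
        mid = lo + best_split
        return recurse(lo, mid) + [float(best_cut)] + recurse(mid, hi)

    return recurse(0, len(xs))


def infogain_scores(matrix: FeatureMatrix) -> FeatureRanking:
    """Information gain of each feature after MDL discretization.

    score(f) = H(class) - H(class | bins of f), in bits; 0 when the MDL
    criterion accepts no cut for the feature.
    """
    _check_two_classes(matrix)
    X, y = matrix.X, matrix.y
    h_y = _entropy(y)
    scores = np.zeros(matrix.n_features)
    for j in range(matrix.n_features):
        cuts = _mdl_cuts(X[:, j], y)
        if not cuts:
            continue
        bins = np.digitize(X[:, j], cuts)
        cond = 0.0
        for b in np.unique(bins):
            mask = bins == b
            cond += mask.mean() * _entropy(y[mask])
        scores[j] = h_y - cond
    return _ranked("infogain", matrix, scores, {"discretization": "mdl"})


# ---------------------------------------------------------------------------
# mRMR


def _discretize_3state(X: np.ndarray) -> np.ndarray:
    """Per-feature 3-state coding: below mean-std, within, above mean+std."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    states = np.ones_like(X, dtype=int)
    states[X < mu - sd] = 0
    states[X > mu + sd] = 2
    return states


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information of two discrete vectors, in bits."""
    n = len(a)
    mi = 0.0
    for av, ca in zip(*np.unique(a, return_counts=True)):
        mask = a == av
        for bv, cab in zip(*np.unique(b[mask], return_counts=True)):
            cb = (b == bv).sum()
            mi += (cab / n) * math.log2(n * cab / (ca * cb))
    return mi


def mrmr_order(matrix: FeatureMatrix, n_select: int) -> FeatureRanking:
    """Greedy mRMR (MID criterion) selection order.

    First pick the feature with maximal mutual information with the class;
    thereafter pick argmax [ I(f; class) - mean_{s in selected} I(f; s) ].
    Ties break toward the lower original feature index.  Scores are the
    stepwise criterion values, so they are not monotone and the order field
    is the selection order, not a sort.
    """
    _check_two_classes(matrix)
    d = matrix.n_features
    if not 1 <= n_select <= d:
        raise ValueError(f"n_select={n_select} out of range [1, {d}]")
    S = _discretize_3state(matrix.X)
    yd = (matrix.y > 0).astype(int)
    relevance = np.array(
        [mutual_information(S[:, j], yd) for j in range(d)]
    )
    selected: list[int] = []
    scores: list[float] = []
    redundancy = np.zeros(d)  # running sum of I(f; s) over selected s
    remaining = list(range(d))
    for step in range(n_select):
        if step == 0:
            crit = relevance[remaining]
        else:
            crit = relevance[remaining] - redundancy[remaining] / step
        best = remaining[int(np.argmax(crit))]  # argmax keeps first on ties
        selected.append(best)
        scores.append(float(crit[remaining.index(best)]))
        remaining.remove(best)
        if remaining:
            for j in remaining:
                redundancy[j] += mutual_information(S[:, j], S[:, best])
    return FeatureRanking(
        method="mrmr",
        feature_ids=tuple(matrix.feature_ids[j] for j in selected),
        scores=tuple(scores),
        params={"n_select": n_select, "criterion": "MID",
                "discretization": "3-state mean+/-std"},
    )


def top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """First k feature ids of a ranking."""
    if not 1 <= k <= len(ranking.feature_ids):
        raise ValueError(
            f"k={k} out of range [1, {len(ranking.feature_ids)}]"
        )
    return list(ranking.feature_ids[:k])
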