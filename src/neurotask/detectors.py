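"""Anomaly detectors: Isolation Forest, plus LOF and Elliptic-Envelope comparators.

The Isolation Forest isolates points by recursive random axis-aligned
splits: at each node an attribute is drawn uniformly and a split value
uniformly between that attribute's min and max within the node.
Anomalies sit in sparse regions and separate after few splits, so their
root-to-leaf path lengths are short.  The score of a point ``d`` against
a forest trained on sub-samples of size ``psi`` is

    A(d) = 2 ^ ( - E[l(d)] / alpha(psi) )

where ``E[l(d)]`` is the mean path length over trees and ``alpha(n)``
the average unsuccessful-search path length of a binary search tree over
``n`` points,

    alpha(n) = 2 (ln(n - 1) + euler_gamma) - 2 (n - 1) / n,   alpha(0) = alpha(1) = 0.

``A`` lies in [0, 1]: close to 1 for anomalies, close to 0 for deep
inliers, near 0.5 when the point is indistinguishable from the training
mass — 0.5 is the conventional decision threshold.

The forest here is implemented from first principles (it is the scoring
core of the package); the LOF and elliptic-envelope comparators delegate
to scikit-learn's implementations of their published definitions.

Defaults follow the mental-task protocol: 150 trees, sub-sample size
256, LOF with 35 neighbors, MCD support fraction 0.9.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2
from sklearn.covariance import MinCovDet
from sklearn.neighbors import LocalOutlierFactor

__all__ = [
    "EULER_GAMMA",
    "IsolationTree",
    "IsolationForestModel",
    "ScoreReport",
    "average_path_length",
    "build_itree",
    "build_iforest",
    "path_length",
    "anomaly_score",
    "forest_scores",
    "decide",
    "lof_scores",
    "ee_scores",
    "forest_to_json",
    "forest_from_json",
]

#: Euler-Mascheroni constant at the precision the scoring formula states.
EULER_GAMMA = 0.5772156649


def average_path_length(n: int) -> float:
    """Average unsuccessful BST search depth over ``n`` points.

    ``alpha(n) = 2 (ln(n-1) + gamma) - 2 (n-1)/n`` for ``n >= 2``; nodes
    with 0 or 1 points cannot be split, so ``alpha(0) = alpha(1) = 0``.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n <= 1:
        return 0.0
    return 2.0 * (math.log(n - 1) + EULER_GAMMA) - 2.0 * (n - 1) / n


@dataclass
class IsolationTree:
    """One randomized binary isolation tree.

    Internal nodes carry ``(split_attribute, split_value)``; external
    nodes carry the residual sample ``size``.  External sizes sum to the
    sub-sample size the tree was grown on.
    """

    split_attribute: int | None = None
    split_value: float | None = None
    left: "IsolationTree | None" = None
    right: "IsolationTree | None" = None
    size: int = 0
    height_limit: int = 0

    @property
    def is_external(self) -> bool:
        return self.split_attribute is None

    def external_sizes(self) -> list[int]:
        if self.is_external:
            return [self.size]
        return self.left.external_sizes() + self.right.external_sizes()


@dataclass
class IsolationForestModel:
    """Ensemble of isolation trees grown on without-replacement sub-samples."""

    trees: list[IsolationTree]
    psi: int
    seed: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def build_itree(X: np.ndarray, height_limit: int,
                rng: np.random.Generator, _depth: int = 0) -> IsolationTree:
    """Grow one tree; stops at the height limit, singleton or constant nodes."""
    n, d = X.shape
    node = IsolationTree(size=n, height_limit=height_limit)
    if _depth >= height_limit or n <= 1:
        return node
    # a constant attribute cannot be split: resample up to d times
    for _ in range(d):
        attr = int(rng.integers(0, d))
        lo, hi = X[:, attr].min(), X[:, attr].max()
        if hi > lo:
            break
    else:
        return node
    split = float(rng.uniform(lo, hi))
    go_left = X[:, attr] < split
    node.split_attribute = attr
    node.split_value = split
    node.left = build_itree(X[go_left], height_limit, rng, _depth + 1)
    node.right = build_itree(X[~go_left], height_limit, rng, _depth + 1)
    return node


def build_iforest(data: np.ndarray, n_trees: int = 150, psi: int = 256,
                  seed: int = 0) -> IsolationForestModel:
    """Grow ``n_trees`` trees, each on a random sub-sample of size ``psi``.

    ``psi`` is clipped to the number of rows; the height limit is
    ``ceil(log2 psi)`` — the expected depth at which most of the
    sub-sample has been isolated.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least two training rows")
    if n_trees < 1 or psi < 2:
        raise ValueError("need n_trees >= 1 and psi >= 2")
    psi = min(psi, n)
    height_limit = math.ceil(math.log2(psi))
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        idx = rng.choice(n, size=psi, replace=False)
        trees.append(build_itree(data[idx], height_limit, rng))
    return IsolationForestModel(trees, psi, seed)


def path_length(point: np.ndarray, tree: IsolationTree) -> float:
    """Edges traversed to the external node, plus the truncation adjustment.

    A point landing in an external node of size ``s`` would need on
    average ``alpha(s)`` further splits, so that term is added.
    """
    point = np.asarray(point, dtype=np.float64)
    depth = 0
    node = tree
    while not node.is_external:
        if point[node.split_attribute] < node.split_value:
            node = node.left
        else:
            node = node.right
        depth += 1
    return depth + average_path_length(node.size)


@dataclass
class ScoreReport:
    """Anomaly score in [0, 1] with its thresholded decision."""

    score: float
    decision: str  # {"anomaly", "normal", "uncertain"}


def anomaly_score(point: np.ndarray, forest: IsolationForestModel,
                  threshold: float = 0.5,
                  uncertain_band: float = 0.0) -> ScoreReport:
    """Score one point: ``A = 2^(-E[l] / alpha(psi))`` plus the decision."""
    if not forest.trees:
        raise ValueError("empty forest")
    norm = average_path_length(forest.psi)
    if norm == 0.0:
        raise ValueError("psi <= 1 gives a zero path-length normalizer")
    mean_l = float(np.mean([path_length(point, t) for t in forest.trees]))
    score = 2.0 ** (-mean_l / norm)
    return ScoreReport(score, decide(score, threshold, uncertain_band))


def forest_scores(forest: IsolationForestModel, X: np.ndarray) -> np.ndarray:
    """Anomaly scores for every row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return np.array([anomaly_score(x, forest).score for x in X])


def decide(A: float, threshold: float = 0.5,
           uncertain_band: float = 0.0) -> str:
    """Threshold rule: anomaly above, normal below, uncertain inside the band."""
    if not 0.0 <= A <= 1.0:
        raise ValueError("score must lie in [0, 1]")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if A > threshold + uncertain_band:
        return "anomaly"
    if A < threshold - uncertain_band:
        return "normal"
    return "uncertain"


def lof_scores(train: np.ndarray, test: np.ndarray,
               n_neighbors: int = 35) -> np.ndarray:
    """Local outlier factor of test points w.r.t. the training cloud.

    Values near 1 mean density comparable to the neighbors; values well
    above 1 flag local outliers.  Higher = more anomalous.
    """
    train = np.atleast_2d(train)
    if n_neighbors >= train.shape[0]:
        raise ValueError("n_neighbors must be smaller than the training size")
    clf = LocalOutlierFactor(n_neighbors=n_neighbors, novelty=True)
    clf.fit(train)
    return -clf.score_samples(np.atleast_2d(test))


def ee_scores(train: np.ndarray, test: np.ndarray,
              support_fraction: float = 0.9, seed: int = 0) -> np.ndarray:
    """Robust Mahalanobis distance to the MCD center of the training cloud.

    Data are standardized on training statistics before the MCD fit;
    Mahalanobis distance is affine-invariant, so this only conditions the
    covariance numerics (latent clouds can have variances ~1e-8).
    """
    train = np.atleast_2d(train)
    if train.shape[0] <= train.shape[1]:
        raise ValueError("need more training rows than dimensions")
    loc = train.mean(axis=0)
    scale = np.maximum(train.std(axis=0), 1e-12)
    mcd = MinCovDet(support_fraction=support_fraction, random_state=seed)
    try:
        mcd.fit((train - loc) / scale)
        d2 = mcd.mahalanobis((np.atleast_2d(test) - loc) / scale)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "degenerate scatter matrix; consider adding regularization noise "
            "to the features"
        ) from exc
    return np.sqrt(d2)


def ee_threshold(dim: int, quantile: float = 0.975) -> float:
    """Decision threshold on the robust distance: chi-square quantile rule."""
    return float(np.sqrt(chi2.ppf(quantile, df=dim)))


def _tree_to_dict(node: IsolationTree) -> dict:
    if node.is_external:
        return {"size": node.size}
    return {
        "attr": node.split_attribute,
        "value": node.split_value,
        "left": _tree_to_dict(node.left),
        "right": _tree_to_dict(node.right),
        "size": node.size,
    }


def _tree_from_dict(d: dict, height_limit: int) -> IsolationTree:
    if "attr" not in d:
        return IsolationTree(size=d["size"], height_limit=height_limit)
    return IsolationTree(
        split_attribute=d["attr"],
        split_value=d["value"],
        left=_tree_from_dict(d["left"], height_limit),
        right=_tree_from_dict(d["right"], height_limit),
        size=d["size"],
        height_limit=height_limit,
    )


def forest_to_json(forest: IsolationForestModel, path: str) -> None:
    """Serialize the forest as nested node records (human-inspectable)."""
    payload = {
        "psi": forest.psi,
        "seed": forest.seed,
        "height_limit": forest.trees[0].height_limit if forest.trees else 0,
        "trees": [_tree_to_dict(t) for t in forest.trees],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def forest_from_json(path: str) -> IsolationForestModel:
    with open(path) as fh:
        payload = json.load(fh)
    hl = payload["height_limit"]
    trees = [_tree_from_dict(t, hl) for t in payload["trees"]]
    return IsolationForestModel(trees, payload["psi"], payload["seed"])
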