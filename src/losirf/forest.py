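"""Signed iterative random forest: fitting, prediction, signed decision paths.

The forest is a bagged ensemble of feature-weighted Gini trees grown on
binarized trait labels. Iterating refits the forest with feature weights
proportional to the previous iteration's impurity importances, stabilizing the
decision paths. Every root-to-leaf path is summarized as a set of *signed*
features: a split ``X > t`` taken on the high branch contributes ``X+``, the
``X <= t`` branch contributes ``X-``; for dosage data ``X+`` means carrier (or
homozygote, for the 1.5 split) and ``X-`` no (or heterozygous-at-most)
alternate allele.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._trees import _apply_tree, _grow_tree
from .binarize import BinarizedLabels
from .io import GenotypeMatrix

__all__ = [
    "Tree",
    "Forest",
    "SignedPath",
    "fit_weighted_forest",
    "iterate_sirf",
    "predict",
    "extract_signed_paths",
    "DEFAULT_N_TREES",
    "DEFAULT_N_ITER",
]

#: full-scale defaults for the iterated fit
DEFAULT_N_TREES = 500
DEFAULT_N_ITER = 3


@dataclass
class Tree:
    """Flat node arrays of one fitted tree (leaf iff ``left == -1``)."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    count0: np.ndarray  # class-0 training count per node
    count1: np.ndarray  # class-1 training count per node
    row_leaf: np.ndarray  # training row -> leaf id, -1 if out of bag

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def leaves(self) -> np.ndarray:
        return np.flatnonzero(self.left < 0)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return _apply_tree(self.feature, self.threshold, self.left, self.right, X)


class Forest:
    """A fitted signed iterative random forest."""

    def __init__(
        self,
        trees: list[Tree],
        feature_names: list[str],
        individual_ids: list[str] | None = None,
        importances: np.ndarray | None = None,
    ):
        self.trees = trees
        self.feature_names = list(feature_names)
        self.individual_ids = individual_ids
        self.importances = importances

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean over trees of the leaf class-1 training fraction."""
        X = np.ascontiguousarray(X, dtype=np.int8)
        if X.shape[0] == 0:
            return np.zeros(0)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"X has {X.shape[1]} features, forest expects {self.n_features}"
            )
        acc = np.zeros(X.shape[0])
        for tree in self.trees:
            leaf = tree.apply(X)
            tot = tree.count0[leaf] + tree.count1[leaf]
            acc += tree.count1[leaf] / np.maximum(tot, 1)
        return acc / self.n_trees

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "count0": t.count0.tolist(),
                    "count1": t.count1.tolist(),
                }
                for t in self.trees
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Forest":
        d = json.loads(Path(path).read_text())
        trees = [
            Tree(
                feature=np.asarray(t["feature"], dtype=np.int32),
                threshold=np.asarray(t["threshold"], dtype=np.float32),
                left=np.asarray(t["left"], dtype=np.int32),
                right=np.asarray(t["right"], dtype=np.int32),
                count0=np.asarray(t["count0"], dtype=np.int64),
                count1=np.asarray(t["count1"], dtype=np.int64),
                row_leaf=np.zeros(0, dtype=np.int32),
            )
            for t in d["trees"]
        ]
        return cls(trees, d["feature_names"])


@dataclass(frozen=True)
class SignedPath:
    """One root-to-leaf decision path as a deduplicated signed-feature set."""

    tree: int
    leaf: int
    signed_features: frozenset[tuple[str, str]]  # (feature label, '+'|'-')
    count0: int
    count1: int


def _resolve_xy(
    X: GenotypeMatrix | np.ndarray,
    y: BinarizedLabels | Sequence[int] | None,
) -> tuple[np.ndarray, np.ndarray | None, list[str], list[str] | None]:
    """Align genotype rows with labels; accept plain arrays for both."""
    if isinstance(X, GenotypeMatrix):
        names = X.variant_ids
        if isinstance(y, BinarizedLabels):
            ids = [i for i in X.individual_ids if i in y.labels]
            sub = X.subset_individuals(ids)
            Xd = np.ascontiguousarray(sub.dosages, dtype=np.int8)
            yv = np.asarray([1 if y.labels[i] == "high" else 0 for i in ids], dtype=np.uint8)
            return Xd, yv, names, ids
        Xd = np.ascontiguousarray(X.dosages, dtype=np.int8)
        ids = list(X.individual_ids)
    else:
        Xd = np.ascontiguousarray(X, dtype=np.int8)
        names = [f"f{j}" for j in range(Xd.shape[1])]
        ids = None
    yv = None if y is None else np.asarray(y, dtype=np.uint8)
    return Xd, yv, names, ids


def fit_weighted_forest(
    X: GenotypeMatrix | np.ndarray,
    y: BinarizedLabels | Sequence[int],
    feature_weights: np.ndarray | None = None,
    n_trees: int = 100,
    min_node: int = 1,
    mtry: int | None = None,
    seed: int = 0,
) -> Forest:
    """Fit one feature-weighted random forest.

    Each tree is grown on a bootstrap of the labeled individuals; at every
    node, ``mtry`` (default ``ceil(sqrt(p))``) candidate features are drawn
    without replacement with probability proportional to ``feature_weights``
    and the best Gini split over thresholds {0.5, 1.5} is taken.
    """
    Xd, yv, names, ids = _resolve_xy(X, y)
    if yv is None:
        raise ValueError("labels are required for fitting")
    if len(yv) != Xd.shape[0]:
        raise ValueError("label vector does not match genotype rows")
    classes = np.unique(yv)
    if len(classes) < 2:
        raise ValueError("single-class labels: cannot fit a classifier")
    p = Xd.shape[1]
    if feature_weights is None:
        weights = np.ones(p)
    else:
        weights = np.asarray(feature_weights, dtype=np.float64)
        if weights.shape != (p,) or (weights < 0).any():
            raise ValueError("feature_weights must be a nonnegative vector of length p")
        if weights.sum() <= 0:
            raise ValueError("feature_weights sum to zero")
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p)))

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    tree_seeds = ss.generate_state(n_trees)
    n = Xd.shape[0]
    trees: list[Tree] = []
    importances = np.zeros(p)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n).astype(np.int64)
        out = _grow_tree(Xd, yv, boot, weights, mtry, min_node, np.int64(tree_seeds[t]))
        feature, threshold, left, right, count0, count1, imp_dec, row_leaf = out
        trees.append(
            Tree(
                feature=feature.copy(),
                threshold=threshold.copy(),
                left=left.copy(),
                right=right.copy(),
                count0=count0.copy(),
                count1=count1.copy(),
                row_leaf=row_leaf,
            )
        )
        importances += imp_dec
    importances /= n_trees
    return Forest(trees, names, individual_ids=ids, importances=importances)


def iterate_sirf(
    X: GenotypeMatrix | np.ndarray,
    y: BinarizedLabels | Sequence[int],
    n_iter: int = DEFAULT_N_ITER,
    n_trees: int = DEFAULT_N_TREES,
    min_node: int = 1,
    mtry: int | None = None,
    seed: int = 0,
) -> Forest:
    """Iteratively refit the forest, reweighting features by importance.

    Iteration 1 uses uniform weights; iteration t uses the normalized
    mean-decrease-in-impurity importances from iteration t-1 (negative values
    clipped to zero; if everything clips to zero the weights reset to
    uniform). Returns the final forest.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    weights: np.ndarray | None = None
    forest: Forest | None = None
    for it in range(n_iter):
        forest = fit_weighted_forest(
            X, y, feature_weights=weights, n_trees=n_trees,
            min_node=min_node, mtry=mtry, seed=seed + it,
        )
        weights = np.clip(forest.importances, 0.0, None)
        if weights.sum() <= 0:
            weights = None
    assert forest is not None
    return forest


def predict(forest: Forest, X_new: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Class-1 probability per individual (mean leaf class fraction)."""
    if isinstance(X_new, GenotypeMatrix):
        X_new = X_new.subset_variants(forest.feature_names).dosages
    return forest.predict_proba(np.asarray(X_new))


def _tree_signed_paths(tree: Tree, names: list[str], tree_index: int) -> list[SignedPath]:
    paths: list[SignedPath] = []
    # DFS carrying the signed-feature set; dedup per (feature, sign)
    stack: list[tuple[int, frozenset[tuple[str, str]]]] = [(0, frozenset())]
    while stack:
        node, signed = stack.pop()
        if tree.left[node] < 0:
            paths.append(
                SignedPath(
                    tree=tree_index,
                    leaf=int(node),
                    signed_features=signed,
                    count0=int(tree.count0[node]),
                    count1=int(tree.count1[node]),
                )
            )
            continue
        label = names[tree.feature[node]]
        stack.append((int(tree.left[node]), signed | {(label, "-")}))
        stack.append((int(tree.right[node]), signed | {(label, "+")}))
    return paths


def extract_signed_paths(forest: Forest) -> list[SignedPath]:
    """One SignedPath per leaf per tree.

    The sign is '-' for the ``<= t`` branch and '+' for the ``> t`` branch; a
    feature split on twice with the same sign is kept once, and a feature that
    appears with both signs on one path (split at 0.5 then 1.5) keeps both
    signed features.
    """
    paths: list[SignedPath] = []
    for t, tree in enumerate(forest.trees):
        paths.extend(_tree_signed_paths(tree, forest.feature_names, t))
    return paths
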