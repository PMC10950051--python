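"""Tree ensembles over the curvature-test trees: bagging and boosted
reweighting, consensus prediction, pruning, and embedded importance.

The ensemble "consensus" is the mean posterior across bagged trees; the
boosted variant combines trees by their stagewise weights (adaptive
reweighting with shrinkage).  Feature importance is the Gini risk reduction
summed over each tree's primary splits, divided by the number of trees —
markers never split on score zero.

Freshly fitted ensembles hold trees in the compiled flat form; pruning
converts them to the ``TreeNode`` object graph (both forms predict
identically).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree import (FlatTree, TreeHyper, TreeNode, grow_flat_tree,
                   predict_tree, tree_importance)
from .tree import prune as prune_tree

__all__ = ["ForestHyper", "Forest", "fit_forest", "predict", "prune_forest",
           "importance", "sens_spec"]


@dataclass
class ForestHyper:
    """The searched hyperparameters: aggregation method, number of learning
    cycles, learn rate (boosting only), minimum leaf size, maximum splits."""

    method: str = "bag"  # "bag" | "boost"
    n_cycles: int = 50
    learn_rate: float = 0.1
    min_leaf: int = 1
    max_splits: int = 20

    def __post_init__(self) -> None:
        if self.method not in ("bag", "boost"):
            raise ValueError(f"unknown aggregation method {self.method!r}")
        if self.method == "boost" and not 0.0 < self.learn_rate <= 1.0:
            raise ValueError("learn_rate must lie in (0, 1] when boosting")
        if self.n_cycles < 1 or self.min_leaf < 1 or self.max_splits < 1:
            raise ValueError("n_cycles, min_leaf, max_splits must be positive")


@dataclass
class Forest:
    trees: list  # FlatTree (fresh fit) or TreeNode (after pruning)
    hyper: ForestHyper
    n_classes: int
    n_features: int
    alphas: np.ndarray | None = None  # boosting stage weights
    priors: np.ndarray = field(default_factory=lambda: np.array([]))


def _tree_posterior(tree, X, out=None):
    if out is None:
        out = np.zeros((X.shape[0], len(tree.posterior[0])
                        if isinstance(tree, FlatTree) else len(tree.posterior)))
    if isinstance(tree, FlatTree):
        tree.predict_into(X, out)
    else:
        out += predict_tree(tree, X)
    return out


def fit_forest(X, y, hyper: ForestHyper, rng: np.random.Generator,
               n_surrogates: int = 5) -> Forest:
    """Fit an ensemble.

    Bagging draws a bootstrap sample per cycle; boosting reweights the full
    sample stagewise (SAMME-style multiplicative updates shrunk by the learn
    rate) and stops early if a stage is perfect or no better than chance.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    n = len(y)
    K = int(y.max()) + 1
    th = TreeHyper(min_leaf=hyper.min_leaf, max_splits=hyper.max_splits,
                   n_surrogates=n_surrogates)
    priors = np.bincount(y, minlength=K) / n
    trees: list[FlatTree] = []

    if hyper.method == "bag":
        for _ in range(hyper.n_cycles):
            idx = rng.integers(0, n, size=n)
            trees.append(grow_flat_tree(X[idx], y[idx], hyper=th, n_classes=K))
        return Forest(trees, hyper, K, X.shape[1], priors=priors)

    w = np.full(n, 1.0 / n)
    alphas = []
    for _ in range(hyper.n_cycles):
        tree = grow_flat_tree(X, y, sample_weight=w, hyper=th, n_classes=K)
        post = np.zeros((n, K))
        tree.predict_into(X, post)
        miss = post.argmax(axis=1) != y
        err = float(w[miss].sum() / w.sum())
        if err <= 0.0:
            trees.append(tree)
            alphas.append(1.0)
            break
        if err >= 1.0 - 1.0 / K:
            if not trees:  # keep at least one stage
                trees.append(tree)
                alphas.append(1e-6)
            break
        alpha = hyper.learn_rate * (np.log((1 - err) / err) + np.log(K - 1))
        trees.append(tree)
        alphas.append(alpha)
        w = w * np.exp(alpha * miss)
        w /= w.sum()
    return Forest(trees, hyper, K, X.shape[1], alphas=np.asarray(alphas),
                  priors=priors)


def predict(model, X) -> np.ndarray:
    """Class posteriors of a Forest or a single TreeNode.

    Bagging: mean posterior across trees.  Boosting: stagewise-weighted vote
    mapped to a probability vector (softmax of the additive class scores).
    """
    if isinstance(model, TreeNode):
        return predict_tree(model, X)
    X = np.ascontiguousarray(X, dtype=np.float64)
    n = X.shape[0]
    if model.hyper.method == "bag":
        out = np.zeros((n, model.n_classes))
        for tree in model.trees:
            _tree_posterior(tree, X, out)
        out /= len(model.trees)
        return out
    scores = np.zeros((n, model.n_classes))
    for alpha, tree in zip(model.alphas, model.trees):
        votes = _tree_posterior(tree, X, np.zeros((n, model.n_classes))).argmax(axis=1)
        scores[np.arange(n), votes] += alpha
    scores -= scores.max(axis=1, keepdims=True)
    post = np.exp(scores)
    post /= post.sum(axis=1, keepdims=True)
    return post


def prune_forest(model: Forest, X_val, y_val) -> Forest:
    """Reduced-error prune every tree of the ensemble on a validation set."""
    pruned = []
    for tree in model.trees:
        node = tree.root if isinstance(tree, FlatTree) else tree
        pruned.append(prune_tree(node, X_val, y_val))
    return Forest(pruned, model.hyper, model.n_classes, model.n_features,
                  model.alphas, model.priors)


def importance(model: Forest, p: int | None = None) -> np.ndarray:
    """Embedded importance: summed primary-split risk reduction per feature,
    averaged over trees."""
    if p is None:
        p = model.n_features
    total = np.zeros(p)
    for tree in model.trees:
        if isinstance(tree, FlatTree):
            total += tree.importance(p)
        else:
            total += tree_importance(tree, p)
    return total / len(model.trees)


def sens_spec(pred_class, true_class, positive_label=1) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP)."""
    pred = np.asarray(pred_class)
    true = np.asarray(true_class)
    pos = true == positive_label
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present in the truth")
    sens = float((pred[pos] == positive_label).mean())
    spec = float((pred[~pos] != positive_label).mean())
    return sens, spec
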