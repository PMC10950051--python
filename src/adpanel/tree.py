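"""Classification trees with curvature-test split selection and surrogate
splits for missing data.

Split-variable choice minimises the p-value of a chi-square test of
independence between the (quartile-binned) predictor and the class — the
"curvature test", which removes the selection bias toward many-valued
predictors that plain impurity search has.  The cut point on the chosen
variable is then the best Gini-gain cut.  Each split stores up to S surrogate
splits on other variables, ranked by how well they reproduce the primary
split on rows where both are observed; rows missing the primary variable are
routed by the first available surrogate, and a row missing all of them stops
where it is and takes that node's posterior.

All computations are mask-aware: missing entries are NaN and never enter a
test, a cut search, or an agreement count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TreeNode",
    "TreeHyper",
    "FlatTree",
    "curvature_test",
    "interaction_curvature_test",
    "grow_tree",
    "grow_flat_tree",
    "predict_tree",
    "prune",
    "tree_importance",
    "count_nodes",
]


@dataclass
class TreeHyper:
    """Per-tree growth limits."""

    min_leaf: int = 1
    max_splits: int = 100
    n_surrogates: int = 5


@dataclass
class TreeNode:
    posterior: np.ndarray  # class-probability vector, sums to 1
    weight: float  # fraction of root training weight reaching this node
    node_risk: float  # weight * Gini impurity
    feature: int | None = None
    threshold: float = float("nan")
    surrogates: list = field(default_factory=list)  # (feat, thr, left_if_le, agreement)
    majority_left: bool = True
    risk_reduction: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _bin_quartiles(X: np.ndarray):
    """Quartile-bin every column of X (NaN-aware).

    Returns (bins, edges): ``bins[i, j]`` in {0..3} counts how many of column
    j's quartile edges value X[i, j] exceeds (0 for NaN; consult the mask),
    ``edges`` is the (3, p) array of per-column quartile boundaries.
    Duplicate edges collapse bins naturally.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN columns
        edges = np.nanquantile(X, [0.25, 0.5, 0.75], axis=0)
    with np.errstate(invalid="ignore"):
        bins = (X[None, :, :] > edges[:, None, :]).sum(axis=0)
    return bins.astype(np.int8), edges


def _chi2_pvals(counts: np.ndarray) -> np.ndarray:
    """Vectorised Pearson chi-square p-values for (K, B, p) contingency stacks.

    Empty bins/classes reduce the degrees of freedom; a table with fewer than
    2 non-empty bins or classes is uninformative (p = 1).
    """
    col = counts.sum(axis=0)  # (B, p) bin margins
    row = counts.sum(axis=1)  # (K, p) class margins
    tot = col.sum(axis=0)  # (p,)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = row[:, None, :] * col[None, :, :] / tot
        contrib = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chi2 = contrib.sum(axis=(0, 1))
    df = ((col > 0).sum(axis=0) - 1) * ((row > 0).sum(axis=0) - 1)
    p = np.ones_like(chi2)
    ok = (df > 0) & (tot > 0)
    p[ok] = sps.chi2.sf(chi2[ok], df[ok])
    return p


def _curvature_pvals(X, y_onehot_w, obs):
    """Curvature-test p-value of every column of X against the class."""
    n, p = X.shape
    K = y_onehot_w.shape[1]
    bins, edges = _bin_quartiles(X)
    counts = np.zeros((K, 4, p))
    for b in range(4):
        in_bin = (bins == b) & obs  # (n, p)
        counts[:, b, :] = y_onehot_w.T @ in_bin
    # rescale weighted counts so each column's total equals its observed-row
    # count (keeps the chi-square statistic on the counting scale even when
    # boosting reweights the sample)
    n_obs = obs.sum(axis=0).astype(float)
    tot_w = counts.sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(tot_w > 0, n_obs / tot_w, 0.0)
    counts *= scale
    return _chi2_pvals(counts), bins, edges


def curvature_test(x: np.ndarray, y: np.ndarray, sample_weight=None) -> float:
    """Chi-square independence test between a quartile-binned predictor and
    the class, over rows where the predictor is observed.

    Constant or all-missing predictors are uninformative (p = 1).
    """
    x = np.asarray(x, dtype=np.float64).reshape(-1, 1)
    y = np.asarray(y)
    classes, yi = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
    onehot = np.zeros((len(y), len(classes)))
    onehot[np.arange(len(y)), yi] = w
    obs = ~np.isnan(x)
    if not obs.any():
        return 1.0
    pvals, _, _ = _curvature_pvals(x, onehot, obs)
    return float(pvals[0])


def interaction_curvature_test(x1, x2, y, sample_weight=None) -> float:
    """Curvature test of the *pair* (x1, x2) against the class: the joint
    quartile-bin cells of the two predictors form the contingency rows.
    Rows missing either predictor are dropped."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    y = np.asarray(y)
    classes, yi = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    ok = ~(np.isnan(x1) | np.isnan(x2))
    if not ok.any():
        return 1.0
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
    b1, _ = _bin_quartiles(x1[ok].reshape(-1, 1))
    b2, _ = _bin_quartiles(x2[ok].reshape(-1, 1))
    joint = (b1[:, 0] * 4 + b2[:, 0]).astype(int)
    K = len(classes)
    counts = np.zeros((K, 16))
    np.add.at(counts, (yi[ok], joint), w[ok])
    n_ok = int(ok.sum())
    counts *= n_ok / counts.sum()
    return float(_chi2_pvals(counts[:, :, None])[0])


def _gini(class_w: np.ndarray) -> float:
    tot = class_w.sum()
    if tot <= 0:
        return 0.0
    pr = class_w / tot
    return float(1.0 - (pr**2).sum())


def _best_gini_cut(x, y_onehot_w, min_leaf):
    """Best Gini-gain threshold on one predictor over its observed rows.

    Candidates are midpoints between consecutive distinct values; both
    children must keep at least ``min_leaf`` observed rows.  Returns
    (threshold, gain_fraction) or None; gain is expressed per unit of the
    node's observed weight.
    """
    obs = ~np.isnan(x)
    xo = x[obs]
    Yo = y_onehot_w[obs]
    n = len(xo)
    if n < 2 * min_leaf:
        return None
    order = np.argsort(xo, kind="stable")
    xs = xo[order]
    Ys = Yo[order]
    cum = np.cumsum(Ys, axis=0)
    total = cum[-1]
    tot_w = total.sum()
    if tot_w <= 0:
        return None
    # split after position i (1-based count of left rows)
    idx = np.arange(min_leaf, n - min_leaf + 1)
    if len(idx) == 0:
        return None
    distinct = xs[idx - 1] < xs[idx]  # only between distinct values
    idx = idx[distinct]
    if len(idx) == 0:
        return None
    left = cum[idx - 1]
    right = total - left
    wl = left.sum(axis=1)
    wr = right.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gini_l = 1.0 - (left**2).sum(axis=1) / wl**2
        gini_r = 1.0 - (right**2).sum(axis=1) / wr**2
    risk = (wl * gini_l + wr * gini_r) / tot_w
    parent = _gini(total)
    gains = parent - risk
    best = int(np.argmax(gains))
    if gains[best] <= 1e-12:
        return None
    i = idx[best]
    thr = 0.5 * (xs[i - 1] + xs[i])
    return float(thr), float(gains[best])


def _find_surrogates(X, obs, bins, edges, feature, go_left, n_surrogates):
    """Surrogate splits ranked by agreement with the primary split.

    Candidate cuts for each other variable are its quartile boundaries at
    this node; agreement is the matched fraction on rows where both the
    primary and the candidate are observed (direction chosen to favour
    agreement, which keeps it >= 0.5 by construction); surrogates must beat
    0.5 strictly.
    """
    n, p = X.shape
    prim_obs = obs[:, feature]
    both = obs & prim_obs[:, None]  # (n, p)
    n_both = both.sum(axis=0).astype(float)
    best_agree = np.zeros(p)
    best_cut = np.zeros(p, dtype=np.int8)
    best_dir = np.ones(p, dtype=bool)
    safe_n = np.where(n_both > 0, n_both, 1.0)
    for k in range(3):
        pred_left = bins <= k
        match = ((pred_left == go_left[:, None]) & both).sum(axis=0)
        agree = np.where(n_both > 0, match / safe_n, 0.0)
        for direction, a in ((True, agree),
                             (False, np.where(n_both > 0, 1.0 - agree, 0.0))):
            upd = a > best_agree
            best_agree = np.where(upd, a, best_agree)
            best_cut = np.where(upd, k, best_cut)
            best_dir = np.where(upd, direction, best_dir)
    best_agree[feature] = 0.0
    best_agree[n_both < 1] = 0.0
    # duplicate edges would make a cut degenerate (everything on one side);
    # such cuts still count — agreement speaks for itself
    order = np.argsort(-best_agree, kind="stable")
    out = []
    for j in order[: 4 * n_surrogates]:
        if best_agree[j] <= 0.5:
            break
        thr = float(edges[best_cut[j], j])
        if np.isnan(thr):
            continue
        out.append((int(j), thr, bool(best_dir[j]), float(best_agree[j])))
        if len(out) == n_surrogates:
            break
    return out


def _route(X, obs, node):
    """Row routing at a split node: primary, then surrogates in agreement
    order.  Returns (go_left, undecided) boolean arrays over the rows."""
    x = X[:, node.feature]
    decided = obs[:, node.feature]
    with np.errstate(invalid="ignore"):
        go_left = np.where(decided, x <= node.threshold, False)
    for j, thr, left_if_le, _ in node.surrogates:
        rem = ~decided & obs[:, j]
        if not rem.any():
            continue
        with np.errstate(invalid="ignore"):
            le = X[rem, j] <= thr
        go_left[rem] = le if left_if_le else ~le
        decided |= rem
    return go_left, ~decided


def _grow_tree_python(X, y, sample_weight=None, hyper: TreeHyper | None = None,
                      n_classes: int | None = None) -> TreeNode:
    """Reference (pure numpy) tree grower; same semantics as the compiled
    engine in ``_fast`` and used to cross-check it."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    n, p = X.shape
    if hyper is None:
        hyper = TreeHyper()
    K = n_classes or int(y.max()) + 1
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    onehot = np.zeros((n, K))
    onehot[np.arange(n), y] = w
    obs_all = ~np.isnan(X)
    root_w = w.sum()

    def make_node(rows):
        cw = onehot[rows].sum(axis=0)
        tot = cw.sum()
        post = cw / tot if tot > 0 else np.full(K, 1.0 / K)
        weight = tot / root_w
        return TreeNode(posterior=post, weight=weight, node_risk=weight * _gini(cw))

    root = TreeNode(posterior=onehot.sum(0) / root_w, weight=1.0,
                    node_risk=_gini(onehot.sum(0)))
    queue: list[tuple[TreeNode, np.ndarray]] = [(root, np.arange(n))]
    splits_used = 0

    while queue:
        node, rows = queue.pop(0)
        if splits_used >= hyper.max_splits or len(rows) < 2 * hyper.min_leaf:
            continue
        yr = y[rows]
        if (yr == yr[0]).all():
            continue
        Xr = X[rows]
        obs = obs_all[rows]
        pvals, bins, edges = _curvature_pvals(Xr, onehot[rows], obs)
        best_p = pvals.min()
        if best_p >= 1.0:
            continue
        tied = np.flatnonzero(pvals <= best_p + 1e-12)
        if len(tied) > 1:
            # refine exact ties with the pairwise interaction test
            scores = []
            for f in tied:
                partners = [g for g in tied if g != f]
                scores.append(min(
                    interaction_curvature_test(Xr[:, f], Xr[:, g], yr, w[rows])
                    for g in partners))
            feature = int(tied[int(np.argmin(scores))])
        else:
            feature = int(tied[0])
        cut = _best_gini_cut(Xr[:, feature], onehot[rows], hyper.min_leaf)
        if cut is None:
            continue
        thr, _ = cut
        node.feature = feature
        node.threshold = thr
        go_left_obs = np.zeros(len(rows), dtype=bool)
        prim = obs[:, feature]
        go_left_obs[prim] = Xr[prim, feature] <= thr
        node.surrogates = _find_surrogates(Xr, obs, bins, edges, feature,
                                           go_left_obs, hyper.n_surrogates)
        go_left, undecided = _route(Xr, obs, node)
        # training rows missing every routing variable follow the heavier child
        wl = w[rows][go_left & ~undecided].sum()
        wr = w[rows][~go_left & ~undecided].sum()
        node.majority_left = bool(wl >= wr)
        go_left[undecided] = node.majority_left
        left_rows = rows[go_left]
        right_rows = rows[~go_left]
        if len(left_rows) == 0 or len(right_rows) == 0:
            node.feature = None
            node.surrogates = []
            continue
        node.left = make_node(left_rows)
        node.right = make_node(right_rows)
        node.risk_reduction = node.node_risk - node.left.node_risk - node.right.node_risk
        splits_used += 1
        queue.append((node.left, left_rows))
        queue.append((node.right, right_rows))

    return root


@dataclass
class FlatTree:
    """Array representation of a fitted tree (the compiled engine's output).

    ``feature[i] < 0`` marks node i as a leaf; surrogate arrays are
    (nodes, S) with -1 padding.  ``root`` materialises the TreeNode graph.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    majority_left: np.ndarray
    posterior: np.ndarray
    weight: np.ndarray
    risk: np.ndarray
    risk_red: np.ndarray
    s_feat: np.ndarray
    s_thr: np.ndarray
    s_dir: np.ndarray
    s_agree: np.ndarray

    @property
    def root(self) -> TreeNode:
        def build(i: int) -> TreeNode:
            node = TreeNode(
                posterior=self.posterior[i].copy(),
                weight=float(self.weight[i]),
                node_risk=float(self.risk[i]),
            )
            if self.feature[i] >= 0:
                node.feature = int(self.feature[i])
                node.threshold = float(self.threshold[i])
                node.majority_left = bool(self.majority_left[i])
                node.risk_reduction = float(self.risk_red[i])
                node.surrogates = [
                    (int(f), float(t), bool(d), float(a))
                    for f, t, d, a in zip(self.s_feat[i], self.s_thr[i],
                                          self.s_dir[i], self.s_agree[i])
                    if f >= 0
                ]
                node.left = build(int(self.left[i]))
                node.right = build(int(self.right[i]))
            return node

        return build(0)

    def importance(self, p: int) -> np.ndarray:
        imp = np.zeros(p)
        split = self.feature >= 0
        np.add.at(imp, self.feature[split], np.clip(self.risk_red[split], 0, None))
        return imp

    def predict_into(self, X: np.ndarray, out: np.ndarray) -> None:
        from ._fast import predict_flat

        predict_flat(self.feature, self.threshold, self.left, self.right,
                     self.posterior, self.s_feat, self.s_thr, self.s_dir,
                     X, out)


def grow_flat_tree(X, y, sample_weight=None, hyper: TreeHyper | None = None,
                   n_classes: int | None = None) -> FlatTree:
    """Grow a tree with the compiled engine, returning the flat form."""
    from ._fast import grow_flat

    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if hyper is None:
        hyper = TreeHyper()
    K = n_classes or int(y.max()) + 1
    w = (np.ones(len(y)) if sample_weight is None
         else np.asarray(sample_weight, dtype=np.float64))
    arrays = grow_flat(X, y, w, K, hyper.min_leaf, hyper.max_splits,
                       hyper.n_surrogates)
    return FlatTree(*arrays)


def grow_tree(X, y, sample_weight=None, hyper: TreeHyper | None = None,
              n_classes: int | None = None, engine: str = "fast") -> TreeNode:
    """Grow a curvature-test tree (breadth-first, ``max_splits`` budget).

    ``y`` must be integer class codes 0..K-1.  Growth is deterministic for
    fixed input: the split variable is the curvature-test argmin (exact ties
    refined by the pairwise interaction test, then smallest index).  The
    compiled and reference engines implement identical semantics.
    """
    if engine == "fast":
        return grow_flat_tree(X, y, sample_weight, hyper, n_classes).root
    if engine == "python":
        return _grow_tree_python(X, y, sample_weight, hyper, n_classes)
    raise ValueError(f"unknown engine {engine!r}")


def predict_tree(tree: TreeNode, X) -> np.ndarray:
    """Class posteriors, one row per input row.

    Rows are routed through primary then surrogate splits; a row missing all
    of a node's routing variables stops there and takes that node's
    posterior (an all-missing row gets the root posterior = class priors).
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    obs = ~np.isnan(X)
    K = len(tree.posterior)
    out = np.empty((n, K))

    def descend(node, rows):
        if len(rows) == 0:
            return
        if node.is_leaf:
            out[rows] = node.posterior
            return
        go_left, undecided = _route(X[rows], obs[rows], node)
        out[rows[undecided]] = node.posterior
        keep = ~undecided
        descend(node.left, rows[keep & go_left])
        descend(node.right, rows[keep & ~go_left])

    descend(tree, np.arange(n))
    return out


def _stop_assignments(tree, X, obs):
    """For each row, the node whose posterior it takes (leaf or stop node)."""
    n = X.shape[0]
    nodes: list[TreeNode] = []
    assign = np.empty(n, dtype=np.int64)

    def descend(node, rows):
        nodes.append(node)
        my_id = len(nodes) - 1
        if len(rows) == 0 and node.is_leaf:
            return my_id
        if node.is_leaf:
            assign[rows] = my_id
            return my_id
        if len(rows):
            go_left, undecided = _route(X[rows], obs[rows], node)
            assign[rows[undecided]] = my_id
            keep = ~undecided
            lrows, rrows = rows[keep & go_left], rows[keep & ~go_left]
        else:
            lrows = rrows = rows
        descend(node.left, lrows)
        descend(node.right, rrows)
        return my_id

    descend(tree, np.arange(n))
    return nodes, assign


def prune(tree: TreeNode, X_val, y_val) -> TreeNode:
    """Reduced-error pruning against a validation set.

    Bottom-up, every internal subtree whose collapse does not increase the
    validation misclassification count becomes a leaf (its surrogates are
    dropped with it).  The pruned tree's validation risk never exceeds the
    unpruned tree's.
    """
    import copy

    X_val = np.asarray(X_val, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.int64)
    tree = copy.deepcopy(tree)
    obs = ~np.isnan(X_val)

    def errors_here(node, rows):
        if len(rows) == 0:
            return 0
        pred = int(np.argmax(node.posterior))
        return int((y_val[rows] != pred).sum())

    def descend(node, rows):
        if node.is_leaf:
            return errors_here(node, rows)
        if len(rows):
            go_left, undecided = _route(X_val[rows], obs[rows], node)
            stop_err = errors_here(node, rows[undecided])
            keep = ~undecided
            lrows, rrows = rows[keep & go_left], rows[keep & ~go_left]
        else:
            stop_err = 0
            lrows = rrows = rows
        sub_err = stop_err + descend(node.left, lrows) + descend(node.right, rrows)
        leaf_err = errors_here(node, rows)
        if leaf_err <= sub_err:
            node.feature = None
            node.surrogates = []
            node.left = node.right = None
            return leaf_err
        return sub_err

    descend(tree, np.arange(len(y_val)))
    return tree


def tree_importance(tree: TreeNode, p: int) -> np.ndarray:
    """Per-feature sum of Gini risk reduction over the tree's primary splits."""
    imp = np.zeros(p)

    def walk(node):
        if node.is_leaf:
            return
        imp[node.feature] += max(node.risk_reduction, 0.0)
        walk(node.left)
        walk(node.right)

    walk(tree)
    return imp


def count_nodes(tree: TreeNode) -> int:
    if tree.is_leaf:
        return 1
    return 1 + count_nodes(tree.left) + count_nodes(tree.right)
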