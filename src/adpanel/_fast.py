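"""Compiled (numba) core for tree growing and prediction.

Semantics mirror the reference engine in ``tree.py`` exactly: curvature-test
split-variable selection on quartile-binned predictors (pairwise interaction
test refining exact ties), best Gini-gain cut on the chosen variable,
surrogate splits ranked by agreement on jointly observed rows, breadth-first
growth under a total-splits budget, and stop-at-node routing for rows missing
every routing variable.  Trees are stored as flat arrays; ``tree.py``
converts them to the ``TreeNode`` object graph on demand.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_NJIT = dict(cache=True, fastmath=False)


@njit(**_NJIT)
def _gammap_series(a, x):
    ap = a
    summ = 1.0 / a
    delta = summ
    for _ in range(500):
        ap += 1.0
        delta *= x / ap
        summ += delta
        if abs(delta) < abs(summ) * 1e-14:
            break
    return summ * math.exp(-x + a * math.log(x) - math.lgamma(a))


@njit(**_NJIT)
def _gammaq_contfrac(a, x):
    tiny = 1e-300
    b = x + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, 500):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-14:
            break
    return math.exp(-x + a * math.log(x) - math.lgamma(a)) * h


@njit(**_NJIT)
def chi2_sf(x, df):
    """Upper-tail probability of the chi-square distribution."""
    if x <= 0.0:
        return 1.0
    a = 0.5 * df
    h = 0.5 * x
    if h < a + 1.0:
        return 1.0 - _gammap_series(a, h)
    return _gammaq_contfrac(a, h)


@njit(**_NJIT)
def _quartile_edges(vals):
    """Linear-interpolation quartiles of a sorted array (np.quantile style)."""
    m = len(vals)
    edges = np.empty(3)
    for k in range(3):
        q = 0.25 * (k + 1)
        pos = q * (m - 1)
        lo = int(math.floor(pos))
        hi = int(math.ceil(pos))
        frac = pos - lo
        edges[k] = vals[lo] * (1.0 - frac) + vals[hi] * frac
    return edges


@njit(**_NJIT)
def _chi2_table_pval(counts, K, B):
    """Pearson chi-square p for a K x B weighted table (df from non-empty
    rows/cols)."""
    tot = 0.0
    for c in range(K):
        for b in range(B):
            tot += counts[c, b]
    if tot <= 0.0:
        return 1.0
    rowm = np.zeros(K)
    colm = np.zeros(B)
    for c in range(K):
        for b in range(B):
            rowm[c] += counts[c, b]
            colm[b] += counts[c, b]
    nzr = 0
    for c in range(K):
        if rowm[c] > 0:
            nzr += 1
    nzc = 0
    for b in range(B):
        if colm[b] > 0:
            nzc += 1
    df = (nzr - 1) * (nzc - 1)
    if df <= 0:
        return 1.0
    chi2 = 0.0
    for c in range(K):
        for b in range(B):
            e = rowm[c] * colm[b] / tot
            if e > 0:
                diff = counts[c, b] - e
                chi2 += diff * diff / e
    return chi2_sf(chi2, df)


@njit(**_NJIT)
def _curvature_pval_col(x, y, w, rows, K, edges_out):
    """Curvature p-value of one column over the row segment; also returns the
    quartile edges (NaN-filled when the column has no observed rows)."""
    m = 0
    for idx in rows:
        if not np.isnan(x[idx]):
            m += 1
    for k in range(3):
        edges_out[k] = np.nan
    if m < 1:
        return 1.0
    vals = np.empty(m)
    j = 0
    for idx in rows:
        v = x[idx]
        if not np.isnan(v):
            vals[j] = v
            j += 1
    vals.sort()
    edges = _quartile_edges(vals)
    for k in range(3):
        edges_out[k] = edges[k]
    counts = np.zeros((K, 4))
    totw = 0.0
    for idx in rows:
        v = x[idx]
        if np.isnan(v):
            continue
        b = 0
        for k in range(3):
            if v > edges[k]:
                b += 1
        counts[y[idx], b] += w[idx]
        totw += w[idx]
    if totw <= 0.0:
        return 1.0
    scale = m / totw
    for c in range(K):
        for b in range(4):
            counts[c, b] *= scale
    return _chi2_table_pval(counts, K, 4)


@njit(**_NJIT)
def _interaction_pval(x1, x2, y, w, rows, K):
    """Joint-bin curvature test of a predictor pair (rows missing either
    predictor dropped)."""
    m = 0
    for idx in rows:
        if not (np.isnan(x1[idx]) or np.isnan(x2[idx])):
            m += 1
    if m < 1:
        return 1.0
    v1 = np.empty(m)
    v2 = np.empty(m)
    j = 0
    for idx in rows:
        if not (np.isnan(x1[idx]) or np.isnan(x2[idx])):
            v1[j] = x1[idx]
            v2[j] = x2[idx]
            j += 1
    s1 = np.sort(v1.copy())
    s2 = np.sort(v2.copy())
    e1 = _quartile_edges(s1)
    e2 = _quartile_edges(s2)
    counts = np.zeros((K, 16))
    totw = 0.0
    for idx in rows:
        a = x1[idx]
        b = x2[idx]
        if np.isnan(a) or np.isnan(b):
            continue
        b1 = 0
        b2 = 0
        for k in range(3):
            if a > e1[k]:
                b1 += 1
            if b > e2[k]:
                b2 += 1
        counts[y[idx], b1 * 4 + b2] += w[idx]
        totw += w[idx]
    scale = m / totw
    for c in range(K):
        for cell in range(16):
            counts[c, cell] *= scale
    return _chi2_table_pval(counts, K, 16)


@njit(**_NJIT)
def _best_gini_cut_col(x, y, w, rows, K, min_leaf):
    """Best Gini-gain threshold on one column (midpoints between distinct
    observed values; both children keep >= min_leaf observed rows).

    Returns (threshold, gain); gain <= 0 means no admissible cut."""
    m = 0
    for idx in rows:
        if not np.isnan(x[idx]):
            m += 1
    if m < 2 * min_leaf:
        return np.nan, -1.0
    vals = np.empty(m)
    cw = np.empty((m, K))
    j = 0
    for idx in rows:
        v = x[idx]
        if np.isnan(v):
            continue
        vals[j] = v
        for c in range(K):
            cw[j, c] = 0.0
        cw[j, y[idx]] = w[idx]
        j += 1
    order = np.argsort(vals, kind="mergesort")
    total = np.zeros(K)
    for i in range(m):
        for c in range(K):
            total[c] += cw[i, c]
    tot_w = 0.0
    for c in range(K):
        tot_w += total[c]
    if tot_w <= 0.0:
        return np.nan, -1.0
    sq = 0.0
    for c in range(K):
        sq += total[c] * total[c]
    parent_gini = 1.0 - sq / (tot_w * tot_w)
    left = np.zeros(K)
    best_gain = 1e-12
    best_thr = np.nan
    wl = 0.0
    for i in range(m - 1):
        oi = order[i]
        for c in range(K):
            left[c] += cw[oi, c]
            wl += cw[oi, c]
        nleft = i + 1
        if nleft < min_leaf or (m - nleft) < min_leaf:
            continue
        if vals[order[i]] >= vals[order[i + 1]]:
            continue
        wr = tot_w - wl
        if wl <= 0.0 or wr <= 0.0:
            continue
        sl = 0.0
        sr = 0.0
        for c in range(K):
            sl += left[c] * left[c]
            r = total[c] - left[c]
            sr += r * r
        gini_l = 1.0 - sl / (wl * wl)
        gini_r = 1.0 - sr / (wr * wr)
        gain = parent_gini - (wl * gini_l + wr * gini_r) / tot_w
        if gain > best_gain:
            best_gain = gain
            best_thr = 0.5 * (vals[order[i]] + vals[order[i + 1]])
    if np.isnan(best_thr):
        return np.nan, -1.0
    return best_thr, best_gain


@njit(**_NJIT)
def grow_flat(X, y, w, K, min_leaf, max_splits, n_surr):
    """Grow one curvature-test tree; returns the flat array representation.

    Arrays (length = number of nodes): feature (-1 = leaf), threshold,
    left/right child ids, majority_left flag, posterior (K wide), weight
    fraction, node risk, risk reduction; surrogate arrays are (nodes, S).
    """
    n, p = X.shape
    max_nodes = 2 * max_splits + 1
    feature = np.full(max_nodes, -1, dtype=np.int64)
    threshold = np.full(max_nodes, np.nan)
    left = np.full(max_nodes, -1, dtype=np.int64)
    right = np.full(max_nodes, -1, dtype=np.int64)
    majority_left = np.ones(max_nodes, dtype=np.bool_)
    posterior = np.zeros((max_nodes, K))
    weight = np.zeros(max_nodes)
    risk = np.zeros(max_nodes)
    risk_red = np.zeros(max_nodes)
    s_feat = np.full((max_nodes, n_surr), -1, dtype=np.int64)
    s_thr = np.full((max_nodes, n_surr), np.nan)
    s_dir = np.ones((max_nodes, n_surr), dtype=np.bool_)
    s_agree = np.zeros((max_nodes, n_surr))

    rows = np.arange(n)
    q_node = np.zeros(max_nodes, dtype=np.int64)
    q_lo = np.zeros(max_nodes, dtype=np.int64)
    q_hi = np.zeros(max_nodes, dtype=np.int64)

    root_w = 0.0
    for i in range(n):
        root_w += w[i]

    def node_stats(lo, hi):
        cw = np.zeros(K)
        for t in range(lo, hi):
            cw[y[rows[t]]] += w[rows[t]]
        tot = 0.0
        for c in range(K):
            tot += cw[c]
        return cw, tot

    cw0 = np.zeros(K)
    for i in range(n):
        cw0[y[i]] += w[i]
    sq = 0.0
    for c in range(K):
        posterior[0, c] = cw0[c] / root_w
        sq += cw0[c] * cw0[c]
    weight[0] = 1.0
    risk[0] = 1.0 - sq / (root_w * root_w)

    q_node[0] = 0
    q_lo[0] = 0
    q_hi[0] = n
    qh = 0
    qt = 1
    n_nodes = 1
    splits = 0
    edges_buf = np.empty(3)

    while qh < qt:
        node = q_node[qh]
        lo = q_lo[qh]
        hi = q_hi[qh]
        qh += 1
        m_rows = hi - lo
        if splits >= max_splits or m_rows < 2 * min_leaf:
            continue
        seg = rows[lo:hi]
        first = y[seg[0]]
        pure = True
        for t in range(m_rows):
            if y[seg[t]] != first:
                pure = False
                break
        if pure:
            continue
        # --- split-variable selection (p-values and edges kept for reuse)
        pvals = np.empty(p)
        edges_all = np.empty((3, p))
        for j in range(p):
            pvals[j] = _curvature_pval_col(X[:, j], y, w, seg, K, edges_buf)
            for k in range(3):
                edges_all[k, j] = edges_buf[k]
        best_p = 2.0
        best_f = -1
        for j in range(p):
            if pvals[j] < best_p - 1e-12:
                best_p = pvals[j]
                best_f = j
        if best_f < 0 or best_p >= 1.0:
            continue
        # exact ties -> pairwise interaction refinement, then smallest index
        n_tied = 0
        tied = np.empty(p, dtype=np.int64)
        for j in range(p):
            if pvals[j] <= best_p + 1e-12:
                tied[n_tied] = j
                n_tied += 1
        if n_tied > 1:
            best_score = 2.0
            for a in range(n_tied):
                f = tied[a]
                sc = 2.0
                for b in range(n_tied):
                    g = tied[b]
                    if g == f:
                        continue
                    q = _interaction_pval(X[:, f], X[:, g], y, w, seg, K)
                    if q < sc:
                        sc = q
                if sc < best_score - 1e-15:
                    best_score = sc
                    best_f = f
        # --- threshold
        thr, gain = _best_gini_cut_col(X[:, best_f], y, w, seg, K, min_leaf)
        if gain <= 0.0 or np.isnan(thr):
            continue
        # --- primary routing of observed rows
        go_left = np.zeros(m_rows, dtype=np.bool_)
        decided = np.zeros(m_rows, dtype=np.bool_)
        for t in range(m_rows):
            v = X[seg[t], best_f]
            if not np.isnan(v):
                decided[t] = True
                go_left[t] = v <= thr
        # --- surrogates: candidate cuts are each variable's quartile edges
        agree_best = np.zeros(p)
        cut_best = np.full(p, np.nan)
        dir_best = np.ones(p, dtype=np.bool_)
        for j in range(p):
            if j == best_f:
                continue
            if np.isnan(edges_all[0, j]):
                continue
            for k in range(3):
                e = edges_all[k, j]
                match = 0
                nboth = 0
                for t in range(m_rows):
                    if not decided[t]:
                        continue
                    v = X[seg[t], j]
                    if np.isnan(v):
                        continue
                    nboth += 1
                    if (v <= e) == go_left[t]:
                        match += 1
                if nboth < 1:
                    continue
                a = match / nboth
                if a > agree_best[j]:
                    agree_best[j] = a
                    cut_best[j] = e
                    dir_best[j] = True
                if 1.0 - a > agree_best[j]:
                    agree_best[j] = 1.0 - a
                    cut_best[j] = e
                    dir_best[j] = False
        ns = 0
        used = np.zeros(p, dtype=np.bool_)
        for _s in range(n_surr):
            bj = -1
            ba = 0.5
            for j in range(p):
                if used[j] or j == best_f:
                    continue
                if agree_best[j] > ba and not np.isnan(cut_best[j]):
                    ba = agree_best[j]
                    bj = j
            if bj < 0:
                break
            used[bj] = True
            s_feat[node, ns] = bj
            s_thr[node, ns] = cut_best[bj]
            s_dir[node, ns] = dir_best[bj]
            s_agree[node, ns] = ba
            ns += 1
        # --- surrogate routing for rows missing the primary
        for t in range(m_rows):
            if decided[t]:
                continue
            for s in range(ns):
                v = X[seg[t], s_feat[node, s]]
                if np.isnan(v):
                    continue
                le = v <= s_thr[node, s]
                go_left[t] = le if s_dir[node, s] else not le
                decided[t] = True
                break
        wl = 0.0
        wr = 0.0
        for t in range(m_rows):
            if decided[t]:
                if go_left[t]:
                    wl += w[seg[t]]
                else:
                    wr += w[seg[t]]
        maj_left = wl >= wr
        majority_left[node] = maj_left
        n_left = 0
        for t in range(m_rows):
            if not decided[t]:
                go_left[t] = maj_left
            if go_left[t]:
                n_left += 1
        if n_left == 0 or n_left == m_rows:
            continue
        # stable in-place partition of the row segment
        buf = np.empty(m_rows, dtype=np.int64)
        a_i = 0
        b_i = n_left
        for t in range(m_rows):
            if go_left[t]:
                buf[a_i] = seg[t]
                a_i += 1
            else:
                buf[b_i] = seg[t]
                b_i += 1
        for t in range(m_rows):
            rows[lo + t] = buf[t]
        # --- create children
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        feature[node] = best_f
        threshold[node] = thr
        left[node] = lid
        right[node] = rid
        for cid, c_lo, c_hi in ((lid, lo, lo + n_left), (rid, lo + n_left, hi)):
            cw, tot = node_stats(c_lo, c_hi)
            sq = 0.0
            for c in range(K):
                posterior[cid, c] = cw[c] / tot if tot > 0 else 1.0 / K
                sq += cw[c] * cw[c]
            weight[cid] = tot / root_w
            risk[cid] = (weight[cid] * (1.0 - sq / (tot * tot))) if tot > 0 else 0.0
        node_risk = weight[node] * _node_gini(posterior[node], K)
        risk[node] = node_risk
        risk_red[node] = node_risk - risk[lid] - risk[rid]
        splits += 1
        q_node[qt] = lid
        q_lo[qt] = lo
        q_hi[qt] = lo + n_left
        qt += 1
        q_node[qt] = rid
        q_lo[qt] = lo + n_left
        q_hi[qt] = hi
        qt += 1

    return (feature[:n_nodes], threshold[:n_nodes], left[:n_nodes],
            right[:n_nodes], majority_left[:n_nodes], posterior[:n_nodes],
            weight[:n_nodes], risk[:n_nodes], risk_red[:n_nodes],
            s_feat[:n_nodes], s_thr[:n_nodes], s_dir[:n_nodes],
            s_agree[:n_nodes])


@njit(**_NJIT)
def _node_gini(post, K):
    sq = 0.0
    for c in range(K):
        sq += post[c] * post[c]
    return 1.0 - sq


@njit(**_NJIT)
def predict_flat(feature, threshold, left, right, posterior,
                 s_feat, s_thr, s_dir, X, out):
    """Accumulate per-row posteriors of one flat tree into ``out``.

    Routing: primary split, then surrogates in stored order; a row missing
    all of them takes the current node's posterior."""
    n = X.shape[0]
    K = posterior.shape[1]
    S = s_feat.shape[1]
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            v = X[i, feature[node]]
            routed = False
            if not np.isnan(v):
                node = left[node] if v <= threshold[node] else right[node]
                routed = True
            else:
                for s in range(S):
                    sf = s_feat[node, s]
                    if sf < 0:
                        break
                    sv = X[i, sf]
                    if np.isnan(sv):
                        continue
                    le = sv <= s_thr[node, s]
                    if not s_dir[node, s]:
                        le = not le
                    node = left[node] if le else right[node]
                    routed = True
                    break
            if not routed:
                break
        for c in range(K):
            out[i, c] += posterior[node, c]
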