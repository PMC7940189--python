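"""Random forest and guided regularized random forest (GRRF), from scratch.

The guided regularized random forest selects a compact feature set in
two passes. First an ordinary random forest is fitted and its mean
decrease in Gini importances are max-normalized to [0, 1]. Those
guidance importances define per-feature penalty coefficients

    lambda_i = (1 - gamma) * lambda0 + gamma * imp_i,   gamma in [0, 1],

and a second forest is grown *sequentially* where a candidate feature i
that is not yet in the shared selected set F has its split gain
multiplied by lambda_i, while features already in F compete with their
raw gain. Every feature used in a split enters F and never leaves. At
gamma = 0 (lambda0 = 1) the procedure reduces exactly to an ordinary
random forest; at gamma = 1 only features with high guidance importance
can open new entries in F, so redundant copies of an already selected
feature are suppressed.

Trees are binary CART trees on numeric thresholds with Gini impurity,
bootstrap sampling, and mtry random candidate features per node. Ties
in candidate gain are broken toward the lowest feature index, and the
best threshold within a feature is the lowest tied one, so the whole
fit is a deterministic function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit


@dataclass
class ForestConfig:
    n_trees: int = 500
    mtry: int | None = None  # None -> ceil(sqrt(p))
    min_leaf: int = 1
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else math.ceil(math.sqrt(p))
        return max(1, min(m, p))


@njit(cache=True)
def _grow_tree(X, y, lam, in_F, mtry, min_leaf, bootstrap, seed):  # pragma: no cover
    n, p = X.shape
    np.random.seed(seed)
    idx = np.empty(n, np.int64)
    inbag = np.zeros(n, np.int64)
    if bootstrap:
        for i in range(n):
            j = np.random.randint(0, n)
            idx[i] = j
            inbag[j] += 1
    else:
        for i in range(n):
            idx[i] = i
            inbag[i] = 1

    max_nodes = 2 * n + 1
    feature = np.full(max_nodes, -1, np.int64)
    threshold = np.zeros(max_nodes, np.float64)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    value = np.zeros(max_nodes, np.float64)
    imp = np.zeros(p, np.float64)
    sel_log = np.empty(p, np.int64)
    n_sel = 0

    stack = np.zeros((max_nodes, 3), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n
    top = 1
    node_count = 1
    feat_buf = np.arange(p)
    tmp_idx = np.empty(n, np.int64)
    v = np.empty(n, np.float64)

    while top > 0:
        top -= 1
        node_id = stack[top, 0]
        s = stack[top, 1]
        e = stack[top, 2]
        nn = e - s
        c1 = 0
        for i in range(s, e):
            c1 += y[idx[i]]
        value[node_id] = c1 / nn
        if c1 == 0 or c1 == nn or nn < 2 * min_leaf:
            continue
        p1 = c1 / nn
        gini_parent = 1.0 - (p1 * p1 + (1.0 - p1) * (1.0 - p1))

        # partial Fisher-Yates: mtry distinct candidate features
        for i in range(mtry):
            j = i + np.random.randint(0, p - i)
            t = feat_buf[i]
            feat_buf[i] = feat_buf[j]
            feat_buf[j] = t
        cand = np.sort(feat_buf[:mtry])

        best_gain_reg = 0.0
        best_gain_raw = 0.0
        best_f = -1
        best_thresh = 0.0
        for ci in range(mtry):
            f = cand[ci]
            for i in range(nn):
                v[i] = X[idx[s + i], f]
            order = np.argsort(v[:nn])
            f_best_gain = -1.0
            f_best_thresh = 0.0
            nl = 0
            n1_left = 0
            for i in range(nn - 1):
                o = order[i]
                nl += 1
                n1_left += y[idx[s + o]]
                if v[o] == v[order[i + 1]]:
                    continue
                nr = nn - nl
                if nl < min_leaf or nr < min_leaf:
                    continue
                n1_right = c1 - n1_left
                pl = n1_left / nl
                pr = n1_right / nr
                gini_l = 1.0 - (pl * pl + (1.0 - pl) * (1.0 - pl))
                gini_r = 1.0 - (pr * pr + (1.0 - pr) * (1.0 - pr))
                gain = gini_parent - (nl * gini_l + nr * gini_r) / nn
                if gain > f_best_gain:
                    f_best_gain = gain
                    f_best_thresh = v[o]
            if f_best_gain <= 0.0:
                continue
            if in_F[f] == 1:
                greg = f_best_gain
            else:
                greg = f_best_gain * lam[f]
            # strict '>' with candidates in ascending index order: ties keep
            # the lowest feature index
            if greg > best_gain_reg:
                best_gain_reg = greg
                best_gain_raw = f_best_gain
                best_f = f
                best_thresh = f_best_thresh

        if best_f < 0:
            continue
        if in_F[best_f] == 0:
            in_F[best_f] = 1
            sel_log[n_sel] = best_f
            n_sel += 1
        imp[best_f] += (nn / n) * best_gain_raw

        k = 0
        for i in range(nn):
            if X[idx[s + i], best_f] <= best_thresh:
                tmp_idx[k] = idx[s + i]
                k += 1
        nl = k
        for i in range(nn):
            if X[idx[s + i], best_f] > best_thresh:
                tmp_idx[k] = idx[s + i]
                k += 1
        for i in range(nn):
            idx[s + i] = tmp_idx[i]

        feature[node_id] = best_f
        threshold[node_id] = best_thresh
        lid = node_count
        rid = node_count + 1
        node_count += 2
        left[node_id] = lid
        right[node_id] = rid
        stack[top, 0] = lid
        stack[top, 1] = s
        stack[top, 2] = s + nl
        top += 1
        stack[top, 0] = rid
        stack[top, 1] = s + nl
        stack[top, 2] = e
        top += 1

    return (
        feature[:node_count],
        threshold[:node_count],
        left[:node_count],
        right[:node_count],
        value[:node_count],
        imp,
        inbag,
        sel_log[:n_sel],
    )


@njit(cache=True)
def _predict_tree(feature, threshold, left, right, value, X):  # pragma: no cover
    n = X.shape[0]
    out = np.empty(n, np.float64)
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = value[node]
    return out


@dataclass
class _Tree:
    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    inbag: np.ndarray

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        return _predict_tree(
            self.feature, self.threshold, self.left, self.right, self.value, X
        )

    def split_features(self) -> set[int]:
        return set(int(f) for f in self.feature if f >= 0)


class RandomForestGini:
    """Ordinary random forest classifier (binary, Gini splits).

    ``importances_`` is the mean decrease in Gini: the bootstrap-weighted
    impurity decrease summed over a feature's splits, averaged over
    trees. ``oob_proba_`` holds out-of-bag class-1 probabilities (NaN
    for samples that were in-bag in every tree).
    """

    def __init__(self, config: ForestConfig | None = None) -> None:
        self.config = config or ForestConfig()
        self.trees_: list[_Tree] = []
        self.importances_: np.ndarray | None = None
        self.selected_features_: list[int] = []
        self.n_features_: int = 0

    def fit(self, X, y) -> "RandomForestGini":
        X = np.asarray(X, dtype=np.float64)
        lam = np.ones(X.shape[1], dtype=np.float64)
        return self._fit(X, np.asarray(y), lam)

    def _fit(self, X, y, lam) -> "RandomForestGini":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("y must contain both classes")
        if not np.all(np.isin(classes, [0, 1])):
            raise ValueError("labels must be 0/1")
        n, p = X.shape
        self.n_features_ = p
        mtry = self.config.resolve_mtry(p)
        rng = np.random.default_rng(self.config.seed)
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.config.n_trees)
        in_F = np.zeros(p, dtype=np.uint8)
        imp_sum = np.zeros(p, dtype=np.float64)
        oob_sum = np.zeros(n, dtype=np.float64)
        oob_cnt = np.zeros(n, dtype=np.int64)
        self.trees_ = []
        self.selected_features_ = []
        for t in range(self.config.n_trees):
            feat, thr, lft, rgt, val, imp, inbag, sel = _grow_tree(
                X,
                y,
                np.asarray(lam, dtype=np.float64),
                in_F,
                mtry,
                self.config.min_leaf,
                self.config.bootstrap,
                int(tree_seeds[t]),
            )
            tree = _Tree(feat.copy(), thr.copy(), lft.copy(), rgt.copy(), val.copy(),
                         inbag.copy())
            self.trees_.append(tree)
            imp_sum += imp
            self.selected_features_.extend(int(f) for f in sel)
            if self.config.bootstrap:
                oob = inbag == 0
                if oob.any():
                    oob_sum[oob] += tree.predict_proba1(X[oob])
                    oob_cnt[oob] += 1
        self.importances_ = imp_sum / self.config.n_trees
        with np.errstate(invalid="ignore"):
            self.oob_proba_ = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1),
                                       np.nan)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
        acc = np.zeros(X.shape[0], dtype=np.float64)
        for tree in self.trees_:
            acc += tree.predict_proba1(X)
        return acc / len(self.trees_)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.int64)

    def features_used(self) -> list[int]:
        """Features appearing in at least one split, in order of first use."""
        return list(self.selected_features_)


def guidance_importance(rf: RandomForestGini) -> np.ndarray:
    """Max-normalized mean-decrease-Gini importances in [0, 1]."""
    imp = np.asarray(rf.importances_, dtype=np.float64)
    top = imp.max()
    if top <= 0:
        return np.zeros_like(imp)
    return imp / top


def penalties(imp_norm, gamma: float, lambda0: float = 1.0) -> np.ndarray:
    """Per-feature penalty lambda_i = (1-gamma)*lambda0 + gamma*imp_i."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    imp = np.asarray(imp_norm, dtype=np.float64)
    if np.any((imp < 0) | (imp > 1)):
        raise ValueError("normalized importances must lie in [0, 1]")
    return (1.0 - gamma) * lambda0 + gamma * imp


class GuidedRegularizedForest(RandomForestGini):
    """GRRF: sequential trees with a shared, growing selected-feature set."""

    def fit(self, X, y, penalty_vector=None) -> "GuidedRegularizedForest":
        X = np.asarray(X, dtype=np.float64)
        if penalty_vector is None:
            penalty_vector = np.ones(X.shape[1], dtype=np.float64)
        lam = np.asarray(penalty_vector, dtype=np.float64)
        if lam.shape != (X.shape[1],):
            raise ValueError("penalty vector length must equal number of features")
        return self._fit(X, np.asarray(y), lam)


@dataclass
class RankedMotif:
    motif: str
    importance: float


def rank_grrf(
    forest: RandomForestGini, feature_names: list[str], k: int = 10
) -> list[RankedMotif]:
    """Top-k features by mean decrease in Gini among the selected set F.

    Ties broken lexicographically by name; features outside F (whose
    importance is exactly 0) are never eligible.
    """
    imp = forest.importances_
    selected = sorted(set(forest.selected_features_))
    ranked = sorted(
        (RankedMotif(feature_names[i], float(imp[i])) for i in selected),
        key=lambda r: (-r.importance, r.motif),
    )
    return ranked[:k]
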