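"""Bagged regression forest, from scratch.

The ensemble follows the classic recipe: each tree is a greedy binary CART
grown on a bootstrap sample (n draws with replacement, so ≈63.2 % of the
rows are in-bag and the remaining ≈1/3 are out-of-bag, OOB), with only a
random subset of ``mtry`` candidate features considered at each split.  The
ensemble prediction is the plain arithmetic mean over trees,

    f_bag(x) = (1/B) * sum_b f_b(x),

OOB error is the mean squared deviation of each row's OOB-only averaged
prediction from its response, and variable importance is the percent
increase in OOB MSE when one feature's values are permuted (%IncMSE,
reported relative to the baseline OOB MSE, not scaled by a standard error).

Deterministic conventions: candidate features are examined in ascending
column order; among equal-error splits the lowest feature index wins, then
the lowest threshold (continuous) or the smallest left-subset encoding
(categorical).  Categorical splits search subsets of levels exhaustively
for up to 10 levels present at a node, and fall back to the mean-response
ordering scan above that.  At prediction time an unseen categorical level
follows the child that received more training rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureTable",
    "RegressionTree",
    "Forest",
    "OOBResult",
    "ImportanceReport",
    "fit_tree",
    "fit_forest",
    "predict",
    "oob_error",
    "permutation_importance",
    "default_mtry",
]

#: Max categorical code (masks are stored in int64 bitfields).
MAX_CATEGORY_CODE = 62

#: Exhaustive subset search is used when a node sees at most this many levels.
EXHAUSTIVE_LEVELS = 10


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """n x p design matrix with per-column type tags and a response in [0,1].

    Categorical columns hold non-negative integer codes (as floats, for a
    homogeneous matrix) drawn from a declared alphabet.
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    categorical: np.ndarray
    categories: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ValueError("y length must match X rows")
        if len(self.columns) != p:
            raise ValueError("column names must match X width")
        self.categorical = np.asarray(self.categorical, dtype=bool)
        if self.categorical.shape != (p,):
            raise ValueError("categorical flags must match X width")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("training table must have no missing values")
        for j in np.nonzero(self.categorical)[0]:
            col = self.X[:, j]
            if not np.array_equal(col, np.round(col)) or col.min() < 0:
                raise ValueError(f"categorical column {self.columns[j]} must hold non-negative integer codes")
            if col.max() > MAX_CATEGORY_CODE:
                raise ValueError(f"categorical codes must be <= {MAX_CATEGORY_CODE}")
            alphabet = self.categories.get(int(j))
            if alphabet is not None and not np.isin(col, alphabet).all():
                raise ValueError(f"column {self.columns[j]} has codes outside its alphabet")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def schema(self) -> dict:
        return {
            "columns": list(self.columns),
            "categorical": self.categorical.astype(int).tolist(),
            "categories": {str(k): np.asarray(v).tolist() for k, v in self.categories.items()},
        }


def default_mtry(p: int) -> int:
    """Conventional regression default: max(1, floor(p/3))."""
    return max(1, p // 3)


# ---------------------------------------------------------------------------
# Regression tree
# ---------------------------------------------------------------------------

@dataclass
class RegressionTree:
    """Binary CART stored as parallel node arrays.

    feature[i] == -1 marks a leaf with prediction value[i].  Continuous
    splits send x <= threshold left; categorical splits send codes whose bit
    is set in mask_left left, codes set in mask_seen but not mask_left
    right, and codes absent from mask_seen (unseen levels) to the child that
    had more training rows (default_left).
    """

    feature: np.ndarray
    threshold: np.ndarray
    mask_left: np.ndarray
    mask_seen: np.ndarray
    default_left: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    n_samples: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def n_leaves(self) -> int:
        return int((self.feature < 0).sum())

    def predict(self, X: np.ndarray, categorical: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        out = np.empty(n, dtype=float)
        node = np.zeros(n, dtype=np.int64)
        active = np.arange(n)
        while active.size:
            nd = node[active]
            f = self.feature[nd]
            leaf = f < 0
            if leaf.any():
                done = active[leaf]
                out[done] = self.value[node[done]]
                active = active[~leaf]
                if not active.size:
                    break
                nd = node[active]
                f = self.feature[nd]
            xv = X[active, f]
            go_left = np.empty(active.size, dtype=bool)
            cat = categorical[f]
            cont = ~cat
            if cont.any():
                go_left[cont] = xv[cont] <= self.threshold[nd[cont]]
            if cat.any():
                code = xv[cat].astype(np.int64)
                ml = self.mask_left[nd[cat]]
                ms = self.mask_seen[nd[cat]]
                in_left = ((ml >> code) & 1).astype(bool)
                in_seen = ((ms >> code) & 1).astype(bool)
                go_left[cat] = np.where(in_seen, in_left, self.default_left[nd[cat]])
            node[active] = np.where(go_left, self.left[nd], self.right[nd])
        return out

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "mask_left": self.mask_left.tolist(),
            "mask_seen": self.mask_seen.tolist(),
            "default_left": self.default_left.astype(int).tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
            "n_samples": self.n_samples.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=float),
            mask_left=np.asarray(d["mask_left"], dtype=np.int64),
            mask_seen=np.asarray(d["mask_seen"], dtype=np.int64),
            default_left=np.asarray(d["default_left"], dtype=bool),
            left=np.asarray(d["left"], dtype=np.int64),
            right=np.asarray(d["right"], dtype=np.int64),
            value=np.asarray(d["value"], dtype=float),
            n_samples=np.asarray(d["n_samples"], dtype=np.int64),
        )

    @classmethod
    def constant(cls, value: float, n_samples: int = 1) -> "RegressionTree":
        """A single-leaf tree predicting a constant (handy for hand-built
        oracles and degenerate fits)."""
        return cls(
            feature=np.array([-1], dtype=np.int64),
            threshold=np.array([np.nan]),
            mask_left=np.zeros(1, dtype=np.int64),
            mask_seen=np.zeros(1, dtype=np.int64),
            default_left=np.ones(1, dtype=bool),
            left=np.array([-1], dtype=np.int64),
            right=np.array([-1], dtype=np.int64),
            value=np.array([float(value)]),
            n_samples=np.array([n_samples], dtype=np.int64),
        )


def _best_continuous_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best threshold for one continuous feature: (sse, threshold) or None.

    Scans the sorted order with prefix sums; among equal-SSE cuts the lowest
    threshold wins (first occurrence in ascending threshold order).
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    n = xs.size
    s1 = np.cumsum(ys)
    s2 = np.cumsum(ys * ys)
    tot1, tot2 = s1[-1], s2[-1]
    k = np.arange(1, n)  # left sizes
    valid = (xs[:-1] < xs[1:]) & (k >= min_leaf) & (n - k >= min_leaf)
    if not valid.any():
        return None
    l1, l2 = s1[:-1], s2[:-1]
    sse = (l2 - l1 * l1 / k) + ((tot2 - l2) - (tot1 - l1) ** 2 / (n - k))
    sse = np.where(valid, sse, np.inf)
    i = int(np.argmin(sse))
    return float(sse[i]), float((xs[i] + xs[i + 1]) / 2.0)


def _best_categorical_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best level-subset for one categorical feature:
    (sse, mask_left, mask_seen) or None.

    Exhaustive over bipartitions when <= EXHAUSTIVE_LEVELS levels are
    present; otherwise scans levels ordered by mean response (optimal for
    squared error).  Ties resolve to the smallest left-mask encoding.
    """
    codes = x.astype(np.int64)
    levels = np.unique(codes)
    mask_seen = int(np.sum(1 << levels.astype(object)))
    if levels.size < 2:
        return None
    # per-level sufficient statistics
    cnt = np.array([(codes == lv).sum() for lv in levels], dtype=float)
    s1 = np.array([y[codes == lv].sum() for lv in levels])
    s2 = np.array([(y[codes == lv] ** 2).sum() for lv in levels])
    tot_n, tot1, tot2 = cnt.sum(), s1.sum(), s2.sum()

    def sse_of(sel: np.ndarray):
        nl = cnt[sel].sum()
        nr = tot_n - nl
        if nl < min_leaf or nr < min_leaf:
            return None
        a1 = s1[sel].sum()
        a2 = s2[sel].sum()
        return (a2 - a1 * a1 / nl) + ((tot2 - a2) - (tot1 - a1) ** 2 / nr)

    best = None  # (sse, mask_left)
    k = levels.size
    if k <= EXHAUSTIVE_LEVELS:
        # enumerate subsets containing levels[0] to skip mirror duplicates;
        # ascending subset index gives a deterministic canonical tie-break
        for sub in range(0, 1 << (k - 1)):
            bits = np.zeros(k, dtype=bool)
            bits[0] = True
            rest = sub
            idx = 1
            while rest:
                if rest & 1:
                    bits[idx] = True
                rest >>= 1
                idx += 1
            if bits.all():
                continue
            sse = sse_of(bits)
            if sse is None:
                continue
            mask = int(np.sum((1 << levels[bits].astype(object))))
            if best is None or sse < best[0] or (sse == best[0] and mask < best[1]):
                best = (sse, mask)
    else:
        means = s1 / cnt
        order = np.argsort(means, kind="stable")
        for cut in range(1, k):
            bits = np.zeros(k, dtype=bool)
            bits[order[:cut]] = True
            sse = sse_of(bits)
            if sse is None:
                continue
            mask = int(np.sum((1 << levels[bits].astype(object))))
            if best is None or sse < best[0] or (sse == best[0] and mask < best[1]):
                best = (sse, mask)
    if best is None:
        return None
    return best[0], best[1], mask_seen


def fit_tree(table: FeatureTable, rows: np.ndarray, mtry: int,
             min_leaf: int = 5, rng: np.random.Generator | None = None) -> RegressionTree:
    """Grow one greedy binary regression tree on the given (bootstrap) rows.

    At each node ``mtry`` candidate features are drawn without replacement;
    the (feature, rule) minimising the summed within-child squared deviation
    of the response is chosen.  Growth stops when a node holds fewer than
    2 x min_leaf rows, the response is constant, or no candidate split
    reduces the error.
    """
    rows = np.asarray(rows, dtype=np.int64)
    if rows.size == 0:
        raise ValueError("cannot fit a tree on an empty row set")
    if not 1 <= mtry <= table.p:
        raise ValueError(f"mtry must be in [1, {table.p}]")
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    rng = rng or np.random.default_rng()
    X, y = table.X, table.y

    feature, threshold = [], []
    mask_left, mask_seen, default_left = [], [], []
    left, right, value, n_samples = [], [], [], []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(np.nan)
        mask_left.append(0)
        mask_seen.append(0)
        default_left.append(True)
        left.append(-1)
        right.append(-1)
        value.append(np.nan)
        n_samples.append(0)
        return len(feature) - 1

    stack = [(new_node(), rows)]
    while stack:
        node_id, idx = stack.pop()
        yn = y[idx]
        n = idx.size
        n_samples[node_id] = n
        value[node_id] = float(yn.mean())
        if n < 2 * min_leaf or np.all(yn == yn[0]):
            continue
        mu = yn.mean()
        parent_sse = float(np.sum((yn - mu) ** 2))
        cand = np.sort(rng.choice(table.p, size=mtry, replace=False))
        best = None  # (sse, feat, kind, payload)
        for j in cand:
            xj = X[idx, j]
            if table.categorical[j]:
                res = _best_categorical_split(xj, yn, min_leaf)
                if res is None:
                    continue
                sse, ml, ms = res
                if best is None or sse < best[0]:
                    best = (sse, int(j), "cat", (ml, ms))
            else:
                res = _best_continuous_split(xj, yn, min_leaf)
                if res is None:
                    continue
                sse, thr = res
                if best is None or sse < best[0]:
                    best = (sse, int(j), "num", thr)
        if best is None or not best[0] < parent_sse:
            continue
        sse, j, kind, payload = best
        xj = X[idx, j]
        if kind == "num":
            go_left = xj <= payload
            threshold[node_id] = float(payload)
        else:
            ml, ms = payload
            codes = xj.astype(np.int64)
            go_left = ((np.asarray(ml, dtype=np.int64) >> codes) & 1).astype(bool)
            mask_left[node_id] = int(ml)
            mask_seen[node_id] = int(ms)
        feature[node_id] = j
        default_left[node_id] = bool(go_left.sum() >= (~go_left).sum())
        lid, rid = new_node(), new_node()
        left[node_id], right[node_id] = lid, rid
        stack.append((rid, idx[~go_left]))
        stack.append((lid, idx[go_left]))

    return RegressionTree(
        feature=np.asarray(feature, dtype=np.int64),
        threshold=np.asarray(threshold, dtype=float),
        mask_left=np.asarray(mask_left, dtype=np.int64),
        mask_seen=np.asarray(mask_seen, dtype=np.int64),
        default_left=np.asarray(default_left, dtype=bool),
        left=np.asarray(left, dtype=np.int64),
        right=np.asarray(right, dtype=np.int64),
        value=np.asarray(value, dtype=float),
        n_samples=np.asarray(n_samples, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Forest
# ---------------------------------------------------------------------------

@dataclass
class Forest:
    """A bag of trees plus the bookkeeping needed for OOB estimation.

    ``boot_rows[b]`` are the (global) row indices, with multiplicity, that
    tree b was trained on; its OOB set is the complement of the distinct
    bootstrap rows within range(n_rows).
    """

    trees: list[RegressionTree]
    boot_rows: list[np.ndarray]
    n_rows: int
    mtry: int
    min_leaf: int
    seed: int | None
    categorical: np.ndarray
    columns: list[str]

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def oob_mask(self, b: int) -> np.ndarray:
        mask = np.ones(self.n_rows, dtype=bool)
        mask[self.boot_rows[b]] = False
        return mask

    def oob_fractions(self) -> np.ndarray:
        """Per-tree fraction of rows out of bag."""
        return np.array([self.oob_mask(b).mean() for b in range(self.n_trees)])

    def tree_predictions(self, X: np.ndarray) -> np.ndarray:
        """(B, n_query) matrix of per-tree predictions."""
        X = np.asarray(X, dtype=float)
        return np.stack([t.predict(X, self.categorical) for t in self.trees])

    # --- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "n_rows": self.n_rows,
            "mtry": self.mtry,
            "min_leaf": self.min_leaf,
            "seed": self.seed,
            "columns": list(self.columns),
            "categorical": self.categorical.astype(int).tolist(),
            "boot_rows": [b.tolist() for b in self.boot_rows],
            "trees": [t.to_dict() for t in self.trees],
        })

    @classmethod
    def from_json(cls, text: str) -> "Forest":
        d = json.loads(text)
        return cls(
            trees=[RegressionTree.from_dict(t) for t in d["trees"]],
            boot_rows=[np.asarray(b, dtype=np.int64) for b in d["boot_rows"]],
            n_rows=int(d["n_rows"]),
            mtry=int(d["mtry"]),
            min_leaf=int(d["min_leaf"]),
            seed=d["seed"],
            categorical=np.asarray(d["categorical"], dtype=bool),
            columns=list(d["columns"]),
        )


def fit_forest(table: FeatureTable, B: int, mtry: int | None = None,
               min_leaf: int = 5, seed: int = 0) -> Forest:
    """Fit B trees, each on a fresh bootstrap of all n rows (n draws with
    replacement, leaving ≈1/3 of rows out of bag per tree).  Fully
    reproducible for a fixed seed."""
    if B < 1:
        raise ValueError("B must be >= 1")
    mtry = default_mtry(table.p) if mtry is None else mtry
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B)
    n = table.n
    trees, boots = [], []
    for b in range(B):
        rng = np.random.default_rng(children[b])
        boot = rng.integers(0, n, size=n)
        trees.append(fit_tree(table, boot, mtry, min_leaf, rng))
        boots.append(boot)
    return Forest(trees, boots, n, mtry, min_leaf, seed,
                  table.categorical.copy(), list(table.columns))


def predict(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Bagged prediction: the arithmetic mean of the B tree outputs,
    f_bag(x) = (1/B) sum_b f_b(x).  No clamping here."""
    return forest.tree_predictions(X).mean(axis=0)


@dataclass(frozen=True)
class OOBResult:
    mse: float
    r2: float
    n_covered: int
    n_uncovered: int
    predictions: np.ndarray  # per-row OOB prediction, NaN where uncovered


def _oob_accumulate(forest: Forest, X: np.ndarray,
                    column_permuter=None,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-row mean prediction over the trees for which the row is OOB.
    ``column_permuter(Xoob, rng)`` may scramble a copy of the OOB block."""
    n = forest.n_rows
    pred_sum = np.zeros(n)
    count = np.zeros(n)
    for b in range(forest.n_trees):
        oob = forest.oob_mask(b)
        if not oob.any():
            continue
        block = X[oob]
        if column_permuter is not None:
            block = column_permuter(block.copy(), rng)
        p = forest.trees[b].predict(block, forest.categorical)
        pred_sum[oob] += p
        count[oob] += 1
    with np.errstate(invalid="ignore"):
        out = pred_sum / count
    out[count == 0] = np.nan
    return out


def oob_error(forest: Forest, table: FeatureTable) -> OOBResult:
    """Out-of-bag MSE and R²: each row is predicted only by the trees whose
    bootstrap never drew it; rows OOB for no tree are excluded and counted."""
    if forest.n_rows != table.n:
        raise ValueError("forest was fitted on a table of different length")
    preds = _oob_accumulate(forest, table.X)
    covered = np.isfinite(preds)
    if not covered.any():
        raise ValueError(
            "no row has OOB coverage; increase the number of trees"
        )
    resid = table.y[covered] - preds[covered]
    mse = float(np.mean(resid**2))
    var = float(np.var(table.y[covered]))
    r2 = 1.0 - mse / var if var > 0 else float("nan")
    return OOBResult(mse, r2, int(covered.sum()), int((~covered).sum()), preds)


@dataclass(frozen=True)
class ImportanceReport:
    """Permutation importance: %IncMSE per feature, ranked descending."""

    columns: list[str]
    pct_inc_mse: np.ndarray
    baseline_mse: float

    @property
    def ranking(self) -> list[str]:
        order = np.argsort(-self.pct_inc_mse, kind="stable")
        return [self.columns[i] for i in order]

    def to_frame(self):
        import pandas as pd

        order = np.argsort(-self.pct_inc_mse, kind="stable")
        return pd.DataFrame(
            {"variable": [self.columns[i] for i in order],
             "pct_inc_mse": self.pct_inc_mse[order]}
        )


def permutation_importance(forest: Forest, table: FeatureTable,
                           rng: np.random.Generator | int | None = None) -> ImportanceReport:
    """%IncMSE_j = 100 x (OOB MSE with column j permuted − OOB MSE) / OOB MSE.

    The permutation is drawn per tree over that tree's OOB rows, so only the
    association between feature j and the response is destroyed; other
    columns are untouched.  A constant column scores exactly 0.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    base = oob_error(forest, table)
    covered = np.isfinite(base.predictions)
    scores = np.zeros(table.p)
    for j in range(table.p):
        col = table.X[:, j]
        if np.all(col == col[0]):
            continue  # permutation is a no-op

        def permute(block: np.ndarray, r: np.random.Generator,
                    _j: int = j) -> np.ndarray:
            block[:, _j] = block[r.permutation(block.shape[0]), _j]
            return block

        preds = _oob_accumulate(forest, table.X, permute, rng)
        resid = table.y[covered] - preds[covered]
        mse_j = float(np.mean(resid**2))
        scores[j] = 100.0 * (mse_j - base.mse) / base.mse
    return ImportanceReport(list(forest.columns), scores, base.mse)
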