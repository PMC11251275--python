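"""Depth-limited regression trees with exact Shapley attribution.

The feature matrix is small (a handful of binary indicators), so Shapley
values are computed exactly by enumerating all 2^d coalitions under the
interventional expectation: features in the coalition are taken from the
explained row, the rest from a background row, and the coalition value is
the mean model prediction over the background set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

FEATURES = [
    "trophic_mode_is_photo",
    "carboxysome",
    "is_alpha_cyano",
    "is_beta_cyano",
    "is_ccm_proteo",
]

MAX_EXACT_FEATURES = 12


def feature_matrix(panel: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Binary feature matrix and kcat response from a panel table."""
    X = np.column_stack([
        (panel["trophic_mode"] == "photo").to_numpy(dtype=float),
        (panel["carboxysome"] == "yes").to_numpy(dtype=float),
        (panel["clade"] == "alpha_cyano").to_numpy(dtype=float),
        (panel["clade"] == "beta_cyano").to_numpy(dtype=float),
        (panel["clade"] == "ccm_proteo").to_numpy(dtype=float),
    ])
    y = panel["kcat"].to_numpy(dtype=float)
    return X, y


# ---------------------------------------------------------------------------
# CART regression tree (variance-reduction splits, mean leaves)


@dataclass
class _Node:
    feature: int = -1  # -1 marks a leaf
    threshold: float = 0.5
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0
    n: int = 0


class RegressionTree:
    """Binary CART regression tree; splits maximise SSE reduction."""

    def __init__(self, max_depth: int = 3, min_leaf: int = 2):
        if max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.root: _Node | None = None
        self.n_features_: int | None = None

    @staticmethod
    def _sse(y: np.ndarray) -> float:
        return float(((y - y.mean()) ** 2).sum()) if y.size else 0.0

    def _best_split(self, X: np.ndarray, y: np.ndarray):
        """Exhaustive search over (feature, midpoint threshold) splits."""
        best = None
        parent_sse = self._sse(y)
        for f in range(X.shape[1]):
            xs = np.unique(X[:, f])
            for lo, hi in zip(xs[:-1], xs[1:]):
                thr = (lo + hi) / 2.0
                mask = X[:, f] <= thr
                nl = int(mask.sum())
                if nl < self.min_leaf or (len(y) - nl) < self.min_leaf:
                    continue
                gain = parent_sse - self._sse(y[mask]) - self._sse(y[~mask])
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, f, thr, mask)
        if best is None or best[0] <= 1e-12:
            return None
        return best

    def _grow(self, X: np.ndarray, y: np.ndarray, depth: int) -> _Node:
        node = _Node(value=float(y.mean()), n=len(y))
        if depth >= self.max_depth or len(y) < 2 * self.min_leaf \
                or np.all(y == y[0]):
            return node
        split = self._best_split(X, y)
        if split is None:
            return node
        _, f, thr, mask = split
        node.feature = f
        node.threshold = thr
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    def fit(self, X, y) -> "RegressionTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per response")
        if len(y) < 2:
            raise ValueError("need at least 2 rows")
        self.n_features_ = X.shape[1]
        self.root = self._grow(X, y, 0)
        return self

    def predict(self, X) -> np.ndarray:
        if self.root is None:
            raise RuntimeError("tree is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(len(X))
        idx = np.arange(len(X))
        stack = [(self.root, idx)]
        while stack:
            node, rows = stack.pop()
            if node.feature < 0 or rows.size == 0:
                out[rows] = node.value
                continue
            mask = X[rows, node.feature] <= node.threshold
            stack.append((node.left, rows[mask]))
            stack.append((node.right, rows[~mask]))
        return out

    def used_features(self) -> set:
        used: set[int] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node is not None and node.feature >= 0:
                used.add(node.feature)
                stack.extend([node.left, node.right])
        return used

    def depth(self) -> int:
        def _d(node):
            if node is None or node.feature < 0:
                return 0
            return 1 + max(_d(node.left), _d(node.right))
        return _d(self.root)


class BaggedTrees:
    """Optional small bagged ensemble (mean of bootstrap-fitted trees)."""

    def __init__(self, n_trees: int, max_depth: int = 3, min_leaf: int = 2,
                 seed: int = 0):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.seed = seed
        self.trees: list = []

    def fit(self, X, y) -> "BaggedTrees":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed)
        self.trees = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, len(y), size=len(y))
            self.trees.append(
                RegressionTree(self.max_depth, self.min_leaf).fit(X[idx], y[idx]))
        return self

    def predict(self, X) -> np.ndarray:
        return np.mean([t.predict(X) for t in self.trees], axis=0)


# ---------------------------------------------------------------------------
# train/test splits


@dataclass
class SplitModel:
    model: object
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


def fit_forest_over_splits(
    X,
    y,
    n_splits: int = 100,
    train_frac: float = 0.75,
    max_depth: int = 3,
    min_leaf: int = 2,
    seed: int = 42,
    trees_per_split: int = 1,
) -> list:
    """Fit one model per random train/test split.

    Sub-seeds are spawned deterministically from the master seed; the
    same master seed reproduces the same split sequence and models.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 8:
        raise ValueError("need at least 8 rows")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1) so test sets are "
                         "non-empty")
    n_train = int(math.floor(train_frac * n))
    if n_train < 2:
        raise ValueError("training set smaller than 2 rows")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_splits)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        sub_seed = int(child.generate_state(1)[0])
        if trees_per_split == 1:
            model = RegressionTree(max_depth, min_leaf).fit(
                X[train_idx], y[train_idx])
        else:
            model = BaggedTrees(trees_per_split, max_depth, min_leaf,
                                seed=sub_seed).fit(X[train_idx], y[train_idx])
        out.append(SplitModel(model, train_idx, test_idx, sub_seed))
    return out


# ---------------------------------------------------------------------------
# exact Shapley values


def _shapley_weights(d: int) -> np.ndarray:
    """w[s] = s! (d-s-1)! / d! for coalition size s."""
    return np.array([
        math.factorial(s) * math.factorial(d - s - 1) / math.factorial(d)
        for s in range(d)
    ])


def exact_shapley(model, background: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Exact interventional Shapley values for one row.

    For every coalition S the value is the mean prediction over
    background rows with the features in S replaced by those of ``x``.
    Efficiency holds exactly: ``phi.sum() == f(x) - mean f(background)``.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    x = np.asarray(x, dtype=float).ravel()
    d = x.size
    if background.shape[1] != d:
        raise ValueError("background and x disagree on feature count")
    if d > MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration supports at most {MAX_EXACT_FEATURES} "
            "features; use a sampling approximation for wider matrices")
    n_bg = len(background)
    n_masks = 1 << d

    # one synthetic row per (mask, background row), single predict call
    comp = np.empty((n_masks, n_bg, d))
    comp[:] = background[None, :, :]
    for f in range(d):
        masks_with_f = np.nonzero(np.arange(n_masks) & (1 << f))[0]
        comp[masks_with_f, :, f] = x[f]
    v = model.predict(comp.reshape(-1, d)).reshape(n_masks, n_bg).mean(axis=1)

    w = _shapley_weights(d)
    sizes = np.array([bin(s).count("1") for s in range(n_masks)])
    phi = np.zeros(d)
    for f in range(d):
        bit = 1 << f
        without = np.nonzero((np.arange(n_masks) & bit) == 0)[0]
        phi[f] = float(np.sum(w[sizes[without]]
                              * (v[without | bit] - v[without])))
    return phi


def _shapley_binary_batch(model, background: np.ndarray,
                          X_expl: np.ndarray) -> np.ndarray:
    """Fast exact Shapley for all-binary features.

    Predictions depend only on the 2^d distinct binary inputs, so the
    model is evaluated once on the full pattern table and everything else
    is integer arithmetic.  Must agree with :func:`exact_shapley` (tested).
    """
    d = X_expl.shape[1]
    n_masks = 1 << d
    patterns = ((np.arange(n_masks)[:, None] >> np.arange(d)) & 1).astype(float)
    table = model.predict(patterns)

    bg_codes = (np.asarray(background, dtype=int) << np.arange(d)).sum(axis=1)
    masks = np.arange(n_masks)
    sizes = np.array([bin(s).count("1") for s in range(n_masks)])
    w = _shapley_weights(d)

    out = np.empty((len(X_expl), d))
    for r, row in enumerate(np.asarray(X_expl, dtype=int)):
        x_code = int((row << np.arange(d)).sum())
        comp = (x_code & masks)[:, None] | (bg_codes[None, :] & ~masks[:, None])
        v = table[comp].mean(axis=1)
        for f in range(d):
            bit = 1 << f
            without = np.nonzero((masks & bit) == 0)[0]
            out[r, f] = float(np.sum(w[sizes[without]]
                                     * (v[without | bit] - v[without])))
    return out


def shapley_for_rows(model, background: np.ndarray,
                     X_expl: np.ndarray) -> np.ndarray:
    """Exact Shapley values for many rows; uses the binary fast path when
    the data allow it."""
    background = np.atleast_2d(np.asarray(background, dtype=float))
    X_expl = np.atleast_2d(np.asarray(X_expl, dtype=float))
    is_binary = (np.isin(background, (0.0, 1.0)).all()
                 and np.isin(X_expl, (0.0, 1.0)).all())
    if is_binary and X_expl.shape[1] <= MAX_EXACT_FEATURES:
        return _shapley_binary_batch(model, background, X_expl)
    return np.vstack([exact_shapley(model, background, x) for x in X_expl])


# ---------------------------------------------------------------------------
# reporting


@dataclass
class ShapReport:
    features: list
    mean_abs_shap: np.ndarray  # across splits, s^-1
    sd_across_splits: np.ndarray
    n_splits: int
    settings: dict = field(default_factory=dict)

    def ranking(self) -> list:
        order = np.argsort(-self.mean_abs_shap)
        return [self.features[i] for i in order]

    def as_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.mean_abs_shap)
        return pd.DataFrame({
            "feature": [self.features[i] for i in order],
            "mean_abs_shap": self.mean_abs_shap[order],
            "sd": self.sd_across_splits[order],
            "rank": np.arange(1, len(order) + 1),
        })

    def to_dict(self) -> dict:
        return {
            "n_splits": self.n_splits,
            "settings": self.settings,
            "importances": self.as_frame().to_dict(orient="records"),
        }


def importance_report(
    split_models: list,
    X,
    y,
    features: list | None = None,
    background: str = "train",
) -> ShapReport:
    """Per-feature mean |Shapley| over each split's test rows, averaged
    across splits, with across-split standard deviations.

    The interventional background for each split is its training rows
    (``background="train"``; ``"all"`` uses the full matrix).
    """
    if not split_models:
        raise ValueError("need at least one fitted split")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    d = X.shape[1]
    if features is None:
        features = FEATURES if d == len(FEATURES) else [
            f"feature_{i}" for i in range(d)]
    per_split = np.empty((len(split_models), d))
    for i, sm in enumerate(split_models):
        bg = X[sm.train_idx] if background == "train" else X
        phi = shapley_for_rows(sm.model, bg, X[sm.test_idx])
        per_split[i] = np.abs(phi).mean(axis=0)
    mean = per_split.mean(axis=0)
    sd = per_split.std(axis=0, ddof=1) if len(split_models) > 1 \
        else np.zeros(d)
    return ShapReport(list(features), mean, sd, len(split_models))


def run_attribution(
    panel: pd.DataFrame,
    n_splits: int = 100,
    train_frac: float = 0.75,
    max_depth: int = 3,
    min_leaf: int = 2,
    seed: int = 42,
    trees_per_split: int = 1,
    activity_threshold: float = 0.5,
) -> ShapReport:
    """Panel table -> feature matrix -> splits -> Shapley importance report.

    Only active variants enter the model, matching the group-comparison
    convention.
    """
    active = panel[panel["kcat"] > activity_threshold]
    X, y = feature_matrix(active)
    models = fit_forest_over_splits(
        X, y, n_splits=n_splits, train_frac=train_frac, max_depth=max_depth,
        min_leaf=min_leaf, seed=seed, trees_per_split=trees_per_split)
    report = importance_report(models, X, y, FEATURES)
    report.settings = {
        "n_splits": n_splits, "train_frac": train_frac,
        "max_depth": max_depth, "min_leaf": min_leaf, "seed": seed,
        "trees_per_split": trees_per_split, "n_rows": int(len(y)),
    }
    return report
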