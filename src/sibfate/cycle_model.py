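"""Relative cell-cycle progression model: a model tree.

The predictor of a cell's relative cycle position x in [0, 1] is a
depth-limited regression tree whose leaves hold multivariate ordinary
least-squares linear models over the six predictors (Lb, dt, dL, GR, dF, F).
Fitting is greedy top-down: at every node, each feature and each candidate
threshold (midpoints between consecutive sorted unique values) is scored by
the summed squared error of one OLS fit per child, and the best split is
taken if it improves on the node's own linear fit; recursion stops at the
depth limit or when a child would fall below the minimum leaf size.

Ties on equal error are broken deterministically (lowest feature index,
then smallest threshold).  Predictions are clipped to [0, 1].

Exposed statsmodels-style: :class:`CyclePositionModel` wraps a training
table, ``fit()`` returns a :class:`CyclePositionResults` with the tree, the
training diagnostics and a ``summary()``; ``cross_validate()`` produces a
:class:`CVReport` with pooled out-of-fold R^2, RMSE, correlation p-value
and per-decile R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

__all__ = [
    "TreeNode",
    "ModelTree",
    "CyclePositionModel",
    "CyclePositionResults",
    "CVReport",
    "fit_model_tree",
    "predict_position",
    "feature_split_counts",
    "cross_validate",
]

# tiny ridge applied to the normal equations for numerical stability; the
# relative bias is ~1e-10 and keeps degenerate (constant-feature) leaves
# well-defined instead of crashing
_RIDGE = 1e-10


@dataclass
class TreeNode:
    feature: str | None = None  # None for leaves
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    coef: np.ndarray | None = None  # leaf: linear coefficients over features
    intercept: float = 0.0
    n: int = 0
    sse: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


class ModelTree:
    """Fitted regression tree with linear models in the leaves."""

    def __init__(
        self,
        root: TreeNode,
        max_depth: int,
        min_leaf: int,
        feature_names: tuple[str, ...] = FEATURE_NAMES,
    ):
        self.root = root
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.feature_names = tuple(feature_names)

    # -- structure ---------------------------------------------------------
    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def rec(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def depth(self) -> int:
        def rec(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(rec(node.left), rec(node.right))

        return rec(self.root)

    def feature_split_counts(self) -> pd.Series:
        """Number of internal nodes splitting on each feature."""
        counts = {name: 0 for name in self.feature_names}

        def rec(node: TreeNode) -> None:
            if not node.is_leaf:
                counts[node.feature] += 1
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return pd.Series(counts, name="n_splits")

    # -- prediction --------------------------------------------------------
    def _as_matrix(self, data) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in data.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            X = data.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(data, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("missing/non-finite feature values")
        return X

    def predict(self, data, clip: bool = True) -> np.ndarray:
        """Route each row to its leaf, evaluate the leaf's linear model and
        (by default) clip the result to [0, 1]."""
        X = self._as_matrix(data)
        fidx = {name: i for i, name in enumerate(self.feature_names)}
        out = np.empty(len(X), dtype=float)

        def rec(node: TreeNode, rows: np.ndarray) -> None:
            if len(rows) == 0:
                return
            if node.is_leaf:
                out[rows] = X[rows] @ node.coef + node.intercept
                return
            go_left = X[rows, fidx[node.feature]] <= node.threshold
            rec(node.left, rows[go_left])
            rec(node.right, rows[~go_left])

        rec(self.root, np.arange(len(X)))
        if clip:
            out = np.clip(out, 0.0, 1.0)
        return out

    # -- serialization -----------------------------------------------------
    def to_text(self) -> str:
        lines = [
            "# sibfate model-tree v1",
            f"max_depth={self.max_depth}",
            f"min_leaf={self.min_leaf}",
            f"features={','.join(self.feature_names)}",
        ]

        def rec(node: TreeNode, depth: int) -> None:
            pad = "  " * depth
            if node.is_leaf:
                coefs = ",".join(format(c, ".17g") for c in node.coef)
                lines.append(
                    f"{pad}leaf n={node.n} sse={node.sse:.17g} "
                    f"intercept={node.intercept:.17g} coef={coefs}"
                )
            else:
                lines.append(
                    f"{pad}split feature={node.feature} "
                    f"threshold={node.threshold:.17g} n={node.n}"
                )
                rec(node.left, depth + 1)
                rec(node.right, depth + 1)

        rec(self.root, 0)
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "ModelTree":
        lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
        meta: dict[str, str] = {}
        i = 0
        while i < len(lines) and "=" in lines[i] and not lines[i].lstrip().startswith(
            ("split", "leaf")
        ):
            k, _, v = lines[i].partition("=")
            meta[k.strip()] = v.strip()
            i += 1
        features = tuple(meta["features"].split(","))

        def parse(i: int, depth: int) -> tuple[TreeNode, int]:
            line = lines[i]
            indent = (len(line) - len(line.lstrip())) // 2
            if indent != depth:
                raise ValueError(f"bad tree indentation at line {i}: {line!r}")
            parts = dict(
                p.split("=", 1) for p in line.strip().split()[1:] if "=" in p
            )
            if line.lstrip().startswith("leaf"):
                node = TreeNode(
                    coef=np.array([float(c) for c in parts["coef"].split(",")]),
                    intercept=float(parts["intercept"]),
                    n=int(parts["n"]),
                    sse=float(parts["sse"]),
                )
                return node, i + 1
            node = TreeNode(
                feature=parts["feature"],
                threshold=float(parts["threshold"]),
                n=int(parts["n"]),
            )
            node.left, i = parse(i + 1, depth + 1)
            node.right, i = parse(i, depth + 1)
            return node, i

        root, _ = parse(i, 0)
        return cls(root, int(meta["max_depth"]), int(meta["min_leaf"]), features)

    @classmethod
    def load(cls, path) -> "ModelTree":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_text(fh.read())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _ols(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit of y on the design matrix A (with intercept column
    already appended); returns (beta, SSE).  A tiny ridge keeps singular
    designs (constant features) well-defined."""
    S = A.T @ A
    b = A.T @ y
    lam = _RIDGE * (np.trace(S) / S.shape[0] + 1.0)
    beta = np.linalg.solve(S + lam * np.eye(S.shape[0]), b)
    resid = y - A @ beta
    return beta, float(resid @ resid)


def _best_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[int, float, float] | None:
    """Exhaustive search over features x midpoint thresholds.

    For every admissible split one OLS model is fitted per child via prefix
    sums of the normal equations; returns (feature_index, threshold,
    total_sse) of the best split, ties broken toward the lowest feature
    index and then the smallest threshold, or None when no admissible split
    exists.
    """
    n, k = X.shape
    if n < 2 * min_leaf:
        return None
    A = np.column_stack([X, np.ones(n)])
    p = k + 1
    eye = np.eye(p)
    best: tuple[int, float, float] | None = None
    for fi in range(k):
        order = np.argsort(X[:, fi], kind="stable")
        xs = X[order, fi]
        As = A[order]
        ys = y[order]
        # candidate split positions: boundaries between distinct values,
        # respecting the minimum leaf size on both sides
        pos = np.nonzero(xs[:-1] < xs[1:])[0] + 1
        pos = pos[(pos >= min_leaf) & (pos <= n - min_leaf)]
        if len(pos) == 0:
            continue
        G = np.cumsum(As[:, :, None] * As[:, None, :], axis=0)
        bvec = np.cumsum(As * ys[:, None], axis=0)
        q = np.cumsum(ys * ys)
        G_tot, b_tot, q_tot = G[-1], bvec[-1], q[-1]
        for split in pos:
            S_l, b_l, q_l = G[split - 1], bvec[split - 1], q[split - 1]
            S_r, b_r, q_r = G_tot - S_l, b_tot - b_l, q_tot - q_l
            sse = 0.0
            for S, b, qq in ((S_l, b_l, q_l), (S_r, b_r, q_r)):
                lam = _RIDGE * (np.trace(S) / p + 1.0)
                beta = np.linalg.solve(S + lam * eye, b)
                sse += max(qq - 2.0 * beta @ b + beta @ S @ beta, 0.0)
            if best is None or sse < best[2] - 1e-12:
                thr = 0.5 * (xs[split - 1] + xs[split])
                best = (fi, float(thr), float(sse))
    return best


def _grow(
    X: np.ndarray, y: np.ndarray, depth: int, max_depth: int, min_leaf: int
) -> TreeNode:
    n = len(y)
    # standardize per node: features span several orders of magnitude and
    # raw normal equations would be badly conditioned; the affine map leaves
    # both the optimal split and the SSE unchanged in exact arithmetic
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    A = np.column_stack([Z, np.ones(n)])
    beta_z, node_sse = _ols(A, y)
    coef = beta_z[:-1] / sd
    intercept = float(beta_z[-1] - np.sum(beta_z[:-1] * mu / sd))

    def leaf() -> TreeNode:
        return TreeNode(coef=coef, intercept=intercept, n=n, sse=node_sse)

    if depth >= max_depth or n < 2 * min_leaf:
        return leaf()
    found = _best_split(Z, y, min_leaf)
    # accept only a strict improvement over the node's own linear fit; the
    # tolerance refuses float-noise "improvements" on already-exact fits
    if found is None or not (found[2] < node_sse - 1e-9 * node_sse - 1e-12):
        return leaf()
    fi, thr_z, _ = found
    thr = float(thr_z * sd[fi] + mu[fi])
    mask = Z[:, fi] <= thr_z
    node = TreeNode(feature=FEATURE_NAMES[fi], threshold=thr, n=n)
    node.left = _grow(X[mask], y[mask], depth + 1, max_depth, min_leaf)
    node.right = _grow(X[~mask], y[~mask], depth + 1, max_depth, min_leaf)
    return node


def _table_to_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in (*FEATURE_NAMES, "x") if c not in table.columns]
    if missing:
        raise ValueError(f"training table lacks columns: {missing}")
    X = table.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = table["x"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training table contains missing/non-finite values")
    return X, y


def fit_model_tree(
    table: pd.DataFrame, max_depth: int = 3, min_leaf: int = 25
) -> ModelTree:
    """Fit the model tree on a training table with columns Lb, dt, dL, GR,
    dF, F and x."""
    X, y = _table_to_xy(table)
    if len(y) < 2 * min_leaf:
        if len(y) < min_leaf:
            raise ValueError(
                f"need at least min_leaf={min_leaf} rows, got {len(y)}"
            )
        # a single leaf is still well-defined
    root = _grow(X, y, 0, max_depth, min_leaf)
    return ModelTree(root, max_depth, min_leaf)


def predict_position(tree: ModelTree, fv) -> np.ndarray | float:
    """Predicted relative cycle position(s), clipped to [0, 1]."""
    from .features import FeatureVector

    if isinstance(fv, FeatureVector):
        row = np.array([[getattr(fv, name) for name in FEATURE_NAMES]])
        return float(tree.predict(row)[0])
    return tree.predict(fv)


def feature_split_counts(tree: ModelTree) -> pd.Series:
    return tree.feature_split_counts()


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Pooled out-of-fold performance of the cycle-position model.

    ``r2`` is the squared Pearson correlation between predicted and actual
    positions (the headline definition, paired with the correlation
    ``p_value``); ``r2_cod`` is the coefficient of determination
    1 - SSE/SST for reference.  ``per_decile_r2`` holds the squared Pearson
    correlation computed within each decile of the *actual* position.
    """

    r2: float
    r2_cod: float
    rmse: float
    p_value: float
    per_decile_r2: np.ndarray
    fold_assignments: np.ndarray
    predicted: np.ndarray
    actual: np.ndarray
    k: int = 10

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "r2_pearson", "value": self.r2},
            {"metric": "r2_cod", "value": self.r2_cod},
            {"metric": "rmse", "value": self.rmse},
            {"metric": "p_value", "value": self.p_value},
        ] + [
            {"metric": f"r2_decile_{i + 1}", "value": v}
            for i, v in enumerate(self.per_decile_r2)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"{self.k}-fold cross-validation (n = {len(self.actual)})",
            f"  R^2 (Pearson)  = {self.r2:.4f}",
            f"  R^2 (1-SSE/SST)= {self.r2_cod:.4f}",
            f"  RMSE           = {self.rmse:.4f}",
            f"  corr. p-value  = {self.p_value:.3e}",
            "  per-decile R^2 : "
            + " ".join(
                "nan" if not np.isfinite(v) else f"{v:.2f}" for v in self.per_decile_r2
            ),
        ]
        return "\n".join(lines)


def _decile_r2(actual: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    out = np.full(10, np.nan)
    bins = np.clip((actual * 10).astype(int), 0, 9)
    for d in range(10):
        m = bins == d
        if m.sum() >= 3 and np.std(actual[m]) > 0 and np.std(predicted[m]) > 0:
            out[d] = stats.pearsonr(actual[m], predicted[m]).statistic ** 2
    return out


def cross_validate(
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    max_depth: int = 3,
    min_leaf: int = 25,
) -> CVReport:
    """Seeded k-fold cross-validation with pooled out-of-fold predictions."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    X, y = _table_to_xy(table)
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(perm, k)):
        folds[idx] = f
    pred = np.empty(n, dtype=float)
    cols = pd.DataFrame(X, columns=list(FEATURE_NAMES)).assign(x=y)
    for f in range(k):
        test = folds == f
        tree = fit_model_tree(cols.loc[~test], max_depth=max_depth, min_leaf=min_leaf)
        pred[test] = tree.predict(X[test])
    r, p = stats.pearsonr(pred, y)
    sse = float(np.sum((pred - y) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return CVReport(
        r2=float(r**2),
        r2_cod=1.0 - sse / sst if sst > 0 else np.nan,
        rmse=math.sqrt(sse / n),
        p_value=float(p),
        per_decile_r2=_decile_r2(y, pred),
        fold_assignments=folds,
        predicted=pred,
        actual=y,
        k=k,
    )


# ---------------------------------------------------------------------------
# statsmodels-style wrapper
# ---------------------------------------------------------------------------


class CyclePositionModel:
    """Cycle-position model over a training table.

    Parameters
    ----------
    data : DataFrame with columns Lb, dt, dL, GR, dF, F and x
    max_depth, min_leaf : model-tree hyperparameters (defaults 3 and 25)
    """

    def __init__(self, data: pd.DataFrame, max_depth: int = 3, min_leaf: int = 25):
        self.data = data.reset_index(drop=True)
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        _table_to_xy(self.data)  # validate eagerly

    @classmethod
    def from_lineage(
        cls,
        ls,
        seed: int,
        n_cells: int | None = None,
        max_depth: int = 3,
        min_leaf: int = 25,
    ) -> "CyclePositionModel":
        """Build the training table from an unstressed lineage set
        (see :func:`sibfate.features.build_training_set`)."""
        from .features import build_training_set

        table = build_training_set(ls, seed=seed, n_cells=n_cells)
        return cls(table, max_depth=max_depth, min_leaf=min_leaf)

    def fit(self) -> "CyclePositionResults":
        tree = fit_model_tree(self.data, self.max_depth, self.min_leaf)
        return CyclePositionResults(self, tree)

    def cross_validate(self, k: int = 10, seed: int = 0) -> CVReport:
        return cross_validate(
            self.data, k=k, seed=seed, max_depth=self.max_depth, min_leaf=self.min_leaf
        )


class CyclePositionResults:
    """Fitted cycle-position model."""

    def __init__(self, model: CyclePositionModel, tree: ModelTree):
        self.model = model
        self.tree = tree
        X, y = _table_to_xy(model.data)
        self.fittedvalues = tree.predict(X)
        self.actual = y
        r, p = stats.pearsonr(self.fittedvalues, y) if len(y) > 2 else (np.nan, np.nan)
        self.rsquared = float(r**2)
        self.pvalue = float(p)
        sst = float(np.sum((y - y.mean()) ** 2))
        self.rsquared_cod = (
            1.0 - float(np.sum((self.fittedvalues - y) ** 2)) / sst if sst > 0 else np.nan
        )
        self.rmse = float(np.sqrt(np.mean((self.fittedvalues - y) ** 2)))

    def predict(self, data) -> np.ndarray:
        return self.tree.predict(data)

    def feature_split_counts(self) -> pd.Series:
        return self.tree.feature_split_counts()

    def summary(self) -> str:
        counts = self.feature_split_counts()
        lines = [
            "Relative cell-cycle progression model tree",
            "=" * 46,
            f"n obs            : {len(self.actual)}",
            f"max depth        : {self.tree.max_depth}"
            f"   (fitted depth {self.tree.depth})",
            f"min cells / leaf : {self.tree.min_leaf}",
            f"leaves (linear models): {self.tree.n_leaves}",
            f"training R^2 (Pearson): {self.rsquared:.4f}",
            f"training RMSE    : {self.rmse:.4f}",
            "splits per feature: "
            + ", ".join(f"{k}={v}" for k, v in counts.items() if v > 0),
        ]
        return "\n".join(lines)
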