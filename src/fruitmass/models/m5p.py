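"""M5-style model tree: variance-reduction splits, linear leaves, pruning.

Growth chooses the (attribute, threshold) split maximizing the reduction in
the standard deviation of the response, stopping when a node's response SD
falls below 5% of the root SD or the node is too small. Each node carries a
linear model over (L, D); pruning collapses a subtree whenever the node
model's compensated error (factor (n+p)/(n-p)) does not exceed the subtree's.
Optional smoothing blends leaf predictions with ancestor models using the
classic (n*p_child + k*p_node)/(n + k) rule with k = 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from fruitmass.errors import FitError
from fruitmass.models.forms import records_to_arrays

_ATTR_NAMES = ("L", "D")
_SD_FRACTION = 0.05
_SMOOTHING_K = 15.0
_BIG = 1e18


@dataclass
class _LinearModel:
    coef: np.ndarray  # (3,): intercept, L slope, D slope

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.coef[0] + X @ self.coef[1:]

    @property
    def n_params(self) -> int:
        return int(self.coef.size)


def _fit_linear(X: np.ndarray, y: np.ndarray) -> _LinearModel:
    A = np.column_stack([np.ones(X.shape[0]), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return _LinearModel(coef=coef)


@dataclass
class _Node:
    n: int
    model: _LinearModel
    attr: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["_Node"] = None
    right: Optional["_Node"] = None
    est_err: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.attr is None


def _best_split(X: np.ndarray, y: np.ndarray, min_instances: int):
    """Maximum-SD-reduction split; returns (attr, threshold, sdr) or None."""
    n = y.size
    sd_all = float(np.std(y))
    best = None
    for attr in range(X.shape[1]):
        order = np.argsort(X[:, attr], kind="stable")
        vals = X[order, attr]
        ys = y[order]
        cum1 = np.cumsum(ys)
        cum2 = np.cumsum(ys**2)
        tot1, tot2 = cum1[-1], cum2[-1]
        i = np.arange(1, n)  # left block size
        valid = (vals[1:] > vals[:-1]) & (i >= min_instances) & (n - i >= min_instances)
        if not valid.any():
            continue
        i = i[valid]
        l1, l2 = cum1[i - 1], cum2[i - 1]
        r1, r2 = tot1 - l1, tot2 - l2
        var_l = np.maximum(l2 / i - (l1 / i) ** 2, 0.0)
        var_r = np.maximum(r2 / (n - i) - (r1 / (n - i)) ** 2, 0.0)
        sdr = sd_all - (i / n) * np.sqrt(var_l) - ((n - i) / n) * np.sqrt(var_r)
        j = int(np.argmax(sdr))
        if best is None or sdr[j] > best[2]:
            pos = i[j]
            thr = 0.5 * (vals[pos - 1] + vals[pos])
            best = (attr, float(thr), float(sdr[j]))
    return best


def _grow(X, y, root_sd, min_instances) -> _Node:
    node = _Node(n=y.size, model=_fit_linear(X, y))
    if y.size < 2 * min_instances or np.std(y) < _SD_FRACTION * root_sd:
        return node
    split = _best_split(X, y, min_instances)
    if split is None or split[2] <= 0:
        return node
    attr, thr, _ = split
    sel = X[:, attr] < thr
    node.attr, node.threshold = attr, thr
    node.left = _grow(X[sel], y[sel], root_sd, min_instances)
    node.right = _grow(X[~sel], y[~sel], root_sd, min_instances)
    return node


def _compensated_error(model: _LinearModel, X, y) -> float:
    n, p = y.size, model.n_params
    mae = float(np.mean(np.abs(y - model.predict(X))))
    if n <= p:
        return mae * _BIG if mae > 0 else 0.0
    return mae * (n + p) / (n - p)


def _prune(node: _Node, X, y) -> None:
    model_err = _compensated_error(node.model, X, y)
    if node.is_leaf:
        node.est_err = model_err
        return
    sel = X[:, node.attr] < node.threshold
    _prune(node.left, X[sel], y[sel])
    _prune(node.right, X[~sel], y[~sel])
    subtree_err = (
        node.left.n * node.left.est_err + node.right.n * node.right.est_err
    ) / node.n
    if model_err <= subtree_err + 1e-12:
        node.attr = node.threshold = node.left = node.right = None
        node.est_err = model_err
    else:
        node.est_err = subtree_err


@dataclass
class ModelTree:
    """A pruned M5-style model tree over (L, D)."""

    root: _Node
    min_instances: int = 4
    smoothing: bool = True
    smoothing_k: float = _SMOOTHING_K

    def _predict_one(self, node: _Node, x: np.ndarray, smooth: bool) -> float:
        if node.is_leaf:
            return float(node.model.predict(x[None, :])[0])
        child = node.left if x[node.attr] < node.threshold else node.right
        p = self._predict_one(child, x, smooth)
        if smooth:
            p_node = float(node.model.predict(x[None, :])[0])
            p = (child.n * p + self.smoothing_k * p_node) / (child.n + self.smoothing_k)
        return p

    def predict(self, L, D, smoothed: Optional[bool] = None):
        smooth = self.smoothing if smoothed is None else smoothed
        X = np.column_stack(
            [np.asarray(L, dtype=float).ravel(), np.asarray(D, dtype=float).ravel()]
        )
        out = np.array([self._predict_one(self.root, x, smooth) for x in X])
        return out if out.size > 1 else float(out[0])

    @property
    def n_leaves(self) -> int:
        def count(node):
            return 1 if node.is_leaf else count(node.left) + count(node.right)

        return count(self.root)

    @property
    def label(self) -> str:
        return "M5P Tree"

    def describe(self) -> str:
        """Human-readable tree structure."""
        lines = []

        def walk(node, indent):
            pad = "  " * indent
            if node.is_leaf:
                c = node.model.coef
                lines.append(
                    f"{pad}leaf(n={node.n}): FW = {c[0]:.4f} + {c[1]:.4f} L + {c[2]:.4f} D"
                )
            else:
                lines.append(f"{pad}{_ATTR_NAMES[node.attr]} < {node.threshold:.3f} ?")
                walk(node.left, indent + 1)
                walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def fit_m5p(records, min_instances: int = 4, smoothing: bool = True) -> ModelTree:
    """Grow and prune an M5-style model tree on a cohort."""
    L, D, FW = records_to_arrays(records)
    if FW is None:
        raise FitError("records lack a weight_g column")
    if L.size < 2 * min_instances:
        raise FitError(f"need at least {2 * min_instances} records")
    X = np.column_stack([L, D])
    root_sd = float(np.std(FW))
    root = _grow(X, FW, root_sd, min_instances)
    _prune(root, X, FW)
    return ModelTree(root=root, min_instances=min_instances, smoothing=smoothing)
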