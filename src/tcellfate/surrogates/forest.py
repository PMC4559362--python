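"""Random forest regression (CART) with bootstrap aggregation and OOB error.

One forest is grown per output readout.  Each tree is fit on a bootstrap
sample of the training rows; at every node ``mtry`` features are drawn
without replacement and the split maximizing the decrease in within-node
sum of squares is taken, with candidate thresholds at midpoints between
consecutive distinct sorted feature values.  Ties break toward the lowest
feature index, then the smallest threshold.  Leaves store the mean target
of their training rows, so predictions are convex combinations of training
targets.
"""

from __future__ import annotations

import numpy as np

from ..dataset import SampleTable
from .base import NotFittedError, Surrogate, SurrogateError

__all__ = ["RFSurrogate", "OOBUndefinedError", "fit_rf"]

_N_FEATURES = 4


class OOBUndefinedError(SurrogateError):
    """Out-of-bag error requested but bootstrap sampling was disabled."""


class _Node:
    __slots__ = ("feature", "threshold", "left", "right", "value")

    def __init__(self, value: float):
        self.feature: int | None = None
        self.threshold = 0.0
        self.left: "_Node | None" = None
        self.right: "_Node | None" = None
        self.value = value


def _best_split(
    X: np.ndarray, y: np.ndarray, features: np.ndarray
) -> tuple[int, float, float] | None:
    """Best (feature, threshold, sse_decrease) over the candidate features."""
    m = len(y)
    total1 = y.sum()
    total2 = (y * y).sum()
    parent_sse = total2 - total1 * total1 / m
    best: tuple[int, float, float] | None = None
    for f in np.sort(features):
        xs = X[:, f]
        order = np.argsort(xs, kind="stable")
        xs_sorted = xs[order]
        ys_sorted = y[order]
        boundary = xs_sorted[:-1] < xs_sorted[1:]
        if not boundary.any():
            continue
        c1 = np.cumsum(ys_sorted)[:-1]
        c2 = np.cumsum(ys_sorted * ys_sorted)[:-1]
        k = np.arange(1, m)
        sse_left = c2 - c1 * c1 / k
        sse_right = (total2 - c2) - (total1 - c1) ** 2 / (m - k)
        score = parent_sse - (sse_left + sse_right)
        score[~boundary] = -np.inf
        pos = int(np.argmax(score))  # first max -> smallest threshold
        if score[pos] > -np.inf and (best is None or score[pos] > best[2]):
            threshold = 0.5 * (xs_sorted[pos] + xs_sorted[pos + 1])
            best = (int(f), float(threshold), float(score[pos]))
    return best


def _build_tree(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    mtry: int,
    min_node_size: int,
) -> _Node:
    node = _Node(float(y.mean()))
    m = len(y)
    if m < min_node_size or np.all(y == y[0]):
        return node
    features = rng.choice(_N_FEATURES, size=mtry, replace=False)
    found = _best_split(X, y, features)
    if found is None or found[2] <= 1e-14:
        return node
    feature, threshold, _ = found
    mask = X[:, feature] <= threshold
    node.feature = feature
    node.threshold = threshold
    node.left = _build_tree(X[mask], y[mask], rng, mtry, min_node_size)
    node.right = _build_tree(X[~mask], y[~mask], rng, mtry, min_node_size)
    return node


def _predict_tree(root: _Node, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    stack = [(root, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0:
            continue
        if node.feature is None:
            out[idx] = node.value
        else:
            mask = X[idx, node.feature] <= node.threshold
            stack.append((node.left, idx[mask]))
            stack.append((node.right, idx[~mask]))
    return out


def _node_to_dict(node: _Node) -> dict:
    if node.feature is None:
        return {"value": node.value}
    return {
        "value": node.value,
        "feature": node.feature,
        "threshold": node.threshold,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(data: dict) -> _Node:
    node = _Node(float(data["value"]))
    if "feature" in data:
        node.feature = int(data["feature"])
        node.threshold = float(data["threshold"])
        node.left = _node_from_dict(data["left"])
        node.right = _node_from_dict(data["right"])
    return node


class RFSurrogate(Surrogate):
    """Per-output random forests with shared hyperparameters."""

    method_name = "rf"

    def __init__(
        self,
        ntree: int = 1000,
        mtry: int = 4,
        min_node_size: int = 5,
        seed: int = 0,
        bootstrap: bool = True,
    ) -> None:
        if ntree < 1:
            raise SurrogateError(f"ntree must be >= 1, got {ntree}")
        if not 1 <= mtry <= _N_FEATURES:
            raise SurrogateError(f"mtry must be in [1, {_N_FEATURES}], got {mtry}")
        if min_node_size < 1:
            raise SurrogateError(f"min_node_size must be >= 1, got {min_node_size}")
        self.ntree = int(ntree)
        self.mtry = int(mtry)
        self.min_node_size = int(min_node_size)
        self.seed = int(seed)
        self.bootstrap = bool(bootstrap)
        self.forests_: list[list[_Node]] | None = None  # [output][tree]
        self.bootstrap_indices_: list[list[np.ndarray]] | None = None
        self.train_X_: np.ndarray | None = None
        self.train_Y_: np.ndarray | None = None

    def fit(self, train: SampleTable) -> "RFSurrogate":
        X, Y = train.inputs, train.outputs
        n, n_out = X.shape[0], Y.shape[1]
        rng = np.random.default_rng(self.seed)
        self.forests_ = []
        self.bootstrap_indices_ = []
        for o in range(n_out):
            trees: list[_Node] = []
            indices: list[np.ndarray] = []
            for _ in range(self.ntree):
                idx = rng.integers(0, n, size=n) if self.bootstrap else np.arange(n)
                trees.append(
                    _build_tree(X[idx], Y[idx, o], rng, self.mtry, self.min_node_size)
                )
                indices.append(idx)
            self.forests_.append(trees)
            self.bootstrap_indices_.append(indices)
        self.train_X_ = X.copy()
        self.train_Y_ = Y.copy()
        return self

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        if self.forests_ is None:
            raise NotFittedError("RFSurrogate is not fitted")
        X = self._check_X(X)
        out = np.zeros((X.shape[0], len(self.forests_)))
        for o, trees in enumerate(self.forests_):
            acc = np.zeros(X.shape[0])
            for tree in trees:
                acc += _predict_tree(tree, X)
            out[:, o] = acc / len(trees)
        return out

    # -- out-of-bag machinery ---------------------------------------------

    def _oob_masks(self, n: int, output: int) -> list[np.ndarray]:
        masks = []
        for idx in self.bootstrap_indices_[output]:
            mask = np.ones(n, dtype=bool)
            mask[idx] = False
            masks.append(mask)
        return masks

    def per_tree_oob_fraction(self) -> float:
        """Mean fraction of training rows left out of a tree's bootstrap.

        Expected value ``(1 - 1/n)^n`` (about 0.366 at n = 100).
        """
        if self.forests_ is None:
            raise NotFittedError("RFSurrogate is not fitted")
        if not self.bootstrap:
            raise OOBUndefinedError("OOB quantities require bootstrap sampling")
        n = self.train_X_.shape[0]
        fractions = [
            mask.mean()
            for o in range(len(self.forests_))
            for mask in self._oob_masks(n, o)
        ]
        return float(np.mean(fractions))

    def oob_error(self) -> tuple[np.ndarray, int]:
        """Per-output OOB mean squared error and the count of never-OOB rows.

        Each row is predicted by averaging only the trees whose bootstrap
        excluded it; rows in every bootstrap are skipped and counted.
        """
        if self.forests_ is None:
            raise NotFittedError("RFSurrogate is not fitted")
        if not self.bootstrap:
            raise OOBUndefinedError("OOB error is undefined without bootstrap sampling")
        n, n_out = self.train_Y_.shape
        mse = np.zeros(n_out)
        never_oob = 0
        for o, trees in enumerate(self.forests_):
            sums = np.zeros(n)
            counts = np.zeros(n)
            for tree, mask in zip(trees, self._oob_masks(n, o)):
                if not mask.any():
                    continue
                sums[mask] += _predict_tree(tree, self.train_X_[mask])
                counts[mask] += 1
            covered = counts > 0
            if not covered.any():
                raise OOBUndefinedError("no training row was ever out-of-bag")
            if o == 0:
                never_oob = int(np.sum(~covered))
            preds = sums[covered] / counts[covered]
            mse[o] = float(np.mean((preds - self.train_Y_[covered, o]) ** 2))
        return mse, never_oob

    def _state_dict(self) -> dict:
        if self.forests_ is None:
            raise NotFittedError("cannot serialize an unfitted RFSurrogate")
        return {
            "ntree": self.ntree,
            "mtry": self.mtry,
            "min_node_size": self.min_node_size,
            "seed": self.seed,
            "bootstrap": self.bootstrap,
            "forests": [[_node_to_dict(t) for t in trees] for trees in self.forests_],
            "bootstrap_indices": [
                [idx.tolist() for idx in per_out] for per_out in self.bootstrap_indices_
            ],
            "train_X": self.train_X_.tolist(),
            "train_Y": self.train_Y_.tolist(),
        }

    def _load_state(self, state: dict) -> None:
        self.ntree = int(state["ntree"])
        self.mtry = int(state["mtry"])
        self.min_node_size = int(state["min_node_size"])
        self.seed = int(state["seed"])
        self.bootstrap = bool(state["bootstrap"])
        self.forests_ = [[_node_from_dict(t) for t in trees] for trees in state["forests"]]
        self.bootstrap_indices_ = [
            [np.asarray(idx, dtype=int) for idx in per_out]
            for per_out in state["bootstrap_indices"]
        ]
        self.train_X_ = np.asarray(state["train_X"], dtype=float)
        self.train_Y_ = np.asarray(state["train_Y"], dtype=float)


def fit_rf(
    train: SampleTable,
    ntree: int = 1000,
    mtry: int = 4,
    min_node_size: int = 5,
    seed: int = 0,
    bootstrap: bool = True,
) -> RFSurrogate:
    """Fit the random forest surrogate on ``train``."""
    return RFSurrogate(ntree, mtry, min_node_size, seed, bootstrap).fit(train)
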