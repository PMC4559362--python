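"""Per-output ε-insensitive support vector regression with an RBF kernel.

The dual problem is solved by sequential minimal optimization over the
extended 2n-variable formulation (α, α*), choosing a maximal-violating pair
each iteration and solving the two-variable subproblem in closed form,
until the KKT gap drops below ``kkt_tol``.  One independent machine is
trained per output readout.

The baseline kernel width for d-dimensional inputs is ``gamma = 1/d``
(0.25 for the four-cytokine milieu).
"""

from __future__ import annotations

import numpy as np

from ..dataset import SampleTable
from .base import NotFittedError, Surrogate, SurrogateError

__all__ = ["SVRSurrogate", "SVRConvergenceError", "baseline_gamma", "fit_svr", "rbf_kernel"]


class SVRConvergenceError(SurrogateError):
    """SMO hit the iteration cap with the KKT gap above tolerance."""

    def __init__(self, violation: float, max_iter: int):
        self.violation = violation
        super().__init__(
            f"SMO did not converge within {max_iter} iterations (KKT gap {violation:.3e})"
        )


def baseline_gamma(n_features: int = 4) -> float:
    """Conventional default RBF width: the inverse of the input dimension."""
    if n_features < 1:
        raise SurrogateError("n_features must be >= 1")
    return 1.0 / n_features


def rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """``exp(-gamma * ||a - b||^2)`` for all row pairs."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    sq = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    return np.exp(-gamma * np.maximum(sq, 0.0))


def _smo(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    epsilon: float,
    kkt_tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, list[float]]:
    """Solve one ε-SVR dual; returns (beta = α - α*, bias, objective path).

    The extended variables are z = (α, α*) in [0, C]^{2n} with signs
    s = (+1, -1) and the equality constraint Σ s_i z_i = 0.  The recorded
    path is the dual objective in maximization form, which is non-decreasing
    across iterations.
    """
    n = len(y)
    s = np.concatenate([np.ones(n), -np.ones(n)])
    p = np.concatenate([epsilon - y, epsilon + y])
    z = np.zeros(2 * n)
    G = p.copy()  # gradient of the minimization objective at z = 0
    eps_box = 1e-12 * max(C, 1.0)
    objective_path: list[float] = []

    def dual_objective() -> float:
        # minimization objective is 0.5 z^T Q z + p^T z = 0.5 z^T (G + p)
        return -0.5 * float(z @ (G + p))

    violation = np.inf
    it = 0
    while it < max_iter:
        msg = -s * G
        up = ((s > 0) & (z < C - eps_box)) | ((s < 0) & (z > eps_box))
        low = ((s > 0) & (z > eps_box)) | ((s < 0) & (z < C - eps_box))
        if not up.any() or not low.any():  # pragma: no cover - C > 0 keeps both nonempty
            violation = 0.0
            break
        i = int(np.flatnonzero(up)[np.argmax(msg[up])])
        j = int(np.flatnonzero(low)[np.argmin(msg[low])])
        m_up, m_low = msg[i], msg[j]
        violation = m_up - m_low
        if violation < kkt_tol:
            break
        ii, jj = i % n, j % n
        curvature = max(K[ii, ii] + K[jj, jj] - 2.0 * K[ii, jj], 1e-12)
        t = (m_up - m_low) / curvature  # unconstrained optimum, > 0
        # box limits: z_i moves by +s_i t, z_j by -s_j t
        hi_i = C - z[i] if s[i] > 0 else z[i]
        hi_j = z[j] if s[j] > 0 else C - z[j]
        t = min(t, hi_i, hi_j)
        if t <= 0.0:  # pragma: no cover - violating pair always admits t > 0
            break
        z[i] += s[i] * t
        z[j] -= s[j] * t
        dcol = K[:, ii] - K[:, jj]
        G += t * s * np.concatenate([dcol, dcol])
        it += 1
        if it % 100 == 0:
            objective_path.append(dual_objective())
    else:
        raise SVRConvergenceError(violation, max_iter)
    objective_path.append(dual_objective())

    msg = -s * G
    free = (z > eps_box) & (z < C - eps_box)
    if free.any():
        bias = float(np.mean(msg[free]))
    else:
        up = ((s > 0) & (z < C - eps_box)) | ((s < 0) & (z > eps_box))
        low = ((s > 0) & (z > eps_box)) | ((s < 0) & (z < C - eps_box))
        hi = np.max(msg[up]) if up.any() else 0.0
        lo = np.min(msg[low]) if low.any() else 0.0
        bias = 0.5 * float(hi + lo)
    beta = z[:n] - z[n:]
    return beta, bias, objective_path


class SVRSurrogate(Surrogate):
    """Five independent ε-SVR machines sharing gamma, C and epsilon."""

    method_name = "svr"

    def __init__(
        self,
        gamma: float | None = None,
        C: float = 1.0,
        epsilon: float = 0.1,
        kkt_tol: float = 1e-3,
        max_iter: int = 500_000,
    ) -> None:
        if gamma is not None and gamma <= 0.0:
            raise SurrogateError(f"gamma must be > 0, got {gamma}")
        if C <= 0.0:
            raise SurrogateError(f"C must be > 0, got {C}")
        if epsilon < 0.0:
            raise SurrogateError(f"epsilon must be >= 0, got {epsilon}")
        self.gamma = gamma  # None -> baseline 1/n_features at fit time
        self.C = float(C)
        self.epsilon = float(epsilon)
        self.kkt_tol = float(kkt_tol)
        self.max_iter = int(max_iter)
        self.support_: np.ndarray | None = None
        self.dual_coef_: np.ndarray | None = None  # (5, n): α - α* per output
        self.bias_: np.ndarray | None = None
        self.gamma_: float | None = None
        self.dual_objective_paths_: list[list[float]] = []

    def fit(self, train: SampleTable) -> "SVRSurrogate":
        X, Y = train.inputs, train.outputs
        self.gamma_ = self.gamma if self.gamma is not None else baseline_gamma(X.shape[1])
        K = rbf_kernel(X, X, self.gamma_)
        n_out = Y.shape[1]
        self.support_ = X.copy()
        self.dual_coef_ = np.zeros((n_out, X.shape[0]))
        self.bias_ = np.zeros(n_out)
        self.dual_objective_paths_ = []
        for o in range(n_out):
            beta, bias, path = _smo(
                K, Y[:, o], self.C, self.epsilon, self.kkt_tol, self.max_iter
            )
            self.dual_coef_[o] = beta
            self.bias_[o] = bias
            self.dual_objective_paths_.append(path)
        return self

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        if self.dual_coef_ is None:
            raise NotFittedError("SVRSurrogate is not fitted")
        X = self._check_X(X)
        if self.support_.shape[0] == 0:
            return np.tile(self.bias_, (X.shape[0], 1))
        Kx = rbf_kernel(X, self.support_, self.gamma_)
        return Kx @ self.dual_coef_.T + self.bias_

    def _state_dict(self) -> dict:
        if self.dual_coef_ is None:
            raise NotFittedError("cannot serialize an unfitted SVRSurrogate")
        return {
            "gamma": self.gamma_,
            "C": self.C,
            "epsilon": self.epsilon,
            "kkt_tol": self.kkt_tol,
            "max_iter": self.max_iter,
            "support": self.support_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "bias": self.bias_.tolist(),
        }

    def _load_state(self, state: dict) -> None:
        self.gamma = self.gamma_ = float(state["gamma"])
        self.C = float(state["C"])
        self.epsilon = float(state["epsilon"])
        self.kkt_tol = float(state["kkt_tol"])
        self.max_iter = int(state["max_iter"])
        self.support_ = np.asarray(state["support"], dtype=float)
        self.dual_coef_ = np.asarray(state["dual_coef"], dtype=float)
        self.bias_ = np.asarray(state["bias"], dtype=float)


def fit_svr(
    train: SampleTable,
    gamma: float | None = None,
    C: float = 1.0,
    epsilon: float = 0.1,
) -> SVRSurrogate:
    """Fit the ε-SVR surrogate; ``gamma=None`` uses the 1/d baseline width."""
    return SVRSurrogate(gamma=gamma, C=C, epsilon=epsilon).fit(train)
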