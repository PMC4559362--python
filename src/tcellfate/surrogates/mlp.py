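"""Feed-forward neural network (4 -> hidden -> 5) trained by back-propagation.

Logistic activations on both the hidden and the output layer (the targets
are normalized to [0, 1]), loss SSE/2, full-batch gradient descent with a
bold-driver step-size schedule: a step that lowers the loss is accepted and
the rate grown slightly; a step that raises it is rejected and the rate
halved.  This keeps plain back-propagation stable without minibatching or
momentum and guarantees the final SSE never exceeds the initial one.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from ..dataset import SampleTable
from .base import NotFittedError, Surrogate, SurrogateError

__all__ = ["MLPSurrogate", "TrainingDivergedError", "fit_mlp", "mlp_sse_and_gradients"]

_N_IN, _N_OUT = 4, 5


class TrainingDivergedError(SurrogateError):
    """SSE became non-finite during training."""


def _forward(X: np.ndarray, W1, b1, W2, b2) -> tuple[np.ndarray, np.ndarray]:
    H = expit(X @ W1 + b1)
    O = expit(H @ W2 + b2)
    return H, O


def mlp_sse_and_gradients(
    X: np.ndarray, Y: np.ndarray, W1: np.ndarray, b1: np.ndarray, W2: np.ndarray, b2: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Back-propagated gradients of SSE/2 for the two-layer logistic network.

    Exposed separately so the analytic gradient can be checked against
    finite differences.
    """
    H, O = _forward(X, W1, b1, W2, b2)
    E = O - Y
    sse = 0.5 * float(np.sum(E * E))
    dO = E * O * (1.0 - O)
    dH = (dO @ W2.T) * H * (1.0 - H)
    grads = {
        "W1": X.T @ dH,
        "b1": dH.sum(axis=0),
        "W2": H.T @ dO,
        "b2": dO.sum(axis=0),
    }
    return sse, grads


class MLPSurrogate(Surrogate):
    """Jointly multi-output multilayer perceptron surrogate."""

    method_name = "mlp"

    def __init__(
        self,
        hidden_size: int = 7,
        learning_rate: float = 0.1,
        max_epochs: int = 50_000,
        tol: float = 1e-8,
        seed: int = 0,
        adapt_lr: bool = True,
    ) -> None:
        if hidden_size < 1:
            raise SurrogateError(f"hidden_size must be >= 1, got {hidden_size}")
        if learning_rate < 0.0:
            raise SurrogateError(f"learning_rate must be >= 0, got {learning_rate}")
        self.hidden_size = int(hidden_size)
        self.learning_rate = float(learning_rate)
        self.max_epochs = int(max_epochs)
        self.tol = float(tol)
        self.seed = int(seed)
        self.adapt_lr = bool(adapt_lr)
        self.W1: np.ndarray | None = None
        self.b1: np.ndarray | None = None
        self.W2: np.ndarray | None = None
        self.b2: np.ndarray | None = None
        self.epochs_run: int = 0
        self.initial_sse: float | None = None
        self.final_sse: float | None = None

    def init_weights(self) -> None:
        """Draw all weights and biases from Uniform(-0.5, 0.5) with the seed."""
        rng = np.random.default_rng(self.seed)
        h = self.hidden_size
        self.W1 = rng.uniform(-0.5, 0.5, size=(_N_IN, h))
        self.b1 = rng.uniform(-0.5, 0.5, size=h)
        self.W2 = rng.uniform(-0.5, 0.5, size=(h, _N_OUT))
        self.b2 = rng.uniform(-0.5, 0.5, size=_N_OUT)

    def fit(self, train: SampleTable) -> "MLPSurrogate":
        X, Y = train.inputs, train.outputs
        # Logistic outputs live in (0, 1); targets must be on that scale.
        # A 10% margin accommodates relative output noise on normalized data.
        if np.any(Y < 0.0) or np.any(Y > 1.1):
            raise SurrogateError(
                "MLP targets must lie in [0, 1] (up to relative noise); "
                "normalize the table before fitting"
            )
        self.init_weights()
        params = [self.W1, self.b1, self.W2, self.b2]
        names = ["W1", "b1", "W2", "b2"]
        sse, grads = mlp_sse_and_gradients(X, Y, *params)
        self.initial_sse = sse
        lr = self.learning_rate
        epoch = 0
        while epoch < self.max_epochs:
            epoch += 1
            proposal = [p - lr * grads[n] for p, n in zip(params, names)]
            new_sse, new_grads = mlp_sse_and_gradients(X, Y, *proposal)
            if not np.isfinite(new_sse):
                if not self.adapt_lr:
                    raise TrainingDivergedError(
                        f"SSE diverged at epoch {epoch} with learning rate {lr:g}"
                    )
                lr *= 0.5
                if lr < 1e-300:
                    raise TrainingDivergedError(
                        f"learning rate underflowed while recovering from divergence (epoch {epoch})"
                    )
                continue
            if new_sse <= sse or not self.adapt_lr:
                delta = sse - new_sse
                params, sse, grads = proposal, new_sse, new_grads
                if self.adapt_lr:
                    lr *= 1.05
                if abs(delta) < self.tol:
                    break
            else:
                lr *= 0.5
                if lr < 1e-15:
                    break
        self.W1, self.b1, self.W2, self.b2 = params
        self.epochs_run = epoch
        self.final_sse = sse
        return self

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        if self.W1 is None:
            raise NotFittedError("MLPSurrogate is not fitted")
        X = self._check_X(X)
        return _forward(X, self.W1, self.b1, self.W2, self.b2)[1]

    def _state_dict(self) -> dict:
        if self.W1 is None:
            raise NotFittedError("cannot serialize an unfitted MLPSurrogate")
        return {
            "hidden_size": self.hidden_size,
            "learning_rate": self.learning_rate,
            "max_epochs": self.max_epochs,
            "tol": self.tol,
            "seed": self.seed,
            "adapt_lr": self.adapt_lr,
            "weights": {
                "W1": self.W1.tolist(),
                "b1": self.b1.tolist(),
                "W2": self.W2.tolist(),
                "b2": self.b2.tolist(),
            },
            "epochs_run": self.epochs_run,
            "initial_sse": self.initial_sse,
            "final_sse": self.final_sse,
        }

    def _load_state(self, state: dict) -> None:
        self.hidden_size = int(state["hidden_size"])
        self.learning_rate = float(state["learning_rate"])
        self.max_epochs = int(state["max_epochs"])
        self.tol = float(state["tol"])
        self.seed = int(state["seed"])
        self.adapt_lr = bool(state["adapt_lr"])
        w = state["weights"]
        self.W1 = np.asarray(w["W1"], dtype=float)
        self.b1 = np.asarray(w["b1"], dtype=float)
        self.W2 = np.asarray(w["W2"], dtype=float)
        self.b2 = np.asarray(w["b2"], dtype=float)
        if self.W1.shape != (_N_IN, self.hidden_size) or self.W2.shape != (
            self.hidden_size,
            _N_OUT,
        ):
            raise SurrogateError("serialized MLP weight shapes are inconsistent")
        self.epochs_run = int(state.get("epochs_run", 0))
        self.initial_sse = state.get("initial_sse")
        self.final_sse = state.get("final_sse")


def fit_mlp(
    train: SampleTable,
    hidden_size: int = 7,
    learning_rate: float = 0.1,
    max_epochs: int = 50_000,
    tol: float = 1e-8,
    seed: int = 0,
) -> MLPSurrogate:
    """Fit the back-propagation MLP surrogate on ``train``."""
    return MLPSurrogate(hidden_size, learning_rate, max_epochs, tol, seed).fit(train)
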