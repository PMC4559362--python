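"""Multi-output ordinary least squares with an explicit transformation matrix.

The fitted model is summarized by a 5x5 matrix mapping the augmented input
``(1, IFNg, IL12, IL6, TGFb)`` to the outputs in the conventional report
order ``(FOXP3, IFNg_out, IL17, RORgt, Tbet)``.
"""

from __future__ import annotations

import numpy as np

from ..dataset import SampleTable
from ..kinetics import OUTPUT_NAMES
from .base import NotFittedError, Surrogate, SurrogateError

__all__ = ["EQ_OUTPUT_ORDER", "LinearSurrogate", "RankDeficientError", "fit_linear"]

#: Row order of the transformation matrix.
EQ_OUTPUT_ORDER = ("FOXP3", "IFNg_out", "IL17", "RORgt", "Tbet")

# Position of each matrix row's output within OUTPUT_NAMES.
_ROW_TO_OUTPUT = tuple(OUTPUT_NAMES.index(name) for name in EQ_OUTPUT_ORDER)


class RankDeficientError(SurrogateError):
    """The augmented training design does not have full column rank."""


class LinearSurrogate(Surrogate):
    """Joint multi-output OLS with intercept."""

    method_name = "linear"

    def __init__(self) -> None:
        self.coef_matrix: np.ndarray | None = None

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "LinearSurrogate":
        """Build a predictor from a given 5x5 transformation matrix.

        Rows follow :data:`EQ_OUTPUT_ORDER`; columns are the augmented input
        ``(1, IFNg, IL12, IL6, TGFb)``.
        """
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (5, 5) or not np.all(np.isfinite(matrix)):
            raise SurrogateError("transformation matrix must be a finite 5x5 array")
        model = cls()
        model.coef_matrix = matrix.copy()
        return model

    def fit(self, train: SampleTable) -> "LinearSurrogate":
        X = train.inputs
        Y = train.outputs
        if X.shape[0] < 5:
            raise RankDeficientError(
                f"need >= 5 training rows for a full-rank augmented design, got {X.shape[0]}"
            )
        A = np.hstack([np.ones((X.shape[0], 1)), X])
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise RankDeficientError("augmented training design is rank deficient")
        beta, *_ = np.linalg.lstsq(A, Y, rcond=None)  # (5, 5): columns per output
        matrix = np.empty((5, 5))
        for row, out_idx in enumerate(_ROW_TO_OUTPUT):
            matrix[row] = beta[:, out_idx]
        self.coef_matrix = matrix
        return self

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        if self.coef_matrix is None:
            raise NotFittedError("LinearSurrogate is not fitted")
        X = self._check_X(X)
        A = np.hstack([np.ones((X.shape[0], 1)), X])
        eq_rows = A @ self.coef_matrix.T  # columns in EQ_OUTPUT_ORDER
        out = np.empty_like(eq_rows)
        for row, out_idx in enumerate(_ROW_TO_OUTPUT):
            out[:, out_idx] = eq_rows[:, row]
        return out

    def _state_dict(self) -> dict:
        if self.coef_matrix is None:
            raise NotFittedError("cannot serialize an unfitted LinearSurrogate")
        return {"coef_matrix": self.coef_matrix.tolist(), "row_order": list(EQ_OUTPUT_ORDER)}

    def _load_state(self, state: dict) -> None:
        self.coef_matrix = np.asarray(state["coef_matrix"], dtype=float)
        if self.coef_matrix.shape != (5, 5):
            raise SurrogateError("serialized coef_matrix must be 5x5")


def fit_linear(train: SampleTable) -> LinearSurrogate:
    """Fit the OLS surrogate on ``train``."""
    return LinearSurrogate().fit(train)
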