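"""Common fit/predict contract shared by the four surrogate families.

Every surrogate learns the steady-state map from a four-cytokine milieu to
the five readouts: ``{IL17, RORgt, IFNg_out, Tbet, FOXP3} = F(IFNg, IL12,
IL6, TGFb)``.  Models are interchangeable in the evaluation harness and
serialize to versioned JSON.
"""

from __future__ import annotations

import abc
import json
from pathlib import Path
from typing import Any, ClassVar

import numpy as np

from ..dataset import SampleTable
from ..kinetics import CytokineInput, OutputPanel

__all__ = ["SurrogateError", "NotFittedError", "Surrogate", "load_surrogate"]

FORMAT_TAG = "tcellfate-surrogate/1"

_REGISTRY: dict[str, type["Surrogate"]] = {}


class SurrogateError(ValueError):
    """Invalid surrogate configuration, input, or serialized payload."""


class NotFittedError(SurrogateError):
    """predict was called before fit."""


class Surrogate(abc.ABC):
    """Abstract regression surrogate: fit on a SampleTable, predict a panel."""

    method_name: ClassVar[str] = "abstract"

    def __init_subclass__(cls, **kwargs: Any) -> None:
        super().__init_subclass__(**kwargs)
        if cls.method_name != "abstract":
            _REGISTRY[cls.method_name] = cls

    @abc.abstractmethod
    def fit(self, train: SampleTable) -> "Surrogate":
        """Train on the table and return self."""

    @abc.abstractmethod
    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Predict an (n, 5) output matrix from an (n, 4) input matrix."""

    def predict(self, cytokines: CytokineInput) -> OutputPanel:
        row = self.predict_matrix(cytokines.as_array()[None, :])[0]
        # Surrogate regression can undershoot zero; the panel is nonnegative.
        return OutputPanel.from_array(np.maximum(row, 0.0))

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise SurrogateError(f"expected an (n, 4) input matrix, got shape {X.shape}")
        return X

    # -- serialization -----------------------------------------------------

    @abc.abstractmethod
    def _state_dict(self) -> dict:
        """JSON-serializable fitted state."""

    @abc.abstractmethod
    def _load_state(self, state: dict) -> None:
        """Restore fitted state written by :meth:`_state_dict`."""

    def to_dict(self) -> dict:
        return {"format": FORMAT_TAG, "method": self.method_name, "state": self._state_dict()}

    @classmethod
    def from_dict(cls, payload: dict) -> "Surrogate":
        if payload.get("format") != FORMAT_TAG:
            raise SurrogateError(f"unsupported model format {payload.get('format')!r}")
        method = payload.get("method")
        if method not in _REGISTRY:
            raise SurrogateError(f"unknown surrogate method {method!r}")
        model = _REGISTRY[method].__new__(_REGISTRY[method])
        model.__init__()  # defaults; state overrides hyperparameters
        model._load_state(payload["state"])
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))


def load_surrogate(path: str | Path) -> Surrogate:
    """Reload any serialized surrogate, dispatching on its method tag."""
    return Surrogate.from_dict(json.loads(Path(path).read_text()))
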