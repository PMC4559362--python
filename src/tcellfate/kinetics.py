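"""Reduced kinetic model of CD4+ T helper cell differentiation.

The model tracks three master regulators (T-bet, RORγt, FOXP3) and two
secreted cytokines (IL-17, IFNγ) of a naïve CD4+ T cell exposed to a
four-cytokine milieu (IFNγ, IL-12, IL-6, TGFβ).  Production is switch-like
(Hill kinetics), loss is first-order mass action, and the three regulators
mutually repress each other, encoding the canonical differentiation rules:

* IFNγ and/or IL-12  → Th1  (T-bet up, secreted IFNγ up)
* TGFβ + IL-6        → Th17 (RORγt up, IL-17 up, FOXP3 suppressed)
* TGFβ alone         → Treg (FOXP3 up)

All five ODEs share the form ``dx/dt = v * drive(inputs, state) - delta*x``
where ``drive`` is a product of Hill activation/repression terms in [0, 1],
so every steady state is bounded by ``v/delta``.  Integration always starts
from the all-zero (naïve) state, which makes the reached steady state unique
and reproducible despite the mutual-inhibition motif.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "INPUT_NAMES",
    "OUTPUT_NAMES",
    "STATE_NAMES",
    "CytokineInput",
    "OutputPanel",
    "RegulatorState",
    "KineticParams",
    "KineticsError",
    "ConvergenceError",
    "hill_activation",
    "hill_inhibition",
    "derivatives",
    "steady_state",
    "simulate_timecourse",
    "KineticPredictor",
]

#: Input cytokine column order used across the package.
INPUT_NAMES = ("IFNg", "IL12", "IL6", "TGFb")
#: Output readout column order used across the package.
OUTPUT_NAMES = ("IL17", "RORgt", "IFNg_out", "Tbet", "FOXP3")
#: Internal ODE state order.
STATE_NAMES = ("Tbet", "RORgt", "FOXP3", "IL17", "IFNg_out")


class KineticsError(ValueError):
    """Invalid parameter or state passed to the kinetic model."""


class ConvergenceError(RuntimeError):
    """Steady-state integration did not reach the residual tolerance.

    Attributes
    ----------
    residual : float
        Max-norm of the rate vector at the integration horizon.
    t_max : float
        Horizon that was reached.
    """

    def __init__(self, residual: float, t_max: float):
        self.residual = residual
        self.t_max = t_max
        super().__init__(
            f"steady state not reached by t={t_max:g} "
            f"(max |dx/dt| = {residual:.3e})"
        )


def _check_unit_interval(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise KineticsError(f"{name} must be finite and in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class CytokineInput:
    """Normalized input cytokine milieu, each level in [0, 1]."""

    ifng: float = 0.0
    il12: float = 0.0
    il6: float = 0.0
    tgfb: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ifng", "il12", "il6", "tgfb"):
            object.__setattr__(self, name, _check_unit_interval(name, getattr(self, name)))

    def as_array(self) -> np.ndarray:
        """Levels in :data:`INPUT_NAMES` order."""
        return np.array([self.ifng, self.il12, self.il6, self.tgfb], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "CytokineInput":
        values = np.asarray(values, dtype=float)
        if values.shape != (4,):
            raise KineticsError(f"expected 4 input levels, got shape {values.shape}")
        return cls(*values)


@dataclass(frozen=True)
class OutputPanel:
    """Steady-state readouts: nonnegative, [0, 1] after dataset normalization."""

    il17: float = 0.0
    rorgt: float = 0.0
    ifng_out: float = 0.0
    tbet: float = 0.0
    foxp3: float = 0.0

    def __post_init__(self) -> None:
        for name in ("il17", "rorgt", "ifng_out", "tbet", "foxp3"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0.0:
                raise KineticsError(f"{name} must be finite and >= 0, got {v!r}")
            object.__setattr__(self, name, v)

    def as_array(self) -> np.ndarray:
        """Levels in :data:`OUTPUT_NAMES` order."""
        return np.array(
            [self.il17, self.rorgt, self.ifng_out, self.tbet, self.foxp3], dtype=float
        )

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "OutputPanel":
        values = np.asarray(values, dtype=float)
        if values.shape != (5,):
            raise KineticsError(f"expected 5 output levels, got shape {values.shape}")
        return cls(*values)


@dataclass(frozen=True)
class RegulatorState:
    """Internal model state (or a rate vector when returned by derivatives)."""

    tbet: float = 0.0
    rorgt: float = 0.0
    foxp3: float = 0.0
    il17: float = 0.0
    ifng_out: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tbet", "rorgt", "foxp3", "il17", "ifng_out"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise KineticsError(f"{name} must be finite, got {v!r}")
            object.__setattr__(self, name, v)

    def as_array(self) -> np.ndarray:
        """Components in :data:`STATE_NAMES` order."""
        return np.array(
            [self.tbet, self.rorgt, self.foxp3, self.il17, self.ifng_out], dtype=float
        )

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "RegulatorState":
        values = np.asarray(values, dtype=float)
        if values.shape != (5,):
            raise KineticsError(f"expected 5 state components, got shape {values.shape}")
        return cls(*values)


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the reduced model.

    Parameters
    ----------
    n_hill : float
        Hill coefficient shared by all sigmoidal terms (>= 1).
    k_act : float
        Half-saturation of activating edges; also of the IL-6 repression of
        FOXP3, the strongest repressive edge in the network.
    k_inh : float
        Half-saturation of the mutual repression between master regulators.
    k_sec : float
        Half-saturation of cytokine secretion driven by its master regulator.
    v, delta : float
        Maximal production rate and first-order decay rate; steady states are
        bounded by ``v / delta``.
    tol_ss : float
        Steady-state residual tolerance (max-norm of the rate vector).
    t_max : float
        Integration horizon after which non-convergence is reported.
    """

    n_hill: float = 2.0
    k_act: float = 0.25
    k_inh: float = 0.35
    k_sec: float = 0.30
    v: float = 1.0
    delta: float = 1.0
    tol_ss: float = 1e-8
    t_max: float = 200.0

    def __post_init__(self) -> None:
        if not self.n_hill >= 1.0:
            raise KineticsError(f"n_hill must be >= 1, got {self.n_hill}")
        for name in ("k_act", "k_inh", "k_sec", "v", "delta", "tol_ss", "t_max"):
            if not getattr(self, name) > 0.0:
                raise KineticsError(f"{name} must be > 0, got {getattr(self, name)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "KineticParams":
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise KineticsError(f"unknown kinetic parameters: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "KineticParams":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise KineticsError(f"parameter file {path} must contain a mapping")
        return cls.from_dict(data)


def hill_activation(x: float, k: float, n: float) -> float:
    """Sigmoidal activation ``x^n / (k^n + x^n)``; 0 at x=0, 0.5 at x=k."""
    if k <= 0.0:
        raise KineticsError(f"half-saturation k must be > 0, got {k}")
    if n < 1.0:
        raise KineticsError(f"Hill coefficient n must be >= 1, got {n}")
    if x < 0.0:
        raise KineticsError(f"level x must be >= 0, got {x}")
    if x == 0.0:
        return 0.0
    xn = x**n
    return xn / (k**n + xn)


def hill_inhibition(y: float, k: float, n: float) -> float:
    """Repression ``k^n / (k^n + y^n)`` = 1 - hill_activation(y, k, n)."""
    return 1.0 - hill_activation(y, k, n)


def _rhs(y: np.ndarray, c: np.ndarray, p: KineticParams) -> np.ndarray:
    """Rate vector for state ``y`` (STATE_NAMES order) and inputs ``c``.

    Clamps tiny negative excursions from the integrator to zero before
    evaluating the Hill terms.
    """
    y = np.maximum(y, 0.0)
    tbet, rorgt, foxp3, il17, ifng_out = y
    ifng, il12, il6, tgfb = c
    n = p.n_hill

    def act(x: float, k: float) -> float:
        if x <= 0.0:
            return 0.0
        xn = x**n
        return xn / (k**n + xn)

    def inh(x: float, k: float) -> float:
        return 1.0 - act(x, k)

    d_tbet = p.v * act(ifng + il12, p.k_act) * inh(rorgt, p.k_inh) * inh(foxp3, p.k_inh) - p.delta * tbet
    d_rorgt = p.v * act(tgfb, p.k_act) * act(il6, p.k_act) * inh(tbet, p.k_inh) * inh(foxp3, p.k_inh) - p.delta * rorgt
    d_foxp3 = p.v * act(tgfb, p.k_act) * inh(il6, p.k_act) * inh(tbet, p.k_inh) * inh(rorgt, p.k_inh) - p.delta * foxp3
    d_il17 = p.v * act(rorgt, p.k_sec) - p.delta * il17
    d_ifng = p.v * act(tbet, p.k_sec) - p.delta * ifng_out
    return np.array([d_tbet, d_rorgt, d_foxp3, d_il17, d_ifng])


def derivatives(
    state: RegulatorState, cytokines: CytokineInput, params: KineticParams | None = None
) -> RegulatorState:
    """Right-hand side of the model ODEs at ``state`` under ``cytokines``."""
    params = params or KineticParams()
    y = state.as_array()
    if np.any(y < 0.0):
        raise KineticsError("state components must be >= 0")
    return RegulatorState.from_array(_rhs(y, cytokines.as_array(), params))


def _integrate(
    y0: np.ndarray, c: np.ndarray, params: KineticParams, t_span: tuple[float, float],
    t_eval: np.ndarray | None = None,
):
    sol = solve_ivp(
        lambda _t, y: _rhs(y, c, params),
        t_span,
        y0,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
        t_eval=t_eval,
    )
    if not sol.success:  # pragma: no cover - LSODA is robust on this RHS
        raise ConvergenceError(float("nan"), t_span[1])
    return sol


def steady_state(cytokines: CytokineInput, params: KineticParams | None = None) -> OutputPanel:
    """Integrate from the naïve (all-zero) state until rates vanish.

    Returns the readouts in :data:`OUTPUT_NAMES` order.  Raises
    :class:`ConvergenceError` with the residual if ``t_max`` is reached with
    ``max |dx/dt| >= tol_ss``.
    """
    params = params or KineticParams()
    c = cytokines.as_array()
    y = np.zeros(5)
    # The origin is a fixed point whenever no production term engages.
    if np.max(np.abs(_rhs(y, c, params))) < params.tol_ss:
        return OutputPanel()
    t, segment = 0.0, 25.0
    while t < params.t_max:
        t_next = min(t + segment, params.t_max)
        sol = _integrate(y, c, params, (t, t_next))
        y = np.maximum(sol.y[:, -1], 0.0)
        t = t_next
        residual = float(np.max(np.abs(_rhs(y, c, params))))
        if residual < params.tol_ss:
            tbet, rorgt, foxp3, il17, ifng_out = y
            return OutputPanel(il17=il17, rorgt=rorgt, ifng_out=ifng_out, tbet=tbet, foxp3=foxp3)
    raise ConvergenceError(residual, params.t_max)


def simulate_timecourse(
    cytokines: CytokineInput,
    params: KineticParams | None = None,
    t_grid: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Trajectory from the all-zero state on ``t_grid`` (strictly increasing).

    Returns a DataFrame with a ``t`` column followed by :data:`STATE_NAMES`.
    """
    params = params or KineticParams()
    t_grid = np.asarray(list(t_grid) if t_grid is not None else np.linspace(0.0, params.t_max, 201), dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise KineticsError("t_grid must be a non-empty 1-D sequence")
    if t_grid[0] < 0.0 or (t_grid.size > 1 and np.any(np.diff(t_grid) <= 0.0)):
        raise KineticsError("t_grid must start >= 0 and be strictly increasing")

    y0 = np.zeros(5)
    if t_grid.size == 1 and t_grid[0] == 0.0:
        states = y0[None, :]
    else:
        sol = _integrate(
            np.zeros(5), cytokines.as_array(), params, (0.0, float(t_grid[-1])), t_eval=t_grid
        )
        states = np.maximum(sol.y.T, 0.0)
    frame = pd.DataFrame(states, columns=list(STATE_NAMES))
    frame.insert(0, "t", t_grid)
    return frame


class KineticPredictor:
    """Adapter exposing the kinetic model through the surrogate predict API.

    Useful as a mechanistic oracle in the directional validation harness.
    Predictions are on the raw (un-normalized) steady-state scale, which is a
    fixed multiple of the normalized scale per output and therefore yields
    identical directional calls.
    """

    method_name = "kinetic"

    def __init__(self, params: KineticParams | None = None):
        self.params = params or KineticParams()

    def predict(self, cytokines: CytokineInput) -> OutputPanel:
        return steady_state(cytokines, self.params)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.vstack(
            [steady_state(CytokineInput.from_array(row), self.params).as_array() for row in X]
        )
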