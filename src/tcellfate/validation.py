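"""Directional validation of trained surrogates against in vitro conditions.

Each condition pairs a stimulus milieu with a control milieu and a single
readout whose published experimental direction (up or down relative to
control) the model prediction should reproduce.  The built-in set covers
five published CD4+ T cell stimulation experiments; the two FOXP3
conditions are mutually contradictory in the literature, so no model can
match all five while remaining self-consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Protocol

import pandas as pd

from .kinetics import OUTPUT_NAMES, CytokineInput, OutputPanel

__all__ = [
    "ValidationError",
    "ValidationCondition",
    "DirectionCall",
    "builtin_conditions",
    "directional_call",
    "agreement_count",
]

DEFAULT_DIRECTION_TOL = 0.01

Direction = Literal["up", "down"]


class ValidationError(ValueError):
    """Invalid validation condition or readout."""


class PanelPredictor(Protocol):
    def predict(self, cytokines: CytokineInput) -> OutputPanel: ...


@dataclass(frozen=True)
class ValidationCondition:
    """One published stimulus/control comparison with its reported direction."""

    label: str
    stimulus: CytokineInput
    control: CytokineInput
    readout: str
    experimental_direction: Direction
    citation: str = ""

    def __post_init__(self) -> None:
        if self.readout not in OUTPUT_NAMES:
            raise ValidationError(
                f"readout must be one of {OUTPUT_NAMES}, got {self.readout!r}"
            )
        if self.experimental_direction not in ("up", "down"):
            raise ValidationError(
                f"experimental_direction must be 'up' or 'down', got {self.experimental_direction!r}"
            )
        if self.stimulus == self.control:
            raise ValidationError(f"{self.label}: stimulus equals control")


@dataclass(frozen=True)
class DirectionCall:
    """Model-predicted direction for one condition."""

    direction: Literal["up", "down", "flat"]
    predicted_stimulus: float
    predicted_control: float
    tol: float


def builtin_conditions() -> list[ValidationCondition]:
    """The five built-in published comparisons (versioned JSON fixture)."""
    payload = json.loads(
        resources.files("tcellfate").joinpath("data/validation_conditions.json").read_text()
    )
    conditions = []
    for row in payload["conditions"]:
        conditions.append(
            ValidationCondition(
                label=row["label"],
                stimulus=CytokineInput(**row["stimulus"]),
                control=CytokineInput(**row["control"]),
                readout=row["readout"],
                experimental_direction=row["experimental_direction"],
                citation=row.get("citation", ""),
            )
        )
    return conditions


def directional_call(
    model: PanelPredictor, condition: ValidationCondition, tol: float = DEFAULT_DIRECTION_TOL
) -> DirectionCall:
    """Predicted direction of the readout under stimulus vs control.

    'up' if the predicted difference exceeds ``tol``, 'down' if below
    ``-tol``, otherwise 'flat'.
    """
    if tol < 0.0:
        raise ValidationError(f"tol must be >= 0, got {tol}")
    idx = OUTPUT_NAMES.index(condition.readout)
    pred_stim = float(model.predict(condition.stimulus).as_array()[idx])
    pred_ctrl = float(model.predict(condition.control).as_array()[idx])
    diff = pred_stim - pred_ctrl
    if diff > tol:
        direction = "up"
    elif diff < -tol:
        direction = "down"
    else:
        direction = "flat"
    return DirectionCall(direction, pred_stim, pred_ctrl, tol)


def agreement_count(
    model: PanelPredictor,
    conditions: Iterable[ValidationCondition] | None = None,
    tol: float = DEFAULT_DIRECTION_TOL,
) -> tuple[int, pd.DataFrame]:
    """Count of conditions whose predicted direction matches the experiment.

    A 'flat' call never matches.  Returns the count and a per-condition
    table with predictions and both directions.
    """
    conditions = list(conditions) if conditions is not None else builtin_conditions()
    rows = []
    count = 0
    for condition in conditions:
        call = directional_call(model, condition, tol)
        match = call.direction == condition.experimental_direction
        count += int(match)
        rows.append(
            {
                "label": condition.label,
                "readout": condition.readout,
                "predicted_stimulus": call.predicted_stimulus,
                "predicted_control": call.predicted_control,
                "predicted_direction": call.direction,
                "experimental_direction": condition.experimental_direction,
                "match": match,
            }
        )
    return count, pd.DataFrame(rows)
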