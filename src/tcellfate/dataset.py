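"""Grid-scan dataset construction, normalization, noise, splitting and CSV I/O.

The training corpus is a full-factorial ("equal-distance") scan of the four
input cytokines.  With the default five levels per input (0, 0.25, 0.5,
0.75, 1) the scan has 5^4 = 625 points; each point is mapped to the model's
steady-state readouts, the outputs are min-max normalized to [0, 1] on the
full table, and a random 100/525 train/test split is drawn.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    INPUT_NAMES,
    OUTPUT_NAMES,
    CytokineInput,
    KineticParams,
    steady_state,
)

__all__ = [
    "DatasetError",
    "GridSpec",
    "SampleTable",
    "NoiseSpec",
    "generate_grid",
    "build_dataset",
    "normalize",
    "add_output_noise",
    "split",
    "read_csv",
    "write_csv",
]

DEFAULT_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


class DatasetError(ValueError):
    """Invalid dataset operation or malformed input file."""


@dataclass(frozen=True)
class GridSpec:
    """Per-input sorted level lists for the full-factorial scan."""

    levels: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {name: DEFAULT_LEVELS for name in INPUT_NAMES}
    )

    def __post_init__(self) -> None:
        if set(self.levels) != set(INPUT_NAMES):
            raise DatasetError(
                f"grid must define levels for exactly {INPUT_NAMES}, got {sorted(self.levels)}"
            )
        clean = {}
        for name in INPUT_NAMES:
            values = tuple(float(v) for v in self.levels[name])
            if not values:
                raise DatasetError(f"empty level list for {name}")
            if any(not 0.0 <= v <= 1.0 for v in values):
                raise DatasetError(f"levels for {name} must lie in [0, 1]")
            if list(values) != sorted(values):
                raise DatasetError(f"levels for {name} must be sorted ascending")
            clean[name] = values
        object.__setattr__(self, "levels", clean)

    @property
    def size(self) -> int:
        return int(np.prod([len(self.levels[name]) for name in INPUT_NAMES]))


@dataclass
class SampleTable:
    """Paired input/output matrices with normalization and provenance metadata.

    ``scaling`` maps output names to the (min, max) used for normalization;
    it is ``None`` for raw tables.  ``provenance`` records generator id,
    seeds and noise level for reproducibility.
    """

    inputs: np.ndarray
    outputs: np.ndarray
    input_names: tuple[str, ...] = INPUT_NAMES
    output_names: tuple[str, ...] = OUTPUT_NAMES
    scaling: dict[str, tuple[float, float]] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        self.input_names = tuple(self.input_names)
        self.output_names = tuple(self.output_names)
        if self.inputs.ndim != 2 or self.outputs.ndim != 2:
            raise DatasetError("input and output matrices must be 2-D")
        if self.inputs.shape[0] != self.outputs.shape[0]:
            raise DatasetError(
                f"row mismatch: {self.inputs.shape[0]} inputs vs {self.outputs.shape[0]} outputs"
            )
        if self.inputs.shape[1] != len(self.input_names):
            raise DatasetError("input width does not match input_names")
        if self.outputs.shape[1] != len(self.output_names):
            raise DatasetError("output width does not match output_names")

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        data = np.hstack([self.inputs, self.outputs])
        return pd.DataFrame(data, columns=list(self.input_names + self.output_names))

    def row_input(self, i: int) -> CytokineInput:
        return CytokineInput.from_array(self.inputs[i])


@dataclass(frozen=True)
class NoiseSpec:
    """Relative uniform output noise of half-width ``half_width`` (e.g. 0.005)."""

    half_width: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.half_width < 0.0:
            raise DatasetError(f"noise half-width must be >= 0, got {self.half_width}")


def generate_grid(spec: GridSpec | None = None) -> list[CytokineInput]:
    """Full factorial product of the per-input levels.

    Rows are in lexicographic order over (IFNγ, IL-12, IL-6, TGFβ) with the
    first input varying slowest, so the first row is the all-zero milieu and
    the last is all-ones under the default spec.
    """
    spec = spec or GridSpec()
    combos = itertools.product(*(spec.levels[name] for name in INPUT_NAMES))
    return [CytokineInput(*combo) for combo in combos]


def build_dataset(
    params: KineticParams | None = None,
    grid: Sequence[CytokineInput] | None = None,
) -> SampleTable:
    """Steady-state outputs for every grid point, on the raw model scale."""
    params = params or KineticParams()
    grid = list(grid) if grid is not None else generate_grid()
    if not grid:
        raise DatasetError("grid must be non-empty")
    inputs = np.vstack([g.as_array() for g in grid])
    outputs = np.empty((len(grid), len(OUTPUT_NAMES)))
    for i, point in enumerate(grid):
        try:
            outputs[i] = steady_state(point, params).as_array()
        except Exception as exc:
            raise DatasetError(f"steady state failed at grid row {i}: {exc}") from exc
    return SampleTable(
        inputs,
        outputs,
        provenance={"generator": "tcellfate.kinetics", "params": params.to_dict()},
    )


def normalize(table: SampleTable) -> SampleTable:
    """Min-max scale every output column to span [0, 1].

    The (min, max) pair per output is recorded in ``scaling``.  A degenerate
    (constant) column maps to all zeros.  Requires at least two rows.
    """
    if table.n_samples < 2:
        raise DatasetError("normalization requires at least 2 rows")
    mins = table.outputs.min(axis=0)
    maxs = table.outputs.max(axis=0)
    span = maxs - mins
    scaled = np.zeros_like(table.outputs)
    nondegenerate = span > 0.0
    scaled[:, nondegenerate] = (table.outputs[:, nondegenerate] - mins[nondegenerate]) / span[nondegenerate]
    scaling = {
        name: (float(mins[j]), float(maxs[j])) for j, name in enumerate(table.output_names)
    }
    provenance = dict(table.provenance)
    provenance["normalized"] = True
    return SampleTable(
        table.inputs.copy(),
        scaled,
        table.input_names,
        table.output_names,
        scaling=scaling,
        provenance=provenance,
    )


def add_output_noise(table: SampleTable, noise: NoiseSpec) -> SampleTable:
    """Multiply each output cell by ``1 + u``, ``u ~ Uniform(-a, a)`` i.i.d.

    Inputs are untouched; results are clamped at zero; the draw is fully
    determined by ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    u = rng.uniform(-noise.half_width, noise.half_width, size=table.outputs.shape)
    noisy = np.maximum(table.outputs * (1.0 + u), 0.0)
    provenance = dict(table.provenance)
    provenance.update({"noise_half_width": noise.half_width, "noise_seed": noise.seed})
    return SampleTable(
        table.inputs.copy(),
        noisy,
        table.input_names,
        table.output_names,
        scaling=None if table.scaling is None else dict(table.scaling),
        provenance=provenance,
    )


def split(table: SampleTable, n_train: int, seed: int = 0) -> tuple[SampleTable, SampleTable]:
    """Uniform random train subset of size ``n_train``; complement is test."""
    n = table.n_samples
    if not 0 < n_train < n:
        raise DatasetError(f"n_train must satisfy 0 < n_train < {n}, got {n_train}")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n, size=n_train, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True

    def _subset(keep: np.ndarray, role: str) -> SampleTable:
        provenance = dict(table.provenance)
        provenance.update({"split_seed": seed, "split_role": role, "n_train": n_train})
        return SampleTable(
            table.inputs[keep],
            table.outputs[keep],
            table.input_names,
            table.output_names,
            scaling=None if table.scaling is None else dict(table.scaling),
            provenance=provenance,
        )

    return _subset(mask, "train"), _subset(~mask, "test")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_csv(table: SampleTable, path: str | Path) -> None:
    """Write the table as CSV plus a JSON sidecar for scaling/provenance.

    Floats are written with 17 significant digits so a round-trip is
    lossless.
    """
    path = Path(path)
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
    meta = {
        "scaling": None
        if table.scaling is None
        else {k: list(v) for k, v in table.scaling.items()},
        "provenance": table.provenance,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_csv(path: str | Path) -> SampleTable:
    """Read a sample table; header must name the 4 inputs then 5 outputs."""
    path = Path(path)
    expected = list(INPUT_NAMES + OUTPUT_NAMES)
    frame = pd.read_csv(path, dtype=str)
    if list(frame.columns) != expected:
        raise DatasetError(
            f"{path}: expected columns {expected}, found {list(frame.columns)}"
        )
    numeric = pd.DataFrame(index=frame.index)
    for col in expected:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise DatasetError(
                f"{path}: non-numeric value {frame[col][row]!r} at row {row + 1}, column {col!r}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise DatasetError(f"{path}: missing value at row {row + 1}, column {col!r}")
        # Python's float() is correctly rounded, so 17-digit round-trips are
        # lossless (pandas' fast parser can be off by one ulp).
        numeric[col] = np.array([float(v) for v in frame[col]])
    scaling = None
    provenance: dict = {"source": str(path)}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("scaling") is not None:
            scaling = {k: (float(v[0]), float(v[1])) for k, v in meta["scaling"].items()}
        provenance.update(meta.get("provenance", {}))
    return SampleTable(
        numeric[list(INPUT_NAMES)].to_numpy(),
        numeric[list(OUTPUT_NAMES)].to_numpy(),
        scaling=scaling,
        provenance=provenance,
    )
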