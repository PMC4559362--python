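"""Error metrics, hyperparameter scans, noise robustness, k-fold CV, timing.

The headline hold-out metric is the per-output mean absolute error on the
test rows together with their sum over the five outputs ("sum of prediction
error").  Cross-validation reports per-output mean squared error averaged
over folds, matching the convention of using MAE for hold-out comparisons
and MSE for the 10-fold estimate.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import DatasetError, NoiseSpec, SampleTable, add_output_noise, split
from .kinetics import OUTPUT_NAMES
from .surrogates import (
    LinearSurrogate,
    MLPSurrogate,
    RFSurrogate,
    Surrogate,
    SVRSurrogate,
)

__all__ = [
    "EvaluationError",
    "ErrorReport",
    "CVReport",
    "TimingReport",
    "MethodSpec",
    "default_methods",
    "mae_per_output",
    "sum_error",
    "evaluate_surrogate",
    "scan_mlp_hidden",
    "scan_svr_gamma",
    "scan_rf",
    "kfold_partition",
    "cross_validate",
    "noise_robustness",
    "measure_runtime",
    "reports_to_frame",
]

DEFAULT_HIDDEN_SIZES = (1, 2, 4, 5, 6, 7, 8, 10, 11)
DEFAULT_GAMMAS = (0.25, 1.0, 0.1, 0.01, 0.001)
DEFAULT_NTREES = (100, 500, 1000)
DEFAULT_MTRYS = (1, 2, 3, 4)
DEFAULT_NOISE_LEVELS = (0.0, 0.005, 0.01)


class EvaluationError(ValueError):
    """Invalid evaluation request."""


@dataclass
class ErrorReport:
    """Per-output mean absolute test error and its sum."""

    method: str
    per_output_mae: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.per_output_mae = np.asarray(self.per_output_mae, dtype=float)
        if self.per_output_mae.shape != (len(OUTPUT_NAMES),):
            raise EvaluationError("per_output_mae must have one entry per output")
        if np.any(self.per_output_mae < 0.0):
            raise EvaluationError("mean absolute errors must be >= 0")

    @property
    def sum_error(self) -> float:
        return sum_error(self.per_output_mae)

    def to_row(self) -> dict:
        row = {"method": self.method}
        row.update(dict(zip(OUTPUT_NAMES, self.per_output_mae)))
        row["sum_error"] = self.sum_error
        row.update(self.provenance)
        return row


@dataclass
class CVReport:
    """k-fold cross-validation summary for one method."""

    method: str
    fold_assignment: np.ndarray  # per-sample fold index in 1..k
    per_fold_mse: np.ndarray  # (k, n_outputs)
    seed: int

    def __post_init__(self) -> None:
        self.fold_assignment = np.asarray(self.fold_assignment, dtype=int)
        self.per_fold_mse = np.asarray(self.per_fold_mse, dtype=float)

    @property
    def k(self) -> int:
        return self.per_fold_mse.shape[0]

    @property
    def per_output_avg_mse(self) -> np.ndarray:
        return self.per_fold_mse.mean(axis=0)

    def to_row(self) -> dict:
        row = {"method": self.method, "k": self.k, "seed": self.seed}
        row.update(dict(zip(OUTPUT_NAMES, self.per_output_avg_mse)))
        row["sum_avg_mse"] = float(self.per_output_avg_mse.sum())
        return row


@dataclass
class TimingReport:
    """Median wall-clock and process-time of training and prediction."""

    method: str
    train_wall: float
    train_cpu: float
    test_wall: float
    test_cpu: float
    repeats: int

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "train_wall_s": self.train_wall,
            "train_cpu_s": self.train_cpu,
            "test_wall_s": self.test_wall,
            "test_cpu_s": self.test_cpu,
            "repeats": self.repeats,
        }


@dataclass(frozen=True)
class MethodSpec:
    """Named factory producing a fresh unfitted surrogate."""

    name: str
    factory: Callable[[], Surrogate]

    def make(self) -> Surrogate:
        return self.factory()


def default_methods(
    seed: int = 0,
    hidden_size: int = 7,
    ntree: int = 1000,
    mtry: int = 4,
) -> list[MethodSpec]:
    """The four benchmark methods at their selected protocol settings."""
    return [
        MethodSpec("linear", LinearSurrogate),
        MethodSpec("mlp", lambda: MLPSurrogate(hidden_size=hidden_size, seed=seed)),
        MethodSpec("svr", SVRSurrogate),  # baseline gamma = 1/4, C=1, eps=0.1
        MethodSpec("rf", lambda: RFSurrogate(ntree=ntree, mtry=mtry, seed=seed)),
    ]


def mae_per_output(predictions: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Column-wise mean of |prediction - truth|."""
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if predictions.shape != truth.shape:
        raise EvaluationError(
            f"shape mismatch: predictions {predictions.shape} vs truth {truth.shape}"
        )
    return np.mean(np.abs(predictions - truth), axis=0)


def sum_error(per_output_values: Sequence[float]) -> float:
    """Sum of the per-output errors (the aggregate benchmark metric)."""
    values = np.asarray(per_output_values, dtype=float)
    if values.shape != (len(OUTPUT_NAMES),) or not np.all(np.isfinite(values)):
        raise EvaluationError("expected 5 finite per-output values")
    return float(values.sum())


def evaluate_surrogate(
    model: Surrogate, test: SampleTable, label: str | None = None, **provenance
) -> ErrorReport:
    """Hold-out MAE report for a fitted surrogate."""
    preds = model.predict_matrix(test.inputs)
    return ErrorReport(
        label or model.method_name,
        mae_per_output(preds, test.outputs),
        provenance=provenance,
    )


def reports_to_frame(reports: Iterable[ErrorReport | CVReport | TimingReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])


# -- hyperparameter scans --------------------------------------------------


def scan_mlp_hidden(
    train: SampleTable,
    test: SampleTable,
    sizes: Sequence[int] = DEFAULT_HIDDEN_SIZES,
    seed: int = 0,
    **mlp_kwargs,
) -> tuple[list[ErrorReport], int]:
    """Fit one MLP per hidden-layer size; select argmin sum error (ties -> smaller)."""
    if not sizes:
        raise EvaluationError("sizes must be non-empty")
    reports = []
    for size in sizes:
        model = MLPSurrogate(hidden_size=size, seed=seed, **mlp_kwargs).fit(train)
        reports.append(evaluate_surrogate(model, test, label="mlp", hidden_size=size))
    best = min(zip(sizes, reports), key=lambda item: (item[1].sum_error, item[0]))
    return reports, int(best[0])


def scan_svr_gamma(
    train: SampleTable,
    test: SampleTable,
    gammas: Sequence[float] = DEFAULT_GAMMAS,
    C: float = 1.0,
    epsilon: float = 0.1,
) -> tuple[list[ErrorReport], float]:
    """Fit one SVR per kernel width; select argmin sum error (ties -> smaller gamma)."""
    if not gammas:
        raise EvaluationError("gammas must be non-empty")
    reports = []
    for gamma in gammas:
        model = SVRSurrogate(gamma=gamma, C=C, epsilon=epsilon).fit(train)
        reports.append(evaluate_surrogate(model, test, label="svr", gamma=gamma))
    best = min(zip(gammas, reports), key=lambda item: (item[1].sum_error, item[0]))
    return reports, float(best[0])


def scan_rf(
    train: SampleTable,
    test: SampleTable,
    ntrees: Sequence[int] = DEFAULT_NTREES,
    mtrys: Sequence[int] = DEFAULT_MTRYS,
    seed: int = 0,
    min_node_size: int = 5,
) -> tuple[list[ErrorReport], tuple[int, int]]:
    """Grid-evaluate (ntree, mtry); ties -> smaller ntree, then smaller mtry."""
    if not ntrees or not mtrys:
        raise EvaluationError("ntrees and mtrys must be non-empty")
    reports = []
    keyed = []
    for ntree in ntrees:
        for mtry in mtrys:
            model = RFSurrogate(
                ntree=ntree, mtry=mtry, min_node_size=min_node_size, seed=seed
            ).fit(train)
            report = evaluate_surrogate(model, test, label="rf", ntree=ntree, mtry=mtry)
            reports.append(report)
            keyed.append(((ntree, mtry), report))
    best = min(keyed, key=lambda item: (item[1].sum_error, item[0][0], item[0][1]))
    return reports, best[0]


# -- cross-validation ------------------------------------------------------


def kfold_partition(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Seeded shuffle then contiguous chunks; fold sizes differ by at most 1.

    Returns a per-sample fold index in 1..k.  For n=625, k=10 this yields
    five folds of 63 and five of 62.
    """
    if not 2 <= k <= n:
        raise EvaluationError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    base, extra = divmod(n, k)
    start = 0
    for fold in range(1, k + 1):
        size = base + (1 if fold <= extra else 0)
        assignment[order[start : start + size]] = fold
        start += size
    return assignment


def cross_validate(
    method: MethodSpec, table: SampleTable, k: int = 10, seed: int = 0
) -> CVReport:
    """k rounds of train/evaluate; per-output MSE averaged over folds."""
    assignment = kfold_partition(table.n_samples, k, seed)
    per_fold = np.empty((k, len(OUTPUT_NAMES)))
    for fold in range(1, k + 1):
        test_mask = assignment == fold
        train_sub = SampleTable(
            table.inputs[~test_mask],
            table.outputs[~test_mask],
            table.input_names,
            table.output_names,
            scaling=table.scaling,
            provenance=dict(table.provenance),
        )
        test_sub = SampleTable(
            table.inputs[test_mask],
            table.outputs[test_mask],
            table.input_names,
            table.output_names,
            scaling=table.scaling,
            provenance=dict(table.provenance),
        )
        try:
            model = method.make().fit(train_sub)
            preds = model.predict_matrix(test_sub.inputs)
        except Exception as exc:
            raise EvaluationError(f"fold {fold} failed for {method.name}: {exc}") from exc
        per_fold[fold - 1] = np.mean((preds - test_sub.outputs) ** 2, axis=0)
    return CVReport(method.name, assignment, per_fold, seed)


# -- noise robustness ------------------------------------------------------


def noise_robustness(
    clean_normalized: SampleTable,
    methods: Sequence[MethodSpec] | None = None,
    levels: Sequence[float] = DEFAULT_NOISE_LEVELS,
    n_train: int = 100,
    split_seed: int = 0,
    noise_seed: int = 0,
) -> list[ErrorReport]:
    """Refit and re-evaluate every method at each relative noise half-width.

    Noise is injected into the full normalized table before the split, so
    both the training targets and the evaluation targets are noisy; level 0
    reproduces the noise-free benchmark exactly under the same seeds.
    """
    if 0.0 not in [float(a) for a in levels]:
        raise EvaluationError("noise levels must include 0 as the reference")
    methods = list(methods) if methods is not None else default_methods()
    reports = []
    for level in levels:
        noisy = add_output_noise(clean_normalized, NoiseSpec(float(level), seed=noise_seed))
        train, test = split(noisy, n_train, seed=split_seed)
        for method in methods:
            model = method.make().fit(train)
            reports.append(
                evaluate_surrogate(model, test, label=method.name, noise_level=float(level))
            )
    return reports


# -- runtime ---------------------------------------------------------------


def measure_runtime(
    method: MethodSpec, train: SampleTable, test: SampleTable, repeats: int = 3
) -> TimingReport:
    """Median wall/CPU seconds of fit and predict over ``repeats`` runs."""
    if repeats < 1:
        raise EvaluationError("repeats must be >= 1")
    train_wall, train_cpu, test_wall, test_cpu = [], [], [], []
    for _ in range(repeats):
        w0, c0 = time.perf_counter(), time.process_time()
        model = method.make().fit(train)
        w1, c1 = time.perf_counter(), time.process_time()
        model.predict_matrix(test.inputs)
        w2, c2 = time.perf_counter(), time.process_time()
        train_wall.append(w1 - w0)
        train_cpu.append(c1 - c0)
        test_wall.append(w2 - w1)
        test_cpu.append(c2 - c1)
    med = lambda xs: float(np.median(xs))
    return TimingReport(
        method.name, med(train_wall), med(train_cpu), med(test_wall), med(test_cpu), repeats
    )
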