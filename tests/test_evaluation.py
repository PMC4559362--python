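import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from reference_values import NN_ERROR_ROW, RF_ERROR_ROW

from tcellfate.dataset import SampleTable, split
from tcellfate.evaluation import (
    ErrorReport,
    EvaluationError,
    MethodSpec,
    cross_validate,
    default_methods,
    evaluate_surrogate,
    kfold_partition,
    mae_per_output,
    measure_runtime,
    noise_robustness,
    reports_to_frame,
    scan_mlp_hidden,
    scan_rf,
    scan_svr_gamma,
    sum_error,
)
from tcellfate.surrogates import LinearSurrogate, MLPSurrogate, RFSurrogate, SVRSurrogate


def affine_table(seed=0, n=60):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, (n, 4))
    return SampleTable(X, 0.1 + X @ rng.uniform(-0.3, 0.3, (4, 5)) + 0.4)


FAST_METHODS = [
    MethodSpec("linear", LinearSurrogate),
    MethodSpec("mlp", lambda: MLPSurrogate(hidden_size=2, max_epochs=200, seed=0)),
    MethodSpec("svr", SVRSurrogate),
    MethodSpec("rf", lambda: RFSurrogate(ntree=5, mtry=2, seed=0)),
]


class TestErrorMetrics:
    def test_identical_matrices_give_zero(self):
        truth = np.random.default_rng(0).uniform(0, 1, (10, 5))
        assert np.all(mae_per_output(truth, truth) == 0.0)

    def test_columnwise_mean_absolute_difference(self):
        truth = np.zeros((2, 5))
        truth[:, 0] = [0.0, 1.0]
        pred = truth.copy()
        pred[:, 0] = [0.1, 0.9]
        assert mae_per_output(pred, truth)[0] == pytest.approx(0.1)

    def test_single_row_allowed(self):
        assert mae_per_output(np.ones((1, 5)), np.zeros((1, 5)))[3] == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            mae_per_output(np.zeros((2, 5)), np.zeros((3, 5)))

    def test_sum_error_aggregates_published_rows(self):
        assert sum_error(NN_ERROR_ROW) == pytest.approx(0.190, abs=0.0005)
        assert sum_error(RF_ERROR_ROW) == pytest.approx(0.2123, abs=1e-12)
        assert sum_error(np.zeros(5)) == 0.0

    def test_report_sum_matches_components(self):
        report = ErrorReport("m", np.array(NN_ERROR_ROW))
        assert report.sum_error == pytest.approx(float(np.sum(NN_ERROR_ROW)), abs=1e-12)
        with pytest.raises(EvaluationError):
            ErrorReport("m", np.array([-0.1, 0, 0, 0, 0]))


class TestScans:
    def test_mlp_scan_selects_and_reproduces(self, small_table):
        train, test = split(small_table, 40, seed=0)
        reports, selected = scan_mlp_hidden(train, test, sizes=(2, 3), seed=1, max_epochs=300)
        reports2, selected2 = scan_mlp_hidden(train, test, sizes=(2, 3), seed=1, max_epochs=300)
        assert selected in (2, 3)
        assert selected == selected2
        assert [r.sum_error for r in reports] == [r.sum_error for r in reports2]

    def test_single_candidate_is_selected(self, small_table):
        train, test = split(small_table, 40, seed=0)
        _, selected = scan_mlp_hidden(train, test, sizes=(4,), seed=0, max_epochs=100)
        assert selected == 4
        _, gamma = scan_svr_gamma(train, test, gammas=(0.5,))
        assert gamma == 0.5
        _, pair = scan_rf(train, test, ntrees=(7,), mtrys=(2,), seed=0)
        assert pair == (7, 2)

    def test_empty_candidates_rejected(self, small_table):
        train, test = split(small_table, 40, seed=0)
        with pytest.raises(EvaluationError):
            scan_svr_gamma(train, test, gammas=())


class TestKFold:
    def test_protocol_fold_sizes_for_625_by_10(self):
        assignment = kfold_partition(625, 10, seed=0)
        sizes = sorted(np.bincount(assignment)[1:], reverse=True)
        assert sizes == [63] * 5 + [62] * 5

    def test_ten_singleton_folds(self):
        assignment = kfold_partition(10, 10, seed=1)
        assert sorted(assignment) == list(range(1, 11))

    @given(
        n=st.integers(2, 200),
        k=st.integers(2, 20),
        seed=st.integers(0, 10_000),
    )
    def test_partition_property(self, n, k, seed):
        if k > n:
            with pytest.raises(EvaluationError):
                kfold_partition(n, k, seed)
            return
        assignment = kfold_partition(n, k, seed)
        counts = np.bincount(assignment, minlength=k + 1)[1:]
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1
        assert np.all(counts > 0)


class TestCrossValidate:
    def test_linear_recovers_affine_data_exactly(self):
        table = affine_table()
        report = cross_validate(MethodSpec("linear", LinearSurrogate), table, k=5, seed=0)
        assert report.k == 5
        assert report.per_fold_mse.shape == (5, 5)
        assert np.all(report.per_output_avg_mse < 1e-12)

    def test_constant_outputs_give_zero_error(self):
        rng = np.random.default_rng(2)
        table = SampleTable(rng.uniform(0, 1, (30, 4)), np.full((30, 5), 0.5))
        report = cross_validate(MethodSpec("linear", LinearSurrogate), table, k=3, seed=0)
        assert np.all(report.per_output_avg_mse < 1e-20)

    def test_fold_failures_are_labelled(self):
        rng = np.random.default_rng(3)
        table = SampleTable(rng.uniform(0, 1, (12, 4)), rng.uniform(0, 2, (12, 5)))
        with pytest.raises(EvaluationError, match="fold 1"):
            cross_validate(MethodSpec("mlp", lambda: MLPSurrogate(hidden_size=2)), table, k=3)


class TestNoiseRobustness:
    def test_zero_level_reproduces_clean_benchmark(self, small_table):
        reports = noise_robustness(
            small_table,
            methods=FAST_METHODS[:1],
            levels=(0.0, 0.01),
            n_train=40,
            split_seed=1,
            noise_seed=2,
        )
        train, test = split(small_table, 40, seed=1)
        clean = evaluate_surrogate(LinearSurrogate().fit(train), test)
        at_zero = [r for r in reports if r.provenance["noise_level"] == 0.0][0]
        assert np.array_equal(at_zero.per_output_mae, clean.per_output_mae)

    def test_report_shape_methods_times_levels(self, small_table):
        reports = noise_robustness(
            small_table, methods=FAST_METHODS, levels=(0.0, 0.005, 0.01), n_train=40
        )
        assert len(reports) == 4 * 3
        frame = reports_to_frame(reports)
        assert set(frame["method"]) == {"linear", "mlp", "svr", "rf"}

    def test_noise_degrades_linear_fit_softly(self, small_table):
        medians = {}
        for level in (0.0, 0.01):
            sums = []
            for noise_seed in range(3):
                reports = noise_robustness(
                    small_table,
                    methods=FAST_METHODS[:1],
                    levels=(0.0, level) if level else (0.0,),
                    n_train=40,
                    split_seed=0,
                    noise_seed=noise_seed,
                )
                sums.append([r for r in reports if r.provenance["noise_level"] == level][0].sum_error)
            medians[level] = float(np.median(sums))
        assert medians[0.01] >= medians[0.0] - 0.005

    def test_levels_must_include_zero(self, small_table):
        with pytest.raises(EvaluationError):
            noise_robustness(small_table, methods=FAST_METHODS[:1], levels=(0.01,), n_train=40)


class TestRuntime:
    def test_single_repeat_nonnegative_durations(self, small_table):
        train, test = split(small_table, 40, seed=0)
        report = measure_runtime(FAST_METHODS[0], train, test, repeats=1)
        assert report.train_wall >= 0 and report.test_wall >= 0
        assert report.repeats == 1

    def test_benchmark_mode_covers_all_methods(self, small_table):
        train, test = split(small_table, 40, seed=0)
        frame = reports_to_frame(
            [measure_runtime(m, train, test, repeats=1) for m in FAST_METHODS]
        )
        assert list(frame["method"]) == ["linear", "mlp", "svr", "rf"]

    def test_invalid_repeats_rejected(self, small_table):
        train, test = split(small_table, 40, seed=0)
        with pytest.raises(EvaluationError):
            measure_runtime(FAST_METHODS[0], train, test, repeats=0)


class TestBenchmarkOrdering:
    def test_nonlinear_methods_beat_kernel_and_linear_baselines(self, benchmark_seed_sweep):
        """Median hold-out sum-of-MAE over five split seeds orders the
        methods: both nonlinear surrogates beat the baseline-width SVR,
        which beats the linear model."""
        medians = {name: float(np.median(v)) for name, v in benchmark_seed_sweep.items()}
        assert medians["mlp"] < medians["svr"] < medians["linear"]
        assert medians["rf"] < medians["svr"]

    def test_default_method_roster(self):
        assert [m.name for m in default_methods()] == ["linear", "mlp", "svr", "rf"]
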