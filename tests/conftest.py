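import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcellfate import (
    GridSpec,
    SampleTable,
    build_dataset,
    default_methods,
    evaluate_surrogate,
    generate_grid,
    normalize,
    split,
)
from tcellfate.surrogates import MLPSurrogate, RFSurrogate

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def kinetic_table():
    """Raw steady-state outputs for the default 625-point grid."""
    return build_dataset()


@pytest.fixture(scope="session")
def normalized_table(kinetic_table):
    return normalize(kinetic_table)


@pytest.fixture(scope="session")
def bench_split(normalized_table):
    """The default benchmark protocol split: 100 training / 525 test rows."""
    return split(normalized_table, 100, seed=0)


@pytest.fixture(scope="session")
def small_table():
    """Normalized 81-row dataset from a 3-level grid (fast fitting)."""
    spec = GridSpec({name: (0.0, 0.5, 1.0) for name in ("IFNg", "IL12", "IL6", "TGFb")})
    return normalize(build_dataset(grid=generate_grid(spec)))


@pytest.fixture(scope="session")
def random_table():
    """Random 100-row table with outputs in [0, 1]; no kinetic structure."""
    rng = np.random.default_rng(2024)
    return SampleTable(rng.uniform(0, 1, (100, 4)), rng.uniform(0, 1, (100, 5)))


@pytest.fixture(scope="session")
def trained_mlp(bench_split):
    """Seven-hidden-neuron MLP trained on the default benchmark split."""
    train, _ = bench_split
    return MLPSurrogate(hidden_size=7, seed=0).fit(train)


@pytest.fixture(scope="session")
def trained_rf(bench_split):
    """1000-tree, mtry=4 random forest trained on the default benchmark split."""
    train, _ = bench_split
    return RFSurrogate(ntree=1000, mtry=4, seed=0).fit(train)


@pytest.fixture(scope="session")
def benchmark_seed_sweep(normalized_table):
    """Hold-out sum-of-MAE for all four methods over five split seeds."""
    sums = {name: [] for name in ("linear", "mlp", "svr", "rf")}
    for seed in range(5):
        train, test = split(normalized_table, 100, seed=seed)
        for spec in default_methods(seed=seed):
            model = spec.make().fit(train)
            sums[spec.name].append(evaluate_surrogate(model, test).sum_error)
    return sums
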