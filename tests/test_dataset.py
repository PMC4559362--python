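import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tcellfate.dataset import (
    DatasetError,
    GridSpec,
    NoiseSpec,
    SampleTable,
    add_output_noise,
    build_dataset,
    generate_grid,
    normalize,
    read_csv,
    split,
    write_csv,
)
from tcellfate.kinetics import INPUT_NAMES, OUTPUT_NAMES, CytokineInput

level_lists = st.lists(
    st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=4, unique=True
).map(lambda xs: tuple(sorted(xs)))


class TestGrid:
    def test_default_grid_has_625_points(self):
        grid = generate_grid()
        assert len(grid) == 625
        assert grid[0] == CytokineInput(0, 0, 0, 0)
        assert grid[-1] == CytokineInput(1, 1, 1, 1)

    def test_two_level_grid_is_full_factorial(self):
        spec = GridSpec({name: (0.0, 1.0) for name in INPUT_NAMES})
        grid = generate_grid(spec)
        assert len(grid) == 16
        assert len({tuple(g.as_array()) for g in grid}) == 16

    @given(ifng=level_lists, il12=level_lists, il6=level_lists, tgfb=level_lists)
    def test_grid_count_is_product_of_level_counts(self, ifng, il12, il6, tgfb):
        spec = GridSpec({"IFNg": ifng, "IL12": il12, "IL6": il6, "TGFb": tgfb})
        assert len(generate_grid(spec)) == len(ifng) * len(il12) * len(il6) * len(tgfb)

    @pytest.mark.parametrize(
        "levels",
        [
            {"IFNg": ()},
            {"IFNg": (0.0, 1.5)},
            {"IFNg": (1.0, 0.0)},
            {"bogus": (0.0,)},
        ],
    )
    def test_invalid_specs_rejected(self, levels):
        full = {name: (0.0, 1.0) for name in INPUT_NAMES}
        if "bogus" in levels:
            full["bogus"] = levels["bogus"]
        else:
            full.update(levels)
        with pytest.raises(DatasetError):
            GridSpec(full)


class TestBuildDataset:
    def test_rows_match_grid_and_closed_forms(self):
        grid = [CytokineInput(), CytokineInput(tgfb=1.0)]
        table = build_dataset(grid=grid)
        assert table.n_samples == 2
        assert np.all(table.outputs[0] == 0.0)
        assert table.outputs[1, 4] == pytest.approx(16.0 / 17.0, abs=1e-8)

    def test_empty_grid_rejected(self):
        with pytest.raises(DatasetError):
            build_dataset(grid=[])


class TestNormalize:
    def test_every_column_spans_unit_interval(self, normalized_table):
        assert np.allclose(normalized_table.outputs.min(axis=0), 0.0)
        assert np.allclose(normalized_table.outputs.max(axis=0), 1.0)
        assert set(normalized_table.scaling) == set(OUTPUT_NAMES)

    def test_specific_column_scaling(self):
        outputs = np.zeros((3, 5))
        outputs[:, 0] = [0.0, 0.4706, 0.9412]
        table = SampleTable(np.zeros((3, 4)), outputs)
        scaled = normalize(table)
        assert np.allclose(scaled.outputs[:, 0], [0.0, 0.5, 1.0], atol=1e-4)

    def test_idempotent_on_normalized_tables(self, normalized_table):
        again = normalize(normalized_table)
        assert np.allclose(again.outputs, normalized_table.outputs, atol=1e-15)

    def test_constant_column_maps_to_zero(self):
        outputs = np.ones((4, 5))
        table = SampleTable(np.zeros((4, 4)), outputs)
        assert np.all(normalize(table).outputs == 0.0)

    def test_single_row_rejected(self):
        with pytest.raises(DatasetError):
            normalize(SampleTable(np.zeros((1, 4)), np.zeros((1, 5))))


class TestNoise:
    def test_zero_amplitude_is_identity(self, random_table):
        noisy = add_output_noise(random_table, NoiseSpec(0.0, seed=3))
        assert np.array_equal(noisy.outputs, random_table.outputs)

    def test_relative_bound_and_untouched_inputs(self, random_table):
        a = 0.01
        noisy = add_output_noise(random_table, NoiseSpec(a, seed=3))
        assert np.all(np.abs(noisy.outputs - random_table.outputs) <= a * random_table.outputs + 1e-15)
        assert np.array_equal(noisy.inputs, random_table.inputs)

    def test_seed_reproducibility(self, random_table):
        first = add_output_noise(random_table, NoiseSpec(0.01, seed=7))
        second = add_output_noise(random_table, NoiseSpec(0.01, seed=7))
        other = add_output_noise(random_table, NoiseSpec(0.01, seed=8))
        assert np.array_equal(first.outputs, second.outputs)
        assert not np.array_equal(first.outputs, other.outputs)

    def test_column_means_preserved_over_seeds(self, random_table):
        a = 0.01
        ratios = []
        for seed in range(30):
            noisy = add_output_noise(random_table, NoiseSpec(a, seed=seed))
            ratios.append(noisy.outputs.mean(axis=0) / random_table.outputs.mean(axis=0))
        # mean multiplicative factor concentrates at 1 with sd a/sqrt(3 n)
        tolerance = 5 * a / np.sqrt(3 * 30 * random_table.n_samples)
        assert np.all(np.abs(np.mean(ratios, axis=0) - 1.0) < tolerance)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(DatasetError):
            NoiseSpec(-0.01)


class TestSplit:
    def test_protocol_split_100_525(self, normalized_table):
        train, test = split(normalized_table, 100, seed=0)
        assert train.n_samples == 100
        assert test.n_samples == 525

    def test_partition_is_disjoint_and_covers(self, random_table):
        train, test = split(random_table, 30, seed=1)
        combined = np.vstack([train.inputs, test.inputs])
        original = random_table.inputs
        assert combined.shape == original.shape
        assert {tuple(r) for r in combined} == {tuple(r) for r in original}

    def test_seed_determinism_and_variation(self, random_table):
        a1, _ = split(random_table, 30, seed=5)
        a2, _ = split(random_table, 30, seed=5)
        b1, _ = split(random_table, 30, seed=6)
        assert np.array_equal(a1.inputs, a2.inputs)
        assert not np.array_equal(a1.inputs, b1.inputs)

    @pytest.mark.parametrize("n_train", [0, 100, 101])
    def test_degenerate_sizes_rejected(self, random_table, n_train):
        with pytest.raises(DatasetError):
            split(random_table, n_train)


class TestCsvIO:
    def test_lossless_round_trip(self, tmp_path, random_table):
        path = tmp_path / "table.csv"
        write_csv(random_table, path)
        loaded = read_csv(path)
        assert np.array_equal(loaded.inputs, random_table.inputs)
        assert np.array_equal(loaded.outputs, random_table.outputs)

    def test_scaling_survives_sidecar(self, tmp_path, normalized_table):
        path = tmp_path / "norm.csv"
        write_csv(normalized_table, path)
        loaded = read_csv(path)
        assert loaded.scaling == normalized_table.scaling

    def test_scientific_notation_row_parses(self, tmp_path):
        path = tmp_path / "fixture.csv"
        path.write_text(
            "IFNg,IL12,IL6,TGFb,IL17,RORgt,IFNg_out,Tbet,FOXP3\n"
            "1,0,0.5,0,0.996,0.989,0.122,0.547,7.51E-06\n"
            "0,0,0,1,0.155,0.117,0.401,0.645,0.000105\n"
        )
        table = read_csv(path)
        assert np.allclose(table.inputs[0], [1, 0, 0.5, 0])
        assert table.outputs[0, 4] == pytest.approx(7.51e-6, rel=1e-12)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("IFNg,IL12,IL6,TGFb\n0,0,0,0\n")
        with pytest.raises(DatasetError, match="expected columns"):
            read_csv(path)

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "IFNg,IL12,IL6,TGFb,IL17,RORgt,IFNg_out,Tbet,FOXP3\n"
            "0,0,0,0,0,0,oops,0,0\n"
        )
        with pytest.raises(DatasetError, match=r"row 1.*IFNg_out"):
            read_csv(path)


class TestSampleTable:
    def test_shape_validation(self):
        with pytest.raises(DatasetError):
            SampleTable(np.zeros((3, 4)), np.zeros((2, 5)))
        with pytest.raises(DatasetError):
            SampleTable(np.zeros((3, 3)), np.zeros((3, 5)))

    def test_frame_columns(self, random_table):
        frame = random_table.to_frame()
        assert list(frame.columns) == list(INPUT_NAMES + OUTPUT_NAMES)
        assert len(frame) == random_table.n_samples
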