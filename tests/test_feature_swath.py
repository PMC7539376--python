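"""Window grids, swath binning against a brute-force oracle, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_scans
from swathnet.feature_swath import (
    build_window_grid,
    concat_matrices,
    extract_feature_swath,
    infer_mz_range,
    make_label_vector,
    normalize_rows,
    parse_window_spec,
)
from swathnet.spectra_io import SpectraRun, SpectrumScan


def brute_force_bin(scans, grid):
    """Independent oracle: per-peak loop with linear window search."""
    edges = grid.edges
    out = np.zeros((len(scans), grid.n_windows))
    for i, scan in enumerate(scans):
        for mz, intensity in zip(scan.mz, scan.intensity):
            if mz < grid.mz_min or mz > grid.mz_max:
                continue
            if mz == grid.mz_max:
                out[i, -1] += intensity
                continue
            for j in range(grid.n_windows):
                if edges[j] <= mz < edges[j + 1]:
                    out[i, j] += intensity
                    break
    return out


def _run(scans, label=0, run_id="r"):
    return SpectraRun(run_id=run_id, scans=scans, sample_label=label)


class TestWindowGrid:
    @pytest.mark.parametrize(
        "spec,expected",
        [("5×5", 25), ("10x10", 100), ("28×28", 784), ("32*32", 1024), (7, 7), ("1x1", 1)],
    )
    def test_square_spec_yields_n_squared_bins(self, spec, expected):
        assert parse_window_spec(spec) == expected

    def test_width_is_range_over_count(self):
        grid = build_window_grid(400, 1400, "28x28")
        assert grid.n_windows == 784
        assert grid.window_width == pytest.approx(1000 / 784)

    def test_single_window_is_the_whole_range(self):
        grid = build_window_grid(100, 200, 1)
        np.testing.assert_allclose(grid.edges, [100, 200])

    @pytest.mark.parametrize("bad", [0, -3, "0x0", "3x4", "banana"])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_window_spec(bad)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            build_window_grid(500, 400, 10)

    def test_tiling_is_disjoint_and_exhaustive(self):
        grid = build_window_grid(350, 1350, 64)
        edges = grid.edges
        assert edges[0] == 350 and edges[-1] == 1350
        assert np.all(np.diff(edges) > 0)
        widths = np.diff(edges)
        np.testing.assert_allclose(widths, grid.window_width)


class TestInferRange:
    def test_floor_and_ceil_of_global_extremes(self):
        scans = [SpectrumScan(1, 1, 0.0, np.array([350.2, 900.0]), np.array([1.0, 2.0])),
                 SpectrumScan(2, 1, 1.0, np.array([1249.8]), np.array([3.0]))]
        assert infer_mz_range([_run(scans)]) == (350.0, 1250.0)

    def test_degenerate_single_point_widened(self):
        scans = [SpectrumScan(1, 1, 0.0, np.array([500.0]), np.array([1.0]))]
        assert infer_mz_range([_run(scans)]) == (500.0, 501.0)

    def test_all_empty_errors(self):
        scans = [SpectrumScan(1, 1, 0.0, np.empty(0), np.empty(0))]
        with pytest.raises(ValueError, match="empty"):
            infer_mz_range([_run(scans)])


class TestExtraction:
    def test_worked_example_row(self):
        scan = SpectrumScan(1, 1, 0.0, np.array([100.5, 100.9, 350.0]),
                            np.array([10.0, 5.0, 7.0]))
        grid = build_window_grid(100, 600, 5)
        m = extract_feature_swath(_run([scan]), grid)
        np.testing.assert_allclose(m.values, [[15.0, 0.0, 7.0, 0.0, 0.0]])

    def test_boundary_peak_goes_to_right_window(self):
        scan = SpectrumScan(1, 1, 0.0, np.array([200.0]), np.array([4.0]))
        grid = build_window_grid(100, 600, 5)  # edges at 100,200,...,600
        m = extract_feature_swath(_run([scan]), grid)
        np.testing.assert_allclose(m.values, [[0.0, 4.0, 0.0, 0.0, 0.0]])

    def test_peak_at_upper_bound_kept_in_last_window(self):
        scan = SpectrumScan(1, 1, 0.0, np.array([600.0]), np.array([2.0]))
        grid = build_window_grid(100, 600, 5)
        m = extract_feature_swath(_run([scan]), grid)
        assert m.values[0, -1] == 2.0

    def test_out_of_range_peaks_dropped(self):
        scan = SpectrumScan(1, 1, 0.0, np.array([50.0, 150.0, 700.0]),
                            np.array([9.0, 1.0, 9.0]))
        grid = build_window_grid(100, 600, 5)
        m = extract_feature_swath(_run([scan]), grid)
        assert m.values.sum() == 1.0

    def test_empty_scans_become_zero_rows(self):
        scans = [SpectrumScan(1, 1, 0.0, np.empty(0), np.empty(0)),
                 SpectrumScan(2, 1, 1.0, np.array([150.0]), np.array([3.0]))]
        m = extract_feature_swath(_run(scans), build_window_grid(100, 600, 5))
        assert m.values[0].sum() == 0.0
        assert m.values[1].sum() == 3.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_windows=st.integers(1, 128))
    def test_vectorized_binning_equals_bruteforce_oracle(self, seed, n_windows):
        rng = np.random.default_rng(seed)
        scans = random_scans(rng, n_scans=4, max_peaks=200)
        grid = build_window_grid(
            float(rng.uniform(50, 150)), float(rng.uniform(1200, 1600)), n_windows
        )
        m = extract_feature_swath(_run(scans), grid)
        np.testing.assert_allclose(m.values, brute_force_bin(scans, grid),
                                   rtol=1e-9, atol=1e-9)

    def test_row_sums_conserve_in_range_intensity(self):
        rng = np.random.default_rng(11)
        scans = random_scans(rng, n_scans=20, max_peaks=500)
        grid = build_window_grid(100, 1500, 77)
        m = extract_feature_swath(_run(scans), grid)
        for i, scan in enumerate(scans):
            keep = (scan.mz >= 100) & (scan.mz <= 1500)
            expected = scan.intensity[keep].sum()
            assert m.values[i].sum() == pytest.approx(expected, rel=1e-9)

    def test_peak_order_shuffle_leaves_matrix_unchanged(self):
        rng = np.random.default_rng(3)
        mz = rng.uniform(100, 600, 50)
        intensity = rng.uniform(0, 10, 50)
        grid = build_window_grid(100, 600, 13)
        order = np.argsort(mz)
        a = SpectrumScan(1, 1, 0.0, mz[order], intensity[order])
        perm = rng.permutation(50)
        b = SpectrumScan(1, 1, 0.0, mz[perm], intensity[perm])  # re-sorts internally
        np.testing.assert_array_equal(
            extract_feature_swath(_run([a]), grid).values,
            extract_feature_swath(_run([b]), grid).values,
        )


class TestNormalization:
    def test_row_divided_by_its_max(self):
        grid = build_window_grid(0.5, 3.5, 3)
        from swathnet.feature_swath import IntensityMatrix

        m = IntensityMatrix(np.array([[2.0, 4.0, 8.0]]), [("r", 1)], grid)
        np.testing.assert_allclose(normalize_rows(m).values, [[0.25, 0.5, 1.0]])

    def test_zero_rows_stay_zero(self):
        grid = build_window_grid(0.5, 3.5, 3)
        from swathnet.feature_swath import IntensityMatrix

        m = IntensityMatrix(np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 2.0]]),
                            [("r", 1), ("r", 2)], grid)
        n = normalize_rows(m)
        np.testing.assert_array_equal(n.values[0], 0.0)
        assert n.normalized

    def test_double_normalization_refused(self):
        grid = build_window_grid(0.5, 3.5, 3)
        from swathnet.feature_swath import IntensityMatrix

        m = IntensityMatrix(np.array([[1.0, 2.0, 4.0]]), [("r", 1)], grid)
        with pytest.raises(ValueError, match="already normalized"):
            normalize_rows(normalize_rows(m))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_every_normalized_row_max_is_zero_or_one(self, seed):
        rng = np.random.default_rng(seed)
        scans = random_scans(rng, n_scans=10, max_peaks=50)
        grid = build_window_grid(100, 1500, 32)
        n = normalize_rows(extract_feature_swath(_run(scans), grid))
        row_max = n.values.max(axis=1)
        assert np.all((row_max == 0.0) | (row_max == 1.0))
        assert np.all(n.values <= 1.0)


class TestLabelsAndConcat:
    def test_label_vector_repeats_sample_label(self):
        scans = random_scans(np.random.default_rng(0), 4, max_peaks=5)
        np.testing.assert_array_equal(make_label_vector(_run(scans, label=1), 4),
                                      [1, 1, 1, 1])
        np.testing.assert_array_equal(
            make_label_vector(_run(scans[:3], label=0), 3), [0, 0, 0]
        )

    def test_label_vector_length_mismatch_errors(self):
        scans = random_scans(np.random.default_rng(0), 4, max_peaks=5)
        with pytest.raises(ValueError, match="scan count"):
            make_label_vector(_run(scans), 3)

    def test_concat_requires_matching_grid(self):
        rng = np.random.default_rng(0)
        r = _run(random_scans(rng, 2, max_peaks=5))
        a = extract_feature_swath(r, build_window_grid(100, 1500, 8))
        b = extract_feature_swath(r, build_window_grid(100, 1500, 16))
        with pytest.raises(ValueError, match="grid"):
            concat_matrices([a, b])
        stacked = concat_matrices([a, a])
        assert stacked.n_rows == 4
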