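"""Preprocessing chain: quantile normalization, flooring/log2, filters."""
import numpy as np
import pandas as pd
import pytest

from restflow import (
    UNNAMED_PREFIX,
    annotation_filter,
    detection_filter,
    floor_and_log2,
    quantile_normalize,
    run_preprocess,
)


def _frame(values, columns=None):
    values = np.asarray(values, dtype=float)
    columns = columns or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"p{i}" for i in range(values.shape[0])], columns=columns)


class TestQuantileNormalize:
    def test_mean_of_sorted_rows_oracle(self):
        """[[1,4],[2,5],[3,6]] -> both columns [2.5, 3.5, 4.5]."""
        out = quantile_normalize(_frame([[1, 4], [2, 5], [3, 6]]))
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.to_numpy(), expected)

    def test_identical_columns_are_unchanged(self):
        frame = _frame([[3, 3], [1, 1], [2, 2]])
        out = quantile_normalize(frame)
        np.testing.assert_allclose(out.to_numpy(), frame.to_numpy())

    def test_rank_order_preserved_within_columns(self, rng):
        frame = _frame(rng.gamma(2.0, 50.0, size=(200, 6)))
        out = quantile_normalize(frame)
        for col in frame.columns:
            original = frame[col].rank(method="average")
            normalized = out[col].rank(method="average")
            pd.testing.assert_series_equal(original, normalized)

    def test_all_columns_share_sorted_values(self, rng):
        frame = _frame(rng.exponential(100.0, size=(300, 5)))
        out = quantile_normalize(frame).to_numpy()
        reference = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), reference, atol=1e-9)

    def test_permuted_columns_map_to_common_distribution(self, rng):
        base = rng.uniform(1.0, 100.0, 50)
        frame = _frame(np.column_stack([base, rng.permutation(base), rng.permutation(base)]))
        out = quantile_normalize(frame).to_numpy()
        # each output column is a permutation of the shared reference
        for j in range(3):
            np.testing.assert_allclose(np.sort(out[:, j]), np.sort(out[:, 0]))

    def test_ties_receive_mean_of_reference_values(self):
        # column 0 has a tie at 1; its tied ranks get the mean of the two
        # lowest reference values
        frame = _frame([[1, 10], [1, 20], [5, 30]])
        out = quantile_normalize(frame)
        reference = np.sort(frame.to_numpy(), axis=0).mean(axis=1)
        expected_tie = reference[:2].mean()
        assert out.iloc[0, 0] == pytest.approx(expected_tie)
        assert out.iloc[1, 0] == pytest.approx(expected_tie)

    def test_rejects_single_column_and_nonfinite(self):
        with pytest.raises(ValueError):
            quantile_normalize(_frame([[1.0], [2.0]]))
        with pytest.raises(ValueError):
            quantile_normalize(_frame([[1, np.nan], [2, 3]]))


class TestFloorLog2:
    def test_values_below_floor_are_clamped(self):
        out = floor_and_log2(_frame([[5, 1024]]))
        assert out.iloc[0, 0] == pytest.approx(np.log2(10), abs=1e-4)
        assert out.iloc[0, 1] == 10.0

    def test_minimum_output_is_log2_floor(self, rng):
        out = floor_and_log2(_frame(rng.uniform(0, 50, (100, 3))))
        assert out.to_numpy().min() >= np.log2(10) - 1e-12

    def test_flooring_idempotent_in_linear_space(self):
        frame = _frame([[5, 20], [0.1, 300]])
        once = np.maximum(frame.to_numpy(), 10.0)
        twice = np.maximum(once, 10.0)
        np.testing.assert_array_equal(once, twice)
        np.testing.assert_allclose(
            floor_and_log2(_frame(once)).to_numpy(), floor_and_log2(frame).to_numpy()
        )

    def test_nonpositive_floor_rejected(self):
        with pytest.raises(ValueError):
            floor_and_log2(_frame([[1, 2]]), floor_value=0.0)


class TestDetectionFilter:
    def test_all_p_above_threshold_removed(self):
        matrix = _frame([[1] * 6])
        p = _frame([[0.02] * 6])
        assert detection_filter(matrix, p).shape[0] == 0

    def test_single_sample_below_threshold_retained(self):
        matrix = _frame([[1] * 6])
        p = _frame([[0.5, 0.5, 0.005, 0.5, 0.5, 0.5]])
        assert detection_filter(matrix, p).shape[0] == 1

    def test_boundary_is_strict(self):
        matrix = _frame([[1] * 6])
        p = _frame([[0.01] * 6])
        assert detection_filter(matrix, p).shape[0] == 0

    def test_hand_enumerated_ten_probe_set(self, rng):
        # probes 0, 3, 5, 9 carry one sub-threshold p-value each
        p_values = np.full((10, 6), 0.5)
        for i, j in [(0, 2), (3, 0), (5, 5), (9, 1)]:
            p_values[i, j] = 0.004
        matrix = _frame(rng.uniform(10, 100, (10, 6)))
        kept = detection_filter(matrix, _frame(p_values))
        assert list(kept.index) == ["p0", "p3", "p5", "p9"]
        # filter is a pure row selection
        pd.testing.assert_frame_equal(kept, matrix.loc[kept.index])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detection_filter(_frame([[1] * 6]), _frame([[0.5] * 5]))


class TestAnnotationFilter:
    def test_unannotated_and_empty_symbols_dropped(self):
        matrix = _frame(np.ones((5, 2)))
        annotations = pd.Series(
            ["GENE1", f"{UNNAMED_PREFIX}0001", "GENE2", "", "GENE3"],
            index=matrix.index,
        )
        kept = annotation_filter(matrix, annotations)
        assert list(kept.index) == ["p0", "p2", "p4"]

    def test_fully_annotated_input_unchanged(self):
        matrix = _frame(np.ones((3, 2)))
        annotations = pd.Series(["A", "B", "C"], index=matrix.index)
        pd.testing.assert_frame_equal(annotation_filter(matrix, annotations), matrix)

    def test_missing_annotation_record_rejected(self):
        matrix = _frame(np.ones((2, 2)))
        annotations = pd.Series(["A"], index=["p0"])
        with pytest.raises(ValueError, match="without annotation"):
            annotation_filter(matrix, annotations)


class TestRunPreprocess:
    def test_provenance_counts_monotone_and_values_untouched(self, rng):
        n = 400
        idx = [f"p{i}" for i in range(n)]
        intensities = pd.DataFrame(
            rng.uniform(5, 500, (n, 6)), index=idx,
            columns=["NF0", "NF1", "RF0", "RF1", "CF0", "CF1"],
        )
        detection = pd.DataFrame(rng.uniform(0, 1, (n, 6)), index=idx,
                                 columns=intensities.columns)
        annotations = pd.Series(
            [f"{UNNAMED_PREFIX}x" if i % 5 == 0 else f"G{i}" for i in range(n)], index=idx
        )
        profile = run_preprocess(intensities, detection, annotations)
        counts = list(profile.provenance.values())
        assert counts == sorted(counts, reverse=True)
        assert profile.provenance["input_probes"] == n
        # the filters selected rows from the normalized+logged matrix without
        # altering them: rebuild the pre-filter matrix and compare
        full = floor_and_log2(quantile_normalize(intensities))
        pd.testing.assert_frame_equal(profile.log2_expr, full.loc[profile.log2_expr.index])

    def test_matched_mode_is_plain_log2(self):
        intensities = _frame([[4.0, 8.0], [16.0, 2.0]])
        detection = _frame([[0.001, 0.5], [0.001, 0.5]])
        annotations = pd.Series(["A", "B"], index=intensities.index)
        profile = run_preprocess(
            intensities, detection, annotations, quantile=False, floor=None
        )
        np.testing.assert_allclose(
            profile.log2_expr.to_numpy(), np.log2(intensities.to_numpy())
        )
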