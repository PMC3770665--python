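"""Synthetic dataset generator: determinism, calibration, truth round-trip."""
import numpy as np
import pandas as pd
import pytest

from restflow import (
    PlantedSet,
    SimConfig,
    UNNAMED_PREFIX,
    generate_dataset,
    planted_collection,
    run_preprocess,
)
from restflow.transform import flow_ratios, rotated_profile, summarize_geometry, time_average


def _analyze_matched(dataset):
    """Matched preprocessing (no normalization, no flooring) + transform."""
    profile = run_preprocess(
        dataset.intensities,
        dataset.detection_p,
        dataset.annotations,
        quantile=False,
        floor=None,
    )
    return rotated_profile(time_average(flow_ratios(profile.log2_expr)))


class TestDeterminism:
    def test_same_seed_bit_identical_different_seed_not(self):
        a = generate_dataset(SimConfig(n_probes=500, seed=7))
        b = generate_dataset(SimConfig(n_probes=500, seed=7))
        c = generate_dataset(SimConfig(n_probes=500, seed=8))
        pd.testing.assert_frame_equal(a.intensities, b.intensities)
        pd.testing.assert_frame_equal(a.detection_p, b.detection_p)
        pd.testing.assert_series_equal(a.annotations, b.annotations)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert not a.intensities.equals(c.intensities)


class TestStructure:
    def test_identity_case_zero_signal_zero_noise(self):
        """No differential spread and no noise: every measured y' is zero."""
        config = SimConfig(
            n_probes=300, frac_detected=1.0, frac_unannotated=0.0,
            common_extent=0.3, differential_extent=0.0,
            noise_var_per_timepoint=0.0, seed=1,
        )
        dataset = generate_dataset(config)
        table = _analyze_matched(dataset)
        np.testing.assert_allclose(table["y_prime"].to_numpy(), 0.0, atol=1e-9)
        np.testing.assert_allclose(
            dataset.truth.loc[table.index, "y_prime_true"].to_numpy(), 0.0
        )

    def test_detection_fraction_within_binomial_error(self):
        config = SimConfig(n_probes=20_000, frac_detected=0.346, seed=3)
        dataset = generate_dataset(config)
        passed = (dataset.detection_p.min(axis=1) < 0.01).mean()
        se = np.sqrt(0.346 * 0.654 / 20_000)
        assert abs(passed - 0.346) < 4 * se

    def test_undetected_probes_have_no_subthreshold_pvalue(self):
        dataset = generate_dataset(SimConfig(n_probes=2000, seed=5))
        undetected = ~dataset.truth["detected"].to_numpy()
        assert (dataset.detection_p.to_numpy()[undetected] >= 0.01).all()

    def test_unannotated_share_carries_marker(self):
        dataset = generate_dataset(SimConfig(n_probes=20_000, frac_unannotated=0.237, seed=9))
        frac = dataset.annotations.str.startswith(UNNAMED_PREFIX).mean()
        se = np.sqrt(0.237 * 0.763 / 20_000)
        assert abs(frac - 0.237) < 4 * se

    def test_intensities_nonnegative_and_pvalues_in_unit_interval(self):
        dataset = generate_dataset(SimConfig(n_probes=1000, seed=2))
        assert (dataset.intensities.to_numpy() >= 0).all()
        p = dataset.detection_p.to_numpy()
        assert ((p >= 0) & (p <= 1)).all()

    def test_planted_set_lands_in_requested_tail(self):
        config = SimConfig(
            n_probes=5000, frac_detected=1.0, frac_unannotated=0.1,
            noise_var_per_timepoint=0.0, seed=4,
            planted_sets=(
                PlantedSet("UP40", 40, "up", 0.25),
                PlantedSet("DOWN40", 40, "down", 0.25),
            ),
        )
        dataset = generate_dataset(config)
        truth = dataset.truth
        up = truth[truth["planted_set"] == "UP40"]["y_prime_true"]
        down = truth[truth["planted_set"] == "DOWN40"]["y_prime_true"]
        background = truth[
            truth["detected"] & (truth["planted_set"] == "")
        ]["y_prime_true"]
        assert up.min() > background.quantile(0.95)
        assert down.max() < background.quantile(0.05)

    def test_planted_set_larger_than_eligible_pool_rejected(self):
        config = SimConfig(
            n_probes=50, frac_detected=0.5, seed=0,
            planted_sets=(PlantedSet("TOO_BIG", 45, "up", 0.2),),
        )
        with pytest.raises(ValueError, match="planted"):
            generate_dataset(config)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(frac_detected=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(noise_var_per_timepoint=-1.0).validate()


class TestCalibration:
    def test_time_averaging_halves_pure_noise_variance(self):
        """Per-time-point noise 8e-3 with zero signal spread: time-averaged
        profile variance ~4e-3 (within 10%)."""
        config = SimConfig(
            n_probes=20_000, frac_detected=1.0, frac_unannotated=0.0,
            common_extent=0.0, differential_extent=0.0,
            noise_var_per_timepoint=8e-3, seed=1,
        )
        table = _analyze_matched(generate_dataset(config))
        summary = summarize_geometry(table)
        assert summary["var_timeavg"] == pytest.approx(4e-3, rel=0.10)
        assert summary["var_single_timepoint"] == pytest.approx(8e-3, rel=0.10)
        assert summary["var_timeavg"] / summary["var_single_timepoint"] == pytest.approx(
            0.5, rel=0.05
        )

    def test_noise_free_truth_round_trip(self):
        """Full matched pipeline recovers true (x', y') to 1e-6."""
        config = SimConfig(
            n_probes=4000, frac_detected=0.8, frac_unannotated=0.2,
            noise_var_per_timepoint=0.0, seed=11,
        )
        dataset = generate_dataset(config)
        table = _analyze_matched(dataset)
        truth = dataset.truth.loc[table.index]
        np.testing.assert_allclose(
            table["x_prime"].to_numpy(), truth["x_prime_true"].to_numpy(), atol=1e-6
        )
        np.testing.assert_allclose(
            table["y_prime"].to_numpy(), truth["y_prime_true"].to_numpy(), atol=1e-6
        )

    def test_noise_free_extents_match_configured_spans(self):
        config = SimConfig(
            n_probes=4000, frac_detected=1.0, frac_unannotated=0.0,
            common_extent=0.52, differential_extent=0.29,
            noise_var_per_timepoint=0.0, seed=13,
        )
        summary = summarize_geometry(_analyze_matched(generate_dataset(config)))
        assert summary["extent_x_prime"] == pytest.approx(0.52, abs=1e-6)
        assert summary["extent_y_prime"] == pytest.approx(0.29, abs=1e-6)


class TestPlantedCollection:
    def test_collection_contains_planted_and_decoy_sets(self):
        config = SimConfig(
            n_probes=3000, frac_detected=0.8, frac_unannotated=0.1, seed=21,
            planted_sets=(PlantedSet("SIG", 25, "up", 0.2),),
        )
        dataset = generate_dataset(config)
        collection = planted_collection(dataset, n_decoy_sets=5, seed=1)
        assert "SIG" in collection.sets
        assert sum(name.startswith("DECOY_") for name in collection.sets) == 5
        assert len(collection.sets["SIG"]) == 25
        for members in collection.sets.values():
            assert set(members) <= collection.universe

    def test_requires_ground_truth(self):
        dataset = generate_dataset(SimConfig(n_probes=200, seed=0))
        dataset.truth = None
        with pytest.raises(ValueError, match="ground truth"):
            planted_collection(dataset)
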