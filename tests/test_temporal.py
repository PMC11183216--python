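"""Seizure-time normalization, engagement matrices, onset estimation."""

import numpy as np
import pytest

from lamseiz.csd import CSDMatrix
from lamseiz.laminar import LayerPartition
from lamseiz.temporal import (
    BinnedBaseline,
    baseline_from_interval,
    engagement_matrix,
    engagement_onset,
    group_engagement_series,
    normalize_seizure_time,
)

PART = LayerPartition.default(24)


def csd_of(values, fs=1000.0):
    return CSDMatrix(np.asarray(values, float), 150.0, fs)


class TestNormalizeSeizureTime:
    def test_output_has_hundred_columns(self):
        rng = np.random.default_rng(0)
        binned = normalize_seizure_time(csd_of(rng.standard_normal((24, 5432))), (0.0, 5.432))
        assert binned.shape == (24, 100)

    def test_constant_input_gives_constant_bins(self):
        binned = normalize_seizure_time(csd_of(np.full((4, 1000), -3.0)), (0.0, 1.0))
        np.testing.assert_allclose(binned, 3.0)  # |CSD|

    def test_linear_ramp_bin_means(self):
        n = 10000
        ramp = np.linspace(0, 1, n, endpoint=False)[None, :]
        binned = normalize_seizure_time(csd_of(ramp), (0.0, 10.0))[0]
        expected = (np.arange(100) + 0.5) / 100
        assert np.all(np.diff(binned) > 0)
        np.testing.assert_allclose(binned, expected, atol=0.01)

    def test_interval_shorter_than_bins_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            normalize_seizure_time(csd_of(np.zeros((4, 50))), (0.0, 0.05))

    def test_time_warp_invariance(self):
        # stretching the seizure uniformly leaves the 100-bin matrix unchanged
        rng = np.random.default_rng(1)
        base = rng.standard_normal((6, 2000))
        stretched = np.repeat(base, 3, axis=1)
        b1 = normalize_seizure_time(csd_of(base), (0.0, 2.0))
        b2 = normalize_seizure_time(csd_of(stretched), (0.0, 6.0))
        np.testing.assert_allclose(b1, b2, atol=1e-9)


class TestEngagementMatrix:
    def test_binned_equal_to_baseline_mean_gives_zero(self):
        binned = np.full((24, 100), 2.0)
        base = BinnedBaseline(np.full(24, 2.0), np.full(24, 0.5))
        eng = engagement_matrix(binned, base)
        assert np.all(eng.values == 0)

    def test_single_engaged_contact_is_point_mass(self):
        binned = np.zeros((24, 100))
        binned[7, 42] = 10.0
        base = BinnedBaseline(np.zeros(24), np.ones(24))
        eng = engagement_matrix(binned, base)
        assert eng.values[7, 42] == 1.0
        assert eng.values.sum() == 1.0

    def test_per_bin_distribution_sums_to_one_when_engaged(self):
        rng = np.random.default_rng(2)
        binned = rng.uniform(0, 4, (24, 100))
        base = BinnedBaseline(np.ones(24), 0.5 * np.ones(24))
        eng = engagement_matrix(binned, base, partition=PART)
        cols = eng.values.sum(axis=0)
        engaged = eng.excess.sum(axis=0) > 0
        np.testing.assert_allclose(cols[engaged], 1.0)
        assert np.all(cols[~engaged] == 0)

    def test_binary_mode_counts_outliers(self):
        binned = np.zeros((4, 100))
        binned[0, :10] = 5.0
        binned[1, :10] = 50.0
        base = BinnedBaseline(np.zeros(4), np.ones(4))
        eng = engagement_matrix(binned, base, binary=True)
        np.testing.assert_allclose(eng.values[0, :10], 0.5)  # equal weight in binary mode

    def test_channel_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            engagement_matrix(np.zeros((4, 100)), BinnedBaseline(np.zeros(3), np.zeros(3)))


class TestBaseline:
    def test_short_baseline_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            baseline_from_interval(csd_of(np.zeros((4, 20000))), (0.0, 5.0), 0.5)

    def test_baseline_statistics_of_constant_signal(self):
        base = baseline_from_interval(csd_of(np.full((4, 20000), 2.0)), (0.0, 12.0), 0.5)
        np.testing.assert_allclose(base.mean, 2.0)
        np.testing.assert_allclose(base.sd, 0.0, atol=1e-12)


class TestEngagementOnset:
    def test_constant_series_has_no_onset(self):
        assert engagement_onset(np.full(100, 0.3)) is None

    def test_noiseless_step_recovered_exactly(self):
        series = np.zeros(100)
        series[29:] = 1.0  # first elevated bin = 30 (1-based)
        onset, p = engagement_onset(series)
        assert onset == 30
        assert p == 0.0

    def test_step_location_equivariance(self):
        for b in (10, 30, 55, 90):
            series = np.zeros(100)
            series[b - 1 :] = 1.0
            onset, _ = engagement_onset(series)
            assert onset == b

    def test_decreasing_step_not_reported(self):
        series = np.ones(100)
        series[40:] = 0.0
        assert engagement_onset(series) is None

    def test_noisy_step_recovered_within_tolerance(self):
        rng = np.random.default_rng(3)
        series = 0.05 * rng.random(100)
        series[27:] += 0.5
        onset, _ = engagement_onset(series)
        assert abs(onset - 28) <= 2


class TestGroupSeries:
    def test_unknown_group_rejected(self):
        binned = np.zeros((24, 100))
        base = BinnedBaseline(np.zeros(24), np.ones(24))
        eng = engagement_matrix(binned, base, partition=PART)
        with pytest.raises(KeyError):
            group_engagement_series(eng, "thalamus")

    def test_onset_zone_supragranular_stays_silent(self, onset_run):
        csd = onset_run["csd"]
        rec = onset_run["rec"]
        ictal = rec.annotations["seizure"]
        binned = normalize_seizure_time(csd, ictal)
        base = baseline_from_interval(csd, rec.annotations["preictal"], (ictal[1] - ictal[0]) / 100)
        eng = engagement_matrix(binned, base, partition=PART)
        assert engagement_onset(group_engagement_series(eng, "supragranular")) is None

    def test_propagation_granular_onset_matches_recruitment(self, propagation_run):
        csd = propagation_run["csd"]
        rec = propagation_run["rec"]
        ictal = rec.annotations["seizure"]
        binned = normalize_seizure_time(csd, ictal)
        base = baseline_from_interval(csd, rec.annotations["preictal"], (ictal[1] - ictal[0]) / 100)
        eng = engagement_matrix(binned, base, partition=PART)
        onset, _ = engagement_onset(group_engagement_series(eng, "granular"))
        truth_frac = propagation_run["truth"].recruitment_onset_fractions["granular"]
        assert abs(onset - 100 * truth_frac) <= 5
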