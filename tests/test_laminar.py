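"""Layer-group statistics: peak assignment, chi-square, sink/source, alternation."""

import numpy as np
import pytest
from scipy import stats

import lamseiz as lz
from lamseiz.csd import CSDMatrix, rescale_sinks_sources
from lamseiz.laminar import (
    GROUP_ORDER,
    LayerPartition,
    alternation_index,
    peak_layer_counts,
    sink_source_layer_stats,
    zone_layer_chi2,
)

PART = LayerPartition.default(24)


def csd_matrix(values, fs=1000.0):
    return CSDMatrix(np.asarray(values, float), 150.0, fs)


class TestPartition:
    def test_default_covers_all_contacts_contiguously(self):
        labels = PART.labels()
        assert labels[0] == "supragranular"
        assert labels[-1] == "infragranular"
        assert list(labels[10:13]) == ["granular"] * 3

    def test_non_contiguous_partition_rejected(self):
        groups = {
            "supragranular": np.array([0, 2]),
            "granular": np.array([1]),
            "infragranular": np.arange(3, 24),
        }
        with pytest.raises(ValueError):
            LayerPartition(groups, 24)


class TestPeakLayerCounts:
    def test_all_events_on_supragranular_contact(self):
        v = np.zeros((24, 1000))
        v[2, :] = 5.0
        counts = peak_layer_counts(csd_matrix(v), [0.1, 0.3, 0.5], PART)
        assert counts == {"supragranular": 3, "granular": 0, "infragranular": 0}

    def test_tie_goes_to_deepest_contact(self):
        v = np.zeros((24, 1000))
        v[2, :] = 5.0
        v[20, :] = 5.0
        counts = peak_layer_counts(csd_matrix(v), [0.5], PART)
        assert counts["infragranular"] == 1

    def test_counts_conserve_events(self, onset_run):
        times = onset_run["detections"].times_s
        counts = peak_layer_counts(onset_run["csd"], times, PART)
        assert sum(counts.values()) == times.size

    def test_onset_zone_peaks_are_deep(self, onset_run):
        counts = peak_layer_counts(
            onset_run["csd"], onset_run["detections"].times_s, PART
        )
        deep = counts["granular"] + counts["infragranular"]
        assert deep / sum(counts.values()) > 0.9

    def test_empty_event_set_gives_zero_counts(self):
        counts = peak_layer_counts(csd_matrix(np.zeros((24, 10))), [], PART)
        assert sum(counts.values()) == 0


class TestZoneLayerChi2:
    def test_homogeneous_table_is_null(self):
        stat, p = zone_layer_chi2([50, 25, 25], [50, 25, 25])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_statistic_matches_hand_computed_pearson_sum(self):
        table = np.array([[10, 10, 80], [80, 10, 10]], dtype=float)
        expected = stats.contingency.expected_freq(table)
        oracle = ((table - expected) ** 2 / expected).sum()
        stat, p = zone_layer_chi2(table[0], table[1])
        assert stat == pytest.approx(oracle)
        assert p < 1e-4

    def test_row_swap_invariance(self):
        s1, _ = zone_layer_chi2([10, 30, 60], [40, 30, 30])
        s2, _ = zone_layer_chi2([40, 30, 30], [10, 30, 60])
        assert s1 == pytest.approx(s2)

    def test_low_expected_counts_fall_back_with_warning(self):
        with pytest.warns(RuntimeWarning, match="permutation"):
            stat, p = zone_layer_chi2([3, 2, 1], [1, 2, 3])
        assert 0 <= p <= 1

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            zone_layer_chi2([0, 10, 10], [0, 5, 5])

    def test_deep_vs_superficial_motifs_highly_significant(self, onset_run, propagation_run):
        c_on = peak_layer_counts(
            onset_run["csd"], onset_run["detections"].times_s, PART
        )
        c_out = peak_layer_counts(
            propagation_run["csd"], propagation_run["detections"].times_s, PART
        )
        _, p = zone_layer_chi2(
            [c_on[g] for g in GROUP_ORDER], [c_out[g] for g in GROUP_ORDER]
        )
        assert p < 1e-4


class TestSinkSourceStats:
    def test_single_group_activity_isolated(self):
        v = np.zeros((24, 100))
        v[PART.groups["granular"]] = 0.8
        report = sink_source_layer_stats(
            [CSDMatrix(v, 150.0, 1000.0, normalized="sink01_sourceneg1")], PART, "onset"
        )
        per = report.per_recording
        gran_sink = per[(per.group == "granular") & (per.polarity == "sink")]["mean"].item()
        supra_sink = per[(per.group == "supragranular") & (per.polarity == "sink")]["mean"].item()
        assert gran_sink == pytest.approx(0.8)
        assert supra_sink == 0.0

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        csds = [
            CSDMatrix(rng.uniform(-1, 1, (24, 300)), 150.0, 1000.0,
                      normalized="sink01_sourceneg1")
            for _ in range(6)
        ]
        report = sink_source_layer_stats(csds, PART, "onset")
        assert (report.tests["p"] > 0.05).all()

    def test_onset_zone_deep_sink_mean_exceeds_superficial(self):
        rows = []
        for seed in (21, 22, 23):
            rec, _ = lz.simulate_seizure(lz.default_onset_config(seed=seed, include_mua=False))
            csd = rescale_sinks_sources(
                lz.compute_csd(rec), scope=rec.annotations["seizure"]
            )
            report = sink_source_layer_stats([csd], PART, "onset",
                                             [rec.annotations["seizure"]])
            per = report.per_recording
            deep = per[(per.group != "supragranular") & (per.polarity == "sink")]["mean"].mean()
            supra = per[(per.group == "supragranular") & (per.polarity == "sink")]["mean"].item()
            rows.append((deep, supra))
        assert all(d > s for d, s in rows)


class TestAlternationIndex:
    def test_constructed_flip_gives_unit_index(self):
        v = np.zeros((24, 2000))
        events = [0.2, 0.6, 1.0]
        for t in events:
            s = int(t * 1000)
            v[15, s] = 1.0
            v[15, s + 50] = -1.0  # +50 ms at fs=1000
        idx = alternation_index(csd_matrix(v), events, noise_floor=0.1)
        assert idx[15] == pytest.approx(1.0)

    def test_no_flip_gives_zero_index(self):
        v = np.zeros((24, 2000))
        events = [0.2, 0.6]
        for t in events:
            s = int(t * 1000)
            v[15, s] = 1.0
            v[15, s + 50] = 1.0
        idx = alternation_index(csd_matrix(v), events, noise_floor=0.1)
        assert idx[15] == 0.0

    def test_symmetric_noise_gives_half(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((4, 300000))
        events = np.arange(0.5, 280.0, 1.0)
        idx = alternation_index(csd_matrix(v), events, noise_floor=0.0)
        assert np.all(np.abs(idx - 0.5) < 0.1)

    def test_generator_alternation_probability_recovered(self, onset_run):
        truth = onset_run["truth"]
        csd = onset_run["csd"]
        idx = alternation_index(
            csd,
            truth.discharge_times_s[:-1],
            baseline_interval=onset_run["rec"].annotations["preictal"],
        )
        # motif-active deep contacts flip reliably (alternation prob = 1)
        active = [14, 15, 16]
        assert np.nanmean(idx[active]) > 0.8

    def test_lag_beyond_recording_rejected(self):
        v = np.zeros((4, 100))
        with pytest.raises(ValueError):
            alternation_index(csd_matrix(v), [0.09], lag_ms=50, noise_floor=0.0)
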