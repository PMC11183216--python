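"""Generator correctness: forward model, event statistics, determinism."""

import numpy as np
import pytest
from scipy import stats

import lamseiz as lz
from lamseiz.synthetic import (
    ConservationError,
    DischargeWaveform,
    NoiseSpec,
    default_onset_config,
    forward_lfp_from_csd,
    onset_motifs,
    ramp_endpoints_from_second_means,
)


def second_difference_oracle(phi, h):
    """Brute-force CSD with zero virtual boundary channels."""
    padded = np.concatenate([[0.0], phi, [0.0]])
    return (padded[:-2] - 2 * padded[1:-1] + padded[2:]) / h**2


class TestForwardModel:
    def test_zero_profile_gives_zero_potential(self):
        phi = forward_lfp_from_csd(np.zeros(24), 150.0)
        assert np.all(phi == 0)

    def test_unit_dipole_is_piecewise_linear(self):
        # +1/-1 dipole: potential curvature only at the two dipole contacts,
        # cross-checked against a dense linear solve
        n, k = 12, 4
        c = np.zeros(n)
        c[k], c[k + 1] = 1.0, -1.0
        h = 0.15
        phi = forward_lfp_from_csd(c, 150.0)
        a = np.diag(-2.0 * np.ones(n)) + np.diag(np.ones(n - 1), 1) + np.diag(np.ones(n - 1), -1)
        dense = np.linalg.solve(a, c * h * h)
        np.testing.assert_allclose(phi, dense, atol=1e-12)
        curvature = second_difference_oracle(phi, h)
        kinks = np.nonzero(np.abs(curvature) > 1e-9)[0]
        np.testing.assert_array_equal(kinks, [k, k + 1])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_recovers_profile_to_machine_precision(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.standard_normal(24)
        c -= c.mean()
        phi = forward_lfp_from_csd(c, 150.0)
        np.testing.assert_allclose(second_difference_oracle(phi, 0.15), c, atol=1e-12)

    def test_nonzero_sum_profile_rejected(self):
        with pytest.raises(ConservationError, match="conserve"):
            forward_lfp_from_csd(np.ones(10), 150.0)


class TestSimulation:
    def test_seed_determinism_bit_identical(self):
        cfg = default_onset_config(seed=7, include_mua=False)
        r1, t1 = lz.simulate_seizure(cfg)
        r2, t2 = lz.simulate_seizure(default_onset_config(seed=7, include_mua=False))
        np.testing.assert_array_equal(r1.lfp, r2.lfp)
        np.testing.assert_array_equal(t1.discharge_times_s, t2.discharge_times_s)

    def test_mua_toggle_does_not_change_lfp_or_events(self):
        r1, t1 = lz.simulate_seizure(default_onset_config(seed=3, include_mua=False))
        r2, t2 = lz.simulate_seizure(default_onset_config(seed=3, include_mua=True))
        np.testing.assert_array_equal(r1.lfp, r2.lfp)
        np.testing.assert_array_equal(t1.discharge_times_s, t2.discharge_times_s)
        assert r2.mua is not None

    def test_zero_amplitude_waveform_leaves_pure_noise(self):
        cfg = default_onset_config(seed=2, include_mua=False)
        for m in cfg.motifs.values():
            m.waveform = DischargeWaveform(amplitude=0.0)
        rec, truth = lz.simulate_seizure(cfg)
        noise_cfg = default_onset_config(seed=2, include_mua=False)
        noise_cfg.phases[0].rate_start_hz = noise_cfg.phases[0].rate_end_hz = 0.0
        noise_cfg.phases[1].rate_start_hz = noise_cfg.phases[1].rate_end_hz = 0.0
        noise_rec, _ = lz.simulate_seizure(noise_cfg)
        # event times exist, but the LFP carries no discharge energy
        assert truth.discharge_times_s.size > 0
        np.testing.assert_array_equal(rec.lfp, noise_rec.lfp)

    def test_current_conservation_noiseless(self):
        cfg = default_onset_config(seed=4, include_mua=False)
        cfg.noise = NoiseSpec(pink_sigma=0.0, line_amplitude=0.0)
        rec, _ = lz.simulate_seizure(cfg)
        csd = lz.compute_csd(rec, vaknin=True, smooth=False)
        colsum = csd.values.sum(axis=0)
        assert np.abs(colsum).max() < 1e-6 * np.abs(csd.values).max()

    def test_noiseless_single_discharge_csd_matches_motif(self):
        cfg = default_onset_config(seed=5, include_mua=False)
        cfg.noise = NoiseSpec(pink_sigma=0.0, line_amplitude=0.0)
        rec, truth = lz.simulate_seizure(cfg)
        csd = lz.compute_csd(rec, vaknin=True, smooth=False)
        t = truth.discharge_times_s[0]
        prof = csd.values[:, csd.sample_at(t)]
        motif = onset_motifs()["onset_initial"].csd_profile
        cos = prof @ motif / (np.linalg.norm(prof) * np.linalg.norm(motif))
        assert cos > 0.99

    def test_constant_phase_rate_recovered(self):
        # ground-truth discharge rate in the constant 7.1 Hz phase, 20 seeds
        rates = []
        for seed in range(20):
            _, truth = lz.simulate_seizure(default_onset_config(seed=seed, include_mua=False))
            b = truth.phase_boundaries_s
            t = truth.discharge_times_s
            rates.append(((t >= b[1]) & (t < b[2])).sum() / (b[2] - b[1]))
        sem = np.std(rates) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - 7.1) <= 2 * sem + 1e-9

    def test_interval_distribution_matches_dead_time_renewal(self):
        # pooled constant-phase inter-event intervals follow dead-time +
        # exponential; KS test against the configured renewal law
        dead = DischargeWaveform().duration_ms / 1000.0
        mu = 1.0 / 7.1 - dead
        pooled = []
        for seed in range(10):
            _, truth = lz.simulate_seizure(default_onset_config(seed=seed, include_mua=False))
            b = truth.phase_boundaries_s
            t = truth.discharge_times_s
            tt = t[(t >= b[1]) & (t < b[2] - 1.0)]
            pooled.append(np.diff(tt))
        pooled = np.concatenate(pooled)
        p = stats.kstest(pooled - dead, "expon", args=(0, mu)).pvalue
        assert p > 0.01

    def test_first_second_rate_matches_configured_anchor(self):
        counts = []
        for seed in range(30):
            _, truth = lz.simulate_seizure(default_onset_config(seed=seed, include_mua=False))
            t = truth.discharge_times_s
            counts.append(((t >= truth.seizure_onset_s) & (t < truth.seizure_onset_s + 1)).sum())
        sem = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 1.3) <= 2 * sem + 0.05

    def test_ramp_anchoring_closed_form(self):
        r0, r1 = ramp_endpoints_from_second_means(1.3, 8.9, 5.3)
        # mean over first and last second of the linear ramp
        slope = (r1 - r0) / 5.3
        assert abs((r0 + slope * 0.5) - 1.3) < 1e-12
        assert abs((r0 + slope * (5.3 - 0.5)) - 8.9) < 1e-12

    def test_unknown_zone_rejected(self):
        with pytest.raises(ValueError, match="zone"):
            lz.synthetic.default_config("thalamus", seed=0)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            default_onset_config(seed=0, preictal_s=5.0)
        with pytest.raises(ValueError):
            default_onset_config(seed=0, n_contacts=4)
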