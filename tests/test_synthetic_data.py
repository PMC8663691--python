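"""Generator contracts: OU process, headset observation model, cohort structure."""

import numpy as np
import pytest

from swayval import (
    CohortConfig,
    HeadsetObservationParams,
    SwayProcessParams,
    generate_cohort,
    icc_two_way_mixed,
    normalized_path_length,
    observe_headset_trace,
    root_mean_square,
    simulate_cop_trace,
    subject_amplitude,
)


class TestCopProcess:
    def test_linearity_in_amplitude_scale(self):
        p = SwayProcessParams()
        a = simulate_cop_trace(p, 1.0, 42)
        b = simulate_cop_trace(p, 2.0, 42)
        np.testing.assert_allclose(b.values, 2 * a.values, rtol=1e-14)

    def test_fixed_seed_determinism(self):
        p = SwayProcessParams()
        a = simulate_cop_trace(p, 0.5, 7)
        b = simulate_cop_trace(p, 0.5, 7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_length_and_rate(self):
        t = simulate_cop_trace(SwayProcessParams(), 1.0, 0)
        assert t.n == 4001
        assert t.rate == 200.0

    def test_white_noise_limit_large_theta(self):
        """theta >> sampling rate collapses the OU series to white noise."""
        p = SwayProcessParams(theta=1000.0)
        for seed in range(5):
            x = simulate_cop_trace(p, 1.0, seed).values
            r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
            assert abs(r1) < 0.1

    def test_stationary_marginal_sd(self):
        # marginal SD tracks amplitude_scale (theta=5, T=20 -> ~7% relative noise)
        vals = [np.std(simulate_cop_trace(SwayProcessParams(), 2.0, s).values) for s in range(40)]
        assert np.mean(vals) == pytest.approx(2.0, rel=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_cop_trace(SwayProcessParams(), -1.0, 0)
        with pytest.raises(ValueError):
            SwayProcessParams(theta=0)
        with pytest.raises(ValueError):
            SwayProcessParams(fp_rate=10, vr_rate=200)


class TestHeadsetObservation:
    def test_identity_observation_preserves_rms(self):
        """gain 1, no noise, cutoff near Nyquist: amplitude passes through."""
        proc = SwayProcessParams(theta=1.0)  # slow process, negligible power above 4.5 Hz
        head = HeadsetObservationParams(gain=1.0, smooth_cutoff=4.5, jitter_sd=0.0, drift_sd=0.0)
        for seed in range(5):
            cop = simulate_cop_trace(proc, 1.0, seed)
            vr = observe_headset_trace(cop, head, seed)
            assert vr.n == 201
            assert root_mean_square(vr) == pytest.approx(root_mean_square(cop), rel=0.05)

    def test_gain_linearity(self):
        proc = SwayProcessParams()
        cop = simulate_cop_trace(proc, 1.0, 3)
        h1 = HeadsetObservationParams(gain=1.0, jitter_sd=0.0, drift_sd=0.0)
        h3 = HeadsetObservationParams(gain=3.0, jitter_sd=0.0, drift_sd=0.0)
        v1 = observe_headset_trace(cop, h1, 3)
        v3 = observe_headset_trace(cop, h3, 3)
        np.testing.assert_allclose(v3.values, 3 * v1.values, rtol=1e-12)
        assert root_mean_square(v3) == pytest.approx(3 * root_mean_square(v1), rel=1e-12)

    def test_jitter_adds_path_length(self):
        """Headset jitter inflates NPL above the gain-scaled decimated COP's."""
        proc = SwayProcessParams()
        noisy = HeadsetObservationParams(jitter_sd=0.15, drift_sd=0.0)
        clean = HeadsetObservationParams(jitter_sd=0.0, drift_sd=0.0)
        for seed in range(100):
            cop = simulate_cop_trace(proc, 0.3, seed)
            npl_noisy = normalized_path_length(observe_headset_trace(cop, noisy, seed))
            npl_clean = normalized_path_length(observe_headset_trace(cop, clean, seed))
            assert npl_noisy > npl_clean

    def test_non_divisor_rate_falls_back_to_interpolation(self, caplog):
        proc = SwayProcessParams()
        cop = simulate_cop_trace(proc, 1.0, 0)
        head = HeadsetObservationParams(gain=1.0, smooth_cutoff=2.0, jitter_sd=0.0, drift_sd=0.0)
        with caplog.at_level("WARNING"):
            vr = observe_headset_trace(cop, head, 0, vr_rate=7.0)
        assert vr.n == 141
        assert any("interpolation" in r.message for r in caplog.records)

    def test_cutoff_above_nyquist_rejected(self):
        cop = simulate_cop_trace(SwayProcessParams(), 1.0, 0)
        with pytest.raises(ValueError):
            observe_headset_trace(cop, HeadsetObservationParams(smooth_cutoff=6.0), 0)


class TestAmplitudeModel:
    def test_zero_variance_components_give_identical_amplitudes(self):
        p = SwayProcessParams(tau2=0.0, omega2=0.0)
        amps = {subject_amplitude("EO", 0.0, 0.0, p) for _ in range(5)}
        assert amps == {p.sigma_base}

    def test_ec_multiplier_applies_only_eyes_closed(self):
        p = SwayProcessParams(ec_multiplier=1.5)
        assert subject_amplitude("EC", 0.0, 0.0, p) == pytest.approx(1.5 * p.sigma_base)
        assert subject_amplitude("EO", 0.0, 0.0, p) == pytest.approx(p.sigma_base)

    def test_log_amplitude_icc_dial(self, rng):
        """tau2 = omega2 = 0.04 puts the log-amplitude ICC near 0.5.

        Oracle: the variance-component ratio realized by directly simulated
        amplitudes for 500 subjects x 3 trials.
        """
        p = SwayProcessParams(tau2=0.04, omega2=0.04)
        n, k = 500, 3
        mat = np.empty((n, k))
        for i in range(n):
            u = rng.normal(0, np.sqrt(p.tau2))
            for j in range(k):
                w = rng.normal(0, np.sqrt(p.omega2))
                mat[i, j] = np.log(subject_amplitude("EC", u, w, p))
        assert icc_two_way_mixed(mat).icc == pytest.approx(0.5, abs=0.05)

    def test_omega_zero_gives_perfect_log_icc(self, rng):
        p = SwayProcessParams(tau2=0.04, omega2=0.0)
        mat = np.empty((10, 3))
        for i in range(10):
            u = rng.normal(0, np.sqrt(p.tau2))
            mat[i] = [np.log(subject_amplitude("EO", u, 0.0, p))] * 3
        assert icc_two_way_mixed(mat).icc == pytest.approx(1.0)


class TestCohort:
    def test_default_cohort_counts(self, default_manifest):
        assert len(default_manifest) == 480  # 20 * 2 * 2 * 3 * 2 devices
        assert len(default_manifest.traces) == 480
        pair_keys = {m.pair_key for m in default_manifest.traces}
        assert len(pair_keys) == 240

    def test_seed_determinism_in_memory(self):
        cfg = CohortConfig(n_subjects=3, n_trials=2, seed=9)
        m1 = generate_cohort(cfg)
        m2 = generate_cohort(cfg)
        assert m1.records.equals(m2.records)
        for meta, t1 in m1.traces.items():
            np.testing.assert_array_equal(t1.values, m2.traces[meta].values)

    def test_seed_determinism_on_disk(self, tmp_path):
        cfg = CohortConfig(n_subjects=2, n_trials=2, conditions=("EO",), directions=("ML",), seed=4)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(cfg, out_dir=d1)
        generate_cohort(cfg, out_dir=d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_adding_subjects_preserves_existing_traces(self):
        small = generate_cohort(CohortConfig(n_subjects=3, n_trials=2, seed=9))
        big = generate_cohort(CohortConfig(n_subjects=5, n_trials=2, seed=9))
        for meta, t in small.traces.items():
            np.testing.assert_array_equal(t.values, big.traces[meta].values)

    def test_refuses_nonempty_output_dir(self, tmp_path):
        (tmp_path / "stale.txt").write_text("x")
        cfg = CohortConfig(n_subjects=2, n_trials=2, conditions=("EO",), directions=("ML",), seed=4)
        with pytest.raises(FileExistsError):
            generate_cohort(cfg, out_dir=tmp_path)
        generate_cohort(cfg, out_dir=tmp_path, overwrite=True)  # flag unblocks

    def test_ec_amplitude_ratio(self, default_metrics):
        """Cohort-mean eyes-closed / eyes-open RMS tracks ec_multiplier = 1.5."""
        fp = default_metrics[default_metrics.device == "FP"]
        ratio = (
            fp[fp.condition == "EC"].rms_cm.mean() / fp[fp.condition == "EO"].rms_cm.mean()
        )
        assert ratio == pytest.approx(1.5, rel=0.10)

    def test_ap_anisotropy(self, default_metrics):
        fp = default_metrics[default_metrics.device == "FP"]
        ratio = fp[fp.direction == "AP"].rms_cm.mean() / fp[fp.direction == "ML"].rms_cm.mean()
        assert ratio == pytest.approx(1.2, rel=0.10)

    def test_paired_device_amplitude_coupling(self):
        """Per-trial RMS correlates across devices -> 1 as headset noise -> 0."""
        from swayval.sway_metrics import metrics_table

        cfg = CohortConfig(
            n_subjects=10,
            n_trials=3,
            conditions=("EC",),
            directions=("ML",),
            seed=21,
            headset=HeadsetObservationParams(
                smooth_cutoff=4.5, jitter_sd=0.0, drift_sd=0.0, gain_log_sd=0.0
            ),
        )
        m = metrics_table(generate_cohort(cfg))
        wide = m.pivot_table(
            index=["subject_id", "trial"], columns="device", values="rms_cm"
        )
        assert np.corrcoef(wide["FP"], wide["VR"])[0, 1] > 0.995

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=1)
        with pytest.raises(ValueError):
            CohortConfig(n_trials=1)
        with pytest.raises(ValueError):
            CohortConfig(conditions=("XX",))
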