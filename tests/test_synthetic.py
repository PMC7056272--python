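"""Ground-truth properties of the synthetic data generators."""

import numpy as np
import pytest

from ephyskit import synth


class TestEEGGenerator:
    def test_no_events_requested_no_annotations(self):
        cfg = synth.EEGSimConfig(duration_s=30.0, sample_rate_hz=500.0,
                                 swd_rate_per_hr=0.0, myoclonus_rate_per_hr=0.0, seed=1)
        rec, ann = synth.generate_eeg(cfg)
        assert ann == []
        assert rec.n_channels == 4  # 3 EEG + 1 EMG
        assert rec.n_samples == 15000

    def test_identical_seeds_identical_output(self):
        cfg = dict(duration_s=60.0, sample_rate_hz=500.0, swd_rate_per_hr=120.0,
                   myoclonus_rate_per_hr=30.0, seed=7)
        rec1, ann1 = synth.generate_eeg(synth.EEGSimConfig(**cfg))
        rec2, ann2 = synth.generate_eeg(synth.EEGSimConfig(**cfg))
        np.testing.assert_array_equal(rec1.data, rec2.data)
        assert ann1 == ann2

    def test_swd_count_matches_poisson_mean(self):
        """Over many seeds, mean SWD count approaches rate x duration
        within 3 standard errors (Poisson mean/variance)."""
        rate_hr, dur_s, n_seeds = 60.0, 720.0, 60
        expected = rate_hr * dur_s / 3600.0
        counts = []
        for seed in range(n_seeds):
            cfg = synth.EEGSimConfig(duration_s=dur_s, sample_rate_hz=500.0,
                                     swd_rate_per_hr=rate_hr, seed=seed)
            _, ann = synth.generate_eeg(cfg)
            counts.append(sum(a.event_kind == "SWD" for a in ann))
        se = np.sqrt(expected / n_seeds)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_every_injected_swd_is_annotated_and_sorted(self):
        cfg = synth.EEGSimConfig(duration_s=300.0, sample_rate_hz=1000.0,
                                 swd_rate_per_hr=240.0, seed=3)
        _, ann = synth.generate_eeg(cfg)
        onsets = [a.onset_s for a in ann]
        assert onsets == sorted(onsets)
        assert all(a.offset_s > a.onset_s for a in ann)

    def test_background_spectrum_is_low_frequency_dominated(self):
        """Average power in 100-300 Hz stays below power in 0.5-80 Hz."""
        cfg = synth.EEGSimConfig(duration_s=60.0, swd_rate_per_hr=0.0, seed=5)
        rec, _ = synth.generate_eeg(cfg)
        x = rec.data[0].astype(float)
        freqs = np.fft.rfftfreq(x.size, 1 / rec.sample_rate_hz)
        power = np.abs(np.fft.rfft(x)) ** 2
        upper = power[(freqs >= 100) & (freqs <= 300)].mean()
        lower = power[(freqs >= 0.5) & (freqs <= 80)].mean()
        assert upper < lower

    def test_cluster_injection_annotated_with_cluster_id(self):
        cfg = synth.EEGSimConfig(duration_s=900.0, sample_rate_hz=500.0,
                                 swd_rate_per_hr=0.0, cluster_spec=(6, 40.0), seed=9)
        _, ann = synth.generate_eeg(cfg)
        members = [a for a in ann if a.cluster_id == 0]
        assert len(members) >= 5
        gaps = [b.onset_s - a.offset_s for a, b in zip(members, members[1:])]
        assert all(g <= 40.0 for g in gaps)

    def test_state_schedule_must_tile_duration(self):
        with pytest.raises(synth.ConfigurationError):
            synth.EEGSimConfig(duration_s=100.0, state_schedule=[("awake", 0.0, 50.0),
                                                                 ("REM", 60.0, 100.0)], seed=0)
        with pytest.raises(synth.ConfigurationError):
            synth.EEGSimConfig(duration_s=100.0, state_schedule=[("awake", 0.0, 60.0),
                                                                 ("NREM", 50.0, 100.0)], seed=0)

    def test_myoclonus_couples_eeg_spike_and_emg_burst(self):
        cfg = synth.EEGSimConfig(duration_s=600.0, sample_rate_hz=1000.0,
                                 swd_rate_per_hr=0.0, myoclonus_rate_per_hr=60.0,
                                 eeg_emg_lag_ms=15.0, seed=13)
        rec, ann = synth.generate_eeg(cfg)
        jerks = [a for a in ann if a.event_kind == "myoclonic_jerk"]
        assert jerks
        emg = rec.data[rec.emg_indices()[0]].astype(float)
        emg_sd = np.std(emg)
        for a in jerks:
            i0 = int((a.onset_s + 0.015) * 1000.0)
            seg = np.abs(emg[i0 : i0 + 50])
            assert seg.max() > 3 * emg_sd  # burst present after the EEG spike


class TestPatchGenerator:
    def test_zero_baseline_rate_puts_all_events_in_light(self):
        cfg = synth.PatchSimConfig(rate_baseline_hz=0.0, seed=2)
        _, truth = synth.generate_patch_sweeps(cfg)
        assert (truth["window"] == "light").all()

    def test_zero_cv_gives_constant_amplitudes(self):
        cfg = synth.PatchSimConfig(amplitude_cv=0.0, seed=2)
        _, truth = synth.generate_patch_sweeps(cfg)
        assert np.allclose(truth["amplitude_pa"], cfg.amplitude_mean_pa)

    def test_determinism(self):
        a, ta = synth.generate_patch_sweeps(synth.PatchSimConfig(seed=4))
        b, tb = synth.generate_patch_sweeps(synth.PatchSimConfig(seed=4))
        np.testing.assert_array_equal(a.data, b.data)
        assert ta.equals(tb)

    def test_evoked_count_matches_rate_difference(self):
        """20 sweeps at 2 Hz light vs 1 Hz baseline yield ~200 extra light
        events on average (difference of Poisson means)."""
        diffs = []
        for seed in range(1, 31):
            cfg = synth.PatchSimConfig(n_sweeps=20, rate_light_hz=2.0,
                                       rate_baseline_hz=1.0, seed=seed)
            _, truth = synth.generate_patch_sweeps(cfg)
            diffs.append((truth["window"] == "light").sum() - (truth["window"] == "baseline").sum())
        expected = 20 * 10 * (2.0 - 1.0)
        se = np.sqrt(20 * 10 * (2.0 + 1.0) / len(diffs))
        assert abs(np.mean(diffs) - expected) < 3 * se

    def test_tonic_current_confined_to_light_window(self):
        cfg = synth.PatchSimConfig(rate_baseline_hz=0.0, rate_light_hz=0.0,
                                   noise_sd_pa=0.0, tonic_ramp_pa=30.0, seed=0)
        sweeps, _ = synth.generate_patch_sweeps(cfg)
        fs = sweeps.sample_rate_hz
        b0, b1 = cfg.baseline_window_s
        assert np.abs(sweeps.data[:, int(b0 * fs) : int(b1 * fs)]).max() == 0.0
        i0 = int(cfg.light_window_s[0] * fs)
        assert sweeps.data[0, i0] == pytest.approx(30.0, rel=1e-3)

    def test_negative_rate_rejected(self):
        with pytest.raises(synth.ConfigurationError):
            synth.PatchSimConfig(rate_light_hz=-1.0, seed=0)


class TestUIPSCGenerator:
    def test_unconnected_sweeps_are_noise_only(self):
        cfg = synth.UIPSCSimConfig(connected=False, seed=6)
        sweeps = synth.generate_uipsc_sweeps(cfg)
        avg = sweeps.data.mean(axis=0)
        # average of pure noise shrinks as 1/sqrt(n_sweeps)
        assert np.abs(avg).max() < 3 * cfg.baseline_noise_sd_pa / np.sqrt(cfg.n_sweeps) * 2.5

    def test_pulse_times_at_10hz_spacing(self):
        sweeps = synth.generate_uipsc_sweeps(synth.UIPSCSimConfig(seed=6))
        stim = np.asarray(sweeps.metadata["stim_times_s"])
        assert np.allclose(np.diff(stim), 0.1)
        assert len(stim) == 6

    def test_flat_depression_profile_gives_equal_amplitudes(self):
        cfg = synth.UIPSCSimConfig(depression_profile=(1.0,) * 6, trial_cv=0.0,
                                   baseline_noise_sd_pa=0.01, seed=6)
        sweeps = synth.generate_uipsc_sweeps(cfg)
        fs = sweeps.sample_rate_hz
        avg = sweeps.data.mean(axis=0)
        amps = [avg[int(t * fs) : int(t * fs) + 300].max() for t in sweeps.metadata["stim_times_s"]]
        assert np.ptp(amps) / np.mean(amps) < 0.02

    def test_depression_profile_length_validated(self):
        with pytest.raises(synth.ConfigurationError):
            synth.UIPSCSimConfig(depression_profile=(1.0, 0.8), seed=0)
        with pytest.raises(synth.ConfigurationError):
            synth.UIPSCSimConfig(depression_profile=(0.9,) * 6, seed=0)

    def test_determinism(self):
        a = synth.generate_uipsc_sweeps(synth.UIPSCSimConfig(seed=4))
        b = synth.generate_uipsc_sweeps(synth.UIPSCSimConfig(seed=4))
        np.testing.assert_array_equal(a.data, b.data)
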