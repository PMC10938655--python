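import numpy as np
import pytest
from scipy import signal as sps

import flowstarve as fs
from flowstarve.preprocessing import (
    condition_recording,
    preprocess_recording,
    segment_breaths,
)


class TestLowpassFilter:
    def test_constant_signal_passes_unchanged(self):
        x = np.full(500, 7.3)
        np.testing.assert_allclose(fs.lowpass_filter(x, fs=200), x, atol=1e-9)

    @pytest.mark.parametrize(
        "freq, check",
        [(2.0, "pass"), (40.0, "stop")],
    )
    def test_frequency_response_matches_design(self, freq, check):
        # oracle: the designed filter's own frequency response, squared for
        # the forward-backward application
        fs_hz = 200.0
        sos = sps.butter(4, 15.0, btype="low", fs=fs_hz, output="sos")
        _, h = sps.sosfreqz(sos, worN=[freq], fs=fs_hz)
        expected_gain = np.abs(h[0]) ** 2
        t = np.arange(int(10 * fs_hz)) / fs_hz
        x = np.sin(2 * np.pi * freq * t)
        y = fs.lowpass_filter(x, fs=fs_hz)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        gain = np.max(np.abs(y[mid]))
        if check == "pass":
            assert gain == pytest.approx(expected_gain, rel=0.01)
            assert gain > 0.99
        else:
            # deep stopband: residual transient leakage dominates, so only
            # the order of magnitude of the designed response is checkable
            assert gain == pytest.approx(expected_gain, rel=0.10)
            assert gain < 0.10  # >90% attenuation

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            fs.lowpass_filter(np.zeros(100), fs=20.0, cutoff=10.0)


class TestDecimate:
    def test_identity_when_rates_equal(self):
        x = np.random.default_rng(0).normal(size=300)
        np.testing.assert_array_equal(fs.decimate(x, 40.0, 40.0), x)

    def test_output_length(self):
        x = np.zeros(2000)  # 10 s at 200 Hz
        assert len(fs.decimate(x, 200.0, 40.0)) == 400

    def test_slow_ramp_is_resampled_pointwise(self):
        t = np.arange(2000) / 200.0
        x = 0.5 * t
        y = fs.decimate(x, 200.0, 40.0)
        expected = 0.5 * np.arange(len(y)) / 40.0
        inner = slice(5, -5)  # polyphase edges excluded
        np.testing.assert_allclose(y[inner], expected[inner], atol=1e-3)

    def test_upsampling_refused(self):
        with pytest.raises(ValueError, match="upsample"):
            fs.decimate(np.zeros(10), 40.0, 100.0)

    def test_mean_preserved_for_bandlimited_signal(self):
        t = np.arange(4000) / 200.0
        x = 10 + np.sin(2 * np.pi * 1.5 * t)
        y = fs.decimate(fs.lowpass_filter(x, 200.0), 200.0, 40.0)
        assert np.mean(y) == pytest.approx(np.mean(x), rel=0.01)


class TestResampleToFixedLength:
    def test_constant_input(self):
        np.testing.assert_allclose(
            fs.resample_to_fixed_length([4.2] * 17), np.full(80, 4.2)
        )

    def test_identity_on_own_grid(self):
        x = np.random.default_rng(1).normal(size=80)
        np.testing.assert_allclose(fs.resample_to_fixed_length(x), x, atol=1e-12)

    def test_linear_ramp_stays_linear(self):
        x = np.linspace(3.0, 9.0, 37)
        y = fs.resample_to_fixed_length(x)
        ideal = np.linspace(3.0, 9.0, 80)
        assert y[0] == x[0] and y[-1] == x[-1]
        np.testing.assert_allclose(y, ideal, atol=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fs.resample_to_fixed_length([1.0])


class TestSegmentation:
    def test_breath_count_matches_ground_truth(self, small_cohort):
        recordings, table = small_cohort
        for rec in recordings:
            cond = condition_recording(rec)
            segments = segment_breaths(cond)
            gt = table[table.patient_id == rec.patient_id]
            assert len(segments) == len(gt)

    def test_all_zero_flow_gives_no_segments(self):
        n = 400
        rec = fs.WaveformRecording(
            "p", 40.0, np.arange(n) / 40.0, np.zeros(n), np.full(n, 5.0)
        )
        assert segment_breaths(rec) == []

    def test_segments_tile_without_overlap(self, small_cohort):
        rec = small_cohort[0][0]
        cond = condition_recording(rec)
        segments = segment_breaths(cond)
        for a, b in zip(segments, segments[1:]):
            assert a.breath_end == b.insufflation_start
            assert a.insufflation_start < a.inspiratory_end < a.breath_end

    def test_patient_trigger_flags_match_simulator(self, small_cohort):
        recordings, table = small_cohort
        rec = recordings[0]
        cond = condition_recording(rec)
        segments = segment_breaths(cond)
        gt = table[table.patient_id == rec.patient_id].reset_index(drop=True)
        flags = [s.patient_triggered for s in segments]
        assert flags == gt["patient_triggered"].tolist()

    def test_passive_breath_not_patient_triggered(self, default_mech, default_vent):
        b = fs.simulate_assisted_breath(
            default_mech, default_vent, fs.EffortProfile(amplitude=0.0),
            fs=40.0, noise_sd=0.0,
        )
        rec = fs.WaveformRecording("p", 40.0, b.time, b.flow, b.paw, b.pes)
        segments = segment_breaths(rec)
        assert len(segments) == 1
        assert not segments[0].patient_triggered

    def test_dip_exactly_at_sensitivity_counts(self):
        # boundary convention: a dip of exactly the sensitivity is a trigger
        fs_hz = 40.0
        n = 200
        paw = np.full(n, 5.0)
        flow = np.zeros(n)
        start = 100
        paw[start - 6 : start] = 5.0 - 0.5  # exact 0.5 cmH2O dip
        flow[start : start + 40] = 30.0
        rec = fs.WaveformRecording("p", fs_hz, np.arange(n) / fs_hz, flow, paw)
        seg = segment_breaths(rec)[0]
        assert fs.detect_patient_trigger(seg, rec, sensitivity=0.5)
        assert seg.trigger_onset < seg.insufflation_start


class TestInspiratoryPhase:
    def test_window_length_matches_timing(self, default_mech, default_vent):
        b = fs.simulate_assisted_breath(
            default_mech, default_vent,
            fs.EffortProfile(amplitude=8.0, onset=0.85),
            fs=40.0, noise_sd=0.0,
        )
        rec = fs.WaveformRecording("p", 40.0, b.time, b.flow, b.paw, b.pes)
        seg = segment_breaths(rec)[0]
        phase = fs.extract_inspiratory_phase(seg, rec)
        # about 1 s insufflation plus the trigger phase at 40 Hz
        assert 40 <= len(phase) <= 55

    def test_phase_is_contiguous_paw_slice(self, small_cohort):
        rec = small_cohort[0][0]
        cond = condition_recording(rec)
        seg = [s for s in segment_breaths(cond) if s.patient_triggered][0]
        phase = fs.extract_inspiratory_phase(seg, cond)
        np.testing.assert_array_equal(
            phase, cond.paw[seg.trigger_onset : seg.inspiratory_end + 1]
        )

    def test_non_triggered_segment_rejected(self, default_mech, default_vent):
        b = fs.simulate_assisted_breath(
            default_mech, default_vent, fs.EffortProfile(amplitude=0.0),
            fs=40.0, noise_sd=0.0,
        )
        rec = fs.WaveformRecording("p", 40.0, b.time, b.flow, b.paw)
        seg = segment_breaths(rec)[0]
        with pytest.raises(ValueError, match="patient-triggered"):
            fs.extract_inspiratory_phase(seg, rec)


class TestBreathFeatures:
    def test_square_flow_closed_forms(self, default_mech, default_vent):
        pb = fs.simulate_passive_breath(default_mech, default_vent, fs=40.0)
        rec = fs.WaveformRecording(
            "p", 40.0, pb["time"], pb["flow"], pb["paw"], pb["pes"]
        )
        seg = segment_breaths(rec)[0]
        feats = fs.compute_breath_features(seg, rec)
        assert feats.peak_insp_flow == pytest.approx(30.0, abs=0.5)
        assert feats.tidal_volume == pytest.approx(500.0, rel=0.02)
        assert feats.Ti == pytest.approx(1.0, abs=1.5 / 40.0)

    def test_peep_recovered_on_noiseless_breath(self, default_mech, default_vent):
        b = fs.simulate_assisted_breath(
            default_mech, default_vent, fs.EffortProfile(amplitude=6.0, onset=0.85),
            fs=40.0, noise_sd=0.0, te=2.5,
        )
        rec = fs.WaveformRecording("p", 40.0, b.time, b.flow, b.paw, b.pes)
        seg = segment_breaths(rec)[0]
        feats = fs.compute_breath_features(seg, rec)
        assert feats.peep == pytest.approx(5.0, abs=0.1)


class TestPipeline:
    def test_one_vector_per_patient_triggered_breath(self, small_cohort):
        recordings, table = small_cohort
        for rec in recordings:
            _, segments, x, feats = preprocess_recording(rec)
            gt = table[table.patient_id == rec.patient_id]
            n_expected = int(gt["patient_triggered"].sum())
            assert x.shape == (n_expected, 80)
            assert len(segments) == len(feats) == n_expected
            assert np.all(np.isfinite(x))
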