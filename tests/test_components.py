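"""Window location, component metrics, evoked-component isolation, MUA path."""

import numpy as np
import pytest

from gainsep import (
    compute_metrics,
    evoked_component,
    generate_roi_traces,
    generate_spike_counts,
    locate_windows,
    normalize_mua,
    normalize_to_first_peak,
)
from gainsep.protocol import default_train_protocol
from gainsep.synth import anesthetized_ground_truth, evoked_waveform

from conftest import S, S_PH, V, V_PH


class TestNormalization:
    def test_control_first_peak_becomes_one(self, train_proto, clean_gt):
        traces = {
            "V": generate_roi_traces(clean_gt, train_proto, V, 2),
            "V_ph": generate_roi_traces(clean_gt, train_proto, V_PH, 2),
        }
        normed, scale = normalize_to_first_peak(traces, train_proto)
        onset = train_proto.stim_onsets[0]
        i0 = int(onset * train_proto.frame_rate)
        i1 = i0 + int(train_proto.frame_rate)
        assert normed["V"].mean(axis=0)[i0:i1].max() == pytest.approx(1.0)

    def test_common_scale_preserves_condition_ratios(self, train_proto, clean_gt):
        traces = {
            "V": generate_roi_traces(clean_gt, train_proto, V, 2),
            "V_ph": generate_roi_traces(clean_gt, train_proto, V_PH, 2),
        }
        before = traces["V_ph"].mean() / traces["V"].mean()
        normed, _ = normalize_to_first_peak(traces, train_proto)
        after = normed["V_ph"].mean() / normed["V"].mean()
        assert after == pytest.approx(before, rel=1e-12)

    def test_nonpositive_peak_rejected(self, train_proto):
        flatline = {"V": -np.ones((1, train_proto.n_frames))}
        with pytest.raises(ValueError, match="peak"):
            normalize_to_first_peak(flatline, train_proto)


class TestWindows:
    def test_peak_found_at_kernel_delay(self, train_proto_100):
        gt = anesthetized_ground_truth(kernel=(0.05, 0.35, 0.35))
        trace = evoked_waveform(gt, train_proto_100, 1.0)
        win = locate_windows(trace, train_proto_100)
        dt = 1.0 / train_proto_100.frame_rate
        for onset, t_pk in zip(train_proto_100.stim_onsets, win.peak_times):
            assert t_pk == pytest.approx(onset + 0.35, abs=2 * dt)

    def test_flat_trace_ties_to_onset_with_warning(self, train_proto):
        with pytest.warns(UserWarning, match="flat"):
            win = locate_windows(np.zeros(train_proto.n_frames), train_proto)
        assert win.peak_times[0] == train_proto.stim_onsets[0]

    def test_late_stimulus_window_truncated(self):
        proto = default_train_protocol(frame_rate=20.0, stim_onsets=(0.2, 29.9))
        trace = np.zeros(proto.n_frames)
        trace[int(29.95 * 20) :] = 1.0  # rising into trial end
        with pytest.warns(UserWarning, match="truncated"):
            win = locate_windows(trace, proto)
        assert win.w1[1][1] <= proto.trial_duration

    def test_w_red_from_significance_mask(self, train_proto):
        m = np.zeros(train_proto.n_frames, dtype=bool)
        i_on = int(2.5 * train_proto.frame_rate)
        m[i_on + 10 : i_on + 40] = True
        win = locate_windows(np.zeros(train_proto.n_frames), train_proto,
                             significance_mask=m)
        t0, t1 = win.w_red
        assert t0 == pytest.approx(2.5 + 10 / train_proto.frame_rate)
        assert t1 == pytest.approx(2.5 + 40 / train_proto.frame_rate)
        on, off = train_proto.photostim_window
        assert on <= t0 and t1 <= off


class TestMetrics:
    def test_constant_trace_metrics(self, train_proto):
        win = locate_windows(np.zeros(train_proto.n_frames), train_proto)
        m = compute_metrics(np.full(train_proto.n_frames, 0.3), win,
                            train_proto.frame_rate)
        assert np.allclose(m.amplitude, 0.3)
        assert np.allclose(m.baseline, 0.3)
        assert np.allclose(m.magnitude, 0.0)

    def test_magnitude_is_absolute_difference(self):
        from gainsep.components import ComponentMetrics

        m = ComponentMetrics(
            amplitude=np.array([0.8]), baseline=np.array([-0.2]),
            magnitude=np.abs(np.array([0.8]) - np.array([-0.2])),
            peak_time=np.array([0.5]),
        )
        assert m.magnitude[0] == pytest.approx(1.0)

    def test_w1_spans_40_frames_at_100hz(self, train_proto_100, clean_gt):
        """The 400 ms peak window covers 40 frames at the 100 Hz acquisition
        rate."""
        trace = evoked_waveform(clean_gt, train_proto_100, 1.0)
        win = locate_windows(trace, train_proto_100)
        from gainsep.protocol import time_to_frames

        i0, i1 = time_to_frames(*win.w1[0], train_proto_100.frame_rate)
        assert i1 - i0 == 40

    def test_magnitude_invariant_to_constant_offset(self, train_proto, clean_gt):
        trace = generate_roi_traces(clean_gt, train_proto, V, 1)[0]
        win = locate_windows(trace, train_proto)
        m0 = compute_metrics(trace, win, train_proto.frame_rate)
        m1 = compute_metrics(trace + 0.7, win, train_proto.frame_rate)
        assert np.allclose(m0.magnitude, m1.magnitude, atol=1e-12)
        assert np.allclose(m1.amplitude, m0.amplitude + 0.7)


class TestEvokedComponent:
    def test_identical_conditions_cancel(self):
        x = np.random.default_rng(0).normal(size=(5, 100))
        eph, avg, used = evoked_component(x, x)
        assert used == "index"
        assert np.allclose(eph, 0.0)

    def test_unequal_counts_fall_back_to_mean(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(4, 50))
        s = rng.normal(size=(3, 50))
        eph, avg, used = evoked_component(v, s)
        assert used == "mean"
        assert np.allclose(eph, v - s.mean(axis=0))

    def test_no_sph_trials_rejected(self):
        with pytest.raises(ValueError, match="S_ph"):
            evoked_component(np.ones((2, 10)), np.empty((0, 10)))

    def test_recovers_scaled_evoked_waveform(self, train_proto):
        """With a shared spontaneous process, V_ph - S_ph recovers g_e
        (during photostimulation) times the injected evoked waveform."""
        gt = anesthetized_ground_truth(seed=3, late_rise=(4.0, 0.0))
        n = 12
        vph = generate_roi_traces(gt, train_proto, V_PH, n)
        sph = generate_roi_traces(gt, train_proto, S_PH, n)
        eph, avg, used = evoked_component(vph, sph)
        assert used == "index"
        ev = evoked_waveform(gt, train_proto, 1.0)
        g_e = np.where(train_proto.photostim_mask(), gt.evoked_gain, 1.0)
        assert np.allclose(avg, ev * g_e, atol=1e-10)

    def test_recovery_error_shrinks_with_trials(self, train_proto):
        """Unpaired subtraction: RMSE versus the injected evoked waveform
        decreases roughly as 1/sqrt(trials)."""
        gt = anesthetized_ground_truth(seed=9, late_rise=(4.0, 0.0),
                                       paired_spontaneous=False)
        ev = evoked_waveform(gt, train_proto, 1.0)
        g_e = np.where(train_proto.photostim_mask(), gt.evoked_gain, 1.0)
        target = ev * g_e

        def rmse(n):
            vph = generate_roi_traces(gt, train_proto, V_PH, n)
            sph = generate_roi_traces(gt, train_proto, S_PH, n)
            _, avg, _ = evoked_component(vph, sph, pairing="mean")
            return np.sqrt(((avg - target) ** 2).mean())

        assert rmse(64) < rmse(4) / 2  # expect ~1/4 ratio, allow slack


class TestSeparability:
    def test_vph_magnitude_matches_evoked_component_magnitude(self, train_proto):
        """V_ph built as evoked + shared spontaneous: magnitudes of V_ph and
        E_ph agree (baseline-independent), amplitudes differ by the injected
        baseline shift."""
        gt = anesthetized_ground_truth(seed=21, late_rise=(4.0, 0.0))
        n = 30
        vph = generate_roi_traces(gt, train_proto, V_PH, n)
        sph = generate_roi_traces(gt, train_proto, S_PH, n)
        v = generate_roi_traces(gt, train_proto, V, n)
        eph, eph_avg, _ = evoked_component(vph, sph)
        win = locate_windows(v.mean(axis=0), train_proto)
        rate = train_proto.frame_rate
        m_vph = compute_metrics(vph.mean(axis=0), win, rate)
        m_eph = compute_metrics(eph_avg, win, rate)
        # last in-photostim stimulus straddles the photostim offset (gain
        # steps inside its peak window) — compare the fully interior ones
        idx = train_proto.stimuli_in_photostim()[:-1]
        assert np.allclose(m_vph.magnitude[idx], m_eph.magnitude[idx], rtol=0.05)
        shift = (m_vph.amplitude - m_eph.amplitude)[idx].mean()
        m_sph = compute_metrics(sph.mean(axis=0), win, rate)
        assert shift == pytest.approx(m_sph.amplitude[idx].mean(), abs=1e-10)


class TestMuaNormalization:
    def test_constant_unit_spontaneous_path_is_unity(self, train_proto):
        gt = anesthetized_ground_truth(
            seed=2, spont_gain=1.0, spont_offset=0.0,
            base_rate_range=(5.0, 5.0),
        )
        mat = generate_spike_counts(gt, train_proto, S, n_units=10, n_trials=400)
        traces, kept, flagged = normalize_mua(mat, train_proto)
        assert not flagged
        # baseline is estimated from the first second only, so each unit's
        # ratio carries ~2% sampling error
        assert np.allclose(traces.mean(axis=1), 1.0, atol=0.08)

    def test_constant_unit_evoked_path_is_zero_before_division(self, train_proto):
        rates = np.full((3, 150, 50), 1, dtype=int)  # 5 Hz at 0.2 s bins
        from gainsep.io import SpikeCountMatrix
        from gainsep.protocol import ConditionLabel

        mat = SpikeCountMatrix(counts=rates, condition=V)
        traces, kept, flagged = normalize_mua(mat, train_proto)
        assert np.allclose(traces, 0.0)

    def test_150_bins_per_30s_trial(self, train_proto, clean_gt):
        mat = generate_spike_counts(clean_gt, train_proto, S, n_units=2,
                                    n_trials=2)
        assert mat.counts.shape[1] == 150

    def test_zero_baseline_unit_flagged(self, train_proto):
        counts = np.ones((2, 150, 3), dtype=int)
        counts[1, :, :] = 0
        from gainsep.io import SpikeCountMatrix

        mat = SpikeCountMatrix(counts=counts, condition=S)
        traces, kept, flagged = normalize_mua(mat, train_proto)
        assert flagged == [1]
        assert traces.shape[0] == 1
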