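"""Δf/f identities, spatial filters, ROI selection and the assembled stage."""

import numpy as np
import pytest

from gainsep import (
    compute_dff,
    generate_trial_stack,
    preprocess_trials,
    remove_artifacts_ica,
    select_roi,
    spatial_average,
    spatial_filter,
)
from gainsep.preprocess import PreprocessError, blank_normalized_mean
from gainsep.protocol import default_train_protocol
from gainsep.synth import anesthetized_ground_truth, roi_signal

from conftest import S, S_PH, V, V_PH


class TestDff:
    def test_stack_equal_to_blank_gives_zero(self, train_proto, noisy_gt):
        stack = generate_trial_stack(noisy_gt, train_proto, S, trial=0)
        blank = blank_normalized_mean([stack], train_proto)
        dff = compute_dff(stack, blank, train_proto)
        assert np.allclose(dff, 0.0, atol=1e-12)

    def test_constant_stack_and_blank_give_zero(self, train_proto):
        stack = np.full((train_proto.n_frames, 4, 4), 7.0)
        blank = np.full_like(stack, 3.0)
        blank_norm = blank_normalized_mean([blank], train_proto)
        assert np.allclose(compute_dff(stack, blank_norm, train_proto), 0.0)

    def test_ten_percent_transient_measures_point_one(self, train_proto):
        """A pixel rising 10% over its own pre-stimulus mean against a flat
        blank reads exactly 0.1 after the three normalization steps."""
        n = train_proto.n_frames
        stack = np.full((n, 2, 2), 50.0)
        stack[100:110, 0, 0] = 55.0  # +10% transient
        blank = blank_normalized_mean([np.full((n, 2, 2), 80.0)], train_proto)
        dff = compute_dff(stack, blank, train_proto)
        assert dff[105, 0, 0] == pytest.approx(0.1, abs=1e-12)
        assert np.allclose(dff[:100], 0.0)

    def test_zero_prestim_pixel_is_named(self, train_proto):
        stack = np.ones((train_proto.n_frames, 3, 3))
        stack[:4, 1, 2] = 0.0
        with pytest.raises(PreprocessError, match=r"y=1, x=2"):
            blank_normalized_mean([stack], train_proto)

    def test_shape_mismatch_rejected(self, train_proto):
        stack = np.ones((train_proto.n_frames, 4, 4))
        blank = np.ones((train_proto.n_frames, 5, 5))
        with pytest.raises(PreprocessError, match="shape"):
            compute_dff(stack, blank, train_proto)


class TestSpatialFilter:
    def test_constant_frame_zeroed_by_highpass(self):
        stack = np.full((3, 32, 32), 5.0)
        out = spatial_filter(stack, smooth_sigma=0.0, cutoff_wavelength=16.0)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_sinusoid_at_cutoff_attenuated_to_half_power(self):
        """|H| at the cutoff frequency is 1/sqrt(2) for any Butterworth
        order."""
        n, wavelength = 66, 33.0
        x = np.arange(n)
        frame = np.sin(2 * np.pi * x / wavelength)[None, :] * np.ones((n, 1))
        out = spatial_filter(frame[None], smooth_sigma=0.0,
                             cutoff_wavelength=wavelength)[0]
        ratio = out.std() / frame.std()
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_identity_when_disabled(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(size=(2, 16, 16))
        out = spatial_filter(stack, smooth_sigma=0.0, cutoff_wavelength=None)
        assert np.allclose(out, stack)

    def test_cutoff_below_nyquist_rejected(self):
        with pytest.raises(PreprocessError, match="Nyquist"):
            spatial_filter(np.zeros((1, 8, 8)), cutoff_wavelength=2.0)


class TestRoi:
    def test_single_bump_mask_contains_peak(self):
        y, x = np.mgrid[0:32, 0:32]
        bump = np.exp(-((y - 10) ** 2 + (x - 20) ** 2) / 20.0)
        mask = select_roi(bump, threshold_frac=0.7)
        assert mask[10, 20]
        from scipy import ndimage

        _, n = ndimage.label(mask)
        assert n == 1

    def test_two_equal_bumps_tie_break_row_major(self):
        m = np.zeros((20, 20))
        m[2:5, 2:5] = 1.0  # first-scanned bump
        m[12:15, 12:15] = 1.0
        mask = select_roi(m, threshold_frac=0.9)
        assert mask[3, 3] and not mask[13, 13]

    def test_threshold_one_keeps_only_argmax(self):
        m = np.zeros((8, 8))
        m[4, 5] = 2.0
        m[1, 1] = 1.0
        mask = select_roi(m, threshold_frac=1.0)
        assert mask.sum() == 1 and mask[4, 5]

    def test_all_zero_map_rejected(self):
        with pytest.raises(PreprocessError, match="no responsive region"):
            select_roi(np.zeros((8, 8)))

    def test_spatial_average_values(self):
        frame = np.zeros((2, 4, 4))
        frame[:, :2, :] = 2.0
        mask = np.ones((4, 4), dtype=bool)
        assert np.allclose(spatial_average(frame, mask), 1.0)
        with pytest.raises(PreprocessError, match="empty"):
            spatial_average(frame, np.zeros((4, 4), dtype=bool))


class TestIca:
    def test_corner_artifact_removed_signal_preserved(self, train_proto):
        """A 20 Hz corner artifact loses >=10x power while the ROI evoked
        peak moves by less than 5%."""
        proto = default_train_protocol()  # full 30 s at 100 Hz
        gt = anesthetized_ground_truth(
            seed=31, image_shape=(16, 16), noise_std=0.5,
            artifacts=(10.0, 3.0, 30.0, 0.3), late_rise=(4.0, 0.0),
        )
        stacks = [generate_trial_stack(gt, proto, V_PH, t) for t in range(2)]
        cleaned, report = remove_artifacts_ica(
            stacks, proto, bands=(20.0,), seed=0
        )
        assert any(r["rejected"] for r in report["trials"])

        def band_power(stack, px):
            from scipy.signal import periodogram

            f, psd = periodogram(stack[:, px[0], px[1]], fs=proto.frame_rate)
            return psd[(f >= 19.5) & (f <= 20.5)].sum()

        corner = (15, 1)  # inside the artifact block
        raw = np.asarray(stacks[0].pixels)
        p_before = band_power(raw, corner)
        p_after = band_power(cleaned[0], corner)
        assert p_before / max(p_after, 1e-12) >= 10

        from gainsep.synth import roi_profile

        roi = roi_profile(gt) > 0.5
        tr_before = spatial_average(raw, roi)
        tr_after = spatial_average(cleaned[0], roi)
        peak_before = (tr_before - tr_before.mean()).max()
        peak_after = (tr_after - tr_after.mean()).max()
        assert peak_after == pytest.approx(peak_before, rel=0.05)

    def test_empty_bands_is_identity(self, train_proto, noisy_gt):
        stacks = [generate_trial_stack(noisy_gt, train_proto, S, t)
                  for t in range(2)]
        cleaned, report = remove_artifacts_ica(stacks, train_proto, bands=())
        for c, s in zip(cleaned, stacks):
            assert np.array_equal(c, s.pixels)

    def test_single_trial_rejected(self, train_proto, noisy_gt):
        stack = generate_trial_stack(noisy_gt, train_proto, S, 0)
        with pytest.raises(PreprocessError, match="2 trials"):
            remove_artifacts_ica([stack], train_proto)


class TestAssembledStage:
    @pytest.fixture
    def traceset(self, train_proto, noisy_gt):
        conds = {
            c.name: [generate_trial_stack(noisy_gt, train_proto, c, t)
                     for t in range(4)]
            for c in (V, V_PH, S, S_PH)
        }
        return preprocess_trials(conds, train_proto, smooth_sigma=1.0,
                                 cutoff_wavelength=None)

    def test_stage_order_recorded(self, traceset):
        assert traceset.stage_log == ["dff", "spatial_filter", "select_roi",
                                      "spatial_average"]

    def test_blank_trace_mean_near_zero(self, traceset, train_proto, noisy_gt):
        blank = traceset.average("S")
        n_px = traceset.roi_mask.sum()
        tol = 3 * noisy_gt.noise_std / np.sqrt(n_px * train_proto.n_frames) \
            + 3 * noisy_gt.spont_process[0] / np.sqrt(4)
        assert abs(blank.mean()) < tol

    def test_preprocessing_linear_in_evoked_amplitude(self, train_proto):
        """Doubling the injected evoked amplitude doubles the ROI evoked
        peak (noiseless)."""
        peaks = []
        for r_max in (0.5, 1.0):
            gt = anesthetized_ground_truth(
                seed=41, image_shape=(24, 24), noise_std=0.0,
                spont_process=(0.0, 1.0), late_rise=(4.0, 0.0),
                tuning=(r_max, 0.25, 2.0, 0.0),
            )
            conds = {
                c.name: [generate_trial_stack(gt, train_proto, c, 0)]
                for c in (V, S)
            }
            ts = preprocess_trials(conds, train_proto, smooth_sigma=0.0,
                                   cutoff_wavelength=None)
            peaks.append(ts.average("V").max())
        assert peaks[1] == pytest.approx(2 * peaks[0], rel=1e-6)

    def test_noiseless_roi_trace_matches_injected_signal(self, train_proto,
                                                         clean_gt):
        """Generator ROI signal s(t) is recovered exactly by the Δf/f + ROI
        averaging chain on clean data (affine relation, unit slope after
        Δf/f because the blank shares the illumination field)."""
        conds = {
            c.name: [generate_trial_stack(clean_gt, train_proto, c, 0)]
            for c in (V, S)
        }
        ts = preprocess_trials(conds, train_proto, smooth_sigma=0.0,
                               cutoff_wavelength=None)
        trace = ts.average("V")
        s = roi_signal(clean_gt, train_proto, V)
        from gainsep.synth import roi_profile

        prof = roi_profile(clean_gt)[ts.roi_mask]
        expected = s * prof.mean()
        assert np.allclose(trace, expected, atol=1e-10)
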