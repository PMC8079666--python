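"""Polarity correction, coil combination, CC splitting, ROI averaging."""

import numpy as np
import pytest

from fdm3pool.fdm import compute_fdm
from fdm3pool.preprocess import (
    CombinedStack,
    EchoStack,
    coil_combine,
    estimate_sensitivities,
    polarity_correct,
    roi_average,
    split_cc_three,
)
from fdm3pool.pipeline import process_stack
from fdm3pool.signal_model import make_te_schedule, model_roi_curves
from fdm3pool.synthetic_mgre import NuisanceSpec, simulate_acquisition


class TestPolarityCorrect:
    def test_identity(self, schedule, rng):
        data = rng.standard_normal((25, 6, 6)) + 1j * rng.standard_normal((25, 6, 6))
        stack = EchoStack(data=data, schedule=schedule)
        out = polarity_correct(stack, stack)
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_opposite_phase_cancels_exactly(self, schedule, rng):
        amp = rng.uniform(0.5, 2.0, (25, 5, 5))
        phi = rng.uniform(-1.2, 1.2, (25, 5, 5))
        delta = rng.uniform(-1.0, 1.0, (25, 5, 5))
        pos = EchoStack(data=amp * np.exp(1j * (phi + delta)), schedule=schedule)
        neg = EchoStack(data=amp * np.exp(1j * (phi - delta)), schedule=schedule)
        out = polarity_correct(pos, neg)
        np.testing.assert_allclose(np.abs(out.data), amp, atol=1e-12)
        np.testing.assert_allclose(np.angle(out.data), phi, atol=1e-10)

    def test_generator_eddy_round_trip(self, small_phantom, schedule):
        nuisance = NuisanceSpec(
            field_poly_coeffs=(0.0,) * 10,
            rf_phase_coeffs=(0.0,) * 10,
            eddy_phase_rad=0.3,
            n_channels=1,
            noise_sigma=0.0,
        )
        stack = simulate_acquisition(small_phantom, nuisance, schedule, seed=5)
        pos = EchoStack(data=stack.data[0, 0], schedule=schedule)
        neg = EchoStack(data=stack.data[1, 0], schedule=schedule)
        out = polarity_correct(pos, neg)
        # the eddy term must cancel exactly; coil phase remains (it is
        # removed later, by coil combination)
        reference = stack.truth["clean_signal"] * stack.truth["coil_maps"][0][None]
        err = np.angle(out.data * np.exp(-1j * np.angle(reference)))
        assert np.abs(err).max() < 1e-10

    def test_mismatched_schedules_rejected(self, schedule, rng):
        other = make_te_schedule(1.0, 1.0, 25)
        data = rng.standard_normal((25, 4, 4)) + 0j
        with pytest.raises(ValueError):
            polarity_correct(
                EchoStack(data=data, schedule=schedule),
                EchoStack(data=data, schedule=other),
            )


class TestSensitivitiesAndCombination:
    def test_constant_single_channel_is_unit(self):
        sens = estimate_sensitivities(np.full((1, 16, 16), 3.0 + 0j))
        np.testing.assert_allclose(np.abs(sens), 1.0, atol=1e-12)

    def test_all_zero_channel_rejected(self):
        imgs = np.zeros((2, 8, 8), dtype=complex)
        imgs[0] = 1.0
        with pytest.raises(ValueError):
            estimate_sensitivities(imgs)

    def test_estimate_tracks_smooth_truth(self, noiseless_stack):
        pos = EchoStack(data=noiseless_stack.data[0], schedule=noiseless_stack.schedule)
        neg = EchoStack(data=noiseless_stack.data[1], schedule=noiseless_stack.schedule)
        corrected = polarity_correct(pos, neg)
        sens = estimate_sensitivities(corrected.data[:, 0])
        truth = noiseless_stack.truth["coil_maps"]
        # estimates are RSS-normalized; compare against relative truth
        rss = np.sqrt((np.abs(truth) ** 2).sum(axis=0))
        mask = noiseless_stack.cc_mask
        for c in range(truth.shape[0]):
            r = np.corrcoef(np.abs(sens[c][mask]), (np.abs(truth[c]) / rss)[mask])[0, 1]
            assert r > 0.99

    def test_single_channel_unit_sensitivity_identity(self, schedule, rng):
        data = rng.standard_normal((1, 25, 6, 6)) + 1j * rng.standard_normal((1, 25, 6, 6))
        stack = EchoStack(data=data, schedule=schedule)
        out = coil_combine(stack, np.ones((1, 6, 6), dtype=complex))
        np.testing.assert_allclose(out.data, data[0], atol=1e-12)

    def test_duplicate_channels_identity(self, schedule, rng):
        obj = rng.standard_normal((25, 6, 6)) + 1j * rng.standard_normal((25, 6, 6))
        sens = np.ones((2, 6, 6), dtype=complex) / np.sqrt(2)
        data = sens[:, None] * obj[None]
        out = coil_combine(EchoStack(data=data, schedule=schedule), sens)
        np.testing.assert_allclose(out.data, obj, atol=1e-12)

    def test_truth_sensitivities_give_exact_closure(self, noiseless_stack):
        pos = EchoStack(data=noiseless_stack.data[0], schedule=noiseless_stack.schedule)
        neg = EchoStack(data=noiseless_stack.data[1], schedule=noiseless_stack.schedule)
        corrected = polarity_correct(pos, neg)
        truth_sens = noiseless_stack.truth["coil_maps"]
        out = coil_combine(corrected, truth_sens)
        clean = noiseless_stack.truth["clean_signal"]
        # rf + field phase remain (TE-static and linear), but with truth coils
        # the combination must reproduce the modulated object signal exactly
        expected = clean * np.exp(
            1j
            * (
                noiseless_stack.truth["rf_phase"][None]
                + 2
                * np.pi
                * noiseless_stack.truth["field_hz"][None]
                * noiseless_stack.schedule.te_s[:, None, None]
            )
        )
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_global_channel_scale_invariance(self, schedule, rng):
        # per-channel receiver phases and a common gain, applied consistently
        # to data and sensitivities, leave the combination unchanged
        data = rng.standard_normal((3, 25, 5, 5)) + 1j * rng.standard_normal((3, 25, 5, 5))
        sens = rng.standard_normal((3, 5, 5)) + 1j * rng.standard_normal((3, 5, 5))
        scales = 1.8 * np.exp(1j * np.array([0.3, -2.1, 1.0]))
        out1 = coil_combine(EchoStack(data=data, schedule=schedule), sens)
        out2 = coil_combine(
            EchoStack(data=data * scales[:, None, None, None], schedule=schedule),
            sens * scales[:, None, None],
        )
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-10)


class TestSplitCcThree:
    def test_divisible_rectangle(self):
        mask = np.zeros((10, 40), bool)
        mask[3:7, 5:35] = True  # 30 columns
        labels = split_cc_three(mask)
        widths = [np.unique(np.nonzero(labels == s)[1]).size for s in (1, 2, 3)]
        assert widths == [10, 10, 10]
        # anterior = leftmost
        assert np.nonzero(labels == 1)[1].max() < np.nonzero(labels == 3)[1].min()

    def test_remainder_goes_anterior(self):
        mask = np.zeros((10, 40), bool)
        mask[3:7, 4:35] = True  # 31 columns
        labels = split_cc_three(mask)
        widths = [np.unique(np.nonzero(labels == s)[1]).size for s in (1, 2, 3)]
        assert widths == [11, 10, 10]

    def test_partition_property(self, small_phantom):
        labels = split_cc_three(small_phantom.cc_mask)
        assert np.array_equal(labels > 0, small_phantom.cc_mask)
        assert set(np.unique(labels[small_phantom.cc_mask])) == {1, 2, 3}

    def test_agrees_with_generator_labels(self, small_phantom):
        labels = split_cc_three(small_phantom.cc_mask)
        cc = small_phantom.cc_mask
        agreement = (labels[cc] == small_phantom.labels[cc]).mean()
        assert agreement >= 0.95

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            split_cc_three(np.zeros((5, 5), bool))


class TestRoiAverage:
    def _combined_and_fdm(self, values, schedule, shape):
        data = np.empty((schedule.n_echoes,) + shape, dtype=complex)
        data[:] = values[:, None, None]
        stack = CombinedStack(data=data, schedule=schedule)
        return stack, compute_fdm(stack)

    def test_uniform_segment_equals_single_pixel(self, seg3_params, schedule):
        from fdm3pool.signal_model import synthesize_three_pool

        values = synthesize_three_pool(seg3_params, schedule).values
        stack, fdm_maps = self._combined_and_fdm(values, schedule, (4, 4))
        labels = np.ones((4, 4), int)
        curves = roi_average(stack, fdm_maps, labels, 1)
        expected = model_roi_curves(seg3_params, schedule)
        np.testing.assert_allclose(curves.magnitude, expected.magnitude, atol=1e-12)
        np.testing.assert_allclose(curves.fdm_hz, expected.fdm_hz, atol=1e-12)

    def test_two_pixel_mean(self, schedule):
        data = np.zeros((schedule.n_echoes, 1, 2), dtype=complex)
        data[:, 0, 0] = 1.0
        data[:, 0, 1] = 3.0
        stack = CombinedStack(data=data, schedule=schedule)
        fdm_maps = compute_fdm(stack)
        curves = roi_average(stack, fdm_maps, np.ones((1, 2), int), 1)
        # mean magnitude 2 at every echo; normalized to 1
        np.testing.assert_allclose(curves.magnitude, 1.0)

    def test_empty_segment_rejected(self, schedule):
        data = np.ones((schedule.n_echoes, 2, 2), dtype=complex)
        stack = CombinedStack(data=data, schedule=schedule)
        with pytest.raises(ValueError):
            roi_average(stack, compute_fdm(stack), np.zeros((2, 2), int), 1)

    def test_posterior_roi_matches_mean_parameter_curves(
        self, small_phantom, noiseless_stack, schedule
    ):
        """Averaging pixel curves ~ curve of mean parameters within 2%."""
        from fdm3pool.fdm import detrend_poly2d

        combined = process_stack(noiseless_stack)
        maps = detrend_poly2d(
            compute_fdm(combined, mask=None), fit_mask=~small_phantom.cc_mask
        )
        curves = roi_average(combined, maps, small_phantom.labels, 3)
        expected = model_roi_curves(small_phantom.segment_mean_params(3), schedule)
        np.testing.assert_allclose(
            curves.magnitude, expected.magnitude, rtol=0.02
        )
        np.testing.assert_allclose(
            curves.fdm_hz[2:], expected.fdm_hz[2:], atol=0.02 * np.abs(expected.fdm_hz[2:]).max()
        )
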