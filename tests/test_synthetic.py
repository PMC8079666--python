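"""Synthetic phantom / acquisition / study generator: determinism and closure."""

import numpy as np
import pandas as pd
import pytest

from fdm3pool.signal_model import make_te_schedule
from fdm3pool.synthetic_mgre import (
    NuisanceSpec,
    PhantomSpec,
    StudySpec,
    generate_phantom,
    simulate_acquisition,
    simulate_study,
)


class TestGeneratePhantom:
    def test_posterior_mean_myelin_fraction(self):
        phantom = generate_phantom(seed=0)
        sel = phantom.labels == 3
        assert abs(phantom.param_maps["f_m"][sel].mean() - 0.16) < 0.01

    def test_zero_pixel_sd_gives_exact_segment_means(self, small_phantom_spec):
        import dataclasses

        spec = dataclasses.replace(
            small_phantom_spec, pixel_sd_fm=0.0, pixel_sd_omega_hz=0.0, pixel_sd_r2s=0.0
        )
        phantom = generate_phantom(spec, seed=3)
        for seg in (1, 2, 3):
            sel = phantom.labels == seg
            assert np.all(
                phantom.param_maps["f_m"][sel] == spec.segment_fm_means[seg - 1]
            )

    def test_deterministic_under_seed(self, small_phantom_spec):
        a = generate_phantom(small_phantom_spec, seed=9)
        b = generate_phantom(small_phantom_spec, seed=9)
        for key in a.param_maps:
            np.testing.assert_array_equal(a.param_maps[key], b.param_maps[key])

    def test_fraction_conservation(self, small_phantom):
        total = (
            small_phantom.param_maps["f_m"]
            + small_phantom.param_maps["f_a"]
            + small_phantom.param_maps["f_e"]
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_segments_have_equal_extent(self, small_phantom):
        widths = [
            np.unique(np.nonzero(small_phantom.labels == s)[1]).size for s in (1, 2, 3)
        ]
        assert max(widths) - min(widths) <= 2  # remainder columns go anterior

    def test_geometry_not_fitting_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom(PhantomSpec(grid=(16, 16), arc_radii_px=(80.0, 35.0)))


class TestSimulateAcquisition:
    def test_identity_nuisance_preserves_model_phase(self, small_phantom, schedule):
        stack = simulate_acquisition(
            small_phantom, NuisanceSpec.off(), schedule, seed=2
        )
        clean = stack.truth["clean_signal"]
        np.testing.assert_allclose(stack.data[0, 0], clean, atol=1e-12)
        np.testing.assert_allclose(stack.data[1, 0], clean, atol=1e-12)

    def test_deterministic_under_seed(self, small_phantom, schedule):
        nuisance = NuisanceSpec(n_channels=2, noise_sigma=0.02)
        a = simulate_acquisition(small_phantom, nuisance, schedule, seed=7)
        b = simulate_acquisition(small_phantom, nuisance, schedule, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_eddy_phase_alternates_and_inverts(self, small_phantom, schedule):
        nuisance = NuisanceSpec(
            field_poly_coeffs=(0.0,) * 10,
            rf_phase_coeffs=(0.0,) * 10,
            eddy_phase_rad=0.25,
            n_channels=1,
            noise_sigma=0.0,
            unit_coils=True,
        )
        stack = simulate_acquisition(small_phantom, nuisance, schedule, seed=2)
        clean = stack.truth["clean_signal"]
        phase_pos = np.angle(stack.data[0, 0] * np.conj(clean))
        phase_neg = np.angle(stack.data[1, 0] * np.conj(clean))
        parity = (-1.0) ** np.arange(schedule.n_echoes)
        np.testing.assert_allclose(
            phase_pos, 0.25 * parity[:, None, None] * np.ones_like(phase_pos), atol=1e-10
        )
        np.testing.assert_allclose(phase_neg, -phase_pos, atol=1e-10)

    def test_ground_truth_closure(self, noiseless_stack):
        """Dividing out stored nuisances recovers the clean signal exactly."""
        t = noiseless_stack.truth
        te = noiseless_stack.schedule.te_s
        parity = (-1.0) ** np.arange(te.size)
        for ip, pol in enumerate((1.0, -1.0)):
            phase = (
                t["rf_phase"][None]
                + 2 * np.pi * t["field_hz"][None] * te[:, None, None]
                + pol * parity[:, None, None] * t["eddy_phase_rad"]
            )
            for c in range(noiseless_stack.data.shape[1]):
                recovered = noiseless_stack.data[ip, c] / (
                    np.exp(1j * phase) * t["coil_maps"][c][None]
                )
                np.testing.assert_allclose(
                    recovered, t["clean_signal"], atol=1e-10
                )

    def test_shape_mismatch_rejected(self, small_phantom):
        import dataclasses

        other = generate_phantom(PhantomSpec(grid=(64, 64), arc_radii_px=(20, 10)), seed=0)
        bad = dataclasses.replace(small_phantom, cc_mask=other.cc_mask)
        with pytest.raises(ValueError):
            simulate_acquisition(bad, NuisanceSpec.off())


class TestSimulateStudy:
    def test_deterministic(self):
        spec = StudySpec(n_hd=3, n_control=3, seed=5, segments=(3,))
        a = simulate_study(spec, fit_curves=False)
        b = simulate_study(spec, fit_curves=False)
        pd.testing.assert_frame_equal(a, b)

    def test_no_visit_noise_gives_zero_cv(self):
        spec = StudySpec(
            n_hd=0,
            n_control=4,
            n_visits=5,
            fm_visit_sd=(0.0, 0.0, 0.0),
            omega_a_visit_sd_hz=(0.0, 0.0, 0.0),
            omega_m_visit_sd_hz=(0.0, 0.0, 0.0),
            seed=1,
        )
        table = simulate_study(spec, fit_curves=False)
        for (_, _), sub in table.groupby(["subject_id", "segment"]):
            assert sub["f_m"].std() == pytest.approx(0.0, abs=1e-12)

    def test_null_interaction_recovery(self):
        """With zero interaction the fitted interaction term centres on 0."""
        from fdm3pool.stats import fit_group_age_model

        coefs = []
        for seed in range(40):
            spec = StudySpec(
                fm_age_slope_hd=-0.0008,  # same slope in both groups
                seed=seed,
                segments=(3,),
            )
            table = simulate_study(spec, fit_curves=False)
            res = fit_group_age_model(table, "f_m", center_age=True)
            coefs.append(res.coef("group_age"))
        mean = np.mean(coefs)
        se = np.std(coefs, ddof=1) / np.sqrt(len(coefs))
        assert abs(mean) < 3 * se

    def test_group_effect_recovered(self):
        """A configured -0.05 group effect is recovered within simulation SE."""
        from fdm3pool.stats import fit_group_age_model

        coefs = []
        for seed in range(100):
            spec = StudySpec(
                fm_group_effect=-0.05,
                fm_age_slope_hd=-0.0008,
                seed=seed,
                segments=(3,),
            )
            table = simulate_study(spec, fit_curves=False)
            coefs.append(
                fit_group_age_model(table, "f_m", center_age=True).coef("group")
            )
        mean = np.mean(coefs)
        se = np.std(coefs, ddof=1) / np.sqrt(len(coefs))
        assert mean == pytest.approx(-0.05, abs=3 * se)
        assert abs(mean + 0.05) < 0.005

    def test_truth_columns_recorded(self):
        table = simulate_study(
            StudySpec(n_hd=2, n_control=2, seed=0, segments=(3,)), fit_curves=False
        )
        assert {"f_m_true", "delta_omega_hz_true"} <= set(table.columns)
        np.testing.assert_array_equal(table["f_m"], table["f_m_true"])

    def test_out_of_range_effects_rejected(self):
        with pytest.raises(ValueError):
            StudySpec(fm_group_effect=-0.2)

    def test_fitted_path_close_to_truth(self, schedule):
        spec = StudySpec(n_hd=0, n_control=3, seed=4, segments=(3,))
        table = simulate_study(spec, schedule, fit_curves=True)
        err = (table["f_m"] - table["f_m_true"]).abs()
        assert err.median() < 0.02
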