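"""Shadow, contrast and attenuation statistics."""

import numpy as np
import pandas as pd
import pytest

from lsim import (AcquiredStack, BeamSpec, attenuation_correct,
                  contrast_profile, edge_rolloff, focus_ratio, sigma_profile)
from lsim.metrics import MetricTable


def make_stack(image, normalized=True, pitch=1.0, mode="DSLM"):
    image = np.asarray(image, dtype=float)
    ny, nz = image.shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * pitch
    z = (np.arange(nz) + 0.5) * pitch
    return AcquiredStack(image=image, y=y, z=z, normalized=normalized,
                         mode=mode)


class TestFocusRatio:
    def test_sphere_free_stack_reads_unity(self):
        stack = make_stack(np.ones((21, 9)))
        assert focus_ratio(stack, z_focus=4.5) == pytest.approx(1.0)

    def test_window_mean_around_focal_pixel(self):
        img = np.ones((21, 9))
        img[9:12, 3:6] = 0.4
        stack = make_stack(img)
        assert focus_ratio(stack, z_focus=4.5, y0=0.0) == pytest.approx(0.4)

    def test_unnormalized_stack_rejected(self):
        stack = make_stack(np.ones((5, 5)), normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            focus_ratio(stack, z_focus=2.0)


class TestSigmaProfile:
    def test_uniform_image_has_zero_sigma(self):
        prof = sigma_profile(make_stack(np.ones((40, 6))))
        assert np.allclose(prof["sigma_I_y"], 0.0)

    def test_two_level_alternation_gives_exact_population_sd(self):
        img = np.tile([[0.7], [1.3]], (20, 6))
        prof = sigma_profile(make_stack(img), y_margin_fraction=0.0)
        assert np.allclose(prof["sigma_I_y"], 0.3)

    def test_margin_excludes_boundary_rows(self):
        img = np.ones((40, 4))
        img[:4, :] = 50.0   # contaminated absorbing-boundary rows
        prof = sigma_profile(make_stack(img), y_margin_fraction=0.15)
        assert np.allclose(prof["sigma_I_y"], 0.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            sigma_profile(make_stack(np.ones((1, 4))), y_margin_fraction=0.0)

    def test_invariant_to_common_rescaling_of_run_and_reference(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0.5, 1.5, size=(30, 8))
        ref = rng.uniform(0.9, 1.1, size=(30, 8))
        a = sigma_profile(make_stack(raw / ref))
        b = sigma_profile(make_stack((3.7 * raw) / (3.7 * ref)))
        assert np.allclose(a["sigma_I_y"], b["sigma_I_y"])


class TestContrastProfile:
    def test_zero_minimum_gives_full_contrast(self):
        img = np.ones((30, 9))
        img[15, 4] = 0.0
        prof = contrast_profile(make_stack(img), roi_width=6.0, robust=False,
                                z_centers=[4.5], y_margin_fraction=0.0)
        assert prof["contrast"].iloc[0] == pytest.approx(1.0)

    def test_constant_roi_gives_zero_contrast(self):
        prof = contrast_profile(make_stack(np.full((30, 9), 0.8)),
                                roi_width=6.0, robust=False)
        assert np.allclose(prof["contrast"], 0.0)

    def test_peak_on_pedestal_closed_form(self):
        # peak 1.0 on pedestal 0.5: C = (1 - 0.5) / (1 + 0.5) = 1/3
        img = np.full((30, 9), 0.5)
        img[10, 4] = 1.0
        prof = contrast_profile(make_stack(img), roi_width=6.0, robust=False,
                                z_centers=[4.5], y_margin_fraction=0.0)
        assert prof["contrast"].iloc[0] == pytest.approx(1.0 / 3.0)

    def test_percentile_clipping_ignores_single_hot_pixel(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0.99, 1.01, size=(200, 9))
        img[100, 4] = 100.0
        robust = contrast_profile(make_stack(img), roi_width=6.0,
                                  z_centers=[4.5], y_margin_fraction=0.0)
        exact = contrast_profile(make_stack(img), roi_width=6.0, robust=False,
                                 z_centers=[4.5], y_margin_fraction=0.0)
        assert robust["contrast"].iloc[0] < 0.05 < exact["contrast"].iloc[0]

    def test_roi_outside_stack_rejected(self):
        with pytest.raises(ValueError, match="ROI|planes"):
            contrast_profile(make_stack(np.ones((30, 2))), roi_width=50.0)

    def test_contrast_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0.0, 5.0, size=(40, 30))
        prof = contrast_profile(make_stack(img), roi_width=6.0)
        assert ((prof["contrast"] >= 0.0) & (prof["contrast"] <= 1.0)).all()


class TestEdgeRolloff:
    def test_flat_axial_profile_has_zero_rolloff(self):
        beam = BeamSpec(na_x=0.06, na_y=0.06, medium_index=1.46)
        # z planes must cover z_focus +/- n*z_R ~ 85.2 um
        img = np.ones((11, 200))
        stack = make_stack(img, normalized=False, pitch=2.0)
        assert edge_rolloff(stack, beam, z_focus=200.0) == pytest.approx(0.0)

    def test_rolloff_reads_edge_to_focus_ratio(self):
        beam = BeamSpec(na_x=0.06, na_y=0.06, medium_index=1.46)
        z = (np.arange(200) + 0.5) * 2.0
        prof = np.where(np.abs(z - 200.0) > 50.0, 0.8, 1.0)
        stack = make_stack(np.tile(prof, (11, 1)), normalized=False, pitch=2.0)
        assert edge_rolloff(stack, beam, z_focus=200.0) == pytest.approx(0.2)

    def test_normalized_stack_rejected(self):
        stack = make_stack(np.ones((11, 200)), normalized=True, pitch=2.0)
        with pytest.raises(ValueError, match="unnormalized"):
            edge_rolloff(stack, BeamSpec(na_x=0.06, na_y=0.06), 200.0)

    def test_edges_outside_stack_rejected(self):
        stack = make_stack(np.ones((11, 20)), normalized=False, pitch=2.0)
        with pytest.raises(ValueError, match="outside"):
            edge_rolloff(stack, BeamSpec(na_x=0.06, na_y=0.06), 20.0)


class TestAttenuationCorrection:
    def synthetic_stack(self, mu_s_per_mm, noise=0.0, seed=0, nz=400, ny=64):
        rng = np.random.default_rng(seed)
        z = (np.arange(nz) + 0.5) * 2.0  # um
        decay = np.exp(-mu_s_per_mm * z / 1000.0)
        img = np.tile(decay, (ny, 1))
        if noise:
            img = img * rng.normal(1.0, noise, size=img.shape)
        return make_stack(np.abs(img), normalized=False, pitch=2.0)

    def test_recovers_imposed_decay_within_1_percent(self):
        stack = self.synthetic_stack(10.0, noise=0.01, seed=3)
        _, mu = attenuation_correct(stack)
        assert mu == pytest.approx(10.0, rel=0.01)

    def test_zero_decay_left_unchanged(self):
        stack = self.synthetic_stack(0.0)
        corrected, mu = attenuation_correct(stack)
        assert abs(mu) < 1e-3
        assert np.allclose(corrected.image, stack.image, rtol=1e-3)

    def test_scale_invariance_of_fitted_coefficient(self):
        stack = self.synthetic_stack(5.0, noise=0.01, seed=4)
        _, mu1 = attenuation_correct(stack)
        stack.image = stack.image * 2.0
        _, mu2 = attenuation_correct(stack)
        assert mu1 == pytest.approx(mu2, abs=1e-9)

    def test_correction_is_idempotent(self):
        stack = self.synthetic_stack(10.0, noise=0.01, seed=5)
        corrected, _ = attenuation_correct(stack)
        _, mu_refit = attenuation_correct(corrected)
        assert abs(mu_refit) < 1e-3

    def test_nonpositive_median_rejected(self):
        stack = make_stack(np.zeros((8, 10)), normalized=False)
        with pytest.raises(ValueError, match="positive"):
            attenuation_correct(stack)


class TestMetricTable:
    def test_csv_round_trip_with_metadata(self, tmp_path):
        frame = pd.DataFrame({"z": [1.0, 2.0], "sigma_I_y": [0.1, 0.2]})
        table = MetricTable(frame=frame, meta={"preset": "scaled",
                                               "config_hash": "abc123"})
        path = tmp_path / "metrics.csv"
        table.to_csv(path)
        back = MetricTable.read_csv(path)
        assert back.meta == {"preset": "scaled", "config_hash": "abc123"}
        pd.testing.assert_frame_equal(back.frame, frame)
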