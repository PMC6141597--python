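"""Acquisition orchestration: mode semantics, scan sums, tiling."""

import numpy as np
import pytest

from lsim import (AcquisitionPlan, BeamSpec, Phantom, SphereSpec,
                  build_phantom, run_acquisition, run_na_sweep, run_tiled_z)
from lsim.scenarios import default_detection


@pytest.fixture(scope="module")
def tiny_grid(tiny_numerics):
    return tiny_numerics.grid()


@pytest.fixture(scope="module")
def tiny_empty(tiny_grid):
    return Phantom(grid=tiny_grid, n_background=1.46)


@pytest.fixture(scope="module")
def tiny_sphere_phantom(tiny_grid):
    return build_phantom(tiny_grid, 1.46,
                         [SphereSpec(center=(0.0, 1.0, 40.0), diameter=6.0,
                                     index=1.59)])


def scanned_plan(mode="DSLM", **kw):
    beam = kw.pop("beam", BeamSpec(na_x=0.08, na_y=0.08))
    defaults = dict(mode=mode, beam=beam, detection=default_detection(),
                    z_focus=90.0, scan_step=2.0, dz=0.5, dz_coarse=5.0)
    defaults.update(kw)
    return AcquisitionPlan(**defaults)


def sheet_plan(mode="SPIM", **kw):
    beam = kw.pop("beam", BeamSpec(na_x=0.08, na_y=0.0))
    defaults = dict(mode=mode, beam=beam,
                    detection=default_detection(mode="widefield"),
                    z_focus=90.0, dz=0.5, dz_coarse=5.0)
    defaults.update(kw)
    return AcquisitionPlan(**defaults)


class TestPlanValidation:
    def test_scan_settings_only_for_scanned_modes(self):
        with pytest.raises(ValueError, match="scan"):
            sheet_plan(scan_step=1.0)
        with pytest.raises(ValueError, match="scan_step"):
            AcquisitionPlan(mode="DSLM", beam=BeamSpec(na_x=0.08, na_y=0.08),
                            detection=default_detection(), z_focus=90.0)

    def test_pivot_settings_only_for_mspim(self):
        with pytest.raises(ValueError, match="pivot"):
            scanned_plan(pivot_half_angle_deg=10.0)
        with pytest.raises(ValueError, match="pivot"):
            sheet_plan(mode="mSPIM")

    def test_detection_mode_must_match_architecture(self):
        with pytest.raises(ValueError, match="confocal-line"):
            scanned_plan(detection=default_detection(mode="widefield"))
        with pytest.raises(ValueError, match="widefield"):
            sheet_plan(detection=default_detection(mode="confocal-line"))

    def test_scanned_architectures_differ_only_in_beam(self):
        from dataclasses import asdict

        a = scanned_plan(mode="DSLM")
        b = scanned_plan(mode="mDSLM", beam=BeamSpec(na_x=0.08, na_y=0.16))
        da, db = asdict(a), asdict(b)
        for key in ("mode", "beam"):
            da.pop(key), db.pop(key)
        assert da == db


class TestScannedAcquisition:
    def test_empty_phantom_normalizes_to_unity(self, tiny_empty):
        stack = run_acquisition(scanned_plan(), tiny_empty, (60.0, 90.0))
        interior = stack.image[:, :][np.abs(stack.y) < 10, :]
        assert np.all(np.abs(interior - 1.0) < 1e-6)

    def test_shift_invariant_fill_matches_direct_propagation(
            self, tiny_sphere_phantom):
        """Restricting propagation to a window around the occluder and
        filling the rest by translation reproduces the full scan."""
        z_planes = (89.5, 90.0, 90.5)
        full = run_acquisition(scanned_plan(scan_window_halfwidth=None),
                               tiny_sphere_phantom, z_planes)
        filled = run_acquisition(scanned_plan(scan_window_halfwidth=8.0),
                                 tiny_sphere_phantom, z_planes)
        assert filled.meta["propagated_positions"] < full.meta[
            "propagated_positions"]
        v_full = full.value_at(0.0, 90.0)
        v_fill = filled.value_at(0.0, 90.0)
        assert v_fill == pytest.approx(v_full, rel=0.01)

    def test_scan_step_convergence_of_normalized_metric(
            self, tiny_sphere_phantom):
        z_planes = (89.5, 90.0, 90.5)
        vals = {}
        for step in (2.0, 1.0):
            stack = run_acquisition(
                scanned_plan(scan_step=step, scan_window_halfwidth=8.0),
                tiny_sphere_phantom, z_planes)
            vals[step] = stack.value_at(0.0, 90.0)
        assert vals[1.0] == pytest.approx(vals[2.0], rel=0.02)

    def test_unnormalized_stack_keeps_raw_and_reference(self, tiny_empty):
        stack = run_acquisition(scanned_plan(normalize=False), tiny_empty,
                                (90.0,))
        assert not stack.normalized
        assert np.array_equal(stack.image, stack.raw)
        assert stack.reference is not None


class TestSheetModes:
    def test_mspim_with_single_zero_angle_equals_spim(self, tiny_empty):
        spim = run_acquisition(sheet_plan(), tiny_empty, (60.0, 90.0))
        mspim = run_acquisition(
            sheet_plan(mode="mSPIM", pivot_half_angle_deg=10.0,
                       n_pivot_angles=1),
            tiny_empty, (60.0, 90.0))
        assert np.allclose(spim.image, mspim.image, rtol=1e-7)

    def test_pivot_averaging_smooths_sheet_artifacts(self, tiny_sphere_phantom):
        """Pivot averaging damps the shadow/caustic pattern behind a sphere.

        A refractive sphere leaves both a dark shadow and a bright caustic
        in the static sheet; time-averaged pivoting flattens the normalized
        image, i.e. reduces its spread across y.
        """
        z_planes = (60.0,)   # 20 um behind the sphere
        spim = run_acquisition(sheet_plan(), tiny_sphere_phantom, z_planes)
        mspim = run_acquisition(
            sheet_plan(mode="mSPIM", pivot_half_angle_deg=10.0,
                       n_pivot_angles=11),
            tiny_sphere_phantom, z_planes)
        band = np.abs(spim.y) < 10
        assert (mspim.image[band, 0].std() < 0.7 * spim.image[band, 0].std())


class TestNaSweep:
    def test_na_y_equal_na_x_cell_matches_plain_scenario(
            self, tiny_sphere_phantom):
        table = run_na_sweep([0.08], [0.08], tiny_sphere_phantom, 90.0,
                             metric="focus_intensity", dz=0.5, dz_coarse=5.0)
        assert table.loc[0, "error"] == ""
        assert 0.0 < table.loc[0, "value"] < 1.0

    def test_under_resolved_cell_recorded_not_raised(self, tiny_sphere_phantom):
        table = run_na_sweep([0.08], [0.08, 0.9], tiny_sphere_phantom, 90.0,
                             metric="focus_intensity", dz=0.5, dz_coarse=5.0)
        ok = table[table.na_y == 0.08].iloc[0]
        bad = table[table.na_y == 0.9].iloc[0]
        assert ok["error"] == ""
        assert bad["error"] != "" and np.isnan(bad["value"])


class TestTiling:
    def test_single_tile_matches_plain_acquisition(self, tiny_sphere_phantom):
        depth = tiny_sphere_phantom.grid.z_extent
        plan = scanned_plan(z_focus=depth / 2)
        tiled = run_tiled_z(plan, tiny_sphere_phantom, tile_step=depth,
                            plane_spacing=20.0)
        z_planes = tuple(tiled.z)
        direct = run_acquisition(plan, tiny_sphere_phantom, z_planes)
        assert np.allclose(tiled.image, direct.image, rtol=1e-6)

    def test_tile_boundaries_continuous_on_homogeneous_phantom(
            self, tiny_empty):
        plan = scanned_plan()
        tiled = run_tiled_z(plan, tiny_empty, tile_step=40.0,
                            plane_spacing=5.0)
        interior = np.abs(tiled.y) < 10
        prof = tiled.image[interior, :].mean(axis=0)
        jumps = np.abs(np.diff(prof)) / prof[:-1]
        assert np.all(jumps < 0.05)
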