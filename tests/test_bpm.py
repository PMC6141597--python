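"""Split-step propagation engine: sources, oracles, conservation laws."""

import math

import numpy as np
import pytest

from lsim import (BeamSpec, GridSpec, Phantom, PropagationConfig, RecordPlan,
                  SphereSpec, build_phantom, in_medium_rayleigh_range,
                  make_source_field, normalized_intensity, propagate,
                  run_beam, unobstructed_reference)
from lsim.scenarios import Numerics


def homogeneous(grid, n=1.46):
    return Phantom(grid=grid, n_background=n)


def moment_radius(profile, coords):
    """1/e^2 radius of a sampled Gaussian via its second moment."""
    profile = profile.astype(float)
    m = (profile * coords).sum() / profile.sum()
    return 2.0 * math.sqrt((profile * (coords - m) ** 2).sum() / profile.sum())


class TestSourceField:
    def test_circular_waist_field_is_real_and_symmetric(self, tiny_numerics):
        grid = tiny_numerics.grid()
        beam = BeamSpec(na_x=0.08, na_y=0.08)
        src = make_source_field(beam, z_focus=0.0, grid=grid)
        assert np.allclose(src.u.imag, 0.0, atol=1e-7)
        I = np.abs(src.u) ** 2
        assert np.allclose(I, I.T, rtol=1e-5)          # x <-> y symmetric
        assert np.allclose(I, I[::-1, :], rtol=1e-5)   # even in x
        wx = moment_radius(I.sum(axis=1), grid.x)
        assert wx == pytest.approx(beam.waist_x, rel=0.01)

    def test_elliptical_waist_narrower_in_y(self, tiny_numerics):
        grid = tiny_numerics.grid()
        beam = BeamSpec(na_x=0.06, na_y=0.18)
        src = make_source_field(beam, z_focus=0.0, grid=grid)
        I = np.abs(src.u) ** 2
        wx = moment_radius(I.sum(axis=1), grid.x)
        wy = moment_radius(I.sum(axis=0), grid.y)
        assert wy < wx

    def test_source_power_is_normalized(self, tiny_numerics):
        grid = tiny_numerics.grid()
        src = make_source_field(BeamSpec(na_x=0.08, na_y=0.12), 60.0, grid)
        assert src.power == pytest.approx(1.0, rel=1e-6)

    def test_backpropagated_source_refocuses_at_z_focus(self, tiny_numerics):
        grid = tiny_numerics.grid()
        beam = BeamSpec(na_x=0.08, na_y=0.16)
        z_focus = 60.0
        planes = tuple(np.arange(z_focus - 5.0, z_focus + 5.5, 1.0))
        cfg = PropagationConfig(beam=beam, z_focus=z_focus,
                                record=RecordPlan(z_planes=planes))
        rec = run_beam(beam, homogeneous(grid), cfg)
        widths = [moment_radius(p.sum(axis=0), grid.y) for p in rec.slab]
        i_min = int(np.argmin(widths))
        # minimum y radius within one step of the requested focus
        assert abs(rec.z_planes[i_min] - z_focus) <= 1.0 + 1e-9

    def test_under_resolved_waist_rejected(self, tiny_numerics):
        grid = tiny_numerics.grid()  # 0.5 um pitch
        with pytest.raises(ValueError, match="under-resolved"):
            make_source_field(BeamSpec(na_x=0.35, na_y=0.06), 10.0, grid)

    def test_focus_outside_grid_rejected(self, tiny_numerics):
        grid = tiny_numerics.grid()
        with pytest.raises(ValueError, match="z_focus"):
            make_source_field(BeamSpec(na_x=0.06, na_y=0.06), 500.0, grid)


class TestHomogeneousPropagation:
    def test_radii_match_gaussian_beam_theory_within_2_percent(self):
        # fitted 1/e^2 radii at 11 depths spanning +/- 2 z_R (in-medium)
        num = Numerics(name="t", pitch=0.5, transverse_extent=80.0,
                       depth=360.0, dz=0.5, dz_coarse=5.0)
        grid = num.grid()
        beam = BeamSpec(na_x=0.06, na_y=0.06, wavelength=0.66,
                        medium_index=1.46)
        z_focus = 180.0
        zr = in_medium_rayleigh_range(beam.na_x, beam.wavelength,
                                      beam.medium_index)
        planes = tuple(np.round(np.linspace(z_focus - 2 * zr,
                                            z_focus + 2 * zr, 11), 3))
        cfg = PropagationConfig(beam=beam, z_focus=z_focus,
                                record=RecordPlan(z_planes=planes),
                                dz=num.dz, dz_coarse=num.dz_coarse)
        rec = run_beam(beam, homogeneous(grid), cfg)
        for zp, plane in zip(rec.z_planes, rec.slab):
            w_fit = moment_radius(plane.sum(axis=1), grid.x)
            w_theory = beam.waist_x * math.sqrt(1 + ((zp - z_focus) / zr) ** 2)
            assert w_fit == pytest.approx(w_theory, rel=0.02)

    def test_power_conserved_within_half_percent(self, tiny_numerics):
        grid = tiny_numerics.grid()
        beam = BeamSpec(na_x=0.10, na_y=0.10)
        cfg = PropagationConfig(beam=beam, z_focus=60.0,
                                record=RecordPlan(z_planes=(120.0,),
                                                  record_power=True),
                                dz=0.5, dz_coarse=5.0)
        rec = run_beam(beam, homogeneous(grid), cfg)
        p = rec.power_history
        assert (p.max() - p.min()) / p[0] < 0.005

    def test_linearity_in_source_power(self, tiny_numerics):
        grid = tiny_numerics.grid()
        beam = BeamSpec(na_x=0.08, na_y=0.08)
        cfg = PropagationConfig(beam=beam, z_focus=60.0,
                                record=RecordPlan(z_planes=(60.0, 100.0)))
        src = make_source_field(beam, 60.0, grid)
        rec1 = propagate(src, homogeneous(grid), cfg)
        src.u = src.u * 2.0
        rec2 = propagate(src, homogeneous(grid), cfg)
        assert np.allclose(rec2.slab, 4.0 * rec1.slab, rtol=1e-4)


@pytest.fixture(scope="module")
def small_sphere_scene(tiny_numerics):
    grid = tiny_numerics.grid()
    phantom = build_phantom(grid, 1.46,
                            [SphereSpec(center=(0.0, 0.0, 40.0),
                                        diameter=8.0, index=1.59)])
    beam = BeamSpec(na_x=0.08, na_y=0.08)
    cfg = PropagationConfig(beam=beam, z_focus=90.0,
                            record=RecordPlan(z_planes=(89.5, 90.0, 90.5)),
                            dz=0.5, dz_coarse=5.0)
    obs = run_beam(beam, phantom, cfg)
    ref = unobstructed_reference(cfg, phantom)
    return grid, phantom, obs, ref


class TestSpherePropagation:

    def test_occluder_reduces_focal_intensity(self, small_sphere_scene):
        grid, phantom, obs, ref = small_sphere_scene
        norm = normalized_intensity(obs, ref)
        ix = int(np.argmin(np.abs(grid.x)))
        iy = int(np.argmin(np.abs(grid.y)))
        assert norm[1, ix, iy] < 0.9

    def test_centred_occluder_preserves_y_symmetry(self, small_sphere_scene):
        grid, phantom, obs, ref = small_sphere_scene
        plane = obs.slab[1]
        assert np.allclose(plane, plane[:, ::-1], rtol=2e-3, atol=1e-10)

    def test_self_normalization_is_exactly_unity(self, tiny_numerics):
        grid = tiny_numerics.grid()
        beam = BeamSpec(na_x=0.08, na_y=0.08)
        cfg = PropagationConfig(beam=beam, z_focus=60.0,
                                record=RecordPlan(z_planes=(30.0, 60.0)))
        empty = homogeneous(grid)
        rec = run_beam(beam, empty, cfg)
        ref = unobstructed_reference(cfg, empty)
        norm = normalized_intensity(rec, ref)
        inside = norm[norm > 0]
        assert np.all(np.abs(inside - 1.0) < 1e-6)

    def test_grid_mismatch_rejected(self, tiny_numerics):
        grid = tiny_numerics.grid()
        other = GridSpec(nx=grid.nx, ny=grid.ny, nz=grid.nz, dx=grid.dx * 2)
        beam = BeamSpec(na_x=0.08, na_y=0.08)
        src = make_source_field(beam, 60.0, grid)
        cfg = PropagationConfig(beam=beam, z_focus=60.0,
                                record=RecordPlan(z_planes=(60.0,)))
        with pytest.raises(ValueError, match="pitch"):
            propagate(src, homogeneous(other), cfg)

    def test_record_plane_outside_grid_rejected(self, tiny_numerics):
        grid = tiny_numerics.grid()
        beam = BeamSpec(na_x=0.08, na_y=0.08)
        cfg = PropagationConfig(beam=beam, z_focus=60.0,
                                record=RecordPlan(z_planes=(500.0,)))
        with pytest.raises(ValueError, match="plane"):
            run_beam(beam, homogeneous(grid), cfg)
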