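"""Shared fixtures: small grids for unit tests, cached scenario runs.

The heavier reference-scenario runs (single-beam occlusion, scanned
acquisitions) are session-scoped so the unit suite and the acceptance
suite share one computation.
"""

from __future__ import annotations

import pytest

from lsim import (AcquisitionPlan, PropagationConfig, RecordPlan, run_beam,
                  run_acquisition, single_beam_stack)
from lsim.scenarios import (SCALED, Numerics, default_detection,
                            dslm_beam, mdslm_beam, single_sphere_phantom)

Z_FOCUS = 350.0
FOCAL_PLANES = (349.5, 350.0, 350.5)


@pytest.fixture(scope="session")
def tiny_numerics() -> Numerics:
    """A fast grid for unit tests: 40 um transverse, 120 um deep."""
    return Numerics(name="tiny", pitch=0.5, transverse_extent=40.0,
                    depth=120.0, dz=0.5, dz_coarse=5.0)


@pytest.fixture(scope="session")
def scaled_phantom():
    return single_sphere_phantom(SCALED)


def _single_beam(beam, phantom):
    det = default_detection()
    cfg = PropagationConfig(
        beam=beam, z_focus=Z_FOCUS,
        record=RecordPlan(z_planes=FOCAL_PLANES,
                          x_slab_halfwidth=det.recommended_slab_halfwidth),
        dz=SCALED.dz, dz_coarse=SCALED.dz_coarse)
    obs = run_beam(beam, phantom, cfg)
    ref = run_beam(beam, phantom.without_spheres(), cfg)
    return obs, ref


@pytest.fixture(scope="session")
def occlusion_run_dslm(scaled_phantom):
    """Stationary circular beam past the 20-um sphere + its reference."""
    return _single_beam(dslm_beam(), scaled_phantom)


@pytest.fixture(scope="session")
def occlusion_run_mdslm(scaled_phantom):
    """Stationary elliptical beam past the 20-um sphere + its reference."""
    return _single_beam(mdslm_beam(), scaled_phantom)


@pytest.fixture(scope="session")
def occlusion_stacks(occlusion_run_dslm, occlusion_run_mdslm):
    return {"DSLM": single_beam_stack(*occlusion_run_dslm),
            "mDSLM": single_beam_stack(*occlusion_run_mdslm)}


def _scanned(mode, beam, phantom):
    plan = AcquisitionPlan(mode=mode, beam=beam,
                           detection=default_detection(), z_focus=Z_FOCUS,
                           scan_step=2.0, scan_window_halfwidth=30.0,
                           dz=SCALED.dz, dz_coarse=SCALED.dz_coarse)
    return run_acquisition(plan, phantom, FOCAL_PLANES)


@pytest.fixture(scope="session")
def scanned_stack_dslm(scaled_phantom):
    return _scanned("DSLM", dslm_beam(), scaled_phantom)


@pytest.fixture(scope="session")
def scanned_stack_mdslm(scaled_phantom):
    return _scanned("mDSLM", mdslm_beam(), scaled_phantom)
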