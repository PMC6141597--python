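"""Canonical study scenarios and numerical presets.

The reference scenario is a glass microsphere (d = 20 um, n = 1.59) in an
index-matched fluorescent gel (n = 1.46), centred 125 um deep and offset
2 um in y from the beam axis, illuminated at 660 nm by a pencil beam
focused 350 um deep; detection uses a 0.40 NA objective at 680 nm with a
20-um confocal slit.  The circular scanned beam (DSLM) uses
NA_x = NA_y = 0.06; the elliptical beam (mDSLM) uses NA_x = 0.06,
NA_y = 0.18.

Two numerical presets are shipped:

* ``full``  - 0.25-um voxels over a 300 x 300 x 700 um volume, the
  reference discretization; streaming keeps memory modest but runs are
  long.
* ``scaled`` - 0.5-um pitch, 150-um transverse extent, 700-um depth, with
  5-um coarse steps in homogeneous slabs; resolves the same beams (waists
  >= 2.3 um are sampled by >= 4 pixels) and is the preset used by the test
  suite and worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass

from .beams import BeamSpec
from .detection import DetectionSpec
from .phantom import GridSpec, Phantom, SphereSpec, build_phantom, random_sphere_phantom

__all__ = [
    "Numerics",
    "SCALED",
    "FULL",
    "SPHERE_FIELD_SCALED",
    "LAMBDA_EX",
    "LAMBDA_EM",
    "N_GEL",
    "N_SPHERE",
    "dslm_beam",
    "mdslm_beam",
    "sheet_beam",
    "default_detection",
    "make_grid",
    "single_sphere_phantom",
    "small_sphere_field",
]

LAMBDA_EX = 0.660   # um, excitation
LAMBDA_EM = 0.680   # um, emission
N_GEL = 1.46
N_SPHERE = 1.59
NA_X = 0.06
NA_Y_DSLM = 0.06
NA_Y_MDSLM = 0.18
SPHERE_DIAMETER = 20.0   # um
SPHERE_DEPTH = 125.0     # um
SPHERE_OFFSET_Y = 2.0    # um
Z_FOCUS = 350.0          # um
SLIT_WIDTH = 20.0        # um
SCAN_STEP_FULL = 0.25    # um
TILE_STEP = 50.0         # um


@dataclass(frozen=True)
class Numerics:
    """Discretization preset: pitch/extents in um."""

    name: str
    pitch: float
    transverse_extent: float
    depth: float
    dz: float
    dz_coarse: float | None
    boundary_fraction: float = 0.10

    def grid(self) -> GridSpec:
        n_t = int(round(self.transverse_extent / self.pitch))
        nz = int(round(self.depth / self.pitch))
        return GridSpec(nx=n_t, ny=n_t, nz=nz, dx=self.pitch, dy=self.pitch,
                        dz=self.pitch)


SCALED = Numerics(name="scaled", pitch=0.5, transverse_extent=150.0,
                  depth=700.0, dz=0.5, dz_coarse=5.0)
FULL = Numerics(name="full", pitch=0.25, transverse_extent=300.0,
                depth=700.0, dz=0.25, dz_coarse=None)
# reduced-volume preset for the seeded small-sphere field (shadow statistics)
SPHERE_FIELD_SCALED = Numerics(name="sphere-field-scaled", pitch=0.5, transverse_extent=80.0,
                       depth=250.0, dz=0.5, dz_coarse=5.0)

PRESETS = {"scaled": SCALED, "full": FULL, "sphere-field-scaled": SPHERE_FIELD_SCALED}


def dslm_beam(wavelength: float = LAMBDA_EX) -> BeamSpec:
    """Circular scanned pencil beam, NA 0.06 / 0.06."""
    return BeamSpec(na_x=NA_X, na_y=NA_Y_DSLM, wavelength=wavelength,
                    medium_index=N_GEL)


def mdslm_beam(wavelength: float = LAMBDA_EX) -> BeamSpec:
    """Elliptical scanned pencil beam, NA 0.06 / 0.18."""
    return BeamSpec(na_x=NA_X, na_y=NA_Y_MDSLM, wavelength=wavelength,
                    medium_index=N_GEL)


def sheet_beam(wavelength: float = LAMBDA_EX) -> BeamSpec:
    """Static-sheet beam: NA_x 0.06, collimated in y."""
    return BeamSpec(na_x=NA_X, na_y=0.0, wavelength=wavelength,
                    medium_index=N_GEL)


def default_detection(mode: str = "confocal-line") -> DetectionSpec:
    return DetectionSpec(na=0.40, wavelength_em=LAMBDA_EM, medium_index=N_GEL,
                         slit_width=SLIT_WIDTH, mode=mode)


def make_grid(numerics: Numerics = SCALED) -> GridSpec:
    return numerics.grid()


def single_sphere_phantom(numerics: Numerics = SCALED,
                          diameter: float = SPHERE_DIAMETER,
                          depth: float = SPHERE_DEPTH,
                          offset_y: float = SPHERE_OFFSET_Y,
                          index: float = N_SPHERE) -> Phantom:
    """The single-occluder scenario phantom."""
    grid = numerics.grid()
    sphere = SphereSpec(center=(0.0, offset_y, depth), diameter=diameter,
                        index=index)
    return build_phantom(grid, N_GEL, [sphere])


def small_sphere_field(seed: int, numerics: Numerics = SPHERE_FIELD_SCALED,
                       diameter: float = 6.0,
                       volume_fraction: float = 0.005) -> Phantom:
    """Seeded field of 6-um spheres emulating a bead-cluster gel."""
    return random_sphere_phantom(numerics.grid(), diameter=diameter,
                                 volume_fraction=volume_fraction, seed=seed,
                                 min_gap=1.0, index=N_SPHERE,
                                 n_background=N_GEL)
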