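"""Closed-form elliptical Gaussian beam optics for light-sheet illumination.

All light-sheet architectures modelled by this package are built from a
Gaussian pencil beam whose numerical aperture may differ between the two
transverse axes: ``na_x`` focuses the beam orthogonal to the sheet (it sets
the sheet thickness and the usable field of view along the propagation
axis), while ``na_y`` focuses in the plane of the sheet and controls the
in-sheet angular diversity that mitigates shadowing behind occlusions.

Conventions
-----------
* Lengths are in micrometres, angles in degrees, NA dimensionless.
* ``z`` is the propagation axis, measured from the common waist plane.
* Beam radii are 1/e^2 *intensity* radii.
* The closed forms below use the vacuum excitation wavelength with no
  medium-index factor; the numerical propagation engine (:mod:`lsim.bpm`)
  handles the immersion index explicitly, and
  :func:`in_medium_rayleigh_range` gives the axial scale a beam actually
  exhibits when propagated in a medium of index ``n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BeamSpec",
    "beam_waist",
    "rayleigh_range",
    "in_medium_rayleigh_range",
    "beam_radius",
    "intensity",
    "equivalent_pivot_half_angle",
    "slit_width_rule",
]


def _check_positive(**values: float) -> None:
    for name, value in values.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class BeamSpec:
    """Excitation pencil-beam parameters.

    Parameters
    ----------
    na_x:
        Numerical aperture orthogonal to the light sheet (``na_x > 0``).
    na_y:
        Numerical aperture in the plane of the sheet.  ``na_y = 0`` denotes
        a beam collimated in ``y`` (a static sheet).
    wavelength:
        Vacuum excitation wavelength, um.
    medium_index:
        Refractive index of the immersion/background medium.  Carried for
        the propagation engine; the closed-form radii below do not use it.
    """

    na_x: float
    na_y: float = 0.0
    wavelength: float = 0.660
    medium_index: float = 1.46

    def __post_init__(self) -> None:
        _check_positive(na_x=self.na_x, wavelength=self.wavelength,
                        medium_index=self.medium_index)
        if self.na_y < 0:
            raise ValueError(f"na_y must be >= 0, got {self.na_y}")
        if self.na_x >= self.medium_index or self.na_y >= self.medium_index:
            raise ValueError("beam NA must be smaller than the medium index")

    # -- derived geometry ---------------------------------------------------
    @property
    def waist_x(self) -> float:
        return beam_waist(self.na_x, self.wavelength)

    @property
    def waist_y(self) -> float:
        """1/e^2 waist radius in y; ``inf`` for a collimated (na_y = 0) beam."""
        if self.na_y == 0:
            return math.inf
        return beam_waist(self.na_y, self.wavelength)

    @property
    def rayleigh_x(self) -> float:
        return rayleigh_range(self.na_x, self.wavelength)

    @property
    def rayleigh_y(self) -> float:
        if self.na_y == 0:
            return math.inf
        return rayleigh_range(self.na_y, self.wavelength)

    def radius_x(self, z):
        return beam_radius(z, self.na_x, self.wavelength)

    def radius_y(self, z):
        if self.na_y == 0:
            raise ValueError("radius_y is undefined for a collimated (na_y=0) beam")
        return beam_radius(z, self.na_y, self.wavelength)


def beam_waist(na: float, wavelength: float) -> float:
    """1/e^2 intensity waist radius ``w0 = lambda / (pi NA)`` (um)."""
    _check_positive(na=na, wavelength=wavelength)
    return wavelength / (math.pi * na)


def rayleigh_range(na: float, wavelength: float) -> float:
    """Rayleigh range ``z_R = pi w0^2 / lambda`` (um).

    The confocal parameter (depth of focus) is ``2 * z_R``.
    """
    w0 = beam_waist(na, wavelength)
    return math.pi * w0 ** 2 / wavelength


def in_medium_rayleigh_range(na: float, wavelength: float,
                             medium_index: float) -> float:
    """Rayleigh range the beam exhibits when propagating in a medium.

    A waist ``w0 = lambda/(pi NA)`` diffracting with the in-medium
    wavelength ``lambda/n`` expands on the scale ``n pi w0^2 / lambda``.
    This is the axial scale the numerical propagation reproduces.
    """
    _check_positive(medium_index=medium_index)
    return medium_index * rayleigh_range(na, wavelength)


def beam_radius(z, na: float, wavelength: float):
    """1/e^2 radius ``w(z) = w0 sqrt(1 + (z/z_R)^2)`` at axial offset ``z``.

    Even in ``z``; minimal at the waist ``z = 0``; ``sqrt(2) w0`` at
    ``z = +/- z_R``.  Accepts scalars or arrays for ``z``.
    """
    w0 = beam_waist(na, wavelength)
    zr = rayleigh_range(na, wavelength)
    z = np.asarray(z, dtype=float)
    out = w0 * np.sqrt(1.0 + (z / zr) ** 2)
    return float(out) if out.ndim == 0 else out


def intensity(x, y, z, beam: BeamSpec):
    """Normalized intensity of an elliptical Gaussian beam, 1/um^2.

    ``I(x, y, z) = 2 / (pi w_x w_y) exp(-2 (x^2/w_x^2 + y^2/w_y^2))`` with
    ``w_x``, ``w_y`` evaluated at ``z`` (both waists coincide at ``z = 0``).
    The transverse integral equals 1 at every ``z`` (unit beam power).
    """
    if beam.na_y == 0:
        raise ValueError("intensity requires na_y > 0 (finite y waist)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    wx = beam.radius_x(z)
    wy = beam.radius_y(z)
    out = (2.0 / (math.pi * wx * wy)
           * np.exp(-2.0 * (x ** 2 / wx ** 2 + y ** 2 / wy ** 2)))
    return float(out) if np.ndim(out) == 0 else out


def equivalent_pivot_half_angle(na: float) -> float:
    """Marginal-ray half angle ``arcsin(NA)`` in degrees.

    Interprets an in-sheet NA as the half-range of an equivalent sheet
    pivot: a sheet rocked over ``+/- arcsin(NA)`` supplies, after time
    averaging, the same angular diversity as a beam focused at that NA.
    """
    if not (0 <= na < 1):
        raise ValueError(f"na must lie in [0, 1), got {na}")
    return math.degrees(math.asin(na))


def slit_width_rule(na_y_ref: float, wavelength: float,
                    factor: float = 1.5) -> float:
    """Confocal-slit width scaled to the beam size at the Rayleigh range.

    Returns ``factor * sqrt(2) * w0_y`` where ``w0_y`` is the in-sheet
    waist of the *reference* beam (conventionally the circular scanned
    beam, so that an elliptical beam is apertured by the same slit).  The
    experiment-level scenarios in :mod:`lsim.scenarios` default to a fixed
    20-um slit instead; this rule is exposed for design studies.
    """
    if factor < 0:
        raise ValueError(f"factor must be >= 0, got {factor}")
    w0 = beam_waist(na_y_ref, wavelength)
    return factor * math.sqrt(2.0) * w0
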