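"""Quantitative statistics of simulated light-sheet acquisitions.

* ``focus_ratio``        - normalized intensity at the beam/sheet focus
  relative to the unobstructed reference (shadow severity of a single
  occluder).
* ``sigma_profile``      - per-depth standard deviation of the normalized
  intensity across the scan axis, sigma_I_y(z), the shadow-accumulation
  statistic for heterogeneous media.
* ``contrast_profile``   - Michelson contrast C = (Imax - Imin) /
  (Imax + Imin) in depth-resolved regions of interest.
* ``edge_rolloff``       - fractional signal loss at the field edges
  z = z_focus +/- z_R,x of a slit-apertured scanned acquisition, caused by
  the beam overfilling the confocal slit away from its waist.
* ``attenuation_correct``- exponential-decay correction I = exp(-mu_s z)
  fitted to the smoothed median depth profile; reports mu_s in 1/mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .acquisition import AcquiredStack
from .beams import BeamSpec, in_medium_rayleigh_range
from .bpm import IntensityRecord, normalized_intensity

__all__ = [
    "MetricTable",
    "single_beam_stack",
    "focus_ratio",
    "sigma_profile",
    "contrast_profile",
    "edge_rolloff",
    "attenuation_correct",
]


@dataclass
class MetricTable:
    """A tidy metric table plus provenance, serializable to annotated CSV."""

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self.meta):
                fh.write(f"# {key}: {self.meta[key]}\n")
            self.frame.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "MetricTable":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("# "):
                    key, _, value = line[2:].partition(":")
                    meta[key.strip()] = value.strip()
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            frame = pd.read_csv(fh)
        return cls(frame=frame, meta=meta)


def single_beam_stack(record: IntensityRecord,
                      reference: IntensityRecord) -> AcquiredStack:
    """Normalized on-axis (x = 0) yz stack of a single unscanned beam."""
    norm = normalized_intensity(record, reference)
    ix = int(np.argmin(np.abs(record.x_slab_coords)))
    return AcquiredStack(image=norm[:, ix, :].T, y=record.grid.y.copy(),
                         z=np.asarray(record.z_planes, dtype=float),
                         normalized=True, mode="beam",
                         meta=dict(record.meta))


def focus_ratio(stack: AcquiredStack, z_focus: float, y0: float = 0.0,
                window: int = 3) -> float:
    """Normalized intensity at the on-axis focal position.

    Mean over a ``window x window`` pixel patch centred at
    ``(y0, z_focus)``.  Equals 1 for a sphere-free stack.
    """
    if not stack.normalized:
        raise ValueError("focus_ratio requires a stack normalized against "
                         "its sphere-free reference")
    return stack.value_at(y0, z_focus, window=window)


def sigma_profile(stack: AcquiredStack,
                  y_margin_fraction: float = 0.15) -> pd.DataFrame:
    """Population SD of intensity across y per depth, within the analysis band.

    The outer ``y_margin_fraction`` of rows on each side (the absorbing
    boundary margin) is excluded.
    """
    ny = stack.image.shape[0]
    margin = int(round(ny * y_margin_fraction))
    band = stack.image[margin:ny - margin, :]
    if band.shape[0] < 2:
        raise ValueError("stack has fewer than 2 usable y rows")
    sigma = band.std(axis=0, ddof=0)
    return pd.DataFrame({"z": stack.z, "sigma_I_y": sigma})


def contrast_profile(stack: AcquiredStack, roi_width: float = 20.0,
                     z_centers=None, robust: bool = True,
                     percentiles: tuple[float, float] = (1.0, 99.0),
                     y_margin_fraction: float = 0.15) -> pd.DataFrame:
    """Michelson contrast per depth-resolved region of interest.

    Each ROI spans ``roi_width`` um in z (full analysis band in y); the
    robust variant reads Imax/Imin from the given percentiles so a single
    hot pixel cannot saturate the contrast.
    """
    z = stack.z
    if len(z) >= 2:
        dz = float(np.median(np.diff(z)))
    else:
        dz = roi_width
    half_px = max(int(round(roi_width / (2 * dz))), 1)
    if 2 * half_px + 1 > len(z) and len(z) > 1:
        raise ValueError("roi_width spans fewer than 3 recorded planes")
    ny = stack.image.shape[0]
    margin = int(round(ny * y_margin_fraction))
    band = stack.image[margin:ny - margin, :]
    if z_centers is None:
        z_centers = z[half_px:len(z) - half_px] if len(z) > 2 * half_px else z
    rows = []
    for zc in np.atleast_1d(z_centers):
        ic = int(np.argmin(np.abs(z - zc)))
        lo, hi = max(ic - half_px, 0), min(ic + half_px + 1, len(z))
        if lo >= hi:
            raise ValueError(f"ROI at z = {zc} um lies outside the stack")
        roi = band[:, lo:hi]
        if robust:
            imin, imax = np.percentile(roi, percentiles)
        else:
            imin, imax = float(roi.min()), float(roi.max())
        denom = imax + imin
        c = (imax - imin) / denom if denom > 0 else 0.0
        rows.append({"z": float(z[ic]), "contrast": float(np.clip(c, 0.0, 1.0))})
    return pd.DataFrame(rows)


def edge_rolloff(stack: AcquiredStack, beam: BeamSpec, z_focus: float,
                 y0: float = 0.0) -> float:
    """Fractional signal loss at the field edges of a slit-scanned image.

    ``1 - mean(S(z_focus - z_R), S(z_focus + z_R)) / S(z_focus)`` read on
    the beam axis of the *raw* (unnormalized) sphere-free scanned stack.
    The edges sit at the beam's in-medium Rayleigh range, where the
    propagated beam has actually expanded to sqrt(2) of its waist.
    """
    if stack.normalized:
        raise ValueError("edge_rolloff expects the raw (unnormalized) "
                         "slit-scanned stack")
    z_r = in_medium_rayleigh_range(beam.na_x, beam.wavelength,
                                   beam.medium_index)
    edges = (z_focus - z_r, z_focus + z_r)
    zmin, zmax = stack.z.min(), stack.z.max()
    tol = max(np.median(np.diff(stack.z)) if len(stack.z) > 1 else 1.0, 1.0)
    for ze in edges:
        if ze < zmin - tol or ze > zmax + tol:
            raise ValueError(f"field edge z = {ze:.1f} um outside the stack")
    def signal(z0: float) -> float:
        # mean over a 3-pixel y window at the single nearest recorded plane
        iy = int(np.argmin(np.abs(stack.y - y0)))
        iz = int(np.argmin(np.abs(stack.z - z0)))
        ylo, yhi = max(iy - 1, 0), min(iy + 2, len(stack.y))
        return float(stack.image[ylo:yhi, iz].mean())

    s_focus = signal(z_focus)
    s_edges = 0.5 * (signal(edges[0]) + signal(edges[1]))
    if s_focus <= 0:
        raise ValueError("non-positive focal signal")
    return 1.0 - s_edges / s_focus


def attenuation_correct(stack: AcquiredStack, smooth_window: int = 10
                        ) -> tuple[AcquiredStack, float]:
    """Fit and remove an exponential depth decay exp(-mu_s z).

    The median intensity per depth is smoothed with a ``smooth_window``
    moving average and fitted by ordinary least squares in log space; the
    corrected stack is the input times ``exp(+mu_s z)``.  Returns the
    corrected stack and mu_s in 1/mm.
    """
    med = np.median(stack.image, axis=0)
    if np.any(med <= 0):
        raise ValueError("attenuation fit requires strictly positive "
                         "median intensity at every depth")
    window = max(int(smooth_window), 1)
    # smooth in log space (the moving average of a log-linear decay stays
    # log-linear) and fit on the interior, clear of filter edge effects
    smooth = ndimage.uniform_filter1d(np.log(med), size=window, mode="nearest")
    z_mm = stack.z / 1000.0
    trim = window // 2
    sl = slice(trim, len(z_mm) - trim) if len(z_mm) > 2 * (trim + 1) else slice(None)
    fit = stats.linregress(z_mm[sl], smooth[sl])
    if not np.isfinite(fit.slope):
        raise RuntimeError(f"exponential fit failed: {fit}")
    mu_s = -float(fit.slope)  # 1/mm
    corrected = stack.image * np.exp(mu_s * z_mm)[None, :]
    out = AcquiredStack(image=corrected, y=stack.y, z=stack.z,
                        normalized=stack.normalized, mode=stack.mode,
                        meta={**stack.meta, "mu_s_per_mm": mu_s,
                              "attenuation_corrected": True})
    return out, mu_s
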