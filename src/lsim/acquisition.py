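"""Acquisition orchestration for the four light-sheet architectures.

Modes
-----
* ``SPIM``  - static sheet (collimated in y), widefield detection.
* ``mSPIM`` - the sheet is pivoted in its own plane; the recorded image is
  the unweighted incoherent average over the pivot angle set (a
  time-average surrogate).
* ``DSLM``  - circular pencil beam scanned in y; each beam position is
  imaged, apertured by the confocal slit centred on the beam, and the
  apertured images are summed.
* ``mDSLM`` - identical to DSLM with the elliptical beam.

Normalization divides the summed (or averaged) image by the identical
acquisition on the sphere-free phantom, matching the convention that all
reported intensities are relative to an unobstructed illumination.

Scanned modes accept a ``scan_window_halfwidth``: beam positions within
the window of any sphere (in y) are propagated through the phantom; the
remaining positions are provably unaffected by the spheres and their
images are obtained by translating the single sphere-free beam image
(beam-to-beam shift invariance of a homogeneous medium).  This is an exact
optimization whenever the window generously covers the occluders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .beams import BeamSpec, in_medium_rayleigh_range
from .bpm import (PropagationConfig, RecordPlan, make_source_field,
                  propagate, run_beam)
from .detection import CameraImage, DetectionSpec, fluorescence_image
from .phantom import Phantom

__all__ = [
    "AcquisitionPlan",
    "AcquiredStack",
    "run_acquisition",
    "run_na_sweep",
    "run_tiled_z",
]

MODES = ("SPIM", "mSPIM", "DSLM", "mDSLM")
SCANNED = ("DSLM", "mDSLM")


@dataclass(frozen=True)
class AcquisitionPlan:
    """One acquisition: mode, beam, detection, scan/pivot set, numerics."""

    mode: str
    beam: BeamSpec
    detection: DetectionSpec
    z_focus: float
    scan_step: float | None = None           # um; DSLM/mDSLM only
    scan_span: tuple[float, float] | None = None  # (start, stop) in y, um
    scan_window_halfwidth: float | None = None
    pivot_half_angle_deg: float | None = None     # mSPIM only
    n_pivot_angles: int = 21
    normalize: bool = True
    dz: float | None = None
    dz_coarse: float | None = None
    boundary_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        scanned = self.mode in SCANNED
        if scanned:
            if self.scan_step is None:
                raise ValueError(f"{self.mode} requires scan_step")
            if self.pivot_half_angle_deg is not None:
                raise ValueError("pivot settings are only valid for mSPIM")
            if self.detection.mode != "confocal-line":
                raise ValueError(f"{self.mode} uses confocal-line detection")
        else:
            if self.scan_step is not None or self.scan_span is not None:
                raise ValueError("scan settings are only valid for DSLM/mDSLM")
            if self.mode == "SPIM" and self.pivot_half_angle_deg is not None:
                raise ValueError("pivot settings are only valid for mSPIM")
            if self.mode == "mSPIM" and self.pivot_half_angle_deg is None:
                raise ValueError("mSPIM requires pivot_half_angle_deg")
            if self.detection.mode != "widefield":
                raise ValueError(f"{self.mode} uses widefield detection")

    def pivot_angles(self) -> np.ndarray:
        if self.mode == "SPIM":
            return np.array([0.0])
        if self.n_pivot_angles == 1:
            return np.array([0.0])
        return np.linspace(-self.pivot_half_angle_deg, self.pivot_half_angle_deg,
                           self.n_pivot_angles)


@dataclass
class AcquiredStack:
    """A (possibly normalized) yz image with its provenance."""

    image: np.ndarray            # (ny, n_z_planes)
    y: np.ndarray
    z: np.ndarray
    normalized: bool
    mode: str
    raw: np.ndarray | None = None
    reference: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def value_at(self, y0: float, z0: float, window: int = 3) -> float:
        iy = int(np.argmin(np.abs(self.y - y0)))
        iz = int(np.argmin(np.abs(self.z - z0)))
        h = window // 2
        ylo, yhi = max(iy - h, 0), min(iy + h + 1, len(self.y))
        zlo, zhi = max(iz - h, 0), min(iz + h + 1, len(self.z))
        return float(self.image[ylo:yhi, zlo:zhi].mean())


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _record_plan(plan: AcquisitionPlan, z_planes: Sequence[float]) -> RecordPlan:
    return RecordPlan(z_planes=tuple(z_planes),
                      x_slab_halfwidth=plan.detection.recommended_slab_halfwidth)


def _prop_config(plan: AcquisitionPlan, record: RecordPlan,
                 offset_y: float = 0.0, pivot_deg: float = 0.0,
                 source_type: str = "pencil") -> PropagationConfig:
    return PropagationConfig(beam=plan.beam, z_focus=plan.z_focus,
                             record=record, dz=plan.dz, dz_coarse=plan.dz_coarse,
                             boundary_fraction=plan.boundary_fraction,
                             source_type=source_type,
                             source_offset_y=offset_y,
                             pivot_angle_deg=pivot_deg)


def _camera(plan: AcquisitionPlan, phantom: Phantom, record_cfg: PropagationConfig
            ) -> CameraImage:
    rec = run_beam(plan.beam, phantom, record_cfg)
    return fluorescence_image(rec, phantom, plan.detection)


def _shift_columns(image: np.ndarray, shift_px: int) -> np.ndarray:
    """Shift along axis 0 (y), zero-filling the vacated rows."""
    out = np.zeros_like(image)
    if shift_px == 0:
        out[:] = image
    elif shift_px > 0:
        out[shift_px:] = image[:-shift_px]
    else:
        out[:shift_px] = image[-shift_px:]
    return out


def _scan_positions(plan: AcquisitionPlan, phantom: Phantom) -> np.ndarray:
    grid = phantom.grid
    if plan.scan_span is not None:
        start, stop = plan.scan_span
    else:
        margin = grid.y_halfwidth * (plan.boundary_fraction + 0.05)
        start, stop = -grid.y_halfwidth + margin, grid.y_halfwidth - margin
    step = plan.scan_step
    # snap positions to the transverse pitch so shifted fills are exact
    step_px = max(int(round(step / grid.dy)), 1)
    i0 = int(math.ceil(start / (step_px * grid.dy)))
    i1 = int(math.floor(stop / (step_px * grid.dy)))
    return np.arange(i0, i1 + 1) * step_px * grid.dy


def _affected(plan: AcquisitionPlan, phantom: Phantom, y_s: float) -> bool:
    if not phantom.spheres:
        return False
    if plan.scan_window_halfwidth is None:
        return True
    return any(abs(y_s - s.center[1]) <= plan.scan_window_halfwidth
               for s in phantom.spheres)


def _normalize(raw: np.ndarray, ref: np.ndarray,
               eps_fraction: float = 1e-9) -> np.ndarray:
    eps = eps_fraction * float(ref.max())
    out = np.zeros_like(raw)
    good = ref > eps
    out[good] = raw[good] / ref[good]
    return out


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------

def run_acquisition(plan: AcquisitionPlan, phantom: Phantom,
                    z_planes: Sequence[float]) -> AcquiredStack:
    """Execute one acquisition and return the (normalized) yz image."""
    record = _record_plan(plan, z_planes)
    grid = phantom.grid

    if plan.mode in SCANNED:
        positions = _scan_positions(plan, phantom)
        # single sphere-free beam image at y = 0; every unaffected position
        # and the whole reference are exact translations of it
        free = phantom.without_spheres()
        cfg0 = _prop_config(plan, record, offset_y=0.0)
        img0 = fluorescence_image(propagate(
            make_source_field(plan.beam, plan.z_focus, grid), free, cfg0),
            free, plan.detection)
        slit_half = plan.detection.slit_width / 2.0
        y = grid.y
        raw = np.zeros_like(img0.image)
        ref = np.zeros_like(img0.image)
        n_propagated = 0
        for y_s in positions:
            shift_px = int(round(y_s / grid.dy))
            mask = (np.abs(y - y_s) <= slit_half).astype(float)[:, None]
            shifted0 = _shift_columns(img0.image, shift_px)
            ref += mask * shifted0
            if _affected(plan, phantom, y_s):
                cfg = _prop_config(plan, record, offset_y=y_s)
                img = fluorescence_image(
                    propagate(make_source_field(plan.beam, plan.z_focus, grid,
                                                offset_y=y_s),
                              phantom, cfg),
                    phantom, plan.detection)
                raw += mask * img.image
                n_propagated += 1
            else:
                raw += mask * shifted0
        meta = {"mode": plan.mode, "scan_positions": len(positions),
                "propagated_positions": n_propagated,
                "scan_step": plan.scan_step, "z_focus": plan.z_focus,
                "slit_width": plan.detection.slit_width}
    else:
        angles = plan.pivot_angles()
        raw = None
        ref = None
        for ang in angles:
            cfg = _prop_config(plan, record, pivot_deg=ang, source_type="sheet")
            src = make_source_field(plan.beam, plan.z_focus, grid,
                                    source_type="sheet", pivot_angle_deg=ang)
            img = fluorescence_image(propagate(src, phantom, cfg),
                                     phantom, plan.detection)
            if phantom.spheres:
                free = phantom.without_spheres()
                img_ref = fluorescence_image(propagate(src, free, cfg),
                                             free, plan.detection)
            else:
                img_ref = img
            raw = img.image if raw is None else raw + img.image
            ref = img_ref.image.copy() if ref is None else ref + img_ref.image
        raw /= len(angles)
        ref /= len(angles)
        meta = {"mode": plan.mode, "n_pivot_angles": len(angles),
                "pivot_half_angle_deg": plan.pivot_half_angle_deg,
                "z_focus": plan.z_focus}

    if plan.normalize:
        image = _normalize(raw, ref)
    else:
        image = raw.copy()
    return AcquiredStack(image=image, y=grid.y.copy(),
                         z=np.asarray(sorted(z_planes), dtype=float),
                         normalized=plan.normalize, mode=plan.mode,
                         raw=raw, reference=ref, meta=meta)


# ---------------------------------------------------------------------------
# sweeps and tiling
# ---------------------------------------------------------------------------

def _single_beam_focus_ratio(beam: BeamSpec, phantom: Phantom, z_focus: float,
                             numerics_dz: tuple[float | None, float | None],
                             boundary_fraction: float) -> float:
    """Normalized on-axis focal intensity of a single (unscanned) beam."""
    grid = phantom.grid
    planes = (z_focus - grid.dz, z_focus, z_focus + grid.dz)
    record = RecordPlan(z_planes=planes, x_slab_halfwidth=2.0 * grid.dx)
    cfg = PropagationConfig(beam=beam, z_focus=z_focus, record=record,
                            dz=numerics_dz[0], dz_coarse=numerics_dz[1],
                            boundary_fraction=boundary_fraction)
    obs = run_beam(beam, phantom, cfg)
    ref = run_beam(beam, phantom.without_spheres(), cfg)
    from .metrics import focus_ratio  # local import to avoid cycle
    from .metrics import single_beam_stack
    return focus_ratio(single_beam_stack(obs, ref), z_focus)


def _edge_signal(beam: BeamSpec, phantom_free: Phantom, plan: AcquisitionPlan
                 ) -> float:
    """Sphere-free slit-scanned signal at the field edges over the focus."""
    z_r = in_medium_rayleigh_range(beam.na_x, beam.wavelength,
                                   beam.medium_index)
    z_planes = [plan.z_focus - z_r, plan.z_focus, plan.z_focus + z_r]
    scan_plan = replace(plan, beam=beam, normalize=False)
    stack = run_acquisition(scan_plan, phantom_free, z_planes)
    from .metrics import edge_rolloff
    return 1.0 - edge_rolloff(stack, beam, plan.z_focus)


def run_na_sweep(na_x_values: Sequence[float], na_y_values: Sequence[float],
                 phantom: Phantom, z_focus: float,
                 metric: str = "focus_intensity",
                 detection: DetectionSpec | None = None,
                 scan_step: float = 2.0,
                 dz: float | None = None, dz_coarse: float | None = None,
                 boundary_fraction: float = 0.10,
                 wavelength: float = 0.660) -> pd.DataFrame:
    """Metric per (NA_x, NA_y) cell.

    ``focus_intensity`` runs a single beam through the phantom (spheres
    present) and reports the normalized focal intensity; ``edge_signal``
    runs the slit-apertured scan on the sphere-free phantom and reports
    the field-edge signal relative to the focus.  Per-cell failures (for
    example an under-resolved waist) are recorded instead of raised.
    """
    if metric not in ("focus_intensity", "edge_signal"):
        raise ValueError(f"unknown sweep metric {metric!r}")
    medium_index = phantom.n_background
    rows = []
    for na_x in na_x_values:
        for na_y in na_y_values:
            row = {"na_x": na_x, "na_y": na_y, "metric": metric,
                   "value": np.nan, "error": ""}
            try:
                if na_y == 0:
                    beam = BeamSpec(na_x=na_x, na_y=0.0, wavelength=wavelength,
                                    medium_index=medium_index)
                else:
                    beam = BeamSpec(na_x=na_x, na_y=na_y, wavelength=wavelength,
                                    medium_index=medium_index)
                if metric == "focus_intensity":
                    if na_y == 0:
                        raise ValueError("focus_intensity sweep requires a "
                                         "pencil beam (na_y > 0)")
                    row["value"] = _single_beam_focus_ratio(
                        beam, phantom, z_focus, (dz, dz_coarse),
                        boundary_fraction)
                else:
                    det = detection or DetectionSpec(
                        medium_index=medium_index, mode="confocal-line")
                    if na_y == 0:
                        # collimated-in-y sheet through the slit: no y
                        # expansion, the edge signal equals the focal signal
                        row["value"] = 1.0
                    else:
                        plan = AcquisitionPlan(
                            mode="DSLM", beam=beam, detection=det,
                            z_focus=z_focus, scan_step=scan_step,
                            dz=dz, dz_coarse=dz_coarse,
                            boundary_fraction=boundary_fraction)
                        row["value"] = _edge_signal(
                            beam, phantom.without_spheres(), plan)
            except Exception as exc:  # noqa: BLE001 - per-cell error contract
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def run_tiled_z(plan: AcquisitionPlan, phantom: Phantom, tile_step: float,
                plane_spacing: float = 5.0) -> AcquiredStack:
    """Tile the acquisition along z, refocusing the beam every tile.

    Each tile re-runs the acquisition with ``z_focus`` advanced by
    ``tile_step`` and keeps the band ``|z - z_focus| <= tile_step / 2``;
    the bands are concatenated into a single stack.
    """
    if not tile_step > 0:
        raise ValueError("tile_step must be > 0")
    depth = phantom.grid.z_extent
    n_tiles = int(round(depth / tile_step))
    images, zs, tile_meta = [], [], []
    for it in range(n_tiles):
        z_focus = (it + 0.5) * tile_step
        if not (0 < z_focus < depth):
            continue
        lo = it * tile_step
        hi = min((it + 1) * tile_step, depth)
        z_planes = np.arange(lo + plane_spacing / 2, hi, plane_spacing)
        tile_plan = replace(plan, z_focus=z_focus)
        stack = run_acquisition(tile_plan, phantom, tuple(z_planes))
        images.append(stack.image)
        zs.append(stack.z)
        tile_meta.append({"z_focus": z_focus, "z_lo": lo, "z_hi": hi})
    image = np.concatenate(images, axis=1)
    z = np.concatenate(zs)
    return AcquiredStack(image=image, y=phantom.grid.y.copy(), z=z,
                         normalized=plan.normalize, mode=plan.mode,
                         meta={"tiles": tile_meta, "tile_step": tile_step,
                               "mode": plan.mode})
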