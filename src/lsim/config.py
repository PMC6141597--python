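"""Run configuration, serialization and the reproducibility shell.

A :class:`RunConfig` fully describes one simulation: grid preset, phantom,
beam, detection, acquisition plan and seed.  Configs round-trip losslessly
through YAML, reject unknown keys, and carry explicit units in their field
names (``*_um`` for micrometre lengths).  Every run directory receives a
:class:`RunManifest` (config hash, package version, seed, produced files)
from which the run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import datetime as _dt
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__ as _pkg_version
from .acquisition import AcquisitionPlan
from .beams import BeamSpec
from .detection import DetectionSpec
from .phantom import GridSpec, Phantom, SphereSpec, build_phantom, random_sphere_phantom
from .scenarios import PRESETS, Numerics

__all__ = [
    "RunConfig",
    "RunManifest",
    "load_config",
    "write_stack",
    "read_stack",
    "generate_fixtures",
]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridModel(_Model):
    pitch_um: float = Field(gt=0)
    transverse_extent_um: float = Field(gt=0)
    depth_um: float = Field(gt=0)
    dz_um: float | None = Field(default=None, gt=0)
    dz_coarse_um: float | None = Field(default=None, gt=0)

    def numerics(self, name: str = "custom") -> Numerics:
        return Numerics(name=name, pitch=self.pitch_um,
                        transverse_extent=self.transverse_extent_um,
                        depth=self.depth_um,
                        dz=self.dz_um or self.pitch_um,
                        dz_coarse=self.dz_coarse_um)


class BeamModel(_Model):
    na_x: float = Field(gt=0)
    na_y: float = Field(ge=0)
    wavelength_um: float = Field(default=0.660, gt=0)
    medium_index: float = Field(default=1.46, gt=0)

    def build(self) -> BeamSpec:
        return BeamSpec(na_x=self.na_x, na_y=self.na_y,
                        wavelength=self.wavelength_um,
                        medium_index=self.medium_index)


class SphereModel(_Model):
    center_um: tuple[float, float, float]
    diameter_um: float = Field(gt=0)
    index: float = Field(gt=0)
    fluorescent: bool = False

    def build(self) -> SphereSpec:
        return SphereSpec(center=tuple(self.center_um),
                          diameter=self.diameter_um, index=self.index,
                          fluorescent=self.fluorescent)


class RandomFieldModel(_Model):
    diameter_um: float = Field(gt=0)
    volume_fraction: float = Field(ge=0, lt=0.1)
    min_gap_um: float = Field(default=0.0, ge=0)
    index: float = Field(default=1.59, gt=0)


class PhantomModel(_Model):
    n_background: float = Field(default=1.46, gt=0)
    spheres: list[SphereModel] = Field(default_factory=list)
    random_field: RandomFieldModel | None = None
    gel_fluorescent: bool = True
    background_fluorescence: float | None = Field(default=None, ge=0, le=1)

    def build(self, grid: GridSpec, seed: int) -> Phantom:
        if self.random_field is not None:
            if self.spheres:
                raise ValueError("specify either explicit spheres or a "
                                 "random_field, not both")
            rf = self.random_field
            return random_sphere_phantom(grid, diameter=rf.diameter_um,
                                         volume_fraction=rf.volume_fraction,
                                         seed=seed, min_gap=rf.min_gap_um,
                                         index=rf.index,
                                         n_background=self.n_background)
        return build_phantom(grid, self.n_background,
                             [s.build() for s in self.spheres],
                             gel_fluorescent=self.gel_fluorescent,
                             background_fluorescence=self.background_fluorescence)


class DetectionModel(_Model):
    na: float = Field(default=0.40, gt=0)
    wavelength_em_um: float = Field(default=0.680, gt=0)
    medium_index: float = Field(default=1.46, gt=0)
    psf_model: Literal["gaussian-approx", "scalar-defocus", "delta"] = "gaussian-approx"
    slit_width_um: float = Field(default=20.0, gt=0)
    mode: Literal["confocal-line", "widefield"] = "confocal-line"

    def build(self) -> DetectionSpec:
        return DetectionSpec(na=self.na, wavelength_em=self.wavelength_em_um,
                             medium_index=self.medium_index,
                             psf_model=self.psf_model,
                             slit_width=self.slit_width_um, mode=self.mode)


class PlanModel(_Model):
    mode: Literal["SPIM", "mSPIM", "DSLM", "mDSLM"]
    z_focus_um: float = Field(gt=0)
    scan_step_um: float | None = Field(default=None, gt=0)
    scan_span_um: tuple[float, float] | None = None
    scan_window_halfwidth_um: float | None = Field(default=None, gt=0)
    pivot_half_angle_deg: float | None = Field(default=None, gt=0)
    n_pivot_angles: int = Field(default=21, ge=1)
    normalize: bool = True
    tile_step_um: float | None = Field(default=None, gt=0)

    def build(self, detection: DetectionSpec, beam: BeamSpec,
              numerics: Numerics) -> AcquisitionPlan:
        return AcquisitionPlan(
            mode=self.mode, beam=beam, detection=detection,
            z_focus=self.z_focus_um, scan_step=self.scan_step_um,
            scan_span=self.scan_span_um,
            scan_window_halfwidth=self.scan_window_halfwidth_um,
            pivot_half_angle_deg=self.pivot_half_angle_deg,
            n_pivot_angles=self.n_pivot_angles, normalize=self.normalize,
            dz=numerics.dz, dz_coarse=numerics.dz_coarse,
            boundary_fraction=numerics.boundary_fraction)


class SweepModel(_Model):
    na_x_values: list[float]
    na_y_values: list[float]
    metric: Literal["focus_intensity", "edge_signal"] = "focus_intensity"
    scan_step_um: float = Field(default=0.5, gt=0)


class RunConfig(_Model):
    """Complete, validated description of one simulation run."""

    scenario: str
    preset: str = "scaled"
    seed: int = 0
    output_dir: str = "out"
    grid: GridModel | None = None
    beam: BeamModel
    phantom: PhantomModel = Field(default_factory=PhantomModel)
    detection: DetectionModel = Field(default_factory=DetectionModel)
    plan: PlanModel | None = None
    sweep: SweepModel | None = None
    record_z_planes_um: list[float] | None = None

    @model_validator(mode="after")
    def _check_preset(self) -> "RunConfig":
        if self.grid is None and self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r} and no explicit grid; "
                f"known presets: {sorted(PRESETS)}")
        return self

    # -- builders -----------------------------------------------------------
    def numerics(self) -> Numerics:
        if self.grid is not None:
            return self.grid.numerics(name=self.preset)
        return PRESETS[self.preset]

    def build_grid(self) -> GridSpec:
        return self.numerics().grid()

    def build_phantom(self) -> Phantom:
        return self.phantom.build(self.build_grid(), self.seed)

    def build_plan(self) -> AcquisitionPlan:
        if self.plan is None:
            raise ValueError("config has no acquisition plan")
        return self.plan.build(self.detection.build(), self.beam.build(),
                               self.numerics())

    # -- serialization ------------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config must be a YAML mapping")
        return cls.model_validate(data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    return RunConfig.from_yaml(Path(path).read_text())


class RunManifest(_Model):
    """Reproducibility record written exactly once per run directory."""

    scenario: str
    config_hash: str
    version: str
    preset: str
    seed: int
    created: str
    files: list[str] = Field(default_factory=list)
    extra: dict = Field(default_factory=dict)

    @classmethod
    def for_run(cls, config: RunConfig, files: list[str],
                extra: dict | None = None) -> "RunManifest":
        return cls(scenario=config.scenario, config_hash=config.config_hash(),
                   version=_pkg_version, preset=config.preset,
                   seed=config.seed,
                   created=_dt.datetime.now(_dt.timezone.utc).isoformat(),
                   files=files, extra=extra or {})

    def write(self, directory) -> Path:
        path = Path(directory) / "manifest.json"
        if path.exists():
            raise FileExistsError(f"manifest already written: {path}")
        path.write_text(json.dumps(self.model_dump(mode="json"), indent=2))
        return path


# ---------------------------------------------------------------------------
# image stack I/O
# ---------------------------------------------------------------------------

def write_stack(stack, path) -> list[Path]:
    """Write an image stack as 32-bit float TIFF plus a JSON sidecar.

    Accepts an :class:`~lsim.acquisition.AcquiredStack` (single yz page) or
    an :class:`~lsim.bpm.IntensityRecord` (one page per recorded plane).
    The sidecar records pitch, axis order and normalization state.
    """
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(stack, Phantom):
        pages = stack.refractive_volume().astype(np.float32)
        g = stack.grid
        sidecar = {
            "kind": "phantom",
            "axes": "page=z, row=x (detection axis), col=y (scan axis)",
            "pitch_um": [g.dx, g.dy, g.dz],
            "shape": [g.nz, g.nx, g.ny],
            "n_background": stack.n_background,
            "n_spheres": len(stack.spheres),
            "normalized": False,
        }
    elif hasattr(stack, "slab"):  # IntensityRecord
        pages = np.asarray(stack.slab, dtype=np.float32)
        sidecar = {
            "kind": "intensity_record",
            "axes": "page=z_plane, row=x (detection axis), col=y (scan axis)",
            "z_planes_um": [float(z) for z in stack.z_planes],
            "x_coords_um": [float(x) for x in stack.x_slab_coords],
            "pitch_um": [stack.grid.dx, stack.grid.dy, stack.grid.dz],
            "normalized": False,
            "meta": _jsonable(stack.meta),
        }
    else:  # AcquiredStack / CameraImage
        pages = np.asarray(stack.image, dtype=np.float32)[None, ...]
        sidecar = {
            "kind": "acquired_stack",
            "axes": "row=y (scan axis), col=z (propagation axis); "
                    "detection along x",
            "y_coords_um": [float(v) for v in stack.y],
            "z_planes_um": [float(v) for v in stack.z],
            "normalized": bool(getattr(stack, "normalized", False)),
            "mode": getattr(stack, "mode", "unknown"),
            "meta": _jsonable(getattr(stack, "meta", {})),
        }
    tifffile.imwrite(path, pages, dtype=np.float32,
                     photometric="minisblack")
    sidecar_path = path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return [path, sidecar_path]


def read_stack(path):
    """Read back a stack written by :func:`write_stack`.

    Returns ``(pages, sidecar)`` with pages as float32 and the sidecar dict.
    """
    import tifffile

    path = Path(path)
    pages = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return np.asarray(pages, dtype=np.float32), sidecar


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _single_sphere_phantom_model() -> PhantomModel:
    return PhantomModel(spheres=[SphereModel(center_um=(0.0, 2.0, 125.0),
                                             diameter_um=20.0, index=1.59)])


def generate_fixtures(seed: int, out_dir) -> dict[str, Path]:
    """Write the canonical scenario configs, runnable at the scaled preset.

    Returns a mapping of scenario name to config path.  The set is
    deterministic given ``seed`` (the seed is embedded in each config).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dslm = BeamModel(na_x=0.06, na_y=0.06)
    mdslm = BeamModel(na_x=0.06, na_y=0.18)
    single = dict(scan_window_halfwidth_um=None)

    configs: dict[str, RunConfig] = {}
    # single stationary beams past the large sphere
    for name, beam in (("single_beam_dslm", dslm), ("single_beam_mdslm", mdslm)):
        configs[name] = RunConfig(
            scenario=name, preset="scaled", seed=seed, beam=beam,
            phantom=_single_sphere_phantom_model(),
            detection=DetectionModel(mode="widefield"),
            record_z_planes_um=[349.5, 350.0, 350.5])
    # scanned, slit-apertured acquisitions
    for name, beam, mode in (("scanned_dslm", dslm, "DSLM"),
                             ("scanned_mdslm", mdslm, "mDSLM")):
        configs[name] = RunConfig(
            scenario=name, preset="scaled", seed=seed, beam=beam,
            phantom=_single_sphere_phantom_model(),
            plan=PlanModel(mode=mode, z_focus_um=350.0, scan_step_um=2.0,
                           scan_window_halfwidth_um=30.0),
            record_z_planes_um=[349.5, 350.0, 350.5])
    # NA sweeps: occluded focus intensity and sphere-free edge signal
    configs["na_sweep_focus"] = RunConfig(
        scenario="na_sweep_focus", preset="scaled", seed=seed, beam=dslm,
        phantom=_single_sphere_phantom_model(),
        sweep=SweepModel(na_x_values=[round(0.03 * i, 2) for i in range(1, 9)],
                         na_y_values=[round(0.03 * i, 2) for i in range(0, 9)],
                         metric="focus_intensity"))
    configs["na_sweep_edge"] = configs["na_sweep_focus"].model_copy(
        update={"scenario": "na_sweep_edge",
                "sweep": SweepModel(
                    na_x_values=[round(0.03 * i, 2) for i in range(1, 9)],
                    na_y_values=[round(0.03 * i, 2) for i in range(0, 9)],
                    metric="edge_signal")})
    # seeded small-sphere field, tiled acquisition
    for name, beam, mode in (("sphere_field_dslm", dslm, "DSLM"),
                             ("sphere_field_mdslm", mdslm, "mDSLM")):
        configs[name] = RunConfig(
            scenario=name, preset="sphere-field-scaled", seed=seed, beam=beam,
            phantom=PhantomModel(random_field=RandomFieldModel(
                diameter_um=6.0, volume_fraction=0.005, min_gap_um=1.0)),
            plan=PlanModel(mode=mode, z_focus_um=25.0, scan_step_um=2.0,
                           tile_step_um=50.0))

    paths: dict[str, Path] = {}
    for name, cfg in configs.items():
        p = out / f"{name}.yaml"
        p.write_text(cfg.to_yaml())
        paths[name] = p
    # synthetic attenuation-recovery stack parameters (known decay)
    atten = {"scenario": "attenuation_recovery", "seed": seed,
             "mu_s_per_mm": 10.0, "noise_fraction": 0.01,
             "ny": 64, "nz": 400, "pitch_um": 2.0}
    p = out / "attenuation.json"
    p.write_text(json.dumps(atten, indent=2))
    paths["attenuation"] = p
    return paths
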