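# lsim

Physical-optics simulation of light-sheet fluorescence microscopy (LSFM)
illumination, and the metrics used to compare light-sheet architectures on
refractive phantoms.

LSFM excites fluorescence in a thin planar region and images it with a
camera along the orthogonal axis.  The classical architectures differ in
how the sheet is formed and detected: **SPIM** (static sheet, widefield
camera), **mSPIM** (sheet pivoted in its own plane to time-average
shadows), **DSLM** (circular Gaussian pencil beam scanned laterally,
synchronized with a rolling-shutter confocal slit), and **mDSLM** (the
same scanned-beam geometry with an *elliptical* beam, NA_y > NA_x, whose
passive in-sheet angular diversity mitigates shadowing while keeping
confocal line detection).  Shadowing arises because refractive occlusions
(cells, beads, lipid droplets) cast dark streaks along the illumination
axis; the severity depends on the beam's angular content.

`lsim` implements this entire comparison in silico:

* **Beam optics** (`lsim.beams`) — elliptical Gaussian beams with
  decoupled NAs: waists `w0 = λ/(π NA)`, Rayleigh ranges
  `z_R = π w0²/λ`, the normalized intensity
  `I = 2/(π w_x w_y) exp(−2x²/w_x² − 2y²/w_y²)`, pivot-angle
  equivalents, and confocal-slit sizing rules.
* **Phantoms** (`lsim.phantom`) — voxelized refractive-index and
  fluorophore volumes: single spheres or seeded random fields of
  spheres in an index-matched fluorescent gel.
* **Propagation** (`lsim.bpm`) — split-step scalar beam propagation
  (angular-spectrum diffraction + thin phase screens + absorbing
  boundary), with adaptive stepping in homogeneous slabs and streaming
  of only the requested intensity planes.
* **Image formation** (`lsim.detection`) — `S = (I·F) ⊗ C` with a
  Gaussian-approximation or scalar-defocus 3D detection PSF, widefield
  or hard-slit confocal-line detection.
* **Acquisition** (`lsim.acquisition`) — the four modes, scanned-beam
  slit summation, sphere-free normalization, NA_x × NA_y sweeps and
  z-tiling.
* **Metrics** (`lsim.metrics`) — focal occlusion ratio, shadow statistic
  σ_I,y(z), Michelson contrast C(z), field-edge roll-off, and
  exponential attenuation correction (`I = e^(−μ_s z)`).

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.

## Worked example

Normalized focal intensity of a stationary beam occluded by a 20-µm
sphere (n = 1.59) embedded 125 µm deep, 2 µm off-axis in an index-matched
gel (n = 1.46), with the beam focused 350 µm deep — first the circular
DSLM beam, then the elliptical mDSLM beam:

```python
from lsim import (PropagationConfig, RecordPlan, run_beam,
                  single_beam_stack, focus_ratio)
from lsim.scenarios import SCALED, dslm_beam, mdslm_beam, single_sphere_phantom

phantom = single_sphere_phantom(SCALED)          # 0.5-µm scaled preset
for name, beam in [("DSLM", dslm_beam()), ("mDSLM", mdslm_beam())]:
    cfg = PropagationConfig(beam=beam, z_focus=350.0,
                            record=RecordPlan(z_planes=(349.5, 350.0, 350.5),
                                              x_slab_halfwidth=1.2),
                            dz=SCALED.dz, dz_coarse=SCALED.dz_coarse)
    obs = run_beam(beam, phantom, cfg)
    ref = run_beam(beam, phantom.without_spheres(), cfg)
    ratio = focus_ratio(single_beam_stack(obs, ref), 350.0)
    print(f"{name}: normalized focal intensity {ratio:.3f}")
```

prints (about one second per beam):

```
DSLM: normalized focal intensity 0.079
mDSLM: normalized focal intensity 0.404
```

i.e. the sphere suppresses the circular beam's focus by 92% while the
elliptical beam, whose in-sheet angular fan partly bypasses the occluder,
retains five times more focal intensity.  The same scenario can be run
scanned and slit-apertured (`run_acquisition`), swept over NA
(`run_na_sweep`), or tiled in depth over a random sphere field
(`run_tiled_z`), and every stack/metric can be exported as float32 TIFF +
JSON sidecar or annotated CSV.

## Command line

```sh
lsim fixtures --seed 0 --out fixtures/      # canonical scenario configs
lsim beam  --config fixtures/single_beam_dslm.yaml --out out/beam
lsim scan  --config fixtures/scanned_mdslm.yaml --out out/scan
lsim sweep --config fixtures/na_sweep_focus.yaml --out out/sweep
lsim tile  --config fixtures/sphere_field_dslm.yaml --out out/tile
```

Every run writes a `manifest.json` (config hash, version, seed, file
list) from which it can be reproduced.

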