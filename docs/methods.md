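# Methods

`lsim` simulates the illumination side of light-sheet fluorescence
microscopy (LSFM) with scalar wave optics and converts the computed
illumination into camera images, so that the four classical architectures
— SPIM (static sheet, widefield camera), mSPIM (pivoted sheet, widefield),
DSLM (scanned circular pencil beam, confocal line detection) and mDSLM
(scanned *elliptical* pencil beam, confocal line detection) — can be
compared on identical digital phantoms.

## Beam model

All beams are Gaussian with decoupled numerical apertures: `NA_x`
orthogonal to the sheet (sets sheet thickness and the usable field along
the propagation axis `z`), `NA_y` in the sheet plane (sets in-sheet
angular diversity).  The closed forms

    w0 = lambda / (pi NA),   z_R = pi w0^2 / lambda,
    w(z) = w0 sqrt(1 + (z / z_R)^2),
    I(x, y, z) = 2 / (pi w_x w_y) exp(-2 x^2 / w_x^2 - 2 y^2 / w_y^2)

are implemented in `lsim.beams` with the *vacuum* wavelength and no
medium-index factor; they reproduce the conventional design numbers for
these instruments (e.g. a 2 z_R ≈ 117 um depth of focus for NA 0.06 at
660 nm, quoted as "~100 um" in instrument descriptions).  A beam
physically propagating in an immersion medium of index n expands on the
longer scale `n pi w0^2 / lambda` (`in_medium_rayleigh_range`); the
numerical engine reproduces that in-medium behaviour, and every metric
that refers to "the Rayleigh range of the simulated beam" (field-edge
positions in `edge_rolloff`) uses the in-medium value, because that is
where the propagated beam has actually expanded by sqrt(2).  The two
conventions differ by the factor n = 1.46; both are exposed.

`equivalent_pivot_half_angle(NA) = arcsin(NA)` maps an in-sheet NA to the
half-range of an equivalent sheet pivot (0.18 → 10.4°), the time-averaged
equivalence used to compare mSPIM with mDSLM.

## Phantoms

Phantoms are index-matched fluorescent gels (n_gel = 1.46) containing
spheres of polystyrene-like index (n_sphere = 1.59).  Voxelization uses a
hard centre-in-sphere test — no anti-aliasing — so phantoms are
bit-reproducible; the voxelized volume converges to the analytic sphere
volume (within 2% at 0.25-um pitch for a 20-um sphere).  The seeded
random field (`random_sphere_phantom`) draws centres uniformly with
rejection on overlap; it emulates bead-cluster gels with a realized
volume fraction within ~10% of the request.  Fluorophore maps are binary:
F = 1 in fluorescent gel, 0 inside non-fluorescent spheres (inverted,
with a 1:10 background ratio, for fluorescent-bead phantoms).

What the generator does **not** emulate: sub-micron Mie/Rayleigh
scatterers (Intralipid-like media), continuous index gradients, bead
polydispersity, and shot/camera noise.  Passing tests therefore
demonstrate correct wave-optical shadowing and slit geometry, not
performance in scattering tissue.

## Propagation engine

`lsim.bpm` advances the complex transverse field u(x, y) slice-wise:
angular-spectrum diffraction over each step with carrier
k = 2 pi n_bg / lambda (evanescent band hard-truncated), then a thin
phase screen `exp(i k0 (n - n_bg) dz)` sampled at the slice mid-plane,
then a separable super-Gaussian absorbing mask over the outer 10% of the
transverse grid.  Sources are defined analytically at the waist and
back-propagated to the entry face in one exact homogeneous step, which
avoids committing to an explicit astigmatic-phase formula.

Two performance refinements preserve the physics:

* **Adaptive stepping** — the angular-spectrum step is exact in
  homogeneous slabs, so sphere-free slabs use a coarse step (5 um at the
  scaled preset) and slabs cut by a sphere use the fine step (one voxel).
  The absorbing mask is applied every step, so light diffracted outward
  after an occlusion is still absorbed before wrap-around.
* **Plane streaming** — only the z-planes named in the record plan are
  kept, optionally restricted to a slab of detection-axis columns, so the
  full intensity volume never exists in memory even at the full preset
  (1200 x 1200 x 2800 voxels).

Fidelity checks: fitted 1/e^2 radii in homogeneous medium agree with the
analytic beam within 2% over ±2 z_R (in practice <0.1%); per-slice power
is conserved to <0.5% before boundary absorption; a run normalized by an
identical sphere-free run is exactly 1.

Waist resolvability: sources are rejected when w0 < 1.5 transverse
pixels; at 1.5 px the Gaussian amplitude spectrum at the grid Nyquist is
below 1e-3, so smaller waists would alias.  This admits the NA_y = 0.18
beam (w0 = 1.17 um = 2.3 px) at the 0.5-um scaled pitch while still
refusing genuinely under-sampled sources.

## Image formation

The camera image is `S = (I x F) ⊗ C` evaluated on the detection focal
plane (x = 0, the beam-axis plane): each recorded slab column is
multiplied by the fluorophore map, blurred laterally, and projected along
the detection axis with the PSF's axial weights.  Three detection models:

* `gaussian-approx` (default): separable Gaussian,
  sigma_lat = 0.21 lambda_em / NA, sigma_ax = 0.66 n lambda_em / NA^2
  (0.36 um and 4.1 um for NA 0.40 at 680 nm).  Its unit-sum normalization
  gives defocused planes a Gaussian axial weight.
* `scalar-defocus`: diffraction of a circular pupil with defocus phase;
  its lateral integral is constant across defocus, i.e. planes within the
  kernel extent are weighted equally (energy conservation).
* `delta`: identity kernel for bookkeeping tests.

For normalized occlusion metrics the model choice is nearly immaterial
(the reference run cancels it; < 1 point for the elliptical-beam
scenario).  It is *not* immaterial in two places, both documented
limitations: (i) when an occluder redistributes light strongly along the
detection axis (circular-beam scenario: normalized focal value 0.08
vs 0.11 between models), and (ii) in the unnormalized field-edge signal,
where the axial envelope of the Gaussian model contributes a ~7%
focus-to-edge loss (from the beam's x-expansion) on top of the ~6%
slit-clipping loss in y.  With the default model the elliptical beam's
edge roll-off is ~12.5% and the circular beam's ~7%; under the
energy-conserving model they are ~6% and ~0%.  The default follows the
convention that the detection kernel is a normalized 3D PSF.

Confocal line detection is geometric: a hard slit of width omega_slit
(default 20 um, the instrument convention; the design rule
`1.5 sqrt(2) w0_y` ≈ 7.4 um for the NA 0.06 reference beam is exposed
separately) masks the camera image around the instantaneous beam
position, and the masked images are summed over scan positions.
Rolling-shutter timing, noise and pixelation are out of scope.

## Acquisition modes

DSLM/mDSLM scan the pencil beam in y (default step 2 um at the scaled
preset; the normalized focal metric changes <2% when the step is halved,
because numerator and denominator share the sampling phase — the
*unnormalized* edge-signal metric instead uses a pitch-matched 0.5-um
step, which is free on sphere-free phantoms, see below).  Normalization
divides the summed image by the identical acquisition on the sphere-free
phantom, after summation.

Beam positions far from every sphere are provably unaffected by the
phantom, so when a scan window is given, only positions inside it are
propagated; the rest reuse the single sphere-free beam image translated
in y (exact by shift invariance of a homogeneous medium).  Scan positions
snap to the transverse pitch so these translations are integer-pixel.

SPIM uses a flat-top sheet in y (soft 5-um cosine edges spanning the grid
interior) focused only in x; mSPIM averages the widefield sheet images
over 21 pivot angles uniformly spanning ±10.4° (= arcsin 0.18) — an
intensity average as a surrogate for time averaging within one exposure.
With a single 0° angle mSPIM reduces to SPIM exactly.  z-tiling repeats
the acquisition with the focus advanced by the tile step (50 um),
keeping the band |z − z_focus| ≤ step/2 from each tile.

## Metrics

* `focus_ratio`: normalized intensity in a 3x3-pixel window at the
  on-axis focal position.
* `sigma_profile`: population SD of normalized intensity across y per
  depth, excluding a 15% boundary margin per side.
* `contrast_profile`: Michelson contrast (Imax − Imin)/(Imax + Imin) in
  20-um-deep ROIs; robust percentiles (1st/99th) by default, exact
  extrema switchable for analytic tests.
* `edge_rolloff`: 1 − (edge signal)/(focal signal) of the raw
  slit-scanned sphere-free image, edges at the in-medium z_R,x.
* `attenuation_correct`: fits `I = exp(-mu_s z)` to the per-depth median;
  the median is smoothed with a 10-pixel moving average *in log space*
  (the moving average of a log-linear decay stays log-linear, making the
  correction idempotent to <1e-3 /mm) and fitted by ordinary least
  squares on the interior, clear of filter edge effects; mu_s is
  reported in 1/mm.

## Presets and problem sizes

The `full` preset is the reference discretization (0.25-um voxels,
300 x 300 x 700 um).  All shipped tests and examples use the `scaled`
preset — 0.5-um pitch, 150-um transverse extent, 700-um depth, 5-um
coarse steps — which resolves the same beams, and a reduced
`sphere-field-scaled` preset (80 x 80 x 250 um, 6-um spheres at 0.5% volume
fraction, 50-um tiles) for the sphere-field shadow statistics.  These
sizes keep a single-beam run around one second and the complete scanned
comparisons in minutes on one core, while leaving all derived trends
unchanged under pitch/step halving (checked to <2% for the occlusion
metric).

## Known limitations

* Scalar, paraxial-free angular-spectrum propagation: no polarization,
  no vectorial high-NA corrections, no absorption in the medium.
* The hard-edged sphere phase screen slightly over-scatters at the sphere
  rim at coarse pitch (the circular-beam focal metric moves by ~0.2
  points, the elliptical one by ~5 points, between 0.5-um and 0.25-um
  pitch).
* The detection-model sensitivity described under *Image formation*.
* Scattering media (Intralipid, tissue) are not simulated; the contrast
  and attenuation statistics are implemented for such data but validated
  here only on synthetic decays and refractive phantoms.
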