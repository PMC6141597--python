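"""Fluorescence image formation: S = (I x F) (x) C.

The recorded illumination intensity ``I`` is multiplied by the fluorophore
map ``F`` and convolved with the 3D point-spread function ``C`` of the
collection objective, whose optical axis lies along ``x`` (orthogonal to
the light sheet).  The camera image is the convolved signal evaluated on
the detection focal plane (``x = 0``, the beam-axis plane), which for a
unit-sum 3D kernel amounts to a PSF-weighted projection of the excited
fluorescence along the detection axis.

Two PSF models are provided:

* ``gaussian-approx`` (default): separable Gaussian with lateral sigma
  ``0.21 lambda_em / NA`` and axial sigma ``0.66 n lambda_em / NA^2``
  (coefficients configurable).  Fast and smooth; the axial Gaussian acts
  as a soft weighting of defocused planes.
* ``scalar-defocus``: kernel built from scalar diffraction of a circular
  pupil with a defocus phase; its lateral integral is constant across
  defocus (energy conservation), i.e. planes within the kernel extent are
  weighted equally.
* ``delta``: identity kernel, for bookkeeping tests.

Confocal line detection is modelled geometrically: a hard rectangular slit
of width ``omega_slit`` centred on the instantaneous beam position masks
the camera image in ``y``.  Rolling-shutter timing is not simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bpm import IntensityRecord
from .phantom import GridSpec, Phantom

__all__ = [
    "DetectionSpec",
    "CameraImage",
    "detection_psf",
    "fluorescence_image",
    "apply_slit",
    "widefield_image",
]


@dataclass(frozen=True)
class DetectionSpec:
    """Collection-side parameters.

    NA 0.40 and lambda_em 0.680 um match a cleared-tissue collection
    objective detecting just red-shifted of a 660-nm excitation line.
    """

    na: float = 0.40
    wavelength_em: float = 0.680
    medium_index: float = 1.46
    psf_model: str = "gaussian-approx"   # gaussian-approx | scalar-defocus | delta
    slit_width: float = 20.0             # um, full width of the confocal slit
    mode: str = "confocal-line"          # confocal-line | widefield
    lateral_sigma_coeff: float = 0.21
    axial_sigma_coeff: float = 0.66

    def __post_init__(self) -> None:
        if not (0 < self.na < self.medium_index):
            raise ValueError("detection NA must satisfy 0 < NA < medium index")
        if self.mode not in ("confocal-line", "widefield"):
            raise ValueError(f"unknown detection mode {self.mode!r}")
        if self.psf_model not in ("gaussian-approx", "scalar-defocus", "delta"):
            raise ValueError(f"unknown psf_model {self.psf_model!r}")
        if self.mode == "confocal-line" and not self.slit_width > 0:
            raise ValueError("slit_width must be > 0 in confocal-line mode")

    @property
    def sigma_lateral(self) -> float:
        """Gaussian-approx lateral sigma (um)."""
        return self.lateral_sigma_coeff * self.wavelength_em / self.na

    @property
    def sigma_axial(self) -> float:
        """Gaussian-approx axial sigma (um)."""
        return (self.axial_sigma_coeff * self.medium_index
                * self.wavelength_em / self.na ** 2)

    @property
    def recommended_slab_halfwidth(self) -> float:
        """Detection-axis half-extent that captures the axial PSF support."""
        return 3.0 * self.sigma_axial


@dataclass
class CameraImage:
    """Detected yz-plane image: shape (ny, n_z_planes)."""

    image: np.ndarray
    y: np.ndarray
    z: np.ndarray
    mode: str = "widefield"
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def copy(self) -> "CameraImage":
        return CameraImage(image=self.image.copy(), y=self.y, z=self.z,
                           mode=self.mode, normalized=self.normalized,
                           meta=dict(self.meta))

    def value_at(self, y0: float, z0: float, window: int = 3) -> float:
        """Mean over a ``window x window`` pixel patch centred at (y0, z0)."""
        iy = int(np.argmin(np.abs(self.y - y0)))
        iz = int(np.argmin(np.abs(self.z - z0)))
        h = window // 2
        ylo, yhi = max(iy - h, 0), min(iy + h + 1, len(self.y))
        zlo, zhi = max(iz - h, 0), min(iz + h + 1, len(self.z))
        return float(self.image[ylo:yhi, zlo:zhi].mean())


# ---------------------------------------------------------------------------
# PSF kernels
# ---------------------------------------------------------------------------

def _odd_count(halfwidth: float, pitch: float) -> int:
    return 2 * max(int(math.ceil(halfwidth / pitch)), 1) + 1


def _scalar_defocus_kernel(spec: DetectionSpec, pitch_lat: float,
                           n_lat: int, defocus: np.ndarray) -> np.ndarray:
    """|PSF|^2 slices of a circular pupil at the given defocus values.

    Returns an array of shape (len(defocus), n_lat, n_lat); each slice is
    normalized to unit lateral sum (energy conservation across defocus).
    """
    pad = 4  # embed in a larger FFT grid to limit wrap-around
    nfft = int(2 ** math.ceil(math.log2(n_lat * pad)))
    k_em = 2.0 * math.pi * spec.medium_index / spec.wavelength_em
    fx = 2.0 * math.pi * np.fft.fftfreq(nfft, d=pitch_lat)
    KX, KY = np.meshgrid(fx, fx, indexing="ij")
    kt2 = KX ** 2 + KY ** 2
    k_cut = 2.0 * math.pi * spec.na / spec.wavelength_em
    pupil = kt2 <= k_cut ** 2
    kz = np.zeros_like(kt2)
    prop_ok = kt2 < k_em ** 2
    kz[prop_ok] = np.sqrt(k_em ** 2 - kt2[prop_ok])
    half = n_lat // 2
    out = np.empty((len(defocus), n_lat, n_lat))
    for i, dz in enumerate(defocus):
        field_k = np.where(pupil, np.exp(1j * kz * dz), 0.0)
        psf = np.abs(np.fft.ifft2(field_k)) ** 2
        psf = np.fft.fftshift(psf)
        c = nfft // 2
        sl = psf[c - half:c + half + 1, c - half:c + half + 1]
        out[i] = sl / sl.sum()
    return out


def detection_psf(spec: DetectionSpec, grid: GridSpec,
                  lateral_halfwidth: float | None = None,
                  axial_halfwidth: float | None = None) -> np.ndarray:
    """Explicit 3D detection kernel, axes ordered (x, y, z), unit sum.

    The optical axis of the kernel lies along ``x``.  For the
    ``gaussian-approx`` model the kernel is a separable Gaussian; for
    ``scalar-defocus`` each x-slice is a diffraction pattern of the
    defocused pupil with constant lateral energy.  ``delta`` returns a
    single-voxel kernel.
    """
    if spec.psf_model == "delta":
        return np.ones((1, 1, 1))
    lat_hw = (lateral_halfwidth if lateral_halfwidth is not None
              else 4.0 * spec.sigma_lateral)
    ax_hw = (axial_halfwidth if axial_halfwidth is not None
             else 3.0 * spec.sigma_axial)
    n_ax = _odd_count(ax_hw, grid.dx)
    n_lat_y = _odd_count(lat_hw, grid.dy)
    n_lat_z = _odd_count(lat_hw, grid.dz)
    if n_ax > grid.nx or n_lat_y > grid.ny or n_lat_z > grid.nz:
        raise ValueError("detection kernel larger than the grid")
    xs = (np.arange(n_ax) - n_ax // 2) * grid.dx
    ys = (np.arange(n_lat_y) - n_lat_y // 2) * grid.dy
    zs = (np.arange(n_lat_z) - n_lat_z // 2) * grid.dz
    if spec.psf_model == "gaussian-approx":
        gx = np.exp(-0.5 * (xs / spec.sigma_axial) ** 2)
        gy = np.exp(-0.5 * (ys / spec.sigma_lateral) ** 2)
        gz = np.exp(-0.5 * (zs / spec.sigma_lateral) ** 2)
        kern = gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    else:
        if abs(grid.dy - grid.dz) > 1e-9:
            raise ValueError("scalar-defocus kernel requires dy == dz")
        n_lat = max(n_lat_y, n_lat_z)
        slices = _scalar_defocus_kernel(spec, grid.dy, n_lat, xs)
        kern = slices  # (x, y, z) with square lateral extent
    return kern / kern.sum()


# ---------------------------------------------------------------------------
# image formation
# ---------------------------------------------------------------------------

def _axial_weights(spec: DetectionSpec, x_coords: np.ndarray) -> np.ndarray:
    """Per-column weights of the detection-axis projection, unit sum."""
    if spec.psf_model == "delta":
        w = (np.abs(x_coords) == np.abs(x_coords).min()).astype(float)
    elif spec.psf_model == "gaussian-approx":
        w = np.exp(-0.5 * (x_coords / spec.sigma_axial) ** 2)
    else:  # scalar-defocus: constant lateral energy across defocus
        w = np.ones_like(x_coords)
    return w / w.sum()


def _uniform_spacing(z: np.ndarray) -> float | None:
    if len(z) < 2:
        return None
    d = np.diff(z)
    return float(d[0]) if np.allclose(d, d[0], rtol=1e-6, atol=1e-9) else None


def fluorescence_image(record: IntensityRecord, phantom: Phantom,
                       det: DetectionSpec) -> CameraImage:
    """Camera-plane image of one illumination run.

    Multiplies the recorded intensity slab by the fluorophore map, blurs
    laterally (y, and z when the recorded planes are uniformly spaced),
    and projects along the detection axis with the model's axial weights.
    Linear in I and in F.
    """
    grid = record.grid
    x_coords = record.x_slab_coords
    weights = _axial_weights(det, x_coords)

    # lateral blur kernels per model
    if det.psf_model == "scalar-defocus":
        n_lat = _odd_count(4.0 * spec_blur_width(det), grid.dy)
        lat = _scalar_defocus_kernel(det, grid.dy, n_lat, x_coords)
        lat_y = lat.sum(axis=2)   # (nx_slab, n_lat) 1D y-kernels per defocus
        lat_y /= lat_y.sum(axis=1, keepdims=True)

    n_planes = len(record.z_planes)
    image = np.empty((grid.ny, n_planes))
    signal = np.empty((len(x_coords), grid.ny, n_planes))
    for ip in range(n_planes):
        iz = grid.nearest_z_index(record.z_planes[ip])
        F = phantom.fluorophore_slice(iz)[record.x_indices, :]
        signal[:, :, ip] = record.slab[ip].astype(np.float64) * F

    if det.psf_model == "gaussian-approx":
        sig_y = det.sigma_lateral / grid.dy
        signal = ndimage.gaussian_filter1d(signal, sig_y, axis=1, mode="nearest")
        dzp = _uniform_spacing(record.z_planes)
        if dzp is not None and len(record.z_planes) >= 3:
            signal = ndimage.gaussian_filter1d(
                signal, det.sigma_lateral / dzp, axis=2, mode="nearest")
    elif det.psf_model == "scalar-defocus":
        for i in range(len(x_coords)):
            signal[i] = ndimage.convolve1d(signal[i], lat_y[i], axis=0,
                                           mode="nearest")
        # z blur omitted for sparse plane sets; applied when contiguous
        dzp = _uniform_spacing(record.z_planes)
        if dzp is not None and abs(dzp - grid.dz) < 1e-9 and n_planes >= 3:
            lat_z = lat.sum(axis=1)
            lat_z /= lat_z.sum(axis=1, keepdims=True)
            for i in range(len(x_coords)):
                signal[i] = ndimage.convolve1d(signal[i], lat_z[i], axis=1,
                                               mode="nearest")

    image = np.tensordot(weights, signal, axes=(0, 0))
    return CameraImage(image=image, y=grid.y.copy(),
                       z=np.asarray(record.z_planes, dtype=float),
                       mode="widefield",
                       meta={"psf_model": det.psf_model, **record.meta})


def spec_blur_width(det: DetectionSpec) -> float:
    """Scale (um) used to size scalar-defocus lateral kernels."""
    # geometric blur radius at the slab edge plus the diffraction width
    half_angle = math.asin(det.na / det.medium_index)
    return (det.recommended_slab_halfwidth * math.tan(half_angle)
            + det.sigma_lateral)


def apply_slit(image: CameraImage, beam_y: float, det: DetectionSpec
               ) -> CameraImage:
    """Mask the camera image to the confocal slit ``|y - beam_y| <= w/2``."""
    if det.mode != "confocal-line":
        raise ValueError("apply_slit requires confocal-line mode; "
                         "use widefield_image for widefield detection")
    if not (image.y.min() <= beam_y <= image.y.max()):
        raise ValueError(f"beam_y = {beam_y} um outside the camera field")
    mask = (np.abs(image.y - beam_y) <= det.slit_width / 2.0).astype(float)
    out = image.copy()
    out.image = out.image * mask[:, None]
    out.mode = "confocal-line"
    out.meta = {**out.meta, "slit_width": det.slit_width, "beam_y": beam_y}
    return out


def widefield_image(image: CameraImage) -> CameraImage:
    """The unapertured camera image (no slit masking)."""
    out = image.copy()
    out.mode = "widefield"
    return out
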