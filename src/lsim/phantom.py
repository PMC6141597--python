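"""Voxelized refractive-index and fluorophore phantoms.

Phantoms emulate index-matched fluorescent gels (TDE-cleared agarose,
n ~ 1.46) containing polystyrene/glass microspheres (n ~ 1.59) that act as
refractive occluders.  The refractive volume ``n(x, y, z)`` drives the beam
propagation engine; the fluorophore map ``F(x, y, z)`` multiplies the
illumination intensity during image formation.

Coordinate conventions (shared package-wide):

* ``z`` is the illumination propagation axis, ``z = 0`` at the entry face,
  voxel centres at ``(i + 1/2) dz`` on the half-open span ``[0, nz dz)``.
* ``x`` (detection axis) and ``y`` (scan / in-sheet axis) are transverse;
  the grid is centred so the beam optical axis passes through
  ``(x, y) = (0, 0)``.
* Transverse arrays are indexed ``[ix, iy]``; volumes ``[iz, ix, iy]``.

Sphere voxelization uses a hard centre-in-sphere test (no anti-aliasing),
which keeps phantoms reproducible bit-for-bit and converges to the analytic
sphere volume as the pitch shrinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "SphereSpec",
    "Phantom",
    "build_phantom",
    "random_sphere_phantom",
    "PackingError",
]


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot realize a requested packing."""

    def __init__(self, message: str, achieved_fraction: float):
        super().__init__(message)
        self.achieved_fraction = achieved_fraction


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid: counts per axis and pitch in um."""

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float = None  # type: ignore[assignment]
    dz: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dy is None:
            object.__setattr__(self, "dy", self.dx)
        if self.dz is None:
            object.__setattr__(self, "dz", self.dx)
        for name in ("nx", "ny", "nz"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("dx", "dy", "dz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    # transverse coordinates are centred on the beam axis
    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.dx

    @property
    def y(self) -> np.ndarray:
        return (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.dy

    @property
    def z(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz

    @property
    def z_extent(self) -> float:
        return self.nz * self.dz

    @property
    def x_halfwidth(self) -> float:
        return self.nx * self.dx / 2.0

    @property
    def y_halfwidth(self) -> float:
        return self.ny * self.dy / 2.0

    def nearest_z_index(self, z: float) -> int:
        return int(np.clip(round(z / self.dz - 0.5), 0, self.nz - 1))

    def nearest_y_index(self, y: float) -> int:
        return int(np.clip(round(y / self.dy + (self.ny - 1) / 2.0), 0, self.ny - 1))


@dataclass(frozen=True)
class SphereSpec:
    """A single sphere: centre (x, y, z) in um, diameter, index, fluorescence."""

    center: tuple[float, float, float]
    diameter: float
    index: float
    fluorescent: bool = False

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("sphere diameter must be > 0")
        if not self.index > 0:
            raise ValueError("sphere index must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class Phantom:
    """Grid + background index + spheres; volumes are generated on demand.

    Slices are computed analytically per z plane rather than materialized
    as full 3D arrays, so full-scale grids never need to fit in memory.
    """

    grid: GridSpec
    n_background: float
    spheres: tuple[SphereSpec, ...] = ()
    background_fluorescence: float = 1.0

    def __post_init__(self) -> None:
        if not self.n_background > 0:
            raise ValueError("n_background must be > 0")
        if not (0.0 <= self.background_fluorescence <= 1.0):
            raise ValueError("background_fluorescence must lie in [0, 1]")
        object.__setattr__(self, "spheres", tuple(self.spheres))

    # -- geometry helpers ---------------------------------------------------
    def without_spheres(self) -> "Phantom":
        """The sphere-free twin used as the normalization reference."""
        return replace(self, spheres=())

    def spheres_intersecting(self, z0: float, z1: float) -> list[SphereSpec]:
        lo, hi = min(z0, z1), max(z0, z1)
        return [s for s in self.spheres
                if s.center[2] + s.radius > lo and s.center[2] - s.radius < hi]

    def _sphere_masks(self, z: float):
        """Yield (sphere, 2D bool mask) for spheres cut by the plane ``z``.

        When overlapping spheres are present a voxel belongs to the sphere
        whose centre is nearest.
        """
        cut = [s for s in self.spheres if abs(z - s.center[2]) < s.radius]
        if not cut:
            return []
        X = self.grid.x[:, None]
        Y = self.grid.y[None, :]
        masks = []
        d2 = []
        for s in cut:
            r2d_sq = s.radius ** 2 - (z - s.center[2]) ** 2
            dist2 = (X - s.center[0]) ** 2 + (Y - s.center[1]) ** 2
            masks.append(dist2 <= r2d_sq)
            d2.append(dist2 + (z - s.center[2]) ** 2)
        if len(cut) > 1:
            # resolve overlaps: nearest centre wins
            stack = np.stack(d2)
            inside_any = np.stack(masks)
            stack = np.where(inside_any, stack, np.inf)
            winner = np.argmin(stack, axis=0)
            masks = [inside_any[i] & (winner == i) for i in range(len(cut))]
        return list(zip(cut, masks))

    def index_slice(self, iz: int) -> np.ndarray:
        """Refractive index n(x, y) at voxel plane ``iz``, shape (nx, ny)."""
        z = self.grid.z[iz]
        n = np.full((self.grid.nx, self.grid.ny), self.n_background, dtype=np.float64)
        for sphere, mask in self._sphere_masks(z):
            n[mask] = sphere.index
        return n

    def fluorophore_slice(self, iz: int) -> np.ndarray:
        """Fluorophore map F(x, y) in [0, 1] at voxel plane ``iz``."""
        z = self.grid.z[iz]
        F = np.full((self.grid.nx, self.grid.ny), self.background_fluorescence,
                    dtype=np.float64)
        for sphere, mask in self._sphere_masks(z):
            F[mask] = 1.0 if sphere.fluorescent else 0.0
        return F

    def refractive_volume(self) -> np.ndarray:
        """Materialize n(x, y, z) as a (nz, nx, ny) array (small grids only)."""
        return np.stack([self.index_slice(i) for i in range(self.grid.nz)])

    def fluorophore_volume(self) -> np.ndarray:
        return np.stack([self.fluorophore_slice(i) for i in range(self.grid.nz)])

    def voxelized_sphere_volume(self, sphere_index: int = 0) -> float:
        """Voxel count x voxel volume attributed to one sphere, um^3."""
        s = self.spheres[sphere_index]
        g = self.grid
        lo = g.nearest_z_index(s.center[2] - s.radius)
        hi = g.nearest_z_index(s.center[2] + s.radius)
        count = 0
        for iz in range(lo, hi + 1):
            for sp, mask in self._sphere_masks(g.z[iz]):
                if sp is s:
                    count += int(mask.sum())
        return count * g.dx * g.dy * g.dz


def _check_in_bounds(sphere: SphereSpec, grid: GridSpec) -> None:
    cx, cy, cz = sphere.center
    r = sphere.radius
    if (abs(cx) + r > grid.x_halfwidth or abs(cy) + r > grid.y_halfwidth
            or cz - r < 0 or cz + r > grid.z_extent):
        raise ValueError(
            f"sphere at {sphere.center} with diameter {sphere.diameter} "
            "extends outside the grid")


def build_phantom(grid: GridSpec, n_background: float,
                  spheres: Sequence[SphereSpec] = (),
                  gel_fluorescent: bool = True,
                  background_fluorescence: float | None = None,
                  allow_overlap: bool = False) -> Phantom:
    """Assemble a phantom from explicit sphere specifications.

    Parameters
    ----------
    gel_fluorescent:
        If True (fluorescent-gel phantoms) the background fluorophore value
        is 1 and non-fluorescent spheres carve F = 0 holes.  If False
        (fluorescent-sphere phantoms) the background takes
        ``background_fluorescence`` (default 0.1, a ~1:10 background ratio)
        and fluorescent spheres have F = 1.
    allow_overlap:
        Overlapping spheres raise unless explicitly permitted; with overlap
        a voxel goes to the sphere whose centre is nearest.
    """
    spheres = tuple(spheres)
    for s in spheres:
        _check_in_bounds(s, grid)
    if not allow_overlap:
        for i in range(len(spheres)):
            for j in range(i + 1, len(spheres)):
                a, b = spheres[i], spheres[j]
                dist = math.dist(a.center, b.center)
                if dist < a.radius + b.radius:
                    raise ValueError(
                        f"spheres {i} and {j} overlap (centre distance {dist:.3g} um); "
                        "pass allow_overlap=True to permit this")
    if background_fluorescence is None:
        background_fluorescence = 1.0 if gel_fluorescent else 0.1
    return Phantom(grid=grid, n_background=n_background, spheres=spheres,
                   background_fluorescence=background_fluorescence)


def random_sphere_phantom(grid: GridSpec, diameter: float,
                          volume_fraction: float, seed: int,
                          min_gap: float = 0.0,
                          index: float = 1.59,
                          n_background: float = 1.46,
                          max_attempts_per_sphere: int = 200) -> Phantom:
    """Seeded field of equal-diameter spheres at a target volume fraction.

    Centres are drawn uniformly over the grid interior (inset by one
    radius) and rejected when closer than ``diameter + min_gap`` to an
    accepted centre.  Identical seeds yield voxel-identical phantoms.
    """
    if not (0.0 <= volume_fraction < 0.1):
        raise ValueError("volume_fraction must lie in [0, 0.1) for rejection "
                         f"sampling to terminate, got {volume_fraction}")
    rng = np.random.default_rng(seed)
    r = diameter / 2.0
    sphere_volume = 4.0 / 3.0 * math.pi * r ** 3
    total = (grid.nx * grid.dx) * (grid.ny * grid.dy) * grid.z_extent
    target = int(round(volume_fraction * total / sphere_volume))
    if target == 0:
        return Phantom(grid=grid, n_background=n_background)

    xlo, xhi = -grid.x_halfwidth + r, grid.x_halfwidth - r
    ylo, yhi = -grid.y_halfwidth + r, grid.y_halfwidth - r
    zlo, zhi = r, grid.z_extent - r
    if xlo >= xhi or ylo >= yhi or zlo >= zhi:
        raise ValueError("grid too small to contain a single sphere")

    centers: list[tuple[float, float, float]] = []
    min_dist = diameter + min_gap
    attempts_budget = max_attempts_per_sphere * target
    attempts = 0
    while len(centers) < target and attempts < attempts_budget:
        attempts += 1
        c = (rng.uniform(xlo, xhi), rng.uniform(ylo, yhi), rng.uniform(zlo, zhi))
        if all(math.dist(c, other) >= min_dist for other in centers):
            centers.append(c)
    if len(centers) < target:
        achieved = len(centers) * sphere_volume / total
        raise PackingError(
            f"placed {len(centers)}/{target} spheres after {attempts} attempts "
            f"(achieved volume fraction {achieved:.2e})", achieved)

    spheres = tuple(SphereSpec(center=c, diameter=diameter, index=index)
                    for c in centers)
    return Phantom(grid=grid, n_background=n_background, spheres=spheres)
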