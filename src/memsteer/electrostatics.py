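"""Electrostatic potential and desolvation grids over the bilayer.

The membrane is a set of point charges, so the linearised (Debye-Hückel)
screened-Coulomb superposition is *exact* for this model and replaces a
finite-difference Poisson-Boltzmann solve:

    Phi(x) = sum_i q_i * C(T) * exp(-|x - x_i| / kappa_inv) / (eps_r |x - x_i|)

with Phi in kT/e. An optional desolvation penalty grid g(x) (kT/e^2)
approximates the cost of bringing a charge near the low-dielectric membrane
interior; a protein charge q at x pays q^2 * g(x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _quat, constants

__all__ = [
    "GridSpec",
    "PotentialGrid",
    "DesolvationGrid",
    "GridBoundsError",
    "debye_length",
    "compute_potential_grid",
    "compute_desolvation_grid",
    "interaction_energy",
    "grid_for_bilayer",
]


def debye_length(ionic_strength: float, temperature: float = 300.0,
                 eps_r: float = 78.5) -> float:
    """Debye screening length kappa^-1 in Å (monovalent electrolyte)."""
    return constants.debye_length_A(ionic_strength, temperature, eps_r)


class GridBoundsError(ValueError):
    """A point fell outside the grid volume."""


@dataclass(frozen=True)
class GridSpec:
    """Regular-lattice geometry: origin (Å), isotropic spacing (Å), shape."""

    origin: tuple
    spacing: float
    shape: tuple

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(n < 2 for n in self.shape):
            raise ValueError("grid needs at least 2 nodes per axis")

    def axes(self):
        o = np.asarray(self.origin, dtype=float)
        return tuple(o[k] + self.spacing * np.arange(self.shape[k])
                     for k in range(3))

    @property
    def upper_corner(self):
        o = np.asarray(self.origin, dtype=float)
        return o + self.spacing * (np.asarray(self.shape) - 1)


@dataclass
class _ScalarGrid:
    origin: tuple
    spacing: float
    values: np.ndarray                 # shape (nx, ny, nz)

    @property
    def shape(self):
        return self.values.shape

    def spec(self) -> GridSpec:
        return GridSpec(tuple(self.origin), self.spacing, self.values.shape)

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at (n, 3) points (Å)."""
        return _trilinear(self.values, np.asarray(self.origin, dtype=float),
                          self.spacing, np.atleast_2d(points))

    def to_dx(self, path):
        """Write in OpenDX scalar format (APBS compatible)."""
        from gridData import Grid

        g = Grid(self.values, origin=np.asarray(self.origin, dtype=float),
                 delta=self.spacing)
        g.export(str(path), file_format="dx")

    @classmethod
    def _read_dx(cls, path):
        from gridData import Grid

        g = Grid(str(path))
        delta = np.diag(g.delta) if np.ndim(g.delta) == 2 else np.asarray(g.delta)
        if not np.allclose(delta, delta.flat[0]):
            raise ValueError("only isotropic grid spacings are supported")
        return tuple(g.origin), float(np.ravel(delta)[0]), g.grid


@dataclass
class PotentialGrid(_ScalarGrid):
    """Electrostatic potential in kT/e on a regular lattice."""

    kappa_inv: float = np.inf
    temperature: float = 300.0
    ionic_strength: float = 0.1

    @classmethod
    def from_dx(cls, path, kappa_inv=np.inf, temperature=300.0,
                ionic_strength=0.1):
        origin, spacing, values = cls._read_dx(path)
        return cls(origin, spacing, values, kappa_inv=kappa_inv,
                   temperature=temperature, ionic_strength=ionic_strength)


@dataclass
class DesolvationGrid(_ScalarGrid):
    """Desolvation penalty factor g >= 0 in kT per e^2."""

    @classmethod
    def from_dx(cls, path):
        origin, spacing, values = cls._read_dx(path)
        return cls(origin, spacing, values)


def _trilinear(values, origin, spacing, pts):
    frac = (pts - origin) / spacing
    shape = np.asarray(values.shape)
    if np.any(frac < 0) or np.any(frac > shape - 1):
        bad = int(np.nonzero(np.any((frac < 0) | (frac > shape - 1), axis=1))[0][0])
        raise GridBoundsError(f"point index {bad} at {pts[bad]} outside grid")
    i0 = np.minimum(frac.astype(np.int64), shape - 2)
    t = frac - i0
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]
    c000 = values[ix, iy, iz]
    c100 = values[ix + 1, iy, iz]
    c010 = values[ix, iy + 1, iz]
    c110 = values[ix + 1, iy + 1, iz]
    c001 = values[ix, iy, iz + 1]
    c101 = values[ix + 1, iy, iz + 1]
    c011 = values[ix, iy + 1, iz + 1]
    c111 = values[ix + 1, iy + 1, iz + 1]
    c00 = c000 * (1 - tx) + c100 * tx
    c10 = c010 * (1 - tx) + c110 * tx
    c01 = c001 * (1 - tx) + c101 * tx
    c11 = c011 * (1 - tx) + c111 * tx
    return (c00 * (1 - ty) + c10 * ty) * (1 - tz) + (c01 * (1 - ty) + c11 * ty) * tz


def grid_for_bilayer(bilayer, spacing: float = 1.0, lateral_margin: float = 10.0,
                     z_bottom: float | None = None, z_top: float = 120.0) -> GridSpec:
    """Grid spec covering the patch laterally (plus margin) and the
    diffusion volume vertically (default: just below the surface up to
    z_top above the midplane)."""
    lx, ly = bilayer.patch_dims
    z_up = bilayer.leaflet_z[0]
    if z_bottom is None:
        z_bottom = z_up - 2.0 * spacing
    hx = lx / 2.0 + lateral_margin
    hy = ly / 2.0 + lateral_margin
    nx = int(np.ceil(2 * hx / spacing)) + 1
    ny = int(np.ceil(2 * hy / spacing)) + 1
    nz = int(np.ceil((z_top - z_bottom) / spacing)) + 1
    return GridSpec((-hx, -hy, z_bottom), spacing, (nx, ny, nz))


def compute_potential_grid(bilayer, grid_spec: GridSpec,
                           kappa_inv: float | None = None,
                           eps_r: float = 78.5, temperature: float = 300.0,
                           ionic_strength: float = 0.1,
                           cap_radius: float = 2.0) -> PotentialGrid:
    """Screened-Coulomb superposition of all bilayer charges on a grid.

    ``kappa_inv=None`` computes the Debye length from ionic strength and
    temperature; ``numpy.inf`` switches screening off. Distances below
    ``cap_radius`` are clamped so grid nodes coincident with a source stay
    finite (no BD pose ever probes that close).
    """
    if kappa_inv is None:
        kappa_inv = debye_length(ionic_strength, temperature, eps_r)
    src_pos, src_q = bilayer.charged_sites()
    xs, ys, zs = grid_spec.axes()
    hi = grid_spec.upper_corner
    lo = np.asarray(grid_spec.origin, dtype=float)
    if len(src_q):
        lateral_ok = (np.all(src_pos[:, 0] >= lo[0]) and np.all(src_pos[:, 0] <= hi[0])
                      and np.all(src_pos[:, 1] >= lo[1]) and np.all(src_pos[:, 1] <= hi[1]))
        if not lateral_ok or np.any(src_pos[:, 2] > hi[2]):
            raise ValueError("grid does not cover the bilayer charge sites")

    coeff = constants.coulomb_kt(temperature) / eps_r
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    phi = np.zeros(grid_spec.shape, dtype=float)
    kap = 1.0 / kappa_inv if np.isfinite(kappa_inv) else 0.0
    for (sx, sy, sz), q in zip(src_pos, src_q):
        r = np.sqrt((X - sx) ** 2 + (Y - sy) ** 2 + (Z - sz) ** 2)
        np.maximum(r, cap_radius, out=r)
        if kap:
            phi += (coeff * q) * np.exp(-kap * r) / r
        else:
            phi += (coeff * q) / r
    return PotentialGrid(tuple(grid_spec.origin), grid_spec.spacing, phi,
                         kappa_inv=kappa_inv, temperature=temperature,
                         ionic_strength=ionic_strength)


def compute_desolvation_grid(bilayer, grid_spec: GridSpec,
                             alpha: float = 1.67,
                             kappa_inv: float | None = None,
                             eps_p: float = 4.0, eps_s: float = 78.5,
                             temperature: float = 300.0,
                             ionic_strength: float = 0.1,
                             element_spacing: float = 5.0,
                             cap_radius: float = 2.0) -> DesolvationGrid:
    """Desolvation penalty from the low-dielectric membrane slab.

    The slab between the leaflet planes is tiled with cubic volume elements
    of side ``element_spacing``; each contributes

        alpha * C(T) * (eps_s - eps_p)/(eps_s (2 eps_s + eps_p))
              * a^3 (1 + kappa r)^2 exp(-2 kappa r) / r^4

    to g(x) (kT/e^2), following the image-charge approximation used by
    rigid-body diffusional-association codes. alpha = 0 gives a zero grid.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if eps_s <= eps_p:
        raise ValueError("solvent dielectric must exceed interior dielectric")
    if kappa_inv is None:
        kappa_inv = debye_length(ionic_strength, temperature, eps_s)
    g = np.zeros(grid_spec.shape, dtype=float)
    if alpha == 0:
        return DesolvationGrid(tuple(grid_spec.origin), grid_spec.spacing, g)

    a = element_spacing
    lx, ly = bilayer.patch_dims
    z_up, z_lo = bilayer.leaflet_z
    exs = np.arange(-lx / 2 + a / 2, lx / 2, a)
    eys = np.arange(-ly / 2 + a / 2, ly / 2, a)
    ezs = np.arange(z_lo + a / 2, z_up, a)

    kap = 1.0 / kappa_inv if np.isfinite(kappa_inv) else 0.0
    pref = (alpha * constants.coulomb_kt(temperature)
            * (eps_s - eps_p) / (eps_s * (2 * eps_s + eps_p)) * a ** 3)
    xs, ys, zs = grid_spec.axes()
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    for ex in exs:
        dx2 = (X - ex) ** 2
        for ey in eys:
            dy2 = (Y - ey) ** 2
            for ez in ezs:
                r = np.sqrt(dx2 + dy2 + (Z - ez) ** 2)
                np.maximum(r, cap_radius, out=r)
                g += pref * (1.0 + kap * r) ** 2 * np.exp(-2.0 * kap * r) / r ** 4
    return DesolvationGrid(tuple(grid_spec.origin), grid_spec.spacing, g)


def interaction_energy(protein, pose, potential: PotentialGrid,
                       desolvation: DesolvationGrid | None = None) -> float:
    """Protein-bilayer free energy of interaction, in kT.

    U = sum_i q_i Phi(x_i) + sum_i q_i^2 g(x_i), with both fields evaluated
    by trilinear interpolation at the posed bead positions. ``pose`` is any
    object with ``position`` (lab-frame COM, Å) and ``orientation``
    (scalar-last quaternion) attributes, or a (position, quaternion) tuple.
    """
    if hasattr(pose, "position"):
        position, orientation = pose.position, pose.orientation
    else:
        position, orientation = pose
    coords = _quat.rotate(orientation, protein.bead_coords) + np.asarray(position)
    try:
        u = float(protein.bead_charges @ potential.interpolate(coords))
    except GridBoundsError as exc:
        raise GridBoundsError(f"protein bead outside potential grid: {exc}") from exc
    if desolvation is not None:
        u += float((protein.bead_charges ** 2) @ desolvation.interpolate(coords))
    return u
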