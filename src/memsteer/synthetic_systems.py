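"""Synthetic input generation: bilayer charge lattices and toy proteins.

Everything the pipeline needs can be generated here without external data:
a planar two-leaflet lattice of headgroup charge sites with a single target
site at the patch centre, decoy-charge schemes on the upper leaflet
(uniform fractional charges, random -1 e subsets, spatially clustered
subsets), and dipolar test proteins with prescribed net charge and dipole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .protein_model import ProteinModel

__all__ = [
    "LipidSite",
    "BilayerModel",
    "ChargeScheme",
    "build_patch",
    "assign_charges",
    "generate_clustered_configuration",
    "make_toy_protein",
    "equivalent_anionic_percent",
    "to_pqr_text",
    "from_pqr_text",
    "to_pdb_text",
]

UPPER = "upper"
LOWER = "lower"


@dataclass(frozen=True)
class LipidSite:
    """One headgroup charge site."""

    position: tuple          # (x, y, z) Å
    charge: float            # e
    leaflet: str             # 'upper' | 'lower'
    species: str             # 'zwitterionic' | 'anionic' | 'pip3'


@dataclass(frozen=True)
class ChargeScheme:
    """Decoy-charge assignment rule for the upper leaflet.

    kind:
      zwitterionic   no decoy charge (target site only)
      fractional     every non-target upper site gets ``fractional_charge``
      random_subset  round(f * N) upper sites get -1.0 e, seeded uniform draw
      clustered      as random_subset but selection grows around seeds,
                     biased by ``cluster_strength``
      explicit       charges supplied externally (read back from file)
    """

    kind: str
    fractional_charge: float = 0.0
    anionic_fraction: float = 0.0
    cluster_strength: float = 0.0
    seed: int = 0

    def validate(self):
        kinds = ("zwitterionic", "fractional", "random_subset", "clustered",
                 "explicit")
        if self.kind not in kinds:
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "fractional" and not (-1.0 <= self.fractional_charge <= 0.0):
            raise ValueError("fractional_charge must lie in [-1.0, 0.0] e")
        if self.kind in ("random_subset", "clustered"):
            if not (0.0 <= self.anionic_fraction <= 1.0):
                raise ValueError("anionic_fraction must lie in [0, 1]")
        if self.cluster_strength < 0:
            raise ValueError("cluster_strength must be >= 0")


@dataclass
class BilayerModel:
    """Planar two-leaflet charge lattice with one central target site."""

    sites: list
    patch_dims: tuple        # (Lx, Ly) Å
    leaflet_z: tuple         # (z_upper, z_lower) Å
    area_per_lipid: float
    scheme: ChargeScheme = field(
        default_factory=lambda: ChargeScheme("zwitterionic"))

    @property
    def pip3_site(self) -> LipidSite:
        """The target site; for a multi-sub-site target, a virtual site at
        the charge-weighted centroid carrying the total target charge."""
        targets = [s for s in self.sites if s.species == "pip3"]
        if not targets:
            raise ValueError("bilayer has no target (pip3) site")
        if len(targets) == 1:
            return targets[0]
        q = sum(s.charge for s in targets)
        w = np.array([s.charge for s in targets])
        pos = (w / w.sum()) @ np.array([s.position for s in targets])
        return LipidSite(tuple(pos), q, UPPER, "pip3")

    @property
    def upper_sites(self):
        return [s for s in self.sites if s.leaflet == UPPER]

    @property
    def lower_sites(self):
        return [s for s in self.sites if s.leaflet == LOWER]

    @property
    def decoy_sites(self):
        return [s for s in self.sites if s.leaflet == UPPER and s.species != "pip3"]

    @property
    def total_charge(self) -> float:
        return float(sum(s.charge for s in self.sites))

    @property
    def decoy_charge(self) -> float:
        return float(sum(s.charge for s in self.decoy_sites))

    @property
    def lattice_pitch(self) -> float:
        return math.sqrt(self.area_per_lipid)

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([s.charge for s in self.sites], dtype=float)

    def charged_sites(self):
        """(positions, charges) of sites with nonzero charge."""
        mask = [s for s in self.sites if s.charge != 0.0]
        pos = np.array([s.position for s in mask], dtype=float)
        q = np.array([s.charge for s in mask], dtype=float)
        return pos.reshape(-1, 3), q


def build_patch(patch_dims=(220.0, 220.0), area_per_lipid: float = 62.0,
                leaflet_separation: float = 40.0,
                pip3_charge: float = -7.0,
                pip3_subsites: int = 1,
                subsite_offset: float | None = None) -> BilayerModel:
    """Build a fresh zwitterionic patch with a central target charge.

    Each leaflet carries ``floor(Lx*Ly / area_per_lipid)`` sites on a square
    lattice (row-major fill of a ceil(sqrt(N))-sided grid, centred on the
    origin). The upper-leaflet site closest to the lateral centre is replaced
    by the target (pip3) site carrying ``pip3_charge``; every other site is
    neutral. The bilayer midplane is z = 0, leaflets at +-separation/2.

    ``pip3_subsites=4`` spreads the target charge over four sub-sites of
    ``pip3_charge/4`` placed diagonally at ``+-subsite_offset`` (default a
    half lattice pitch) around the central position, a coarse stand-in for
    the spatial extent of a phosphoinositide headgroup; ``pip3_site`` then
    reports the virtual centroid site.
    """
    lx, ly = float(patch_dims[0]), float(patch_dims[1])
    if lx <= 0 or ly <= 0 or area_per_lipid <= 0 or leaflet_separation <= 0:
        raise ValueError("patch dimensions, area per lipid and separation must be positive")
    if pip3_subsites not in (1, 4):
        raise ValueError("pip3_subsites must be 1 or 4")
    n_sites = int(lx * ly // area_per_lipid)
    if n_sites < 1:
        raise ValueError("lattice too small to host the target site")

    n_side = math.ceil(math.sqrt(n_sites))
    dx, dy = lx / n_side, ly / n_side
    xy = []
    for i in range(n_side):
        for j in range(n_side):
            if len(xy) == n_sites:
                break
            xy.append(((i + 0.5) * dx - lx / 2.0, (j + 0.5) * dy - ly / 2.0))
    xy = np.array(xy)

    z_up = leaflet_separation / 2.0
    z_lo = -z_up
    central = int(np.argmin(np.einsum("ij,ij->i", xy, xy)))

    sites = []
    for k, (x, y) in enumerate(xy):
        if k != central:
            sites.append(LipidSite((x, y, z_up), 0.0, UPPER, "zwitterionic"))
    cx, cy = xy[central]
    if pip3_subsites == 1:
        sites.append(LipidSite((cx, cy, z_up), pip3_charge, UPPER, "pip3"))
    else:
        off = subsite_offset if subsite_offset is not None else math.sqrt(area_per_lipid) / 2.0
        for sx, sy in ((off, off), (off, -off), (-off, off), (-off, -off)):
            sites.append(LipidSite((cx + sx, cy + sy, z_up),
                                   pip3_charge / 4.0, UPPER, "pip3"))
    for x, y in xy:
        sites.append(LipidSite((x, y, z_lo), 0.0, LOWER, "zwitterionic"))

    return BilayerModel(sites, (lx, ly), (z_up, z_lo), area_per_lipid)


def _reset_decoys(model: BilayerModel) -> list:
    """Fresh site list with all decoy charges zeroed, target untouched."""
    out = []
    for s in model.sites:
        if s.species == "pip3":
            out.append(s)
        else:
            out.append(LipidSite(s.position, 0.0, s.leaflet, "zwitterionic"))
    return out


def assign_charges(model: BilayerModel, scheme: ChargeScheme) -> BilayerModel:
    """Apply a decoy-charge scheme to the upper leaflet (target untouched).

    The lower leaflet is always neutral; repeated application is idempotent
    because charges are reassigned from a clean slate each time.
    """
    scheme.validate()
    if scheme.kind == "clustered":
        return generate_clustered_configuration(
            model, scheme.anionic_fraction, scheme.cluster_strength, scheme.seed)
    sites = _reset_decoys(model)
    decoy_idx = [i for i, s in enumerate(sites)
                 if s.leaflet == UPPER and s.species != "pip3"]

    if scheme.kind in ("zwitterionic", "explicit"):
        pass
    elif scheme.kind == "fractional":
        q = scheme.fractional_charge
        for i in decoy_idx:
            s = sites[i]
            sp = "anionic" if q < 0 else "zwitterionic"
            sites[i] = LipidSite(s.position, q, s.leaflet, sp)
    elif scheme.kind == "random_subset":
        n_sel = int(round(scheme.anionic_fraction * len(decoy_idx)))
        rng = np.random.default_rng(scheme.seed)
        chosen = rng.choice(len(decoy_idx), size=n_sel, replace=False)
        for c in chosen:
            i = decoy_idx[c]
            s = sites[i]
            sites[i] = LipidSite(s.position, -1.0, s.leaflet, "anionic")
    return replace(model, sites=sites, scheme=scheme)


def generate_clustered_configuration(model: BilayerModel,
                                     anionic_fraction: float,
                                     cluster_strength: float,
                                     seed: int) -> BilayerModel:
    """Seeded neighbour-preferential growth of an anionic subset.

    Exactly ``round(f * N)`` decoy sites receive -1.0 e. Sites are picked
    one at a time with weight ``1 + cluster_strength * k`` where k is the
    number of already-selected lattice neighbours (within 1.5 lattice
    pitches), so ``cluster_strength = 0`` reduces to uniform selection
    without replacement and large values produce spatial aggregation.
    """
    if not (0.0 <= anionic_fraction <= 1.0):
        raise ValueError("anionic_fraction must lie in [0, 1]")
    if cluster_strength < 0:
        raise ValueError("cluster_strength must be >= 0")

    sites = _reset_decoys(model)
    decoy_idx = [i for i, s in enumerate(sites)
                 if s.leaflet == UPPER and s.species != "pip3"]
    n = len(decoy_idx)
    n_sel = int(round(anionic_fraction * n))
    rng = np.random.default_rng(seed)

    if n_sel > 0:
        from scipy.spatial import cKDTree

        pos = np.array([sites[i].position for i in decoy_idx])[:, :2]
        tree = cKDTree(pos)
        cutoff = 1.5 * model.lattice_pitch
        neighbours = tree.query_ball_point(pos, cutoff)

        selected = np.zeros(n, dtype=bool)
        n_sel_nb = np.zeros(n)  # selected-neighbour counts
        for _ in range(n_sel):
            weights = np.where(selected, 0.0, 1.0 + cluster_strength * n_sel_nb)
            weights /= weights.sum()
            pick = rng.choice(n, p=weights)
            selected[pick] = True
            for nb in neighbours[pick]:
                if nb != pick:
                    n_sel_nb[nb] += 1

        for local in np.nonzero(selected)[0]:
            i = decoy_idx[local]
            s = sites[i]
            sites[i] = LipidSite(s.position, -1.0, s.leaflet, "anionic")

    scheme = ChargeScheme("clustered", anionic_fraction=anionic_fraction,
                          cluster_strength=cluster_strength, seed=seed)
    return replace(model, sites=sites, scheme=scheme)


def equivalent_anionic_percent(fractional_charge: float,
                               anionic_valence: float = -1.0,
                               n_leaflets: int = 2) -> float:
    """Overall anionic-lipid percentage equivalent to a uniform fractional
    charge on one leaflet, assuming monovalent anionic lipids and equal
    lipid counts per leaflet.

    E.g. -0.2 e per upper-leaflet lipid == 20% anionic in that leaflet
    == 10% of the whole bilayer.
    """
    if fractional_charge > 0:
        raise ValueError("fractional_charge must be <= 0")
    frac_in_leaflet = fractional_charge / anionic_valence
    return 100.0 * frac_in_leaflet / n_leaflets


def make_toy_protein(n_beads: int = 8, radius: float = 12.0,
                     net_charge: float = 8.0, dipole_moment: float = 20.0,
                     seed: int = 0, axis=(0.0, 0.0, 1.0),
                     **model_kwargs) -> ProteinModel:
    """Random spherical bead protein with exact net charge and dipole.

    Beads are scattered inside a sphere (seeded), recentred so the centre of
    mass (equal bead masses) is at the origin; charges are then the
    minimum-norm solution matching the requested net charge and dipole
    vector ``dipole_moment * axis`` (e·Å). The binding-face reference vector
    is set along the dipole axis.
    """
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    if radius <= 0:
        raise ValueError("radius must be positive")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    target_p = dipole_moment * axis

    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n_beads:
        p = rng.uniform(-1.0, 1.0, size=3)
        if p @ p <= 1.0:
            pts.append(p)
    coords = np.array(pts) * radius * 0.9
    coords -= coords.mean(axis=0)
    # keep beads inside the nominal radius after recentring
    rmax = np.linalg.norm(coords, axis=1).max()
    if rmax > radius:
        coords *= radius / rmax

    # constraints: sum q = Q ; sum q r = p  -> min-norm least squares
    A = np.vstack([np.ones(n_beads), coords.T])          # (4, n)
    b = np.concatenate([[net_charge], target_p])
    q, *_ = np.linalg.lstsq(A, b, rcond=None)
    if not np.allclose(A @ q, b, atol=1e-8):
        raise ValueError(
            "infeasible net charge / dipole combination for this bead geometry")

    if abs(dipole_moment) > 1e-12:
        ref = axis * np.sign(dipole_moment)
    else:
        ref = np.array([0.0, 0.0, 1.0])
    return ProteinModel(coords, q, [f"BEAD{i}" for i in range(n_beads)],
                        ref_vector=ref, hydrodynamic_radius=radius,
                        **model_kwargs)


# ---------------------------------------------------------------------------
# text IO

def to_pqr_text(model: BilayerModel) -> str:
    """PQR-like dump: header metadata plus ``x y z q species leaflet`` rows."""
    lines = [
        "# memsteer bilayer sites",
        f"# patch_dims {model.patch_dims[0]:.6f} {model.patch_dims[1]:.6f}",
        f"# leaflet_z {model.leaflet_z[0]:.6f} {model.leaflet_z[1]:.6f}",
        f"# area_per_lipid {model.area_per_lipid:.6f}",
        "# x y z q species leaflet",
    ]
    for s in model.sites:
        x, y, z = s.position
        lines.append(f"{x:.6f} {y:.6f} {z:.6f} {s.charge:.6f} {s.species} {s.leaflet}")
    return "\n".join(lines) + "\n"


def from_pqr_text(text: str) -> BilayerModel:
    """Read a bilayer written by :func:`to_pqr_text` (scheme = explicit)."""
    meta = {}
    sites = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] in ("patch_dims", "leaflet_z", "area_per_lipid"):
                meta[parts[0]] = [float(v) for v in parts[1:]]
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ValueError(f"line {lineno}: expected 'x y z q species leaflet'")
        x, y, z, q = (float(v) for v in parts[:4])
        sites.append(LipidSite((x, y, z), q, parts[5], parts[4]))
    if not sites:
        raise ValueError("no sites in bilayer file")
    if "patch_dims" not in meta or "leaflet_z" not in meta:
        raise ValueError("missing patch_dims/leaflet_z header metadata")
    return BilayerModel(sites, tuple(meta["patch_dims"]),
                        tuple(meta["leaflet_z"]),
                        meta.get("area_per_lipid", [62.0])[0],
                        scheme=ChargeScheme("explicit"))


def to_pdb_text(model: BilayerModel) -> str:
    """Minimal PDB rendering of the charge sites, for visualisation only."""
    lines = []
    for i, s in enumerate(model.sites, 1):
        name = {"pip3": "P3", "anionic": "N", "zwitterionic": "N"}[s.species]
        resname = {"pip3": "PIP", "anionic": "ANI", "zwitterionic": "POP"}[s.species]
        chain = "U" if s.leaflet == UPPER else "L"
        x, y, z = s.position
        lines.append(
            f"HETATM{i % 100000:5d} {name:<4s}{resname:<4s}{chain}{i % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{s.charge:6.2f}")
    lines.append("END")
    return "\n".join(lines) + "\n"
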