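"""Rigid-body protein representation.

A protein is reduced to a set of charge-carrying beads in a body-fixed frame
with its centre of mass at the origin, plus scalar translational/rotational
diffusion constants and a body-fixed reference vector pointing from the
centre of mass toward the binding face. Structures are loaded from PDB text
with formal charges placed on ionisable groups, or from PQR-like text with
explicit per-site charges.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants

__all__ = [
    "ProteinModel",
    "load_structure",
    "load_pqr",
    "to_pqr_text",
    "compute_dipole",
    "stokes_einstein",
    "diffusion_time",
    "mutate_charge",
    "ligand_com_distance",
]

# formal-charge rules: residue -> (charge, atoms defining the charge centroid)
_FORMAL_RULES = {
    "ASP": (-1.0, ("OD1", "OD2", "CG")),
    "GLU": (-1.0, ("OE1", "OE2", "CD")),
    "LYS": (+1.0, ("NZ",)),
    "ARG": (+1.0, ("NH1", "NH2", "CZ")),
}

_ONE_LETTER = {"ASP": "D", "GLU": "E", "LYS": "K", "ARG": "R", "HIS": "H"}


@dataclass
class ProteinModel:
    """Rigid body: bead coordinates (body frame, COM at origin) and charges.

    Attributes
    ----------
    bead_coords : (n, 3) float array, Å
    bead_charges : (n,) float array, e
    residue_labels : list of str, one per bead
    ref_vector : (3,) unit vector, body frame (COM -> binding face)
    D_trans : translational diffusion constant, cm^2 s^-1
    D_rot : rotational diffusion constant, rad^2 s^-1
    hydrodynamic_radius : Å
    """

    bead_coords: np.ndarray
    bead_charges: np.ndarray
    residue_labels: list
    ref_vector: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    D_trans: float = constants.D_TRANS_DEFAULT
    D_rot: float = constants.D_ROT_DEFAULT
    hydrodynamic_radius: float = 20.9

    def __post_init__(self):
        self.bead_coords = np.atleast_2d(np.asarray(self.bead_coords, dtype=float))
        self.bead_charges = np.asarray(self.bead_charges, dtype=float)
        if self.bead_coords.shape[0] != self.bead_charges.shape[0]:
            raise ValueError("bead_coords and bead_charges length mismatch")
        n = np.linalg.norm(self.ref_vector)
        if n > 0:
            self.ref_vector = np.asarray(self.ref_vector, dtype=float) / n
        if self.D_trans <= 0 or self.D_rot <= 0:
            raise ValueError("diffusion constants must be positive")

    @property
    def n_beads(self) -> int:
        return self.bead_coords.shape[0]

    @property
    def net_charge(self) -> float:
        return float(self.bead_charges.sum())

    @property
    def dipole(self) -> np.ndarray:
        """Dipole moment about the centre of mass, e·Å (body frame)."""
        return self.bead_charges @ self.bead_coords

    def __eq__(self, other):
        if not isinstance(other, ProteinModel):
            return NotImplemented
        return (
            np.array_equal(self.bead_coords, other.bead_coords)
            and np.array_equal(self.bead_charges, other.bead_charges)
            and self.residue_labels == other.residue_labels
            and np.allclose(self.ref_vector, other.ref_vector)
        )


class PDBParseError(ValueError):
    pass


def _parse_structure(pdb_text: str):
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("model", io.StringIO(pdb_text))
    except Exception as exc:  # Biopython raises assorted exceptions
        raise PDBParseError(f"failed to parse PDB records: {exc}") from exc
    return structure


def _mass_weighted_com(atoms) -> np.ndarray:
    coords = np.array([a.coord for a in atoms], dtype=float)
    masses = np.array([a.mass if a.mass == a.mass else 12.0 for a in atoms])
    return masses @ coords / masses.sum()


def load_structure(pdb_text: str, charge_rule: str = "formal",
                   binding_site_residues=("LYS279", "ARG284"),
                   D_trans: float = constants.D_TRANS_DEFAULT,
                   D_rot: float = constants.D_ROT_DEFAULT,
                   hydrodynamic_radius: float = 20.9) -> ProteinModel:
    """Build a rigid-body model from PDB text.

    ``charge_rule='formal'`` places -1 e on Asp/Glu carboxylates, +1 e on
    Lys/Arg amine/guanidinium centroids, 0 on His, and +-1 on the chain
    termini. Coordinates are recentred on the mass-weighted centre of mass
    of all protein atoms (hydrogens absent from X-ray files are simply not
    counted).

    The reference vector points from the COM to the centroid of
    ``binding_site_residues`` (matched as RESNAME+RESSEQ, e.g. ``LYS279``);
    if none are present it falls back to the dipole direction.
    """
    if charge_rule not in ("formal", "file"):
        raise ValueError(f"unknown charge_rule {charge_rule!r}")
    if charge_rule == "file":
        raise ValueError("charge_rule='file' expects PQR input; use load_pqr()")

    structure = _parse_structure(pdb_text)
    from Bio.PDB.Polypeptide import is_aa

    chains = {}
    for chain in structure.get_chains():
        residues = [r for r in chain if is_aa(r, standard=True)]
        if residues:
            chains[chain.id] = residues
    if not chains:
        raise PDBParseError("no protein residues found in PDB input")

    protein_atoms = [a for residues in chains.values() for r in residues
                     for a in r if a.element != "H"]
    com = _mass_weighted_com(protein_atoms)

    coords, charges, labels = [], [], []

    def add_site(pos, q, label):
        coords.append(np.asarray(pos, dtype=float) - com)
        charges.append(q)
        labels.append(label)

    for chain_id, residues in chains.items():
        for i, res in enumerate(residues):
            resname = res.get_resname()
            resseq = res.id[1]
            label = f"{resname}{resseq}"
            if resname in _FORMAL_RULES:
                q, atom_names = _FORMAL_RULES[resname]
                pts = [res[a].coord for a in atom_names if a in res]
                if pts:
                    add_site(np.mean(pts, axis=0), q, label)
            # termini
            if i == 0 and "N" in res:
                add_site(res["N"].coord, +1.0, f"{label}:NTER")
            if i == len(residues) - 1:
                pts = [res[a].coord for a in ("C", "O", "OXT") if a in res]
                if pts:
                    add_site(np.mean(pts, axis=0), -1.0, f"{label}:CTER")

    model = ProteinModel(np.array(coords), np.array(charges), labels,
                         D_trans=D_trans, D_rot=D_rot,
                         hydrodynamic_radius=hydrodynamic_radius)

    # reference vector: COM -> binding-pocket centroid
    pocket = []
    wanted = set(binding_site_residues or ())
    for residues in chains.values():
        for res in residues:
            if f"{res.get_resname()}{res.id[1]}" in wanted:
                pocket.append(_mass_weighted_com([a for a in res if a.element != "H"]) - com)
    if pocket:
        model.ref_vector = np.mean(pocket, axis=0)
        model.ref_vector /= np.linalg.norm(model.ref_vector)
    elif np.linalg.norm(model.dipole) > 0:
        model.ref_vector = model.dipole / np.linalg.norm(model.dipole)
    return model


def load_pqr(pqr_text: str, **kwargs) -> ProteinModel:
    """Read a PQR-like charge file: ``x y z q [label]`` per line.

    Lines beginning with ``#`` are comments. Coordinates are recentred on the
    (equal-mass) centroid of the sites.
    """
    coords, charges, labels = [], [], []
    for lineno, line in enumerate(pqr_text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise PDBParseError(f"line {lineno}: expected 'x y z q [label]'")
        try:
            x, y, z, q = (float(v) for v in parts[:4])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: {exc}") from exc
        coords.append((x, y, z))
        charges.append(q)
        labels.append(parts[4] if len(parts) > 4 else f"SITE{lineno}")
    if not coords:
        raise PDBParseError("no charge sites in PQR input")
    coords = np.asarray(coords, dtype=float)
    coords -= coords.mean(axis=0)
    return ProteinModel(coords, np.asarray(charges), labels, **kwargs)


def to_pqr_text(model: ProteinModel) -> str:
    lines = ["# memsteer protein sites: x y z q label"]
    for pos, q, label in zip(model.bead_coords, model.bead_charges,
                             model.residue_labels):
        lines.append(f"{pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f} {q:.6f} {label}")
    return "\n".join(lines) + "\n"


def compute_dipole(model: ProteinModel, lab_axis=(0.0, 0.0, 1.0),
                   orientation=None):
    """Dipole vector (e·Å), magnitude (Debye) and angle to a lab axis (deg).

    ``orientation`` is an optional scalar-last quaternion giving the lab-frame
    pose; the angle is measured between the rotated dipole and ``lab_axis``.
    A zero dipole has an undefined angle, reported as NaN with a warning.
    """
    from . import _quat

    p = model.dipole
    magnitude_debye = float(np.linalg.norm(p)) * constants.DEBYE_PER_E_ANGSTROM
    p_lab = _quat.rotate(orientation, p) if orientation is not None else p
    norm = np.linalg.norm(p_lab)
    axis = np.asarray(lab_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if norm < 1e-12:
        warnings.warn("zero dipole moment: angle to axis is undefined")
        angle = float("nan")
    else:
        angle = float(np.degrees(np.arccos(np.clip(p_lab @ axis / norm, -1, 1))))
    return p, magnitude_debye, angle


def stokes_einstein(radius: float, temperature: float = 300.0,
                    viscosity: float = 1.0e-3):
    """Stokes-Einstein diffusion constants for a sphere.

    Returns ``(D_trans, D_rot)`` in cm^2 s^-1 and rad^2 s^-1:
    D = k_BT / (6 pi eta a), D_rot = k_BT / (8 pi eta a^3).
    """
    if radius <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("radius, temperature and viscosity must be positive")
    a = radius * 1e-10  # m
    kt = constants.KB_SI * temperature
    d_trans = kt / (6.0 * np.pi * viscosity * a) * 1e4  # m^2/s -> cm^2/s
    d_rot = kt / (8.0 * np.pi * viscosity * a ** 3)
    return d_trans, d_rot


def diffusion_time(L: float, D: float, dimensionality: int = 3) -> float:
    """Characteristic time, in ns, for a diffusional displacement L (Å).

    t = L^2 / (2 n D) with n the dimensionality, D in cm^2 s^-1.
    """
    if dimensionality not in (2, 3):
        raise ValueError("dimensionality must be 2 or 3")
    if L < 0 or D <= 0:
        raise ValueError("L must be >= 0 and D > 0")
    L_cm = L * 1e-8
    t_s = L_cm ** 2 / (2.0 * dimensionality * D)
    return t_s * 1e9


def mutate_charge(model: ProteinModel, residue_label: str,
                  new_charge: float) -> ProteinModel:
    """Return a copy with one residue's charge site altered.

    Geometry is untouched (no COM recentring) so the mutant remains the same
    rigid body; only the charge at the named site changes.
    """
    try:
        idx = model.residue_labels.index(residue_label)
    except ValueError:
        raise KeyError(f"unknown residue label {residue_label!r}") from None
    charges = model.bead_charges.copy()
    charges[idx] = new_charge
    return replace(model, bead_coords=model.bead_coords.copy(),
                   bead_charges=charges,
                   residue_labels=list(model.residue_labels))


def ligand_com_distance(pdb_text: str, ligand_resnames) -> float:
    """Mass-weighted COM separation (Å) of protein atoms vs a het ligand."""
    structure = _parse_structure(pdb_text)
    from Bio.PDB.Polypeptide import is_aa

    ligand_resnames = set(ligand_resnames)
    protein_atoms, ligand_atoms = [], []
    for res in structure.get_residues():
        atoms = [a for a in res if a.element != "H"]
        if is_aa(res, standard=True):
            protein_atoms.extend(atoms)
        elif res.get_resname().strip() in ligand_resnames:
            ligand_atoms.extend(atoms)
    if not protein_atoms:
        raise PDBParseError("no protein atoms found")
    if not ligand_atoms:
        raise PDBParseError(f"no ligand atoms with resname in {sorted(ligand_resnames)}")
    return float(np.linalg.norm(_mass_weighted_com(protein_atoms)
                                - _mass_weighted_com(ligand_atoms)))
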