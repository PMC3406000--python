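"""Steering statistics: Jacobian-reweighted histograms and pose analysis.

Positions sampled in plane polar coordinates over-represent large radii by
the 2*pi*r area factor, and orientations over-represent theta ~ 90 deg by
the sin(theta) factor; densities here divide those Jacobians back out at
the bin centres and renormalise to unit integral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _quat

__all__ = [
    "SteeringCoordinates",
    "SteeringHistogram",
    "compute_coordinates",
    "radial_histogram",
    "reweight_radial",
    "angular_histogram",
    "reweight_angular",
    "fit_hwhm",
    "histogram2d_r_theta",
    "first_encounter_distribution",
    "select_optimal_pose",
    "fingerprint_contacts",
    "fingerprint_from_pdb",
    "average_densities",
]

HWHM_FACTOR = np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class SteeringCoordinates:
    r: float        # in-plane distance, COM -> target site, Å
    d: float        # height of COM above the target plane, Å
    theta: float    # angle of lab-frame ref vector to the downward normal, deg


@dataclass
class SteeringHistogram:
    """Binned, Jacobian-reweighted density.

    For 1D variables ``bin_edges`` is an array and ``density`` integrates to
    one over the bin widths; for 'r_theta' both are pairs/2D arrays.
    """

    bin_edges: object
    raw_counts: np.ndarray
    density: np.ndarray
    variable: str   # 'r' | 'd' | 'theta' | 'r_theta'

    @property
    def bin_centres(self):
        if self.variable == "r_theta":
            er, et = self.bin_edges
            return 0.5 * (er[1:] + er[:-1]), 0.5 * (et[1:] + et[:-1])
        e = self.bin_edges
        return 0.5 * (e[1:] + e[:-1])

    def integral(self) -> float:
        if self.variable == "r_theta":
            er, et = self.bin_edges
            return float(np.sum(self.density * np.outer(np.diff(er), np.diff(et))))
        return float(np.sum(self.density * np.diff(self.bin_edges)))


def compute_coordinates(state, protein, bilayer) -> SteeringCoordinates:
    """Map a rigid-body pose to the (r, d, theta) steering coordinates.

    theta is measured between the body reference vector expressed in the lab
    frame and the *downward* bilayer normal, so theta = 0 corresponds to the
    binding face pointing at the membrane.
    """
    pip3 = np.asarray(bilayer.pip3_site.position, dtype=float)
    pos = np.asarray(state.position, dtype=float)
    r = float(np.hypot(pos[0] - pip3[0], pos[1] - pip3[1]))
    d = float(pos[2] - pip3[2])
    ref_lab = _quat.rotate(state.orientation, protein.ref_vector)
    cos_t = np.clip(-ref_lab[2], -1.0, 1.0)
    return SteeringCoordinates(r, d, float(np.degrees(np.arccos(cos_t))))


def _edges(values, bin_width, vmax=None, vmin=0.0):
    if vmax is None:
        vmax = float(np.max(values)) + bin_width
    n = max(int(np.ceil((vmax - vmin) / bin_width)), 1)
    return vmin + bin_width * np.arange(n + 1)


def reweight_radial(counts, bin_edges) -> SteeringHistogram:
    """Divide out the 2*pi*r Jacobian at bin centres and renormalise."""
    counts = np.asarray(counts, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(counts < 0):
        raise ValueError("histogram counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("cannot reweight an empty histogram")
    centres = 0.5 * (bin_edges[1:] + bin_edges[:-1])
    if np.any(centres <= 0):
        raise ValueError("radial bins must have positive bin centres")
    density = counts / (2.0 * np.pi * centres)
    density /= np.sum(density * np.diff(bin_edges))
    return SteeringHistogram(bin_edges, counts, density, "r")


def radial_histogram(r_values, bin_width: float = 2.0,
                     r_max: float | None = None) -> SteeringHistogram:
    """Histogram radial samples and reweight by the polar Jacobian."""
    r_values = np.asarray(r_values, dtype=float)
    edges = _edges(r_values, bin_width, r_max)
    counts, _ = np.histogram(r_values, bins=edges)
    return reweight_radial(counts, edges)


def reweight_angular(counts, bin_edges) -> SteeringHistogram:
    """Divide out the sin(theta) Jacobian at bin centres and renormalise.

    Bins must lie within [0, 180] degrees; the polar bins use the sine of
    the bin centre, which is strictly positive for any bin of nonzero width.
    """
    counts = np.asarray(counts, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges[0] < -1e-9 or bin_edges[-1] > 180.0 + 1e-9:
        raise ValueError("theta bins must lie within [0, 180] degrees")
    if counts.sum() == 0:
        raise ValueError("cannot reweight an empty histogram")
    centres = 0.5 * (bin_edges[1:] + bin_edges[:-1])
    density = counts / np.sin(np.radians(centres))
    density /= np.sum(density * np.diff(bin_edges))
    return SteeringHistogram(bin_edges, counts, density, "theta")


def angular_histogram(theta_values, bin_width: float = 2.0) -> SteeringHistogram:
    theta_values = np.asarray(theta_values, dtype=float)
    n = int(np.ceil(180.0 / bin_width))
    edges = bin_width * np.arange(n + 1)
    counts, _ = np.histogram(theta_values, bins=edges)
    return reweight_angular(counts, edges)


def fit_hwhm(radial_hist: SteeringHistogram) -> float:
    """HWHM (Å) of a single Gaussian centred at r = 0 fitted to the density.

    Least-squares fit of A exp(-r^2 / 2 sigma^2) with the centre pinned at
    zero; HWHM = sigma * sqrt(2 ln 2).
    """
    from scipy.optimize import curve_fit

    centres = radial_hist.bin_centres
    density = radial_hist.density
    if np.count_nonzero(density) < 3:
        raise ValueError("need at least 3 nonzero bins for a Gaussian fit")

    def gauss(r, amp, sigma):
        return amp * np.exp(-r ** 2 / (2.0 * sigma ** 2))

    amp0 = float(density.max())
    sigma0 = max(float(np.sqrt(np.sum(density * centres ** 2) / np.sum(density)) / 2), 1e-3)
    try:
        popt, _ = curve_fit(gauss, centres, density, p0=(amp0, sigma0),
                            maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Gaussian HWHM fit did not converge (p0 amp={amp0:.3g}, "
            f"sigma={sigma0:.3g}): {exc}") from exc
    return float(abs(popt[1]) * HWHM_FACTOR)


def histogram2d_r_theta(r_values, theta_values, r_bin_width: float = 2.0,
                        theta_bin_width: float = 2.0,
                        r_max: float | None = None) -> SteeringHistogram:
    """Joint (r, theta) density reweighted by both Jacobian factors."""
    r_values = np.asarray(r_values, dtype=float)
    theta_values = np.asarray(theta_values, dtype=float)
    r_edges = _edges(r_values, r_bin_width, r_max)
    nt = int(np.ceil(180.0 / theta_bin_width))
    t_edges = theta_bin_width * np.arange(nt + 1)
    counts, _, _ = np.histogram2d(r_values, theta_values, bins=(r_edges, t_edges))
    if counts.sum() == 0:
        raise ValueError("cannot reweight an empty histogram")
    r_c = 0.5 * (r_edges[1:] + r_edges[:-1])
    t_c = 0.5 * (t_edges[1:] + t_edges[:-1])
    weight = np.outer(2.0 * np.pi * r_c, np.sin(np.radians(t_c)))
    density = counts / weight
    density /= np.sum(density * np.outer(np.diff(r_edges), np.diff(t_edges)))
    return SteeringHistogram((r_edges, t_edges), counts, density, "r_theta")


def first_encounter_distribution(ensemble, bin_width: float = 2.0,
                                 r_max: float | None = None) -> SteeringHistogram:
    """Radial-reweighted histogram of first-encounter r values."""
    if len(ensemble.first_encounters) == 0:
        raise ValueError("no encounters in ensemble")
    return radial_histogram(ensemble.first_encounters[:, 0], bin_width, r_max)


def select_optimal_pose(ensemble, r_max: float, d_max: float,
                        theta_max: float) -> pd.DataFrame:
    """All recorded samples with r <= r_max, d <= d_max, theta <= theta_max.

    Sorted by r^2 + d^2 ascending, ties broken on theta. Returns an empty
    frame if nothing qualifies.
    """
    if r_max < 0 or d_max < 0 or theta_max < 0:
        raise ValueError("thresholds must be non-negative")
    df = pd.DataFrame({
        "trajectory": ensemble.sample_traj,
        "time_ps": ensemble.sample_time,
        "r": ensemble.sample_r,
        "d": ensemble.sample_d,
        "theta": ensemble.sample_theta,
    })
    sel = df[(df.r <= r_max) & (df.d <= d_max) & (df.theta <= theta_max)].copy()
    sel["score"] = sel.r ** 2 + sel.d ** 2
    return sel.sort_values(["score", "theta"], kind="mergesort").reset_index(drop=True)


def fingerprint_contacts(residue_atoms: dict, phosphorus_atoms: dict) -> pd.DataFrame:
    """Minimum-distance matrix between residues and phosphorus sites.

    ``residue_atoms`` maps residue label -> (n, 3) atom coordinates;
    ``phosphorus_atoms`` maps phosphorus label (e.g. P1, P3, P4, P5) ->
    (3,) coordinate. Entry (i, j) is the minimum distance (Å) from any atom
    of residue i to phosphorus j.
    """
    if not residue_atoms or not phosphorus_atoms:
        raise ValueError("need at least one residue and one phosphorus atom")
    p_labels = list(phosphorus_atoms)
    p_coords = np.array([phosphorus_atoms[k] for k in p_labels], dtype=float)
    rows = {}
    for label, atoms in residue_atoms.items():
        atoms = np.atleast_2d(np.asarray(atoms, dtype=float))
        dists = np.linalg.norm(atoms[:, None, :] - p_coords[None, :, :], axis=2)
        rows[label] = dists.min(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=p_labels)


def fingerprint_from_pdb(pdb_text: str, ligand_resname: str) -> pd.DataFrame:
    """Residue vs ligand-phosphorus fingerprint straight from PDB text."""
    from .protein_model import _parse_structure
    from Bio.PDB.Polypeptide import is_aa

    structure = _parse_structure(pdb_text)
    residue_atoms, phosphorus = {}, {}
    for res in structure.get_residues():
        name = res.get_resname().strip()
        if is_aa(res, standard=True):
            label = f"{name}{res.id[1]}"
            residue_atoms[label] = np.array([a.coord for a in res])
        elif name == ligand_resname:
            for atom in res:
                if atom.element == "P":
                    phosphorus[atom.get_name()] = np.asarray(atom.coord, dtype=float)
    if not phosphorus:
        raise ValueError(f"ligand {ligand_resname!r} has no phosphorus atoms")
    return fingerprint_contacts(residue_atoms, phosphorus)


def average_densities(histograms) -> SteeringHistogram:
    """Unweighted mean of reweighted densities over equal-binning histograms."""
    histograms = list(histograms)
    if not histograms:
        raise ValueError("no histograms to average")
    ref = histograms[0]

    def _same_edges(a, b):
        if isinstance(a, tuple) or isinstance(b, tuple):
            return (isinstance(a, tuple) and isinstance(b, tuple)
                    and all(np.array_equal(x, y) for x, y in zip(a, b)))
        return np.array_equal(a, b)

    for h in histograms[1:]:
        if h.variable != ref.variable or not _same_edges(h.bin_edges, ref.bin_edges):
            raise ValueError("histograms must share variable and binning")
    density = np.mean([h.density for h in histograms], axis=0)
    counts = np.sum([h.raw_counts for h in histograms], axis=0)
    return SteeringHistogram(ref.bin_edges, counts, density, ref.variable)
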