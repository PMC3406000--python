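"""Rigid-body Brownian dynamics over a static bilayer.

Overdamped Ermak-McCammon propagation: per step,

    dr   = (D_trans dt) F + R,          <R_a R_b> = 2 D_trans dt delta_ab
    dphi = (D_rot   dt) T + W,          <W_a W_b> = 2 D_rot   dt delta_ab

with forces/torques from central finite differences of the grid interaction
energy (energies are in kT so the thermal factor is absorbed). Trajectories
start on a truncated spherical (b) surface, terminate on an outer q-surface
or at a time cap, and record the steering coordinates (r, d, theta) at a
fixed sampling interval plus the pose at first bilayer encounter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels, _quat, constants
from .electrostatics import DesolvationGrid, PotentialGrid, interaction_energy

__all__ = [
    "BDParams",
    "BDState",
    "Trajectory",
    "EnsembleRecord",
    "sample_start",
    "compute_force_torque",
    "step",
    "run_trajectory",
    "run_ensemble",
]


@dataclass
class BDParams:
    """Propagation and geometry parameters (lengths Å, times ps)."""

    dt_near: float = 1.0
    dt_far: float = 10.0
    dt_switch_height: float = 90.0   # lab z below which dt_near applies
    b_radius: float = 100.0
    q_radius: float = 105.0
    z_min_start: float = 60.0
    contact_height: float = 4.5      # encounter: lowest bead within this of the surface
    max_time: float = 2.0e7          # 20 us
    sample_interval: float = 100.0
    n_trajectories: int = 5000
    temperature: float = 300.0
    seed: int = 0
    delta_trans: Optional[float] = None   # FD step; default = grid spacing
    delta_rot_deg: float = 2.0
    noise_scale: float = 1.0         # test hook: scales the random displacements

    def __post_init__(self):
        if self.q_radius <= self.b_radius:
            raise ValueError("q_radius must exceed b_radius")
        if self.z_min_start >= self.b_radius:
            raise ValueError("z_min_start must be below b_radius")
        if self.dt_near > self.dt_far:
            raise ValueError("dt_near must be <= dt_far")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")


@dataclass
class BDState:
    """Instantaneous rigid-body pose."""

    position: np.ndarray             # (3,) lab-frame COM, Å
    orientation: np.ndarray          # (4,) unit quaternion, scalar-last
    time: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(self.orientation)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("orientation quaternion must be normalised")
        self.orientation = self.orientation / n


@dataclass
class Trajectory:
    times: np.ndarray
    r: np.ndarray
    d: np.ndarray
    theta: np.ndarray
    termination: str                 # 'encounter' | 'escape' | 'timeout'
    first_encounter: Optional[tuple] # (r, d, theta) or None

    @property
    def n_samples(self) -> int:
        return len(self.times)


@dataclass
class EnsembleRecord:
    """Aggregated output of an ensemble of independent trajectories."""

    params: BDParams
    sample_traj: np.ndarray
    sample_time: np.ndarray
    sample_r: np.ndarray
    sample_d: np.ndarray
    sample_theta: np.ndarray
    terminations: list
    first_encounters: np.ndarray     # (n_enc, 3): r, d, theta
    first_encounter_traj: np.ndarray

    @property
    def n_trajectories(self) -> int:
        return len(self.terminations)

    @property
    def termination_counts(self) -> dict:
        return dict(Counter(self.terminations))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trajectory": self.sample_traj,
            "time_ps": self.sample_time,
            "r": self.sample_r,
            "d": self.sample_d,
            "theta": self.sample_theta,
            "termination": [self.terminations[t] for t in self.sample_traj],
        })

    def write_csv(self, path):
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def _unpack_grids(grids):
    if isinstance(grids, PotentialGrid):
        return grids, None
    pot, des = grids
    return pot, des


def sample_start(params: BDParams, rng: np.random.Generator) -> BDState:
    """Uniform start pose on the truncated b-sphere cap, z > z_min_start.

    By Archimedes' hat-box theorem a z drawn uniformly on (z_min, b] gives
    area-uniform points on the cap; orientation is uniform on SO(3).
    """
    z = rng.uniform(params.z_min_start, params.b_radius)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    rho = np.sqrt(max(params.b_radius ** 2 - z ** 2, 0.0))
    pos = np.array([rho * np.cos(phi), rho * np.sin(phi), z])
    quat = _quat.random_uniform(rng)
    return BDState(pos, quat, 0.0)


def compute_force_torque(state: BDState, protein, grids,
                         delta_trans: float | None = None,
                         delta_rot_deg: float = 2.0):
    """Finite-difference force (lab, kT/Å) and torque (body axes, kT/rad).

    Central differences of the interaction energy over +-delta_trans along
    each lab axis and +-delta_rot about each body axis. Using
    ``delta_trans`` equal to the grid spacing keeps trilinear interpolation
    error from leaking into the gradient.
    """
    pot, des = _unpack_grids(grids)
    if delta_trans is None:
        delta_trans = pot.spacing
    drot = np.radians(delta_rot_deg)
    pos, quat = state.position, state.orientation

    force = np.empty(3)
    for k in range(3):
        shift = np.zeros(3)
        shift[k] = delta_trans
        up = interaction_energy(protein, (pos + shift, quat), pot, des)
        dn = interaction_energy(protein, (pos - shift, quat), pot, des)
        force[k] = -(up - dn) / (2.0 * delta_trans)

    torque = np.empty(3)
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        qp = _quat.multiply(quat, _quat.from_rotvec(axis * drot))
        qm = _quat.multiply(quat, _quat.from_rotvec(-axis * drot))
        up = interaction_energy(protein, (pos, qp), pot, des)
        dn = interaction_energy(protein, (pos, qm), pot, des)
        torque[k] = -(up - dn) / (2.0 * drot)
    return force, torque


def step(state: BDState, protein, grids, params: BDParams,
         rng: np.random.Generator | None = None,
         noise: np.ndarray | None = None,
         z_surface: float = 20.0) -> BDState:
    """One Ermak-McCammon update (reference implementation).

    ``noise`` may supply the six standard normals explicitly (tests use
    zeros to switch randomness off); otherwise they are drawn from ``rng``.
    A move placing the lowest protein bead below the surface plane is
    reflected in z.
    """
    if noise is None:
        if rng is None:
            raise ValueError("provide either rng or explicit noise")
        noise = rng.standard_normal(6)
    dt = params.dt_near if state.position[2] < params.dt_switch_height else params.dt_far
    D_t = protein.D_trans * constants.CM2_S_TO_A2_PS
    D_r = protein.D_rot * constants.RAD2_S_TO_RAD2_PS

    force, torque = compute_force_torque(state, protein, grids,
                                         params.delta_trans,
                                         params.delta_rot_deg)
    sig_t = params.noise_scale * np.sqrt(2.0 * D_t * dt)
    sig_r = params.noise_scale * np.sqrt(2.0 * D_r * dt)
    pos = state.position + D_t * dt * force + sig_t * noise[:3]
    rotvec = D_r * dt * torque + sig_r * noise[3:]
    quat = _quat.normalize(_quat.multiply(state.orientation,
                                          _quat.from_rotvec(rotvec)))
    min_z = _quat.rotate(quat, protein.bead_coords)[:, 2].min()
    if pos[2] + min_z < z_surface:
        pos = pos.copy()
        pos[2] = 2.0 * (z_surface - min_z) - pos[2]
    return BDState(pos, quat, state.time + dt)


_NOISE_CHUNK = 4096


def run_trajectory(protein, bilayer, grids, params: BDParams,
                   rng: np.random.Generator,
                   start: BDState | None = None) -> Trajectory:
    """Propagate a single trajectory to termination.

    Runs the compiled kernel in fixed-size noise chunks so results are a
    deterministic function of the generator state. Samples are recorded
    every ``params.sample_interval`` (the start pose is sample zero);
    termination is 'escape' at the q-surface, 'timeout' at ``max_time``,
    with the label upgraded to 'encounter' if the protein ever came within
    ``contact_height`` of the surface.
    """
    pot, des = _unpack_grids(grids)
    state = start if start is not None else sample_start(params, rng)

    pip3 = np.asarray(bilayer.pip3_site.position, dtype=float)
    z_surf = float(bilayer.leaflet_z[0])
    ref_vec = np.asarray(protein.ref_vector, dtype=float)

    D_t = protein.D_trans * constants.CM2_S_TO_A2_PS
    D_r = protein.D_rot * constants.RAD2_S_TO_RAD2_PS
    dtr = params.delta_trans if params.delta_trans is not None else pot.spacing
    drot = np.radians(params.delta_rot_deg)

    max_samples = int(params.max_time / params.sample_interval) + 2 \
        if params.max_time > 0 else 1
    samples = np.empty((max_samples, 4))
    counters = np.zeros(1, dtype=np.int64)
    next_sample = np.array([params.sample_interval])
    fe = np.zeros(4)

    pos = state.position.astype(float).copy()
    quat = state.orientation.astype(float).copy()
    time_arr = np.array([state.time])

    # sample zero: the start pose
    R = _quat.to_matrix(quat)
    r0 = float(np.hypot(pos[0] - pip3[0], pos[1] - pip3[1]))
    d0 = float(pos[2] - pip3[2])
    th0 = float(np.degrees(np.arccos(np.clip(-(R @ ref_vec)[2], -1, 1))))
    samples[0] = (state.time, r0, d0, th0)
    counters[0] = 1

    if des is not None:
        des_values, has_des = des.values, True
    else:
        des_values, has_des = np.zeros((1, 1, 1)), False
    pox, poy, poz = (float(v) for v in pot.origin)
    pih = 1.0 / pot.spacing

    status = _kernels.TIMEOUT if params.max_time <= 0 else _kernels.NOISE_EXHAUSTED
    while status == _kernels.NOISE_EXHAUSTED:
        noise = rng.standard_normal((_NOISE_CHUNK, 6))
        status = _kernels._propagate(
            pos, quat, time_arr, protein.bead_coords, protein.bead_charges,
            pot.values, pox, poy, poz, pih, des_values, has_des,
            params.dt_near, params.dt_far, params.dt_switch_height,
            params.q_radius, z_surf, params.contact_height,
            params.max_time, params.sample_interval, D_t, D_r, dtr, drot,
            params.noise_scale, pip3[0], pip3[1], pip3[2], ref_vec,
            noise, samples, counters, next_sample, fe)

    n = int(counters[0])
    encountered = fe[0] > 0.0
    if encountered:
        termination = "encounter"
    else:
        termination = "escape" if status == _kernels.ESCAPE else "timeout"
    return Trajectory(samples[:n, 0].copy(), samples[:n, 1].copy(),
                      samples[:n, 2].copy(), samples[:n, 3].copy(),
                      termination,
                      (fe[1], fe[2], fe[3]) if encountered else None)


def run_ensemble(protein, bilayer, grids, params: BDParams,
                 progress: bool = False) -> EnsembleRecord:
    """Run ``params.n_trajectories`` independent trajectories.

    Per-trajectory RNG streams are spawned from the master seed with
    ``numpy.random.SeedSequence``, so enlarging the ensemble never changes
    earlier trajectories.
    """
    children = np.random.SeedSequence(params.seed).spawn(params.n_trajectories)
    traj_ids, times, rs, ds, thetas = [], [], [], [], []
    terminations = []
    fes, fe_ids = [], []
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        traj = run_trajectory(protein, bilayer, grids, params, rng)
        traj_ids.append(np.full(traj.n_samples, i, dtype=np.int64))
        times.append(traj.times)
        rs.append(traj.r)
        ds.append(traj.d)
        thetas.append(traj.theta)
        terminations.append(traj.termination)
        if traj.first_encounter is not None:
            fes.append(traj.first_encounter)
            fe_ids.append(i)
        if progress and (i + 1) % 100 == 0:
            print(f"  trajectory {i + 1}/{params.n_trajectories}")
    return EnsembleRecord(
        params=params,
        sample_traj=np.concatenate(traj_ids),
        sample_time=np.concatenate(times),
        sample_r=np.concatenate(rs),
        sample_d=np.concatenate(ds),
        sample_theta=np.concatenate(thetas),
        terminations=terminations,
        first_encounters=np.array(fes, dtype=float).reshape(-1, 3),
        first_encounter_traj=np.array(fe_ids, dtype=np.int64),
    )
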