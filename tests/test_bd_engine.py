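import numpy as np
import pytest
from scipy import stats

from memsteer import _quat, bd_engine as bd, constants
from memsteer import electrostatics as es
from memsteer import synthetic_systems as ss
from memsteer.bd_engine import BDParams, BDState
from memsteer.protein_model import ProteinModel

from conftest import make_linear_grid, make_zero_grid

D_T = constants.D_TRANS_DEFAULT * constants.CM2_S_TO_A2_PS      # Å^2/ps
D_R = constants.D_ROT_DEFAULT * constants.RAD2_S_TO_RAD2_PS     # rad^2/ps
IDENT = np.array([0.0, 0.0, 0.0, 1.0])


class TestBDParams:
    def test_defaults_valid(self):
        p = BDParams()
        assert p.b_radius == 100.0 and p.q_radius == 105.0

    @pytest.mark.parametrize("kwargs", [
        {"q_radius": 90.0},
        {"z_min_start": 150.0},
        {"dt_near": 20.0, "dt_far": 10.0},
        {"n_trajectories": 0},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            BDParams(**kwargs)


class TestSampleStart:
    def test_on_truncated_sphere(self, rng):
        params = BDParams()
        for _ in range(500):
            s = bd.sample_start(params, rng)
            assert np.isclose(np.linalg.norm(s.position), 100.0, atol=1e-9)
            assert s.position[2] > 60.0
            assert np.isclose(np.linalg.norm(s.orientation), 1.0, atol=1e-9)

    def test_cap_height_uniform(self, rng):
        # Archimedes: area-uniform on the cap <=> z uniform on (60, 100]
        params = BDParams()
        zs = np.array([bd.sample_start(params, rng).position[2]
                       for _ in range(3000)])
        p = stats.kstest(zs, stats.uniform(loc=60.0, scale=40.0).cdf).pvalue
        assert p > 0.01

    def test_orientation_axis_isotropic(self, rng):
        # cos(angle of body z-axis to lab z) must be uniform on [-1, 1]
        params = BDParams()
        cosines = []
        for _ in range(10_000):
            s = bd.sample_start(params, rng)
            cosines.append(_quat.to_matrix(s.orientation)[2, 2])
        p = stats.kstest(np.array(cosines),
                         stats.uniform(loc=-1.0, scale=2.0).cdf).pvalue
        assert p > 0.01


class TestForceTorque:
    def test_uniform_potential_zero_force(self, single_bead_protein):
        grid = make_zero_grid()
        grid.values += 2.5
        state = BDState(np.array([0.0, 0.0, 100.0]), IDENT)
        f, t = bd.compute_force_torque(state, single_bead_protein, grid)
        assert np.allclose(f, 0.0, atol=1e-12)
        assert np.allclose(t, 0.0, atol=1e-12)

    def test_linear_potential_force(self):
        c = 0.5
        grid = make_linear_grid(coeff=c)
        prot = ProteinModel(np.zeros((2, 3)), np.array([1.0, 2.0]), ["a", "b"])
        state = BDState(np.array([0.0, 0.0, 150.0]), IDENT)
        f, _ = bd.compute_force_torque(state, prot, grid)
        assert np.allclose(f, [0.0, 0.0, -prot.net_charge * c], atol=1e-9)

    def test_point_source_force_matches_analytic_gradient(self):
        kappa = 9.65
        src = np.array([0.0, 0.0, 20.0])
        src_q = -5.0
        sites = [ss.LipidSite(tuple(src), src_q, ss.UPPER, "pip3")]
        bil = ss.BilayerModel(sites, (60.0, 60.0), (20.0, -20.0), 62.0)
        spec = es.GridSpec((-20.0, -20.0, 25.0), 0.5, (81, 81, 61))
        grid = es.compute_potential_grid(bil, spec, kappa_inv=kappa)
        prot = ProteinModel(np.zeros((1, 3)), np.array([1.0]), ["q"])
        pos = np.array([3.0, -2.0, 40.0])  # ~20 Å from the source
        f, _ = bd.compute_force_torque(BDState(pos, IDENT), prot, grid,
                                       delta_trans=0.5)
        # analytic gradient of q*coeff*exp(-kr)/r
        coeff = constants.coulomb_kt(300.0) / 78.5 * src_q
        dvec = pos - src
        r = np.linalg.norm(dvec)
        dphi_dr = coeff * np.exp(-r / kappa) * (-(1 / kappa) * r - 1) / r ** 2
        f_ref = -dphi_dr * dvec / r
        assert np.linalg.norm(f - f_ref) / np.linalg.norm(f_ref) < 0.01

    def test_dipole_torque_matches_cross_product(self):
        # uniform field E_z: Phi = -E*z, torque on dipole p is p x E
        E = 0.8
        grid = make_linear_grid(coeff=-E)
        prot = ProteinModel(np.array([[0.5, 0, 0], [-0.5, 0, 0]]),
                            np.array([1.0, -1.0]), ["p", "m"])  # p along body x
        # tilt body x into the lab xz-plane at 45 degrees
        quat = _quat.from_rotvec(np.array([0.0, -np.pi / 4, 0.0]))
        state = BDState(np.array([0.0, 0.0, 150.0]), quat)
        _, t_body = bd.compute_force_torque(state, prot, grid,
                                            delta_rot_deg=0.5)
        p_lab = _quat.rotate(quat, prot.dipole)
        t_lab_ref = np.cross(p_lab, np.array([0.0, 0.0, E]))
        t_lab = _quat.rotate(quat, t_body)  # body -> lab
        assert np.linalg.norm(t_lab - t_lab_ref) / np.linalg.norm(t_lab_ref) < 0.01


class TestStep:
    def test_deterministic_drift(self, single_bead_protein):
        # F_z = +1 kT/Å on +1 e in Phi = -z; dz = D dt F = 0.104 Å at dt 10
        grid = make_linear_grid(coeff=-1.0)
        params = BDParams(dt_far=10.0, dt_switch_height=90.0)
        state = BDState(np.array([0.0, 0.0, 150.0]), IDENT)
        new = bd.step(state, single_bead_protein, grid, params,
                      noise=np.zeros(6))
        assert np.isclose(new.position[2] - 150.0, D_T * 10.0, atol=1e-9)
        assert np.isclose(new.position[2] - 150.0, 0.104, atol=1e-3)
        assert new.time == 10.0

    def test_free_diffusion_msd(self, single_bead_protein, rng):
        grid = make_zero_grid()
        params = BDParams(dt_far=10.0)
        state = BDState(np.array([0.0, 0.0, 250.0]), IDENT)
        n, acc = 10_000, 0.0
        for _ in range(n):
            new = bd.step(state, single_bead_protein, grid, params, rng=rng)
            acc += np.sum((new.position - state.position) ** 2)
        assert np.isclose(acc / n, 6 * D_T * 10.0, rtol=0.02)

    def test_dipole_aligns_with_field(self):
        # noise off: a tilted dipole in an upward uniform field rotates
        # toward +z, monotonically
        grid = make_linear_grid(coeff=-2.0)  # E_z = +2
        prot = ProteinModel(np.array([[0, 0, 0.5], [0, 0, -0.5]]),
                            np.array([3.0, -3.0]), ["p", "m"])
        quat = _quat.from_rotvec(np.array([0.0, np.radians(60.0), 0.0]))
        state = BDState(np.array([0.0, 0.0, 150.0]), quat)
        params = BDParams(dt_far=10.0)
        angles = []
        for _ in range(300):
            p_lab = _quat.rotate(state.orientation, prot.dipole)
            angles.append(np.degrees(np.arccos(
                np.clip(p_lab[2] / np.linalg.norm(p_lab), -1, 1))))
            state = bd.step(state, prot, grid, params, noise=np.zeros(6))
        assert all(b < a for a, b in zip(angles, angles[1:]))
        assert angles[-1] < angles[0] - 10.0

    def test_reflecting_wall(self, single_bead_protein):
        grid = make_zero_grid(z_lo=0.0)
        params = BDParams(dt_near=1.0, dt_switch_height=90.0)
        state = BDState(np.array([0.0, 0.0, 21.0]), IDENT)
        # push hard toward the wall: huge downward noise
        new = bd.step(state, single_bead_protein, grid, params,
                      noise=np.array([0.0, 0.0, -50.0, 0.0, 0.0, 0.0]),
                      z_surface=20.0)
        assert new.position[2] >= 20.0


@pytest.fixture(scope="module")
def charged_system():
    patch = ss.build_patch()
    m = ss.assign_charges(patch, ss.ChargeScheme("fractional",
                                                 fractional_charge=-1.0))
    spec = es.grid_for_bilayer(m, spacing=2.0, lateral_margin=15.0, z_top=130.0)
    pot = es.compute_potential_grid(m, spec)
    prot = ss.make_toy_protein(n_beads=8, radius=12.0)
    return prot, m, pot


@pytest.fixture(scope="module")
def neutral_system():
    patch = ss.build_patch(pip3_charge=-7.0)
    m = ss.assign_charges(patch, ss.ChargeScheme("zwitterionic"))
    # zero out everything including the target for pure-diffusion controls
    sites = [ss.LipidSite(s.position, 0.0, s.leaflet, s.species)
             for s in m.sites]
    m = ss.BilayerModel(sites, m.patch_dims, m.leaflet_z, m.area_per_lipid)
    spec = es.grid_for_bilayer(m, spacing=2.0, lateral_margin=15.0, z_top=130.0)
    pot = es.PotentialGrid(tuple(spec.origin), spec.spacing,
                           np.zeros(spec.shape))
    prot = ss.make_toy_protein(n_beads=8, radius=12.0, net_charge=0.0,
                               dipole_moment=0.0)
    return prot, m, pot


class TestRunTrajectory:
    def test_zero_max_time_single_sample_timeout(self, charged_system):
        prot, m, pot = charged_system
        params = BDParams(max_time=0.0)
        traj = bd.run_trajectory(prot, m, (pot, None), params,
                                 np.random.default_rng(0))
        assert traj.n_samples == 1
        assert traj.termination == "timeout"
        assert traj.first_encounter is None

    def test_seed_determinism_bitwise(self, charged_system):
        prot, m, pot = charged_system
        params = BDParams(max_time=5e3)
        a = bd.run_trajectory(prot, m, (pot, None), params,
                              np.random.default_rng(77))
        b = bd.run_trajectory(prot, m, (pot, None), params,
                              np.random.default_rng(77))
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.r, b.r)
        assert np.array_equal(a.d, b.d)
        assert np.array_equal(a.theta, b.theta)
        assert a.termination == b.termination

    def test_samples_time_ordered(self, charged_system):
        prot, m, pot = charged_system
        params = BDParams(max_time=1e4)
        traj = bd.run_trajectory(prot, m, (pot, None), params,
                                 np.random.default_rng(5))
        assert np.all(np.diff(traj.times) > 0)

    def test_strong_attraction_mostly_encounters(self, charged_system):
        # deterministic limit: scaled-down noise lets the drift win
        prot, m, pot = charged_system
        # long enough for the slow high-start drift to reach the surface, and
        # a wide q-surface so residual noise cannot push starts over the edge
        spec = es.grid_for_bilayer(m, spacing=3.0, lateral_margin=40.0,
                                   z_top=155.0)
        pot_wide = es.compute_potential_grid(m, spec)
        params = BDParams(n_trajectories=100, max_time=1e6, noise_scale=0.1,
                          q_radius=130.0, dt_near=10.0, dt_far=20.0,
                          dt_switch_height=60.0, seed=99)
        ens = bd.run_ensemble(prot, m, (pot_wide, None), params)
        n_enc = ens.termination_counts.get("encounter", 0)
        assert n_enc / 100 > 0.9

    def test_first_encounter_within_contact(self, charged_system):
        prot, m, pot = charged_system
        params = BDParams(n_trajectories=30, max_time=2e4, seed=4, dt_near=2.0)
        ens = bd.run_ensemble(prot, m, (pot, None), params)
        if len(ens.first_encounters):
            # d at encounter: COM height above the target plane; the lowest
            # bead is within contact_height of the plane, so d cannot exceed
            # the largest bead radius plus the contact height
            extent = np.linalg.norm(prot.bead_coords, axis=1).max()
            assert np.all(ens.first_encounters[:, 1] <= extent + 4.5 + 1e-6)


class TestRunEnsemble:
    def test_termination_counts_sum(self, charged_system):
        prot, m, pot = charged_system
        params = BDParams(n_trajectories=25, max_time=5e3, seed=8)
        ens = bd.run_ensemble(prot, m, (pot, None), params)
        assert sum(ens.termination_counts.values()) == 25

    def test_first_encounter_list_length(self, charged_system):
        prot, m, pot = charged_system
        params = BDParams(n_trajectories=25, max_time=2e4, seed=8, dt_near=2.0)
        ens = bd.run_ensemble(prot, m, (pot, None), params)
        assert len(ens.first_encounters) == \
            ens.termination_counts.get("encounter", 0)

    def test_ensemble_determinism(self, charged_system):
        prot, m, pot = charged_system
        params = BDParams(n_trajectories=10, max_time=5e3, seed=21)
        a = bd.run_ensemble(prot, m, (pot, None), params)
        b = bd.run_ensemble(prot, m, (pot, None), params)
        assert np.array_equal(a.sample_r, b.sample_r)
        assert np.array_equal(a.sample_theta, b.sample_theta)
        assert a.terminations == b.terminations

    def test_extending_ensemble_preserves_prefix(self, charged_system):
        prot, m, pot = charged_system
        pa = BDParams(n_trajectories=5, max_time=5e3, seed=31)
        pb = BDParams(n_trajectories=10, max_time=5e3, seed=31)
        a = bd.run_ensemble(prot, m, (pot, None), pa)
        b = bd.run_ensemble(prot, m, (pot, None), pb)
        na = len(a.sample_r)
        assert np.array_equal(b.sample_r[:na], a.sample_r)
        assert b.terminations[:5] == a.terminations

    def test_zero_charge_matches_pure_diffusion_control(self, neutral_system):
        # same zero-field physics through two different charge routes must
        # produce statistically identical d-distributions
        prot, m, pot_zero = neutral_system
        params_a = BDParams(n_trajectories=200, max_time=2e3, seed=1)
        params_b = BDParams(n_trajectories=200, max_time=2e3, seed=2)
        a = bd.run_ensemble(prot, m, (pot_zero, None), params_a)
        spec = pot_zero.spec()
        pot_dh = es.compute_potential_grid(m, spec)  # all charges zero
        b = bd.run_ensemble(prot, m, (pot_dh, None), params_b)
        assert np.all(pot_dh.values == 0.0)

        def final_d(ens):
            # one independent value per trajectory (KS assumes iid samples)
            import pandas as pd
            return pd.Series(ens.sample_d).groupby(ens.sample_traj).last().values

        p = stats.ks_2samp(final_d(a), final_d(b)).pvalue
        assert p > 0.01

    def test_no_sample_below_wall(self, charged_system):
        prot, m, pot = charged_system
        params = BDParams(n_trajectories=20, max_time=2e4, seed=13, dt_near=2.0)
        ens = bd.run_ensemble(prot, m, (pot, None), params)
        extent = np.abs(prot.bead_coords[:, 2]).max()
        # COM height d >= -(bead extent): lowest bead never below the plane
        assert np.all(ens.sample_d >= -extent - 1e-9)


class TestRotationalDiffusion:
    def test_orientation_autocorrelation(self, neutral_system):
        # <e(t)·e(0)> = exp(-2 D_R t): start with the reference vector at -z
        # (theta = 0) so cos(theta(t)) is the autocorrelation directly
        prot, m, _ = neutral_system
        pot = make_zero_grid(half_extent=1500.0, spacing=50.0,
                             z_lo=0.0, z_hi=3000.0)
        # ref_vector defaults to +z for the zero-dipole toy; rotate to -z
        start_q = _quat.from_rotvec(np.array([np.pi, 0.0, 0.0]))
        params = BDParams(b_radius=1e5, q_radius=1.1e5, z_min_start=1e4,
                          max_time=3.0e4, sample_interval=1000.0,
                          dt_switch_height=0.0, dt_far=10.0, seed=0)
        rng = np.random.default_rng(0)
        acc = {}
        for i in range(2000):
            start = BDState(np.array([0.0, 0.0, 400.0]), start_q, 0.0)
            traj = bd.run_trajectory(prot, m, (pot, None), params, rng,
                                     start=start)
            for t, th in zip(traj.times, traj.theta):
                acc.setdefault(t, []).append(np.cos(np.radians(th)))
        times = np.array(sorted(acc))
        corr = np.array([np.mean(acc[t]) for t in times])
        expected = np.exp(-2 * D_R * times)
        mask = times <= 1.0 / (2 * D_R)
        assert np.all(np.abs(corr[mask] - expected[mask]) / expected[mask]
                      < 0.05)
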