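"""Builders, neighbor lists, and Langevin dynamics against closed-form oracles."""

import numpy as np
import pytest

from hpcg.engine import (SimState, build_cubic, build_single_chain, build_slab,
                         build_two_chains, neighbor_pairs, read_xyz, run_langevin,
                         unwrap_chains, write_xyz)
from hpcg.forcefield import default_forcefield
from hpcg.sequences import generate_sequence
from hpcg.units import KB, KCAL_TO_INTERNAL, BEAD_MASS
from tests.conftest import random_state


def _free_particle(seed=0):
    pos = np.array([[25.0, 25.0, 25.0]])
    vel = np.zeros((1, 3))
    return SimState(pos, vel, np.array([1], dtype=np.int64),
                    np.array([0], dtype=np.int64), np.full(3, 50.0), rng_seed=seed)


def _bonded_dimer(seed=0):
    pos = np.array([[25.0, 25.0, 25.0], [25.38, 25.0, 25.0]])
    return SimState(pos, np.zeros((2, 3)), np.array([1, 1], dtype=np.int64),
                    np.array([0, 0], dtype=np.int64), np.full(3, 50.0), rng_seed=seed)


class TestBuilders:
    def test_single_chain_geometry(self, seq_h20):
        st = build_single_chain(seq_h20, box=50.0, seed=4)
        assert st.n_particles == 20
        assert st.bonds.shape == (19, 2)
        bl = np.linalg.norm(np.diff(st.positions, axis=0), axis=1)
        assert np.all(np.abs(bl - 0.38) < 0.05)

    def test_two_chain_com_distance(self, seq_h20):
        st = build_two_chains(seq_h20, r_com=5.0, box=30.0, seed=4)
        a = st.positions[:20].mean(axis=0)
        b = st.positions[20:].mean(axis=0)
        assert np.linalg.norm(b - a) == pytest.approx(5.0, abs=1e-9)

    def test_slab_centers_chains_in_z(self, seq_h20):
        st = build_slab([seq_h20] * 20, box=(7.0, 7.0, 30.0), seed=4)
        assert st.n_particles == 400
        z = st.positions[:, 2]
        assert z.min() > 30.0 * 0.2 and z.max() < 30.0 * 0.8
        # no nonbonded pair closer than 0.8 sigma
        from scipy.spatial import cKDTree
        t = cKDTree(st.positions % st.box, boxsize=st.box)
        pairs = t.query_pairs(0.4 - 1e-9, output_type="ndarray")
        bonded = (np.abs(pairs[:, 0] - pairs[:, 1]) == 1) & \
                 (st.chain_ids[pairs[:, 0]] == st.chain_ids[pairs[:, 1]])
        assert np.all(bonded)

    def test_cubic_disperses_chains(self, seq_h20):
        st = build_cubic([seq_h20] * 10, edge=20.0, seed=4)
        assert st.n_particles == 200
        assert st.positions.min() >= 0 and st.positions.max() <= 20.0


class TestNeighborPairs:
    def test_two_particle_cutoff_logic(self):
        st = random_state(2, 10.0, seed=1, n_chains=2)
        st.positions[0] = [1.0, 1.0, 1.0]
        st.positions[1] = [1.0 + 0.9 * 2.0, 1.0, 1.0]
        assert len(neighbor_pairs(st, cutoff=2.0)) == 1
        st.positions[1] = [1.0 + 1.1 * 2.4, 1.0, 1.0]
        assert len(neighbor_pairs(st, cutoff=2.0, skin=0.4)) == 0

    def test_matches_brute_force_on_random_configuration(self):
        st = random_state(50, 6.0, seed=8, n_chains=1)
        got = {tuple(p) for p in neighbor_pairs(st, cutoff=1.5).tolist()}
        want = set()
        for i in range(50):
            for j in range(i + 1, 50):
                d = st.positions[i] - st.positions[j]
                d -= st.box * np.rint(d / st.box)
                if np.linalg.norm(d) <= 1.5:
                    want.add((i, j))
        assert got == want

    def test_oversized_cutoff_rejected(self):
        st = random_state(5, 4.0, seed=2)
        with pytest.raises(ValueError):
            neighbor_pairs(st, cutoff=2.5)


class TestLangevin:
    def test_same_seed_bit_identical(self, seq_h20, ff_hp):
        st = build_single_chain(seq_h20, seed=5)
        t1 = run_langevin(st, ff_hp, 20_000, sample_every=1000, seed=17)
        t2 = run_langevin(st, ff_hp, 20_000, sample_every=1000, seed=17)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.velocities, t2.velocities)
        t3 = run_langevin(st, ff_hp, 20_000, sample_every=1000, seed=18)
        assert not np.array_equal(t1.positions, t3.positions)

    def test_free_particle_msd_obeys_einstein_relation(self, ff_hp):
        # diffusion coefficient D = kT/gamma for a free Langevin particle;
        # at lag >> m/gamma the MSD is 6 D (t - m/gamma), the inertial
        # Ornstein-Uhlenbeck correction to the Einstein relation
        st = _free_particle()
        traj = run_langevin(st, ff_hp, 4_000_000, sample_every=100, seed=3)
        pos = traj.positions[:, 0, :]
        dt_frame = traj.sample_interval
        D = KB * 300 * KCAL_TO_INTERNAL / 0.1  # nm^2/fs
        tau_m = 100.0 / 0.1                    # fs
        for lag in (20, 30, 40):
            t = lag * dt_frame
            disp = pos[lag:] - pos[:-lag]
            msd = (disp ** 2).sum(axis=1).mean()
            expected = 6 * D * (t - tau_m * (1 - np.exp(-t / tau_m)))
            assert msd == pytest.approx(expected, rel=0.05)

    def test_bonded_dimer_bond_length_matches_boltzmann_quadrature(self, ff_hp):
        st = _bonded_dimer()
        traj = run_langevin(st, ff_hp, 1_000_000, sample_every=50, seed=21)
        r = np.linalg.norm(traj.positions[:, 1, :] - traj.positions[:, 0, :], axis=1)
        r = r[len(r) // 10:]
        # 1D quadrature oracle: p(r) ~ r^2 exp(-k (r-r0)^2 / kT)
        kT = KB * 300
        grid = np.linspace(0.30, 0.46, 2000)
        w = grid ** 2 * np.exp(-2000.0 * (grid - 0.38) ** 2 / kT)
        w /= np.trapezoid(w, grid)
        mean_expected = np.trapezoid(grid * w, grid)
        var_expected = np.trapezoid((grid - mean_expected) ** 2 * w, grid)
        assert r.mean() == pytest.approx(mean_expected, abs=3e-4)
        assert r.var() == pytest.approx(var_expected, rel=0.05)

    def test_velocity_autocorrelation_time_is_m_over_gamma(self, ff_hp):
        # free particle: OU process with relaxation time m/gamma = 1000 fs
        st = _free_particle()
        traj = run_langevin(st, ff_hp, 400_000, dt=10.0, sample_every=10, seed=5)
        v = traj.velocities[:, 0, :]
        v = v - v.mean(axis=0)
        n = len(v)
        lags = np.arange(0, 30)
        acf = np.array([np.sum(v[l:] * v[:n - l]) / (n - l) for l in lags])
        acf /= acf[0]
        tau_fit = -1.0 / np.polyfit(lags * 100.0, np.log(np.maximum(acf, 1e-9)), 1)[0]
        assert tau_fit == pytest.approx(1000.0, rel=0.1)

    def test_equipartition_kinetic_temperature(self, seq_h20, ff_hp):
        st = build_single_chain(seq_h20, seed=2)
        traj = run_langevin(st, ff_hp, 200_000, sample_every=200, seed=9)
        T_kin = traj.kinetic_temperature()[50:]
        assert T_kin.mean() == pytest.approx(300.0, rel=0.02)

    def test_energy_conservation_in_velocity_verlet_limit(self, seq_h20):
        # gamma = 0 disables the thermostat; BAOAB reduces to velocity Verlet.
        # The WCA (lambda = 0) limit is used so the potential is continuous at
        # the cutoff and any drift is purely integrator error.
        ff = default_forcefield("HP", 0.0)
        st = build_single_chain(seq_h20, seed=6)
        warm = run_langevin(st, ff, 2_000, dt=10.0, sample_every=2000, seed=3)
        st2 = warm.frame(-1)
        st2.chain_ids = st.chain_ids
        traj = run_langevin(st2, ff, 100_000, dt=1.0, gamma=0.0,
                            sample_every=1000, seed=3)
        e_tot = traj.potential_energy + traj.kinetic_energy
        drift = abs(e_tot[-1] - e_tot[0]) / st.n_particles
        assert drift < 1e-4

    def test_blowup_reports_integration_error(self, ff_hp):
        st = random_state(2, 10.0, seed=1, n_chains=2)
        st.types[:] = 0
        st.positions[0] = [5.0, 5.0, 5.0]
        st.positions[1] = [5.02, 5.0, 5.0]  # deep core overlap
        with pytest.raises(RuntimeError, match="integration error"):
            run_langevin(st, ff_hp, 2_000, dt=50.0, sample_every=100, seed=1)

    def test_rejects_zero_steps(self, seq_h20, ff_hp):
        st = build_single_chain(seq_h20, seed=5)
        with pytest.raises(ValueError):
            run_langevin(st, ff_hp, 0)


def test_unwrap_restores_bond_continuity(seq_h20, ff_hp):
    st = build_slab([seq_h20] * 10, box=(6.0, 6.0, 20.0), seed=3)
    traj = run_langevin(st, ff_hp, 20_000, sample_every=10_000, seed=3)
    pos = traj.positions[-1]
    coords = unwrap_chains(pos, traj.chain_ids, traj.box)
    for c in range(10):
        sel = traj.chain_ids == c
        bl = np.linalg.norm(np.diff(coords[sel], axis=0), axis=1)
        assert np.all(bl < 0.6)


def test_xyz_round_trip(tmp_path, seq_h20, ff_hp):
    st = build_single_chain(seq_h20, seed=5)
    traj = run_langevin(st, ff_hp, 5_000, sample_every=1000, seed=2)
    path = tmp_path / "traj.xyz"
    write_xyz(traj, path)
    back = read_xyz(path)
    assert back.n_frames == traj.n_frames
    assert np.allclose(back.positions, traj.positions, atol=1e-6)
    assert np.array_equal(back.types, traj.types)
    assert np.array_equal(back.chain_ids, traj.chain_ids)
    assert np.allclose(back.box, traj.box)
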