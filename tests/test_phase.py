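"""Profiles, coexistence fits, clustering, and phase classification on
synthetic configurations with known construction parameters."""

import numpy as np
import pytest

from hpcg.engine import SimState, Trajectory
from hpcg.phase import (ClusterSizeDistribution, classify_phase_state, cluster_chains,
                        cluster_size_distribution, density_profile, extract_coexistence,
                        largest_cluster_fraction, phase_rg_split, rdf_HH, threshold_scan)
from hpcg.units import number_density_to_mg_per_ml


def _traj(positions, box, types=None, chain_ids=None, n_per_chain=1):
    positions = np.asarray(positions, dtype=float)
    nf, n, _ = positions.shape
    if types is None:
        types = np.zeros(n, dtype=np.int64)
    if chain_ids is None:
        chain_ids = (np.arange(n) // n_per_chain).astype(np.int64)
    z = np.zeros(nf)
    return Trajectory(positions, np.zeros_like(positions), z, z.copy(),
                      types, chain_ids, np.asarray(box, dtype=float), 1000.0)


def _frame(positions, box, chain_ids=None, types=None, n_per_chain=1):
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if chain_ids is None:
        chain_ids = (np.arange(n) // n_per_chain).astype(np.int64)
    if types is None:
        types = np.zeros(n, dtype=np.int64)
    return SimState(positions, np.zeros_like(positions), types,
                    np.asarray(chain_ids, dtype=np.int64),
                    np.asarray(box, dtype=float))


class TestDensityProfile:
    def test_uniform_gas_is_flat_at_total_concentration(self, rng):
        box = [5.0, 5.0, 20.0]
        pos = rng.random((40, 2000, 3)) * box
        prof = density_profile(_traj(pos, box), bin_width=1.0, center=False)
        assert np.allclose(prof.concentration, prof.total_concentration, rtol=0.1)

    def test_mass_conservation(self, rng):
        box = [5.0, 5.0, 20.0]
        pos = rng.random((10, 500, 3)) * box
        pos[:, :, 2] = np.abs(rng.normal(10.0, 1.0, size=(10, 500)))  # clumped in z
        prof = density_profile(_traj(pos, box), bin_width=0.5, center=False)
        bin_vol = box[0] * box[1] * 0.5
        total_mass_conc = prof.concentration.sum() * bin_vol / (np.prod(box))
        assert total_mass_conc == pytest.approx(prof.total_concentration, rel=1e-6)

    def test_single_bin_spike_conserves_mass(self):
        box = [4.0, 4.0, 12.0]
        pos = np.full((3, 100, 3), [2.0, 2.0, 6.1])
        prof = density_profile(_traj(pos, box), bin_width=1.0, center=False)
        assert (prof.concentration > 0).sum() == 1
        expected = number_density_to_mg_per_ml(100 / (4.0 * 4.0 * 1.0))
        assert prof.concentration.max() == pytest.approx(expected, rel=1e-9)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            density_profile(_traj(np.zeros((0, 5, 3)), [5, 5, 5]))

    def test_centering_aligns_drifting_slab(self, rng):
        # same slab built at two z offsets (one wrapped) -> identical profiles
        box = [5.0, 5.0, 30.0]
        base = rng.random((1, 600, 3)) * [5.0, 5.0, 4.0]
        profs = []
        for z0 in (3.0, 27.0):  # second slab wraps around the boundary
            pos = base.copy()
            pos[:, :, 2] = (pos[:, :, 2] + z0) % 30.0
            profs.append(density_profile(_traj(pos, box, n_per_chain=20),
                                         bin_width=1.0, center=True).concentration)
        assert np.allclose(profs[0], profs[1], rtol=0.25, atol=30)
        assert np.argmax(profs[0]) in (14, 15, 16)


def _tanh_profile_traj(c_dense, c_dilute, box, z0=4.0, width=0.8, n_frames=20,
                       seed=0):
    """Rejection-sample bead z positions from a symmetric tanh density."""
    rng = np.random.default_rng(seed)
    Lz = box[2]
    mean_c = None
    # target density in beads/nm^3 from mg/mL
    rho_d = c_dense / number_density_to_mg_per_ml(1.0)
    rho_l = c_dilute / number_density_to_mg_per_ml(1.0)
    frames = []
    area = box[0] * box[1]

    def dens(z):
        return 0.5 * (rho_d + rho_l) - 0.5 * (rho_d - rho_l) * np.tanh(
            (np.abs(z - Lz / 2) - z0) / width)

    n_total = int(np.trapezoid(dens(np.linspace(0, Lz, 500)), np.linspace(0, Lz, 500)) * area)
    zmaxd = dens(Lz / 2)
    for _ in range(n_frames):
        zs = []
        while len(zs) < n_total:
            z = rng.random() * Lz
            if rng.random() < dens(z) / zmaxd:
                zs.append(z)
        pos = np.empty((n_total, 3))
        pos[:, 0] = rng.random(n_total) * box[0]
        pos[:, 1] = rng.random(n_total) * box[1]
        pos[:, 2] = zs
        frames.append(pos)
    return _traj(np.stack(frames), box)


class TestExtractCoexistence:
    def test_exact_step_profile_recovers_plateaus(self):
        from hpcg.phase import DensityProfile
        z = np.linspace(-15, 15, 61)
        c = np.where(np.abs(z) < 5.0, 600.0, 10.0)
        prof = DensityProfile(z, c, np.ones_like(c), 108.0,
                              np.array([5.0, 5.0, 30.0]), 1000)
        c_l, c_d, diag = extract_coexistence(prof)
        assert c_d == pytest.approx(600.0, rel=0.01)
        assert c_l == pytest.approx(10.0, abs=6.0)

    def test_synthetic_tanh_recovered_within_one_percent(self):
        traj = _tanh_profile_traj(600.0, 10.0, [6.0, 6.0, 30.0], n_frames=60)
        prof = density_profile(traj, bin_width=0.5, center=False)
        c_l, c_d, diag = extract_coexistence(prof)
        assert c_d == pytest.approx(600.0, rel=0.01)
        assert c_l == pytest.approx(10.0, abs=0.01 * 600)

    def test_flat_profile_is_classification_error(self):
        from hpcg.phase import DensityProfile
        z = np.linspace(-10, 10, 41)
        c = np.full_like(z, 100.0)
        prof = DensityProfile(z, c, np.ones_like(c), 100.0,
                              np.array([5.0, 5.0, 20.0]), 500)
        with pytest.raises(RuntimeError, match="classification"):
            extract_coexistence(prof)


class TestClassifyPhaseState:
    def test_slab_conditions(self):
        traj = _tanh_profile_traj(600.0, 5.0, [6.0, 6.0, 30.0], z0=5.0, n_frames=40)
        prof = density_profile(traj, bin_width=0.5, center=False)
        state, diag = classify_phase_state(prof, cluster_fraction=0.97)
        assert state == "slab"
        assert not diag["indeterminate"]

    def test_parabolic_droplet_is_cluster(self, rng):
        # spherical droplet: parabolic z profile, modest largest-cluster share
        box = [10.0, 10.0, 30.0]
        center = np.array([5.0, 5.0, 15.0])
        pos = center + rng.normal(0, 1.2, size=(30, 800, 3))
        state, diag = (lambda p: classify_phase_state(p, cluster_fraction=0.5))(
            density_profile(_traj(pos, box), bin_width=1.0, center=False))
        assert state == "cluster"

    def test_dilute_gas_is_homogeneous(self, rng):
        box = [10.0, 10.0, 30.0]
        pos = rng.random((60, 300, 3)) * box
        prof = density_profile(_traj(pos, box), bin_width=3.0, center=False)
        state, diag = classify_phase_state(prof, cluster_fraction=0.05)
        assert state == "homogeneous"


class TestRdfHH:
    def test_ideal_gas_is_unity(self, rng):
        box = [8.0, 8.0, 8.0]
        pos = rng.random((25, 600, 3)) * box
        r, g = rdf_HH(_traj(pos, box), r_max=2.5, n_bins=25)
        assert np.allclose(g[3:], 1.0, atol=0.15)

    def test_fixed_pair_peaks_at_separation(self):
        box = [10.0, 10.0, 10.0]
        pos = np.array([[[2.0, 5.0, 5.0], [3.5, 5.0, 5.0]]] * 5)
        r, g = rdf_HH(_traj(pos, box), r_max=2.5, n_bins=25)
        assert r[np.argmax(g)] == pytest.approx(1.55, abs=0.06)
        assert (g > 0).sum() == 1

    def test_requires_h_monomers(self, rng):
        box = [5.0, 5.0, 5.0]
        pos = rng.random((2, 10, 3)) * box
        types = np.ones(10, dtype=np.int64)
        with pytest.raises(ValueError):
            rdf_HH(_traj(pos, box, types=types))

    def test_matches_brute_force_histogram(self, rng):
        box = np.array([6.0, 6.0, 6.0])
        pos = rng.random((1, 200, 3)) * box
        r, g = rdf_HH(_traj(pos, box), r_max=2.0, n_bins=20)
        # python oracle
        edges = np.linspace(0, 2.0, 21)
        hist = np.zeros(20)
        p = pos[0]
        for i in range(200):
            for j in range(i + 1, 200):
                d = p[i] - p[j]
                d -= box * np.rint(d / box)
                rr = np.linalg.norm(d)
                if rr < 2.0:
                    hist[int(rr / 0.1)] += 1
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        g_oracle = hist / (200 * 199 / 2 / box.prod() * shell)
        assert np.allclose(g, g_oracle, atol=1e-9)


class TestClustering:
    def test_two_separated_chains_are_two_clusters(self):
        box = [10.0, 10.0, 10.0]
        chain_a = np.array([[1.0, 1, 1], [1.38, 1, 1]])
        chain_b = chain_a + [2.0 * 0.5, 0, 0]  # min distance 2 sigma - bond
        pos = np.vstack([chain_a, chain_b + [1.0, 0, 0]])
        labels = cluster_chains(_frame(pos, box, chain_ids=[0, 0, 1, 1]))
        assert labels.shape == (2,)
        assert labels[0] != labels[1]

    def test_touching_chains_merge(self):
        box = [10.0, 10.0, 10.0]
        chain_a = np.array([[1.0, 1, 1], [1.38, 1, 1]])
        chain_b = chain_a + [0.6, 0, 0]  # within 1.5 sigma = 0.75
        pos = np.vstack([chain_a, chain_b])
        labels = cluster_chains(_frame(pos, box, chain_ids=[0, 0, 1, 1]))
        assert labels[0] == labels[1]

    def test_contact_through_periodic_boundary(self):
        box = [10.0, 10.0, 10.0]
        pos = np.array([[0.1, 5, 5], [9.9, 5, 5]])
        labels = cluster_chains(_frame(pos, box, chain_ids=[0, 1]))
        assert labels[0] == labels[1]

    def test_matches_graph_traversal_oracle(self, rng):
        import networkx as nx
        box = np.array([6.0, 6.0, 6.0])
        n_chains, n_per = 10, 5
        pos = []
        for c in range(n_chains):
            start = rng.random(3) * box
            pos.append(start + rng.normal(0, 0.3, size=(n_per, 3)))
        pos = np.vstack(pos) % box
        frame = _frame(pos, box, n_per_chain=n_per)
        labels = cluster_chains(frame, contact_cutoff=0.75)
        g = nx.Graph()
        g.add_nodes_from(range(n_chains))
        for i in range(n_chains * n_per):
            for j in range(i + 1, n_chains * n_per):
                ci, cj = i // n_per, j // n_per
                if ci == cj:
                    continue
                d = pos[i] - pos[j]
                d -= box * np.rint(d / box)
                if np.linalg.norm(d) < 0.75:
                    g.add_edge(ci, cj)
        oracle = {frozenset(c) for c in nx.connected_components(g)}
        got = {frozenset(np.nonzero(labels == l)[0].tolist()) for l in set(labels)}
        assert got == oracle

    def test_labels_invariant_under_translation(self, rng):
        box = np.array([6.0, 6.0, 6.0])
        pos = rng.random((20, 3)) * box
        frame = _frame(pos, box, n_per_chain=2)
        l1 = cluster_chains(frame, contact_cutoff=1.0)
        frame2 = _frame((pos + 2.345) % box, box, n_per_chain=2)
        l2 = cluster_chains(frame2, contact_cutoff=1.0)
        # same partition structure
        p1 = {frozenset(np.nonzero(l1 == l)[0].tolist()) for l in set(l1)}
        p2 = {frozenset(np.nonzero(l2 == l)[0].tolist()) for l in set(l2)}
        assert p1 == p2

    def test_oversized_cutoff_rejected(self):
        frame = _frame(np.zeros((2, 3)) + 1.0, [4.0, 4.0, 4.0], chain_ids=[0, 1])
        with pytest.raises(ValueError):
            cluster_chains(frame, contact_cutoff=2.5)

    def test_size_distribution_sums_to_one(self, rng):
        box = [8.0, 8.0, 8.0]
        pos = rng.random((6, 40, 3)) * box
        dist = cluster_size_distribution(_traj(pos, box, n_per_chain=4))
        assert dist.P.sum() == pytest.approx(1.0, abs=1e-9)

    def test_compact_blob_insensitive_to_cutoff(self, rng):
        # all chains in one dense blob: P(N_c) is a point mass for any cutoff
        box = [12.0, 12.0, 12.0]
        pos = 6.0 + rng.normal(0, 0.8, size=(4, 60, 3))
        traj = _traj(pos, box, n_per_chain=6)
        dists = [cluster_size_distribution(traj, contact_cutoff=c * 0.5)
                 for c in (1.3, 1.5, 1.7)]
        for d in dists[1:]:
            # total variation distance on the common support
            all_sizes = sorted(set(dists[0].N_c) | set(d.N_c))
            p0 = {n: p for n, p in zip(dists[0].N_c, dists[0].P)}
            p1 = {n: p for n, p in zip(d.N_c, d.P)}
            tv = 0.5 * sum(abs(p0.get(n, 0) - p1.get(n, 0)) for n in all_sizes)
            assert tv < 0.1


def test_dense_phase_chains_not_more_compact(rng):
    # dense blob + isolated stretched chains: split reports both phases
    box = [20.0, 20.0, 20.0]
    blob = 10.0 + rng.normal(0, 1.0, size=(30, 3))
    lone1 = np.array([[1.0 + 0.4 * i, 1.0, 1.0] for i in range(5)])
    lone2 = np.array([[1.0 + 0.4 * i, 5.0, 1.0] for i in range(5)])
    pos = np.vstack([blob, lone1, lone2])
    cid = np.concatenate([np.repeat(np.arange(6), 5), [6] * 5, [7] * 5])
    traj = _traj(pos[None, :, :], box, chain_ids=cid)
    rg_dense, rg_dilute = phase_rg_split(traj, contact_cutoff=1.0)
    assert np.isfinite(rg_dense) and np.isfinite(rg_dilute)


class TestThresholdScan:
    def test_threshold_is_largest_slab_xp(self, monkeypatch):
        from hpcg import phase as ph

        def fake_run(seq, ff, seed=0, a=None, **kw):
            state = "slab" if seq.X_P <= 0.41 else "cluster"
            pp = ph.PhasePoint(seq.X_P, ff.model_kind, 10.0, 1.0, 500.0, 5.0,
                               state, a)
            return pp, None, None

        monkeypatch.setattr(ph, "coexistence_run", fake_run)
        calib = {x: 1.0 for x in (0.0, 0.2, 0.4, 0.6, 0.8)}
        x_star, points = threshold_scan("HP", calib)
        assert x_star == 0.4
        assert len(points) == 5

    def test_degenerate_scan_flags_none(self, monkeypatch):
        from hpcg import phase as ph

        def fake_run(seq, ff, seed=0, a=None, **kw):
            return ph.PhasePoint(seq.X_P, ff.model_kind, 10.0, 1.0, 20.0, 5.0,
                                 "homogeneous", a), None, None

        monkeypatch.setattr(ph, "coexistence_run", fake_run)
        x_star, points = threshold_scan("HP", {0.0: 1.0, 0.5: 1.2})
        assert x_star is None

    def test_missing_calibration_is_dependency_error(self):
        with pytest.raises(KeyError, match="tune"):
            threshold_scan("HP", {0.0: 1.0}, X_P_grid=[0.5])
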