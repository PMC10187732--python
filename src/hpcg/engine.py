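"""System construction and Langevin dynamics propagation.

Bead-spring chains in orthorhombic periodic boxes are propagated with
BAOAB-discretized Langevin dynamics in the low-friction limit (friction
0.1 g/(mol fs), T = 300 K, dt = 10 fs by default).  Small systems (single
chains, chain pairs) use an all-pairs force loop; many-chain systems use a
cell-list-backed Verlet neighbor list.  Given the same seed and inputs the
trajectory is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence as _Seq, Tuple

import numpy as np

from hpcg import _kernels
from hpcg.forcefield import ForceField
from hpcg.sequences import Sequence
from hpcg.units import BEAD_MASS, KB, KCAL_TO_INTERNAL, T_DEFAULT

DT_DEFAULT = 10.0       # fs
GAMMA_DEFAULT = 0.1     # g/(mol fs)
ALLPAIRS_MAX = 200      # particle count below which the all-pairs path is used


@dataclass
class SimState:
    """Instantaneous configuration of a multi-chain system."""

    positions: np.ndarray          # (n, 3) nm, wrapped into the box
    velocities: np.ndarray         # (n, 3) nm/fs
    types: np.ndarray              # (n,) int: 0 = H, 1 = P
    chain_ids: np.ndarray          # (n,) int
    box: np.ndarray                # (3,) nm
    time: float = 0.0              # fs
    rng_seed: Optional[int] = None
    pbc: bool = True

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_ids.max()) + 1

    @property
    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) consecutive-bead bonds within each chain."""
        ids = self.chain_ids
        idx = np.arange(len(ids) - 1)
        mask = ids[:-1] == ids[1:]
        return np.column_stack([idx[mask], idx[mask] + 1]).astype(np.int64)

    def copy(self) -> "SimState":
        return SimState(self.positions.copy(), self.velocities.copy(),
                        self.types.copy(), self.chain_ids.copy(), self.box.copy(),
                        self.time, self.rng_seed, self.pbc)


@dataclass
class Trajectory:
    """Time-ordered frame series from one run."""

    positions: np.ndarray          # (n_frames, n, 3) nm
    velocities: np.ndarray         # (n_frames, n, 3) nm/fs
    potential_energy: np.ndarray   # (n_frames,) kcal/mol
    kinetic_energy: np.ndarray     # (n_frames,) kcal/mol
    types: np.ndarray
    chain_ids: np.ndarray
    box: np.ndarray
    sample_interval: float         # fs
    rng_seed: Optional[int] = None

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def frame(self, i: int) -> SimState:
        return SimState(self.positions[i].copy(), self.velocities[i].copy(),
                        self.types, self.chain_ids, self.box,
                        time=(i + 1) * self.sample_interval, rng_seed=self.rng_seed)

    def kinetic_temperature(self) -> np.ndarray:
        """Instantaneous kinetic temperature per frame, K."""
        n = self.positions.shape[1]
        return 2.0 * self.kinetic_energy / (3.0 * n * KB)

    def discard(self, fraction: float) -> "Trajectory":
        """Drop the first ``fraction`` of frames (equilibration)."""
        k = int(self.n_frames * fraction)
        return replace(self, positions=self.positions[k:], velocities=self.velocities[k:],
                       potential_energy=self.potential_energy[k:],
                       kinetic_energy=self.kinetic_energy[k:])


def _maxwell_boltzmann(n: int, T: float, rng: np.random.Generator) -> np.ndarray:
    scale = np.sqrt(KB * T * KCAL_TO_INTERNAL / BEAD_MASS)
    return rng.normal(0.0, scale, size=(n, 3))


def _chain_coords(N: int, r0: float, rng: np.random.Generator,
                  max_extent: Optional[float] = None) -> np.ndarray:
    """Self-avoiding random walk with step r0; optionally confined to a cube."""
    pos = np.zeros((N, 3))
    for i in range(1, N):
        for _ in range(500):
            v = rng.normal(size=3)
            v *= r0 / np.linalg.norm(v)
            cand = pos[i - 1] + v
            if max_extent is not None and (np.abs(cand) > max_extent / 2).any():
                continue
            d = np.linalg.norm(pos[:i] - cand, axis=1)
            if (d[:-1] > 0.8 * 0.5).all():   # no nonbonded overlap below 0.8 sigma
                pos[i] = cand
                break
        else:
            raise RuntimeError("packing error: could not grow self-avoiding chain")
    return pos


def build_single_chain(seq: Sequence, box: float | _Seq[float] = 50.0,
                       seed: int = 0, T: float = T_DEFAULT) -> SimState:
    """One chain centered in a (large) periodic box."""
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    rng = np.random.default_rng(seed)
    pos = _chain_coords(seq.N, 0.38, rng)
    pos -= pos.mean(axis=0)
    pos += box / 2
    return SimState(pos, _maxwell_boltzmann(seq.N, T, rng),
                    seq.types.astype(np.int64), np.zeros(seq.N, dtype=np.int64),
                    box, rng_seed=seed)


def build_two_chains(seq: Sequence, r_com: float, box: float | _Seq[float] = 30.0,
                     seed: int = 0, T: float = T_DEFAULT) -> SimState:
    """Two copies of ``seq`` with centers of mass ``r_com`` apart (along x)."""
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    rng = np.random.default_rng(seed)
    for _ in range(200):
        a = _chain_coords(seq.N, 0.38, rng)
        b = _chain_coords(seq.N, 0.38, rng)
        a -= a.mean(axis=0)
        b -= b.mean(axis=0)
        b[:, 0] += r_com
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
        if d2.min() > (0.8 * 0.5) ** 2:
            break
    else:
        raise RuntimeError("packing error: chains overlap at requested r_com")
    pos = np.vstack([a, b])
    pos += box / 2 - np.array([r_com / 2, 0, 0])
    types = np.concatenate([seq.types, seq.types]).astype(np.int64)
    cid = np.repeat([0, 1], seq.N).astype(np.int64)
    return SimState(pos, _maxwell_boltzmann(2 * seq.N, T, rng), types, cid,
                    box, rng_seed=seed)


def _lattice_pack(seqs: List[Sequence], box: np.ndarray, region_lo: np.ndarray,
                  region_hi: np.ndarray, rng: np.random.Generator,
                  min_sep: float = 0.42, r0: float = 0.38) -> np.ndarray:
    """Grow self-avoiding chains sequentially inside a box sub-region.

    Every candidate bead must keep ``min_sep`` (~0.8 sigma) from all placed
    beads under the full periodic box; chains that jam are regrown.
    """
    from scipy.spatial import cKDTree

    span = region_hi - region_lo
    constrained = span < box - 1e-9  # axes where the region is a strict sub-box
    placed: List[np.ndarray] = []
    tree = None
    for s in seqs:
        for attempt in range(200):
            chain = np.empty((s.N, 3))
            for _ in range(500):
                start = region_lo + rng.random(3) * span
                if tree is None or tree.query(start % box, k=1)[0] >= min_sep:
                    break
            else:
                continue
            chain[0] = start
            ok = True
            for i in range(1, s.N):
                for _ in range(150):
                    v = rng.normal(size=3)
                    v *= r0 / np.linalg.norm(v)
                    cand = chain[i - 1] + v
                    out = (cand < region_lo) | (cand > region_hi)
                    if (out & constrained).any():
                        continue
                    d_own = np.linalg.norm(chain[:i] - cand, axis=1)
                    if i >= 2 and (d_own[:-1] < min_sep).any():
                        continue
                    if tree is not None:
                        wrapped = cand % box
                        if tree.query(wrapped, k=1)[0] < min_sep:
                            continue
                    chain[i] = cand
                    break
                else:
                    ok = False
                    break
            if ok:
                placed.append(chain)
                all_pos = np.vstack(placed) % box
                tree = cKDTree(all_pos, boxsize=box)
                break
        else:
            raise RuntimeError("packing error: requested density unachievable")
    return np.vstack(placed)


def build_slab(seqs: List[Sequence], box: _Seq[float] = (10.0, 10.0, 75.0),
               slab_fraction: float = 0.22, seed: int = 0,
               T: float = T_DEFAULT) -> SimState:
    """Chains packed into a dense z-central slab of an elongated periodic box.

    ``slab_fraction`` sets the initial slab thickness as a fraction of the z
    edge; the default gives roughly 80% of the dense-phase concentration of
    the purely hydrophobic system for the standard 500-chain geometry.
    """
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    zc = box[2] / 2
    half = slab_fraction * box[2] / 2
    lo = np.array([0.0, 0.0, zc - half])
    hi = np.array([box[0], box[1], zc + half])
    pos = _lattice_pack(seqs, box, lo, hi, rng)
    n = pos.shape[0]
    types = np.concatenate([s.types for s in seqs]).astype(np.int64)
    cid = np.repeat(np.arange(len(seqs)), [s.N for s in seqs]).astype(np.int64)
    pos = pos - box * np.floor(pos / box)
    return SimState(pos, _maxwell_boltzmann(n, T, rng), types, cid, box,
                    rng_seed=seed)


def build_cubic(seqs: List[Sequence], edge: float = 40.0, seed: int = 0,
                T: float = T_DEFAULT) -> SimState:
    """Chains dispersed throughout a cubic periodic box (self-assembly runs)."""
    box = np.array([edge, edge, edge], dtype=float)
    rng = np.random.default_rng(seed)
    pos = _lattice_pack(seqs, box, np.zeros(3), box.copy(), rng)
    types = np.concatenate([s.types for s in seqs]).astype(np.int64)
    cid = np.repeat(np.arange(len(seqs)), [s.N for s in seqs]).astype(np.int64)
    pos = pos - box * np.floor(pos / box)
    return SimState(pos, _maxwell_boltzmann(pos.shape[0], T, rng), types, cid,
                    box, rng_seed=seed)


def run_langevin(state: SimState, ff: ForceField, n_steps: int,
                 dt: float = DT_DEFAULT, gamma: float = GAMMA_DEFAULT,
                 T: float = T_DEFAULT, sample_every: int = 1000,
                 seed: Optional[int] = None, skin: float = 0.4,
                 bias: Optional[Tuple[float, float]] = None) -> Trajectory:
    """Propagate ``state`` for ``n_steps`` of BAOAB Langevin dynamics.

    Parameters
    ----------
    bias : optional (spring_k, r0) harmonic umbrella on the COM distance
        between the first chain and the rest (two-chain PMF sampling);
        U_bias = 0.5 k (d - d0)^2.
    seed : RNG seed for the thermostat noise; falls back to ``state.rng_seed``.
    gamma = 0 disables drag and noise (velocity-Verlet limit, for energy
    conservation checks).

    The input state is not modified.  Raises on non-finite coordinates.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if seed is None:
        seed = state.rng_seed if state.rng_seed is not None else 0
    seed = int(seed) % (2 ** 31)
    st = state.copy()
    pos = np.ascontiguousarray(st.positions, dtype=np.float64)
    vel = np.ascontiguousarray(st.velocities, dtype=np.float64)
    types = np.ascontiguousarray(st.types, dtype=np.int64)
    bonds = np.ascontiguousarray(st.bonds, dtype=np.int64)
    box = np.asarray(st.box, dtype=np.float64)
    lam = np.ascontiguousarray(ff.lambda_array, dtype=np.float64)
    kT = KB * T
    n = pos.shape[0]
    if bias is not None:
        na = int(np.sum(st.chain_ids == 0))
        bk, br0 = float(bias[0]), float(bias[1])
    else:
        na, bk, br0 = 0, -1.0, 0.0
    if n <= ALLPAIRS_MAX or bias is not None:
        fpos, fvel, fpe, fke = _kernels.run_baoab_allpairs(
            pos, vel, types, bonds, box, st.pbc, lam, ff.epsilon, ff.sigma,
            ff.r_cut, ff.k_b, ff.r0, BEAD_MASS, dt, gamma, kT, n_steps,
            sample_every, seed, na, bk, br0)
    else:
        fpos, fvel, fpe, fke = _kernels.run_baoab_nlist(
            pos, vel, types, bonds, box, lam, ff.epsilon, ff.sigma, ff.r_cut,
            ff.k_b, ff.r0, BEAD_MASS, dt, gamma, kT, n_steps, sample_every,
            seed, skin)
    if fpos.shape[0] < n_steps // sample_every:
        raise RuntimeError(
            f"integration error: non-finite coordinates near step "
            f"{(fpos.shape[0] + 1) * sample_every}")
    return Trajectory(fpos, fvel, fpe, fke, types, st.chain_ids, box,
                      sample_interval=sample_every * dt, rng_seed=seed)


def neighbor_pairs(state: SimState, cutoff: float, skin: float = 0.0) -> np.ndarray:
    """(n_pairs, 2) minimum-image pairs within ``cutoff + skin`` (half list)."""
    if cutoff + skin >= state.box.min() / 2:
        raise ValueError("cutoff + skin must be below half the smallest box edge")
    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    box = np.asarray(state.box, dtype=np.float64)
    pi, pj = _kernels.build_pairs_cells(pos, box, cutoff + skin)
    return np.column_stack([pi, pj])


def unwrap_chains(positions: np.ndarray, chain_ids: np.ndarray,
                  box: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping along each chain by minimum-image bond walking."""
    out = positions.copy()
    n = positions.shape[0]
    for i in range(1, n):
        if chain_ids[i] != chain_ids[i - 1]:
            continue
        d = out[i] - out[i - 1]
        d -= box * np.rint(d / box)
        out[i] = out[i - 1] + d
    return out


# ---------------------------------------------------------------------------
# extended-XYZ trajectory I/O (text; box, types and chain ids per frame)

def write_xyz(traj: Trajectory, path) -> None:
    letters = np.where(np.asarray(traj.types) == 0, "H", "P")
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.positions.shape[1]}\n")
            bx, by, bz = traj.box
            fh.write(f'Lattice="{bx} 0 0 0 {by} 0 0 0 {bz}" '
                     f"Properties=species:S:1:pos:R:3:chain:I:1 "
                     f"Time={(f + 1) * traj.sample_interval}\n")
            for i in range(traj.positions.shape[1]):
                x, y, z = traj.positions[f, i]
                fh.write(f"{letters[i]} {x:.6f} {y:.6f} {z:.6f} {traj.chain_ids[i]}\n")


def read_xyz(path) -> Trajectory:
    frames, times = [], []
    types = chain_ids = box = None
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            header = fh.readline()
            lat = header.split('Lattice="')[1].split('"')[0].split()
            box = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
            t = float(header.split("Time=")[1].split()[0]) if "Time=" in header else 0.0
            pos = np.empty((n, 3))
            tp = np.empty(n, dtype=np.int64)
            cid = np.empty(n, dtype=np.int64)
            for i in range(n):
                parts = fh.readline().split()
                tp[i] = 0 if parts[0] == "H" else 1
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
                cid[i] = int(parts[4])
            frames.append(pos)
            times.append(t)
            types, chain_ids = tp, cid
    if not frames:
        raise ValueError(f"no frames found in {path}")
    fpos = np.stack(frames)
    dt = times[1] - times[0] if len(times) > 1 else times[0] or 1.0
    z = np.zeros(len(frames))
    return Trajectory(fpos, np.zeros_like(fpos), z, z.copy(), types, chain_ids,
                      box, sample_interval=dt)
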