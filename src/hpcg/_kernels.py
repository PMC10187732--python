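"""Compiled (numba) kernels: pair interactions, cell/Verlet lists, BAOAB Langevin.

All kernels work in the package's internal units (kcal/mol, nm, fs, g/mol).
Forces returned by the pair loops are in kcal/(mol nm); the integrators
convert to accelerations with the 4.184e-6 kcal -> g nm^2/fs^2 factor.

Exclusions: nonbonded loops receive a per-particle (n, 2) table of directly
bonded partners (-1 padded) and skip those pairs; linear bead-spring chains
have at most two bonded neighbors per bead.
"""

import numpy as np
from numba import njit

KCAL2INT = 4.184e-6
_MIN_R2 = 1e-12  # nm^2 floor; below this pair energies are singular


@njit(cache=True, inline="always", fastmath=True)
def _min_image(dx, dy, dz, bx, by, bz):
    dx -= bx * np.rint(dx / bx)
    dy -= by * np.rint(dy / by)
    dz -= bz * np.rint(dz / bz)
    return dx, dy, dz


@njit(cache=True, inline="always", fastmath=True)
def _min_image_wrapped(dx, dy, dz, bx, by, bz):
    """Minimum image for displacements already within one box length."""
    if dx > 0.5 * bx:
        dx -= bx
    elif dx < -0.5 * bx:
        dx += bx
    if dy > 0.5 * by:
        dy -= by
    elif dy < -0.5 * by:
        dy += by
    if dz > 0.5 * bz:
        dz -= bz
    elif dz < -0.5 * bz:
        dz += bz
    return dx, dy, dz


@njit(cache=True, inline="always", fastmath=True)
def _pair_u_f(r2, lam, eps, sigma, rcut2, rmin2):
    """Energy and force/r for the scaled-LJ pair at squared distance r2."""
    if r2 > rcut2:
        return 0.0, 0.0
    sr2 = sigma * sigma / r2
    sr6 = sr2 * sr2 * sr2
    u_lj = 4.0 * eps * (sr6 * sr6 - sr6)
    fr = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2  # (-dU/dr)/r
    if r2 <= rmin2:
        return u_lj + (1.0 - lam) * eps, fr
    return lam * u_lj, lam * fr


@njit(cache=True)
def nonbonded_energy_allpairs(pos, types, bonds, box, lam, eps, sigma, rcut):
    n = pos.shape[0]
    excl = _excl_table(n, bonds)
    rcut2 = rcut * rcut
    rmin2 = 2.0 ** (1.0 / 3.0) * sigma * sigma
    u = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if excl[i, 0] == j or excl[i, 1] == j:
                continue
            dx, dy, dz = _min_image(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                                    pos[i, 2] - pos[j, 2], box[0], box[1], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < _MIN_R2:
                return np.inf
            du, _ = _pair_u_f(r2, lam[types[i], types[j]], eps, sigma, rcut2, rmin2)
            u += du
    return u


@njit(cache=True)
def _excl_table(n, bonds):
    excl = np.full((n, 2), -1, dtype=np.int64)
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        for k in range(2):
            if excl[i, k] == -1:
                excl[i, k] = j
                break
        for k in range(2):
            if excl[j, k] == -1:
                excl[j, k] = i
                break
    return excl


@njit(cache=True)
def _cell_index(pos, box, ncx, ncy, ncz):
    n = pos.shape[0]
    idx = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / box[0] * ncx) % ncx
        cy = int(pos[i, 1] / box[1] * ncy) % ncy
        cz = int(pos[i, 2] / box[2] * ncz) % ncz
        idx[i] = (cx * ncy + cy) * ncz + cz
    return idx


@njit(cache=True)
def build_pairs_cells(pos, box, cutoff):
    """Half list of minimum-image pairs within cutoff, via a linked cell list."""
    n = pos.shape[0]
    ncx = max(1, int(box[0] / cutoff))
    ncy = max(1, int(box[1] / cutoff))
    ncz = max(1, int(box[2] / cutoff))
    # degenerate cell grids fall back to an all-pairs sweep
    if ncx < 3 or ncy < 3 or ncz < 3:
        cap = n * (n - 1) // 2
        pi = np.empty(cap, dtype=np.int64)
        pj = np.empty(cap, dtype=np.int64)
        cnt = 0
        c2 = cutoff * cutoff
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx, dy, dz = _min_image(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                                        pos[i, 2] - pos[j, 2], box[0], box[1], box[2])
                if dx * dx + dy * dy + dz * dz <= c2:
                    pi[cnt] = i
                    pj[cnt] = j
                    cnt += 1
        return pi[:cnt], pj[:cnt]
    ncell = ncx * ncy * ncz
    cidx = _cell_index(pos, box, ncx, ncy, ncz)
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        c = cidx[i]
        nxt[i] = head[c]
        head[c] = i
    cap = max(1024, n * 128)
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    cnt = 0
    c2 = cutoff * cutoff
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                for ox in range(-1, 2):
                    for oy in range(-1, 2):
                        for oz in range(-1, 2):
                            nx = (cx + ox) % ncx
                            ny = (cy + oy) % ncy
                            nz = (cz + oz) % ncz
                            c2i = (nx * ncy + ny) * ncz + nz
                            if c2i < c:
                                continue
                            i = head[c]
                            while i >= 0:
                                j = head[c2i] if c2i != c else nxt[i]
                                while j >= 0:
                                    dx, dy, dz = _min_image(
                                        pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                                        pos[i, 2] - pos[j, 2], box[0], box[1], box[2])
                                    r2 = dx * dx + dy * dy + dz * dz
                                    if r2 <= c2:
                                        if cnt >= cap:
                                            newcap = cap * 2
                                            npi = np.empty(newcap, dtype=np.int64)
                                            npj = np.empty(newcap, dtype=np.int64)
                                            npi[:cnt] = pi[:cnt]
                                            npj[:cnt] = pj[:cnt]
                                            pi = npi
                                            pj = npj
                                            cap = newcap
                                        if i < j:
                                            pi[cnt] = i
                                            pj[cnt] = j
                                        else:
                                            pi[cnt] = j
                                            pj[cnt] = i
                                        cnt += 1
                                    j = nxt[j]
                                i = nxt[i]
    # duplicates can arise when a neighbor cell wraps onto itself; dedupe
    if cnt > 0:
        keys = pi[:cnt] * n + pj[:cnt]
        order = np.argsort(keys)
        upi = np.empty(cnt, dtype=np.int64)
        upj = np.empty(cnt, dtype=np.int64)
        m = 0
        last = -1
        for k in range(cnt):
            o = order[k]
            key = keys[o]
            if key != last:
                upi[m] = pi[o]
                upj[m] = pj[o]
                m += 1
                last = key
        return upi[:m], upj[:m]
    return pi[:cnt], pj[:cnt]


@njit(cache=True)
def nonbonded_energy_cells(pos, types, bonds, box, lam, eps, sigma, rcut):
    excl = _excl_table(pos.shape[0], bonds)
    pi, pj = build_pairs_cells(pos, box, rcut)
    rcut2 = rcut * rcut
    rmin2 = 2.0 ** (1.0 / 3.0) * sigma * sigma
    u = 0.0
    for k in range(pi.shape[0]):
        i, j = pi[k], pj[k]
        if excl[i, 0] == j or excl[i, 1] == j or excl[j, 0] == i or excl[j, 1] == i:
            continue
        dx, dy, dz = _min_image(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                                pos[i, 2] - pos[j, 2], box[0], box[1], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < _MIN_R2:
            return np.inf
        du, _ = _pair_u_f(r2, lam[types[i], types[j]], eps, sigma, rcut2, rmin2)
        u += du
    return u


@njit(cache=True, fastmath=True)
def _forces_allpairs(pos, types, excl, box, pbc, lam, eps, sigma, rcut,
                     k_b, r0, bonds, forces):
    n = pos.shape[0]
    rcut2 = rcut * rcut
    rmin2 = 2.0 ** (1.0 / 3.0) * sigma * sigma
    forces[:] = 0.0
    u = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if excl[i, 0] == j or excl[i, 1] == j:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if pbc:
                dx, dy, dz = _min_image(dx, dy, dz, box[0], box[1], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > rcut2:
                continue
            du, fr = _pair_u_f(r2, lam[types[i], types[j]], eps, sigma, rcut2, rmin2)
            u += du
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if pbc:
            dx, dy, dz = _min_image(dx, dy, dz, box[0], box[1], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        u += k_b * (r - r0) ** 2
        fr = -2.0 * k_b * (r - r0) / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    return u


@njit(cache=True)
def _com_bias_force(pos, na, bias_k, bias_r0, forces):
    """Harmonic umbrella U = 0.5 k (d - d0)^2 on the COM distance between the
    first ``na`` particles (chain A) and the rest (equal masses assumed)."""
    n = pos.shape[0]
    nb = n - na
    ax = ay = az = 0.0
    for i in range(na):
        ax += pos[i, 0]
        ay += pos[i, 1]
        az += pos[i, 2]
    bx = by = bz = 0.0
    for i in range(na, n):
        bx += pos[i, 0]
        by += pos[i, 1]
        bz += pos[i, 2]
    ax /= na
    ay /= na
    az /= na
    bx /= nb
    by /= nb
    bz /= nb
    dx = bx - ax
    dy = by - ay
    dz = bz - az
    d = np.sqrt(dx * dx + dy * dy + dz * dz)
    if d < 1e-9:
        return 0.0
    pref = bias_k * (d - bias_r0) / d
    # dU/dx_i(A) = -pref * (r_B - r_A) / na  -> force = +pref*(dx)/na on A
    for i in range(na):
        forces[i, 0] += pref * dx / na
        forces[i, 1] += pref * dy / na
        forces[i, 2] += pref * dz / na
    for i in range(na, n):
        forces[i, 0] -= pref * dx / nb
        forces[i, 1] -= pref * dy / nb
        forces[i, 2] -= pref * dz / nb
    return 0.5 * bias_k * (d - bias_r0) ** 2


@njit(cache=True, fastmath=True)
def run_baoab_allpairs(pos, vel, types, bonds, box, pbc, lam, eps, sigma, rcut,
                       k_b, r0, mass, dt, gamma, kT, n_steps, sample_every, seed,
                       bias_na, bias_k, bias_r0):
    """BAOAB Langevin propagation with all-pairs forces (small systems).

    Returns (frames_pos, frames_vel, frames_pe, frames_ke).  ``bias_na > 0``
    switches on the two-group COM-distance umbrella.  With gamma = 0 the
    scheme reduces to velocity Verlet (no noise, no drag).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    excl = _excl_table(n, bonds)
    inv_m = 1.0 / mass
    f2a = KCAL2INT * inv_m  # force (kcal/mol/nm) -> acceleration (nm/fs^2)
    kT_int = kT * KCAL2INT
    if gamma > 0.0:
        c1 = np.exp(-gamma * inv_m * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kT_int * inv_m)
    else:
        c1 = 1.0
        c2 = 0.0
    n_frames = n_steps // sample_every
    fpos = np.empty((n_frames, n, 3))
    fvel = np.empty((n_frames, n, 3))
    fpe = np.empty(n_frames)
    fke = np.empty(n_frames)
    forces = np.zeros((n, 3))
    u = _forces_allpairs(pos, types, excl, box, pbc, lam, eps, sigma, rcut,
                         k_b, r0, bonds, forces)
    if bias_na > 0:
        u += _com_bias_force(pos, bias_na, bias_k, bias_r0, forces)
    frame = 0
    half = 0.5 * dt
    for step in range(n_steps):
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * forces[i, k] * f2a
                pos[i, k] += half * vel[i, k]
        if c2 > 0.0:
            for i in range(n):
                for k in range(3):
                    vel[i, k] = c1 * vel[i, k] + c2 * np.random.normal()
        for i in range(n):
            for k in range(3):
                pos[i, k] += half * vel[i, k]
        u = _forces_allpairs(pos, types, excl, box, pbc, lam, eps, sigma, rcut,
                             k_b, r0, bonds, forces)
        if bias_na > 0:
            u += _com_bias_force(pos, bias_na, bias_k, bias_r0, forces)
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * forces[i, k] * f2a
        if (step + 1) % sample_every == 0:
            ke = 0.0
            for i in range(n):
                for k in range(3):
                    ke += vel[i, k] * vel[i, k]
            ke *= 0.5 * mass / KCAL2INT  # back to kcal/mol
            if (not np.isfinite(pos[0, 0])) or (not np.isfinite(ke)) or ke > 1e8 * n:
                return fpos[:frame], fvel[:frame], fpe[:frame], fke[:frame]
            for i in range(n):
                for k in range(3):
                    fpos[frame, i, k] = pos[i, k]
                    fvel[frame, i, k] = vel[i, k]
            fpe[frame] = u
            fke[frame] = ke
            frame += 1
    return fpos, fvel, fpe, fke


@njit(cache=True, fastmath=True)
def _forces_nlist(pos, types, excl, box, lam, eps, sigma, rcut, k_b, r0,
                  bonds, pi, pj, forces):
    rcut2 = rcut * rcut
    rmin2 = 2.0 ** (1.0 / 3.0) * sigma * sigma
    forces[:] = 0.0
    u = 0.0
    for kk in range(pi.shape[0]):
        i, j = pi[kk], pj[kk]
        if excl[i, 0] == j or excl[i, 1] == j:
            continue
        dx, dy, dz = _min_image_wrapped(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                                        pos[i, 2] - pos[j, 2], box[0], box[1], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > rcut2:
            continue
        du, fr = _pair_u_f(r2, lam[types[i], types[j]], eps, sigma, rcut2, rmin2)
        u += du
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx, dy, dz = _min_image_wrapped(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                                        pos[i, 2] - pos[j, 2], box[0], box[1], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        u += k_b * (r - r0) ** 2
        fr = -2.0 * k_b * (r - r0) / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    return u


@njit(cache=True, fastmath=True)
def run_baoab_nlist(pos, vel, types, bonds, box, lam, eps, sigma, rcut,
                    k_b, r0, mass, dt, gamma, kT, n_steps, sample_every, seed,
                    skin):
    """BAOAB Langevin with a Verlet neighbor list (periodic, large systems)."""
    np.random.seed(seed)
    n = pos.shape[0]
    excl = _excl_table(n, bonds)
    inv_m = 1.0 / mass
    f2a = KCAL2INT * inv_m
    kT_int = kT * KCAL2INT
    if gamma > 0.0:
        c1 = np.exp(-gamma * inv_m * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kT_int * inv_m)
    else:
        c1 = 1.0
        c2 = 0.0
    n_frames = n_steps // sample_every
    fpos = np.empty((n_frames, n, 3))
    fvel = np.empty((n_frames, n, 3))
    fpe = np.empty(n_frames)
    fke = np.empty(n_frames)
    forces = np.zeros((n, 3))
    # wrap before building cells
    for i in range(n):
        for k in range(3):
            pos[i, k] -= box[k] * np.floor(pos[i, k] / box[k])
    pi, pj = build_pairs_cells(pos, box, rcut + skin)
    ref = pos.copy()
    u = _forces_nlist(pos, types, excl, box, lam, eps, sigma, rcut, k_b, r0,
                      bonds, pi, pj, forces)
    frame = 0
    half = 0.5 * dt
    half_skin2 = (0.5 * skin) ** 2
    for step in range(n_steps):
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * forces[i, k] * f2a
                pos[i, k] += half * vel[i, k]
        if c2 > 0.0:
            for i in range(n):
                for k in range(3):
                    vel[i, k] = c1 * vel[i, k] + c2 * np.random.normal()
        for i in range(n):
            for k in range(3):
                pos[i, k] += half * vel[i, k]
        # rebuild check: max squared displacement since last build
        need = False
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            if dx * dx + dy * dy + dz * dz > half_skin2:
                need = True
                break
        if need:
            for i in range(n):
                for k in range(3):
                    pos[i, k] -= box[k] * np.floor(pos[i, k] / box[k])
            pi, pj = build_pairs_cells(pos, box, rcut + skin)
            ref = pos.copy()
        u = _forces_nlist(pos, types, excl, box, lam, eps, sigma, rcut, k_b, r0,
                          bonds, pi, pj, forces)
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * forces[i, k] * f2a
        if (step + 1) % sample_every == 0:
            ke = 0.0
            for i in range(n):
                for k in range(3):
                    ke += vel[i, k] * vel[i, k]
            ke *= 0.5 * mass / KCAL2INT
            if (not np.isfinite(pos[0, 0])) or (not np.isfinite(ke)) or ke > 1e8 * n:
                return fpos[:frame], fvel[:frame], fpe[:frame], fke[:frame]
            for i in range(n):
                wx = pos[i, 0] - box[0] * np.floor(pos[i, 0] / box[0])
                wy = pos[i, 1] - box[1] * np.floor(pos[i, 1] / box[1])
                wz = pos[i, 2] - box[2] * np.floor(pos[i, 2] / box[2])
                fpos[frame, i, 0] = wx
                fpos[frame, i, 1] = wy
                fpos[frame, i, 2] = wz
                for k in range(3):
                    fvel[frame, i, k] = vel[i, k]
            fpe[frame] = u
            fke[frame] = ke
            frame += 1
    return fpos, fvel, fpe, fke


@njit(cache=True)
def chain_adjacency(pos, chain_ids, box, cutoff, n_chains):
    """Boolean chain-chain contact matrix: any inter-chain monomer pair < cutoff."""
    adj = np.zeros((n_chains, n_chains), dtype=np.bool_)
    pi, pj = build_pairs_cells(pos, box, cutoff)
    for k in range(pi.shape[0]):
        ci = chain_ids[pi[k]]
        cj = chain_ids[pj[k]]
        if ci != cj:
            adj[ci, cj] = True
            adj[cj, ci] = True
    return adj


@njit(cache=True)
def rdf_histogram(pos, box, r_max, n_bins):
    """Raw pair-distance histogram (minimum image) for g(r) normalization."""
    n = pos.shape[0]
    hist = np.zeros(n_bins, dtype=np.int64)
    dr = r_max / n_bins
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx, dy, dz = _min_image(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                                    pos[i, 2] - pos[j, 2], box[0], box[1], box[2])
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < r_max:
                hist[int(r / dr)] += 1
    return hist
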