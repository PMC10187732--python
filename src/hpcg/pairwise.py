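"""Two-chain potential of mean force and the second virial coefficient.

The dilute chain-chain PMF ``w(r)`` along the center-of-mass separation is
sampled with harmonic umbrella windows combined by WHAM; the radial Jacobian
(4 pi r^2) is divided out so that ``w`` is the pair free energy entering the
virial integral

    B22 = -2 pi \\int [exp(-w(r)/kT) - 1] r^2 dr.

A Mayer-sampling estimator over rigid single-chain conformation pools serves
as an independent cross-check of the umbrella route.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence as _Seq, Tuple, Union

import numpy as np

from hpcg.engine import SimState, run_langevin, unwrap_chains, _maxwell_boltzmann, _chain_coords
from hpcg.forcefield import ForceField
from hpcg.sequences import Sequence
from hpcg.units import KB, T_DEFAULT

R_MIN_DEFAULT = 0.4    # nm
R_MAX_DEFAULT = 6.0    # nm
SPACING_DEFAULT = 0.2  # nm
SPRING_DEFAULT = 5.0   # kcal/(mol nm^2); U_bias = 0.5 k (d - d0)^2


@dataclass
class PMFCurve:
    """w(r) on a COM-distance grid, zeroed at large separation."""

    r_grid: np.ndarray     # nm, strictly increasing
    w: np.ndarray          # kcal/mol
    se: np.ndarray         # kcal/mol

    def __post_init__(self):
        if not (np.diff(self.r_grid) > 0).all():
            raise ValueError("r_grid must be strictly increasing")


def _monomer_string(seq: Union[Sequence, str]) -> str:
    return seq.monomers if isinstance(seq, Sequence) else str(seq)


def _pair_state(monomers: str, r_com: float, box: float, seed: int,
                T: float = T_DEFAULT) -> SimState:
    """Two copies of a monomer string (length >= 1) at COM distance r_com.

    Periodic boundaries are off: the PMF is defined at infinite dilution.
    """
    n = len(monomers)
    rng = np.random.default_rng(seed)
    types1 = np.frombuffer(monomers.encode(), dtype=np.uint8) == ord("P")
    if n == 1:
        a = np.zeros((1, 3))
        b = np.array([[r_com, 0.0, 0.0]])
    else:
        for _ in range(200):
            a = _chain_coords(n, 0.38, rng)
            b = _chain_coords(n, 0.38, rng)
            a -= a.mean(axis=0)
            b -= b.mean(axis=0)
            b[:, 0] += r_com
            d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
            if d2.min() > 0.16:
                break
    pos = np.vstack([a, b]) + box / 2
    types = np.concatenate([types1, types1]).astype(np.int64)
    cid = np.repeat([0, 1], n).astype(np.int64)
    st = SimState(pos, _maxwell_boltzmann(2 * n, T, rng), types, cid,
                  np.full(3, float(box)), rng_seed=seed, pbc=False)
    return st


def _com_distance_series(traj, n_per_chain: int) -> np.ndarray:
    a = traj.positions[:, :n_per_chain, :].mean(axis=1)
    b = traj.positions[:, n_per_chain:, :].mean(axis=1)
    return np.linalg.norm(b - a, axis=1)


def _wham(samples: List[np.ndarray], centers: np.ndarray, spring_k: float,
          edges: np.ndarray, kT: float, tol: float = 1e-8,
          max_iter: int = 50_000) -> np.ndarray:
    """Self-consistent WHAM on binned COM-distance samples.

    Returns the unnormalized distance distribution P(r) on bin midpoints.
    """
    n_win = len(samples)
    n_bins = edges.size - 1
    mids = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros((n_win, n_bins))
    for k, s in enumerate(samples):
        counts[k], _ = np.histogram(s, bins=edges)
    # adjacent-window overlap check
    for k in range(n_win - 1):
        if not ((counts[k] > 0) & (counts[k + 1] > 0)).any():
            raise RuntimeError(
                f"coverage error: umbrella windows at {centers[k]:.2f} and "
                f"{centers[k + 1]:.2f} nm have non-overlapping histograms")
    n_k = counts.sum(axis=1)
    total = counts.sum(axis=0)
    bias = 0.5 * spring_k * (mids[None, :] - centers[:, None]) ** 2  # (win, bin)
    boltz = np.exp(-bias / kT)
    f = np.zeros(n_win)
    for _ in range(max_iter):
        denom = (n_k[:, None] * np.exp(f[:, None] / kT) * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        zk = (p[None, :] * boltz).sum(axis=1)
        f_new = -kT * np.log(np.maximum(zk, 1e-300))
        f_new -= f_new[0]
        if np.abs(f_new - f).max() < tol:
            f = f_new
            break
        f = f_new
    denom = (n_k[:, None] * np.exp(f[:, None] / kT) * boltz).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, total / denom, 0.0)
    return p


def umbrella_pmf(seq: Union[Sequence, str], ff: ForceField,
                 windows: Optional[np.ndarray] = None,
                 spring_k: float = SPRING_DEFAULT,
                 steps_per_window: int = 400_000,
                 seed: int = 0, T: float = T_DEFAULT,
                 sample_every: int = 200, bin_width: float = 0.05,
                 equilibration: float = 0.2, n_blocks: int = 5) -> PMFCurve:
    """Umbrella-sampled PMF of the chain-chain COM distance.

    One Langevin run per window with a harmonic COM-distance bias; window
    histograms are combined with WHAM, the 4 pi r^2 Jacobian divided out,
    and the curve shifted so the mean over the outer 10% of the grid is zero.
    Per-point SE comes from repeating WHAM on contiguous sample blocks.
    """
    mono = _monomer_string(seq)
    n = len(mono)
    if windows is None:
        windows = np.arange(R_MIN_DEFAULT, R_MAX_DEFAULT + 1e-9, SPACING_DEFAULT)
    windows = np.asarray(windows, dtype=float)
    kT = KB * T
    box = 2 * windows.max() + 6.0
    all_samples: List[np.ndarray] = []
    ss = np.random.SeedSequence(seed)
    win_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(windows))]
    for k, d0 in enumerate(windows):
        st = _pair_state(mono, d0, box, win_seeds[k], T)
        traj = run_langevin(st, ff, steps_per_window, sample_every=sample_every,
                            seed=win_seeds[k], bias=(spring_k, d0), T=T)
        d = _com_distance_series(traj, n)
        all_samples.append(d[int(len(d) * equilibration):])
    lo = max(1e-3, windows.min() - 1.0)
    edges = np.arange(lo, windows.max() + 1.0 + bin_width, bin_width)
    mids = 0.5 * (edges[:-1] + edges[1:])
    counts_total = np.zeros(mids.size)
    for s in all_samples:
        counts_total += np.histogram(s, bins=edges)[0]

    def pmf_from(samples):
        p = _wham(samples, windows, spring_k, edges, kT)
        with np.errstate(divide="ignore"):
            w = -kT * np.log(np.where(p > 0, p / mids ** 2, np.nan))
        return w

    w_full = pmf_from(all_samples)
    # block SE: WHAM repeated on contiguous blocks of every window's samples
    blocks = []
    for b in range(n_blocks):
        sub = []
        for s in all_samples:
            m = len(s) // n_blocks
            sub.append(s[b * m:(b + 1) * m])
        try:
            blocks.append(pmf_from(sub))
        except RuntimeError:
            pass
    if blocks:
        bstack = np.vstack(blocks)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            se = np.nanstd(bstack, axis=0, ddof=0) / np.sqrt(len(blocks))
    else:
        se = np.full_like(w_full, np.nan)
    # keep only well-sampled bins inside the window span: bins beyond the
    # outermost center are visited only by one spring tail and their noise
    # would contaminate the zero-shift
    min_count = max(20.0, 0.02 * np.median(counts_total[counts_total > 0]))
    good = np.isfinite(w_full) & (counts_total >= min_count) & (mids <= windows.max())
    r, w, se = mids[good], w_full[good], se[good]
    tail = r >= r[0] + 0.9 * (r[-1] - r[0])
    w = w - w[tail].mean()
    return PMFCurve(r, w, np.where(np.isfinite(se), se, np.nanmax(se[np.isfinite(se)]) if np.isfinite(se).any() else 0.0))


def conformation_pool(seq: Union[Sequence, str], ff: ForceField, n_conf: int = 200,
                      seed: int = 0, T: float = T_DEFAULT,
                      steps_between: int = 20_000) -> np.ndarray:
    """(n_conf, N, 3) pool of single-chain conformations, COM at the origin."""
    from hpcg.engine import build_single_chain

    mono = _monomer_string(seq)
    if len(mono) == 1:
        return np.zeros((1, 1, 3))
    s = seq if isinstance(seq, Sequence) else Sequence(mono, label="pool")
    st = build_single_chain(s, box=50.0, seed=seed)
    traj = run_langevin(st, ff, steps_between * (n_conf + n_conf // 4),
                        sample_every=steps_between, seed=seed, T=T)
    coords = traj.positions[-n_conf:]
    coords = coords - coords.mean(axis=1, keepdims=True)
    return coords


def _random_rotations(n: int, rng) -> np.ndarray:
    """(n, 3, 3) uniform random rotation matrices (quaternion method)."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def _interchain_energy(a: np.ndarray, b: np.ndarray, ta: np.ndarray,
                       tb: np.ndarray, ff: ForceField) -> np.ndarray:
    """Pairwise scaled-LJ energy between conformation batches a and b.

    a, b: (n_samp, N, 3); returns (n_samp,)."""
    d2 = ((a[:, :, None, :] - b[:, None, :, :]) ** 2).sum(-1)
    lam = ff.lambda_array[ta][:, tb]  # (N, N)
    rmin2 = 2 ** (1 / 3) * ff.sigma ** 2
    sr6 = (ff.sigma ** 2 / np.maximum(d2, 1e-12)) ** 3
    u_lj = 4 * ff.epsilon * (sr6 * sr6 - sr6)
    u = np.where(d2 <= rmin2, u_lj + (1 - lam) * ff.epsilon,
                 np.where(d2 <= ff.r_cut ** 2, lam * u_lj, 0.0))
    return u.sum(axis=(1, 2))


def mayer_oracle(seq: Union[Sequence, str], ff: ForceField,
                 r_grid: Optional[np.ndarray] = None, n_samples: int = 2000,
                 seed: int = 0, T: float = T_DEFAULT,
                 pool: Optional[np.ndarray] = None,
                 n_boot: int = 50) -> PMFCurve:
    """Rigid-conformation Mayer estimate of w(r).

    w(r) = -kT ln < exp(-dU/kT) > over random conformation pairs and
    orientations at fixed COM distance r.  SE by bootstrap resampling.
    """
    mono = _monomer_string(seq)
    if r_grid is None:
        r_grid = np.arange(R_MIN_DEFAULT, R_MAX_DEFAULT + 1e-9, SPACING_DEFAULT)
    r_grid = np.asarray(r_grid, dtype=float)
    kT = KB * T
    if pool is None:
        pool = conformation_pool(seq, ff, seed=seed, T=T)
    rng = np.random.default_rng(seed + 1)
    ta = (np.frombuffer(mono.encode(), dtype=np.uint8) == ord("P")).astype(np.int64)
    w = np.empty(r_grid.size)
    se = np.empty(r_grid.size)
    for k, r in enumerate(r_grid):
        ia = rng.integers(0, pool.shape[0], n_samples)
        ib = rng.integers(0, pool.shape[0], n_samples)
        Ra = _random_rotations(n_samples, rng)
        Rb = _random_rotations(n_samples, rng)
        a = np.einsum("sij,snj->sni", Ra, pool[ia])
        b = np.einsum("sij,snj->sni", Rb, pool[ib])
        b = b + np.array([r, 0.0, 0.0])
        du = _interchain_energy(a, b, ta, ta, ff)
        boltz = np.exp(-du / kT)
        mean = boltz.mean()
        if mean <= 0 or not np.isfinite(mean):
            raise RuntimeError(f"sampling error: Mayer average underflow at r={r}")
        w[k] = -kT * np.log(mean)
        bs = rng.integers(0, n_samples, (n_boot, n_samples))
        bm = boltz[bs].mean(axis=1)
        se[k] = kT * np.std(np.log(np.maximum(bm, 1e-300)), ddof=0)
    w -= w[-1]
    return PMFCurve(r_grid, w, se)


def effective_sample_size(seq: Union[Sequence, str], ff: ForceField, r: float,
                          n_samples: int = 2000, seed: int = 0,
                          T: float = T_DEFAULT,
                          pool: Optional[np.ndarray] = None) -> float:
    """Kish effective sample size of the Mayer weights at distance r."""
    mono = _monomer_string(seq)
    kT = KB * T
    if pool is None:
        pool = conformation_pool(seq, ff, seed=seed, T=T)
    rng = np.random.default_rng(seed + 1)
    ta = (np.frombuffer(mono.encode(), dtype=np.uint8) == ord("P")).astype(np.int64)
    ia = rng.integers(0, pool.shape[0], n_samples)
    ib = rng.integers(0, pool.shape[0], n_samples)
    a = np.einsum("sij,snj->sni", _random_rotations(n_samples, rng), pool[ia])
    b = np.einsum("sij,snj->sni", _random_rotations(n_samples, rng), pool[ib])
    b = b + np.array([r, 0.0, 0.0])
    wgt = np.exp(-_interchain_energy(a, b, ta, ta, ff) / kT)
    return float(wgt.sum() ** 2 / (wgt ** 2).sum())


def b22(pmf: PMFCurve, T: float = T_DEFAULT,
        tail_tolerance: float = 0.05) -> Tuple[float, float]:
    """Second virial coefficient (nm^3) from a PMF by trapezoidal quadrature.

    B22 = -2 pi int [exp(-w/kT) - 1] r^2 dr, with the region below the first
    sampled distance treated as a hard core (integrand -r^2) and w = 0 beyond
    the grid.  Returns (B22, propagated SE).
    """
    kT = KB * T
    r, w = pmf.r_grid, pmf.w
    if abs(w[-1]) > tail_tolerance:
        raise RuntimeError(
            f"unconverged tail: |w(r_max)| = {abs(w[-1]):.3g} kcal/mol > {tail_tolerance}")
    mayer = np.exp(-w / kT) - 1.0
    integral = np.trapezoid(mayer * r ** 2, r)
    hard_core = -(r[0] ** 3) / 3.0
    val = -2.0 * np.pi * (integral + hard_core)
    dIdw = 2.0 * np.pi / kT * np.exp(-w / kT) * r ** 2
    # trapezoid weights
    dr = np.gradient(r)
    se = float(np.sqrt(np.nansum((dIdw * dr * np.nan_to_num(pmf.se)) ** 2)))
    return float(val), se
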