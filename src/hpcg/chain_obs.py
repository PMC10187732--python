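"""Single-chain ensemble observables.

Size and shape come from the per-frame gyration tensor; chain dynamics from
the end-to-end vector autocorrelation; statistical errors from five-block
averaging of the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import gamma as _gamma_fn

from hpcg.engine import Trajectory, unwrap_chains


@dataclass
class ChainEnsembleStats:
    """Summary of a single-chain ensemble."""

    mean_Rg: float                 # nm
    se_Rg: float
    Rg_hist: Tuple[np.ndarray, np.ndarray]  # (density, bin_edges)
    kappa2: float
    se_kappa2: float
    U_nb_mean: float               # kcal/mol
    se_U_nb: float
    tau_e: Optional[float]         # ns, None if not requested/convergent
    nu: Optional[float]
    n_blocks: int = 5


def _check_unwrapped(coords: np.ndarray, box: Optional[np.ndarray]) -> None:
    if box is None:
        return
    bl = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if (bl > box.min() / 4).any():
        raise ValueError("chain appears wrapped across the periodic box; unwrap first")


def gyration_tensor(coords: np.ndarray, box: Optional[np.ndarray] = None) -> np.ndarray:
    """Mass-weighted (equal masses) gyration tensor of one chain, nm^2."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 particles")
    _check_unwrapped(coords, box)
    d = coords - coords.mean(axis=0)
    return d.T @ d / coords.shape[0]


def radius_of_gyration(coords: np.ndarray, box: Optional[np.ndarray] = None) -> float:
    """R_g = sqrt(trace of the gyration tensor), nm."""
    return float(np.sqrt(np.trace(gyration_tensor(coords, box))))


def shape_anisotropy(eigenvalues: np.ndarray) -> float:
    """kappa^2 = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1 + l2 + l3)^2.

    0 for spherically symmetric mass distributions, 1 for a rod.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    if (lam < -1e-12).any():
        raise ValueError("gyration-tensor eigenvalues must be non-negative")
    s = lam.sum()
    if s <= 0:
        raise ValueError("undefined shape: all eigenvalues are zero")
    return float(1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / s ** 2)


def block_error(series: np.ndarray, n_blocks: int = 5) -> Tuple[float, float]:
    """Mean and block standard error of a correlated series.

    The series is cut into ``n_blocks`` contiguous equal blocks (remainder
    dropped from the front); SE = std(block means) / sqrt(n_blocks).
    """
    x = np.asarray(series, dtype=float)
    if x.size < n_blocks:
        raise ValueError(f"series of length {x.size} shorter than {n_blocks} blocks")
    m = x.size // n_blocks
    x = x[x.size - m * n_blocks:]
    bm = x.reshape(n_blocks, m).mean(axis=1)
    return float(x.mean()), float(bm.std(ddof=0) / np.sqrt(n_blocks))


def _per_frame_chain_coords(traj: Trajectory, chain: int = 0) -> np.ndarray:
    sel = np.asarray(traj.chain_ids) == chain
    out = np.empty((traj.n_frames, sel.sum(), 3))
    for f in range(traj.n_frames):
        coords = unwrap_chains(traj.positions[f], traj.chain_ids, traj.box)
        out[f] = coords[sel]
    return out


def rg_series(traj: Trajectory, chain: int = 0) -> np.ndarray:
    """Per-frame R_g of one chain, nm."""
    coords = _per_frame_chain_coords(traj, chain)
    d = coords - coords.mean(axis=1, keepdims=True)
    return np.sqrt((d ** 2).sum(axis=(1, 2)) / coords.shape[1])


def kappa2_series(traj: Trajectory, chain: int = 0) -> np.ndarray:
    coords = _per_frame_chain_coords(traj, chain)
    d = coords - coords.mean(axis=1, keepdims=True)
    tensors = np.einsum("fni,fnj->fij", d, d) / coords.shape[1]
    lam = np.linalg.eigvalsh(tensors)
    s = lam.sum(axis=1)
    return 1.0 - 3.0 * (lam[:, 0] * lam[:, 1] + lam[:, 1] * lam[:, 2]
                        + lam[:, 2] * lam[:, 0]) / s ** 2


def end_to_end_relaxation(traj: Trajectory, chain: int = 0,
                          max_lag_fraction: float = 0.25) -> Tuple[float, dict]:
    """Relaxation time tau_e (ns) of the end-to-end vector ACF.

    The normalized autocorrelation is fitted to a stretched exponential
    exp[-(t/tau0)^beta]; the reported relaxation time is the integral
    tau_e = (tau0/beta) Gamma(1/beta).  Returns (tau_e, diagnostics).
    """
    coords = _per_frame_chain_coords(traj, chain)
    e2e = coords[:, -1, :] - coords[:, 0, :]
    nf = e2e.shape[0]
    max_lag = max(3, int(nf * max_lag_fraction))
    # FFT-based vector autocorrelation
    x = e2e - 0.0
    acf = np.zeros(max_lag)
    for k in range(3):
        a = x[:, k]
        fa = np.fft.rfft(a, n=2 * nf)
        c = np.fft.irfft(fa * np.conj(fa))[:max_lag]
        acf += c.real
    acf /= (nf - np.arange(max_lag))
    acf /= acf[0]
    t = np.arange(max_lag) * traj.sample_interval * 1e-6  # ns
    if acf.min() > 1.0 / np.e:
        raise RuntimeError("insufficient sampling: ACF does not decay below 1/e")
    # fit over the decaying head (down to where ACF first drops below 0.02)
    below = np.nonzero(acf < 0.02)[0]
    stop = below[0] if below.size else max_lag
    stop = max(stop, 5)

    def f(tt, tau0, beta):
        return np.exp(-(tt / tau0) ** np.clip(beta, 0.05, 2.0))

    p0 = (max(t[np.searchsorted(-acf[:stop], -1 / np.e)], t[1]), 1.0)
    popt, pcov = curve_fit(f, t[:stop], acf[:stop], p0=p0, maxfev=20000)
    tau0, beta = popt
    beta = float(np.clip(beta, 0.05, 2.0))
    tau_e = float(tau0 / beta * _gamma_fn(1.0 / beta))
    diag = {"tau0_ns": float(tau0), "beta": beta,
            "rmse": float(np.sqrt(np.mean((f(t[:stop], *popt) - acf[:stop]) ** 2))),
            "acf": acf, "t_ns": t}
    return tau_e, diag


def intrachain_scaling(traj: Trajectory, chain: int = 0,
                       sep_range: Optional[Tuple[int, int]] = None) -> Tuple[float, float]:
    """Intrachain distance scaling exponent nu.

    Fits log sqrt(<R^2(s)>) vs log s for monomer separations s = |i - j|
    in ``sep_range`` (default [3, N-1]).  Returns (nu, fit standard error).
    """
    coords = _per_frame_chain_coords(traj, chain)
    N = coords.shape[1]
    if N < 10:
        raise ValueError("chain too short for a scaling fit (need N >= 10)")
    lo, hi = sep_range if sep_range is not None else (3, N - 1)
    seps = np.arange(lo, hi + 1)
    if seps.size < 4:
        raise ValueError("fewer than 4 separations available for the fit")
    msd = np.empty(seps.size)
    for k, s in enumerate(seps):
        d = coords[:, s:, :] - coords[:, :-s, :] if s < N else None
        msd[k] = (d ** 2).sum(-1).mean()
    logs, logr = np.log(seps), 0.5 * np.log(msd)
    A = np.vstack([logs, np.ones_like(logs)]).T
    coef, res, *_ = np.linalg.lstsq(A, logr, rcond=None)
    nu = float(coef[0])
    dof = max(1, seps.size - 2)
    resid = logr - A @ coef
    s2 = (resid ** 2).sum() / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    return nu, float(np.sqrt(cov[0, 0]))


def u_nb_series(traj: Trajectory, ff) -> np.ndarray:
    """Per-frame nonbonded potential energy U_nb, kcal/mol."""
    from hpcg.forcefield import system_nonbonded_energy

    return np.array([system_nonbonded_energy(traj.frame(f), ff)
                     for f in range(traj.n_frames)])


def rg_histogram(rg: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Probability density of R_g with Scott-rule bins; integrates to 1."""
    n = rg.size
    width = 3.49 * rg.std(ddof=0) / n ** (1 / 3)
    n_bins = max(10, int(np.ceil((rg.max() - rg.min()) / max(width, 1e-9))))
    dens, edges = np.histogram(rg, bins=n_bins, density=True)
    return dens, edges


def bhattacharyya_overlap(rg_a: np.ndarray, rg_b: np.ndarray, n_bins: int = 40) -> float:
    """Bhattacharyya coefficient between two R_g samples on a common grid."""
    lo = min(rg_a.min(), rg_b.min())
    hi = max(rg_a.max(), rg_b.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(rg_a, bins=edges, density=True)
    pb, _ = np.histogram(rg_b, bins=edges, density=True)
    w = np.diff(edges)
    return float(np.sum(np.sqrt(pa * pb) * w))


def chain_ensemble_stats(traj: Trajectory, chain: int = 0, n_blocks: int = 5,
                         ff=None, with_tau_e: bool = False,
                         with_nu: bool = False) -> ChainEnsembleStats:
    """All single-chain summary observables from one trajectory."""
    rg = rg_series(traj, chain)
    k2 = kappa2_series(traj, chain)
    mean_rg, se_rg = block_error(rg, n_blocks)
    mean_k2, se_k2 = block_error(k2, n_blocks)
    if ff is not None:
        u = u_nb_series(traj, ff)
    else:
        u = traj.potential_energy  # includes bond energy
    u_mean, u_se = block_error(u, n_blocks)
    tau = nu = None
    if with_tau_e:
        tau, _ = end_to_end_relaxation(traj, chain)
    if with_nu:
        nu, _ = intrachain_scaling(traj, chain)
    return ChainEnsembleStats(mean_rg, se_rg, rg_histogram(rg), mean_k2, se_k2,
                              u_mean, u_se, tau, nu, n_blocks)
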