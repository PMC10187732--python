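"""Direct-coexistence and self-assembly analysis.

Slab trajectories yield z-resolved concentration profiles; a symmetric
hyperbolic-tangent fit extracts the coexisting dilute and dense
concentrations.  Chains are clustered by inter-chain monomer contacts
(default cutoff 1.5 sigma) and the probability of finding a chain in a
cluster of size N_c distinguishes bulk slabs from finite clusters.  Sweeping
the polar fraction locates the threshold X_P* above which no bulk condensed
phase forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from hpcg import _kernels
from hpcg.engine import SimState, Trajectory, build_slab, run_langevin, unwrap_chains
from hpcg.forcefield import ForceField, default_forcefield, scaled_lambda_H
from hpcg.sequences import Sequence, generate_sequence
from hpcg.units import BEAD_MASS, number_density_to_mg_per_ml

logger = logging.getLogger(__name__)

CONTACT_CUTOFF_SIGMA = 1.5


@dataclass
class DensityProfile:
    """z-binned mass concentration of a slab system."""

    z_bins: np.ndarray          # bin centers, nm (slab-centered frame)
    concentration: np.ndarray   # mg/mL
    se: np.ndarray              # mg/mL
    total_concentration: float  # mg/mL
    box: np.ndarray
    n_particles: int


@dataclass
class PhasePoint:
    """One point of the phase diagram."""

    X_P: float
    model: str
    c_dilute: float
    c_dilute_se: float
    c_dense: float
    c_dense_se: float
    state: str                  # slab | cluster | homogeneous
    a: Optional[float] = None
    indeterminate: bool = False


@dataclass
class ClusterSizeDistribution:
    """Probability that a chain resides in a cluster of size N_c."""

    N_c: np.ndarray
    P: np.ndarray
    se: np.ndarray

    def __post_init__(self):
        if abs(self.P.sum() - 1.0) > 1e-6:
            raise ValueError("P(N_c) must sum to 1")


def _circular_center(z: np.ndarray, Lz: float) -> float:
    """Center of a possibly wrapped mass distribution via circular mean."""
    theta = 2 * np.pi * z / Lz
    return float(Lz * np.arctan2(np.sin(theta).mean(), np.cos(theta).mean()) / (2 * np.pi)) % Lz


def density_profile(traj: Trajectory, bin_width: float = 0.5,
                    center: bool = True, n_blocks: int = 5) -> DensityProfile:
    """Time-averaged mass concentration profile along z.

    When ``center`` is set, each frame is shifted so the z center of mass of
    the largest chain cluster sits at the box middle before binning, which
    prevents slab drift from smearing the interfaces.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    box = traj.box
    Lz = box[2]
    n_bins = max(4, int(round(Lz / bin_width)))
    edges = np.linspace(0, Lz, n_bins + 1)
    vol_bin = box[0] * box[1] * Lz / n_bins
    counts = np.zeros((traj.n_frames, n_bins))
    cutoff = CONTACT_CUTOFF_SIGMA * 0.5
    for f in range(traj.n_frames):
        z = traj.positions[f, :, 2].copy()
        if center:
            labels = cluster_chains(traj.frame(f), contact_cutoff=cutoff)
            sizes = np.bincount(labels)
            big = np.argmax(sizes)
            members = np.isin(traj.chain_ids, np.nonzero(labels == big)[0])
            zc = _circular_center(z[members], Lz)
            z = (z - zc + Lz / 2) % Lz
        counts[f], _ = np.histogram(z, bins=edges)
    conc = counts / vol_bin  # number density per bin
    conc = number_density_to_mg_per_ml(conc)
    mean = conc.mean(axis=0)
    m = traj.n_frames // n_blocks
    # block SE (correlation-aware) with a per-frame-statistics floor, which
    # stabilizes the estimate when only a handful of blocks are available
    frame_se = conc.std(axis=0, ddof=0) / np.sqrt(max(traj.n_frames, 1))
    if m >= 1:
        bm = conc[traj.n_frames - m * n_blocks:].reshape(n_blocks, m, n_bins).mean(axis=1)
        se = np.maximum(bm.std(axis=0, ddof=0) / np.sqrt(n_blocks), frame_se)
    else:
        se = frame_se
    n = traj.positions.shape[1]
    total = number_density_to_mg_per_ml(n / box.prod())
    return DensityProfile(0.5 * (edges[:-1] + edges[1:]) - Lz / 2, mean, se,
                          total, box, n)


def _tanh_profile(z, c_d, c_l, z0, d):
    return 0.5 * (c_d + c_l) - 0.5 * (c_d - c_l) * np.tanh((np.abs(z) - z0) / d)


def extract_coexistence(profile: DensityProfile) -> Tuple[float, float, dict]:
    """Coexistence concentrations from a symmetric tanh fit of the profile.

    Returns (c_dilute, c_dense, diagnostics); raises on non-convergence or
    inverted plateaus.
    """
    z, c = profile.z_bins, profile.concentration
    c_d0 = np.percentile(c, 95)
    c_l0 = np.percentile(c, 10)
    z00 = max(1.0, np.abs(z[c > 0.5 * (c_d0 + c_l0)]).max() if (c > 0.5 * (c_d0 + c_l0)).any() else 2.0)
    try:
        popt, pcov = curve_fit(_tanh_profile, z, c, p0=(c_d0, c_l0, z00, 1.0),
                               maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"classification error: tanh fit did not converge ({exc})")
    c_d, c_l, z0, d = popt
    d = abs(d)
    if c_d <= c_l:
        raise RuntimeError("classification error: inverted plateaus (no dense slab)")
    perr = np.sqrt(np.abs(np.diag(pcov)))
    resid = c - _tanh_profile(z, *popt)
    diag = {"z0": float(z0), "width": float(d), "perr": perr,
            "rmse": float(np.sqrt((resid ** 2).mean())),
            "plateau_width": float(2 * z0)}
    return float(c_l), float(c_d), diag


def cluster_chains(frame: SimState, contact_cutoff: Optional[float] = None,
                   sigma: float = 0.5) -> np.ndarray:
    """Cluster label per chain; two chains join a cluster when any inter-chain
    monomer pair is closer than the contact cutoff (default 1.5 sigma)."""
    cutoff = contact_cutoff if contact_cutoff is not None else CONTACT_CUTOFF_SIGMA * sigma
    if cutoff >= frame.box.min() / 2:
        raise ValueError("contact cutoff must be below half the smallest box edge")
    n_chains = frame.n_chains
    adj = _kernels.chain_adjacency(
        np.ascontiguousarray(frame.positions, dtype=np.float64),
        np.ascontiguousarray(frame.chain_ids, dtype=np.int64),
        np.asarray(frame.box, dtype=np.float64), cutoff, n_chains)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def cluster_size_distribution(traj: Trajectory,
                              contact_cutoff: Optional[float] = None,
                              n_blocks: int = 5) -> ClusterSizeDistribution:
    """Chain-weighted P(N_c) time-averaged over the trajectory."""
    n_chains = int(traj.chain_ids.max()) + 1
    per_frame = np.zeros((traj.n_frames, n_chains + 1))
    for f in range(traj.n_frames):
        labels = cluster_chains(traj.frame(f), contact_cutoff)
        sizes = np.bincount(labels)
        for s in sizes:
            per_frame[f, s] += s  # chain-weighted: s chains live in this cluster
    per_frame /= n_chains
    mean = per_frame.mean(axis=0)
    m = traj.n_frames // n_blocks
    if m >= 1:
        bm = per_frame[traj.n_frames - m * n_blocks:].reshape(
            n_blocks, m, n_chains + 1).mean(axis=1)
        se = bm.std(axis=0, ddof=0) / np.sqrt(n_blocks)
    else:
        se = np.zeros(n_chains + 1)
    keep = np.nonzero(mean > 0)[0]
    P = mean[keep]
    return ClusterSizeDistribution(keep, P / P.sum(), se[keep])


def largest_cluster_fraction(traj: Trajectory,
                             contact_cutoff: Optional[float] = None) -> float:
    """Mean fraction of chains in the largest cluster."""
    n_chains = int(traj.chain_ids.max()) + 1
    fr = []
    for f in range(traj.n_frames):
        labels = cluster_chains(traj.frame(f), contact_cutoff)
        fr.append(np.bincount(labels).max() / n_chains)
    return float(np.mean(fr))


def classify_phase_state(profile: DensityProfile,
                         cluster_fraction: float,
                         min_plateau_widths: float = 4.0,
                         largest_fraction_threshold: float = 0.9) -> Tuple[str, dict]:
    """Classify a coexistence run as slab, cluster, or homogeneous.

    slab: the tanh fit converges, the dense plateau is at least
    ``min_plateau_widths`` interface widths wide, and the largest cluster
    holds >= 90% of chains.  homogeneous: profile flat within 3 SE.
    Otherwise cluster.  Contradictory indicators set an ``indeterminate``
    flag in the diagnostics instead of raising.
    """
    z = np.abs(profile.concentration - profile.concentration.mean()) \
        / np.maximum(profile.se, 1e-12)
    # flat within 3 SE, Bonferroni-style: one moderate outlier among many
    # bins is expected noise, not structure
    n_exceed = int((z > 3).sum())
    flat = n_exceed == 0 or (n_exceed <= max(1, int(0.02 * z.size)) and z.max() <= 4.5)
    diag: dict = {"flat": bool(flat), "largest_cluster_fraction": cluster_fraction,
                  "indeterminate": False}
    if flat:
        if cluster_fraction >= largest_fraction_threshold:
            diag["indeterminate"] = True
            logger.warning("flat profile but a dominant cluster: indeterminate")
        return "homogeneous", diag
    try:
        c_l, c_d, fit = extract_coexistence(profile)
        diag.update(fit, c_dilute=c_l, c_dense=c_d)
        slab_shape = fit["plateau_width"] >= min_plateau_widths * fit["width"]
    except RuntimeError as exc:
        diag["fit_error"] = str(exc)
        slab_shape = False
    if slab_shape and cluster_fraction >= largest_fraction_threshold:
        return "slab", diag
    if slab_shape != (cluster_fraction >= largest_fraction_threshold):
        diag["indeterminate"] = True
        logger.warning("profile shape and cluster statistics disagree "
                       "(slab_shape=%s, fraction=%.2f)", slab_shape, cluster_fraction)
    return "cluster", diag


def rdf_HH(traj: Trajectory, dense_region: Optional[Tuple[float, float]] = None,
           r_max: float = 2.5, n_bins: int = 125) -> Tuple[np.ndarray, np.ndarray]:
    """Radial distribution function between H monomers.

    ``dense_region`` is an optional (z_lo, z_hi) window (box frame); the
    ideal-gas normalization uses the H-monomer density of that region.
    Returns (r, g).
    """
    h_sel = np.asarray(traj.types) == 0
    if h_sel.sum() < 2:
        raise ValueError("need at least two H monomers for g(r)")
    box = traj.box.copy()
    hist = np.zeros(n_bins, dtype=np.int64)
    n_pairs_norm = 0.0
    for f in range(traj.n_frames):
        pos = traj.positions[f][h_sel]
        if dense_region is not None:
            z_lo, z_hi = dense_region
            m = (pos[:, 2] >= z_lo) & (pos[:, 2] < z_hi)
            pos = pos[m]
            vol = box[0] * box[1] * (z_hi - z_lo)
        else:
            vol = box.prod()
        n = pos.shape[0]
        if n < 2:
            continue
        sub_box = box.copy()
        if dense_region is not None:
            sub_box[2] = box[2]  # pair distances still minimum-imaged in full box
        hist += _kernels.rdf_histogram(np.ascontiguousarray(pos), sub_box,
                                       r_max, n_bins)
        n_pairs_norm += n * (n - 1) / 2.0 / vol
    edges = np.linspace(0, r_max, n_bins + 1)
    r = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = hist / (n_pairs_norm * shell)
    return r, g


def phase_rg_split(traj: Trajectory, contact_cutoff: Optional[float] = None,
                   min_cluster: Optional[int] = None) -> Tuple[float, float]:
    """Mean per-chain R_g in the dense phase vs the dilute phase.

    Dense-phase chains are members of the largest cluster; all other chains
    count as dilute.  Returns (Rg_dense, Rg_dilute); either may be nan when a
    phase holds no chains.
    """
    dense_rg, dilute_rg = [], []
    for f in range(traj.n_frames):
        frame = traj.frame(f)
        labels = cluster_chains(frame, contact_cutoff)
        sizes = np.bincount(labels)
        big = np.argmax(sizes)
        coords = unwrap_chains(frame.positions, frame.chain_ids, frame.box)
        for c in range(frame.n_chains):
            sel = frame.chain_ids == c
            x = coords[sel]
            rg = np.sqrt(((x - x.mean(axis=0)) ** 2).sum(axis=1).mean())
            (dense_rg if labels[c] == big and sizes[big] > 1 else dilute_rg).append(rg)
    return (float(np.mean(dense_rg)) if dense_rg else float("nan"),
            float(np.mean(dilute_rg)) if dilute_rg else float("nan"))


def coexistence_run(seq: Sequence, ff: ForceField, n_chains: int = 100,
                    box: Tuple[float, float, float] = (10.0, 10.0, 40.0),
                    n_steps: int = 2_000_000, sample_every: int = 10_000,
                    seed: int = 0, equilibration: float = 0.5,
                    a: Optional[float] = None) -> Tuple[PhasePoint, DensityProfile, Trajectory]:
    """Build a dense slab of ``n_chains`` copies of ``seq``, run, and classify.

    The default desk-scale geometry (100 chains, 10 x 10 x 40 nm) is a
    scaled-down version of the full 500-chain 10 x 10 x 75 nm campaign.
    """
    seqs = [seq] * n_chains
    st = build_slab(seqs, box=box, seed=seed)
    traj = run_langevin(st, ff, n_steps, sample_every=sample_every, seed=seed)
    prod = traj.discard(equilibration)
    profile = density_profile(prod)
    frac = largest_cluster_fraction(prod)
    state, diag = classify_phase_state(profile, frac)
    if state == "slab":
        c_l, c_d = diag["c_dilute"], diag["c_dense"]
        perr = diag["perr"]
        pp = PhasePoint(seq.X_P, ff.model_kind, c_l, float(perr[1]), c_d,
                        float(perr[0]), state, a, diag["indeterminate"])
    else:
        # report region-based concentrations for non-slab states
        mid = np.abs(profile.z_bins) < profile.box[2] / 8
        outer = np.abs(profile.z_bins) > 3 * profile.box[2] / 8
        pp = PhasePoint(seq.X_P, ff.model_kind,
                        float(profile.concentration[outer].mean()),
                        float(profile.se[outer].mean()),
                        float(profile.concentration[mid].mean()),
                        float(profile.se[mid].mean()), state, a,
                        diag["indeterminate"])
    return pp, profile, traj


def threshold_scan(model_kind: str, calib_table: Dict[float, float],
                   X_P_grid: Optional[List[float]] = None, N: int = 20,
                   seq_seed: int = 0, scaled: bool = True,
                   **run_kwargs) -> Tuple[Optional[float], List[PhasePoint]]:
    """Sweep X_P, classify each coexistence run, and report the threshold.

    ``calib_table`` maps X_P -> calibrated scaling factor a (ignored when
    ``scaled`` is False, which runs the unscaled lambda_H = 1 model).
    Returns (X_P*, phase points) where X_P* is the largest grid X_P whose run
    is classified as a slab; the grid spacing is the threshold's resolution.
    None when no slab forms anywhere (degenerate scan).
    """
    if X_P_grid is None:
        X_P_grid = sorted(calib_table)
    points = []
    ss = np.random.SeedSequence(seq_seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(X_P_grid))]
    for x, sd in zip(X_P_grid, seeds):
        seq = generate_sequence(N, x, seed=sd)
        if scaled:
            if x not in calib_table:
                raise KeyError(f"dependency error: no calibrated a for X_P={x}; run tune first")
            a = calib_table[x]
            lam = scaled_lambda_H(a, x) if x < 1 else 0.0
        else:
            a, lam = None, 1.0
        ff = default_forcefield(model_kind, lam)
        pp, _, _ = coexistence_run(seq, ff, seed=sd, a=a, **run_kwargs)
        points.append(pp)
        logger.info("X_P=%.2f -> %s (c_l=%.1f, c_d=%.1f mg/mL)", x, pp.state,
                    pp.c_dilute, pp.c_dense)
    slabs = [p.X_P for p in points if p.state == "slab"]
    if not slabs:
        logger.warning("degenerate scan: no slab at any X_P")
        return None, points
    return max(slabs), points
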