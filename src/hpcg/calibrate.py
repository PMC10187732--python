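"""Calibration of the H-monomer attraction to a common single-chain size.

Every sequence is given the hydropathy ``lambda_H = a / (1 - X_P)`` and the
scaling factor ``a`` is tuned until the chain's mean radius of gyration
matches that of the purely hydrophobic reference chain (X_P = 0,
lambda_H = 1).  Because <R_g> decreases monotonically with a (stronger
attraction compacts the chain), a bracketed bisection converges quickly; the
search stops once the relative mismatch falls below the tolerance or once
statistical noise dominates the residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from hpcg.chain_obs import block_error, rg_series
from hpcg.engine import build_single_chain, run_langevin
from hpcg.forcefield import default_forcefield, scaled_lambda_H
from hpcg.sequences import Sequence, generate_sequence

# per-evaluation single-chain run defaults (steps of 10 fs)
RUN_STEPS_DEFAULT = 4_000_000
SAMPLE_EVERY_DEFAULT = 2_000
EQUILIBRATION_FRACTION = 0.1


@dataclass
class CalibrationResult:
    """Outcome of matching one sequence's <R_g> to the reference."""

    a: float
    lambda_H: float
    achieved_Rg: float
    achieved_SE: float
    reference_Rg: float
    reference_SE: float
    rel_dev: float
    converged: bool
    evaluations: List[Tuple[float, float, float]] = field(default_factory=list)


def _mean_rg(seq: Sequence, model_kind: str, lambda_H: float, seed: int,
             n_steps: int, sample_every: int) -> Tuple[float, float]:
    ff = default_forcefield(model_kind, lambda_H)
    st = build_single_chain(seq, box=50.0, seed=seed)
    traj = run_langevin(st, ff, n_steps, sample_every=sample_every, seed=seed)
    traj = traj.discard(EQUILIBRATION_FRACTION)
    return block_error(rg_series(traj))


def reference_Rg(model_kind: str = "HP", N: int = 20, seed: int = 0,
                 n_steps: int = RUN_STEPS_DEFAULT,
                 sample_every: int = SAMPLE_EVERY_DEFAULT,
                 max_rel_se: float = 0.02) -> Tuple[float, float]:
    """<R_g> +/- SE of the purely hydrophobic reference chain (X_P=0, lambda_H=1)."""
    seq = generate_sequence(N, 0.0, seed=seed)
    mean, se = _mean_rg(seq, model_kind, 1.0, seed, n_steps, sample_every)
    if se > max_rel_se * mean:
        raise RuntimeError(
            f"sampling error: reference R_g block SE {se:.3g} exceeds "
            f"{max_rel_se:.0%} of the mean {mean:.3g}")
    return mean, se


def match_rg(seq: Sequence, model_kind: str, reference: Tuple[float, float],
             tolerance: float = 0.03, seed: int = 0,
             n_steps: int = RUN_STEPS_DEFAULT,
             sample_every: int = SAMPLE_EVERY_DEFAULT,
             a_bounds: Tuple[float, float] = (0.1, 20.0),
             max_iter: int = 12) -> CalibrationResult:
    """Find the scaling factor a whose <R_g> matches the reference.

    f(a) = <R_g(a)> - R_g,ref is assumed (and verified from the evaluation
    trace) to be monotone decreasing; bisection stops when |f| falls within
    ``tolerance * reference`` or when the block SE exceeds |f| (noise-limited).
    """
    x_p = seq.X_P
    if x_p >= 1.0:
        raise ValueError("cannot calibrate a purely polar chain (no H monomers)")
    ref_rg, ref_se = reference
    evals: List[Tuple[float, float, float]] = []

    def f(a: float) -> Tuple[float, float]:
        lam = scaled_lambda_H(a, x_p)
        rg, se = _mean_rg(seq, model_kind, lam, seed, n_steps, sample_every)
        evals.append((a, rg, se))
        return rg - ref_rg, se

    def result(a: float, rg: float, se: float, converged: bool) -> CalibrationResult:
        return CalibrationResult(a=a, lambda_H=scaled_lambda_H(a, x_p),
                                 achieved_Rg=rg, achieved_SE=se,
                                 reference_Rg=ref_rg, reference_SE=ref_se,
                                 rel_dev=abs(rg - ref_rg) / ref_rg,
                                 converged=converged, evaluations=evals)

    # bracket: grow a geometrically until f changes sign
    lo, hi = a_bounds
    a_lo = max(lo, 0.25)
    f_lo, se_lo = f(a_lo)
    while f_lo < 0 and a_lo > lo * 1.001:
        a_lo = max(lo, a_lo / 2)
        f_lo, se_lo = f(a_lo)
    if abs(f_lo) <= tolerance * ref_rg:
        return result(a_lo, f_lo + ref_rg, se_lo, True)
    if f_lo < 0:
        raise RuntimeError("calibration failure: <R_g> below reference even at "
                           f"minimum a = {a_lo}")
    a_hi = max(2 * a_lo, 1.0)
    f_hi, se_hi = f(a_hi)
    while f_hi > 0:
        if abs(f_hi) <= tolerance * ref_rg:
            return result(a_hi, f_hi + ref_rg, se_hi, True)
        a_hi *= 2
        if a_hi > hi:
            raise RuntimeError(f"calibration failure: no bracket found for a in "
                               f"[{lo}, {hi}] (X_P = {x_p:.2f}, {model_kind})")
        f_hi, se_hi = f(a_hi)
    # bisection
    best = None
    for _ in range(max_iter):
        a_mid = 0.5 * (a_lo + a_hi)
        f_mid, se_mid = f(a_mid)
        best = (a_mid, f_mid, se_mid)
        if abs(f_mid) <= tolerance * ref_rg or se_mid > abs(f_mid):
            return result(a_mid, f_mid + ref_rg, se_mid,
                          abs(f_mid) <= tolerance * ref_rg)
        if f_mid > 0:
            a_lo, f_lo = a_mid, f_mid
        else:
            a_hi, f_hi = a_mid, f_mid
    a_mid, f_mid, se_mid = best
    return result(a_mid, f_mid + ref_rg, se_mid,
                  abs(f_mid) <= tolerance * ref_rg)


def monotone_trace(result: CalibrationResult, slack_sigma: float = 3.0) -> bool:
    """Check that <R_g(a)> decreased with a across the evaluation trace,
    allowing ``slack_sigma`` combined-SE violations (stochastic estimates)."""
    evs = sorted(result.evaluations)
    for (a1, r1, s1), (a2, r2, s2) in zip(evs, evs[1:]):
        if r2 - r1 > slack_sigma * np.hypot(s1, s2):
            return False
    return True
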