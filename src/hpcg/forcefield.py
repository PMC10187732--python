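"""Bonded and nonbonded interactions for the HP and HP+ models.

Nonbonded pairs interact through an Ashbaugh-Hatch scaled Lennard-Jones
potential in which the attractive tail is scaled by a pairwise hydropathy
``lambda_ij`` while the short-range repulsion is left untouched::

    U(r) = U_LJ(r) + (1 - lambda) * eps        r <= 2^(1/6) sigma
         = lambda * U_LJ(r)                    2^(1/6) sigma < r <= r_cut
         = 0                                   r > r_cut

with ``U_LJ = 4 eps [(sigma/r)^12 - (sigma/r)^6]``.  At ``lambda = 0`` this
is the purely repulsive Weeks-Chandler-Andersen potential (good-solvent
excluded volume); at ``lambda = 1`` it is the full Lennard-Jones potential.
The form is C0-continuous at the minimum ``2^(1/6) sigma`` for every lambda.

Hydropathies: ``lambda_PP = 0`` always and ``lambda_HH = lambda_H``.  The
cross term distinguishes the two models: ``lambda_HP = 0`` in the HP model
(strong localized attraction between H monomers only) and
``lambda_HP = lambda_H / 2`` in the HP+ model (weak distributed attraction
spread over H-P contacts as well).

Bonds are harmonic, ``U_b = k_b (r - r0)^2`` (the spring prefactor is
absorbed into ``k_b``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Union

import numpy as np

from hpcg.units import KB, T_DEFAULT

MIN_R = 1e-6  # nm; below this a pair distance is treated as singular

EPSILON_DEFAULT = 0.2        # kcal/mol
SIGMA_DEFAULT = 0.5          # nm
KBOND_DEFAULT = 2000.0       # kcal/(mol nm^2)
R0_DEFAULT = 0.38            # nm
RCUT_DEFAULT = 4 * SIGMA_DEFAULT   # nm; tail beyond is < 1e-3 eps


@dataclass(frozen=True)
class ForceField:
    """Parameter set for one model variant (HP or HP+).

    ``lambda_table`` is the symmetric 2x2 pair-hydropathy table indexed by
    integer type codes (0 = H, 1 = P).
    """

    epsilon: float = EPSILON_DEFAULT
    sigma: float = SIGMA_DEFAULT
    k_b: float = KBOND_DEFAULT
    r0: float = R0_DEFAULT
    lambda_table: tuple = ((1.0, 0.0), (0.0, 0.0))
    r_cut: float = RCUT_DEFAULT
    model_kind: str = "HP"

    def __post_init__(self):
        lt = np.asarray(self.lambda_table, dtype=float)
        if lt.shape != (2, 2) or not np.allclose(lt, lt.T):
            raise ValueError("lambda_table must be a symmetric 2x2 table")
        if (lt < 0).any():
            raise ValueError("hydropathies must be non-negative")
        if self.r_cut <= 2 ** (1 / 6) * self.sigma:
            raise ValueError("r_cut must exceed the potential minimum 2^(1/6) sigma")

    @property
    def lambda_array(self) -> np.ndarray:
        return np.asarray(self.lambda_table, dtype=float)

    @property
    def lambda_H(self) -> float:
        return self.lambda_table[0][0]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda_table"] = [list(row) for row in self.lambda_table]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ForceField":
        d = dict(d)
        d["lambda_table"] = tuple(tuple(row) for row in d["lambda_table"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "ForceField":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_forcefield(model_kind: str, lambda_H: float = 1.0, **overrides) -> ForceField:
    """Force field with the study's default parameters and the model's mixing rule.

    HP:  lambda_HP = 0 (attraction only between H-H pairs).
    HP+: lambda_HP = lambda_H / 2 (mean of lambda_H and lambda_P = 0).
    """
    if lambda_H < 0:
        raise ValueError(f"lambda_H must be >= 0, got {lambda_H}")
    kind = model_kind.upper().replace("PLUS", "+")
    if kind == "HP":
        l_hp = 0.0
    elif kind == "HP+":
        l_hp = lambda_H / 2.0
    else:
        raise ValueError(f"unknown model kind {model_kind!r}; expected 'HP' or 'HP+'")
    table = ((lambda_H, l_hp), (l_hp, 0.0))
    return ForceField(lambda_table=table, model_kind=kind, **overrides)


def scaled_lambda_H(a: float, X_P: float) -> float:
    """H-monomer hydropathy under composition scaling, lambda_H = a / (1 - X_P).

    The scaling compensates the dilution of attractive sites as the polar
    fraction grows; it is undefined for a purely polar chain (X_P = 1).
    """
    if not 0.0 <= X_P < 1.0:
        raise ValueError(f"X_P must lie in [0, 1), got {X_P}")
    return a / (1.0 - X_P)


def _u_lj(r, epsilon, sigma):
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def pair_energy(r: Union[float, np.ndarray], lambda_ij: float, ff: ForceField):
    """Nonbonded pair energy (kcal/mol) at separation r (nm)."""
    scalar = np.isscalar(r)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if (r < MIN_R).any():
        raise ValueError("pair separation at or below the numeric floor (singular)")
    rmin = 2 ** (1 / 6) * ff.sigma
    u = np.zeros_like(r)
    inner = r <= rmin
    mid = (~inner) & (r <= ff.r_cut)
    u[inner] = _u_lj(r[inner], ff.epsilon, ff.sigma) + (1.0 - lambda_ij) * ff.epsilon
    u[mid] = lambda_ij * _u_lj(r[mid], ff.epsilon, ff.sigma)
    return float(u[0]) if scalar else u


def pair_force(r: Union[float, np.ndarray], lambda_ij: float, ff: ForceField):
    """Radial force -dU/dr (kcal/(mol nm)); positive = repulsive."""
    scalar = np.isscalar(r)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if (r < MIN_R).any():
        raise ValueError("pair separation at or below the numeric floor (singular)")
    rmin = 2 ** (1 / 6) * ff.sigma
    sr6 = (ff.sigma / r) ** 6
    # -dU_LJ/dr = 24 eps (2 sr12 - sr6) / r
    f_lj = 24.0 * ff.epsilon * (2.0 * sr6 * sr6 - sr6) / r
    f = np.where(r <= rmin, f_lj, np.where(r <= ff.r_cut, lambda_ij * f_lj, 0.0))
    return float(f[0]) if scalar else f


def bond_energy(r: Union[float, np.ndarray], ff: ForceField):
    """Harmonic bond energy k_b (r - r0)^2 in kcal/mol."""
    r = np.asarray(r, dtype=float)
    out = ff.k_b * (r - ff.r0) ** 2
    return float(out) if out.ndim == 0 else out


def bond_force(r: Union[float, np.ndarray], ff: ForceField):
    """Radial bond force -dU/dr = -2 k_b (r - r0)."""
    r = np.asarray(r, dtype=float)
    out = -2.0 * ff.k_b * (r - ff.r0)
    return float(out) if out.ndim == 0 else out


def system_nonbonded_energy(state, ff: ForceField, use_celllist: str = "auto") -> float:
    """Total nonbonded energy U_nb of a configuration (kcal/mol).

    Sums ``pair_energy`` over all non-bonded pairs within ``r_cut`` under the
    minimum-image convention; directly bonded (1-2) pairs are excluded.  For
    large systems a cell list is used; ``use_celllist`` in {"auto", "always",
    "never"} controls the path (the two agree to ~1e-12 and are cross-checked
    in the test suite).
    """
    from hpcg import _kernels

    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    box = np.asarray(state.box, dtype=np.float64)
    types = np.ascontiguousarray(state.types, dtype=np.int64)
    bonds = np.ascontiguousarray(state.bonds, dtype=np.int64)
    lam = np.ascontiguousarray(ff.lambda_array, dtype=np.float64)
    n = pos.shape[0]
    big = {"auto": n > 400, "always": True, "never": False}[use_celllist]
    if big and (box > 3 * ff.r_cut).all():
        big = True
    if big:
        u = _kernels.nonbonded_energy_cells(pos, types, bonds, box, lam,
                                            ff.epsilon, ff.sigma, ff.r_cut)
    else:
        u = _kernels.nonbonded_energy_allpairs(pos, types, bonds, box, lam,
                                               ff.epsilon, ff.sigma, ff.r_cut)
    if not np.isfinite(u):
        raise ValueError("overlapping particles: nonbonded energy is singular")
    return float(u)
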