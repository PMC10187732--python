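"""H/P sequence generation and FASTA-like serialization.

Chains are strings over the two-letter alphabet {H, P}.  The polar fraction
``X_P`` is treated as a controlled variable: a sequence of length N carries
exactly ``round(N * X_P)`` polar monomers (round-half-to-even), placed either
uniformly at random (default) or maximally evenly along the chain
(``patterned=True``, emulating highly patterned designs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence as _Seq

import numpy as np

ALPHABET = frozenset("HP")


@dataclass(frozen=True)
class Sequence:
    """An ordered H/P monomer string with composition metadata."""

    monomers: str
    label: str = ""
    seed: Optional[int] = None

    def __post_init__(self):
        bad = set(self.monomers) - ALPHABET
        if bad:
            raise ValueError(f"illegal monomer characters {sorted(bad)} in sequence {self.label!r}")
        if len(self.monomers) < 2:
            raise ValueError(f"sequence must have N >= 2 monomers, got {len(self.monomers)}")

    @property
    def N(self) -> int:
        return len(self.monomers)

    @property
    def n_polar(self) -> int:
        return self.monomers.count("P")

    @property
    def X_P(self) -> float:
        """Measured polar fraction."""
        return self.n_polar / self.N

    @property
    def types(self) -> np.ndarray:
        """Integer type codes: 0 for H, 1 for P."""
        return np.frombuffer(self.monomers.encode(), dtype=np.uint8) == ord("P")

    def __str__(self) -> str:
        return self.monomers


def _n_polar(N: int, X_P: float) -> int:
    # numpy round is round-half-to-even, the convention adopted for ties
    return int(np.round(N * X_P))


def generate_sequence(N: int, X_P: float, seed: int = 0, patterned: bool = False,
                      label: Optional[str] = None) -> Sequence:
    """Generate a single H/P sequence with exactly ``round(N*X_P)`` P monomers.

    Parameters
    ----------
    N : chain length (>= 2).
    X_P : nominal polar fraction in [0, 1].
    seed : RNG seed controlling random placement; ignored when ``patterned``.
    patterned : place the minority monomer maximally evenly instead of randomly.
    """
    if not 0.0 <= X_P <= 1.0:
        raise ValueError(f"X_P must lie in [0, 1], got {X_P}")
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    n_p = _n_polar(N, X_P)
    if label is None:
        label = f"XP{X_P:.2f}" + ("_patterned" if patterned else "")
    chars = np.full(N, "H", dtype="<U1")
    if patterned:
        # place the minority species at evenly spaced (centered-stride) positions
        minority, count = ("P", n_p) if n_p <= N - n_p else ("H", N - n_p)
        if minority == "H":
            chars[:] = "P"
        if count > 0:
            pos = np.floor((np.arange(count) + 0.5) * N / count).astype(int)
            chars[pos] = minority
    else:
        rng = np.random.default_rng(seed)
        pos = rng.choice(N, size=n_p, replace=False)
        chars[pos] = "P"
    return Sequence("".join(chars), label=label, seed=None if patterned else seed)


def sequence_grid(N: int, step: float, seed: int = 0, patterned: bool = False) -> List[Sequence]:
    """One sequence per grid point X_P in {0, step, 2*step, ..., 1}.

    ``step`` must divide 1 evenly.  Each grid point draws from an independent
    seed stream derived from ``seed`` so the whole set is reproducible.
    """
    n_steps = 1.0 / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {step} does not divide 1 evenly")
    n_steps = int(round(n_steps))
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_steps + 1)]
    out = []
    for i in range(n_steps + 1):
        x = i / n_steps
        out.append(generate_sequence(N, x, seed=child_seeds[i], patterned=patterned))
    return out


def write_sequences(seqs: Iterable[Sequence], path) -> None:
    """Write sequences in FASTA; headers carry label, X_P and seed."""
    from Bio.Seq import Seq as _BioSeq
    from Bio.SeqIO import write as _write
    from Bio.SeqRecord import SeqRecord

    records = []
    for i, s in enumerate(seqs):
        desc = f"X_P={s.X_P:.6g}" + (f" seed={s.seed}" if s.seed is not None else "")
        records.append(SeqRecord(_BioSeq(s.monomers), id=s.label or f"seq{i}", description=desc))
    _write(records, str(path), "fasta")


def read_sequences(path) -> List[Sequence]:
    """Read a FASTA file of H/P sequences; raises on illegal characters."""
    from Bio.SeqIO import parse as _parse

    out = []
    for rec in _parse(str(path), "fasta"):
        mono = str(rec.seq).upper()
        bad = set(mono) - ALPHABET
        if bad:
            raise ValueError(f"record {rec.id!r} contains illegal characters {sorted(bad)}")
        seed = None
        for tok in rec.description.split():
            if tok.startswith("seed="):
                seed = int(tok[5:])
        out.append(Sequence(mono, label=rec.id, seed=seed))
    return out
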