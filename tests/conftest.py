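"""Shared fixtures: small, seeded systems reused across the suite."""

import numpy as np
import pytest

from hpcg.engine import SimState
from hpcg.forcefield import default_forcefield
from hpcg.sequences import generate_sequence


@pytest.fixture(scope="session")
def ff_hp():
    return default_forcefield("HP", 1.0)


@pytest.fixture(scope="session")
def ff_hpp():
    return default_forcefield("HP+", 1.0)


@pytest.fixture(scope="session")
def seq_h20():
    return generate_sequence(20, 0.0, seed=1)


def random_state(n_particles: int, box, seed: int, n_chains: int = 1,
                 min_sep: float = 0.45) -> SimState:
    """Random non-overlapping configuration with linear-chain topology."""
    rng = np.random.default_rng(seed)
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    pos = []
    while len(pos) < n_particles:
        cand = rng.random(3) * box
        ok = True
        for p in pos:
            d = cand - p
            d -= box * np.rint(d / box)
            if np.linalg.norm(d) < min_sep:
                ok = False
                break
        if ok:
            pos.append(cand)
    pos = np.asarray(pos)
    types = rng.integers(0, 2, n_particles).astype(np.int64)
    per = n_particles // n_chains
    cid = np.minimum(np.arange(n_particles) // per, n_chains - 1).astype(np.int64)
    return SimState(pos, np.zeros_like(pos), types, cid, box, rng_seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
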