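import numpy as np
import pandas as pd
import pytest

from dqt import (
    ModelParams,
    TopologySpec,
    build_duplex,
    build_origami,
    to_atom_blocks,
)
from dqt.system import ElectronicSystem

GC = "GGGGCCCC"
AT = "AAAATTTT"


def make_atom_table(orbital_counts, **overrides):
    """Minimal valid annotation table for hand-built matrices."""
    n = len(orbital_counts)
    offsets = np.concatenate([[0], np.cumsum(orbital_counts)])[:-1]
    cols = {
        "atom_id": np.arange(n),
        "element": ["X"] * n,
        "orbital_offset": offsets,
        "orbital_count": list(orbital_counts),
        "base_id": np.arange(n),
        "base_label": ["G"] * n,
        "strand_id": ["I"] * n,
        "helix_id": [1] * n,
        "region": ["base"] * n,
        "pos": np.arange(n),
    }
    cols.update(overrides)
    return pd.DataFrame(cols)


def random_annotated_system(rng, max_atoms=20, max_orb_per_atom=3):
    """Random Hermitian H + well-conditioned SPD overlap + random partition."""
    n_atoms = int(rng.integers(2, max_atoms + 1))
    counts = rng.integers(1, max_orb_per_atom + 1, size=n_atoms)
    n = int(counts.sum())
    h = rng.normal(size=(n, n))
    h = 0.5 * (h + h.T)
    q = np.linalg.qr(rng.normal(size=(n, n)))[0]
    s = (q * rng.uniform(0.5, 1.5, size=n)) @ q.T
    s = 0.5 * (s + s.T)
    atoms = make_atom_table(counts)
    n_occ = int(rng.integers(1, n))
    return ElectronicSystem(hamiltonian=h, overlap=s, atoms=atoms, n_occupied=n_occ)


@pytest.fixture(scope="session")
def gc_duplex():
    return build_duplex(GC, ModelParams(seed=1))


@pytest.fixture(scope="session")
def gc_duplex_block(gc_duplex):
    return to_atom_blocks(gc_duplex)


@pytest.fixture(scope="session")
def at_duplex():
    return build_duplex(AT, ModelParams(seed=1))


@pytest.fixture(scope="session")
def origami_c1():
    return build_origami(TopologySpec.origami(GC, GC), ModelParams(seed=1),
                         conformation="C1")


@pytest.fixture(scope="session")
def origami_c2():
    return build_origami(TopologySpec.origami(GC, GC), ModelParams(seed=1),
                         conformation="C2")


@pytest.fixture(scope="session")
def origami_c1_block(origami_c1):
    return to_atom_blocks(origami_c1)
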