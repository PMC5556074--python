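import numpy as np
import pytest

from hotspots.structure import build_complex, parse_structure
from hotspots.synthetic import make_synthetic_complex, make_synthetic_table


@pytest.fixture(scope="session")
def small_complex():
    """Two 10-residue chains with a 4-residue contact patch."""
    pdb, info = make_synthetic_complex(
        n_residues_per_chain=10, patch_size=4, separation=4.0, seed=1
    )
    cx = build_complex(parse_structure(pdb), "A", "B", source_id="fixture")
    return cx, info, pdb


@pytest.fixture(scope="session")
def far_complex():
    """Two chains 30 A apart everywhere: no interface."""
    pdb, info = make_synthetic_complex(
        n_residues_per_chain=6, patch_size=0, separation=30.0, seed=2
    )
    return build_complex(parse_structure(pdb), "A", "B", source_id="far")


@pytest.fixture(scope="session")
def labelled_table():
    """Small imbalanced labelled table with an informative block."""
    table, info = make_synthetic_table(
        n_obs=200, hs_fraction=0.25, n_features=12, n_informative=6,
        effect_size=1.5, n_complexes=10, seed=7,
    )
    return table, info


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
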