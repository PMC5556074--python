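"""Synthetic fixtures: labelled feature tables and two-chain complexes.

The table generator emulates the training data's study conditions: a
minority of hot-spots (~24% of interfacial residues), observations
grouped into complexes, experimental ddG values consistent with the
labels, and a block of informative features whose class means differ by
a controlled effect size among uninformative noise features.

The complex generator emits parseable PDB text for two synthetic chains
with a controllable contact patch, together with the geometric record
needed to serve as an oracle in interface and contact tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._aa import AA1, AA1_TO_3
from .preprocessing import DDG_COLUMN, HS_THRESHOLD, LABEL_COLUMN

# Burial bound for Shrake-Rupley spheres: two atoms occlude each other's
# accessible surface iff their distance is below r_i + r_j + 2 * probe.
# With Bondi radii (max 1.80 for S) and a 1.4 A probe this is < 6.4 A.
_BURIAL_BOUND = 6.4


@dataclass
class SyntheticTableInfo:
    informative: list[str]
    effect_size: float
    hs_fraction: float
    seed: int


def make_synthetic_table(
    n_obs: int = 534,
    hs_fraction: float = 0.24,
    n_features: int = 30,
    n_informative: int = 10,
    effect_size: float = 1.0,
    n_complexes: int = 53,
    seed: int = 0,
    exact_counts: bool = False,
) -> tuple[pd.DataFrame, SyntheticTableInfo]:
    """Labelled feature table with a class-mean shift on informative features.

    Labels are drawn Bernoulli(hs_fraction) unless ``exact_counts`` asks
    for exactly round(hs_fraction * n_obs) hot-spots.  ddG values are
    drawn consistently with the labels around the 2.0 kcal/mol boundary.
    """
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    rng = np.random.default_rng(seed)
    if exact_counts:
        n_hs = int(round(hs_fraction * n_obs))
        labels = np.array([1] * n_hs + [0] * (n_obs - n_hs))
        rng.shuffle(labels)
    else:
        labels = rng.binomial(1, hs_fraction, size=n_obs)
    width = max(3, len(str(n_features)))
    names = [f"f{i + 1:0{width}d}" for i in range(n_features)]
    X = rng.standard_normal((n_obs, n_features))
    informative = names[:n_informative]
    X[:, :n_informative] += effect_size * labels[:, None]
    ddg = np.where(
        labels == 1,
        HS_THRESHOLD + rng.exponential(1.5, size=n_obs),
        HS_THRESHOLD - 0.05 - rng.exponential(1.0, size=n_obs),
    )
    table = pd.DataFrame(X, columns=names)
    table.insert(0, "complex", [f"CPX{1 + i % n_complexes:03d}" for i in range(n_obs)])
    table.insert(1, "chain", "A")
    table.insert(2, "residue", np.arange(1, n_obs + 1))
    table[DDG_COLUMN] = np.round(ddg, 3)
    table[LABEL_COLUMN] = np.where(labels == 1, "HS", "NS")
    info = SyntheticTableInfo(
        informative=informative,
        effect_size=effect_size,
        hs_fraction=hs_fraction,
        seed=seed,
    )
    return table, info


def make_curated_style_table(
    seed: int = 0,
    n_obs: int = 534,
    n_complexes: int = 53,
    n_hs: int = 127,
    n_features: int = 881,
    n_informative: int = 30,
    effect_size: float = 0.8,
) -> tuple[pd.DataFrame, SyntheticTableInfo]:
    """Synthetic stand-in (fully simulated) for the curated training table.

    Mirrors the printed composition of the curated alanine-scanning
    dataset — 534 interfacial residues from 53 complexes, 127 with
    ddG >= 2.0 kcal/mol — with 881 feature columns of which a small
    informative block separates the classes.
    """
    table, info = make_synthetic_table(
        n_obs=n_obs,
        hs_fraction=n_hs / n_obs,
        n_features=n_features,
        n_informative=n_informative,
        effect_size=effect_size,
        n_complexes=n_complexes,
        seed=seed,
        exact_counts=True,
    )
    return table, info


@dataclass
class SyntheticComplexInfo:
    """Geometric record of a generated complex (the test oracle)."""

    n_atoms: int
    sequences: dict[str, str]
    #: residues (chain, resseq, icode) with an intermolecular atom pair
    #: close enough that mutual burial is certain
    contact_residues: set = field(default_factory=set)
    #: residues with any intermolecular pair below the burial bound;
    #: the true interface is contained in this set
    possible_interface: set = field(default_factory=set)
    min_cross_distance: dict = field(default_factory=dict)


_RES_TEMPLATE = (
    # name, local offset (A); a compact plausible residue footprint
    ("N", (-0.65, 0.70, 0.00)),
    ("CA", (0.00, 0.00, 0.00)),
    ("C", (1.20, 0.60, 0.45)),
    ("O", (1.60, 1.60, -0.10)),
    ("CB", (0.10, -1.10, 1.00)),
)


def _chain_atoms(sequence: str, chain_id: str, y: np.ndarray, z: float):
    atoms = []
    for i, aa in enumerate(sequence):
        res_name = AA1_TO_3[aa]
        for name, (dx, dy, dz) in _RES_TEMPLATE:
            if name == "CB" and res_name == "GLY":
                continue
            atoms.append(
                (name, name[0], (3.8 * i + dx, y[i] + dy, z + dz),
                 chain_id, i + 1, res_name)
            )
    return atoms


def make_synthetic_complex(
    n_residues_per_chain: int = 12,
    patch_size: int = 4,
    separation: float = 4.0,
    far_separation: float = 30.0,
    seed: int = 0,
    sequence_a: str | None = None,
    sequence_b: str | None = None,
) -> tuple[str, SyntheticComplexInfo]:
    """PDB text for two synthetic chains with a central contact patch.

    Chain A lies along the x-axis; chain B runs parallel, displaced in y
    by ``far_separation`` except for ``patch_size`` central residues
    pulled to ``separation``.  The returned record lists, per residue,
    the minimum intermolecular atom distance, the residues guaranteed to
    be buried, and the superset of residues that can possibly be buried.
    """
    if patch_size > n_residues_per_chain:
        raise ValueError("patch must fit inside the chain")
    rng = np.random.default_rng(seed)
    n = n_residues_per_chain
    seq_a = sequence_a or "".join(rng.choice(list(AA1), size=n))
    seq_b = sequence_b or "".join(rng.choice(list(AA1), size=n))
    if len(seq_a) != n or len(seq_b) != n:
        raise ValueError("explicit sequences must match n_residues_per_chain")
    start = (n - patch_size) // 2
    y_b = np.full(n, far_separation, dtype=float)
    y_b[start : start + patch_size] = separation
    y_a = np.zeros(n)
    atoms = _chain_atoms(seq_a, "A", y_a, 0.0) + _chain_atoms(seq_b, "B", y_b, 0.0)

    lines = []
    for i, (name, element, (x, y, z), chain, resseq, res_name) in enumerate(atoms, 1):
        lines.append(
            f"ATOM  {i:5d} {name:^4s} {res_name:>3s} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
        )
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    coords_a = np.array([a[2] for a in atoms if a[3] == "A"])
    coords_b = np.array([a[2] for a in atoms if a[3] == "B"])
    keys_a = [("A", a[4], "") for a in atoms if a[3] == "A"]
    keys_b = [("B", a[4], "") for a in atoms if a[3] == "B"]
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)
    info = SyntheticComplexInfo(
        n_atoms=len(atoms), sequences={"A": seq_a, "B": seq_b}
    )
    for keys, dist in ((keys_a, d.min(axis=1)), (keys_b, d.min(axis=0))):
        for key, dm in zip(keys, dist):
            info.min_cross_distance[key] = min(
                float(dm), info.min_cross_distance.get(key, math.inf)
            )
    for key, dm in info.min_cross_distance.items():
        if dm < 4.5:
            info.contact_residues.add(key)
        if dm < _BURIAL_BOUND:
            info.possible_interface.add(key)
    return pdb_text, info


def make_synthetic_pssm(sequence: str, n_homologs: int = 50, seed: int = 0):
    """Random but well-formed positional profile for a chain sequence."""
    from .sequence import PssmProfile

    rng = np.random.default_rng(seed)
    n = len(sequence)
    return PssmProfile(
        sequence=sequence,
        log_odds=np.round(rng.normal(0, 2, size=(n, 20)), 2),
        percentages=np.round(rng.uniform(0, 100, size=(n, 20)), 1),
        n_homologs=n_homologs,
    )
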