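"""Reading protein-protein complexes from PDB files.

Only protein ATOM records are retained: waters, ions, ligands and nucleic
acids are dropped.  Alternate locations are resolved to the
highest-occupancy conformer (ties keep the first encountered).  Modified
residues with an unambiguous parent (MSE, SEP, ...) are renamed to that
parent; anything else non-standard is dropped with a warning.

A complex is described by two disjoint chain groups; which group is "A"
and which is "B" is arbitrary and no downstream feature depends on it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from ._aa import AA3_TO_1, NONSTANDARD_PARENT, STANDARD_RESIDUES

logger = logging.getLogger(__name__)

#: (chain_id, res_seq, i_code) — author numbering, preserved end to end.
ResidueKey = tuple[str, int, str]


class PDBParseError(ValueError):
    """Malformed or unusable PDB input."""


class ComplexValidationError(ValueError):
    """Chain groups that do not describe a valid two-partner complex."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]
    chain_id: str
    res_seq: int
    i_code: str
    res_name: str
    alt_loc: str = ""
    occupancy: float = 1.0

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.i_code)


@dataclass(frozen=True)
class ComplexStructure:
    atoms: tuple[Atom, ...]
    group_a: frozenset[str]
    group_b: frozenset[str]
    source_id: str = ""

    def group_of(self, chain_id: str) -> str:
        if chain_id in self.group_a:
            return "A"
        if chain_id in self.group_b:
            return "B"
        raise KeyError(chain_id)

    def atoms_in_group(self, group: str) -> tuple[Atom, ...]:
        chains = self.group_a if group == "A" else self.group_b
        return tuple(a for a in self.atoms if a.chain_id in chains)

    def residue_keys(self) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def residue_names(self) -> dict[ResidueKey, str]:
        return {a.residue_key: a.res_name for a in self.atoms}

    def swapped(self) -> "ComplexStructure":
        return replace(self, group_a=self.group_b, group_b=self.group_a)


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    # PDB convention: columns 13-14 hold the element, right-justified;
    # names starting in col 13 with a digit (e.g. "1HB1") are hydrogens.
    if stripped and stripped[0].isdigit():
        return "H"
    alpha = "".join(ch for ch in stripped if ch.isalpha())
    if not alpha:
        return ""
    if alpha[:2].upper() in ("SE", "CL", "BR", "FE", "ZN", "MG"):
        return alpha[:2].upper()
    return alpha[0].upper()


def parse_structure(pdb_text: str) -> list[Atom]:
    """Parse PDB text into protein atoms.

    Returns only ATOM records whose residue is (or maps to) one of the 20
    standard amino acids.  Raises :class:`PDBParseError` when coordinate
    fields are malformed (naming the line) or when no protein atom
    survives filtering.
    """
    raw: list[Atom] = []
    dropped_resnames: set[str] = set()
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith("ATOM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM record too short")
        res_name = line[17:20].strip().upper()
        if res_name in NONSTANDARD_PARENT:
            res_name = NONSTANDARD_PARENT[res_name]
        if res_name not in STANDARD_RESIDUES:
            dropped_resnames.add(res_name)
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(
                f"line {lineno}: malformed coordinate fields ({exc})"
            ) from None
        if not all(np.isfinite([x, y, z])):
            raise PDBParseError(f"line {lineno}: non-finite coordinates")
        try:
            res_seq = int(line[22:26])
        except ValueError:
            raise PDBParseError(f"line {lineno}: malformed residue number") from None
        occ_field = line[54:60].strip() if len(line) >= 60 else ""
        try:
            occupancy = float(occ_field) if occ_field else 1.0
        except ValueError:
            occupancy = 1.0
        name = line[12:16].strip()
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(line[12:16])
        raw.append(
            Atom(
                name=name,
                element=element,
                coords=(x, y, z),
                chain_id=line[21],
                res_seq=res_seq,
                i_code=line[26].strip() if len(line) > 26 else "",
                res_name=res_name,
                alt_loc=line[16].strip(),
                occupancy=occupancy,
            )
        )
    if dropped_resnames:
        logger.warning(
            "dropped non-protein/unmapped residues: %s",
            ", ".join(sorted(dropped_resnames)),
        )
    atoms = _resolve_altlocs(raw)
    if not atoms:
        raise PDBParseError("no protein atoms found in input")
    return atoms


def _resolve_altlocs(atoms: Sequence[Atom]) -> list[Atom]:
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom.chain_id, atom.res_seq, atom.i_code, atom.name)
        if key not in best:
            best[key] = atom
            order.append(key)
        elif atom.occupancy > best[key].occupancy:  # ties keep the first seen
            best[key] = atom
    return [best[k] for k in order]


def parse_chain_spec(spec: str) -> frozenset[str]:
    """Parse a comma-separated chain list such as ``"A"`` or ``"A,B"``."""
    chains = frozenset(c.strip() for c in spec.split(",") if c.strip())
    if not chains:
        raise ComplexValidationError(f"empty chain specification: {spec!r}")
    return chains


def build_complex(
    atoms: Iterable[Atom],
    group_a: str | Iterable[str],
    group_b: str | Iterable[str],
    source_id: str = "",
) -> ComplexStructure:
    """Partition atoms into two chain groups.

    Chains named in neither group are dropped (warning).  Overlapping
    groups or chain ids absent from the structure raise
    :class:`ComplexValidationError`.
    """
    ga = parse_chain_spec(group_a) if isinstance(group_a, str) else frozenset(group_a)
    gb = parse_chain_spec(group_b) if isinstance(group_b, str) else frozenset(group_b)
    if not ga or not gb:
        raise ComplexValidationError("both chain groups must be non-empty")
    overlap = ga & gb
    if overlap:
        raise ComplexValidationError(
            f"chain groups overlap: {sorted(overlap)}"
        )
    atoms = tuple(atoms)
    present = {a.chain_id for a in atoms}
    for group_name, group in (("A", ga), ("B", gb)):
        missing = group - present
        if missing:
            raise ComplexValidationError(
                f"chain id(s) {sorted(missing)} of group {group_name} "
                f"not present in structure (chains: {sorted(present)})"
            )
    unassigned = present - ga - gb
    if unassigned:
        logger.warning("dropping chains in neither group: %s", sorted(unassigned))
    kept = tuple(a for a in atoms if a.chain_id in ga or a.chain_id in gb)
    cx = ComplexStructure(atoms=kept, group_a=ga, group_b=gb, source_id=source_id)
    for g in ("A", "B"):
        if not cx.atoms_in_group(g):
            raise ComplexValidationError(f"group {g} contains no atoms")
    return cx


def load_complex(path, group_a: str, group_b: str) -> ComplexStructure:
    """Read a PDB file and build the two-partner complex."""
    with open(path) as fh:
        atoms = parse_structure(fh.read())
    import os

    return build_complex(
        atoms, group_a, group_b, source_id=os.path.basename(str(path))
    )


def write_pdb(atoms: Sequence[Atom]) -> str:
    """Serialize atoms back to minimal PDB ATOM records (parse round-trip)."""
    lines = []
    for i, a in enumerate(atoms, start=1):
        x, y, z = a.coords
        lines.append(
            f"ATOM  {i:5d} {a.name:^4s}{a.alt_loc or ' ':1s}{a.res_name:>3s} "
            f"{a.chain_id:1s}{a.res_seq:4d}{a.i_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def chain_sequences(atoms: Sequence[Atom]) -> dict[str, str]:
    """One-letter sequence per chain, in order of first appearance."""
    seqs: dict[str, list[str]] = {}
    seen: set[ResidueKey] = set()
    for a in atoms:
        key = a.residue_key
        if key in seen:
            continue
        seen.add(key)
        seqs.setdefault(a.chain_id, []).append(AA3_TO_1[a.res_name])
    return {c: "".join(s) for c, s in seqs.items()}


def residue_index_in_chain(atoms: Sequence[Atom]) -> dict[ResidueKey, int]:
    """0-based position of each residue within its chain sequence."""
    index: dict[ResidueKey, int] = {}
    counters: dict[str, int] = {}
    for a in atoms:
        key = a.residue_key
        if key in index:
            continue
        pos = counters.get(a.chain_id, 0)
        index[key] = pos
        counters[a.chain_id] = pos + 1
    return index
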