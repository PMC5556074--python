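"""Structure-based interface features.

Three families, 35 features in total per observation:

* 12 SASA-derived per-residue features computed from two Shrake-Rupley
  runs (complex state and isolated-monomer state);
* 3 per-residue intermolecular contact counts (atomic contacts within
  2.5 A and 4.0 A, and hydrophobic carbon-carbon contacts within 4.5 A
  between apolar residues);
* 20 protein-level interfacial composition counts (one per amino-acid
  type), attached identically to every residue of the complex.

The interface is defined by burial: a residue is interfacial when its
SASA in the isolated binding partner exceeds its SASA in the complex.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._aa import (
    BACKBONE_ATOMS,
    DEFAULT_RADIUS,
    HYDROPHOBIC_RESIDUES,
    MAX_SASA_GXG,
    STANDARD_RESIDUES,
    VDW_RADII,
)
from .structure import Atom, ComplexStructure, ResidueKey

logger = logging.getLogger(__name__)

PROBE_RADIUS = 1.4  # water probe, Angstrom
N_SPHERE_POINTS = 960
INTERFACE_TOL = 1e-6  # Angstrom^2 of burial required to call a residue interfacial

SASA_FEATURE_NAMES = (
    "sasa_complex",
    "sasa_monomer",
    "sasa_delta",
    "rel_sasa_complex",
    "rel_sasa_monomer",
    "rel_sasa_delta",
    "sc_sasa_complex",
    "sc_sasa_monomer",
    "sc_sasa_delta",
    "fraction_buried",
    "sasa_complex_over_typemean",
    "sasa_monomer_over_typemean",
)

CONTACT_FEATURE_NAMES = ("n_contacts_2p5", "n_contacts_4p0", "n_hydrophobic")


class NoInterfaceError(ValueError):
    """The two chain groups bury no residue upon complexation."""


def _unit_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def atom_radius(atom: Atom, radii: Mapping[str, float] | None = None) -> float:
    table = radii if radii is not None else VDW_RADII
    return table.get(atom.element.upper(), DEFAULT_RADIUS)


def shrake_rupley(
    atoms: Sequence[Atom],
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    radii: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent accessible surface area, Angstrom^2.

    Shrake-Rupley quadrature: each atom's expanded sphere (vdW + probe) is
    sampled at ``n_points`` quasi-uniform points; a point is accessible if
    it lies outside every neighbouring atom's expanded sphere.
    """
    if not atoms:
        return np.zeros(0)
    coords = np.array([a.coords for a in atoms], dtype=float)
    rad = np.array([atom_radius(a, radii) for a in atoms], dtype=float) + probe_radius
    sphere = _unit_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * rad.max()
    pairs = tree.query_pairs(max_reach, output_type="ndarray")
    neighbours: list[list[int]] = [[] for _ in atoms]
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        touching = d < rad[pairs[:, 0]] + rad[pairs[:, 1]]
        for i, j in pairs[touching]:
            neighbours[i].append(j)
            neighbours[j].append(i)
    sasa = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + rad[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours[i]:
            if not accessible.any():
                break
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > rad[j] * rad[j]
        sasa[i] = 4.0 * math.pi * rad[i] ** 2 * accessible.sum() / n_points
    return sasa


@dataclass
class SasaProfile:
    """Per-residue SASA in the complex and in the isolated monomer."""

    total_complex: dict[ResidueKey, float]
    total_monomer: dict[ResidueKey, float]
    sidechain_complex: dict[ResidueKey, float]
    sidechain_monomer: dict[ResidueKey, float]
    res_names: dict[ResidueKey, str]

    def delta(self, key: ResidueKey) -> float:
        return self.total_monomer[key] - self.total_complex[key]


def _per_residue(atoms: Sequence[Atom], sasa: np.ndarray):
    total: dict[ResidueKey, float] = {}
    side: dict[ResidueKey, float] = {}
    for atom, area in zip(atoms, sasa):
        key = atom.residue_key
        total[key] = total.get(key, 0.0) + float(area)
        if atom.name not in BACKBONE_ATOMS:
            side[key] = side.get(key, 0.0) + float(area)
        else:
            side.setdefault(key, 0.0)
    return total, side


def compute_sasa(
    atoms: Sequence[Atom],
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    radii: Mapping[str, float] | None = None,
) -> tuple[dict[ResidueKey, float], dict[ResidueKey, float]]:
    """Per-residue total and side-chain SASA for one set of atoms."""
    if not atoms:
        raise ValueError("compute_sasa requires at least one atom")
    sasa = shrake_rupley(atoms, probe_radius, n_points, radii)
    return _per_residue(atoms, sasa)


def sasa_profile(
    cx: ComplexStructure,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    radii: Mapping[str, float] | None = None,
) -> SasaProfile:
    """Two-state SASA: complex vs each group taken in isolation."""
    tot_cx, sc_cx = compute_sasa(cx.atoms, probe_radius, n_points, radii)
    tot_mon: dict[ResidueKey, float] = {}
    sc_mon: dict[ResidueKey, float] = {}
    for group in ("A", "B"):
        t, s = compute_sasa(cx.atoms_in_group(group), probe_radius, n_points, radii)
        tot_mon.update(t)
        sc_mon.update(s)
    return SasaProfile(
        total_complex=tot_cx,
        total_monomer=tot_mon,
        sidechain_complex=sc_cx,
        sidechain_monomer=sc_mon,
        res_names=cx.residue_names(),
    )


def interface_residues(
    cx: ComplexStructure,
    profile: SasaProfile | None = None,
    tol: float = INTERFACE_TOL,
    **sasa_kwargs,
) -> set[ResidueKey]:
    """Residues buried on complexation (monomer SASA - complex SASA > tol)."""
    if profile is None:
        profile = sasa_profile(cx, **sasa_kwargs)
    buried = {k for k in profile.total_complex if profile.delta(k) > tol}
    if not buried:
        raise NoInterfaceError(
            "no residue is buried upon complexation; the chain groups do "
            "not form an interface"
        )
    return buried


def sasa_feature_vector(
    res: ResidueKey,
    profile: SasaProfile,
    restype_reference: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """The 12 SASA features for one residue.

    Absolute complex/monomer/delta SASA, the same three normalised by the
    residue type's theoretical maximum (Gly-X-Gly), side-chain
    complex/monomer/delta, the fraction of monomer SASA buried, and the
    complex/monomer SASA relative to the mean over same-type residues.
    """
    if res not in profile.total_complex:
        raise KeyError(f"residue {res} absent from SASA profile")
    ref = restype_reference if restype_reference is not None else MAX_SASA_GXG
    res_name = profile.res_names[res]
    if res_name not in ref:
        raise ValueError(f"unknown residue type {res_name!r} in max-SASA reference")
    comp = profile.total_complex[res]
    mon = profile.total_monomer[res]
    delta = mon - comp
    max_sasa = ref[res_name]
    same_type = [k for k, n in profile.res_names.items() if n == res_name]
    mean_comp = float(np.mean([profile.total_complex[k] for k in same_type]))
    mean_mon = float(np.mean([profile.total_monomer[k] for k in same_type]))
    return {
        "sasa_complex": comp,
        "sasa_monomer": mon,
        "sasa_delta": delta,
        "rel_sasa_complex": comp / max_sasa,
        "rel_sasa_monomer": mon / max_sasa,
        "rel_sasa_delta": delta / max_sasa,
        "sc_sasa_complex": profile.sidechain_complex[res],
        "sc_sasa_monomer": profile.sidechain_monomer[res],
        "sc_sasa_delta": profile.sidechain_monomer[res] - profile.sidechain_complex[res],
        "fraction_buried": (delta / mon) if mon > 0 else 0.0,
        "sasa_complex_over_typemean": comp / mean_comp if mean_comp > 0 else 0.0,
        "sasa_monomer_over_typemean": mon / mean_mon if mean_mon > 0 else 0.0,
    }


def contact_counts(cx: ComplexStructure, cutoff: float) -> dict[ResidueKey, int]:
    """Per-residue intermolecular atomic contacts within ``cutoff`` Angstrom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atoms_a = cx.atoms_in_group("A")
    atoms_b = cx.atoms_in_group("B")
    counts = {a.residue_key: 0 for a in cx.atoms}
    ca = np.array([a.coords for a in atoms_a])
    cb = np.array([b.coords for b in atoms_b])
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), cutoff)
    for i, hits in enumerate(pairs):
        key_a = atoms_a[i].residue_key
        for j in hits:
            counts[key_a] += 1
            counts[atoms_b[j].residue_key] += 1
    return counts


def hydrophobic_contacts(
    cx: ComplexStructure, cutoff: float = 4.5
) -> dict[ResidueKey, int]:
    """Intermolecular C-C contacts (<= cutoff) between apolar residues.

    Both partner atoms must be carbons belonging to residues in the
    hydrophobic set {ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO}.
    """
    def eligible(atoms):
        return [
            a for a in atoms
            if a.element.upper() == "C" and a.res_name in HYDROPHOBIC_RESIDUES
        ]

    atoms_a = eligible(cx.atoms_in_group("A"))
    atoms_b = eligible(cx.atoms_in_group("B"))
    counts = {a.residue_key: 0 for a in cx.atoms}
    if atoms_a and atoms_b:
        ca = np.array([a.coords for a in atoms_a])
        cb = np.array([b.coords for b in atoms_b])
        pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), cutoff)
        for i, hits in enumerate(pairs):
            for j in hits:
                counts[atoms_a[i].residue_key] += 1
                counts[atoms_b[j].residue_key] += 1
    return counts


def interface_composition(
    cx: ComplexStructure, interface: set[ResidueKey] | None = None, **kwargs
) -> dict[str, int]:
    """Counts of interfacial residues per amino-acid type (whole complex).

    A protein-level feature: the same 20-vector is attached to every
    residue observation of the complex.
    """
    if interface is None:
        interface = interface_residues(cx, **kwargs)
    names = cx.residue_names()
    counts = {res: 0 for res in sorted(STANDARD_RESIDUES)}
    for key in interface:
        counts[names[key]] += 1
    return {f"ifc_count_{res}": n for res, n in counts.items()}


@dataclass
class StructuralFeatures:
    """All structure-based features for one complex, keyed by residue."""

    interface: set[ResidueKey]
    per_residue: dict[ResidueKey, dict[str, float]]
    composition: dict[str, int]
    profile: SasaProfile = field(repr=False, default=None)


def structural_features(
    cx: ComplexStructure,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    radii: Mapping[str, float] | None = None,
    restype_reference: Mapping[str, float] | None = None,
) -> StructuralFeatures:
    """Compute the full 35-feature structural block for a complex."""
    profile = sasa_profile(cx, probe_radius, n_points, radii)
    interface = interface_residues(cx, profile)
    c25 = contact_counts(cx, 2.5)
    c40 = contact_counts(cx, 4.0)
    hyd = hydrophobic_contacts(cx)
    composition = interface_composition(cx, interface)
    per_residue = {}
    for key in interface:
        feats = sasa_feature_vector(key, profile, restype_reference)
        feats["n_contacts_2p5"] = c25[key]
        feats["n_contacts_4p0"] = c40[key]
        feats["n_hydrophobic"] = hyd[key]
        per_residue[key] = feats
    return StructuralFeatures(
        interface=interface,
        per_residue=per_residue,
        composition=composition,
        profile=profile,
    )
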