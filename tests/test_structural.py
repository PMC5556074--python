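"""SASA, interface detection and contact counting."""

import math

import numpy as np
import pytest

from hotspots._aa import VDW_RADII
from hotspots.structural import (
    NoInterfaceError,
    contact_counts,
    hydrophobic_contacts,
    interface_composition,
    interface_residues,
    sasa_feature_vector,
    sasa_profile,
    shrake_rupley,
    structural_features,
)
from hotspots.structure import Atom, build_complex


def make_atom(name="CA", element="C", coords=(0.0, 0.0, 0.0), chain="A",
              res_seq=1, res_name="ALA"):
    return Atom(name=name, element=element, coords=coords, chain_id=chain,
                res_seq=res_seq, i_code="", res_name=res_name)


class TestShrakeRupley:
    def test_lone_atom_matches_closed_form(self):
        r = VDW_RADII["C"] + 1.4
        sasa = shrake_rupley([make_atom()], n_points=960)
        assert sasa[0] == pytest.approx(4 * math.pi * r**2, rel=1e-9)

    def test_fully_buried_atom_has_zero_area(self):
        # central atom caged by 26 neighbours on a 2 A grid
        atoms = [make_atom(coords=(0, 0, 0))]
        for dx in (-2, 0, 2):
            for dy in (-2, 0, 2):
                for dz in (-2, 0, 2):
                    if (dx, dy, dz) != (0, 0, 0):
                        atoms.append(make_atom(coords=(dx, dy, dz)))
        sasa = shrake_rupley(atoms, n_points=960)
        assert sasa[0] == pytest.approx(0.0, abs=1e-9)

    def test_dipeptide_stable_under_finer_quadrature(self):
        atoms = [
            make_atom("N", "N", (0.0, 0.8, 0.0)),
            make_atom("CA", "C", (1.2, 0.0, 0.0)),
            make_atom("C", "C", (2.4, 0.8, 0.0)),
            make_atom("O", "O", (2.5, 2.0, 0.0)),
            make_atom("N", "N", (3.4, 0.1, 0.2), res_seq=2),
            make_atom("CA", "C", (4.6, 0.8, 0.3), res_seq=2),
            make_atom("CB", "C", (5.3, 0.3, 1.5), res_seq=2),
        ]
        coarse = shrake_rupley(atoms, n_points=960)
        fine = shrake_rupley(atoms, n_points=9600)
        assert np.abs(coarse - fine).max() <= 0.02 * fine.max()

    def test_matches_independent_biopython_oracle(self, small_complex):
        import io
        import warnings

        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley as BioSR

        cx, _, pdb = small_complex
        ours = shrake_rupley(cx.atoms, n_points=960)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = PDBParser(QUIET=True).get_structure("x", io.StringIO(pdb))
            BioSR(probe_radius=1.4, n_points=960, radii_dict=dict(VDW_RADII)).compute(
                s, level="A"
            )
        theirs = np.array([a.sasa for a in s.get_atoms()])
        # same radii, same probe; only the sphere point sets differ
        assert np.abs(ours - theirs).sum() <= 0.02 * theirs.sum()


class TestInterface:
    def test_far_apart_chains_raise_no_interface(self, far_complex):
        with pytest.raises(NoInterfaceError):
            interface_residues(far_complex, n_points=240)

    def test_interface_bracketed_by_generator_oracle(self, small_complex):
        cx, info, _ = small_complex
        interface = interface_residues(cx)
        assert info.contact_residues <= interface <= info.possible_interface

    def test_group_swap_gives_identical_interface(self, small_complex):
        cx, _, _ = small_complex
        assert interface_residues(cx) == interface_residues(cx.swapped())

    def test_monomer_sasa_never_below_complex(self, small_complex):
        cx, _, _ = small_complex
        prof = sasa_profile(cx)
        for key in prof.total_complex:
            assert prof.total_monomer[key] >= prof.total_complex[key] - 0.5


class TestSasaFeatures:
    def test_unburied_residue_has_zero_deltas(self, small_complex):
        cx, info, _ = small_complex
        prof = sasa_profile(cx)
        key = max(prof.total_complex, key=lambda k: info.min_cross_distance[k])
        feats = sasa_feature_vector(key, prof)
        assert feats["sasa_delta"] == pytest.approx(0.0, abs=1e-6)
        assert feats["fraction_buried"] == pytest.approx(0.0, abs=1e-9)

    def test_vector_equals_hand_computed_ratios(self, small_complex):
        from hotspots._aa import MAX_SASA_GXG

        cx, _, _ = small_complex
        prof = sasa_profile(cx)
        key = sorted(interface_residues(cx, prof))[0]
        feats = sasa_feature_vector(key, prof)
        comp, mon = prof.total_complex[key], prof.total_monomer[key]
        res_name = prof.res_names[key]
        assert feats["sasa_delta"] == pytest.approx(mon - comp)
        assert feats["rel_sasa_monomer"] == pytest.approx(mon / MAX_SASA_GXG[res_name])
        assert feats["fraction_buried"] == pytest.approx((mon - comp) / mon)
        same = [k for k, n in prof.res_names.items() if n == res_name]
        mean_comp = np.mean([prof.total_complex[k] for k in same])
        assert feats["sasa_complex_over_typemean"] == pytest.approx(comp / mean_comp)

    def test_unknown_residue_type_rejected(self, small_complex):
        cx, _, _ = small_complex
        prof = sasa_profile(cx)
        key = next(iter(prof.total_complex))
        with pytest.raises(ValueError, match=prof.res_names[key]):
            sasa_feature_vector(key, prof, restype_reference={"XXX": 1.0})


class TestContacts:
    def test_single_pair_at_cutoff_boundaries(self):
        atoms = [
            make_atom(coords=(0, 0, 0), chain="A"),
            make_atom(coords=(3.0, 0, 0), chain="B"),
        ]
        cx = build_complex(atoms, "A", "B")
        assert contact_counts(cx, 2.5)[("A", 1, "")] == 0
        assert contact_counts(cx, 4.0)[("A", 1, "")] == 1

    def test_counts_match_brute_force_oracle(self, small_complex):
        cx, _, _ = small_complex
        for cutoff in (2.5, 4.0):
            counts = contact_counts(cx, cutoff)
            atoms_a = cx.atoms_in_group("A")
            atoms_b = cx.atoms_in_group("B")
            expected = {a.residue_key: 0 for a in cx.atoms}
            for a in atoms_a:
                for b in atoms_b:
                    d = math.dist(a.coords, b.coords)
                    if d <= cutoff:
                        expected[a.residue_key] += 1
                        expected[b.residue_key] += 1
            assert counts == expected

    def test_monotonic_in_cutoff_and_conserved_across_groups(self, small_complex):
        cx, _, _ = small_complex
        c25 = contact_counts(cx, 2.5)
        c40 = contact_counts(cx, 4.0)
        for key in c25:
            assert c25[key] <= c40[key]
        for counts in (c25, c40):
            total_a = sum(v for k, v in counts.items() if k[0] == "A")
            total_b = sum(v for k, v in counts.items() if k[0] == "B")
            assert total_a == total_b


class TestHydrophobicContacts:
    def test_leu_leu_carbon_pair_counts(self):
        atoms = [
            make_atom("CB", "C", (0, 0, 0), "A", 1, "LEU"),
            make_atom("CB", "C", (4.0, 0, 0), "B", 1, "LEU"),
        ]
        cx = build_complex(atoms, "A", "B")
        assert hydrophobic_contacts(cx)[("A", 1, "")] == 1

    def test_polar_residue_never_counts(self):
        atoms = [
            make_atom("CB", "C", (0, 0, 0), "A", 1, "SER"),
            make_atom("CB", "C", (3.0, 0, 0), "B", 1, "LEU"),
        ]
        cx = build_complex(atoms, "A", "B")
        assert all(v == 0 for v in hydrophobic_contacts(cx).values())

    def test_matches_brute_force_rule(self, small_complex):
        from hotspots._aa import HYDROPHOBIC_RESIDUES

        cx, _, _ = small_complex
        counts = hydrophobic_contacts(cx)
        expected = {a.residue_key: 0 for a in cx.atoms}
        for a in cx.atoms_in_group("A"):
            for b in cx.atoms_in_group("B"):
                if (
                    a.element == "C" and b.element == "C"
                    and a.res_name in HYDROPHOBIC_RESIDUES
                    and b.res_name in HYDROPHOBIC_RESIDUES
                    and math.dist(a.coords, b.coords) <= 4.5
                ):
                    expected[a.residue_key] += 1
                    expected[b.residue_key] += 1
        assert counts == expected


class TestComposition:
    def test_counts_sum_to_interface_size(self, small_complex):
        cx, _, _ = small_complex
        interface = interface_residues(cx)
        comp = interface_composition(cx, interface)
        assert sum(comp.values()) == len(interface)

    def test_all_ala_interface(self):
        atoms = [
            make_atom("CB", "C", (3.8 * i, 0, 0), "A", i + 1, "ALA")
            for i in range(3)
        ] + [
            make_atom("CB", "C", (3.8 * i, 4.0, 0), "B", i + 1, "ALA")
            for i in range(3)
        ]
        cx = build_complex(atoms, "A", "B")
        comp = interface_composition(cx, n_points=240)
        assert comp["ifc_count_ALA"] == 6
        assert sum(v for k, v in comp.items() if k != "ifc_count_ALA") == 0

    def test_group_swap_identical_vector(self, small_complex):
        cx, _, _ = small_complex
        assert interface_composition(cx) == interface_composition(cx.swapped())


def test_rigid_body_invariance(small_complex):
    """All structural features survive rotation + translation."""
    from scipy.spatial.transform import Rotation

    from dataclasses import replace

    cx, _, _ = small_complex
    rot = Rotation.from_euler("xyz", [31, -57, 12], degrees=True).as_matrix()
    shift = np.array([5.0, -3.0, 11.0])
    moved = replace(
        cx,
        atoms=tuple(
            replace(a, coords=tuple(rot @ np.array(a.coords) + shift))
            for a in cx.atoms
        ),
    )
    f0 = structural_features(cx, n_points=960)
    f1 = structural_features(moved, n_points=960)
    assert f0.interface == f1.interface
    assert f0.composition == f1.composition
    for key in f0.per_residue:
        for name, v in f0.per_residue[key].items():
            if name.startswith("n_"):
                assert f1.per_residue[key][name] == v
            else:
                # SASA quadrature is orientation-dependent at finite n_points
                assert f1.per_residue[key][name] == pytest.approx(v, abs=2.0, rel=0.05)
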