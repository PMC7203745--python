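"""Core hierarchy: StructureSet multimap, metric properties, dehydration."""

import math

import pytest

from structparse.structures import (Atom, Het, Chain, Model, StructureSet,
                                    get_by_id)
from tests.conftest import random_model


def atom(element, x=0.0, y=0.0, z=0.0, **kwargs):
    return Atom(element, x, y, z, **kwargs)


class TestStructureSet:

    def test_lookup_returns_all_members_with_id(self):
        r1 = Het("A.1", "GLY", kind=Het.RESIDUE)
        s = StructureSet(r1)
        assert get_by_id(s, "A.1") == [r1]

    def test_duplicate_ids_all_retrievable(self):
        # duplicate IDs arise from biological-assembly chain copies
        c1, c2 = Chain("B"), Chain("B")
        s = StructureSet(c1, c2)
        assert get_by_id(s, "B") == [c1, c2]
        assert len(s) == 2

    def test_missing_id_yields_empty_list_without_error(self):
        assert get_by_id(StructureSet(), "X") == []

    def test_iteration_covers_every_member(self):
        hets = [Het(f"A.{i}", "GLY") for i in range(5)] + [Het("A.1", "ALA")]
        s = StructureSet(*hets)
        assert sorted(id(h) for h in s) == sorted(id(h) for h in hets)

    def test_remove(self):
        h = Het("A.1", "GLY")
        s = StructureSet(h)
        s.remove(h)
        assert len(s) == 0 and get_by_id(s, "A.1") == []


class TestMassAndFormula:

    def test_empty_structure_mass_is_zero(self):
        assert Het("A.1", "LIG").mass == 0.0

    def test_water_mass_from_bundled_weights(self):
        water = Het("A.1", "HOH", atoms=[atom("O"), atom("H"), atom("H")])
        assert water.mass == pytest.approx(15.999 + 2 * 1.008)

    def test_single_carbon(self):
        assert Het("A.1", "LIG", atoms=[atom("C")]).mass == pytest.approx(12.011)

    def test_unknown_element_contributes_zero_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="structparse.elements"):
            mass = Het("A.1", "LIG", atoms=[atom("Qq"), atom("C")]).mass
        assert mass == pytest.approx(12.011)

    def test_formula_counts(self):
        water = Het("A.1", "HOH", atoms=[atom("O"), atom("H"), atom("H")])
        assert water.formula == {"O": 1, "H": 2}
        assert Het("A.1", "LIG").formula == {}
        glycine = Het("A.1", "GLY", atoms=[atom("N"), atom("C"), atom("C"),
                                           atom("O")])
        assert glycine.formula == {"N": 1, "C": 2, "O": 1}

    def test_mass_and_formula_additive_over_disjoint_parts(self):
        model = random_model()
        chains = list(model.chains())
        total = sum(c.mass for c in chains) + \
            sum(h.mass for h in model.ligands()) + \
            sum(w.mass for w in model.waters())
        assert model.mass == pytest.approx(total)
        combined = {}
        for structure in list(chains) + list(model.ligands()) + \
                list(model.waters()):
            for element, count in structure.formula.items():
                combined[element] = combined.get(element, 0) + count
        assert model.formula == combined


class TestCenterOfMassAndGyration:

    def test_single_atom_com_is_its_location(self):
        h = Het("A.1", "LIG", atoms=[atom("C", 1, 2, 3)])
        assert h.center_of_mass == pytest.approx((1, 2, 3))

    def test_equal_masses_midpoint(self):
        h = Het("A.1", "LIG", atoms=[atom("C", 0, 0, 0), atom("C", 2, 0, 0)])
        assert h.center_of_mass == pytest.approx((1, 0, 0))

    def test_water_com_matches_weighted_mean(self):
        o, h1, h2 = (atom("O", 0, 0, 0), atom("H", 0.96, 0, 0),
                     atom("H", -0.24, 0.93, 0))
        water = Het("A.1", "HOH", atoms=[o, h1, h2])
        mo, mh = 15.999, 1.008
        total = mo + 2 * mh
        expected = tuple((mo * getattr(o, d) + mh * getattr(h1, d)
                          + mh * getattr(h2, d)) / total for d in "xyz")
        assert water.center_of_mass == pytest.approx(expected, abs=1e-12)

    def test_empty_structure_com_errors(self):
        with pytest.raises(ValueError):
            Het("A.1", "LIG").center_of_mass

    def test_radius_of_gyration_single_atom_zero(self):
        assert Het("A.1", "LIG", atoms=[atom("C", 5, 5, 5)]).radius_of_gyration == 0.0

    def test_two_equal_atoms_two_angstroms_apart(self):
        h = Het("A.1", "LIG", atoms=[atom("C", 0, 0, 0), atom("C", 2, 0, 0)])
        assert h.radius_of_gyration == pytest.approx(1.0)

    def test_gyration_matches_brute_force(self):
        atoms = [atom("C", 1, 0, 0), atom("N", 0, 2, 0), atom("O", 0, 0, 3),
                 atom("S", -1, -1, -1)]
        h = Het("A.1", "LIG", atoms=atoms)
        masses = [12.011, 14.007, 15.999, 32.060]
        com = [sum(m * getattr(a, d) for m, a in zip(masses, atoms))
               / sum(masses) for d in "xyz"]
        ssq = sum(m * ((a.x - com[0]) ** 2 + (a.y - com[1]) ** 2
                       + (a.z - com[2]) ** 2)
                  for m, a in zip(masses, atoms))
        assert h.radius_of_gyration == pytest.approx(
            math.sqrt(ssq / sum(masses)), rel=1e-12)
        assert h.radius_of_gyration >= 0


class TestModel:

    def test_atom_count_conservation(self):
        model = random_model()
        by_parts = sum(len(c.atoms()) for c in model.chains()) + \
            sum(len(h.atoms()) for h in model.ligands()) + \
            sum(len(w.atoms()) for w in model.waters())
        assert len(model.atoms()) == by_parts

    def test_dehydrate_removes_only_waters(self):
        model = random_model(waters=2, ligands=1)
        non_water = {a.id for a in model.atoms()} - \
            {a.id for w in model.waters() for a in w.atoms()}
        model.dehydrate()
        assert len(model.waters()) == 0
        assert len(model.ligands()) == 1
        assert {a.id for a in model.atoms()} == non_water

    def test_dehydrate_idempotent(self):
        model = random_model(waters=0)
        before = {a.id for a in model.atoms()}
        model.dehydrate()
        model.dehydrate()
        assert {a.id for a in model.atoms()} == before

    def test_parent_wiring(self):
        model = random_model()
        for chain in model.chains():
            assert chain.model is model
            for residue in chain.residues:
                assert residue.chain is chain
                for a in residue.atoms():
                    assert a.het is residue and a.chain is chain \
                        and a.model is model

    def test_water_kind_inferred_from_name(self):
        assert Het("A.1", "HOH").kind == Het.WATER
        assert Het("A.1", "DOD").kind == Het.WATER
        assert Het("A.1", "ZN").kind == Het.LIGAND


class TestChain:

    def test_residues_ordered_by_number_and_insertion(self):
        residues = [Het("A.3", "GLY", kind=Het.RESIDUE),
                    Het("A.1", "ALA", kind=Het.RESIDUE),
                    Het("A.2B", "SER", kind=Het.RESIDUE),
                    Het("A.2", "VAL", kind=Het.RESIDUE)]
        chain = Chain("A", residues=residues)
        assert [r.id for r in chain.residues] == ["A.1", "A.2", "A.2B", "A.3"]

    def test_length_counts_present_residues_not_sequence(self):
        chain = Chain("A", residues=[Het("A.1", "GLY", kind=Het.RESIDUE)],
                      sequence="GAS")
        assert chain.length == 1
        assert len(chain.sequence) == 3


class TestAtom:

    def test_invalid_construction(self):
        with pytest.raises(ValueError):
            Atom("", 0, 0, 0)
        with pytest.raises(ValueError):
            Atom("C", float("nan"), 0, 0)
        with pytest.raises(ValueError):
            Atom("C", float("inf"), 0, 0)

    def test_distance(self):
        assert atom("C", 0, 0, 0).distance_to(atom("C", 3, 4, 0)) == \
            pytest.approx(5.0)
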