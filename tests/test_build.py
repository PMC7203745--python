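"""Data dictionary → object hierarchy, and assembly generation."""

import copy
import math

import pytest

from structparse.build import (build_file, generate_assembly,
                               structure_to_data_dict)
from structparse.fixtures import FixtureSpec, make_fixture


def test_single_model_file(rich_fixture):
    file = build_file(copy.deepcopy(rich_fixture["data"]))
    assert len(file.models) == 1
    model = file.model
    assert {c.id for c in model.chains()} == {"A", "B"}
    assert {l.id for l in model.ligands()} == {"A.100", "B.101"}
    assert len(model.waters()) == 2
    assert file.code == "1XYZ"
    assert file.rvalue == 0.193 and file.rfree == 0.229


def test_nmr_style_multi_model():
    fx = make_fixture(FixtureSpec(models=3, chains=(2,), seed=12))
    file = build_file(copy.deepcopy(fx["data"]))
    assert len(file.models) == 3
    ids = [{c.id for c in m.chains()} for m in file.models]
    assert ids[0] == ids[1] == ids[2] == {"A"}


def test_flatten_round_trip(rich_fixture):
    data = copy.deepcopy(rich_fixture["data"])
    file = build_file(data)
    flattened = structure_to_data_dict(file)
    assert flattened["models"] == data["models"]
    assert flattened["geometry"] == data["geometry"]
    assert flattened["missing_residues"] == data["missing_residues"]
    assert flattened["quality"] == data["quality"]
    assert flattened["description"] == data["description"]


def test_dangling_assembly_chain_warns_but_keeps_instruction(caplog):
    fx = make_fixture(FixtureSpec(seed=1))
    data = copy.deepcopy(fx["data"])
    data["geometry"]["assemblies"] = [{
        "id": 1, "software": None,
        "transformations": [{"chain_ids": ["Z"],
                             "matrix": [[1, 0, 0], [0, 1, 0], [0, 0, 1]],
                             "vector": [0, 0, 0]}]}]
    import logging
    with caplog.at_level(logging.WARNING, logger="structparse.build"):
        file = build_file(data)
    assert len(file.assemblies) == 1
    assert "Z" in caplog.text


IDENTITY = [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]


def _hexamer_file():
    rotations = [
        IDENTITY,
        [[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]],
        [[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]],
        [[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]],
        [[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]],
        [[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]],
    ]
    assembly = {"id": 1, "software": None, "transformations": [
        {"chain_ids": ["A"], "matrix": m, "vector": [10.0 * i, 0.0, 0.0]}
        for i, m in enumerate(rotations)]}
    fx = make_fixture(FixtureSpec(chains=(4,), ligands=(("A.50", "ZN", 1),),
                                  assemblies=(assembly,), seed=21))
    return build_file(copy.deepcopy(fx["data"]))


class TestGenerateAssembly:

    def test_identity_transform_reproduces_asymmetric_unit(self):
        fx = make_fixture(FixtureSpec(chains=(3,), waters=1, assemblies=(
            {"id": 1, "software": None,
             "transformations": [{"chain_ids": ["A"], "matrix": IDENTITY,
                                  "vector": [0.0, 0.0, 0.0]}]},), seed=2))
        file = build_file(copy.deepcopy(fx["data"]))
        assembly_model = generate_assembly(file, 1)
        source = file.model
        assert len(assembly_model.atoms()) == len(source.atoms())
        paired = {a.id: a for a in source.atoms()}
        for atom in assembly_model.atoms():
            assert atom.location == pytest.approx(
                paired[atom.id].location, abs=1e-9)

    def test_two_transformations_double_one_chain(self):
        fx = make_fixture(FixtureSpec(chains=(3,), assemblies=(
            {"id": 1, "software": None, "transformations": [
                {"chain_ids": ["A"], "matrix": IDENTITY,
                 "vector": [0.0, 0.0, 0.0]},
                {"chain_ids": ["A"], "matrix": IDENTITY,
                 "vector": [25.0, 0.0, 0.0]}]},), seed=2))
        file = build_file(copy.deepcopy(fx["data"]))
        model = generate_assembly(file, 1)
        copies = model.chain_set.get("A")
        assert len(copies) == 2
        assert all(chain.id == "A" for chain in copies)
        assert len(model.atoms()) == 2 * len(file.model.atoms())

    def test_hexamer_six_copies_under_one_id(self):
        file = _hexamer_file()
        model = generate_assembly(file, 1)
        assert len(model.chain_set.get("A")) == 6
        # attached zinc follows its chain through every operator
        assert len(model.ligand_set.get("A.50")) == 6
        assert len(model.atoms()) == 6 * len(file.model.atoms())

    def test_source_model_never_mutated(self):
        file = _hexamer_file()
        before = sorted(a.location for a in file.model.atoms())
        generate_assembly(file, 1)
        assert sorted(a.location for a in file.model.atoms()) == before
        assert len(file.model.chain_set.get("A")) == 1

    def test_rigid_transforms_preserve_intra_chain_distances(self):
        file = _hexamer_file()
        source_atoms = sorted(
            (a for c in file.model.chains() for a in c.atoms()),
            key=lambda a: a.id)
        reference = [math.dist(source_atoms[i].location,
                               source_atoms[i + 1].location)
                     for i in range(len(source_atoms) - 1)]
        model = generate_assembly(file, 1)
        for chain in model.chain_set.get("A"):
            atoms = sorted(chain.atoms(), key=lambda a: a.id)
            distances = [math.dist(atoms[i].location, atoms[i + 1].location)
                         for i in range(len(atoms) - 1)]
            assert distances == pytest.approx(reference, abs=1e-6)

    def test_unknown_assembly_id_lists_available(self):
        file = _hexamer_file()
        with pytest.raises(ValueError, match=r"available: \[1\]"):
            generate_assembly(file, 7)

    def test_optional_chain_renaming(self):
        file = _hexamer_file()
        model = generate_assembly(file, 1, rename_chains=True)
        ids = sorted(c.id for c in model.chains())
        assert ids == ["A", "A1", "A2", "A3", "A4", "A5"]
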