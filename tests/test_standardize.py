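"""File-specific dictionaries → the standard data dictionary."""

import pytest

import structparse as sp
from structparse.standardize import (standardize, resolve_altlocs,
                                     extract_missing_residues,
                                     extract_assemblies,
                                     empty_data_dictionary)
from structparse.fixtures import FixtureSpec, make_fixture


def record(name="CA", altloc="", chain="A", seq=1, icode=""):
    return {"chain": chain, "res_seq": seq, "icode": icode, "name": name,
            "altloc": altloc, "res_name": "GLY", "serial": 1,
            "x": 0.0, "y": 0.0, "z": 0.0, "charge": 0, "bvalue": 0.0,
            "element": "C", "polymer": True}


class TestResolveAltlocs:

    def test_alphabetically_first_letter_wins(self):
        kept = resolve_altlocs([record(altloc="A"), record(altloc="B")])
        assert [r["altloc"] for r in kept] == ["A"]

    def test_rule_without_letter_a(self):
        kept = resolve_altlocs([record(altloc="C"), record(altloc="B")])
        assert [r["altloc"] for r in kept] == ["B"]

    def test_blank_altlocs_always_kept(self):
        records = [record(name="N"), record(altloc="B"), record(altloc="A")]
        kept = resolve_altlocs(records)
        assert len(kept) == 2
        assert {r["altloc"] for r in kept} == {"", "A"}

    def test_no_altlocs_unchanged(self):
        records = [record(name="N"), record(name="CA")]
        assert resolve_altlocs(records) == records

    def test_groups_are_independent(self):
        records = [record(name="CA", altloc="B"), record(name="CA", altloc="C"),
                   record(name="CB", altloc="A"), record(name="CB", altloc="B")]
        kept = resolve_altlocs(records)
        assert {(r["name"], r["altloc"]) for r in kept} == \
            {("CA", "B"), ("CB", "A")}
        assert len(kept) <= len(records)


class TestMissingResidues:

    def test_remark_465(self):
        fx = make_fixture(FixtureSpec(missing_residues=(("A", 4, "GLY"),),
                                      seed=1))
        raw = sp.parse_pdb_string(fx["pdb_text"])
        assert extract_missing_residues(raw, "pdb") == \
            [{"id": "A.4", "name": "GLY"}]

    def test_cif_unobs_category(self):
        fx = make_fixture(FixtureSpec(missing_residues=(("A", 4, "GLY"),
                                                        ("B", 9, "ALA")),
                                      chains=(3, 2), seed=1))
        raw = sp.parse_mmcif_string(fx["cif_text"])
        assert extract_missing_residues(raw, "cif") == [
            {"id": "A.4", "name": "GLY"}, {"id": "B.9", "name": "ALA"}]

    def test_mmtf_carries_none(self):
        fx = make_fixture(FixtureSpec(missing_residues=(("A", 4, "GLY"),),
                                      seed=1))
        raw = sp.decode_mmtf(fx["mmtf_bytes"])
        assert extract_missing_residues(raw, "mmtf") == []


ASSEMBLY = {"id": 1, "software": None, "transformations": [
    {"chain_ids": ["A"],
     "matrix": [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
     "vector": [0.0, 0.0, 0.0]},
    {"chain_ids": ["A"],
     "matrix": [[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]],
     "vector": [5.5, 0.0, 0.0]}]}


class TestAssemblies:

    @pytest.mark.parametrize("fmt,parser", [
        ("pdb", sp.parse_pdb_string),
        ("cif", sp.parse_mmcif_string),
        ("mmtf", sp.decode_mmtf)])
    def test_two_operator_assembly_extracted(self, fmt, parser):
        fx = make_fixture(FixtureSpec(assemblies=(ASSEMBLY,), seed=1))
        raw = parser(fx["pdb_text"] if fmt == "pdb" else
                     fx["cif_text"] if fmt == "cif" else fx["mmtf_bytes"])
        assemblies = extract_assemblies(
            raw, fmt, internal_to_auth={"A": "A"})
        assert len(assemblies) == 1
        assert assemblies[0]["id"] == 1
        transformations = assemblies[0]["transformations"]
        assert len(transformations) == 2
        assert transformations[0]["matrix"] == ASSEMBLY["transformations"][0]["matrix"]
        assert transformations[1]["vector"] == [5.5, 0.0, 0.0]
        assert transformations[1]["chain_ids"] == ["A"]

    def test_no_assembly_records(self):
        fx = make_fixture(FixtureSpec(seed=1))
        raw = sp.parse_pdb_string(fx["pdb_text"])
        assert extract_assemblies(raw, "pdb") == []

    def test_software_field_from_pdb_and_cif(self):
        assembly = dict(ASSEMBLY, software="PISA")
        fx = make_fixture(FixtureSpec(assemblies=(assembly,), seed=1))
        for fmt, content in (("pdb", fx["pdb_text"]), ("cif", fx["cif_text"])):
            raw = sp.parse_filestring(content, fmt)
            assert extract_assemblies(raw, fmt,
                                      internal_to_auth={"A": "A"})[0][
                "software"] == "PISA"


class TestStandardize:

    def test_minimal_single_atom_pdb(self):
        text = ("ATOM      1  CA  GLY A   1       1.000   2.000   3.000"
                "  1.00  0.00           C  ").ljust(80)
        data = standardize(sp.parse_pdb_string(text), "pdb")
        polymer = data["models"][0]["polymer"]
        assert list(polymer) == ["A"]
        residues = polymer["A"]["residues"]
        assert list(residues) == ["A.1"]
        atoms = residues["A.1"]["atoms"]
        assert atoms == {"1": {"name": "CA", "element": "C", "x": 1.0,
                               "y": 2.0, "z": 3.0, "charge": 0,
                               "bvalue": 0.0}}

    def test_skeleton_always_complete(self):
        text = ("ATOM      1  CA  GLY A   1       1.000   2.000   3.000"
                "  1.00  0.00           C  ").ljust(80)
        data = standardize(sp.parse_pdb_string(text), "pdb")
        skeleton = empty_data_dictionary()
        assert set(data) == set(skeleton)
        for section in ("description", "experiment", "quality", "geometry"):
            assert set(data[section]) == set(skeleton[section])
        assert data["missing_residues"] == []

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError, match="empty structure"):
            standardize(sp.parse_pdb_string("HEADER    X\nEND\n"), "pdb")
        with pytest.raises(ValueError):
            standardize({}, "nonsense")

    def test_cross_format_convergence(self, rich_fixture):
        parsed = {
            fmt: standardize(sp.parse_filestring(content, fmt), fmt)
            for fmt, content in (("pdb", rich_fixture["pdb_text"]),
                                 ("cif", rich_fixture["cif_text"]),
                                 ("mmtf", rich_fixture["mmtf_bytes"]))}
        assert parsed["pdb"]["models"] == parsed["cif"]["models"] == \
            parsed["mmtf"]["models"]
        assert parsed["pdb"]["geometry"] == parsed["cif"]["geometry"] == \
            parsed["mmtf"]["geometry"]
        assert parsed["pdb"]["missing_residues"] == \
            parsed["cif"]["missing_residues"] != []
        assert parsed["mmtf"]["missing_residues"] == []
        assert parsed["pdb"]["quality"] == parsed["cif"]["quality"] == \
            parsed["mmtf"]["quality"]

    def test_each_format_matches_expected_dictionary(self, rich_fixture):
        for fmt, content in (("pdb", rich_fixture["pdb_text"]),
                             ("cif", rich_fixture["cif_text"]),
                             ("mmtf", rich_fixture["mmtf_bytes"])):
            data = standardize(sp.parse_filestring(content, fmt), fmt)
            assert data == rich_fixture["data_" + fmt]

    def test_deterministic(self, rich_fixture):
        raw1 = sp.parse_pdb_string(rich_fixture["pdb_text"])
        raw2 = sp.parse_pdb_string(rich_fixture["pdb_text"])
        assert standardize(raw1, "pdb") == standardize(raw2, "pdb")

    def test_multi_model_entry(self):
        fx = make_fixture(FixtureSpec(models=3, chains=(2,), seed=6))
        for fmt, content in (("pdb", fx["pdb_text"]), ("cif", fx["cif_text"]),
                             ("mmtf", fx["mmtf_bytes"])):
            data = standardize(sp.parse_filestring(content, fmt), fmt)
            assert len(data["models"]) == 3
            assert list(data["models"][0]["polymer"]) == \
                list(data["models"][2]["polymer"]) == ["A"]
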