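"""Deterministic synthetic-structure generator for offline testing.

A :class:`FixtureSpec` describes a small structure (chains, ligands,
waters, models, altloc groups, missing residues, assemblies); from it and
its seed, :func:`make_fixture` produces mutually consistent renderings in
all three formats plus the expected standard data dictionary. The
renderings and the expected dictionary are assembled here with independent
template code — never through the package's parsers or writers — so tests
against them are non-circular.

Coordinates are quantized to 3 decimals and B-factors to 2 at generation
time, the precision of the text formats, so text round trips are exact.
Atom serial numbers are assigned once per model and reused verbatim in
every rendering (alternate-location conformers share their atom's serial),
so the three data dictionaries converge on identical atom keys. The
geometry is a topological/metric scaffold, not biophysically real.
"""

import copy
import random
import struct
from dataclasses import dataclass, field

import msgpack

from .elements import ATOMIC_WEIGHTS, CODES_3TO1, CODES_1TO3

_RESIDUE_CYCLE = ["GLY", "ALA", "SER", "VAL", "LEU", "THR", "PRO", "ASP"]
_RESIDUE_ATOMS = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
_LIGAND_ELEMENT_CYCLE = ["C", "O", "N"]
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

_MONTHS = ["JAN", "FEB", "MAR", "APR", "MAY", "JUN",
           "JUL", "AUG", "SEP", "OCT", "NOV", "DEC"]


@dataclass(frozen=True)
class FixtureSpec:
    """Description of one synthetic structure.

    ``chains`` gives the residue count per chain (IDs A, B, ...);
    ``ligands`` is a tuple of (dotted het id, name, atom count);
    ``altloc_groups`` is a tuple of letter tuples, group *i* applying to
    the CA atom of residue *i* of the first chain; ``missing_residues``
    is a tuple of (chain id, residue number, residue name); ``assemblies``
    is a tuple of assembly-instruction dicts (id, software,
    transformations).
    """
    chains: tuple = (3,)
    ligands: tuple = ()
    waters: int = 0
    models: int = 1
    altloc_groups: tuple = ()
    missing_residues: tuple = ()
    assemblies: tuple = ()
    seed: int = 0
    code: str = "1XYZ"
    title: str = "SYNTHETIC TEST STRUCTURE"
    serial_start: int = 1
    software: object = None

    def __post_init__(self):
        if self.models < 1 or self.waters < 0 or \
                any(n < 0 for n in self.chains):
            raise ValueError("Fixture counts must be non-negative "
                             "(and at least one model)")


_METADATA = {
    "deposition_date": "2020-02-11",
    "classification": "SYNTHETIC",
    "keywords": ["PARSER", "TEST"],
    "authors": ["J.DOE", "R.ROE"],
    "technique": "X-RAY DIFFRACTION",
    "source_organism": "ESCHERICHIA COLI",
    "expression_system": "ESCHERICHIA COLI BL21",
    "resolution": 2.0,
    "rvalue": 0.193,
    "rfree": 0.229,
}


def _ligand_atoms(name, count):
    if count == 1 and name.upper() in ATOMIC_WEIGHTS and len(name) <= 2:
        return [(name.upper(), name.upper(), 2 if name.upper() == "ZN" else 0)]
    return [(f"{_LIGAND_ELEMENT_CYCLE[i % 3]}{i + 1}",
             _LIGAND_ELEMENT_CYCLE[i % 3], 0) for i in range(count)]


def _split_id(het_id):
    chain, _, tail = het_id.partition(".")
    number = "".join(c for c in tail if c.isdigit() or c == "-")
    icode = "".join(c for c in tail if c.isalpha())
    return chain, int(number) if number else 0, icode


def _build_sites(spec, rng):
    """One model's worth of sites, in serial order.

    A site is (kind, chain, het_id, res_name, atoms) where each atom is a
    dict with serial/name/element/charge/altloc/x/y/z/bvalue; altloc
    conformers are consecutive atoms sharing a serial.
    """
    sites = []
    serial = spec.serial_start - 1

    def coords():
        return (round(rng.uniform(-30, 30), 3), round(rng.uniform(-30, 30), 3),
                round(rng.uniform(-30, 30), 3))

    def make_atom(name, element, charge, altloc=""):
        x, y, z = coords()
        return {"serial": serial, "name": name, "element": element,
                "charge": charge, "altloc": altloc, "x": x, "y": y, "z": z,
                "bvalue": round(rng.uniform(5.0, 60.0), 2)}

    for chain_index, residue_count in enumerate(spec.chains):
        chain_id = _CHAIN_IDS[chain_index]
        for residue_index in range(residue_count):
            res_name = _RESIDUE_CYCLE[residue_index % len(_RESIDUE_CYCLE)]
            atoms = []
            for atom_name, element in _RESIDUE_ATOMS:
                serial += 1
                if chain_index == 0 and atom_name == "CA" and \
                        residue_index < len(spec.altloc_groups):
                    for letter in sorted(spec.altloc_groups[residue_index]):
                        atoms.append(make_atom(atom_name, element, 0, letter))
                else:
                    atoms.append(make_atom(atom_name, element, 0))
            sites.append(("polymer", chain_id,
                          f"{chain_id}.{residue_index + 1}", res_name, atoms))
    for het_id, name, count in sorted(spec.ligands,
                                      key=lambda l: _split_id(l[0])[:2]):
        atoms = []
        for atom_name, element, charge in _ligand_atoms(name, count):
            serial += 1
            atoms.append(make_atom(atom_name, element, charge))
        sites.append(("non-polymer", _split_id(het_id)[0], het_id, name,
                      atoms))
    water_chain = _CHAIN_IDS[0] if spec.chains else "W"
    for water_index in range(spec.waters):
        serial += 1
        sites.append(("water", water_chain,
                      f"{water_chain}.{400 + water_index}", "HOH",
                      [make_atom("O", "O", 0)]))
    return sites


def _sequence_for(spec, chain_index):
    chain_id = _CHAIN_IDS[chain_index]
    entries = [(number + 1,
                _RESIDUE_CYCLE[number % len(_RESIDUE_CYCLE)])
               for number in range(spec.chains[chain_index])]
    entries += [(number, name) for chain, number, name
                in spec.missing_residues if chain == chain_id]
    return "".join(CODES_3TO1.get(name, "X")
                   for _, name in sorted(entries))


def _winning_atoms(atoms):
    """Collapse altloc conformers onto the alphabetically first letter."""
    winners = {}
    for atom in atoms:
        current = winners.get(atom["serial"])
        if current is None or (atom["altloc"] or "0") < \
                (current["altloc"] or "0"):
            winners[atom["serial"]] = atom
    return [winners[serial] for serial in sorted(winners)]


def _expected_data(spec, models_sites):
    data = {
        "description": {"code": spec.code, "title": spec.title,
                        "deposition_date": _METADATA["deposition_date"],
                        "classification": _METADATA["classification"],
                        "keywords": list(_METADATA["keywords"]),
                        "authors": list(_METADATA["authors"])},
        "experiment": {"technique": _METADATA["technique"],
                       "source_organism": _METADATA["source_organism"],
                       "expression_system": _METADATA["expression_system"]},
        "quality": {"resolution": _METADATA["resolution"],
                    "rvalue": _METADATA["rvalue"],
                    "rfree": _METADATA["rfree"]},
        "geometry": {"assemblies": [
            {"id": assembly["id"], "software": assembly.get("software"),
             "transformations": [
                 {"chain_ids": list(t["chain_ids"]),
                  "matrix": [[float(v) for v in row] for row in t["matrix"]],
                  "vector": [float(v) for v in t["vector"]]}
                 for t in assembly["transformations"]]}
            for assembly in spec.assemblies]},
        "models": [],
        "missing_residues": [
            {"id": f"{chain}.{number}", "name": name}
            for chain, number, name in spec.missing_residues],
    }
    for sites in models_sites:
        model = {"polymer": {}, "non-polymer": {}, "water": {}}
        for kind, chain_id, het_id, res_name, atoms in sites:
            atom_map = {
                str(atom["serial"]): {
                    "name": atom["name"], "element": atom["element"],
                    "x": atom["x"], "y": atom["y"], "z": atom["z"],
                    "charge": atom["charge"], "bvalue": atom["bvalue"]}
                for atom in _winning_atoms(atoms)}
            if kind == "polymer":
                chain_index = _CHAIN_IDS.index(chain_id)
                chain = model["polymer"].setdefault(chain_id, {
                    "internal_id": chain_id,
                    "sequence": _sequence_for(spec, chain_index),
                    "residues": {}})
                chain["residues"][het_id] = {"name": res_name,
                                             "atoms": atom_map}
            else:
                model[kind][het_id] = {"name": res_name, "atoms": atom_map}
        data["models"].append(model)
    return data


def degrade_for_format(data, filetype):
    """The data dictionary a given format can actually carry.

    PDB and mmCIF carry everything the generator emits; the MMTF container
    has no fields for classification, keywords, authors, source organism,
    expression system, missing residues or assembly software.
    """
    data = copy.deepcopy(data)
    if filetype == "mmtf":
        data["description"]["classification"] = None
        data["description"]["keywords"] = []
        data["description"]["authors"] = []
        data["experiment"]["source_organism"] = None
        data["experiment"]["expression_system"] = None
        data["missing_residues"] = []
        for assembly in data["geometry"]["assemblies"]:
            assembly["software"] = None
    return data


# ----------------------------------------------------------- PDB template

def _render_pdb(spec, models_sites):
    year, month, day = (int(x) for x in
                        _METADATA["deposition_date"].split("-"))
    date = f"{day:02d}-{_MONTHS[month - 1]}-{year % 100:02d}"
    lines = [
        f"HEADER    {_METADATA['classification']:<40}{date:<9}   {spec.code:<4}",
        f"TITLE     {spec.title}",
        f"KEYWDS    {', '.join(_METADATA['keywords'])}",
        f"AUTHOR    {','.join(_METADATA['authors'])}",
        f"EXPDTA    {_METADATA['technique']}",
        f"SOURCE    ORGANISM_SCIENTIFIC: {_METADATA['source_organism']};",
        f"SOURCE   2 EXPRESSION_SYSTEM: {_METADATA['expression_system']};",
        f"REMARK   2 RESOLUTION. {_METADATA['resolution']:>7.2f} ANGSTROMS.",
        f"REMARK   3   R VALUE            (WORKING SET) : {_METADATA['rvalue']}",
        f"REMARK   3   FREE R VALUE                     : {_METADATA['rfree']}",
    ]
    for assembly in spec.assemblies:
        lines.append(f"REMARK 350 BIOMOLECULE: {assembly['id']}")
        if assembly.get("software"):
            lines.append(f"REMARK 350 SOFTWARE USED: {assembly['software']}")
        for op_number, transformation in enumerate(
                assembly["transformations"], start=1):
            lines.append("REMARK 350 APPLY THE FOLLOWING TO CHAINS: "
                         + ", ".join(transformation["chain_ids"]))
            for row in range(3):
                values = list(transformation["matrix"][row]) + \
                    [transformation["vector"][row]]
                lines.append(f"REMARK 350   BIOMT{row + 1}{op_number:>4}"
                             + "".join(f"{float(v):>10.6f}"
                                       for v in values[:3])
                             + f"{float(values[3]):>15.5f}")
    if spec.missing_residues:
        lines.append("REMARK 465 MISSING RESIDUES")
        lines.append("REMARK 465   M RES C SSSEQI")
        for chain, number, name in spec.missing_residues:
            lines.append(f"REMARK 465     {name:>3} {chain:1} {number:>5}")
    for chain_index in range(len(spec.chains)):
        sequence = _sequence_for(spec, chain_index)
        names = [CODES_1TO3.get(letter, "UNK") for letter in sequence]
        for line_number, start in enumerate(range(0, len(names), 13),
                                            start=1):
            chunk = " ".join(f"{n:>3}" for n in names[start:start + 13])
            lines.append(f"SEQRES {line_number:>3} {_CHAIN_IDS[chain_index]:1}"
                         f" {len(names):>4}  {chunk}")
    multi = len(models_sites) > 1
    for model_number, sites in enumerate(models_sites, start=1):
        if multi:
            lines.append(f"MODEL     {model_number:>4}")
        previous_chain = None
        for kind, chain_id, het_id, res_name, atoms in sites:
            if kind == "polymer" and previous_chain not in (None, chain_id):
                lines.append("TER")
            if kind != "polymer" and previous_chain is not None:
                lines.append("TER")
                previous_chain = None
            record = "ATOM" if kind == "polymer" else "HETATM"
            _, number, icode = _split_id(het_id)
            for atom in atoms:
                name = (f" {atom['name']:<3}" if len(atom["name"]) < 4
                        and len(atom["element"]) < 2 else f"{atom['name']:<4}")
                charge = ("  " if not atom["charge"] else
                          f"{abs(atom['charge'])}"
                          f"{'+' if atom['charge'] > 0 else '-'}")
                lines.append(
                    f"{record:<6}{atom['serial']:>5} {name}"
                    f"{atom['altloc'] or ' '}{res_name:>3} {chain_id:1}"
                    f"{number:>4}{icode or ' ':1}   "
                    f"{atom['x']:>8.3f}{atom['y']:>8.3f}{atom['z']:>8.3f}"
                    f"{0.5 if atom['altloc'] else 1.0:>6.2f}"
                    f"{atom['bvalue']:>6.2f}          "
                    f"{atom['element']:>2}{charge}")
            if kind == "polymer":
                previous_chain = chain_id
        if previous_chain is not None:
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(line.ljust(80)[:80] for line in lines) + "\n"


# ----------------------------------------------------------- CIF template

def _quote(value):
    text = str(value)
    if any(c.isspace() for c in text) or not text:
        return f"'{text}'"
    return text


def _render_cif(spec, models_sites):
    lines = [f"data_{spec.code}",
             f"_entry.id   {spec.code}",
             f"_struct.title   {_quote(spec.title)}",
             f"_pdbx_database_status.recvd_initial_deposition_date   "
             f"{_METADATA['deposition_date']}",
             f"_struct_keywords.pdbx_keywords   "
             f"{_quote(_METADATA['classification'])}",
             f"_struct_keywords.text   {_quote(', '.join(_METADATA['keywords']))}",
             f"_exptl.method   {_quote(_METADATA['technique'])}",
             "_entity_src_gen.pdbx_gene_src_scientific_name   "
             + _quote(_METADATA["source_organism"]),
             "_entity_src_gen.pdbx_host_org_scientific_name   "
             + _quote(_METADATA["expression_system"]),
             f"_refine.ls_d_res_high   {_METADATA['resolution']}",
             f"_refine.ls_R_factor_R_work   {_METADATA['rvalue']}",
             f"_refine.ls_R_factor_R_free   {_METADATA['rfree']}",
             "loop_", "_audit_author.pdbx_ordinal", "_audit_author.name"]
    for ordinal, author in enumerate(_METADATA["authors"], start=1):
        lines.append(f"{ordinal} {_quote(author)}")

    entities = []
    entity_of_chain = {}
    ligand_entities = {}
    water_entity = None
    for chain_index in range(len(spec.chains)):
        entities.append(("polymer", _CHAIN_IDS[chain_index]))
        entity_of_chain[_CHAIN_IDS[chain_index]] = str(len(entities))
    for _, name, _ in spec.ligands:
        if name not in ligand_entities:
            entities.append(("non-polymer", name))
            ligand_entities[name] = str(len(entities))
    if spec.waters:
        entities.append(("water", "HOH"))
        water_entity = str(len(entities))
    if entities:
        lines += ["loop_", "_entity.id", "_entity.type"]
        lines += [f"{i + 1} {etype}" for i, (etype, _) in enumerate(entities)]
    if spec.chains:
        lines += ["loop_", "_entity_poly.entity_id", "_entity_poly.type",
                  "_entity_poly.pdbx_seq_one_letter_code",
                  "_entity_poly.pdbx_strand_id"]
        for chain_index in range(len(spec.chains)):
            chain_id = _CHAIN_IDS[chain_index]
            lines.append(f"{entity_of_chain[chain_id]} polypeptide(L) "
                         f"{_sequence_for(spec, chain_index) or '?'} "
                         f"{chain_id}")
    if spec.assemblies:
        lines += ["loop_", "_pdbx_struct_assembly.id",
                  "_pdbx_struct_assembly.method_details"]
        for assembly in spec.assemblies:
            lines.append(f"{assembly['id']} "
                         f"{_quote(assembly['software']) if assembly.get('software') else '?'}")
        lines += ["loop_", "_pdbx_struct_assembly_gen.assembly_id",
                  "_pdbx_struct_assembly_gen.oper_expression",
                  "_pdbx_struct_assembly_gen.asym_id_list"]
        op_counter = 0
        oper_rows = []
        for assembly in spec.assemblies:
            for transformation in assembly["transformations"]:
                op_counter += 1
                lines.append(f"{assembly['id']} {op_counter} "
                             f"{','.join(transformation['chain_ids'])}")
                oper_rows.append((op_counter, transformation))
        lines += ["loop_", "_pdbx_struct_oper_list.id",
                  "_pdbx_struct_oper_list.type"]
        lines += [f"_pdbx_struct_oper_list.matrix[{i}][{j}]"
                  for i in (1, 2, 3) for j in (1, 2, 3)]
        lines += [f"_pdbx_struct_oper_list.vector[{i}]" for i in (1, 2, 3)]
        for op_id, transformation in oper_rows:
            values = [f"{float(v):.6f}" for row in transformation["matrix"]
                      for v in row]
            values += [f"{float(v):.5f}" for v in transformation["vector"]]
            lines.append(f"{op_id} 'identity operation' " + " ".join(values))
    if spec.missing_residues:
        lines += ["loop_", "_pdbx_unobs_or_zero_occ_residues.auth_asym_id",
                  "_pdbx_unobs_or_zero_occ_residues.auth_comp_id",
                  "_pdbx_unobs_or_zero_occ_residues.auth_seq_id",
                  "_pdbx_unobs_or_zero_occ_residues.PDB_ins_code"]
        for chain, number, name in spec.missing_residues:
            lines.append(f"{chain} {name} {number} ?")

    lines += ["loop_"] + [f"_atom_site.{column}" for column in (
        "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
        "label_comp_id", "label_asym_id", "label_entity_id", "label_seq_id",
        "pdbx_PDB_ins_code", "Cartn_x", "Cartn_y", "Cartn_z", "occupancy",
        "B_iso_or_equiv", "pdbx_formal_charge", "auth_seq_id",
        "auth_comp_id", "auth_asym_id", "auth_atom_id",
        "pdbx_PDB_model_num")]
    for model_number, sites in enumerate(models_sites, start=1):
        for kind, chain_id, het_id, res_name, atoms in sites:
            group = "ATOM" if kind == "polymer" else "HETATM"
            if kind == "polymer":
                entity_id = entity_of_chain[chain_id]
            elif kind == "water":
                entity_id = water_entity
            else:
                entity_id = ligand_entities[res_name]
            _, number, icode = _split_id(het_id)
            for atom in atoms:
                lines.append(" ".join(str(x) for x in (
                    group, atom["serial"], atom["element"], atom["name"],
                    atom["altloc"] or ".", res_name, chain_id, entity_id,
                    number, icode or "?", f"{atom['x']:.3f}",
                    f"{atom['y']:.3f}", f"{atom['z']:.3f}",
                    "0.50" if atom["altloc"] else "1.00",
                    f"{atom['bvalue']:.2f}", atom["charge"], number,
                    res_name, chain_id, atom["name"], model_number)))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------- MMTF template

def _bin(codec, values, param, payload):
    return struct.pack(">iii", codec, len(values), param) + payload


def _enc_int32(values):
    return _bin(4, values, 0, b"".join(struct.pack(">i", v) for v in values))


def _enc_strings(values, width=4):
    payload = b"".join(v.encode("ascii").ljust(width, b"\x00")
                       for v in values)
    return _bin(5, values, width, payload)


def _enc_chars(values):
    pairs = []
    for value in values:
        pairs += [ord(value) if value else 0, 1]
    return _bin(6, values, 0,
                b"".join(struct.pack(">i", v) for v in pairs))


def _enc_fixed(values, divisor):
    pairs = []
    for value in values:
        pairs += [int(round(value * divisor)), 1]
    return _bin(9, values, divisor,
                b"".join(struct.pack(">i", v) for v in pairs))


def _render_mmtf(spec, models_sites):
    chain_names, chain_ids, groups_per_chain, chains_per_model = [], [], [], []
    group_types, group_ids, ins_codes = [], [], []
    group_list, group_keys = [], {}
    xs, ys, zs, bfactors, occupancies, atom_ids, altlocs = \
        [], [], [], [], [], [], []
    entity_list = []

    for sites in models_sites:
        chain_groups = []  # (kind, chain name, [site, ...]) in order
        for site in sites:
            kind, chain_id = site[0], site[1]
            if chain_groups and chain_groups[-1][0] == kind and \
                    chain_groups[-1][1] == chain_id and kind == "polymer":
                chain_groups[-1][2].append(site)
            elif chain_groups and chain_groups[-1][0] == kind and \
                    chain_groups[-1][1] == chain_id:
                chain_groups[-1][2].append(site)
            else:
                chain_groups.append((kind, chain_id, [site]))
        # merge non-adjacent hets of the same chain/kind
        merged = []
        index_of = {}
        for kind, chain_id, group_sites in chain_groups:
            key = (kind, chain_id)
            if key in index_of and kind != "polymer":
                merged[index_of[key]][2].extend(group_sites)
            else:
                index_of[key] = len(merged)
                merged.append((kind, chain_id, list(group_sites)))
        chains_per_model.append(len(merged))
        for kind, chain_id, group_sites in merged:
            chain_index = len(chain_names)
            chain_names.append(chain_id)
            chain_ids.append(chain_id)
            groups_per_chain.append(len(group_sites))
            if kind == "polymer":
                sequence = _sequence_for(spec, _CHAIN_IDS.index(chain_id))
            else:
                sequence = ""
            entity_list.append(
                {"type": "polymer" if kind == "polymer" else kind,
                 "chainIndexList": [chain_index],
                 "sequence": sequence, "description": ""})
            for _, _, het_id, res_name, atoms in group_sites:
                key = (res_name,
                       tuple((a["name"], a["element"], a["charge"])
                             for a in atoms))
                if key not in group_keys:
                    group_keys[key] = len(group_list)
                    group_list.append({
                        "groupName": res_name,
                        "atomNameList": [a["name"] for a in atoms],
                        "elementList": [a["element"] for a in atoms],
                        "formalChargeList": [a["charge"] for a in atoms],
                        "singleLetterCode": "?", "chemCompType": "?",
                        "bondAtomList": [], "bondOrderList": []})
                group_types.append(group_keys[key])
                _, number, icode = _split_id(het_id)
                group_ids.append(number)
                ins_codes.append(icode)
                for atom in atoms:
                    xs.append(atom["x"])
                    ys.append(atom["y"])
                    zs.append(atom["z"])
                    bfactors.append(atom["bvalue"])
                    occupancies.append(0.5 if atom["altloc"] else 1.0)
                    atom_ids.append(atom["serial"])
                    altlocs.append(atom["altloc"])

    bio_assembly_list = []
    for assembly in spec.assemblies:
        transforms = []
        for transformation in assembly["transformations"]:
            indices = [i for i, name in enumerate(chain_names)
                       if name in transformation["chain_ids"]]
            matrix16 = []
            for row in range(3):
                matrix16 += [float(v) for v in transformation["matrix"][row]]
                matrix16.append(float(transformation["vector"][row]))
            matrix16 += [0.0, 0.0, 0.0, 1.0]
            transforms.append({"chainIndexList": indices,
                               "matrix": matrix16})
        bio_assembly_list.append({"name": str(assembly["id"]),
                                  "transformList": transforms})

    fields = {
        "mmtfVersion": "1.0.0",
        "mmtfProducer": "structparse-fixtures",
        "structureId": spec.code,
        "title": spec.title,
        "depositionDate": _METADATA["deposition_date"],
        "experimentalMethods": [_METADATA["technique"]],
        "resolution": _METADATA["resolution"],
        "rWork": _METADATA["rvalue"],
        "rFree": _METADATA["rfree"],
        "numModels": len(models_sites),
        "numChains": len(chain_names),
        "numGroups": len(group_ids),
        "numAtoms": len(xs),
        "numBonds": 0,
        "chainsPerModel": chains_per_model,
        "groupsPerChain": groups_per_chain,
        "chainIdList": _enc_strings(chain_ids),
        "chainNameList": _enc_strings(chain_names),
        "groupTypeList": _enc_int32(group_types),
        "groupIdList": _enc_int32(group_ids),
        "insCodeList": _enc_chars(ins_codes),
        "altLocList": _enc_chars(altlocs),
        "groupList": group_list,
        "xCoordList": _enc_fixed(xs, 1000),
        "yCoordList": _enc_fixed(ys, 1000),
        "zCoordList": _enc_fixed(zs, 1000),
        "bFactorList": _enc_fixed(bfactors, 100),
        "occupancyList": _enc_fixed(occupancies, 100),
        "atomIdList": _enc_int32(atom_ids),
        "entityList": entity_list,
        "bioAssemblyList": bio_assembly_list,
    }
    return msgpack.packb(fields, use_bin_type=True)


_ROTATIONS = [
    [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],        # identity
    [[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]],       # z, 90
    [[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]],      # x, 180
    [[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]],       # y, 90
    [[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]],      # z, 180
    [[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]],       # z, -90
]


def random_transformations(rng, count, chain_ids):
    """``count`` rigid transformations over ``chain_ids``, with rotation
    matrices exact at 6 decimals and translations quantized to 3."""
    transformations = []
    for i in range(count):
        transformations.append({
            "chain_ids": list(chain_ids),
            "matrix": _ROTATIONS[i % len(_ROTATIONS)],
            "vector": [round(rng.uniform(-20, 20), 3) for _ in range(3)]})
    return transformations


def fixture_matrix(count=20, seed=0):
    """A deterministic family of varied fixture specs.

    Cycles through chain layouts, ligand/water mixes, multi-model
    entries, altloc groups, missing residues and assembly instructions so
    that parser, standardizer, writer and assembly code paths are all
    exercised. Same count and seed, same specs, every run.
    """
    rng = random.Random(seed)
    specs = []
    for index in range(count):
        chains = [(3,), (4, 2), (2, 3, 2), (5,)][index % 4]
        ligands = []
        if index % 3 != 1:
            first = _CHAIN_IDS[0]
            ligands.append((f"{first}.{100 + index}", "ZN", 1))
        if index % 4 == 2:
            second = _CHAIN_IDS[min(1, len(chains) - 1)]
            ligands.append((f"{second}.150", "LIG", 3))
        waters = index % 3
        models = 3 if index % 5 == 4 else 1
        altloc_groups = (("A", "B"),) if index % 4 == 3 else ()
        if index % 6 == 5:
            altloc_groups = (("B", "C"), ("A", "C"))
        missing = ((("A", chains[0] + 1, "GLY"),)
                   if index % 3 == 0 else ())
        assemblies = ()
        if index % 2 == 0:
            chain_ids = [_CHAIN_IDS[i] for i in range(len(chains))]
            n_ops = 1 + index % 3
            assemblies = ({"id": 1, "software": None,
                           "transformations": random_transformations(
                               rng, n_ops, chain_ids)},)
        specs.append(FixtureSpec(
            chains=tuple(chains), ligands=tuple(ligands), waters=waters,
            models=models, altloc_groups=altloc_groups,
            missing_residues=missing, assemblies=assemblies,
            seed=rng.randrange(2 ** 31), code=f"{1000 + index}"))
    return specs


def make_fixture(spec):
    """Build a fixture bundle from a spec.

    Returns a dict with the expected standard data dictionary (``data``),
    the three renderings (``pdb_text``, ``cif_text``, ``mmtf_bytes``),
    the per-format expected dictionaries (``data_pdb``, ``data_cif``,
    ``data_mmtf``, reflecting what each format carries) and a built
    ``file`` object. Same spec, same bytes, every run.
    """
    total_atoms = (sum(spec.chains) * len(_RESIDUE_ATOMS)
                   + sum(count for _, _, count in spec.ligands)
                   + spec.waters)
    if spec.serial_start + total_atoms - 1 > 99999:
        raise ValueError("Fixture would exceed the PDB serial limit of 99999")
    rng = random.Random(spec.seed)
    models_sites = [_build_sites(spec, rng) for _ in range(spec.models)]
    data = _expected_data(spec, models_sites)
    from .build import build_file
    return {
        "spec": spec,
        "data": data,
        "data_pdb": degrade_for_format(data, "pdb"),
        "data_cif": degrade_for_format(data, "cif"),
        "data_mmtf": degrade_for_format(data, "mmtf"),
        "pdb_text": _render_pdb(spec, models_sites),
        "cif_text": _render_cif(spec, models_sites),
        "mmtf_bytes": _render_mmtf(spec, models_sites),
        "file": build_file(copy.deepcopy(data), source_format=None),
    }
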