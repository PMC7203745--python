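"""Serialize File objects back to PDB, mmCIF, MMTF and JSON.

The writers only emit records they can source from the data model; atom
serial numbers are renumbered sequentially per model on write (the PDB
serial field is five columns wide, so serials above 99999 are refused —
the historical limit of the format). Every PDB line is exactly 80
characters. MMTF coordinates use the fixed-point divisor 1000 and
B-factors the divisor 100, the format's conventions, so coordinates
survive an MMTF round trip to 0.001 Å.
"""

import json

from .elements import CODES_1TO3
from .build import structure_to_data_dict
from . import mmtf as mmtf_codec

_MONTHS = ["JAN", "FEB", "MAR", "APR", "MAY", "JUN",
           "JUL", "AUG", "SEP", "OCT", "NOV", "DEC"]


def _iter_model_structures(model_data):
    """Yield (kind, chain/het id, record) in canonical write order:
    polymer chains, then ligands, then waters."""
    for chain_id, chain in model_data["polymer"].items():
        yield "polymer", chain_id, chain
    for het_id, het in model_data["non-polymer"].items():
        yield "non-polymer", het_id, het
    for het_id, het in model_data["water"].items():
        yield "water", het_id, het


def _split_het_id(het_id):
    chain, _, tail = het_id.partition(".")
    number = "".join(c for c in tail if c.isdigit() or c == "-")
    icode = "".join(c for c in tail if c.isalpha())
    return chain, int(number) if number else 0, icode


# -------------------------------------------------------------------- PDB

def _pdb_date(iso):
    try:
        year, month, day = (int(x) for x in iso.split("-"))
        return f"{day:02d}-{_MONTHS[month - 1]}-{year % 100:02d}"
    except (ValueError, AttributeError, IndexError):
        return ""


def _pdb_atom_name(name, element):
    name = name or ""
    if len(name) < 4 and len(element or "") < 2:
        return f" {name:<3}"
    return f"{name:<4}"


def _pdb_charge(charge):
    charge = int(charge) if charge == int(charge) else charge
    if not charge:
        return "  "
    return f"{abs(charge)}{'+' if charge > 0 else '-'}"


def _wrap_record(record_name, text, width=70):
    lines = []
    words = text.split()
    current = ""
    for word in words:
        candidate = f"{current} {word}".strip()
        if len(candidate) > width and current:
            lines.append(current)
            current = word
        else:
            current = candidate
    if current:
        lines.append(current)
    out = []
    for number, line in enumerate(lines, start=1):
        cont = "  " if number == 1 else f"{number:>2}"
        out.append(f"{record_name:<6}  {cont}{line}" if number > 1
                   else f"{record_name:<6}    {line}")
    return out


def _pdb_atom_line(record_name, serial, record, chain, number, icode,
                   res_name):
    if serial > 99999:
        raise ValueError(f"Atom serial {serial} exceeds the PDB format "
                         f"maximum of 99999")
    if len(str(chain)) > 1:
        raise ValueError(f"Chain ID {chain!r} does not fit the PDB "
                         f"single-column chain field")
    return (f"{record_name:<6}{serial:>5} "
            f"{_pdb_atom_name(record['name'], record['element'])}"
            f" {res_name:>3} {chain:1}{number:>4}{icode or ' ':1}   "
            f"{record['x']:>8.3f}{record['y']:>8.3f}{record['z']:>8.3f}"
            f"{1.0:>6.2f}{record['bvalue']:>6.2f}          "
            f"{record['element']:>2}{_pdb_charge(record['charge'])}")


def write_pdb(file):
    """Render a File as PDB v3.3 fixed-column text (every line exactly 80
    characters, serials renumbered sequentially per model)."""
    data = structure_to_data_dict(file)
    lines = []
    description = data["description"]
    if description.get("classification") or description.get("code") \
            or description.get("deposition_date"):
        lines.append(
            f"HEADER    {description.get('classification') or '':<40}"
            f"{_pdb_date(description.get('deposition_date')):<9}   "
            f"{description.get('code') or '':<4}")
    if description.get("title"):
        lines.extend(_wrap_record("TITLE", description["title"]))
    if description.get("keywords"):
        lines.extend(_wrap_record("KEYWDS", ", ".join(description["keywords"])))
    if description.get("authors"):
        lines.extend(_wrap_record("AUTHOR", ",".join(description["authors"])))
    experiment = data["experiment"]
    if experiment.get("technique"):
        lines.extend(_wrap_record("EXPDTA", experiment["technique"]))
    source_parts = []
    if experiment.get("source_organism"):
        source_parts.append(
            f"ORGANISM_SCIENTIFIC: {experiment['source_organism']};")
    if experiment.get("expression_system"):
        source_parts.append(
            f"EXPRESSION_SYSTEM: {experiment['expression_system']};")
    if source_parts:
        lines.extend(_wrap_record("SOURCE", " ".join(source_parts)))
    quality = data["quality"]
    if quality.get("resolution") is not None:
        lines.append(f"REMARK   2 RESOLUTION. {quality['resolution']:>7.2f} "
                     f"ANGSTROMS.")
    if quality.get("rvalue") is not None:
        lines.append(f"REMARK   3   R VALUE            (WORKING SET) : "
                     f"{quality['rvalue']}")
    if quality.get("rfree") is not None:
        lines.append(f"REMARK   3   FREE R VALUE                     : "
                     f"{quality['rfree']}")
    for assembly in data["geometry"]["assemblies"]:
        lines.append(f"REMARK 350 BIOMOLECULE: {assembly['id']}")
        if assembly.get("software"):
            lines.append(f"REMARK 350 SOFTWARE USED: {assembly['software']}")
        for op_number, transformation in enumerate(
                assembly["transformations"], start=1):
            lines.append("REMARK 350 APPLY THE FOLLOWING TO CHAINS: "
                         + ", ".join(transformation["chain_ids"]))
            for row in range(3):
                values = transformation["matrix"][row] + \
                    [transformation["vector"][row]]
                lines.append(
                    f"REMARK 350   BIOMT{row + 1}{op_number:>4}"
                    + "".join(f"{v:>10.6f}" for v in values[:3])
                    + f"{values[3]:>15.5f}")
    if data["missing_residues"]:
        lines.append("REMARK 465 MISSING RESIDUES")
        lines.append("REMARK 465   M RES C SSSEQI")
        for entry in data["missing_residues"]:
            chain, number, icode = _split_het_id(entry["id"])
            lines.append(f"REMARK 465     {entry['name']:>3} {chain:1} "
                         f"{number:>5}{icode}")
    for chain_id, chain in data["models"][0]["polymer"].items():
        sequence = chain.get("sequence", "")
        if sequence:
            names = [CODES_1TO3.get(letter, "UNK") for letter in sequence]
            for line_number, start in enumerate(range(0, len(names), 13),
                                                start=1):
                chunk = " ".join(f"{n:>3}" for n in names[start:start + 13])
                lines.append(f"SEQRES {line_number:>3} {chain_id:1} "
                             f"{len(names):>4}  {chunk}")
    multi_model = len(data["models"]) > 1
    for model_number, model_data in enumerate(data["models"], start=1):
        if multi_model:
            lines.append(f"MODEL     {model_number:>4}")
        serial = 0
        for kind, structure_id, structure in _iter_model_structures(model_data):
            if kind == "polymer":
                last = None
                for het_id, residue in structure["residues"].items():
                    chain, number, icode = _split_het_id(het_id)
                    for atom in residue["atoms"].values():
                        serial += 1
                        lines.append(_pdb_atom_line(
                            "ATOM", serial, atom, chain, number, icode,
                            residue["name"]))
                    last = (chain, number, icode, residue["name"])
                if last is not None:
                    # TER carries no serial so atom numbering stays
                    # aligned with the mmCIF and MMTF renderings
                    lines.append(f"TER         {last[3]:>3} "
                                 f"{last[0]:1}{last[1]:>4}{last[2] or ' ':1}")
            else:
                chain, number, icode = _split_het_id(structure_id)
                for atom in structure["atoms"].values():
                    serial += 1
                    lines.append(_pdb_atom_line(
                        "HETATM", serial, atom, chain, number, icode,
                        structure["name"]))
        if multi_model:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(line.ljust(80)[:80] for line in lines) + "\n"


# -------------------------------------------------------------------- CIF

def _cif_value(value):
    if value is None or value == "":
        return "?"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, (int, float)):
        return repr(value) if isinstance(value, float) else str(value)
    text = str(value)
    if "\n" in text or ("'" in text and '"' in text):
        return ";" + text + "\n;"
    if any(c.isspace() for c in text) or text[0] in "_#$'\"[];" \
            or text.lower() in ("loop_", "stop_", "global_") \
            or text in ("?", "."):
        quote = '"' if "'" in text else "'"
        return f"{quote}{text}{quote}"
    return text


def _cif_loop(category, columns, rows):
    lines = ["loop_"]
    lines.extend(f"_{category}.{column}" for column in columns)
    for row in rows:
        values = [_cif_value(row.get(column)) for column in columns]
        line = ""
        for value in values:
            if value.startswith(";"):
                if line:
                    lines.append(line)
                lines.append(value)
                line = ""
            else:
                line = f"{line} {value}".strip()
        if line:
            lines.append(line)
    lines.append("#")
    return lines


def _cif_single(category, items):
    lines = []
    for key, value in items.items():
        rendered = _cif_value(value)
        if rendered.startswith(";"):
            lines.append(f"_{category}.{key}")
            lines.append(rendered)
        else:
            lines.append(f"_{category}.{key}   {rendered}")
    lines.append("#")
    return lines


def write_mmcif(file):
    """Render a File as an mmCIF text block that round-trips through the
    parser and standardizer."""
    data = structure_to_data_dict(file)
    description = data["description"]
    lines = [f"data_{description.get('code') or 'XXXX'}"]
    lines += _cif_single("entry", {"id": description.get("code")})
    if description.get("title"):
        lines += _cif_single("struct", {"title": description["title"]})
    if description.get("deposition_date"):
        lines += _cif_single("pdbx_database_status", {
            "recvd_initial_deposition_date": description["deposition_date"]})
    if description.get("classification") or description.get("keywords"):
        lines += _cif_single("struct_keywords", {
            "pdbx_keywords": description.get("classification"),
            "text": ", ".join(description.get("keywords") or []) or None})
    if description.get("authors"):
        lines += _cif_loop("audit_author", ["pdbx_ordinal", "name"],
                           [{"pdbx_ordinal": i, "name": name}
                            for i, name in enumerate(description["authors"],
                                                     start=1)])
    experiment = data["experiment"]
    if experiment.get("technique"):
        lines += _cif_single("exptl", {"method": experiment["technique"]})
    if experiment.get("source_organism") or experiment.get("expression_system"):
        lines += _cif_single("entity_src_gen", {
            "pdbx_gene_src_scientific_name": experiment.get("source_organism"),
            "pdbx_host_org_scientific_name":
                experiment.get("expression_system")})
    quality = data["quality"]
    if any(value is not None for value in quality.values()):
        lines += _cif_single("refine", {
            "ls_d_res_high": quality.get("resolution"),
            "ls_R_factor_R_work": quality.get("rvalue"),
            "ls_R_factor_R_free": quality.get("rfree")})

    # entities: one per polymer chain, one per distinct ligand name, one water
    entities = []
    entity_of_chain = {}
    entity_of_ligand_name = {}
    water_entity = None
    model0 = data["models"][0]
    for chain_id, chain in model0["polymer"].items():
        entities.append({"id": str(len(entities) + 1), "type": "polymer"})
        entity_of_chain[chain_id] = entities[-1]["id"]
    for het in model0["non-polymer"].values():
        if het["name"] not in entity_of_ligand_name:
            entities.append({"id": str(len(entities) + 1),
                             "type": "non-polymer"})
            entity_of_ligand_name[het["name"]] = entities[-1]["id"]
    if model0["water"]:
        entities.append({"id": str(len(entities) + 1), "type": "water"})
        water_entity = entities[-1]["id"]
    if entities:
        lines += _cif_loop("entity", ["id", "type"], entities)
    poly_rows = []
    for chain_id, chain in model0["polymer"].items():
        if chain.get("sequence"):
            poly_rows.append({"entity_id": entity_of_chain[chain_id],
                              "type": "polypeptide(L)",
                              "pdbx_seq_one_letter_code": chain["sequence"],
                              "pdbx_strand_id": chain_id})
    if poly_rows:
        lines += _cif_loop("entity_poly",
                           ["entity_id", "type", "pdbx_seq_one_letter_code",
                            "pdbx_strand_id"], poly_rows)

    assemblies = data["geometry"]["assemblies"]
    if assemblies:
        lines += _cif_loop("pdbx_struct_assembly", ["id", "method_details"],
                           [{"id": a["id"],
                             "method_details": a.get("software")}
                            for a in assemblies])
        oper_rows, gen_rows = [], []
        op_counter = 0
        for assembly in assemblies:
            for transformation in assembly["transformations"]:
                op_counter += 1
                row = {"id": str(op_counter), "type": "?"}
                for i in (1, 2, 3):
                    for j in (1, 2, 3):
                        row[f"matrix[{i}][{j}]"] = \
                            transformation["matrix"][i - 1][j - 1]
                    row[f"vector[{i}]"] = transformation["vector"][i - 1]
                oper_rows.append(row)
                gen_rows.append({"assembly_id": assembly["id"],
                                 "oper_expression": str(op_counter),
                                 "asym_id_list":
                                     ",".join(transformation["chain_ids"])})
        lines += _cif_loop("pdbx_struct_assembly_gen",
                           ["assembly_id", "oper_expression", "asym_id_list"],
                           gen_rows)
        oper_columns = ["id", "type"] + \
            [f"matrix[{i}][{j}]" for i in (1, 2, 3) for j in (1, 2, 3)] + \
            [f"vector[{i}]" for i in (1, 2, 3)]
        lines += _cif_loop("pdbx_struct_oper_list", oper_columns, oper_rows)
    if data["missing_residues"]:
        rows = []
        for entry in data["missing_residues"]:
            chain, number, icode = _split_het_id(entry["id"])
            rows.append({"auth_asym_id": chain, "auth_comp_id": entry["name"],
                         "auth_seq_id": number,
                         "PDB_ins_code": icode or "?"})
        lines += _cif_loop("pdbx_unobs_or_zero_occ_residues",
                           ["auth_asym_id", "auth_comp_id", "auth_seq_id",
                            "PDB_ins_code"], rows)

    atom_columns = ["group_PDB", "id", "type_symbol", "label_atom_id",
                    "label_alt_id", "label_comp_id", "label_asym_id",
                    "label_entity_id", "label_seq_id", "pdbx_PDB_ins_code",
                    "Cartn_x", "Cartn_y", "Cartn_z", "occupancy",
                    "B_iso_or_equiv", "pdbx_formal_charge", "auth_seq_id",
                    "auth_comp_id", "auth_asym_id", "auth_atom_id",
                    "pdbx_PDB_model_num"]
    atom_rows = []
    for model_number, model_data in enumerate(data["models"], start=1):
        serial = 0
        for kind, structure_id, structure in _iter_model_structures(model_data):
            if kind == "polymer":
                entity_id = entity_of_chain.get(structure_id, "?")
                internal = structure.get("internal_id") or structure_id
                for het_id, residue in structure["residues"].items():
                    chain, number, icode = _split_het_id(het_id)
                    for atom in residue["atoms"].values():
                        serial += 1
                        atom_rows.append(_cif_atom_row(
                            "ATOM", serial, atom, residue["name"], chain,
                            internal, entity_id, number, icode, model_number))
            else:
                chain, number, icode = _split_het_id(structure_id)
                entity_id = (water_entity if kind == "water"
                             else entity_of_ligand_name.get(
                                 structure["name"], "?"))
                for atom in structure["atoms"].values():
                    serial += 1
                    atom_rows.append(_cif_atom_row(
                        "HETATM", serial, atom, structure["name"], chain,
                        chain, entity_id, number, icode, model_number))
    lines += _cif_loop("atom_site", atom_columns, atom_rows)
    return "\n".join(lines) + "\n"


def _cif_atom_row(group, serial, atom, res_name, chain, internal, entity_id,
                  number, icode, model_number):
    return {"group_PDB": group, "id": serial, "type_symbol": atom["element"],
            "label_atom_id": atom["name"], "label_alt_id": ".",
            "label_comp_id": res_name, "label_asym_id": internal,
            "label_entity_id": entity_id, "label_seq_id": number,
            "pdbx_PDB_ins_code": icode or "?",
            "Cartn_x": f"{atom['x']:.3f}", "Cartn_y": f"{atom['y']:.3f}",
            "Cartn_z": f"{atom['z']:.3f}", "occupancy": "1.00",
            "B_iso_or_equiv": f"{atom['bvalue']:.2f}",
            "pdbx_formal_charge": int(atom["charge"]),
            "auth_seq_id": number, "auth_comp_id": res_name,
            "auth_asym_id": chain, "auth_atom_id": atom["name"],
            "pdbx_PDB_model_num": model_number}


# ------------------------------------------------------------------- MMTF

def write_mmtf(file):
    """Render a File as MMTF v1.0 bytes (msgpack container, coordinates
    fixed-point at divisor 1000 with delta + recursive-index encoding)."""
    data = structure_to_data_dict(file)
    chains_per_model = []
    groups_per_chain = []
    chain_id_list, chain_name_list = [], []
    group_type_list, group_id_list, ins_code_list = [], [], []
    group_list, group_index = [], {}
    xs, ys, zs, bfactors, occupancies, atom_ids, altlocs = \
        [], [], [], [], [], [], []
    entity_list = []

    def group_type_for(name, atoms):
        key = (name, tuple((a["name"], a["element"], int(a["charge"]))
                           for a in atoms))
        if key not in group_index:
            group_index[key] = len(group_list)
            group_list.append({
                "groupName": name,
                "atomNameList": [a["name"] for a in atoms],
                "elementList": [a["element"] for a in atoms],
                "formalChargeList": [int(a["charge"]) for a in atoms],
                "singleLetterCode": "?", "chemCompType": "?",
                "bondAtomList": [], "bondOrderList": []})
        return group_index[key]

    chain_counter = 0
    for model_data in data["models"]:
        serial = 0
        model_chains = 0

        def add_chain(name, internal, entity_type, sequence, groups):
            # groups: list of (het_id, res_name, atom list)
            nonlocal chain_counter, model_chains, serial
            chain_id_list.append(internal)
            chain_name_list.append(name)
            groups_per_chain.append(len(groups))
            entity_list.append({"type": entity_type,
                                "chainIndexList": [chain_counter],
                                "sequence": sequence, "description": ""})
            for het_id, res_name, atoms in groups:
                _, number, icode = _split_het_id(het_id)
                group_type_list.append(group_type_for(res_name, atoms))
                group_id_list.append(number)
                ins_code_list.append(icode)
                for atom in atoms:
                    serial += 1
                    xs.append(atom["x"])
                    ys.append(atom["y"])
                    zs.append(atom["z"])
                    bfactors.append(atom["bvalue"])
                    occupancies.append(1.0)
                    atom_ids.append(serial)
                    altlocs.append("")
            chain_counter += 1
            model_chains += 1

        for chain_id, chain in model_data["polymer"].items():
            groups = [(het_id, residue["name"],
                       list(residue["atoms"].values()))
                      for het_id, residue in chain["residues"].items()]
            add_chain(chain_id, chain.get("internal_id") or chain_id,
                      "polymer", chain.get("sequence", ""), groups)
        for key, entity_type in (("non-polymer", "non-polymer"),
                                 ("water", "water")):
            by_chain = {}
            for het_id, het in model_data[key].items():
                by_chain.setdefault(het_id.partition(".")[0], []).append(
                    (het_id, het["name"], list(het["atoms"].values())))
            for chain_id, groups in by_chain.items():
                add_chain(chain_id, chain_id, entity_type, "", groups)
        chains_per_model.append(model_chains)

    # merge entities of identical type+sequence across chains
    merged = {}
    for entity in entity_list:
        key = (entity["type"], entity["sequence"])
        if key in merged:
            merged[key]["chainIndexList"].extend(entity["chainIndexList"])
        else:
            merged[key] = entity
    entity_list = list(merged.values())

    bio_assembly_list = []
    name_to_indices = {}
    for index, name in enumerate(chain_name_list):
        name_to_indices.setdefault(name, []).append(index)
    for assembly in data["geometry"]["assemblies"]:
        transforms = []
        for transformation in assembly["transformations"]:
            matrix = transformation["matrix"]
            vector = transformation["vector"]
            matrix16 = (list(matrix[0]) + [vector[0]]
                        + list(matrix[1]) + [vector[1]]
                        + list(matrix[2]) + [vector[2]]
                        + [0.0, 0.0, 0.0, 1.0])
            indices = []
            for chain_id in transformation["chain_ids"]:
                indices.extend(name_to_indices.get(chain_id, []))
            transforms.append({"chainIndexList": indices, "matrix": matrix16})
        bio_assembly_list.append({"name": str(assembly["id"]),
                                  "transformList": transforms})

    description = data["description"]
    quality = data["quality"]
    encode = mmtf_codec.encode_binary_field
    fields = {
        "mmtfVersion": "1.0.0",
        "mmtfProducer": "structparse",
        "structureId": description.get("code") or "",
        "title": description.get("title") or "",
        "depositionDate": description.get("deposition_date") or "",
        "experimentalMethods":
            [data["experiment"]["technique"]]
            if data["experiment"].get("technique") else [],
        "numModels": len(data["models"]),
        "numChains": len(chain_id_list),
        "numGroups": len(group_id_list),
        "numAtoms": len(xs),
        "numBonds": 0,
        "chainsPerModel": chains_per_model,
        "groupsPerChain": groups_per_chain,
        "chainIdList": encode(5, chain_id_list, 4),
        "chainNameList": encode(5, chain_name_list, 4),
        "groupTypeList": encode(4, group_type_list),
        "groupIdList": encode(8, group_id_list),
        "insCodeList": encode(6, ins_code_list),
        "altLocList": encode(6, altlocs),
        "groupList": group_list,
        "xCoordList": encode(10, xs, 1000),
        "yCoordList": encode(10, ys, 1000),
        "zCoordList": encode(10, zs, 1000),
        "bFactorList": encode(10, bfactors, 100),
        "occupancyList": encode(9, occupancies, 100),
        "atomIdList": encode(8, atom_ids),
        "entityList": entity_list,
        "bioAssemblyList": bio_assembly_list,
    }
    if quality.get("resolution") is not None:
        fields["resolution"] = quality["resolution"]
    if quality.get("rvalue") is not None:
        fields["rWork"] = quality["rvalue"]
    if quality.get("rfree") is not None:
        fields["rFree"] = quality["rfree"]
    return mmtf_codec.pack_mmtf(fields)


# ------------------------------------------------------------------- JSON

def to_json(data, indent=None):
    """Serialize a data dictionary (or any sub-dictionary) to JSON text.

    Key order is deterministic (insertion order of the schema). A value
    outside the JSON model raises ValueError.
    """
    try:
        return json.dumps(data, indent=indent, allow_nan=False)
    except (TypeError, ValueError) as error:
        raise ValueError(f"Not JSON-serializable: {error}") from None


def traverse(data, path):
    """Descend mapping keys and zero-based list indices.

    ``path`` is an ordered sequence of string segments; list indices must
    be decimal integer strings. An empty path returns ``data`` itself.
    Raises KeyError naming the first segment that cannot be resolved.
    """
    value = data
    for segment in path:
        if isinstance(value, list):
            if not str(segment).lstrip("-").isdigit():
                raise KeyError(f"List index expected, got {segment!r}")
            index = int(segment)
            if not -len(value) <= index < len(value):
                raise KeyError(f"Index {segment!r} out of range")
            value = value[index]
        elif isinstance(value, dict):
            if segment not in value:
                raise KeyError(f"No key {segment!r}")
            value = value[segment]
        else:
            raise KeyError(f"Cannot descend into a "
                           f"{type(value).__name__} at {segment!r}")
    return value
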