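"""Convert file-specific dictionaries into the standard data dictionary.

This is the convergence point of the three parsers: whatever the source
format, the output has the same key skeleton —

    description   code, title, deposition_date, classification, keywords,
                  authors
    experiment    technique, source_organism, expression_system
    quality       resolution, rvalue, rfree
    geometry      assemblies (id, software, transformations)
    models        list of {polymer, non-polymer, water} mappings
    missing_residues  list of {id, name}

so it can always be serialized to the same JSON shape. Unavailable fields
are null or empty, never absent. Values may still differ between formats
(title case, atom numbering); the MMTF container simply does not carry
missing-residue records, so that list is empty for MMTF sources.

Alternate locations are resolved here: within each (het, atom name) group
holding several altloc letters, only the records with the alphabetically
first letter survive; blank-altloc records always survive.
"""

import logging
import re

from .elements import WATER_NAMES, CODES_3TO1
from .pdb import parse_atom_line

logger = logging.getLogger(__name__)

_MISSING_ROW = re.compile(r"^-?\d+[A-Za-z]?$")


def empty_data_dictionary():
    return {
        "description": {"code": None, "title": None, "deposition_date": None,
                        "classification": None, "keywords": [], "authors": []},
        "experiment": {"technique": None, "source_organism": None,
                       "expression_system": None},
        "quality": {"resolution": None, "rvalue": None, "rfree": None},
        "geometry": {"assemblies": []},
        "models": [],
        "missing_residues": [],
    }


def standardize(raw, source):
    """Build the standard data dictionary from a parser's output.

    ``source`` is one of ``"pdb"``, ``"cif"``, ``"mmtf"``. Raises
    ValueError on an unknown source or when the file holds no atom
    records at all.
    """
    if source == "pdb":
        data = _standardize_pdb(raw)
    elif source == "cif":
        data = _standardize_cif(raw)
    elif source == "mmtf":
        data = _standardize_mmtf(raw)
    else:
        raise ValueError(f"Unknown source format {source!r}")
    if not any(model["polymer"] or model["non-polymer"] or model["water"]
               for model in data["models"]):
        raise ValueError("empty structure: no atom records found")
    return data


# ----------------------------------------------------------------- shared

def resolve_altlocs(records):
    """Keep, per (chain, residue, atom name) group, only the records whose
    altloc letter comes first alphabetically; blank altlocs always stay."""
    winners = {}
    for record in records:
        if not record["altloc"]:
            continue
        key = (record["chain"], record["res_seq"], record["icode"],
               record["name"])
        if key not in winners or record["altloc"] < winners[key]:
            winners[key] = record["altloc"]
    kept = []
    for record in records:
        if record["altloc"]:
            key = (record["chain"], record["res_seq"], record["icode"],
                   record["name"])
            if record["altloc"] != winners[key]:
                continue
        kept.append(record)
    return kept


def _het_id(chain, number, icode):
    return f"{chain}.{number}{icode or ''}"


def _atom_record(record):
    return {"name": record["name"], "element": record["element"],
            "x": record["x"], "y": record["y"], "z": record["z"],
            "charge": record["charge"], "bvalue": record["bvalue"]}


def _records_to_model(records, sequences=None, internal_ids=None):
    """Assemble one model mapping from generic atom records.

    Each record carries chain, res_seq, icode, res_name, serial, name,
    altloc, element, coordinates, charge, bvalue and a ``polymer`` flag.
    """
    records = resolve_altlocs(records)
    sequences = sequences or {}
    internal_ids = internal_ids or {}
    polymer, nonpoly, water = {}, {}, {}
    for record in records:
        if record["polymer"]:
            chain = polymer.setdefault(record["chain"], {
                "internal_id": internal_ids.get(record["chain"],
                                                record["chain"]),
                "sequence": sequences.get(record["chain"], ""),
                "residues": {},
            })
            het_id = _het_id(record["chain"], record["res_seq"],
                             record["icode"])
            residue = chain["residues"].setdefault(
                het_id, {"name": record["res_name"], "atoms": {}})
            residue["atoms"][str(record["serial"])] = _atom_record(record)
        else:
            target = water if record["res_name"] in WATER_NAMES else nonpoly
            het_id = _het_id(record["chain"], record["res_seq"],
                             record["icode"])
            het = target.setdefault(
                het_id, {"name": record["res_name"], "atoms": {}})
            het["atoms"][str(record["serial"])] = _atom_record(record)
    return {"polymer": _sorted_mapping(polymer),
            "non-polymer": _sorted_mapping(nonpoly),
            "water": _sorted_mapping(water)}


def _dotted_sort_key(het_id):
    chain, _, tail = het_id.partition(".")
    number = "".join(c for c in tail if c.isdigit() or c == "-")
    icode = "".join(c for c in tail if c.isalpha())
    return (chain, int(number) if number else 0, icode)


def _sorted_mapping(mapping):
    out = {}
    for key in sorted(mapping, key=_dotted_sort_key):
        value = mapping[key]
        if "residues" in value:
            value = dict(value)
            value["residues"] = {
                rid: {"name": r["name"],
                      "atoms": dict(sorted(r["atoms"].items(),
                                           key=lambda kv: int(kv[0])))}
                for rid, r in sorted(value["residues"].items(),
                                     key=lambda kv: _dotted_sort_key(kv[0]))}
        else:
            value = {"name": value["name"],
                     "atoms": dict(sorted(value["atoms"].items(),
                                          key=lambda kv: int(kv[0])))}
        out[key] = value
    return out


def _number(value):
    """String to int/float where possible; '?' and '.' become None."""
    if value is None or value in ("?", "."):
        return None
    try:
        return int(value)
    except (ValueError, TypeError):
        try:
            return float(value)
        except (ValueError, TypeError):
            return value


def extract_missing_residues(raw, source):
    """Unresolved residues as [{id, name}] with dotted IDs. The MMTF
    format does not carry this information, so that source yields []."""
    if source == "pdb":
        return _pdb_missing_residues(raw)
    if source == "cif":
        return _cif_missing_residues(raw)
    return []


def extract_assemblies(raw, source, internal_to_auth=None):
    if source == "pdb":
        return _pdb_assemblies(raw)
    if source == "cif":
        return _cif_assemblies(raw, internal_to_auth or {})
    return _mmtf_assemblies(raw)


# -------------------------------------------------------------------- PDB

_MONTHS = {"JAN": 1, "FEB": 2, "MAR": 3, "APR": 4, "MAY": 5, "JUN": 6,
           "JUL": 7, "AUG": 8, "SEP": 9, "OCT": 10, "NOV": 11, "DEC": 12}


def _pdb_date(field):
    try:
        day, month, year = field.strip().split("-")
        year = int(year)
        year += 2000 if year < 50 else 1900
        return f"{year:04d}-{_MONTHS[month.upper()]:02d}-{int(day):02d}"
    except (ValueError, KeyError):
        return None


def _continuation_text(lines, start=10):
    return " ".join(line[start:].strip() for line in lines).strip() or None


def _standardize_pdb(pdb):
    data = empty_data_dictionary()
    header = pdb.get("HEADER", [""])[0].ljust(80)
    if header.strip():
        data["description"]["code"] = header[62:66].strip() or None
        data["description"]["classification"] = header[10:50].strip() or None
        data["description"]["deposition_date"] = _pdb_date(header[50:59])
    data["description"]["title"] = _continuation_text(pdb.get("TITLE", []))
    keywords = _continuation_text(pdb.get("KEYWDS", []))
    data["description"]["keywords"] = (
        [k.strip() for k in keywords.split(",")] if keywords else [])
    authors = _continuation_text(pdb.get("AUTHOR", []))
    data["description"]["authors"] = (
        [a.strip() for a in authors.split(",")] if authors else [])
    data["experiment"]["technique"] = _continuation_text(pdb.get("EXPDTA", []))
    source = _continuation_text(pdb.get("SOURCE", []))
    if source:
        for token, key in (("ORGANISM_SCIENTIFIC:", "source_organism"),
                           ("EXPRESSION_SYSTEM:", "expression_system")):
            if token in source:
                value = source.split(token)[1].split(";")[0].strip()
                data["experiment"][key] = value or None
    for line in pdb.get("REMARK", []):
        remark = line[7:10].strip()
        content = line[11:].strip()
        if remark == "2" and "RESOLUTION" in content:
            for token in content.split():
                try:
                    data["quality"]["resolution"] = float(token)
                    break
                except ValueError:
                    continue
        if remark == "3" and ":" in content:
            label, _, value = content.rpartition(":")
            label = label.strip()
            try:
                value = float(value.strip())
            except ValueError:
                continue
            if label.startswith("R VALUE") and "WORKING" in label:
                data["quality"]["rvalue"] = value
            elif label.startswith("FREE R VALUE") and "SET" not in label:
                data["quality"]["rfree"] = value
    data["missing_residues"] = _pdb_missing_residues(pdb)
    data["geometry"]["assemblies"] = _pdb_assemblies(pdb)
    sequences = _pdb_sequences(pdb)
    for group in pdb.get("MODEL", [[]]):
        records = []
        for line in group:
            record_name = line[:6].strip()
            if record_name not in ("ATOM", "HETATM"):
                continue
            parsed = parse_atom_line(line)
            parsed["polymer"] = record_name == "ATOM"
            records.append(parsed)
        if records or len(pdb.get("MODEL", [])) == 1:
            data["models"].append(_records_to_model(records, sequences))
    data["models"] = [m for m in data["models"]
                      if m["polymer"] or m["non-polymer"] or m["water"]] or \
                     [_records_to_model([])]
    return data


def _pdb_sequences(pdb):
    sequences = {}
    for line in pdb.get("SEQRES", []):
        chain = line[11].strip()
        names = line[19:70].split()
        sequences[chain] = sequences.get(chain, "") + "".join(
            CODES_3TO1.get(name, "X") for name in names)
    return sequences


def _pdb_missing_residues(pdb):
    missing = []
    for line in pdb.get("REMARK", []):
        if line[7:10].strip() != "465":
            continue
        parts = line[10:].split()
        # data rows are "<RES> <chain> <number><icode?>"; skip headers
        if len(parts) != 3:
            continue
        name, chain, seq = parts
        if not _MISSING_ROW.match(seq) or not name.isalpha():
            continue
        number = "".join(c for c in seq if c.isdigit() or c == "-")
        icode = "".join(c for c in seq if c.isalpha())
        missing.append({"id": _het_id(chain, int(number), icode),
                        "name": name})
    return missing


def _pdb_assemblies(pdb):
    assemblies = []
    current = None
    operators = {}
    chains = []
    software = None

    def flush_operators():
        if current is not None and operators:
            for op_id in sorted(operators, key=int):
                rows = operators[op_id]
                if len(rows) != 3 or any(len(r) != 4 for r in rows):
                    raise ValueError(
                        f"Malformed BIOMT rows for operator {op_id}")
                current["transformations"].append({
                    "chain_ids": list(chains),
                    "matrix": [r[:3] for r in rows],
                    "vector": [r[3] for r in rows]})
            operators.clear()

    for line in pdb.get("REMARK", []):
        if line[7:10].strip() != "350":
            continue
        content = line[11:].strip()
        if content.startswith("BIOMOLECULE:"):
            flush_operators()
            if current is not None:
                assemblies.append(current)
            current = {"id": int(content.split(":")[1].strip()),
                       "software": None, "transformations": []}
            chains = []
            software = None
        elif content.startswith("SOFTWARE USED:"):
            if current is not None:
                current["software"] = content.split(":", 1)[1].strip()
        elif "TO CHAINS:" in content:
            flush_operators()
            chains = [c.strip() for c in
                      content.split("TO CHAINS:")[1].split(",") if c.strip()]
        elif content.startswith("BIOMT"):
            parts = content.split()
            op_id = parts[1]
            try:
                values = [float(p) for p in parts[2:]]
            except ValueError:
                raise ValueError(f"Malformed BIOMT row: {content!r}") from None
            operators.setdefault(op_id, []).append(values)
    flush_operators()
    if current is not None:
        assemblies.append(current)
    return assemblies


# -------------------------------------------------------------------- CIF

def _cif_row(raw, category):
    rows = raw.get(category, [])
    return rows[0] if rows else {}


def _standardize_cif(cif):
    data = empty_data_dictionary()
    data["description"]["code"] = _cif_row(cif, "entry").get("id") or None
    data["description"]["title"] = _cif_row(cif, "struct").get("title") or None
    date = _cif_row(cif, "pdbx_database_status").get(
        "recvd_initial_deposition_date")
    data["description"]["deposition_date"] = None if date in (None, "?", ".") \
        else date
    keywords_row = _cif_row(cif, "struct_keywords")
    data["description"]["classification"] = (
        keywords_row.get("pdbx_keywords") or None)
    text = keywords_row.get("text")
    data["description"]["keywords"] = (
        [k.strip() for k in text.split(",")] if text and text not in "?." else [])
    data["description"]["authors"] = [
        row["name"] for row in cif.get("audit_author", []) if "name" in row]
    data["experiment"]["technique"] = _cif_row(cif, "exptl").get("method") or None
    src = _cif_row(cif, "entity_src_gen")
    data["experiment"]["source_organism"] = _number(
        src.get("pdbx_gene_src_scientific_name")) or None
    data["experiment"]["expression_system"] = _number(
        src.get("pdbx_host_org_scientific_name")) or None
    refine = _cif_row(cif, "refine")
    data["quality"]["rvalue"] = _number(refine.get("ls_R_factor_R_work"))
    data["quality"]["rfree"] = _number(refine.get("ls_R_factor_R_free"))
    data["quality"]["resolution"] = _number(
        refine.get("ls_d_res_high")
        or _cif_row(cif, "reflns").get("d_resolution_high"))
    data["missing_residues"] = _cif_missing_residues(cif)

    entity_types = {row.get("id"): row.get("type")
                    for row in cif.get("entity", [])}
    sequences = {}
    for row in cif.get("entity_poly", []):
        seq = (row.get("pdbx_seq_one_letter_code") or "").replace("\n", "")
        for chain in (row.get("pdbx_strand_id") or "").split(","):
            if chain.strip():
                sequences[chain.strip()] = seq

    internal_to_auth = {}
    by_model = {}
    for row in cif.get("atom_site", []):
        model_num = _number(row.get("pdbx_PDB_model_num", "1")) or 1
        chain = row.get("auth_asym_id") or row.get("label_asym_id") or ""
        internal = row.get("label_asym_id") or chain
        internal_to_auth[internal] = chain
        entity_type = entity_types.get(row.get("label_entity_id"))
        if entity_type is None:
            polymer = row.get("group_PDB", "ATOM") == "ATOM"
        else:
            polymer = entity_type == "polymer"
        res_name = (row.get("auth_comp_id") or row.get("label_comp_id") or "")
        seq = row.get("auth_seq_id") or row.get("label_seq_id") or "0"
        icode = row.get("pdbx_PDB_ins_code") or ""
        record = {
            "chain": chain, "internal_chain": internal,
            "res_seq": int(seq) if seq not in "?." else 0,
            "icode": "" if icode in "?." else icode,
            "res_name": res_name,
            "serial": _number(row.get("id")) or 0,
            "name": row.get("auth_atom_id") or row.get("label_atom_id") or "",
            "altloc": "" if (row.get("label_alt_id") or ".") in "?."
                      else row["label_alt_id"],
            "x": _number(row.get("Cartn_x")),
            "y": _number(row.get("Cartn_y")),
            "z": _number(row.get("Cartn_z")),
            "charge": _number(row.get("pdbx_formal_charge")) or 0,
            "bvalue": _number(row.get("B_iso_or_equiv")) or 0.0,
            "element": row.get("type_symbol") or "",
            "polymer": polymer,
        }
        by_model.setdefault(model_num, []).append(record)
    internal_ids = {}
    for model_num in sorted(by_model):
        records = by_model[model_num]
        for record in records:
            internal_ids[record["chain"]] = record["internal_chain"]
        data["models"].append(
            _records_to_model(records, sequences, internal_ids))
    data["geometry"]["assemblies"] = _cif_assemblies(cif, internal_to_auth)
    return data


def _cif_missing_residues(cif):
    missing = []
    for row in cif.get("pdbx_unobs_or_zero_occ_residues", []):
        chain = row.get("auth_asym_id") or row.get("label_asym_id") or ""
        seq = row.get("auth_seq_id") or row.get("label_seq_id") or "0"
        icode = row.get("PDB_ins_code") or ""
        name = row.get("auth_comp_id") or row.get("label_comp_id") or ""
        missing.append({"id": _het_id(chain, int(seq),
                                      "" if icode in "?." else icode),
                        "name": name})
    return missing


def _expand_oper_expression(expression):
    expression = expression.strip().strip("()")
    ids = []
    for part in expression.split(","):
        part = part.strip()
        if "-" in part and not part.startswith("-"):
            low, high = part.split("-")
            ids.extend(str(i) for i in range(int(low), int(high) + 1))
        elif part:
            ids.append(part)
    return ids


def _cif_assemblies(cif, internal_to_auth):
    operators = {}
    for row in cif.get("pdbx_struct_oper_list", []):
        try:
            matrix = [[float(row[f"matrix[{i}][{j}]"]) for j in (1, 2, 3)]
                      for i in (1, 2, 3)]
            vector = [float(row[f"vector[{i}]"]) for i in (1, 2, 3)]
        except (KeyError, ValueError):
            raise ValueError(
                f"Malformed pdbx_struct_oper_list row {row.get('id')}") from None
        operators[row.get("id")] = {"matrix": matrix, "vector": vector}
    assemblies = []
    for row in cif.get("pdbx_struct_assembly", []):
        assembly = {"id": _number(row.get("id")),
                    "software": None if (row.get("method_details") or "?")
                    in "?." else row["method_details"],
                    "transformations": []}
        for gen in cif.get("pdbx_struct_assembly_gen", []):
            if gen.get("assembly_id") != row.get("id"):
                continue
            chain_ids = [internal_to_auth.get(c.strip(), c.strip())
                         for c in (gen.get("asym_id_list") or "").split(",")
                         if c.strip()]
            for op_id in _expand_oper_expression(
                    gen.get("oper_expression") or ""):
                operator = operators.get(op_id)
                if operator is None:
                    raise ValueError(f"Assembly references unknown "
                                     f"operator {op_id}")
                assembly["transformations"].append(
                    {"chain_ids": chain_ids,
                     "matrix": operator["matrix"],
                     "vector": operator["vector"]})
        assemblies.append(assembly)
    return assemblies


# ------------------------------------------------------------------- MMTF

def _standardize_mmtf(mmtf):
    data = empty_data_dictionary()
    data["description"]["code"] = mmtf.get("structureId") or None
    data["description"]["title"] = mmtf.get("title") or None
    data["description"]["deposition_date"] = mmtf.get("depositionDate") or None
    methods = mmtf.get("experimentalMethods") or []
    data["experiment"]["technique"] = methods[0] if methods else None
    data["quality"]["resolution"] = mmtf.get("resolution")
    data["quality"]["rvalue"] = mmtf.get("rWork")
    data["quality"]["rfree"] = mmtf.get("rFree")
    data["geometry"]["assemblies"] = _mmtf_assemblies(mmtf)

    chain_names = mmtf.get("chainNameList") or mmtf.get("chainIdList") or []
    chain_ids = mmtf.get("chainIdList") or chain_names
    entity_by_chain = {}
    for entity in mmtf.get("entityList", []):
        for index in entity.get("chainIndexList", []):
            entity_by_chain[index] = entity
    groups_per_chain = mmtf.get("groupsPerChain", [])
    chains_per_model = mmtf.get("chainsPerModel", [])
    group_types = mmtf.get("groupTypeList", [])
    group_ids = mmtf.get("groupIdList", [])
    ins_codes = mmtf.get("insCodeList") or [""] * len(group_ids)
    group_list = mmtf.get("groupList", [])
    xs, ys, zs = (mmtf.get("xCoordList", []), mmtf.get("yCoordList", []),
                  mmtf.get("zCoordList", []))
    bfactors = mmtf.get("bFactorList") or [0.0] * len(xs)
    altlocs = mmtf.get("altLocList") or [""] * len(xs)
    atom_ids = mmtf.get("atomIdList") or list(range(1, len(xs) + 1))

    atom_cursor = 0
    group_cursor = 0
    chain_cursor = 0
    for model_chain_count in chains_per_model:
        records = []
        sequences = {}
        internal_ids = {}
        for _ in range(model_chain_count):
            chain_name = chain_names[chain_cursor]
            internal_ids[chain_name] = chain_ids[chain_cursor]
            entity = entity_by_chain.get(chain_cursor, {})
            polymer = entity.get("type") == "polymer"
            if polymer and entity.get("sequence"):
                sequences[chain_name] = entity["sequence"]
            for _ in range(groups_per_chain[chain_cursor]):
                group = group_list[group_types[group_cursor]]
                names = group.get("atomNameList", [])
                elements = group.get("elementList", [""] * len(names))
                charges = group.get("formalChargeList", [0] * len(names))
                for a in range(len(names)):
                    records.append({
                        "chain": chain_name,
                        "res_seq": group_ids[group_cursor],
                        "icode": ins_codes[group_cursor] or "",
                        "res_name": group.get("groupName", ""),
                        "serial": atom_ids[atom_cursor],
                        "name": names[a],
                        "altloc": altlocs[atom_cursor] or "",
                        "x": xs[atom_cursor], "y": ys[atom_cursor],
                        "z": zs[atom_cursor],
                        "charge": charges[a],
                        "bvalue": bfactors[atom_cursor],
                        "element": elements[a],
                        "polymer": polymer,
                    })
                    atom_cursor += 1
                group_cursor += 1
            chain_cursor += 1
        data["models"].append(
            _records_to_model(records, sequences, internal_ids))
    return data


def _mmtf_assemblies(mmtf):
    chain_names = mmtf.get("chainNameList") or mmtf.get("chainIdList") or []
    assemblies = []
    for index, assembly in enumerate(mmtf.get("bioAssemblyList", []), start=1):
        name = assembly.get("name", "")
        out = {"id": int(name) if str(name).isdigit() else index,
               "software": None, "transformations": []}
        for transform in assembly.get("transformList", []):
            matrix16 = transform.get("matrix", [])
            if len(matrix16) != 16:
                raise ValueError("MMTF assembly matrix must have 16 entries")
            seen = []
            for i in transform.get("chainIndexList", []):
                if chain_names[i] not in seen:
                    seen.append(chain_names[i])
            out["transformations"].append({
                "chain_ids": seen,
                "matrix": [matrix16[0:3], matrix16[4:7], matrix16[8:11]],
                "vector": [matrix16[3], matrix16[7], matrix16[11]]})
        assemblies.append(out)
    return assemblies
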