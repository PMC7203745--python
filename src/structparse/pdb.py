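"""PDB fixed-column format: parsing to the file-specific dictionary.

The file-specific dictionary is lossless: every line of the source is kept
verbatim (right-padded to 80 columns), bucketed by its 6-character record
name, with coordinate records additionally grouped per MODEL block. Column
slicing into typed atom records happens on demand via
:func:`parse_atom_line`, per the v3.3 fixed-column table.
"""

from .elements import ATOMIC_WEIGHTS

#: Records that belong to a coordinate MODEL block.
COORDINATE_RECORDS = {"ATOM", "HETATM", "ANISOU", "TER"}


def parse_pdb_string(text):
    """Bucket the lines of a PDB filestring by record name.

    Returns a dict mapping record name to a list of 80-character lines,
    plus a ``"MODEL"`` key holding one list of coordinate lines per MODEL
    block (a single implicit block when no MODEL records are present).
    ATOM/HETATM coordinate fields are validated; a conversion failure
    raises ValueError naming the line number.
    """
    pdb = {"MODEL": [[]]}
    started_models = 0
    for number, raw in enumerate(text.split("\n"), start=1):
        if not raw.strip():
            continue
        line = raw.rstrip("\r").ljust(80)[:80]
        record = line[:6].strip()
        if record == "MODEL":
            if started_models:
                pdb["MODEL"].append([])
            started_models += 1
            continue
        if record == "ENDMDL":
            continue
        if record in COORDINATE_RECORDS:
            if record in ("ATOM", "HETATM"):
                for start, end in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[start:end])
                    except ValueError:
                        raise ValueError(
                            f"Line {number}: cannot read coordinate "
                            f"field {line[start:end]!r}") from None
            pdb["MODEL"][-1].append(line)
            continue
        pdb.setdefault(record, []).append(line)
    return pdb


def _parse_charge(field):
    field = field.strip()
    if not field:
        return 0
    if field[-1] in "+-":
        field = field[-1] + field[:-1]
    try:
        return int(field)
    except ValueError:
        try:
            return float(field)
        except ValueError:
            return 0


def _infer_element(name_field):
    # Legacy files omit columns 77-78; fall back on the atom-name field.
    # A name starting in column 13 is a two-letter element (FE, ZN...);
    # otherwise the leading alphabetic character is the element.
    stripped = "".join(c for c in name_field if c.isalpha())
    if not stripped:
        return ""
    if name_field[0] != " " and stripped[:2].upper() in ATOMIC_WEIGHTS:
        return stripped[:2]
    return stripped[0]


def parse_atom_line(line):
    """Slice one ATOM/HETATM line into a typed record (1-based columns:
    serial 7-11, name 13-16, altloc 17, resName 18-20, chain 22,
    resSeq 23-26, iCode 27, x/y/z 31-54, occupancy 55-60, b 61-66,
    element 77-78, charge 79-80)."""
    line = line.ljust(80)[:80]
    element = line[76:78].strip()
    if not element:
        element = _infer_element(line[12:16])
    occupancy = line[54:60].strip()
    bvalue = line[60:66].strip()
    return {
        "hetatm": line[:6].strip() == "HETATM",
        "serial": int(line[6:11]),
        "name": line[12:16].strip(),
        "altloc": line[16].strip(),
        "res_name": line[17:20].strip(),
        "chain": line[21].strip(),
        "res_seq": int(line[22:26]),
        "icode": line[26].strip(),
        "x": float(line[30:38]),
        "y": float(line[38:46]),
        "z": float(line[46:54]),
        "occupancy": float(occupancy) if occupancy else 1.0,
        "bvalue": float(bvalue) if bvalue else 0.0,
        "element": element,
        "charge": _parse_charge(line[78:80]),
    }
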