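"""Build File/Model hierarchies from a data dictionary, and generate
biological assemblies from the stored transformation instructions."""

import logging

import numpy as np

from .structures import Atom, Het, Chain, Model, File, StructureSet

logger = logging.getLogger(__name__)


def _build_atoms(atom_mapping):
    atoms = []
    for serial, record in atom_mapping.items():
        atoms.append(Atom(record["element"], record["x"], record["y"],
                          record["z"], id=int(serial), name=record["name"],
                          charge=record["charge"], bvalue=record["bvalue"]))
    return atoms


def build_file(data, source_format=None):
    """Turn a standard data dictionary into a File of wired-up models.

    NMR-style entries with several coordinate sets yield several models.
    Assembly instructions referencing a chain absent from the first model
    are kept, with a warning.
    """
    if not data.get("models"):
        raise ValueError("Data dictionary holds no models")
    models = []
    for model_data in data["models"]:
        model = Model()
        for chain_id, chain_data in model_data.get("polymer", {}).items():
            residues = []
            for het_id, residue_data in chain_data.get("residues", {}).items():
                residues.append(Het(het_id, residue_data["name"],
                                    kind=Het.RESIDUE,
                                    atoms=_build_atoms(residue_data["atoms"])))
            model.add(Chain(chain_id, residues=residues,
                            sequence=chain_data.get("sequence", ""),
                            internal_id=chain_data.get("internal_id")))
        for key, kind in (("non-polymer", Het.LIGAND), ("water", Het.WATER)):
            for het_id, het_data in model_data.get(key, {}).items():
                model.add(Het(het_id, het_data["name"], kind=kind,
                              atoms=_build_atoms(het_data["atoms"])))
        models.append(model)
    assemblies = data.get("geometry", {}).get("assemblies", [])
    if models:
        known = {chain.id for chain in models[0].chains()}
        for assembly in assemblies:
            for transformation in assembly.get("transformations", []):
                for chain_id in transformation.get("chain_ids", []):
                    if chain_id not in known:
                        logger.warning(
                            "Assembly %s references unknown chain %r; "
                            "instruction kept", assembly.get("id"), chain_id)
    description = data.get("description", {})
    quality = data.get("quality", {})
    return File(
        models=models,
        code=description.get("code"),
        title=description.get("title"),
        resolution=quality.get("resolution"),
        rvalue=quality.get("rvalue"),
        rfree=quality.get("rfree"),
        missing_residues=list(data.get("missing_residues", [])),
        assemblies=[_copy_assembly(a) for a in assemblies],
        source_format=source_format,
        description=dict(description),
        experiment=dict(data.get("experiment", {})),
    )


def _copy_assembly(assembly):
    return {"id": assembly["id"], "software": assembly.get("software"),
            "transformations": [
                {"chain_ids": list(t["chain_ids"]),
                 "matrix": [list(row) for row in t["matrix"]],
                 "vector": list(t["vector"])}
                for t in assembly.get("transformations", [])]}


def structure_to_data_dict(file):
    """Flatten a File back into the standard data dictionary (the inverse
    of :func:`build_file` up to key ordering)."""
    from .standardize import empty_data_dictionary, _dotted_sort_key
    data = empty_data_dictionary()
    data["description"].update(file.description)
    data["description"]["code"] = file.code
    data["description"]["title"] = file.title
    data["experiment"].update(file.experiment)
    data["quality"] = {"resolution": file.resolution, "rvalue": file.rvalue,
                       "rfree": file.rfree}
    data["geometry"]["assemblies"] = [_copy_assembly(a)
                                      for a in file.assemblies]
    data["missing_residues"] = [dict(m) for m in file.missing_residues]
    for model in file.models:
        model_data = {"polymer": {}, "non-polymer": {}, "water": {}}
        for chain in sorted(model.chains(), key=lambda c: c.id):
            model_data["polymer"][chain.id] = {
                "internal_id": chain.internal_id,
                "sequence": chain.sequence,
                "residues": {residue.id: {
                    "name": residue.name,
                    "atoms": _flatten_atoms(residue)}
                    for residue in chain.residues},
            }
        for key, hets in (("non-polymer", model.ligands()),
                          ("water", model.waters())):
            for het in sorted(hets, key=lambda h: _dotted_sort_key(h.id)):
                model_data[key][het.id] = {"name": het.name,
                                           "atoms": _flatten_atoms(het)}
        data["models"].append(model_data)
    return data


def _flatten_atoms(structure):
    atoms = sorted(structure.atoms(), key=lambda a: a.id)
    return {str(atom.id): {"name": atom.name, "element": atom.element,
                           "x": atom.x, "y": atom.y, "z": atom.z,
                           "charge": atom.charge, "bvalue": atom.bvalue}
            for atom in atoms}


def generate_assembly(file, assembly_id, rename_chains=False):
    """Build the biological assembly ``assembly_id`` as a new Model.

    Each transformation copies every referenced chain — along with the
    ligands and waters attached to it through the dotted-ID chain prefix —
    and maps every coordinate r to M.r + v. Copies keep their original
    IDs (the StructureSet multimap holds them all) unless
    ``rename_chains`` is set, in which case copies beyond the first get a
    fresh numeric-suffix ID. The asymmetric-unit model is never mutated.
    """
    assembly = next((a for a in file.assemblies if a["id"] == assembly_id),
                    None)
    if assembly is None:
        available = sorted(a["id"] for a in file.assemblies)
        raise ValueError(f"No assembly with id {assembly_id!r}; "
                         f"available: {available}")
    source = file.model
    new_model = Model()
    copy_counts = {}
    for transformation in assembly["transformations"]:
        matrix = np.array(transformation["matrix"], dtype=float)
        vector = np.array(transformation["vector"], dtype=float)
        for chain_id in transformation["chain_ids"]:
            for chain in source.chain_set.get(chain_id):
                copy = chain.copy()
                copy.transform(matrix, vector)
                if rename_chains:
                    count = copy_counts.get(chain_id, 0)
                    copy_counts[chain_id] = count + 1
                    if count:
                        copy.id = f"{chain_id}{count}"
                new_model.add(copy)
            for collection in (source.ligand_set, source.water_set):
                for het in collection:
                    if het.id.split(".")[0] == chain_id:
                        het_copy = het.copy()
                        het_copy.transform(matrix, vector)
                        new_model.add(het_copy)
    return new_model
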