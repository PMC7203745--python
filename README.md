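# structparse

A lightweight Python library and CLI for **parsing, manipulating and saving
macromolecular structures** in the three principal formats of structural
biology: the fixed-column **PDB** format, the category/loop table **mmCIF**
format, and the binary msgpack-based **MMTF** container. All three converge
on a single *standard data dictionary* — a nested, JSON-serializable
key-value representation — so any entry can be rendered as the same JSON
whatever file it came from, and any sub-value can be addressed by a key
path such as `models/0/non-polymer/O.153/atoms/4382`.

It is aimed at structural bioinformaticians who need to read heterogeneous
archive files into one consistent object model, query and measure the
structures, rebuild biological assemblies, and write results back out.

## What it does

**Parsing pipeline.** Every read follows the same five steps: obtain the
content (disk or HTTP), detect the format (extension, then content
sniffing), parse to a *file-specific* dictionary that loses nothing from
the source (this backs the raw `--file` view), standardize it to the
shared data dictionary, and build `File` → `Model` → `Chain` → residue /
ligand / water → `Atom` objects. Alternate-location groups are resolved
during standardization: within each (residue, atom name) group only the
alphabetically first altloc letter survives. Unresolved residues are
captured from `REMARK 465` (PDB) or `pdbx_unobs_or_zero_occ_residues`
(mmCIF); MMTF does not carry them.

**Object model.** Parent–child collections are `StructureSet`s — multimaps
from ID to a *list* of members, so duplicate IDs (the normal outcome of
assembly generation) stay retrievable, with O(1) ID lookup.

**Query syntax.** Any collection can be filtered by property, nested
property, regular expression or numeric comparator via double-underscore
keywords:

```python
model.atoms(element="N")              # all nitrogens
model.atoms(mass__gt=14)              # standard atomic weight > 14 Da
model.atoms(het__name__regex="CYS|HIS")
model.atoms(chain__length__lt=100)
```

**Metrics and transforms.** Mass (sum of bundled IUPAC standard atomic
weights), elemental formula, centre of mass, radius of gyration
sqrt(Σ mᵢ‖rᵢ−COM‖²/Σ mᵢ), RMSD over atoms paired by (het ID, atom name)
with no superposition, closed-ball proximity search, bounding-box lattice
grids, in-place translation/rotation, and `dehydrate()`.

**Biological assemblies.** Deposited transformation matrices
(`REMARK 350` / `pdbx_struct_oper_list` / `bioAssemblyList`) are applied
with r′ = M·r + v to every referenced chain and its attached ligands and
waters, producing a new model with duplicated chain IDs — e.g. six copies
of one insulin-like subunit from a hexamer instruction.

## Worked example

```python
import structparse as sp
from structparse.fixtures import FixtureSpec, make_fixture

# a small synthetic entry: one 3-residue chain plus a zinc ligand O.153
fx = make_fixture(FixtureSpec(chains=(3,), ligands=(("O.153", "ZN", 1),),
                              serial_start=4370, code="2SOD", seed=19))
data = sp.standardize(sp.parse_filestring(fx["cif_text"], "cif"), "cif")

print(sp.traverse(data, ["quality"]))
print(sp.traverse(data, ["models", "0", "non-polymer", "O.153",
                         "atoms", "4382"])["element"])

file = sp.build_file(data)
zinc = file.model.ligand("O.153")
print(round(zinc.mass, 3), len(file.model.atoms()))
```

prints

```
{'resolution': 2.0, 'rvalue': 0.193, 'rfree': 0.229}
ZN
65.38 13
```

— the quality sub-dictionary addressed by key path, the element of the
atom with serial 4382 inside non-polymer `O.153` of model 0, the zinc's
standard atomic weight in daltons and the structure's atom count (twelve
backbone atoms and the zinc).

The same APIs drive the CLI:

```bash
structparse json entry.cif quality        # one sub-dictionary as JSON
structparse json entry.pdb --file         # the raw pre-processing view
structparse convert entry.cif entry.mmtf  # format conversion
structparse assembly entry.cif hexamer.pdb --id 1
```

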