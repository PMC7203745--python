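"""Core structure classes: the Atom/Het/Chain/Model/File hierarchy.

Every parent-child relationship is backed by a :class:`StructureSet`, an
ID-to-members multimap: lookup by ID is O(1) and duplicate IDs are allowed,
which is what biological-assembly generation needs (six copies of chain "A"
all remain retrievable under "A").
"""

import logging

from .elements import atomic_weight, WATER_NAMES
from . import geometry as _geometry
from .query import filter_structures

logger = logging.getLogger(__name__)


class StructureSet:
    """A multimap from member ID to a list of members with that ID.

    Behaves like an unordered set for iteration and length, but supports
    fast lookup by ID and permits several members to share one ID.
    """

    def __init__(self, *members):
        self._map = {}
        for member in members:
            self.add(member)

    def add(self, member):
        self._map.setdefault(member.id, []).append(member)

    def remove(self, member):
        members = self._map.get(member.id, [])
        if member in members:
            members.remove(member)
            if not members:
                del self._map[member.id]

    def get(self, id):
        """Every member carrying ``id`` — possibly empty, never raises."""
        return list(self._map.get(id, []))

    def get_one(self, id):
        """An arbitrary single member with ``id``, or None."""
        members = self._map.get(id)
        return members[0] if members else None

    @property
    def ids(self):
        return set(self._map)

    def __iter__(self):
        for members in self._map.values():
            yield from members

    def __len__(self):
        return sum(len(members) for members in self._map.values())

    def __contains__(self, member):
        return member in self._map.get(getattr(member, "id", None), [])

    def __add__(self, other):
        new = StructureSet()
        for member in self:
            new.add(member)
        for member in other:
            new.add(member)
        return new

    def __repr__(self):
        return f"<StructureSet ({len(self)} members, {len(self._map)} ids)>"


class AtomContainer:
    """Mixin giving any atom-holding structure its metric and transform API."""

    def atoms(self, **kwargs):
        """The set of contained atoms, optionally filtered.

        Keyword filters use the double-underscore syntax: ``element="N"``,
        ``mass__gt=14``, ``het__name__regex="CYS|HIS"`` and so on.
        """
        atoms = self._atoms()
        if kwargs:
            atoms = filter_structures(atoms, kwargs)
        return set(atoms)

    @property
    def mass(self):
        """Sum of the standard atomic weights of the contained atoms (Da)."""
        return sum(atom.mass for atom in self._atoms())

    @property
    def formula(self):
        """Multiset count of element symbols, as a dict."""
        counts = {}
        for atom in self._atoms():
            counts[atom.element] = counts.get(atom.element, 0) + 1
        return counts

    @property
    def center_of_mass(self):
        return _geometry.center_of_mass(self)

    @property
    def radius_of_gyration(self):
        return _geometry.radius_of_gyration(self)

    def translate(self, vector):
        return _geometry.translate(self, vector)

    def rotate(self, matrix):
        return _geometry.rotate(self, matrix)

    def transform(self, matrix, vector):
        return _geometry.transform(self, matrix, vector)

    def rmsd_with(self, other):
        return _geometry.rmsd_with(self, other)

    def grid(self, spacing=1):
        return _geometry.grid(self, spacing)

    def pairing_with(self, other):
        """Map this structure's atoms 1:1 onto ``other``'s by (het id, name)."""
        return _geometry.pair_atoms(self, other)


class Atom:
    """A single atom: the leaf of the hierarchy.

    Coordinates are in angstroms, charge in elementary-charge units and
    bvalue (the temperature factor) in square angstroms.
    """

    def __init__(self, element, x, y, z, id=0, name=None, charge=0,
                 bvalue=0, parent=None):
        if not element or not str(element).strip():
            raise ValueError("Atom element must be a non-empty string")
        for value in (x, y, z):
            if value != value or value in (float("inf"), float("-inf")):
                raise ValueError("Atom coordinates must be finite")
        self.element = str(element)
        self.x, self.y, self.z = float(x), float(y), float(z)
        self.id = id
        self.name = name
        self.charge = charge
        self.bvalue = bvalue
        self._parent = parent

    @property
    def location(self):
        return (self.x, self.y, self.z)

    @property
    def mass(self):
        return atomic_weight(self.element)

    @property
    def het(self):
        """The residue/ligand/water the atom belongs to, or None."""
        return self._parent

    @property
    def chain(self):
        return self._parent.chain if self._parent is not None else None

    @property
    def model(self):
        return self._parent.model if self._parent is not None else None

    def distance_to(self, other):
        """Euclidean distance to another atom or (x, y, z) point, in Å."""
        return _geometry.distance(self.location, getattr(other, "location", other))

    def nearby_atoms(self, radius, **kwargs):
        """All other atoms of the owning model within ``radius`` Å."""
        if self.model is None:
            return set()
        return _geometry.nearby_atoms(self, radius, self.model, **kwargs)

    def copy(self):
        return Atom(self.element, self.x, self.y, self.z, id=self.id,
                    name=self.name, charge=self.charge, bvalue=self.bvalue)

    def __repr__(self):
        return f"<Atom {self.id} ({self.name})>"


class Het(AtomContainer):
    """A named group of atoms: a polymer residue, a ligand or a water.

    IDs are dotted, ``<chain>.<number>[<insertion>]`` — e.g. ``"A.12"``,
    ``"A.12B"`` or the non-polymer ``"O.153"``.
    """

    RESIDUE, LIGAND, WATER = "residue", "ligand", "water"

    def __init__(self, id, name, kind=None, atoms=(), parent=None):
        if kind is None:
            kind = Het.WATER if name in WATER_NAMES else Het.LIGAND
        self.id = id
        self.name = name
        self.kind = kind
        self._atoms_set = StructureSet()
        self._parent = parent
        for atom in atoms:
            self.add(atom)

    def add(self, atom):
        atom._parent = self
        self._atoms_set.add(atom)

    def _atoms(self):
        return set(self._atoms_set)

    def atom(self, id):
        return self._atoms_set.get_one(id)

    @property
    def chain(self):
        return self._parent if isinstance(self._parent, Chain) else None

    @property
    def model(self):
        if isinstance(self._parent, Chain):
            return self._parent.model
        return self._parent if isinstance(self._parent, Model) else None

    @property
    def number(self):
        """The integer part of the dotted ID."""
        tail = self.id.split(".", 1)[1] if "." in self.id else self.id
        digits = "".join(c for c in tail if c.isdigit() or c == "-")
        return int(digits) if digits else 0

    @property
    def insertion(self):
        tail = self.id.split(".", 1)[1] if "." in self.id else self.id
        return "".join(c for c in tail if c.isalpha())

    def copy(self):
        return Het(self.id, self.name, kind=self.kind,
                   atoms=[a.copy() for a in self._atoms_set])

    def __repr__(self):
        return f"<{self.kind.capitalize()} {self.name} ({self.id})>"


class Chain(AtomContainer):
    """An ordered polymer of residues.

    ``length`` counts residues actually present in the coordinates;
    ``sequence`` is the full one-letter sequence including residues that
    were not resolved in the experiment.
    """

    def __init__(self, id, residues=(), sequence="", internal_id=None,
                 parent=None):
        self.id = id
        self.internal_id = internal_id if internal_id is not None else id
        self.sequence = sequence
        self._residues = []
        self._parent = parent
        for residue in residues:
            self.add(residue)

    def add(self, residue):
        residue._parent = self
        self._residues.append(residue)
        self._residues.sort(key=lambda r: (r.number, r.insertion))

    @property
    def residues(self):
        return list(self._residues)

    def residue(self, id):
        for residue in self._residues:
            if residue.id == id:
                return residue
        return None

    @property
    def length(self):
        return len(self._residues)

    def __len__(self):
        return self.length

    @property
    def model(self):
        return self._parent

    def _atoms(self):
        atoms = set()
        for residue in self._residues:
            atoms |= residue._atoms()
        return atoms

    def copy(self):
        return Chain(self.id, residues=[r.copy() for r in self._residues],
                     sequence=self.sequence, internal_id=self.internal_id)

    def __repr__(self):
        return f"<Chain {self.id} ({self.length} residues)>"


class Model(AtomContainer):
    """A container of chains, ligands and waters — one coordinate set."""

    def __init__(self, chains=(), ligands=(), waters=()):
        self._chains = StructureSet()
        self._ligands = StructureSet()
        self._waters = StructureSet()
        for chain in chains:
            self.add(chain)
        for ligand in ligands:
            self.add(ligand)
        for water in waters:
            self.add(water)

    def add(self, structure):
        structure._parent = self
        if isinstance(structure, Chain):
            self._chains.add(structure)
        elif structure.kind == Het.WATER:
            self._waters.add(structure)
        else:
            self._ligands.add(structure)

    def chains(self, **kwargs):
        chains = set(self._chains)
        return set(filter_structures(chains, kwargs)) if kwargs else chains

    def ligands(self, **kwargs):
        ligands = set(self._ligands)
        return set(filter_structures(ligands, kwargs)) if kwargs else ligands

    def waters(self, **kwargs):
        waters = set(self._waters)
        return set(filter_structures(waters, kwargs)) if kwargs else waters

    def residues(self, **kwargs):
        residues = set()
        for chain in self._chains:
            residues |= set(chain.residues)
        return set(filter_structures(residues, kwargs)) if kwargs else residues

    def chain(self, id):
        return self._chains.get_one(id)

    def ligand(self, id):
        return self._ligands.get_one(id)

    def water(self, id):
        return self._waters.get_one(id)

    @property
    def chain_set(self):
        return self._chains

    @property
    def ligand_set(self):
        return self._ligands

    @property
    def water_set(self):
        return self._waters

    def _atoms(self):
        atoms = set()
        for collection in (self._chains, self._ligands, self._waters):
            for structure in collection:
                atoms |= structure._atoms()
        return atoms

    def atom(self, id):
        for atom in self._atoms():
            if atom.id == id:
                return atom
        return None

    def dehydrate(self):
        """Remove every water from the model. Idempotent."""
        self._waters = StructureSet()
        return self

    def nearby_atoms(self, origin, radius, **kwargs):
        return _geometry.nearby_atoms(origin, radius, self, **kwargs)

    def copy(self):
        return Model(chains=[c.copy() for c in self._chains],
                     ligands=[l.copy() for l in self._ligands],
                     waters=[w.copy() for w in self._waters])

    def __repr__(self):
        return (f"<Model ({len(self._chains)} chains, "
                f"{len(self._ligands)} ligands, {len(self._waters)} waters)>")


class File(AtomContainer):
    """A parsed structure file: one or more models plus entry metadata."""

    def __init__(self, models=(), code=None, title=None, resolution=None,
                 rvalue=None, rfree=None, missing_residues=None,
                 assemblies=None, source_format=None, description=None,
                 experiment=None):
        self.models = list(models)
        self.code = code
        self.title = title
        self.resolution = resolution
        self.rvalue = rvalue
        self.rfree = rfree
        self.missing_residues = missing_residues if missing_residues is not None else []
        self.assemblies = assemblies if assemblies is not None else []
        self.source_format = source_format
        self.description = description or {}
        self.experiment = experiment or {}

    @property
    def model(self):
        """The first (often only) model."""
        return self.models[0] if self.models else None

    def _atoms(self):
        return self.model._atoms() if self.models else set()

    def generate_assembly(self, assembly_id, rename_chains=False):
        from .build import generate_assembly
        return generate_assembly(self, assembly_id, rename_chains=rename_chains)

    def __repr__(self):
        return f"<File {self.code or self.title or ''} ({len(self.models)} models)>"


def structure_mass(structure):
    """Total standard-atomic-weight mass of any atom container, in daltons."""
    return structure.mass


def structure_formula(structure):
    return structure.formula


def center_of_mass(structure):
    return _geometry.center_of_mass(structure)


def radius_of_gyration(structure):
    return _geometry.radius_of_gyration(structure)


def dehydrate(model):
    return model.dehydrate()


def get_by_id(structure_set, id):
    """All members of a StructureSet carrying ``id`` (possibly empty)."""
    return structure_set.get(id)
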