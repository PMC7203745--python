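"""Geometric transforms, distance metrics and spatial queries.

All functions act on any atom container (an object exposing ``atoms()``)
or on a bare iterable of atoms. Transformations are applied in place as
r' = M.r + v; rotation is about the origin with no implicit centring, so
in-place rotation about a centre is composed as translate-rotate-translate.
"""

import math
from dataclasses import dataclass, field

import numpy as np


def _atoms_of(structure):
    if hasattr(structure, "_atoms"):
        return structure._atoms()
    if hasattr(structure, "atoms"):
        return structure.atoms()
    return set(structure)


@dataclass
class Transformation:
    """A rigid (or general affine) map r' = matrix @ r + vector."""
    matrix: object = field(default_factory=lambda: np.eye(3))
    vector: object = field(default_factory=lambda: np.zeros(3))
    chain_ids: list = field(default_factory=list)

    def apply(self, structure):
        return transform(structure, self.matrix, self.vector)


def distance(a, b):
    """Euclidean distance between two (x, y, z) points in Å."""
    return math.dist(a, b)


def translate(structure, vector):
    """Shift every atom coordinate by ``vector`` (Å). Mutates in place."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (3,) or not np.all(np.isfinite(vector)):
        raise ValueError("Translation vector must be 3 finite numbers")
    for atom in _atoms_of(structure):
        atom.x += vector[0]
        atom.y += vector[1]
        atom.z += vector[2]
    return structure


def rotate(structure, matrix):
    """Map every atom coordinate r to matrix @ r. Mutates in place."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3) or not np.all(np.isfinite(matrix)):
        raise ValueError("Rotation matrix must be 3x3 with finite entries")
    for atom in _atoms_of(structure):
        atom.x, atom.y, atom.z = matrix @ (atom.x, atom.y, atom.z)
    return structure


def transform(structure, matrix, vector):
    """Apply r' = matrix @ r + vector to every atom. Mutates in place."""
    matrix = np.asarray(matrix, dtype=float)
    vector = np.asarray(vector, dtype=float)
    if matrix.shape != (3, 3) or vector.shape != (3,):
        raise ValueError("Transformation needs a 3x3 matrix and a 3-vector")
    for atom in _atoms_of(structure):
        atom.x, atom.y, atom.z = matrix @ (atom.x, atom.y, atom.z) + vector
    return structure


def center_of_mass(structure):
    """Mass-weighted mean coordinate, in Å."""
    atoms = list(_atoms_of(structure))
    if not atoms:
        raise ValueError("Centre of mass is undefined for an empty structure")
    masses = np.array([a.mass for a in atoms])
    total = masses.sum()
    if total <= 0:
        raise ValueError("Centre of mass needs positive total mass")
    coords = np.array([a.location for a in atoms])
    return tuple(masses @ coords / total)


def radius_of_gyration(structure):
    """sqrt(sum m_i |r_i - COM|^2 / sum m_i), in Å."""
    atoms = list(_atoms_of(structure))
    if not atoms:
        raise ValueError("Radius of gyration is undefined for an empty structure")
    com = np.array(center_of_mass(structure))
    masses = np.array([a.mass for a in atoms])
    coords = np.array([a.location for a in atoms])
    sq = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt(masses @ sq / masses.sum()))


def _pair_key(atom):
    het_id = atom.het.id if atom.het is not None else None
    return (het_id, atom.name)


def pair_atoms(a, b):
    """1:1 pairing of the two structures' atoms keyed by (het id, atom name).

    Raises ValueError naming the unmatched keys when the two atom sets do
    not pair exactly.
    """
    map_a = {}
    map_b = {}
    for structure, mapping in ((a, map_a), (b, map_b)):
        for atom in _atoms_of(structure):
            key = _pair_key(atom)
            if key in mapping:
                raise ValueError(f"Duplicate pairing key {key}")
            mapping[key] = atom
    unmatched = set(map_a) ^ set(map_b)
    if unmatched:
        raise ValueError(f"Atoms cannot be paired 1:1; unmatched keys: "
                         f"{sorted(unmatched, key=str)}")
    return {map_a[key]: map_b[key] for key in map_a}


def rmsd_with(a, b):
    """Root-mean-square deviation over paired atoms, in Å (no superposition)."""
    pairing = pair_atoms(a, b)
    if not pairing:
        raise ValueError("RMSD is undefined for empty structures")
    sq = [distance(x.location, y.location) ** 2 for x, y in pairing.items()]
    return math.sqrt(sum(sq) / len(sq))


def nearby_atoms(origin, radius, model, accelerate=False, **filters):
    """All atoms of ``model`` within ``radius`` Å of ``origin``.

    ``origin`` is an Atom (itself excluded from the result) or a bare
    (x, y, z) point. Distance uses the closed ball: atoms exactly at the
    radius are included. Extra keyword filters apply the query syntax to
    the result (e.g. ``element="ZN"`` or exclude waters with
    ``het__kind="residue"``).
    """
    if radius <= 0:
        raise ValueError("Radius must be positive")
    point = getattr(origin, "location", None)
    origin_atom = origin if point is not None else None
    if point is None:
        point = tuple(origin)
    atoms = _atoms_of(model)
    if accelerate:
        found = _cell_list_search(atoms, point, radius)
    else:
        found = {a for a in atoms if distance(a.location, point) <= radius}
    found.discard(origin_atom)
    if filters:
        from .query import filter_structures
        found = set(filter_structures(found, filters))
    return found


def _cell_list_search(atoms, point, radius):
    """Uniform-grid accelerated ball query; agrees exactly with the scan."""
    cells = {}
    for atom in atoms:
        key = (int(atom.x // radius), int(atom.y // radius), int(atom.z // radius))
        cells.setdefault(key, []).append(atom)
    cx, cy, cz = (int(point[0] // radius), int(point[1] // radius),
                  int(point[2] // radius))
    found = set()
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                for atom in cells.get((cx + dx, cy + dy, cz + dz), ()):
                    if distance(atom.location, point) <= radius:
                        found.add(atom)
    return found


def grid(structure, spacing=1):
    """Ordered lattice points covering the atoms' axis-aligned bounding box.

    Yields every (i*s, j*s, k*s) with floor(min/s) <= i <= ceil(max/s) per
    axis, so the lattice hull always contains every atom, boundary cells
    included.
    """
    atoms = list(_atoms_of(structure))
    if not atoms:
        raise ValueError("Grid is undefined for an empty structure")
    if spacing <= 0:
        raise ValueError("Grid spacing must be positive")
    coords = np.array([a.location for a in atoms])
    lows = np.floor(coords.min(axis=0) / spacing).astype(int)
    highs = np.ceil(coords.max(axis=0) / spacing).astype(int)
    points = []
    for i in range(lows[0], highs[0] + 1):
        for j in range(lows[1], highs[1] + 1):
            for k in range(lows[2], highs[2] + 1):
                points.append((i * spacing, j * spacing, k * spacing))
    return points
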