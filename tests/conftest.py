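import random

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from structparse.structures import Atom, Het, Chain, Model
from structparse.fixtures import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def rich_fixture():
    """One structure exercising every feature: two chains, a zinc and a
    three-atom ligand, waters, an altloc pair, a missing residue and a
    two-operator assembly."""
    return make_fixture(FixtureSpec(
        chains=(3, 2),
        ligands=(("A.100", "ZN", 1), ("B.101", "LIG", 3)),
        waters=2,
        altloc_groups=(("A", "B"),),
        missing_residues=(("A", 4, "GLY"),),
        assemblies=({"id": 1, "software": None, "transformations": [
            {"chain_ids": ["A", "B"],
             "matrix": [[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]],
             "vector": [1.5, 0.0, -2.25]},
            {"chain_ids": ["A"],
             "matrix": [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
             "vector": [0.0, 0.0, 0.0]}]},),
        seed=3))


def random_model(rng=None, n_chains=2, residues=3, waters=2, ligands=1):
    """A small random Model built object-by-object (independent of the
    fixture generator and parsers)."""
    rng = rng or random.Random(0)
    model = Model()
    serial = 0
    elements = ["C", "N", "O", "S", "H"]
    for c in range(n_chains):
        chain_id = "ABCDEFG"[c]
        residues_list = []
        for r in range(residues):
            atoms = []
            for name, element in (("N", "N"), ("CA", "C"), ("C", "C")):
                serial += 1
                atoms.append(Atom(element, rng.uniform(-10, 10),
                                  rng.uniform(-10, 10), rng.uniform(-10, 10),
                                  id=serial, name=name,
                                  bvalue=round(rng.uniform(0, 50), 2)))
            residues_list.append(Het(f"{chain_id}.{r + 1}", "GLY",
                                     kind=Het.RESIDUE, atoms=atoms))
        model.add(Chain(chain_id, residues=residues_list, sequence="G" * residues))
    for l in range(ligands):
        serial += 1
        model.add(Het(f"A.{100 + l}", "ZN", kind=Het.LIGAND,
                      atoms=[Atom("ZN", rng.uniform(-10, 10),
                                  rng.uniform(-10, 10), rng.uniform(-10, 10),
                                  id=serial, name="ZN", charge=2)]))
    for w in range(waters):
        serial += 1
        model.add(Het(f"A.{200 + w}", "HOH", kind=Het.WATER,
                      atoms=[Atom("O", rng.uniform(-10, 10),
                                  rng.uniform(-10, 10), rng.uniform(-10, 10),
                                  id=serial, name="O")]))
    return model
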