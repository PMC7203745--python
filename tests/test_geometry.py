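"""Transforms, RMSD, proximity search and grid generation."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from structparse.geometry import (translate, rotate, rmsd_with, nearby_atoms,
                                  grid, _cell_list_search)
from structparse.structures import Atom, Het, Model
from tests.conftest import random_model


def het_of(coords, element="C"):
    atoms = [Atom(element, x, y, z, id=i + 1, name=f"C{i + 1}")
             for i, (x, y, z) in enumerate(coords)]
    return Het("A.1", "LIG", atoms=atoms)


class TestTranslate:

    def test_zero_vector_is_identity(self):
        h = het_of([(1, 2, 3)])
        translate(h, (0, 0, 0))
        assert next(iter(h.atoms())).location == (1, 2, 3)

    def test_direct_addition(self):
        h = het_of([(1, 1, 1)])
        translate(h, (1, 2, 3))
        assert next(iter(h.atoms())).location == (2, 3, 4)

    def test_inverse_recovers_original(self):
        h = het_of([(0.5, -2.25, 7.125), (3, 4, 5)])
        originals = sorted(a.location for a in h.atoms())
        translate(h, (1.1, -2.2, 3.3))
        translate(h, (-1.1, 2.2, -3.3))
        for got, want in zip(sorted(a.location for a in h.atoms()), originals):
            assert got == pytest.approx(want, abs=1e-9)

    def test_non_finite_vector_rejected(self):
        with pytest.raises(ValueError):
            translate(het_of([(0, 0, 0)]), (float("nan"), 0, 0))

    def test_metadata_untouched(self):
        h = het_of([(1, 1, 1)])
        atom = next(iter(h.atoms()))
        translate(h, (5, 5, 5))
        assert (atom.id, atom.name, atom.element) == (1, "C1", "C")


class TestRotate:

    def test_identity_matrix(self):
        h = het_of([(1, 2, 3)])
        rotate(h, np.eye(3))
        assert next(iter(h.atoms())).location == pytest.approx((1, 2, 3))

    def test_quarter_turn_about_z(self):
        h = het_of([(1, 0, 0)])
        rotate(h, [[0, -1, 0], [1, 0, 0], [0, 0, 1]])
        assert next(iter(h.atoms())).location == pytest.approx((0, 1, 0))

    def test_transpose_inverts_orthonormal_rotation(self):
        theta = 0.7
        m = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        h = het_of([(1.5, -2.5, 3.5)])
        rotate(h, m)
        rotate(h, m.T)
        assert next(iter(h.atoms())).location == \
            pytest.approx((1.5, -2.5, 3.5), abs=1e-9)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            rotate(het_of([(0, 0, 0)]), np.eye(2))

    def test_no_implicit_centring(self):
        # rotation is about the origin, not the centre of mass
        h = het_of([(2, 0, 0), (4, 0, 0)])
        rotate(h, [[0, -1, 0], [1, 0, 0], [0, 0, 1]])
        assert sorted(a.location[1] for a in h.atoms()) == \
            pytest.approx([2, 4])


class TestRmsd:

    def test_self_rmsd_zero(self):
        h = het_of([(0, 0, 0), (1, 1, 1)])
        assert rmsd_with(h, h) == 0.0

    def test_single_pair_is_plain_distance(self):
        a = het_of([(0, 0, 0)])
        b = het_of([(3, 0, 0)])
        assert rmsd_with(a, b) == pytest.approx(3.0)

    def test_matches_brute_force_formula(self):
        rng = random.Random(4)
        coords_a = [(rng.uniform(-5, 5),) * 3 for _ in range(5)]
        coords_b = [(rng.uniform(-5, 5),) * 3 for _ in range(5)]
        a, b = het_of(coords_a), het_of(coords_b)
        expected = math.sqrt(sum(
            sum((p - q) ** 2 for p, q in zip(ca, cb))
            for ca, cb in zip(coords_a, coords_b)) / 5)
        assert rmsd_with(a, b) == pytest.approx(expected, rel=1e-12)

    def test_symmetry_and_translation_invariance(self):
        rng = random.Random(7)
        a = het_of([(rng.uniform(-5, 5), rng.uniform(-5, 5),
                     rng.uniform(-5, 5)) for _ in range(6)])
        b = het_of([(rng.uniform(-5, 5), rng.uniform(-5, 5),
                     rng.uniform(-5, 5)) for _ in range(6)])
        d = rmsd_with(a, b)
        assert rmsd_with(b, a) == pytest.approx(d)
        translate(a, (3.5, -1.25, 0.75))
        translate(b, (3.5, -1.25, 0.75))
        assert rmsd_with(a, b) == pytest.approx(d, abs=1e-9)

    def test_unpairable_sets_error_names_keys(self):
        a = het_of([(0, 0, 0)])
        b = Het("A.1", "LIG", atoms=[Atom("C", 0, 0, 0, name="CB")])
        with pytest.raises(ValueError, match="C1|CB"):
            rmsd_with(a, b)


class TestNearbyAtoms:

    def test_lone_atom_excluded_from_own_search(self):
        model = Model()
        zn = Atom("ZN", 0, 0, 0, id=1, name="ZN")
        model.add(Het("A.1", "ZN", kind=Het.LIGAND, atoms=[zn]))
        assert zn.nearby_atoms(100) == set()

    def test_closed_ball_selection(self):
        model = Model()
        origin = Atom("ZN", 0, 0, 0, id=1, name="ZN")
        others = [Atom("C", 1, 0, 0, id=2, name="C1"),
                  Atom("C", 0, 2, 0, id=3, name="C2"),
                  Atom("C", 0, 0, 5, id=4, name="C3"),
                  Atom("C", 3, 0, 0, id=5, name="C4")]  # exactly at radius
        model.add(Het("A.1", "LIG", kind=Het.LIGAND, atoms=[origin] + others))
        found = origin.nearby_atoms(3)
        assert sorted(a.id for a in found) == [2, 3, 5]

    def test_radius_covering_everything(self):
        model = random_model()
        some_atom = next(iter(model.atoms()))
        assert some_atom.nearby_atoms(1000) == model.atoms() - {some_atom}

    def test_invalid_radius(self):
        model = random_model()
        with pytest.raises(ValueError):
            nearby_atoms((0, 0, 0), 0, model)

    def test_point_origin_and_filters(self):
        model = random_model(waters=3)
        found = nearby_atoms((0, 0, 0), 50, model)
        assert found == model.atoms()
        no_waters = nearby_atoms((0, 0, 0), 50, model, het__kind="residue")
        assert no_waters == {a for a in model.atoms()
                             if a.het.kind == "residue"}

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_and_cell_list_agree(self, seed):
        rng = random.Random(seed)
        model = random_model(rng, n_chains=3, residues=4, waters=3)
        point = (rng.uniform(-5, 5), rng.uniform(-5, 5), rng.uniform(-5, 5))
        radius = rng.uniform(1, 8)
        brute = {a for a in model.atoms()
                 if math.dist(a.location, point) <= radius}
        assert nearby_atoms(point, radius, model) == brute
        assert _cell_list_search(model.atoms(), point, radius) == brute
        assert nearby_atoms(point, radius, model, accelerate=True) == brute


class TestGrid:

    def test_unit_cell_corners_around_interior_atom(self):
        points = grid(het_of([(0.5, 0.5, 0.5)]), spacing=1)
        assert sorted(points) == sorted(
            [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)])

    def test_atom_on_lattice_point_gives_single_point(self):
        assert grid(het_of([(2.0, 3.0, -1.0)]), spacing=1) == [(2, 3, -1)]

    def test_point_count_formula(self):
        h = het_of([(0, 0, 0), (2, 1, 1)])
        points = grid(h, spacing=1)
        assert len(points) == 3 * 2 * 2

    def test_every_atom_inside_lattice_hull(self):
        model = random_model()
        points = grid(model, spacing=1.5)
        xs = [p[0] for p in points]
        ys = [p[1] for p in points]
        zs = [p[2] for p in points]
        for a in model.atoms():
            assert min(xs) <= a.x <= max(xs)
            assert min(ys) <= a.y <= max(ys)
            assert min(zs) <= a.z <= max(zs)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            grid(Het("A.1", "LIG"))
        with pytest.raises(ValueError):
            grid(het_of([(0, 0, 0)]), spacing=0)


@settings(deadline=None, max_examples=20)
@given(seed=st.integers(0, 10 ** 6))
def test_rigid_motion_preserves_counts_ids_and_rmsd_zero(seed):
    rng = random.Random(seed)
    model = random_model(rng)
    reference = random_model(random.Random(seed))
    ids = sorted(a.id for a in model.atoms())
    theta = rng.uniform(0, 2 * math.pi)
    m = [[math.cos(theta), -math.sin(theta), 0],
         [math.sin(theta), math.cos(theta), 0], [0, 0, 1]]
    rotate(model, m)
    translate(model, (rng.uniform(-5, 5),) * 3)
    assert sorted(a.id for a in model.atoms()) == ids
    # a rigid motion never changes internal geometry
    assert model.radius_of_gyration == \
        pytest.approx(reference.radius_of_gyration, abs=1e-9)
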