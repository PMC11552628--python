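"""Distance restraints: penalty closed forms, gradients, composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microdock.constraints import (AtomSelector, ConstraintError,
                                   DistanceConstraint, MatrixConstraint,
                                   constraint_as_sf, harmonic_penalty,
                                   matrix_penalty, read_matrix_constraint,
                                   wall_penalty, write_matrix_constraint)
from microdock.fixtures import native_distance_matrix
from microdock.scoring import make_hybrid_sf


class TestPenaltyForms:
    def test_harmonic_zero_at_target(self):
        assert harmonic_penalty(2.5, 2.5, k=3.0) == 0.0

    def test_harmonic_closed_form(self):
        assert harmonic_penalty(3.0, 1.0, k=1.0) == 4.0

    def test_harmonic_gradient_is_analytic(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            d, d0, k = rng.uniform(0.1, 5.0, 3)
            h = 1e-7
            num = (harmonic_penalty(d + h, d0, k)
                   - harmonic_penalty(d - h, d0, k)) / (2 * h)
            assert np.isclose(num, 2 * k * (d - d0), atol=1e-5)

    def test_wall_zero_inside_bounds(self):
        assert wall_penalty(1.5, lower=1.0, upper=2.0, k=5.0) == 0.0

    def test_upper_wall_closed_form(self):
        assert wall_penalty(3.0, upper=1.0, k=1.0) == 4.0

    def test_lower_wall_closed_form(self):
        assert wall_penalty(1.0, lower=2.0, k=2.0) == 2.0

    def test_wall_requires_ordered_bounds(self):
        with pytest.raises(ConstraintError, match="lower < upper"):
            wall_penalty(1.0, lower=3.0, upper=2.0)

    def test_wall_needs_at_least_one_bound(self):
        with pytest.raises(ConstraintError, match="bound"):
            wall_penalty(1.0)

    @pytest.mark.parametrize("kind, kwargs", [
        ("harmonic", dict(target=2.0)),
        ("upper_wall", dict(upper=3.0)),
        ("lower_wall", dict(lower=1.0)),
        ("wall", dict(lower=1.0, upper=3.0)),
    ])
    def test_penalties_nonnegative_zero_on_feasible_set(self, kind, kwargs):
        c = DistanceConstraint(a=AtomSelector("ligand", index=0),
                               b=AtomSelector("receptor", index=0),
                               kind=kind, force_constant=2.0, **kwargs)
        for d in np.linspace(0.0, 6.0, 61):
            p = c.penalty(d)
            assert p >= 0.0
        feasible = kwargs.get("target", 2.0)
        assert c.penalty(feasible) == 0.0

    def test_violation_monotonicity(self):
        c = DistanceConstraint(a=AtomSelector("ligand", index=0),
                               b=AtomSelector("receptor", index=0),
                               kind="harmonic", target=2.0)
        ds = np.linspace(2.0, 6.0, 20)
        pens = [c.penalty(d) for d in ds]
        assert all(b >= a for a, b in zip(pens, pens[1:]))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(d=st.floats(0.0, 20.0), lower=st.floats(0.5, 5.0),
       width=st.floats(0.1, 5.0), k=st.floats(0.0, 10.0))
def test_wall_penalty_properties(d, lower, width, k):
    """Walls are non-negative, exactly zero inside the feasible band, and
    non-decreasing in the violation on either side."""
    upper = lower + width
    p = float(wall_penalty(d, lower=lower, upper=upper, k=k))
    assert p >= 0.0
    if lower <= d <= upper:
        assert p == 0.0
    else:
        further = d + 0.5 if d > upper else d - 0.5
        assert float(wall_penalty(further, lower=lower, upper=upper, k=k)) >= p


class TestMatrixPenalty:
    def test_zero_when_current_equals_native(self):
        rng = np.random.default_rng(1)
        lig = rng.normal(size=(3, 3))
        rec = rng.normal(size=(4, 3)) + 5
        native = native_distance_matrix(lig, rec, np.arange(3), np.arange(4))
        mc = MatrixConstraint(np.arange(3), np.arange(4), native)
        assert matrix_penalty(lig, rec, mc) == 0.0

    def test_small_closed_form(self):
        lig = np.array([[0.0, 0.0, 0.0]])
        rec = np.array([[3.0, 0.0, 0.0], [0.0, 4.0, 0.0]])
        mc = MatrixConstraint([0], [0, 1], np.array([[1.0, 2.0]]))
        assert matrix_penalty(lig, rec, mc) == (3 - 1) ** 2 + (4 - 2) ** 2

    def test_noise_identity_at_native_pose(self):
        # perturbing the native matrix by eps makes the penalty at the native
        # pose exactly the summed squared perturbation
        rng = np.random.default_rng(2)
        lig = rng.normal(size=(4, 3))
        rec = rng.normal(size=(5, 3)) + 4
        native = native_distance_matrix(lig, rec, np.arange(4), np.arange(5))
        noise = rng.normal(0, 0.3, native.shape)
        mc = MatrixConstraint(np.arange(4), np.arange(5), native + noise)
        assert np.isclose(matrix_penalty(lig, rec, mc), np.sum(noise ** 2))

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ConstraintError, match="shape"):
            MatrixConstraint([0, 1], [0], np.ones((1, 1)))

    def test_nonpositive_entries_are_an_error(self):
        with pytest.raises(ConstraintError, match="positive"):
            MatrixConstraint([0], [0], np.array([[0.0]]))

    def test_file_round_trip(self, tmp_path):
        mc = MatrixConstraint([0, 2], [1, 3, 4],
                              np.arange(1, 7, dtype=float).reshape(2, 3),
                              weight=0.5)
        path = tmp_path / "native.mat"
        write_matrix_constraint(mc, path)
        back = read_matrix_constraint(path)
        assert np.allclose(back.native_matrix, mc.native_matrix)
        assert list(back.ligand_atoms) == [0, 2]
        assert list(back.receptor_atoms) == [1, 3, 4]
        assert back.weight == 0.5


class TestConstraintScoringFunction:
    def _harmonic_native(self, system, planted):
        """Harmonic restraint at the native donor-acceptor contact."""
        lig_i = next(i for i, a in enumerate(system.ligand.atoms)
                     if a.name == "N1")
        rec_oa = [j for j, a in enumerate(system.receptor.atoms)
                  if a.adtype == "OA"]
        d = [np.linalg.norm(planted[lig_i] - system.receptor.atoms[j].coords)
             for j in rec_oa]
        j = rec_oa[int(np.argmin(d))]
        return DistanceConstraint(
            a=AtomSelector("receptor", atom_name=system.receptor.atoms[j].name),
            b=AtomSelector("ligand", atom_name="N1"),
            kind="harmonic", target=float(min(d)))

    def test_satisfied_constraints_evaluate_to_zero(self, system, pocket):
        _, planted, _ = pocket
        sf = constraint_as_sf([self._harmonic_native(system, planted)], system)
        assert np.isclose(sf.evaluate(planted, system.receptor_coords()).total,
                          0.0, atol=1e-12)

    def test_hybrid_with_vina_at_equal_weights(self, system, vina, pocket):
        # the constrained-docking recipe: score = 0.5 * empirical + 0.5 * restraint
        _, planted, _ = pocket
        costr = constraint_as_sf([self._harmonic_native(system, planted)],
                                 system)
        hy = make_hybrid_sf([(vina, 0.5), (costr, 0.5)])
        rng = np.random.default_rng(3)
        lig = system.ligand_coords(system.random_pose(rng))
        rec = system.receptor_coords()
        expect = 0.5 * vina.evaluate(lig, rec).total \
            + 0.5 * costr.evaluate(lig, rec).total
        assert np.isclose(hy.evaluate(lig, rec).total, expect, atol=1e-12)

    def test_unresolvable_selector_fails_at_construction(self, system):
        bad = DistanceConstraint(
            a=AtomSelector("receptor", atom_name="NOPE"),
            b=AtomSelector("ligand", atom_name="N1"),
            kind="harmonic", target=2.0)
        with pytest.raises(ConstraintError, match="NOPE|0 atoms"):
            constraint_as_sf([bad], system)

    def test_empty_constraint_list_is_an_error(self, system):
        with pytest.raises(ConstraintError, match="restraint"):
            constraint_as_sf([], system)

    def test_gradients_match_finite_differences(self, system, pocket):
        _, planted, _ = pocket
        lig_idx = np.flatnonzero(system.ligand.heavy_mask)[:3]
        rec_idx = np.flatnonzero(system.receptor.heavy_mask)[:4]
        native = native_distance_matrix(planted, system.receptor_coords(),
                                        lig_idx, rec_idx)
        constraints = [
            self._harmonic_native(system, planted),
            DistanceConstraint(a=AtomSelector("receptor", index=0),
                               b=AtomSelector("ligand", index=0),
                               kind="wall", lower=2.0, upper=6.0,
                               force_constant=1.5),
            MatrixConstraint(lig_idx, rec_idx, native),
        ]
        sf = constraint_as_sf(constraints, system)
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = system.random_pose(rng).to_array()
            g = system.gradient_array(x, sf)
            h = 1e-6
            fd = np.zeros_like(x)
            for i in range(len(x)):
                e = np.zeros_like(x)
                e[i] = h
                fd[i] = (system.score_array(x + e, sf)
                         - system.score_array(x - e, sf)) / (2 * h)
            assert np.linalg.norm(g - fd) <= 1e-6 * max(np.linalg.norm(fd), 1.0)

    def test_constraint_preserves_ranking_of_feasible_poses(self, system,
                                                            vina, pocket):
        # two poses that both satisfy the restraint exactly keep their order
        _, planted, _ = pocket
        c = DistanceConstraint(a=AtomSelector("receptor", index=0),
                               b=AtomSelector("ligand", atom_name="N1"),
                               kind="upper_wall", upper=50.0)
        costr = constraint_as_sf([c], system)
        hy = make_hybrid_sf([(vina, 0.5), (costr, 0.5)])
        rng = np.random.default_rng(5)
        rec = system.receptor_coords()
        a = system.ligand_coords(system.random_pose(rng))
        b = system.ligand_coords(system.random_pose(rng))
        va, vb = vina.evaluate(a, rec).total, vina.evaluate(b, rec).total
        ha, hb = hy.evaluate(a, rec).total, hy.evaluate(b, rec).total
        assert costr.evaluate(a, rec).total == costr.evaluate(b, rec).total == 0
        assert (va < vb) == (ha < hb)
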