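"""Empirical scoring: closed forms, invariances, gradients, composition."""

import numpy as np
import pytest

from microdock import DockingSystem, VinaScore
from microdock.conformation import DockingBox, PoseVector
from microdock.minimize import local_minimize
from microdock.pdbqt import parse_pdbqt_ligand, parse_pdbqt_receptor
from microdock.scoring import (VinaParams, make_hybrid_sf,
                               register_external_sf, score_gradient,
                               score_pose, surface_distance, vina_terms)
from conftest import atom_line

W = VinaParams().weights


def _pair_system(distance, lig_type="C", rec_type="C"):
    """One-atom ligand at the origin, one receptor atom on the x axis."""
    lig_text = "\n".join([
        "ROOT",
        atom_line(1, "X1", "LIG", "A", 1, (0.0, 0.0, 0.0), 0.0, lig_type),
        "ENDROOT", "TORSDOF 0"]) + "\n"
    rec_text = atom_line(1, "Y1", "POC", "A", 1,
                         (distance, 0.0, 0.0), 0.0, rec_type) + "\n"
    lig = parse_pdbqt_ligand(lig_text)
    rec = parse_pdbqt_receptor(rec_text)
    box = DockingBox(center=np.zeros(3), size=np.full(3, 20.0))
    return DockingSystem(lig, rec, box)


def _expected_pair_score(d, r_i, r_j, hydrophobic=False, hbond=False):
    """Independent hand evaluation of the weighted five-term sum."""
    s = d - r_i - r_j
    total = W["gauss1"] * np.exp(-((s / 0.5) ** 2))
    total += W["gauss2"] * np.exp(-(((s - 3.0) / 2.0) ** 2))
    if s < 0:
        total += W["repulsion"] * s * s
    if hydrophobic:
        total += W["hydrophobic"] * min(1.0, max(0.0, (1.5 - s) / 1.0))
    if hbond:
        total += W["hbond"] * min(1.0, max(0.0, (0.0 - s) / 0.7))
    return total


class TestClosedForms:
    def test_surface_distance(self):
        assert surface_distance(3.8, 1.9, 1.9) == 0.0
        assert surface_distance(0.0, 1.9, 1.9) == -3.8
        rng = np.random.default_rng(0)
        for _ in range(20):
            d, ri, rj = rng.uniform(0, 5, 3)
            assert np.isclose(surface_distance(d, ri, rj), d - ri - rj)

    def test_terms_at_zero_surface_distance(self):
        g1, g2, rep, phob, hb = vina_terms(0.0, "C", "C")
        assert g1 == 1.0
        assert rep == 0.0
        assert np.isclose(g2, np.exp(-2.25))

    def test_repulsion_is_squared_clash(self):
        terms = vina_terms(-1.0, "C", "C")
        assert terms[2] == 1.0

    def test_unknown_type_pair_is_an_error(self):
        with pytest.raises(KeyError):
            vina_terms(0.0, "C", "Zz")

    @pytest.mark.parametrize("d", [3.5, 4.2, 5.0])
    def test_carbon_pair_total_matches_hand_sum(self, d):
        system = _pair_system(d)
        bd = score_pose(system.ligand.reference_coords,
                        system.receptor.coords, system)
        assert np.isclose(bd.total, _expected_pair_score(d, 1.9, 1.9,
                                                         hydrophobic=True),
                          atol=1e-12)
        assert bd.intra == 0.0
        assert np.isclose(bd.predicted_free_energy, bd.inter)  # N_rot = 0

    def test_beyond_cutoff_everything_is_zero(self):
        system = _pair_system(8.5)
        bd = score_pose(system.ligand.reference_coords,
                        system.receptor.coords, system)
        assert bd.total == 0.0
        assert bd.predicted_free_energy == 0.0
        assert all(v == 0.0 for v in bd.per_term.values())

    def test_breakdown_total_is_weighted_term_sum(self, system, vina):
        rng = np.random.default_rng(1)
        pose = system.random_pose(rng)
        bd = system.score(pose, vina)
        recon = sum(bd.term_weights[t] * bd.per_term[t] for t in bd.per_term)
        assert np.isclose(bd.total, recon, atol=1e-9)

    def test_free_energy_divides_inter_by_torsion_penalty(self, system, vina):
        bd = system.score(system.identity_pose(), vina)
        n_rot = system.ligand.n_rot_torsdof
        assert np.isclose(bd.predicted_free_energy,
                          bd.inter / (1 + VinaParams().w_rot * n_rot))


class TestInvariances:
    def test_rigid_translation_of_complex_leaves_score_unchanged(self, system,
                                                                 vina):
        rng = np.random.default_rng(2)
        lig = system.ligand_coords(system.random_pose(rng))
        rec = system.receptor_coords()
        base = vina.evaluate(lig, rec).total
        for _ in range(5):
            shift = rng.normal(size=3) * 5
            assert np.isclose(vina.evaluate(lig + shift, rec + shift).total,
                              base, atol=1e-9)

    def test_rigid_rotation_of_complex_leaves_score_unchanged(self, system,
                                                              vina):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(3)
        lig = system.ligand_coords(system.random_pose(rng))
        rec = system.receptor_coords()
        base = vina.evaluate(lig, rec).total
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            assert np.isclose(vina.evaluate(lig @ R.T, rec @ R.T).total, base,
                              atol=1e-9)

    def test_score_is_continuous_in_coordinates(self, system, vina):
        rng = np.random.default_rng(4)
        rec = system.receptor_coords()
        for _ in range(10):
            lig = system.ligand_coords(system.random_pose(rng))
            base = vina.evaluate(lig, rec).total
            for eps in (1e-4, 1e-6):
                pert = lig + rng.normal(size=lig.shape) * eps
                assert abs(vina.evaluate(pert, rec).total - base) < 1e3 * eps


def _fd_pose_gradient(system, sf, x, h=1e-4):
    fd = np.zeros_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h
        fd[i] = (system.score_array(x + e, sf)
                 - system.score_array(x - e, sf)) / (2 * h)
    return fd


class TestGradients:
    def test_out_of_range_ligand_has_zero_intermolecular_gradient(self):
        system = _pair_system(30.0)
        sf = VinaScore(system)
        g = score_gradient(system.identity_pose(), sf, system)
        assert np.allclose(g, 0.0)

    def test_matches_central_finite_differences(self, system, vina):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = system.random_pose(rng).to_array()
            g = system.gradient_array(x, vina)
            fd = _fd_pose_gradient(system, vina, x)
            assert np.linalg.norm(g - fd) <= 1e-4 * max(np.linalg.norm(fd),
                                                        1e-3)

    def test_gradient_step_from_clash_decreases_score(self):
        # two carbons pressed 0.5 A into each other: one plain gradient step
        # at the default learning rate must relieve the clash
        clash_system = _pair_system(3.3)  # surface distance -0.5
        sf = VinaScore(clash_system)
        pose = clash_system.identity_pose()
        bd = clash_system.score(pose, sf)
        assert bd.per_term["repulsion"] > 0
        out, score = local_minimize(pose, sf, clash_system, steps=1, lr=0.1,
                                    method="sgd")
        assert score < bd.total

    def test_non_differentiable_scorer_raises_helpful_error(self, system):
        const = register_external_sf(lambda lig, rec: -1.0, name="const")
        with pytest.raises(NotImplementedError, match="sampler"):
            score_gradient(system.identity_pose(), const, system)


class TestHybrid:
    def test_single_component_identity(self, system, vina):
        hy = make_hybrid_sf([(vina, 1.0)])
        rng = np.random.default_rng(6)
        lig = system.ligand_coords(system.random_pose(rng))
        rec = system.receptor_coords()
        assert np.isclose(hy.evaluate(lig, rec).total,
                          vina.evaluate(lig, rec).total, atol=1e-12)

    def test_equal_weights_half_and_half(self, system, vina):
        const = register_external_sf(lambda lig, rec: 4.0, name="const")
        hy = make_hybrid_sf([(vina, 0.5), (const, 0.5)])
        rng = np.random.default_rng(7)
        lig = system.ligand_coords(system.random_pose(rng))
        rec = system.receptor_coords()
        expect = 0.5 * vina.evaluate(lig, rec).total + 0.5 * 4.0
        assert np.isclose(hy.evaluate(lig, rec).total, expect, atol=1e-12)

    def test_three_components_are_linear(self, system, vina):
        rng = np.random.default_rng(8)
        c1 = register_external_sf(lambda lig, rec: 2.0, name="c1")
        c2 = register_external_sf(lambda lig, rec: -3.0, name="c2")
        w = rng.normal(size=3)
        hy = make_hybrid_sf([(vina, w[0]), (c1, w[1]), (c2, w[2])])
        lig = system.ligand_coords(system.random_pose(rng))
        rec = system.receptor_coords()
        expect = (w[0] * vina.evaluate(lig, rec).total + w[1] * 2.0
                  + w[2] * -3.0)
        assert np.isclose(hy.evaluate(lig, rec).total, expect, atol=1e-12)

    def test_empty_component_list_is_an_error(self):
        with pytest.raises(ValueError, match="component"):
            make_hybrid_sf([])

    def test_gradient_requires_all_components_differentiable(self, system,
                                                             vina):
        const = register_external_sf(lambda lig, rec: 0.0, name="c")
        hy = make_hybrid_sf([(vina, 0.5), (const, 0.5)])
        assert not hy.supports_gradient


class TestExternal:
    def test_constant_scorer_scores_every_pose_the_same(self, system):
        sf = register_external_sf(lambda lig, rec: -1.0, name="const")
        rng = np.random.default_rng(9)
        vals = {system.score(system.random_pose(rng), sf).total
                for _ in range(5)}
        assert vals == {-1.0}

    def test_gradient_callable_enables_minimization(self, system):
        target = system.ligand.reference_coords

        def f(lig, rec):
            return float(np.sum((lig - target) ** 2))

        def g(lig, rec):
            return 2.0 * (lig - target), None

        sf = register_external_sf(f, gradient_func=g, name="quad",
                                  probe_shape=(target.shape[0], 3))
        assert sf.supports_gradient
        pose = system.identity_pose()
        pose.translation = pose.translation + 0.5
        out, score = local_minimize(pose, sf, system, steps=20, lr=0.1,
                                    method="lbfgs")
        assert score < f(system.ligand_coords(pose), None)

    def test_raising_callable_is_rejected_at_registration(self):
        def bad(lig, rec):
            raise RuntimeError("boom")

        with pytest.raises(ValueError, match="probe"):
            register_external_sf(bad, name="bad")


def test_numba_and_numpy_scoring_routes_agree(system, vina):
    """The compiled kernel must reproduce the reference numpy arithmetic."""
    from microdock import scoring as scoring_mod
    if not scoring_mod.HAVE_NUMBA:
        return  # numpy route is the only route; nothing to compare
    rng = np.random.default_rng(10)
    rec = system.receptor_coords()
    for _ in range(10):
        lig = system.ligand_coords(system.random_pose(rng))
        vk, glk, grk = vina.value_and_gradient(lig, rec)
        scoring_mod.HAVE_NUMBA = False
        try:
            vn, gln, grn = vina.value_and_gradient(lig, rec)
        finally:
            scoring_mod.HAVE_NUMBA = True
        assert np.isclose(vk, vn, atol=1e-10)
        assert np.allclose(glk, gln, atol=1e-10)
        assert np.allclose(grk, grn, atol=1e-10)
        assert np.isclose(vk, vina.evaluate(lig, rec).total, atol=1e-10)
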