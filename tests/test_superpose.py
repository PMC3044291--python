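import copy

import numpy as np
import pytest
from dataclasses import replace

from apfbss.apf_core import apf_energy, build_grids
from apfbss.site_io import Atom, Site, property_vector
from apfbss.superpose import (
    MCConfig,
    Pose,
    apply_pose,
    initial_pose,
    ligand_rmsd,
    local_minimize,
    metropolis_accept,
    monte_carlo_superpose,
    random_step,
    site_rmsd,
)
from apfbss.synthetic import perturb_site


class TestPose:
    def test_rotation_matrix_is_proper(self, rng):
        for _ in range(50):
            pose = Pose(angles=rng.uniform(-np.pi, np.pi, 3))
            rot = pose.rotation_matrix()
            np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_euler_convention(self, rng):
        from scipy.spatial.transform import Rotation

        angles = rng.uniform(-np.pi, np.pi, 3)
        mine = Pose(angles=angles).rotation_matrix()
        theirs = Rotation.from_euler("xyz", angles).as_matrix()
        np.testing.assert_allclose(mine, theirs, atol=1e-12)

    def test_identity_leaves_coordinates(self, rng):
        coords = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(Pose().apply(coords), coords)

    def test_pure_translation(self, rng):
        coords = rng.normal(size=(5, 3))
        pose = Pose(translation=np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            pose.apply(coords), coords + [1.0, 2.0, 3.0], atol=1e-12
        )

    def test_inverse_round_trip(self, rng):
        coords = rng.normal(size=(20, 3)) * 5
        pose = Pose(
            translation=rng.normal(0, 3, 3),
            angles=rng.uniform(-np.pi, np.pi, 3),
            center=rng.normal(0, 2, 3),
        )
        back = pose.inverse().apply(pose.apply(coords))
        assert np.abs(back - coords).max() < 1e-9

    def test_matrix_agrees_with_apply(self, rng):
        coords = rng.normal(size=(7, 3))
        pose = Pose(
            translation=rng.normal(0, 3, 3),
            angles=rng.uniform(-np.pi, np.pi, 3),
            center=rng.normal(0, 2, 3),
        )
        hom = np.hstack([coords, np.ones((7, 1))])
        via_matrix = (hom @ pose.matrix().T)[:, :3]
        np.testing.assert_allclose(via_matrix, pose.apply(coords), atol=1e-12)


class TestInitialPose:
    def test_identical_sites_give_identity(self, site30):
        pose = initial_pose(site30, site30, "centroid")
        np.testing.assert_allclose(pose.translation, np.zeros(3), atol=1e-12)
        np.testing.assert_array_equal(pose.angles, np.zeros(3))

    def test_random_mode_is_seeded(self, site30, small_site):
        a = initial_pose(site30, small_site, "random", rng=42)
        b = initial_pose(site30, small_site, "random", rng=42)
        np.testing.assert_array_equal(a.params, b.params)

    def test_random_rotations_are_proper(self, site30, small_site):
        rng = np.random.default_rng(3)
        dets = [
            np.linalg.det(
                initial_pose(site30, small_site, "random", rng=rng)
                .rotation_matrix()
            )
            for _ in range(1000)
        ]
        np.testing.assert_allclose(dets, 1.0, atol=1e-9)


class TestRandomStep:
    def test_zero_steps_leave_pose(self):
        config = MCConfig(step_translation=0.0, step_rotation=0.0)
        pose = Pose(translation=np.ones(3), angles=np.full(3, 0.2))
        stepped = random_step(pose, config, np.random.default_rng(0))
        np.testing.assert_array_equal(stepped.params, pose.params)

    def test_same_rng_state_same_step(self):
        config = MCConfig()
        pose = Pose()
        a = random_step(pose, config, np.random.default_rng(9))
        b = random_step(pose, config, np.random.default_rng(9))
        np.testing.assert_array_equal(a.params, b.params)

    def test_empirical_sigma(self):
        config = MCConfig()
        pose = Pose()
        rng = np.random.default_rng(10)
        increments = np.array(
            [random_step(pose, config, rng).translation for _ in range(10_000)]
        )
        assert increments.std() == pytest.approx(config.step_translation, rel=0.05)


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-5.0, 10.0, rng) for _ in range(100))

    def test_greedy_limit_rejects_uphill(self):
        rng = np.random.default_rng(0)
        assert not metropolis_accept(1.0, 1e-12, rng)

    def test_acceptance_probability(self):
        rng = np.random.default_rng(2)
        kt = 10.0
        hits = sum(metropolis_accept(kt, kt, rng) for _ in range(20_000))
        assert hits / 20_000 == pytest.approx(np.exp(-1), abs=0.02)


class TestLocalMinimize:
    def test_zero_gradient_start_returns_unchanged(self, site30, model):
        grid = build_grids(site30, spacing=0.5, width=1.0)
        probe = replace(site30, properties=np.zeros_like(site30.properties))
        pose = Pose(center=probe.centroid)
        out, energy = local_minimize(pose, grid, probe, model)
        np.testing.assert_array_equal(out.params, pose.params)
        assert energy == 0.0

    def test_descent_contract(self, small_site, model):
        grid = build_grids(small_site, spacing=0.5, width=1.0)
        rng = np.random.default_rng(8)
        for _ in range(50):
            pose = Pose(
                translation=rng.normal(0, 2, 3),
                angles=rng.uniform(-np.pi, np.pi, 3),
                center=small_site.centroid,
            )
            start = apf_energy(grid, small_site, pose, model)
            _, energy = local_minimize(pose, grid, small_site, model, max_steps=30)
            assert energy <= start + 1e-12

    def test_single_atom_closed_form_landscape(self, model):
        atom = Atom(element="C", name="C1", coords=np.zeros(3),
                    residue_name="SYN", residue_id=1, chain="A")
        template = Site(atoms=[atom], properties=property_vector(size=1.0)[None])
        probe = copy.deepcopy(template)
        grid = build_grids(template, spacing=0.5, width=1.0)
        pose = Pose(translation=np.array([1.0, 0.0, 0.0]))
        out, energy = local_minimize(pose, grid, probe, model)
        assert np.linalg.norm(out.translation) < 0.01
        assert energy == pytest.approx(-1.0, abs=1e-3)


class TestMonteCarlo:
    def test_recovers_known_transform(self, site30):
        rng = np.random.default_rng(0)
        moved, _ = perturb_site(
            site30,
            rotation_angle=float(rng.uniform(0, np.pi)),
            translation=float(rng.uniform(0, 5)),
            seed=100,
        )
        result = monte_carlo_superpose(site30, moved, MCConfig(seed=0))
        assert site_rmsd(site30, moved, result.best_pose) < 0.5

    def test_identity_probe_matches_self_energy(self, site30, model):
        from apfbss.similarity_cluster import self_energy

        result = monte_carlo_superpose(
            site30, site30, MCConfig(seed=2, max_evaluations=3000), model
        )
        assert abs(result.e_apf - self_energy(site30, model)) <= 1e-6 * abs(
            self_energy(site30, model)
        )

    def test_budget_respected_and_trace_monotone(self, site30, fast_config):
        moved, _ = perturb_site(site30, 1.0, 2.0, seed=5)
        result = monte_carlo_superpose(site30, moved, fast_config)
        assert result.evaluations_used <= fast_config.max_evaluations
        trace = np.array(result.best_energy_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_bit_identical_determinism(self, site30, fast_config):
        moved, _ = perturb_site(site30, 1.5, 3.0, seed=6)
        a = monte_carlo_superpose(site30, moved, fast_config)
        b = monte_carlo_superpose(site30, moved, fast_config)
        np.testing.assert_array_equal(a.best_pose.params, b.best_pose.params)
        assert a.e_apf == b.e_apf
        assert a.evaluations_used == b.evaluations_used
        assert a.accepted_moves == b.accepted_moves

    def test_swapping_roles_gives_similar_optima(self, site30):
        moved, _ = perturb_site(site30, 1.0, 2.0, jitter=0.4, seed=9)
        moved.source_id = "jittered"
        forward = monte_carlo_superpose(site30, moved, MCConfig(seed=3))
        backward = monte_carlo_superpose(moved, site30, MCConfig(seed=4))
        low = min(forward.e_apf, backward.e_apf)
        assert abs(forward.e_apf - backward.e_apf) / abs(low) <= 0.10

    def test_empty_budget_is_error(self, site30):
        with pytest.raises(ValueError):
            MCConfig(max_evaluations=0)


class TestApplyPoseAndRmsd:
    def _ligand(self, offset=0.0, resname="LIG", scramble=False):
        coords = np.array(
            [[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5], [1.5, 1.5, 0]]
        ) + offset
        elements = ["C", "C", "N", "O", "C"]
        order = [3, 1, 4, 0, 2] if scramble else range(5)
        return [
            Atom(element=elements[i], name=f"X{i + 1}", coords=coords[i],
                 residue_name=resname, residue_id=1, chain="L", is_het=True)
            for i in order
        ]

    def test_apply_identity_and_translation(self):
        ligand = self._ligand()
        same = apply_pose(ligand, Pose())
        np.testing.assert_array_equal(same[0].coords, ligand[0].coords)
        shifted = apply_pose(ligand, Pose(translation=np.array([1.0, 2.0, 3.0])))
        np.testing.assert_allclose(
            shifted[2].coords, ligand[2].coords + [1, 2, 3], atol=1e-12
        )

    def test_identical_ligands_zero_rmsd(self):
        assert ligand_rmsd(self._ligand(), self._ligand(), Pose()) == 0.0

    def test_translation_gives_exact_rmsd(self):
        pose = Pose(translation=np.array([1.0, 0.0, 0.0]))
        assert ligand_rmsd(self._ligand(), self._ligand(), pose) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_scrambled_order_matched_by_name(self):
        assert ligand_rmsd(
            self._ligand(), self._ligand(scramble=True), Pose()
        ) == pytest.approx(0.0, abs=1e-12)

    def test_different_codes_matched_by_assignment(self):
        a = self._ligand()
        b = self._ligand(resname="UNL", scramble=True)
        for i, atom in enumerate(b):
            b[i] = replace(atom, name=f"Y{i + 1}")
        assert ligand_rmsd(a, b, Pose()) == pytest.approx(0.0, abs=1e-12)

    def test_incompatible_ligands_raise(self):
        a = self._ligand()
        b = self._ligand()[:3]
        with pytest.raises(ValueError):
            ligand_rmsd(a, b, Pose())
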