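"""Derivative-free optimizers and the two-stage registration workflows."""

import numpy as np
import pytest

from autorsa.geometry import RigidPose
from autorsa.registration import (RegistrationConfig, crs_maximize,
                                  nelder_mead_maximize, optimize_global,
                                  optimize_local, pose_from_params,
                                  register_bone, register_implant)
from conftest import fast_registration_config


def _pose_params(pose: RigidPose, reference: RigidPose) -> np.ndarray:
    """Translation offset of a pose relative to a reference."""
    return pose.translation - reference.translation


class TestCRS:
    def test_quadratic_surrogate_recovery(self):
        """Negative squared distance to a known pose offset: the global
        search localizes the optimum well within the bounds."""
        target = np.array([1.2, -0.7, 2.1, 0.5, -1.4, 0.9])
        f = lambda p: -np.sum((p - target) ** 2)  # noqa: E731
        rng = np.random.default_rng(0)
        x, v, trace = crs_maximize(f, -5 * np.ones(6), 5 * np.ones(6),
                                   2000, rng)
        assert np.abs(x - target).max() < 0.05
        assert trace == sorted(trace)      # best-so-far is non-decreasing

    def test_seeded_determinism(self):
        f = lambda p: -np.sum(p ** 2)  # noqa: E731
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            runs.append(crs_maximize(f, -np.ones(4), np.ones(4), 300, rng))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][2] == runs[1][2]

    def test_optimum_on_bound_stays_feasible(self):
        f = lambda p: float(np.sum(p))  # noqa: E731
        rng = np.random.default_rng(1)
        x, _, _ = crs_maximize(f, -np.ones(3), np.ones(3), 500, rng)
        assert np.all(x <= 1.0 + 1e-12) and np.all(x >= -1.0 - 1e-12)
        assert np.all(x > 0.9)

    def test_budget_below_population_rejected(self):
        from autorsa.registration import RegistrationError

        with pytest.raises(RegistrationError):
            crs_maximize(lambda p: 0.0, -np.ones(3), np.ones(3), 5,
                         np.random.default_rng(0))


class TestNelderMead:
    def test_already_optimal_start_returned(self):
        f = lambda p: -np.sum(p ** 2)  # noqa: E731
        x, v, _, ok = nelder_mead_maximize(f, np.zeros(4), -5 * np.ones(4),
                                           5 * np.ones(4), 0.5, 1e-6, 1e-12,
                                           2000)
        assert np.abs(x).max() < 1e-4

    def test_offset_start_recovers_optimum(self):
        target = np.array([0.3, -0.2, 0.5, 0.1, 0.0, -0.4])
        f = lambda p: -np.sum((p - target) ** 2)  # noqa: E731
        x0 = target + np.array([1.0, 0, 0, 0, 0, 0])
        x, _, _, ok = nelder_mead_maximize(f, x0, -5 * np.ones(6),
                                           5 * np.ones(6), 0.5, 1e-7, 1e-14,
                                           4000)
        assert np.abs(x - target).max() < 1e-4
        assert ok

    def test_flat_objective_flagged(self):
        f = lambda p: 1.0  # noqa: E731
        x0 = np.array([0.5, -0.5, 0.1])
        x, v, _, ok = nelder_mead_maximize(f, x0, -np.ones(3), np.ones(3),
                                           0.2, 1e-6, 1e-12, 200)
        assert not ok
        assert np.array_equal(x, x0)


class TestPoseOptimizers:
    def test_global_pose_wrapper_surrogate(self):
        initial = RigidPose.identity()
        target = pose_from_params(initial, [1.0, -2.0, 0.5, 1.0, 0.0, -1.0])

        def objective(pose):
            return -np.sum((pose.translation - target.translation) ** 2) \
                - np.sum((pose.rotation - target.rotation) ** 2)

        cfg = RegistrationConfig(global_budget=3000, seed=3)
        found = optimize_global(objective, initial, cfg)
        assert np.abs(found.translation - target.translation).max() < 0.1

    def test_local_pose_wrapper_surrogate(self):
        initial = RigidPose.identity()
        target = pose_from_params(initial, [0.8, 0.3, -0.6, 0, 0, 0])

        def objective(pose):
            return -np.sum((pose.translation - target.translation) ** 2)

        cfg = RegistrationConfig(local_max_evals=2000, local_xatol=1e-7)
        found, ok = optimize_local(objective, initial, cfg)
        assert ok
        assert np.abs(found.translation - target.translation).max() < 1e-3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RegistrationConfig(bounds_mm=-1.0)
        with pytest.raises(ValueError):
            RegistrationConfig(global_budget=10, population=35)


class TestRegisterImplant:
    def test_noise_free_start_at_truth_is_stable(self, scene, clean_exam):
        """Silhouette refinement from the exact pose must not diverge: the
        recovered translation is numerically exact on the noise-free exam."""
        cfg = fast_registration_config("surface", global_budget=0)
        res = register_implant(scene.implant, clean_exam.pair,
                               clean_exam.implant_pose, cfg)
        err = np.abs(res.pose.translation
                     - clean_exam.implant_pose.translation).max()
        assert err < 0.01
        assert res.objective >= res.initial_objective

    def test_perturbed_start_recovers_pose(self, scene, clean_exam):
        """1 mm / 1 degree perturbed start, silhouette mode: sub-0.15 mm
        per-axis recovery on the noise-free exam."""
        pert = np.array([0.6, -0.6, 0.5, 0.6, -0.5, 0.6])
        init = pose_from_params(clean_exam.implant_pose, pert)
        cfg = fast_registration_config("surface", seed=1)
        res = register_implant(scene.implant, clean_exam.pair, init, cfg)
        err = np.abs(res.pose.translation
                     - clean_exam.implant_pose.translation)
        assert np.all(err < 0.15)

    def test_volume_mode_comparable_to_surface(self, scene, clean_exam):
        """DRR registration of the voxelized implant lands within a voxel
        of the truth from the same perturbed start."""
        pert = np.array([0.6, -0.6, 0.5, 0.6, -0.5, 0.6])
        init = pose_from_params(clean_exam.implant_pose, pert)
        cfg = fast_registration_config("volume", seed=1)
        res = register_implant(scene.implant_volume, clean_exam.pair, init,
                               cfg)
        err = np.abs(res.pose.translation
                     - clean_exam.implant_pose.translation)
        assert np.all(err < 0.3)

    def test_renderer_model_mismatch_rejected(self, scene, clean_exam):
        from autorsa.registration import RegistrationError

        with pytest.raises(RegistrationError):
            register_implant(scene.implant, clean_exam.pair,
                             clean_exam.implant_pose,
                             fast_registration_config("volume"))

    def test_seeded_registration_bit_reproducible(self, scene, clean_exam):
        cfg = fast_registration_config("surface", seed=5, global_budget=70,
                                       local_max_evals=120)
        runs = [register_implant(scene.implant, clean_exam.pair,
                                 clean_exam.implant_pose, cfg)
                for _ in range(2)]
        assert np.array_equal(runs[0].pose.translation,
                              runs[1].pose.translation)
        assert np.array_equal(runs[0].pose.rotation, runs[1].pose.rotation)
        assert runs[0].objective == runs[1].objective

    def test_trace_best_so_far_monotone(self, scene, clean_exam):
        cfg = fast_registration_config("surface", seed=2, global_budget=70,
                                       local_max_evals=120)
        res = register_implant(scene.implant, clean_exam.pair,
                               clean_exam.implant_pose, cfg)
        for trace in res.traces.values():
            assert list(trace) == sorted(trace)


class TestRegisterBone:
    def test_masked_bone_start_at_truth(self, scene, clean_exam):
        """Bone registration with the fixed implant mask must hold the true
        pose on a noise-free exam."""
        cfgv = fast_registration_config("volume", global_budget=0)
        rv = register_implant(scene.implant_volume, clean_exam.pair,
                              clean_exam.implant_pose, cfgv)
        res = register_bone(scene.bone, clean_exam.pair, [rv],
                            clean_exam.bone_pose,
                            fast_registration_config("volume",
                                                     global_budget=0))
        err = np.abs(res.pose.translation
                     - clean_exam.bone_pose.translation).max()
        assert err < 0.02

    def test_perturbed_start_bone_recovery(self, scene, clean_exam):
        pert = np.array([0.6, -0.6, 0.5, 0.6, -0.5, 0.6])
        cfgv = fast_registration_config("volume", global_budget=0)
        rv = register_implant(scene.implant_volume, clean_exam.pair,
                              clean_exam.implant_pose, cfgv)
        init = pose_from_params(clean_exam.bone_pose, pert)
        res = register_bone(scene.bone, clean_exam.pair, [rv], init,
                            fast_registration_config("volume", seed=3))
        err = np.abs(res.pose.translation
                     - clean_exam.bone_pose.translation)
        assert np.all(err < 0.15)

    def test_fixed_mask_improves_bone_accuracy(self, scene, calib):
        """When the implant has moved relative to the bone (migration
        between model acquisition and exam), excluding its dilated
        silhouette gives a better bone pose than registering through it."""
        import copy

        from autorsa.phantom import NoiseParams, simulate_exam

        moved = copy.deepcopy(scene)
        shift = RigidPose(np.eye(3), np.array([3.0, -2.0, 0.0]))
        moved.implant_pose = shift @ moved.implant_pose
        rec = simulate_exam(moved, calib, None, NoiseParams(), seed=21)
        cfg0 = fast_registration_config("volume", global_budget=0)
        rv = register_implant(moved.implant_volume, rec.pair,
                              rec.implant_pose, cfg0)
        init = pose_from_params(rec.bone_pose, [0.8, -0.5, 0.6, 0.5, 0.5, -0.5])
        with_mask = register_bone(moved.bone, rec.pair, [rv], init,
                                  fast_registration_config("volume", seed=4))
        without_mask = register_bone(moved.bone, rec.pair, [], init,
                                     fast_registration_config("volume",
                                                              seed=4))
        e_with = np.abs(with_mask.pose.translation
                        - rec.bone_pose.translation).max()
        e_without = np.abs(without_mask.pose.translation
                           - rec.bone_pose.translation).max()
        assert e_with < 0.1
        assert e_with <= e_without + 1e-6
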