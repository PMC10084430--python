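"""Bead detection, triangulation and rigid marker-configuration matching."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from autorsa.markers import (MarkerError, MarkerSet, centroid_position,
                             detect_beads, fit_rigid_body, match_views,
                             reconstruct_markers, triangulate)


def _disc_image(centers, radius=4.0, snr=20.0, shape=(128, 128), seed=0):
    """Bright anti-aliased discs on a noisy background."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.zeros(shape)
    for (u, v) in centers:
        d = np.sqrt((xx - u) ** 2 + (yy - v) ** 2)
        img += np.clip(radius + 0.5 - d, 0.0, 1.0) * 100.0
    img += rng.normal(0.0, 100.0 / snr, shape)
    return img


class TestDetectBeads:
    def test_ten_discs_recovered_subpixel(self):
        rng = np.random.default_rng(1)
        centers = np.column_stack([rng.uniform(15, 113, 10),
                                   rng.uniform(15, 113, 10)])
        # enforce separation so discs are distinct
        keep = [centers[0]]
        for c in centers[1:]:
            if min(np.linalg.norm(c - k) for k in keep) > 18:
                keep.append(c)
        centers = np.array(keep)
        img = _disc_image(centers, seed=2)
        det = detect_beads(img, (3, 6))
        assert len(det) == len(centers)
        for c in centers:
            err = np.linalg.norm(det - c, axis=1).min()
            assert err < 0.3

    def test_blank_image_gives_empty_list(self):
        assert len(detect_beads(np.zeros((64, 64)), (2, 6))) == 0
        rng = np.random.default_rng(0)
        assert len(detect_beads(rng.normal(0, 1e-3, (64, 64)) + 100,
                                (2, 6))) <= 1

    def test_overlapping_pair_not_over_detected(self):
        r = 4.0
        centers = np.array([[60.0, 64.0], [60.0 + 1.5 * r, 64.0]])
        img = _disc_image(centers, radius=r, seed=3)
        det = detect_beads(img, (3, 6))
        assert len(det) <= 2
        for d in det:
            assert 50 < d[0] < 74 and 56 < d[1] < 72


class TestTriangulate:
    def test_project_triangulate_round_trip_exact(self, calib):
        rng = np.random.default_rng(4)
        for _ in range(25):
            p = np.array([rng.uniform(-40, 40), rng.uniform(-40, 40),
                          rng.uniform(120, 200)])
            obs = {v: calib.camera(v).project_to_pixels(p[None])[0]
                   for v in ("left", "right")}
            q, cld = triangulate(obs["left"], obs["right"], calib)
            assert np.linalg.norm(q - p) < 1e-9
            assert cld < 1e-9

    def test_constructed_skew_rays_distance(self, calib):
        """Shifting one observation perpendicular to the epipolar direction
        creates a known crossing-line distance."""
        p = np.array([5.0, -10.0, 160.0])
        obs_l = calib.camera_left.project_to_pixels(p[None])[0]
        # the views share the x-z plane: a y-offset is perpendicular to it
        p_shift = p + np.array([0.0, 0.2, 0.0])
        obs_r = calib.camera_right.project_to_pixels(p_shift[None])[0]
        q, cld = triangulate(obs_l, obs_r, calib)
        # the perpendicular between the rays is <= the 0.2 mm world offset
        assert 0.05 < cld < 0.2 + 1e-6
        assert np.linalg.norm(q - p) < 0.25

    def test_noise_scaling_of_3d_error(self, calib):
        """Median reconstruction error grows linearly with pixel noise."""
        rng = np.random.default_rng(5)
        meds = []
        for sigma in (0.1, 0.4):
            errs = []
            for _ in range(300):
                p = np.array([rng.uniform(-30, 30), rng.uniform(-30, 30),
                              rng.uniform(140, 180)])
                obs = {}
                for v in ("left", "right"):
                    uv = calib.camera(v).project_to_pixels(p[None])[0]
                    obs[v] = uv + rng.normal(0, sigma, 2)
                q, _ = triangulate(obs["left"], obs["right"], calib)
                errs.append(np.linalg.norm(q - p))
            meds.append(np.median(errs))
        ratio = meds[1] / meds[0]
        assert 2.5 < ratio < 6.0     # ~4x noise -> ~4x error

    def test_same_view_rays_rejected(self, calib):
        obs = np.array([10.0, 10.0])
        from autorsa.geometry import StereoCalibration

        degenerate = StereoCalibration.__new__(StereoCalibration)
        degenerate.camera_left = calib.camera_left
        degenerate.camera_right = calib.camera_left
        with pytest.raises(MarkerError):
            triangulate(obs, obs, degenerate)


class TestCentroid:
    def test_single_marker(self):
        m = MarkerSet(np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(centroid_position(m), [1, 2, 3])

    def test_symmetric_pair_midpoint(self):
        m = MarkerSet(np.array([[1.0, 0, 0], [-1.0, 0, 0]]))
        assert np.allclose(centroid_position(m), 0.0)

    def test_mean_against_manual_sum(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(-10, 10, (8, 3))
        manual = np.array([sum(pts[:, k]) / 8.0 for k in range(3)])
        assert np.allclose(centroid_position(MarkerSet(pts)), manual)

    def test_empty_set_rejected(self):
        with pytest.raises(MarkerError):
            centroid_position(MarkerSet(np.zeros((0, 3))))


def _procrustes_oracle(A, B):
    """Independent rigid fit: direct minimization over Euler angles and
    translation (no SVD), used to cross-check the closed-form solver."""
    def cost(p):
        R = Rotation.from_euler("xyz", p[:3]).as_matrix()
        return np.sum((A @ R.T + p[3:] - B) ** 2)

    best = None
    for x0 in ([0, 0, 0, 0, 0, 0], [1, -1, 1, 0, 0, 0], [-2, 2, 0, 1, 1, 1]):
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"maxfev": 6000, "xatol": 1e-12,
                                "fatol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
    R = Rotation.from_euler("xyz", best.x[:3]).as_matrix()
    resid = np.linalg.norm(A @ R.T + best.x[3:] - B, axis=1)
    return resid.mean()


class TestRigidBodyFit:
    def test_exact_recovery_of_random_transform(self):
        rng = np.random.default_rng(7)
        A = rng.uniform(-20, 20, (9, 3))
        R = Rotation.from_euler("xyz", [14, -33, 51], degrees=True).as_matrix()
        t = np.array([4.0, -7.0, 2.5])
        fit = fit_rigid_body(A, A @ R.T + t)
        assert np.abs(fit.pose.rotation - R).max() < 1e-9
        assert np.abs(fit.pose.translation - t).max() < 1e-9
        assert fit.mean_rigid_body_error < 1e-9
        assert fit.passes_gate

    def test_perturbed_marker_matches_independent_oracle(self):
        rng = np.random.default_rng(8)
        A = rng.uniform(-20, 20, (9, 3))
        B = A.copy()
        B[3] += np.array([0.9, 0.0, 0.0])
        fit = fit_rigid_body(A, B)
        oracle = _procrustes_oracle(A, B)
        assert fit.mean_rigid_body_error == pytest.approx(oracle, abs=1e-5)

    def test_gate_fires_iff_oracle_error_exceeds_threshold(self):
        rng = np.random.default_rng(9)
        A = rng.uniform(-25, 25, (10, 3))
        for scale in (0.1, 3.0):
            B = A + rng.normal(0, scale, A.shape)
            fit = fit_rigid_body(A, B)
            oracle = _procrustes_oracle(A, B)
            assert fit.passes_gate == (oracle <= fit.gate_threshold)

    def test_reflection_not_accepted_as_rotation(self):
        rng = np.random.default_rng(10)
        A = rng.uniform(-20, 20, (8, 3))
        B = A * np.array([1.0, 1.0, -1.0])      # mirrored configuration
        fit = fit_rigid_body(A, B)
        assert np.linalg.det(fit.pose.rotation) == pytest.approx(1.0)
        assert fit.mean_rigid_body_error > fit.gate_threshold
        assert not fit.passes_gate

    def test_consistent_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        A = rng.uniform(-20, 20, (7, 3))
        R = Rotation.from_euler("xyz", [5, 10, -15], degrees=True).as_matrix()
        B = A @ R.T + [1, 2, 3] + rng.normal(0, 0.1, A.shape)
        perm = rng.permutation(7)
        f1 = fit_rigid_body(A, B)
        f2 = fit_rigid_body(A[perm], B[perm])
        assert f1.mean_rigid_body_error == pytest.approx(
            f2.mean_rigid_body_error)

    def test_collinear_configuration_rejected(self):
        A = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(MarkerError):
            fit_rigid_body(A, A + 1.0)


class TestMatchViews:
    def test_phantom_beads_matched_by_epipolar_distance(self, scene, calib,
                                                        clean_exam):
        obs_l = clean_exam.bead_observations["left"]
        obs_r = clean_exam.bead_observations["right"]
        rng = np.random.default_rng(12)
        perm = rng.permutation(len(obs_r))
        pairs, ambiguous = match_views(obs_l, obs_r[perm], calib)
        assert len(ambiguous) == 0
        pairs = pairs[np.argsort(pairs[:, 0])]
        assert np.array_equal(perm[pairs[:, 1]], np.arange(len(obs_l)))

    def test_reconstruct_phantom_beads(self, calib, clean_exam):
        ms = reconstruct_markers(clean_exam.bead_observations["left"],
                                 clean_exam.bead_observations["right"], calib)
        assert np.abs(ms.positions - clean_exam.bead_world).max() < 1e-9
        assert ms.crossing_distances.max() < 1e-9
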