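"""Stereo pin-hole geometry and calibration-cage fitting for RSA setups.

The world frame of every pose in this package is the calibration-cage frame:
the fiducial bead plane is z = 0, the X-ray sources sit at positive z, and all
coordinates are millimetres.  Each of the two views is a pin-hole camera made
of a 3D focal point (the X-ray source) and a planar projective transform that
maps detector pixel indices to fiducial-plane mm coordinates.

Pixel convention: 0-based indices, pixel centers at integer coordinates,
``u`` = column, ``v`` = row.  2D pixel points are ``(u, v)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from skimage.transform import ProjectiveTransform


class GeometryError(ValueError):
    """Degenerate or ill-conditioned geometric input."""


# ---------------------------------------------------------------------------
# Rigid poses
# ---------------------------------------------------------------------------

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidPose:
    """6-DOF rigid transform mapping model-local coordinates into the cage frame.

    ``x_world = rotation @ x_local + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-6:
            raise GeometryError(f"rotation is not orthonormal (deviation {err:.2e})")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation has determinant -1 (improper transform)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidPose":
        return RigidPose(np.eye(3), np.zeros(3))

    @staticmethod
    def from_euler(angles_deg: Sequence[float], translation: Sequence[float],
                   convention: str = "xyz") -> "RigidPose":
        """Pose from Euler angles in degrees (default intrinsic-equivalent 'xyz')."""
        R = Rotation.from_euler(convention, np.asarray(angles_deg, float),
                                degrees=True).as_matrix()
        return RigidPose(R, np.asarray(translation, float))

    def euler(self, convention: str = "xyz") -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_euler(convention, degrees=True)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidPose") -> "RigidPose":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidPose(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidPose":
        return RigidPose(self.rotation.T, -self.rotation.T @ self.translation)

    def __matmul__(self, other: "RigidPose") -> "RigidPose":
        return self.compose(other)

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "euler_xyz_deg": self.euler().tolist(),
            "convention": "x_world = R @ x_local + t; euler 'xyz' degrees",
        }

    @staticmethod
    def from_dict(d: dict) -> "RigidPose":
        return RigidPose(np.asarray(d["rotation"], float),
                         np.asarray(d["translation"], float))


def compose_pose(a: RigidPose, b: RigidPose) -> RigidPose:
    return a.compose(b)


def invert_pose(a: RigidPose) -> RigidPose:
    return a.inverse()


# ---------------------------------------------------------------------------
# Homographies and the pin-hole camera
# ---------------------------------------------------------------------------

def apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Apply a 3x3 planar projective transform to an (N, 2) point array."""
    pts = np.atleast_2d(np.asarray(pts, float))
    hom = np.column_stack([pts, np.ones(len(pts))]) @ H.T
    w = hom[:, 2]
    if np.any(np.abs(w) < 1e-14):
        raise GeometryError("point maps to infinity under homography")
    return hom[:, :2] / w[:, None]


@dataclass
class PinholeCamera:
    """One X-ray view: focal point (source) plus pixel-to-fiducial-plane transform.

    Parameters
    ----------
    focal_point
        3D source position in the cage frame, mm; strictly above the z=0 plane.
    pixel_to_plane
        3x3 homography mapping pixel ``(u, v, 1)`` to plane ``(x, y, 1)`` mm.
    pixel_pitch
        Detector pixel width, mm.
    image_shape
        ``(rows, cols)`` of this view's image.
    """

    focal_point: np.ndarray
    pixel_to_plane: np.ndarray
    pixel_pitch: float
    image_shape: tuple

    def __post_init__(self) -> None:
        self.focal_point = np.asarray(self.focal_point, float).reshape(3)
        self.pixel_to_plane = np.asarray(self.pixel_to_plane, float).reshape(3, 3)
        if self.focal_point[2] <= 0:
            raise GeometryError("focal point must lie on the source side (z > 0)")
        if abs(np.linalg.det(self.pixel_to_plane)) < 1e-14:
            raise GeometryError("pixel_to_plane transform is singular")
        self.image_shape = tuple(int(s) for s in self.image_shape)

    @property
    def plane_to_pixel(self) -> np.ndarray:
        return np.linalg.inv(self.pixel_to_plane)

    def pixel_to_plane_pts(self, uv: np.ndarray) -> np.ndarray:
        return apply_homography(self.pixel_to_plane, uv)

    def plane_to_pixel_pts(self, xy: np.ndarray) -> np.ndarray:
        return apply_homography(self.plane_to_pixel, xy)

    def project_to_pixels(self, points: np.ndarray) -> np.ndarray:
        return self.plane_to_pixel_pts(project_point(points, self))

    def ray_through_pixel(self, uv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Origin (focal point) and unit directions of rays through pixel centers."""
        xy = self.pixel_to_plane_pts(uv)
        tgt = np.column_stack([xy, np.zeros(len(xy))])
        d = tgt - self.focal_point
        d /= np.linalg.norm(d, axis=1)[:, None]
        return self.focal_point, d

    def scaled(self, factor: float) -> "PinholeCamera":
        """Camera for an image downsampled by block averaging.

        ``factor`` = 0.5 means half resolution: the new pixel ``u'`` covers the
        2x2 block of full-resolution pixels, whose center sits at ``2 u' + 0.5``.
        """
        k = 1.0 / factor
        S = np.array([[k, 0.0, (k - 1.0) / 2.0],
                      [0.0, k, (k - 1.0) / 2.0],
                      [0.0, 0.0, 1.0]])
        shape = tuple(int(np.floor(s * factor)) for s in self.image_shape)
        return PinholeCamera(self.focal_point, self.pixel_to_plane @ S,
                             self.pixel_pitch / factor, shape)

    def cropped(self, r0: int, c0: int, rows: int, cols: int) -> "PinholeCamera":
        """Camera for the sub-image ``[r0:r0+rows, c0:c0+cols]``."""
        T = np.array([[1.0, 0.0, float(c0)],
                      [0.0, 1.0, float(r0)],
                      [0.0, 0.0, 1.0]])
        return PinholeCamera(self.focal_point, self.pixel_to_plane @ T,
                             self.pixel_pitch, (rows, cols))

    def to_dict(self) -> dict:
        return {
            "focal_point": self.focal_point.tolist(),
            "pixel_to_plane": self.pixel_to_plane.tolist(),
            "pixel_pitch": self.pixel_pitch,
            "image_shape": list(self.image_shape),
        }

    @staticmethod
    def from_dict(d: dict) -> "PinholeCamera":
        return PinholeCamera(np.asarray(d["focal_point"]),
                             np.asarray(d["pixel_to_plane"]),
                             float(d["pixel_pitch"]), tuple(d["image_shape"]))


@dataclass
class StereoCalibration:
    """Two co-calibrated views sharing the cage frame."""

    camera_left: PinholeCamera
    camera_right: PinholeCamera
    inter_tube_angle_deg: float = 40.0
    source_to_image_mm: float = 1600.0
    residuals: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.allclose(self.camera_left.focal_point, self.camera_right.focal_point):
            raise GeometryError("the two focal points coincide")

    def camera(self, view: str) -> PinholeCamera:
        if view == "left":
            return self.camera_left
        if view == "right":
            return self.camera_right
        raise KeyError(f"unknown view {view!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "camera_left": self.camera_left.to_dict(),
                "camera_right": self.camera_right.to_dict(),
                "inter_tube_angle_deg": self.inter_tube_angle_deg,
                "source_to_image_mm": self.source_to_image_mm,
                "residuals": self.residuals,
            }, fh, indent=2)

    @staticmethod
    def from_json(path) -> "StereoCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return StereoCalibration(PinholeCamera.from_dict(d["camera_left"]),
                                 PinholeCamera.from_dict(d["camera_right"]),
                                 d.get("inter_tube_angle_deg", 40.0),
                                 d.get("source_to_image_mm", 1600.0),
                                 d.get("residuals", {}))


def project_point(p: np.ndarray, cam: PinholeCamera) -> np.ndarray:
    """Perspective-project cage-frame point(s) onto the fiducial plane (z = 0).

    Returns the intersection of the ray ``focal_point -> p`` with the plane,
    as (N, 2) mm coordinates (or (2,) for a single point).
    """
    pts = np.atleast_2d(np.asarray(p, float))
    f = cam.focal_point
    dz = f[2] - pts[:, 2]
    if np.any(np.abs(dz) < 1e-12):
        raise GeometryError("ray parallel to the fiducial plane")
    t = f[2] / dz
    if np.any(t <= 0):
        raise GeometryError("point does not project forward onto the plane")
    q = f[:2] + t[:, None] * (pts[:, :2] - f[:2])
    return q[0] if np.asarray(p).ndim == 1 else q


# ---------------------------------------------------------------------------
# Calibration cage
# ---------------------------------------------------------------------------

@dataclass
class CageSpec:
    """Bead layout of a uniplanar calibration cage.

    Fiducial beads lie in the z = 0 plane and define the 2D reference;
    control beads sit at known positive heights and define the focal points
    through back-projected lines.  ``visibility`` maps each view name to the
    index lists of the beads seen in that view; correspondence between spec
    and detected beads is by ordering.
    """

    fiducial_points: np.ndarray
    control_points: np.ndarray
    visibility: dict

    def __post_init__(self) -> None:
        self.fiducial_points = np.asarray(self.fiducial_points, float).reshape(-1, 3)
        self.control_points = np.asarray(self.control_points, float).reshape(-1, 3)
        if np.any(np.abs(self.fiducial_points[:, 2]) > 1e-9):
            raise GeometryError("fiducial points must lie in the z=0 plane")
        if np.any(self.control_points[:, 2] <= 0):
            raise GeometryError("control points must have strictly positive z")
        for view, vis in self.visibility.items():
            fid = np.asarray(vis["fiducials"], int)
            ctl = np.asarray(vis["controls"], int)
            if len(fid) < 4:
                raise GeometryError(f"view {view}: need >=4 fiducial beads")
            if len(ctl) < 2:
                raise GeometryError(f"view {view}: need >=2 control beads")
            if _collinear(self.fiducial_points[fid, :2]):
                raise GeometryError(f"view {view}: fiducial beads are collinear")

    def fiducials_for(self, view: str) -> np.ndarray:
        return self.fiducial_points[np.asarray(self.visibility[view]["fiducials"], int)]

    def controls_for(self, view: str) -> np.ndarray:
        return self.control_points[np.asarray(self.visibility[view]["controls"], int)]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "fiducial_points": self.fiducial_points.tolist(),
                "control_points": self.control_points.tolist(),
                "visibility": {v: {"fiducials": list(map(int, d["fiducials"])),
                                   "controls": list(map(int, d["controls"]))}
                               for v, d in self.visibility.items()},
            }, fh, indent=2)

    @staticmethod
    def from_json(path) -> "CageSpec":
        with open(path) as fh:
            d = json.load(fh)
        return CageSpec(np.asarray(d["fiducial_points"]),
                        np.asarray(d["control_points"]), d["visibility"])


def _collinear(xy: np.ndarray, tol: float = 1e-9) -> bool:
    xy = xy - xy.mean(axis=0)
    s = np.linalg.svd(xy, compute_uv=False)
    return len(s) < 2 or s[1] <= tol * max(s[0], 1.0)


def fit_pixel_to_plane(observed_pixels: np.ndarray, cage: CageSpec,
                       view: str = "left") -> tuple[np.ndarray, float]:
    """Least-squares homography from detected fiducial pixels to plane mm.

    Normalized-DLT estimate; returns ``(H, residual_rms_mm)``.
    """
    obs = np.asarray(observed_pixels, float).reshape(-1, 2)
    ref = cage.fiducials_for(view)[:, :2]
    if len(obs) != len(ref):
        raise GeometryError("observation count does not match cage fiducials")
    if len(obs) < 4:
        raise GeometryError("need at least 4 fiducial correspondences")
    if _collinear(obs) or _collinear(ref):
        raise GeometryError("fiducial configuration is collinear/rank-deficient")
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(obs, ref)
        if not tf:
            raise GeometryError("homography estimation failed")
    else:  # scikit-image < 0.26
        tf = ProjectiveTransform()
        if not tf.estimate(obs, ref):
            raise GeometryError("homography estimation failed")
    H = tf.params
    res = apply_homography(H, obs) - ref
    rms = float(np.sqrt(np.mean(np.sum(res ** 2, axis=1))))
    return H, rms


def estimate_focal_point(control_obs: np.ndarray, transform: np.ndarray,
                         cage: CageSpec, view: str = "left") -> np.ndarray:
    """Focal point as the least-squares intersection of control-bead lines.

    Each control bead's known 3D position and its observed fiducial-plane
    projection define a line; the source is the point minimizing the summed
    squared distance to all such lines.
    """
    obs = np.asarray(control_obs, float).reshape(-1, 2)
    beads = cage.controls_for(view)
    if len(obs) != len(beads):
        raise GeometryError("observation count does not match cage controls")
    if len(obs) < 2:
        raise GeometryError("need at least 2 control beads")
    plane_xy = apply_homography(transform, obs)
    anchors = np.column_stack([plane_xy, np.zeros(len(obs))])
    dirs = beads - anchors
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(norms < 1e-9):
        raise GeometryError("control bead coincides with its projection")
    dirs /= norms[:, None]
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for a, d in zip(anchors, dirs):
        P = np.eye(3) - np.outer(d, d)
        A += P
        b += P @ a
    w = np.linalg.eigvalsh(A)
    if w[0] < 1e-6 * max(w[-1], 1.0):
        raise GeometryError("control-bead lines are near-parallel; focus ill-conditioned")
    return np.linalg.solve(A, b)


def calibrate(cage: CageSpec,
              fiducial_obs: dict,
              control_obs: dict,
              pixel_pitch: float,
              image_shape: tuple,
              inter_tube_angle_deg: float = 40.0,
              source_to_image_mm: float = 1600.0) -> StereoCalibration:
    """Full stereo calibration from per-view bead observations.

    ``fiducial_obs`` / ``control_obs`` map view name ('left'/'right') to
    (N, 2) pixel arrays ordered like the cage visibility lists.
    """
    cams = {}
    residuals = {}
    for view in ("left", "right"):
        H, rms = fit_pixel_to_plane(fiducial_obs[view], cage, view)
        focus = estimate_focal_point(control_obs[view], H, cage, view)
        cams[view] = PinholeCamera(focus, H, pixel_pitch, image_shape)
        residuals[view] = {"fiducial_rms_mm": rms}
    return StereoCalibration(cams["left"], cams["right"],
                             inter_tube_angle_deg, source_to_image_mm,
                             residuals)


# ---------------------------------------------------------------------------
# Nominal phantom setup
# ---------------------------------------------------------------------------

def nominal_stereo_calibration(image_shape: tuple = (552, 667),
                               pixel_pitch: float = 0.64,
                               inter_tube_angle_deg: float = 40.0,
                               source_to_image_mm: float = 1600.0,
                               crossing_height_mm: float = 160.0) -> StereoCalibration:
    """Analytic two-tube setup: beams crossing above a uniplanar detector.

    The two sources sit symmetrically about the z axis in the x-z plane, each
    a beam length ``source_to_image_mm`` from its own detector-window center,
    with the stated inter-tube angle; the beams cross at
    ``(0, 0, crossing_height_mm)`` where the specimen is placed.  Defaults are
    a quarter-scale detector (552 x 667 px at 0.64 mm) of the full-size
    2208 x 2668 at 0.16 mm setup.
    """
    half = np.radians(inter_tube_angle_deg / 2.0)
    cams = {}
    for view, sgn in (("left", -1.0), ("right", 1.0)):
        # beam direction from source toward detector
        d = np.array([-sgn * np.sin(half), 0.0, -np.cos(half)])
        cross = np.array([0.0, 0.0, crossing_height_mm])
        s = crossing_height_mm / np.cos(half)
        center = cross + s * d          # central ray hits the plane here
        focus = center - source_to_image_mm * d
        rows, cols = image_shape
        H = np.array([
            [pixel_pitch, 0.0, center[0] - pixel_pitch * (cols - 1) / 2.0],
            [0.0, -pixel_pitch, center[1] + pixel_pitch * (rows - 1) / 2.0],
            [0.0, 0.0, 1.0],
        ])
        cams[view] = PinholeCamera(focus, H, pixel_pitch, image_shape)
    return StereoCalibration(cams["left"], cams["right"],
                             inter_tube_angle_deg, source_to_image_mm)


def make_default_cage(calib: StereoCalibration,
                      n_fiducial_grid: int = 4,
                      n_control_grid: int = 3,
                      control_heights: tuple = (40.0, 60.0),
                      window_fraction: float = 0.6) -> CageSpec:
    """Self-defined phantom cage matched to a calibration's detector windows.

    Per view: an ``n x n`` fiducial grid in the detector window (z = 0) and an
    ``m x m`` control grid lifted onto the view's rays at alternating heights,
    so every bead projects inside its window.
    """
    fids, ctls = [], []
    visibility = {}
    for view in ("left", "right"):
        cam = calib.camera(view)
        rows, cols = cam.image_shape
        corners = cam.pixel_to_plane_pts(
            np.array([[0.0, 0.0], [cols - 1.0, rows - 1.0]]))
        center = corners.mean(axis=0)
        span = np.abs(corners[1] - corners[0]) * window_fraction / 2.0
        g = np.linspace(-1, 1, n_fiducial_grid)
        fi0 = len(fids)
        for gy in g:
            for gx in g:
                fids.append([center[0] + gx * span[0], center[1] + gy * span[1], 0.0])
        gc = np.linspace(-1, 1, n_control_grid)
        ci0 = len(ctls)
        k = 0
        f = cam.focal_point
        for gy in gc:
            for gx in gc:
                q = np.array([center[0] + gx * span[0] * 0.8,
                              center[1] + gy * span[1] * 0.8, 0.0])
                h = control_heights[k % len(control_heights)]
                k += 1
                s = (f[2] - h) / f[2]
                ctls.append(f + s * (q - f))
        visibility[view] = {
            "fiducials": list(range(fi0, fi0 + n_fiducial_grid ** 2)),
            "controls": list(range(ci0, ci0 + n_control_grid ** 2)),
        }
    return CageSpec(np.asarray(fids), np.asarray(ctls), visibility)


def simulate_cage_observations(cage: CageSpec, calib: StereoCalibration,
                               noise_px: float = 0.0,
                               rng: np.random.Generator | None = None
                               ) -> tuple[dict, dict]:
    """Project cage beads through true cameras; optionally add pixel noise.

    Returns ``(fiducial_obs, control_obs)`` dicts as accepted by `calibrate`.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    fid_obs, ctl_obs = {}, {}
    for view in ("left", "right"):
        cam = calib.camera(view)
        fid = cam.plane_to_pixel_pts(cage.fiducials_for(view)[:, :2])
        ctl = cam.project_to_pixels(cage.controls_for(view))
        if noise_px > 0:
            fid = fid + rng.normal(0.0, noise_px, fid.shape)
            ctl = ctl + rng.normal(0.0, noise_px, ctl.shape)
        fid_obs[view] = fid
        ctl_obs[view] = ctl
    return fid_obs, ctl_obs
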