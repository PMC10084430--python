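"""Marker-based RSA: bead detection, triangulation and rigid-body matching.

The gold-standard pipeline detects tantalum bead projections (circular Hough
transform with sub-pixel centroid refinement), reconstructs each bead in 3D
by minimizing the crossing-line distance between its two view rays (midpoint
of the common perpendicular), summarizes a body as the centroid of its
markers, and matches a predefined 3D marker-configuration model by
least-squares rigid (Kabsch/Procrustes, det = +1) fitting.  The mean
rigid-body error -- the mean per-marker residual distance after the fit --
is gated at 0.35 mm per the RSA guidelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .geometry import RigidPose, StereoCalibration

RIGID_BODY_ERROR_GATE_MM = 0.35


class MarkerError(ValueError):
    """Degenerate marker configuration or ill-conditioned reconstruction."""


@dataclass
class MarkerSet:
    """Labeled 3D bead positions with optional per-view 2D observations."""

    positions: np.ndarray
    labels: list = field(default_factory=list)
    observations: dict = field(default_factory=dict)   # view -> (N, 2) px
    crossing_distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        if not self.labels:
            self.labels = [str(i) for i in range(len(self.positions))]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class RigidBodyFit:
    """Least-squares rigid match of a marker-configuration model."""

    pose: RigidPose
    residuals: np.ndarray
    mean_rigid_body_error: float
    gate_threshold: float = RIGID_BODY_ERROR_GATE_MM

    @property
    def passes_gate(self) -> bool:
        return self.mean_rigid_body_error <= self.gate_threshold


# ---------------------------------------------------------------------------
# 2D bead detection
# ---------------------------------------------------------------------------

def detect_beads(image: np.ndarray, radius_range_px: tuple = (2, 8),
                 sensitivity: float = 0.5, max_beads: int | None = None
                 ) -> np.ndarray:
    """Sub-pixel centers of circular high-contrast blobs, as (u, v) pixels.

    Circular Hough transform on Canny edges proposes candidates; each center
    is refined by the intensity-weighted centroid of the background-
    subtracted local window.  ``sensitivity`` in (0, 1] lowers the Hough
    accumulator acceptance threshold; an empty array is a valid result.
    """
    img = np.asarray(image, float)
    span = float(np.ptp(img))
    if span <= 0:
        return np.empty((0, 2))
    norm = (img - img.min()) / span
    edges = canny(norm, sigma=1.0)
    if not edges.any():
        return np.empty((0, 2))
    radii = np.arange(int(radius_range_px[0]), int(radius_range_px[1]) + 1)
    h = hough_circle(edges, radii)
    thresh = (1.0 - sensitivity) * h.max()
    accums, cx, cy, rad = hough_circle_peaks(
        h, radii, threshold=thresh, min_xdistance=int(radii.max()),
        min_ydistance=int(radii.max()),
        total_num_peaks=max_beads if max_beads else np.inf)
    # robust image noise scale, to reject circles hallucinated from noise
    med = np.median(img)
    noise = 1.4826 * np.median(np.abs(img - med)) + 1e-12
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    centers = []
    for u, v, r in zip(cx, cy, rad):
        d = np.sqrt((xx - u) ** 2 + (yy - v) ** 2)
        inner = d <= r
        annulus = (d > r + 1) & (d <= r + 4)
        if not inner.any() or not annulus.any():
            continue
        contrast = img[inner].mean() - img[annulus].mean()
        if contrast < 5.0 * noise:
            continue
        w = int(r) + 2
        r0, r1 = max(int(v) - w, 0), min(int(v) + w + 1, img.shape[0])
        c0, c1 = max(int(u) - w, 0), min(int(u) + w + 1, img.shape[1])
        patch = img[r0:r1, c0:c1] - img[r0:r1, c0:c1].min()
        if patch.sum() <= 0:
            centers.append((float(u), float(v)))
            continue
        vv, uu = np.mgrid[r0:r1, c0:c1]
        centers.append((float((patch * uu).sum() / patch.sum()),
                        float((patch * vv).sum() / patch.sum())))
    out = np.asarray(centers, float).reshape(-1, 2)
    # suppress duplicate refinements landing on the same bead
    keep = []
    for i, c in enumerate(out):
        if all(np.linalg.norm(c - out[j]) > radii.min() for j in keep):
            keep.append(i)
    return out[keep]


# ---------------------------------------------------------------------------
# 3D reconstruction
# ---------------------------------------------------------------------------

def _view_ray(obs: np.ndarray, calib: StereoCalibration, view: str
              ) -> tuple[np.ndarray, np.ndarray]:
    cam = calib.camera(view)
    origin, dirs = cam.ray_through_pixel(np.atleast_2d(obs))
    return origin, dirs


def triangulate(obs_left: np.ndarray, obs_right: np.ndarray,
                calib: StereoCalibration) -> tuple[np.ndarray, float]:
    """3D bead position minimizing the crossing-line distance of its rays.

    Returns the midpoint of the common perpendicular of the two view rays
    and the perpendicular's length (the crossing-line distance, mm).
    """
    o1, d1 = _view_ray(obs_left, calib, "left")
    o2, d2 = _view_ray(obs_right, calib, "right")
    d1, d2 = d1[0], d2[0]
    b = float(d1 @ d2)
    denom = 1.0 - b * b
    if denom < 1e-12:
        raise MarkerError("view rays are near-parallel; triangulation "
                          "ill-conditioned")
    w0 = o1 - o2
    d = float(d1 @ w0)
    e = float(d2 @ w0)
    s1 = (b * e - d) / denom
    s2 = (e - b * d) / denom
    p1 = o1 + s1 * d1
    p2 = o2 + s2 * d2
    return (p1 + p2) / 2.0, float(np.linalg.norm(p1 - p2))


def reconstruct_markers(obs_left: np.ndarray, obs_right: np.ndarray,
                        calib: StereoCalibration,
                        labels: list | None = None) -> MarkerSet:
    """Triangulate corresponding bead observations of the two views."""
    obs_left = np.asarray(obs_left, float).reshape(-1, 2)
    obs_right = np.asarray(obs_right, float).reshape(-1, 2)
    if len(obs_left) != len(obs_right):
        raise MarkerError("views have different bead counts")
    pts, dists = [], []
    for ol, orr in zip(obs_left, obs_right):
        p, c = triangulate(ol, orr, calib)
        pts.append(p)
        dists.append(c)
    return MarkerSet(np.asarray(pts), labels or [],
                     {"left": obs_left, "right": obs_right},
                     np.asarray(dists))


def match_views(obs_left: np.ndarray, obs_right: np.ndarray,
                calib: StereoCalibration, gate_mm: float = 2.0
                ) -> tuple[np.ndarray, np.ndarray]:
    """Correspond unlabeled detections across views by crossing-line distance.

    Globally optimal assignment (Hungarian) on the pairwise crossing-line
    distance matrix; pairs whose distance exceeds ``gate_mm`` are reported
    as ambiguous (second return value), not guessed.
    """
    obs_left = np.asarray(obs_left, float).reshape(-1, 2)
    obs_right = np.asarray(obs_right, float).reshape(-1, 2)
    n, m = len(obs_left), len(obs_right)
    cost = np.full((n, m), np.inf)
    for i in range(n):
        for j in range(m):
            try:
                _, cost[i, j] = triangulate(obs_left[i], obs_right[j], calib)
            except MarkerError:
                pass
    cost = np.where(np.isfinite(cost), cost, 1e6)
    ri, ci = linear_sum_assignment(cost)
    ok = cost[ri, ci] <= gate_mm
    pairs = np.column_stack([ri[ok], ci[ok]])
    ambiguous = np.column_stack([ri[~ok], ci[~ok]])
    return pairs, ambiguous


def centroid_position(markers: MarkerSet) -> np.ndarray:
    """Body position as the arithmetic mean of its reconstructed markers."""
    if len(markers) == 0:
        raise MarkerError("no markers to summarize")
    return markers.positions.mean(axis=0)


# ---------------------------------------------------------------------------
# Rigid-body (marker-configuration) matching
# ---------------------------------------------------------------------------

def fit_rigid_body(model_config: MarkerSet | np.ndarray,
                   measured: MarkerSet | np.ndarray,
                   gate_threshold: float = RIGID_BODY_ERROR_GATE_MM
                   ) -> RigidBodyFit:
    """Least-squares rigid transform taking the model markers onto the
    measured markers (orthogonal Procrustes with det = +1)."""
    A = model_config.positions if isinstance(model_config, MarkerSet) \
        else np.asarray(model_config, float).reshape(-1, 3)
    B = measured.positions if isinstance(measured, MarkerSet) \
        else np.asarray(measured, float).reshape(-1, 3)
    if len(A) != len(B):
        raise MarkerError("marker counts differ between model and measurement")
    if len(A) < 3:
        raise MarkerError("need at least 3 corresponding markers")
    Ac = A - A.mean(axis=0)
    s = np.linalg.svd(Ac, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise MarkerError("marker configuration is collinear; pose degenerate")
    Bc = B - B.mean(axis=0)
    H = Ac.T @ Bc
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = B.mean(axis=0) - R @ A.mean(axis=0)
    pose = RigidPose(R, t)
    res = np.linalg.norm(pose.apply(A) - B, axis=1)
    return RigidBodyFit(pose, res, float(res.mean()), gate_threshold)
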