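"""Virtual views: silhouettes of surface models and DRRs of volume models.

A DRR (digitally reconstructed radiograph) pixel is the ray's cumulative
attenuation through the voxel grid: the sum over traversed voxels of
voxel value x exact intersection length (mm), computed by incremental
Amanatides-Woo grid traversal.  A silhouette pixel is true iff the ray
through its center hits the posed mesh, obtained by perspective-projecting
every triangle onto the fiducial plane and rasterizing the union (exact for
silhouettes, since central projection maps triangles to triangles).

Rays are cast through pixel centers; there is no sub-pixel supersampling.
Higher attenuation means higher pixel value in both the simulator and the
DRRs (matching polarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import binary_dilation
from skimage.draw import polygon as _sk_polygon
from skimage.morphology import disk

from .geometry import PinholeCamera, RigidPose, StereoCalibration
from .models import SurfaceModel, VolumeModel


class ProjectionError(ValueError):
    """Invalid scene or degenerate projection request."""


@dataclass
class MaskImage:
    """Boolean inclusion mask over an image; True = pixel participates."""

    data: np.ndarray
    kind: str = "fixed"     # fixed | dynamic | combined

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, bool)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def combine(self, other: "MaskImage") -> "MaskImage":
        if self.shape != other.shape:
            raise ProjectionError("mask shapes differ; cannot combine")
        return MaskImage(self.data & other.data, "combined")


@dataclass
class RadiographPair:
    """Two co-calibrated intensity images with optional per-view masks."""

    left: np.ndarray
    right: np.ndarray
    calibration: StereoCalibration
    masks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for view in ("left", "right"):
            img = np.asarray(getattr(self, view), float)
            setattr(self, view, img)
            cam = self.calibration.camera(view)
            if img.shape != cam.image_shape:
                raise ProjectionError(
                    f"{view} image shape {img.shape} does not match camera "
                    f"{cam.image_shape}")

    def image(self, view: str) -> np.ndarray:
        return self.left if view == "left" else self.right


# ---------------------------------------------------------------------------
# Silhouette rendering
# ---------------------------------------------------------------------------

def render_silhouette(mesh: SurfaceModel, pose: RigidPose, cam: PinholeCamera,
                      scale: float = 1.0) -> np.ndarray:
    """Binary perspective silhouette of a posed mesh (pixel-center rule)."""
    if scale != 1.0:
        cam = cam.scaled(scale)
    out = np.zeros(cam.image_shape, dtype=bool)
    if len(mesh.triangles) == 0:
        return out
    world = pose.apply(mesh.vertices)
    if np.any(world[:, 2] >= cam.focal_point[2] - 1e-9):
        raise ProjectionError("mesh vertex at or behind the focal point")
    from .geometry import project_point
    plane = project_point(world, cam)
    px = cam.plane_to_pixel_pts(plane)           # (u, v) = (col, row)
    tris = px[mesh.triangles]                    # (M, 3, 2)
    for tri in tris:
        rr, cc = _sk_polygon(tri[:, 1], tri[:, 0], shape=out.shape)
        out[rr, cc] = True
    return out


# ---------------------------------------------------------------------------
# DRR rendering
# ---------------------------------------------------------------------------

@njit(cache=True)
def _raycast_kernel(vox, a, dirs, out):  # pragma: no cover - numba
    n0, n1, n2 = vox.shape
    nray = dirs.shape[0]
    for p in range(nray):
        b = dirs[p]
        tmin = 0.0
        tmax = 1.0e30
        ok = True
        for ax in range(3):
            n = vox.shape[ax]
            lo = -0.5
            hi = n - 0.5
            if abs(b[ax]) < 1e-12:
                if a[ax] < lo or a[ax] > hi:
                    ok = False
            else:
                t1 = (lo - a[ax]) / b[ax]
                t2 = (hi - a[ax]) / b[ax]
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
        if (not ok) or tmax <= tmin:
            out[p] = 0.0
            continue
        eps = 1e-9 * (tmax - tmin)
        t = tmin
        p0 = a[0] + (tmin + eps) * b[0]
        p1 = a[1] + (tmin + eps) * b[1]
        p2 = a[2] + (tmin + eps) * b[2]
        i0 = int(np.floor(p0 + 0.5))
        i1 = int(np.floor(p1 + 0.5))
        i2 = int(np.floor(p2 + 0.5))
        if i0 < 0:
            i0 = 0
        if i1 < 0:
            i1 = 0
        if i2 < 0:
            i2 = 0
        if i0 > n0 - 1:
            i0 = n0 - 1
        if i1 > n1 - 1:
            i1 = n1 - 1
        if i2 > n2 - 1:
            i2 = n2 - 1
        # next-boundary parameters and per-cell increments
        big = 1.0e30
        if b[0] > 1e-12:
            tn0 = (i0 + 0.5 - a[0]) / b[0]
            dt0 = 1.0 / b[0]
            s0 = 1
        elif b[0] < -1e-12:
            tn0 = (i0 - 0.5 - a[0]) / b[0]
            dt0 = -1.0 / b[0]
            s0 = -1
        else:
            tn0 = big
            dt0 = big
            s0 = 0
        if b[1] > 1e-12:
            tn1 = (i1 + 0.5 - a[1]) / b[1]
            dt1 = 1.0 / b[1]
            s1 = 1
        elif b[1] < -1e-12:
            tn1 = (i1 - 0.5 - a[1]) / b[1]
            dt1 = -1.0 / b[1]
            s1 = -1
        else:
            tn1 = big
            dt1 = big
            s1 = 0
        if b[2] > 1e-12:
            tn2 = (i2 + 0.5 - a[2]) / b[2]
            dt2 = 1.0 / b[2]
            s2 = 1
        elif b[2] < -1e-12:
            tn2 = (i2 - 0.5 - a[2]) / b[2]
            dt2 = -1.0 / b[2]
            s2 = -1
        else:
            tn2 = big
            dt2 = big
            s2 = 0
        acc = 0.0
        while True:
            tstop = tn0
            ax = 0
            if tn1 < tstop:
                tstop = tn1
                ax = 1
            if tn2 < tstop:
                tstop = tn2
                ax = 2
            if tstop > tmax:
                tstop = tmax
                ax = -1
            seg = tstop - t
            if seg > 0.0:
                acc += vox[i0, i1, i2] * seg
            if ax < 0:
                break
            t = tstop
            if ax == 0:
                i0 += s0
                tn0 += dt0
                if i0 < 0 or i0 > n0 - 1:
                    break
            elif ax == 1:
                i1 += s1
                tn1 += dt1
                if i1 < 0 or i1 > n1 - 1:
                    break
            else:
                i2 += s2
                tn2 += dt2
                if i2 < 0 or i2 > n2 - 1:
                    break
        out[p] = acc


def _pixel_grid_dirs(cam: PinholeCamera) -> np.ndarray:
    """Unit world directions of the rays through every pixel center."""
    rows, cols = cam.image_shape
    uu, vv = np.meshgrid(np.arange(cols, dtype=float),
                         np.arange(rows, dtype=float))
    uv = np.column_stack([uu.ravel(), vv.ravel()])
    _, dirs = cam.ray_through_pixel(uv)
    return dirs


def cast_rays(vol: VolumeModel, pose: RigidPose, origin_world: np.ndarray,
              dirs_world: np.ndarray) -> np.ndarray:
    """Line integrals of a posed volume along arbitrary world-space rays.

    ``dirs_world`` must be unit vectors so the accumulated lengths are mm.
    """
    R = pose.rotation
    t = pose.translation
    M = vol.orientation
    S = vol.spacing
    # world ray -> continuous voxel-index coordinates (centers at integers)
    local = R.T @ (np.asarray(origin_world, float) - t)
    a = (M.T @ (local - vol.origin)) / S
    B = (dirs_world @ R) @ M / S          # rows: S^-1 M^T R^T d
    out = np.empty(len(B), dtype=np.float64)
    _raycast_kernel(vol.voxels, np.ascontiguousarray(a),
                    np.ascontiguousarray(B), out)
    return out


def render_drr(vol: VolumeModel, pose: RigidPose, cam: PinholeCamera,
               scale: float = 1.0) -> np.ndarray:
    """DRR of a posed volume: per-pixel cumulative attenuation (value x mm)."""
    if scale != 1.0:
        cam = cam.scaled(scale)
    dirs = _pixel_grid_dirs(cam)
    vals = cast_rays(vol, pose, cam.focal_point, dirs)
    return vals.reshape(cam.image_shape)


# ---------------------------------------------------------------------------
# Masks and resolution pyramid
# ---------------------------------------------------------------------------

def make_dynamic_mask(model_projection: np.ndarray,
                      dilation_radius_px: int = 15) -> MaskImage:
    """Inclusion mask: the dilated initial model projection (region of interest)."""
    proj = np.asarray(model_projection, bool)
    if not proj.any():
        raise ProjectionError("empty model projection; no region of interest")
    r = int(round(dilation_radius_px))
    data = binary_dilation(proj, disk(r).astype(bool)) if r > 0 \
        else proj.copy()
    return MaskImage(data, "dynamic")


def make_fixed_mask(implant_silhouette: np.ndarray,
                    dilation_radius_px: int = 5) -> MaskImage:
    """Exclusion mask: everything but the dilated implant silhouette.

    Used for bone registration, where the metallic implant and the surgically
    removed bone must not contribute to the similarity.
    """
    sil = np.asarray(implant_silhouette, bool)
    r = int(round(dilation_radius_px))
    dil = binary_dilation(sil, disk(r).astype(bool)) if r > 0 else sil
    return MaskImage(~dil, "fixed")


def downsample_half(image: np.ndarray) -> np.ndarray:
    """2x2 block averaging; odd trailing row/column dropped."""
    img = np.asarray(image, float)
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ProjectionError("image too small to downsample")
    r = (img.shape[0] // 2) * 2
    c = (img.shape[1] // 2) * 2
    v = img[:r, :c]
    return v.reshape(r // 2, 2, c // 2, 2).mean(axis=(1, 3))


def downsample_mask_half(mask: MaskImage) -> MaskImage:
    """Half-resolution mask: a block is included iff any of its pixels is."""
    m = downsample_half(mask.data.astype(float)) > 0.0
    return MaskImage(m, mask.kind)
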