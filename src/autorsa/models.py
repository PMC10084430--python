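"""Model assets: triangle surface models and voxel volume models.

Three model kinds drive the registration methods: implant surface meshes
(silhouette projection), synthetic volumetric implants built by flood-filling
the mesh interior with a constant value of 3000 on an isometric 0.4 mm grid,
and CT-style bone volumes whose intensities are used as-is (the gradient
correlation metric is invariant to affine intensity scaling, so no
Hounsfield-to-attenuation conversion is applied).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh
from numba import njit


class ModelError(ValueError):
    """Unreadable or geometrically unusable model input."""


# ---------------------------------------------------------------------------
# Surface models
# ---------------------------------------------------------------------------

@dataclass
class SurfaceModel:
    """Triangle mesh with its local frame metadata.

    ``vertices`` (N, 3) mm and ``triangles`` (M, 3) vertex indices.
    Watertightness (every edge shared by exactly two triangles) is required
    for voxelization.
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, int).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ModelError("mesh has non-finite vertex coordinates")

    @property
    def mesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    @property
    def watertight(self) -> bool:
        return bool(self.mesh.is_watertight)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def bounding_radius(self) -> float:
        """Radius of the vertex cloud about the local origin."""
        return float(np.linalg.norm(self.vertices, axis=1).max())

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "SurfaceModel":
        return SurfaceModel(self.vertices @ np.asarray(R).T + np.asarray(t),
                            self.triangles)

    def centered(self) -> "SurfaceModel":
        return SurfaceModel(self.vertices - self.centroid, self.triangles)

    def save(self, path) -> None:
        self.mesh.export(str(path))


def load_surface_model(path) -> SurfaceModel:
    """Read an STL/PLY triangle mesh."""
    path = Path(path)
    if not path.exists():
        raise ModelError(f"mesh file not found: {path}")
    try:
        m = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:  # noqa: BLE001 - wrap parser failures
        raise ModelError(f"cannot parse mesh {path}: {exc}") from exc
    if not isinstance(m, trimesh.Trimesh) or len(m.faces) == 0:
        raise ModelError(f"{path} does not contain a triangle mesh")
    # STL stores one vertex triple per facet; restore shared topology
    m.merge_vertices()
    return SurfaceModel(np.asarray(m.vertices), np.asarray(m.faces))


# ---------------------------------------------------------------------------
# Volume models
# ---------------------------------------------------------------------------

@dataclass
class VolumeModel:
    """Voxel grid with spacing/origin/orientation in its local frame.

    ``voxels`` is indexed ``[ix, iy, iz]``; the world position of voxel
    center ``(i, j, k)`` is ``origin + orientation @ (spacing * (i, j, k))``.
    ``provenance`` tags the model kind: 'synthetic-implant' or 'bone'.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    provenance: str = "bone"

    def __post_init__(self) -> None:
        self.voxels = np.ascontiguousarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ModelError("voxels must be a 3D array")
        self.spacing = np.asarray(self.spacing, float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ModelError("voxel spacing must be positive")
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.orientation = np.asarray(self.orientation, float).reshape(3, 3)

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def voxel_centers_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, float).reshape(-1, 3)
        return (idx * self.spacing) @ self.orientation.T + self.origin

    @property
    def bounding_radius(self) -> float:
        """Radius about the local origin of the volume's corner box."""
        n = np.array(self.shape, float)
        corners = np.array([[i, j, k] for i in (-0.5, n[0] - 0.5)
                            for j in (-0.5, n[1] - 0.5)
                            for k in (-0.5, n[2] - 0.5)])
        pts = self.voxel_centers_world(corners)
        return float(np.linalg.norm(pts, axis=1).max())


def voxelize_surface(mesh: SurfaceModel, spacing: float = 0.4,
                     inside_value: float = 3000.0,
                     padding_voxels: int = 2) -> VolumeModel:
    """Synthetic volumetric model: constant-valued solid interior of a mesh.

    A voxel gets ``inside_value`` iff its center lies inside the closed
    surface (signed ray-parity test); all other voxels are zero.  The grid is
    isometric, centered and dimensioned on the mesh bounding box with a
    padding margin so gradient kernels have border context.
    """
    if not mesh.watertight:
        raise ModelError("voxelization requires a watertight mesh")
    if spacing <= 0:
        raise ModelError("spacing must be positive")
    lo, hi = mesh.bounds
    lo = lo - padding_voxels * spacing
    hi = hi + padding_voxels * spacing
    n = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    # center the grid on the bounding box
    origin = (lo + hi) / 2.0 - (n - 1) * spacing / 2.0
    ii, jj, kk = np.meshgrid(*(np.arange(m) for m in n), indexing="ij")
    centers = origin + spacing * np.column_stack(
        [ii.ravel(), jj.ravel(), kk.ravel()])
    inside = _contains(mesh.mesh, centers)
    vox = np.where(inside.reshape(tuple(n)), float(inside_value), 0.0)
    return VolumeModel(vox, np.full(3, float(spacing)), origin,
                       np.eye(3), provenance="synthetic-implant")


@njit(cache=True)
def _parity_kernel(v0, e1, e2, points, d, inside, suspect):  # pragma: no cover
    eps = 1e-9
    edge_eps = 1e-7
    ntri = v0.shape[0]
    for p in range(points.shape[0]):
        count = 0
        bad = False
        for t in range(ntri):
            # Moller-Trumbore ray/triangle intersection
            px = d[1] * e2[t, 2] - d[2] * e2[t, 1]
            py = d[2] * e2[t, 0] - d[0] * e2[t, 2]
            pz = d[0] * e2[t, 1] - d[1] * e2[t, 0]
            det = e1[t, 0] * px + e1[t, 1] * py + e1[t, 2] * pz
            if abs(det) < eps:
                continue
            inv = 1.0 / det
            tx = points[p, 0] - v0[t, 0]
            ty = points[p, 1] - v0[t, 1]
            tz = points[p, 2] - v0[t, 2]
            u = (tx * px + ty * py + tz * pz) * inv
            if u < -edge_eps or u > 1.0 + edge_eps:
                continue
            qx = ty * e1[t, 2] - tz * e1[t, 1]
            qy = tz * e1[t, 0] - tx * e1[t, 2]
            qz = tx * e1[t, 1] - ty * e1[t, 0]
            v = (d[0] * qx + d[1] * qy + d[2] * qz) * inv
            if v < -edge_eps or u + v > 1.0 + edge_eps:
                continue
            th = (e2[t, 0] * qx + e2[t, 1] * qy + e2[t, 2] * qz) * inv
            if th <= eps:
                if abs(th) < eps:
                    bad = True
                continue
            # grazing an edge/vertex makes the parity unreliable
            if u < edge_eps or v < edge_eps or u + v > 1.0 - edge_eps:
                bad = True
            count += 1
        inside[p] = (count % 2) == 1
        suspect[p] = bad


def points_in_mesh(vertices: np.ndarray, faces: np.ndarray,
                   points: np.ndarray, max_retries: int = 4) -> np.ndarray:
    """Point-in-polyhedron by signed ray parity.

    Casts one ray per point in a shared pseudo-random direction and counts
    triangle crossings; points whose ray grazes an edge, vertex or the
    surface are re-tested with a jittered direction.
    """
    V = np.ascontiguousarray(vertices, dtype=np.float64)
    F = np.asarray(faces, dtype=np.int64)
    P = np.ascontiguousarray(points, dtype=np.float64)
    v0 = np.ascontiguousarray(V[F[:, 0]])
    e1 = np.ascontiguousarray(V[F[:, 1]] - V[F[:, 0]])
    e2 = np.ascontiguousarray(V[F[:, 2]] - V[F[:, 0]])
    rng = np.random.default_rng(12345)
    inside = np.zeros(len(P), dtype=np.bool_)
    suspect = np.ones(len(P), dtype=np.bool_)
    todo = np.arange(len(P))
    for _ in range(max_retries):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        sub_in = np.zeros(len(todo), dtype=np.bool_)
        sub_bad = np.zeros(len(todo), dtype=np.bool_)
        _parity_kernel(v0, e1, e2, np.ascontiguousarray(P[todo]), d,
                       sub_in, sub_bad)
        inside[todo] = sub_in
        suspect[todo] = sub_bad
        todo = todo[sub_bad]
        if len(todo) == 0:
            break
    return inside


def _contains(tm: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Ray-parity inside test on voxel centers (jittered-ray fallback)."""
    return points_in_mesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                          points)


def load_volume(path) -> VolumeModel:
    """Read a MetaImage (.mhd/.mha) or NIfTI (.nii/.nii.gz) volume.

    Spacing, origin and direction cosines are honored; intensities are not
    rescaled or resampled.
    """
    path = Path(path)
    if not path.exists():
        raise ModelError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # noqa: BLE001
        raise ModelError(f"cannot read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ModelError("expected a 3D volume")
    arr = sitk.GetArrayFromImage(img)          # [z, y, x]
    vox = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)).astype(np.float64))
    return VolumeModel(vox,
                       np.asarray(img.GetSpacing(), float),
                       np.asarray(img.GetOrigin(), float),
                       np.asarray(img.GetDirection(), float).reshape(3, 3))


def save_volume(vol: VolumeModel, path) -> None:
    """Write a VolumeModel as MetaImage/NIfTI (format from the extension)."""
    arr = np.transpose(vol.voxels, (2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetDirection(tuple(vol.orientation.ravel()))
    sitk.WriteImage(img, str(path))
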