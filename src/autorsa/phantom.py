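"""Synthetic knee phantom: scene generation and stereo exam simulation.

This module stands in for the cadaver study material: it builds an
asymmetric knee-implant mesh (tray, keel and peg, all extruded polygons), a
parametric long-bone volume (tapered cortical shell around a textured
trabecular interior, with the bone under the implant resected), a
wide-spread set of intraosseous beads, and simulates calibrated stereo
exams -- bone DRR and analytic bead projections composited in transmission
space with the opaque implant's partial-pixel coverage, then read and
photon-scaled noise -- at scripted ground-truth displacements following the
micrometer protocol (five baseline recordings, then two each at 15
displacement steps from 10 um to 5 mm).

Default geometry is the quarter-scale detector (552 x 667 px at 0.64 mm) of
the full 2208 x 2668 / 0.16 mm setup, with voxel sizes scaled accordingly;
the full-scale detector is available through `nominal_stereo_calibration`.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from .geometry import RigidPose, StereoCalibration, nominal_stereo_calibration
from .migration import PROTOCOL_DISPLACEMENTS_UM, N_BASELINE
from .models import SurfaceModel, VolumeModel, points_in_mesh
from .projection import RadiographPair, cast_rays, _pixel_grid_dirs


class PhantomError(ValueError):
    """Invalid phantom parameters."""


@dataclass
class NoiseParams:
    """Detector noise: Gaussian read noise plus a signal-scaled term.

    The signal term has SD = signal / photon_scale, so doubling
    ``photon_scale`` halves the relative noise in a flat region.  Defaults
    give bead contrast-to-noise around 20.
    """

    gaussian_sd: float = 800.0
    photon_scale: float = 50.0

    @property
    def enabled(self) -> bool:
        return self.gaussian_sd > 0 or np.isfinite(self.photon_scale)


@dataclass
class PhantomParams:
    """Geometry of the synthetic specimen (mm)."""

    bone_length: float = 100.0
    bone_outer_radius: float = 16.0
    cortical_thickness: float = 3.0
    bone_spacing: float = 1.5
    cortical_value: float = 1200.0
    trabecular_value: float = 300.0
    trabecular_texture_sd: float = 120.0
    implant_spacing: float = 0.4
    implant_value: float = 3000.0
    tray_thickness: float = 10.0
    keel_depth: float = 18.0
    n_beads: int = 10
    bead_radius: float = 1.0
    bead_value: float = 8000.0
    specimen_height: float = 160.0   # cage z of the specimen center
    # detector model: an inverted-exposure radiograph,
    #   display = scale * (1 - T_tissue * T_metal),
    # with T_tissue = exp(-attenuation / saturation) for bone and beads.
    # Implant alloys are orders of magnitude more attenuating than bone, so
    # the implant is treated as opaque: T_metal is the unblocked fraction of
    # each pixel, computed as supersampled partial coverage of the exact
    # mesh silhouette (metal_supersample sub-rays per pixel edge).
    detector_saturation: float = 60000.0
    display_scale: float = 60000.0
    metal_supersample: int = 4


@dataclass
class PhantomScene:
    """Generated specimen with its ground-truth component poses."""

    implant: SurfaceModel                  # concatenated, centered mesh
    implant_components: list               # per-solid meshes, same frame
    implant_volume: VolumeModel            # binary occupancy, value 3000
    bone: VolumeModel
    beads_local: np.ndarray                # (n, 3) in the bone local frame
    implant_pose: RigidPose
    bone_pose: RigidPose
    params: PhantomParams
    seed: int = 0

    def bead_world(self, offset: RigidPose | None = None) -> np.ndarray:
        pose = self.bone_pose if offset is None else offset @ self.bone_pose
        return pose.apply(self.beads_local)


@dataclass
class ExamRecord:
    """One simulated stereoradiograph with its ground truth."""

    pair: RadiographPair | None
    implant_pose: RigidPose
    bone_pose: RigidPose
    bead_world: np.ndarray
    bead_observations: dict                # view -> (n, 2) exact pixels
    imposed_um: float
    axis_world: np.ndarray | None
    seed: int


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

_TRAY_OUTLINE = [(-28.0, -20.0), (28.0, -20.0), (28.0, 6.0), (14.0, 20.0),
                 (-4.0, 14.0), (-18.0, 20.0), (-28.0, 6.0)]
_KEEL_OUTLINE = [(2.0, -8.0), (16.0, -8.0), (16.0, 2.0), (12.0, 6.0),
                 (2.0, 4.0)]
_PEG_OUTLINE = [(-22.0, -12.0), (-12.0, -12.0), (-12.0, -2.0), (-22.0, -2.0)]


def _ear_clip(pts: np.ndarray) -> list:
    """Triangulate a simple CCW polygon by ear clipping (small n)."""
    idx = list(range(len(pts)))
    tris = []

    def cross(o, a, b):
        return ((pts[a, 0] - pts[o, 0]) * (pts[b, 1] - pts[o, 1])
                - (pts[a, 1] - pts[o, 1]) * (pts[b, 0] - pts[o, 0]))

    def point_in_tri(p, a, b, c):
        d1 = (pts[b, 0] - pts[a, 0]) * (p[1] - pts[a, 1]) \
            - (pts[b, 1] - pts[a, 1]) * (p[0] - pts[a, 0])
        d2 = (pts[c, 0] - pts[b, 0]) * (p[1] - pts[b, 1]) \
            - (pts[c, 1] - pts[b, 1]) * (p[0] - pts[b, 0])
        d3 = (pts[a, 0] - pts[c, 0]) * (p[1] - pts[c, 1]) \
            - (pts[a, 1] - pts[c, 1]) * (p[0] - pts[c, 0])
        return d1 > 1e-12 and d2 > 1e-12 and d3 > 1e-12

    guard = 0
    while len(idx) > 3 and guard < 10000:
        guard += 1
        n = len(idx)
        for k in range(n):
            a, b, c = idx[(k - 1) % n], idx[k], idx[(k + 1) % n]
            if cross(a, b, c) <= 1e-12:
                continue        # reflex vertex
            if any(point_in_tri(pts[j], a, b, c)
                   for j in idx if j not in (a, b, c)):
                continue
            tris.append((a, b, c))
            idx.pop(k)
            break
        else:
            raise PhantomError("polygon triangulation failed")
    tris.append(tuple(idx))
    return tris


def _extrude(outline, z0: float, z1: float) -> trimesh.Trimesh:
    """Watertight prism from a simple polygon outline (own triangulator)."""
    pts = np.asarray(outline, float)
    area = 0.5 * np.sum(pts[:, 0] * np.roll(pts[:, 1], -1)
                        - np.roll(pts[:, 0], -1) * pts[:, 1])
    if area < 0:
        pts = pts[::-1]
    n = len(pts)
    verts = np.vstack([np.column_stack([pts, np.full(n, z0)]),
                       np.column_stack([pts, np.full(n, z1)])])
    faces = []
    for a, b, c in _ear_clip(pts):
        faces.append((a, c, b))                  # bottom cap, normal -z
        faces.append((n + a, n + b, n + c))      # top cap, normal +z
    for i in range(n):
        j = (i + 1) % n
        faces.append((i, j, n + j))              # outward side walls
        faces.append((i, n + j, n + i))
    return trimesh.Trimesh(verts, np.asarray(faces), process=False)


def make_implant_mesh(params: PhantomParams
                      ) -> tuple[SurfaceModel, list]:
    """Asymmetric tray + keel implant; every rotation changes the silhouette.

    The keel overlaps 2 mm into the tray so the concatenated surface has no
    coincident faces; occupancy is the union of the two solids.
    """
    tray = _extrude(_TRAY_OUTLINE, 0.0, params.tray_thickness)
    keel = _extrude(_KEEL_OUTLINE, -params.keel_depth, 2.0)
    peg = _extrude(_PEG_OUTLINE, -0.75 * params.keel_depth, 2.0)
    solids = [tray, keel, peg]
    combined = trimesh.util.concatenate(solids)
    center = combined.vertices.mean(axis=0)
    # tilt the solid inside its local frame so no flat face is aligned with
    # the voxel grid: grid-aligned faces would voxelize with a systematic
    # sub-voxel phase offset instead of an unbiased dithered boundary
    tilt = Rotation.from_euler("xyz", [8.0, 5.0, 12.0], degrees=True
                               ).as_matrix()
    comps = []
    for m in solids:
        comps.append(SurfaceModel((np.asarray(m.vertices) - center) @ tilt.T,
                                  np.asarray(m.faces)))
    full = SurfaceModel((np.asarray(combined.vertices) - center) @ tilt.T,
                        np.asarray(combined.faces))
    return full, comps


def _voxelize_union(components: list, spacing: float, value: float,
                    padding_voxels: int = 2,
                    supersample: int = 1) -> VolumeModel:
    """Union occupancy of several watertight solids on one isometric grid.

    ``supersample`` = 1 gives the binary center-rule occupancy (the synthetic
    volumetric model); > 1 averages an s^3 sub-grid per voxel into fractional
    occupancy, giving a surface-unbiased volume for the exam simulator.
    """
    lo = np.min([c.bounds[0] for c in components], axis=0) \
        - padding_voxels * spacing
    hi = np.max([c.bounds[1] for c in components], axis=0) \
        + padding_voxels * spacing
    n = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    origin = (lo + hi) / 2.0 - (n - 1) * spacing / 2.0
    ii, jj, kk = np.meshgrid(*(np.arange(m) for m in n), indexing="ij")
    centers = origin + spacing * np.column_stack(
        [ii.ravel(), jj.ravel(), kk.ravel()])
    s = max(int(supersample), 1)
    offsets = (np.arange(s) - (s - 1) / 2.0) / s * spacing
    occ = np.zeros(len(centers))
    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                pts = centers + np.array([ox, oy, oz])
                inside = np.zeros(len(pts), bool)
                for c in components:
                    inside |= points_in_mesh(c.vertices, c.triangles, pts)
                occ += inside
    vox = (occ / s ** 3 * float(value)).reshape(tuple(n))
    return VolumeModel(vox, np.full(3, spacing), origin, np.eye(3),
                       provenance="synthetic-implant")


def make_phantom(seed: int = 0, params: PhantomParams | None = None
                 ) -> PhantomScene:
    """Deterministically generate the full synthetic specimen."""
    params = params or PhantomParams()
    if not 3 <= params.n_beads <= 20:
        raise PhantomError("bead count must be in [3, 20]")
    rng = np.random.default_rng(seed)
    implant, comps = make_implant_mesh(params)
    implant_vol = _voxelize_union(comps, params.implant_spacing,
                                  params.implant_value)

    # poses: bone long axis along cage y; implant tray normal along y too
    # (the extrusion axis, local z, is rotated onto world y)
    z0 = params.specimen_height
    R_imp = Rotation.from_euler("x", -90, degrees=True).as_matrix()
    y_cut = 36.0
    implant_pose = RigidPose(R_imp, np.array([0.0, y_cut + 2.0, z0]))
    bone_pose = RigidPose(np.eye(3), np.array([0.0, y_cut - params.bone_length
                                               / 2.0, z0]))

    bone = _make_bone_volume(params, rng)
    _resect(bone, bone_pose, implant_pose, implant.bounds, margin=2.0)
    beads = _place_beads(params, rng, bone)
    return PhantomScene(implant, comps, implant_vol, bone, beads,
                        implant_pose, bone_pose, params, seed)


def _make_bone_volume(params: PhantomParams, rng: np.random.Generator
                      ) -> VolumeModel:
    sp = params.bone_spacing
    rmax = params.bone_outer_radius * 1.3
    half = params.bone_length / 2.0
    nx = int(np.ceil(2 * rmax / sp)) + 4
    ny = int(np.ceil(2 * half / sp)) + 4
    n = np.array([nx, ny, nx])
    origin = -(n - 1) * sp / 2.0 * np.ones(3)
    ii, jj, kk = np.meshgrid(*(np.arange(m) for m in n), indexing="ij")
    x = origin[0] + sp * ii
    y = origin[1] + sp * jj
    z = origin[2] + sp * kk
    # tapered radius: flares toward the (resected) proximal end
    taper = 1.0 + 0.3 * np.clip(y / half, 0.0, 1.0) ** 2
    r_out = params.bone_outer_radius * taper
    r_in = r_out - params.cortical_thickness
    rad = np.sqrt(x ** 2 + z ** 2)
    inside_len = np.abs(y) <= half
    cortical = (rad <= r_out) & (rad > r_in) & inside_len
    trabecular = (rad <= r_in) & inside_len
    texture = gaussian_filter(rng.normal(0.0, 1.0, tuple(n)), sigma=1.5)
    texture *= params.trabecular_texture_sd / max(texture.std(), 1e-9)
    vox = np.zeros(tuple(n))
    vox[cortical] = params.cortical_value
    vox[trabecular] = np.maximum(
        params.trabecular_value + texture[trabecular], 0.0)
    return VolumeModel(vox, np.full(3, sp), origin, np.eye(3),
                       provenance="bone")


def _resect(bone: VolumeModel, bone_pose: RigidPose, implant_pose: RigidPose,
            implant_bounds: np.ndarray, margin: float) -> None:
    """Remove bone inside the dilated implant bounding box: the void left by
    the surgical cut, so the implant never overlaps remaining bone."""
    n = bone.shape
    ii, jj, kk = np.meshgrid(*(np.arange(m) for m in n), indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    world = bone_pose.apply(bone.voxel_centers_world(idx))
    local = implant_pose.inverse().apply(world)
    lo = implant_bounds[0] - margin
    hi = implant_bounds[1] + margin
    cut = np.all((local >= lo) & (local <= hi), axis=1)
    flat = bone.voxels.ravel()
    flat[cut] = 0.0


def _place_beads(params: PhantomParams, rng: np.random.Generator,
                 bone: VolumeModel) -> np.ndarray:
    """Wide-spread beads strictly inside the remaining bone tissue."""
    beads = []
    half = params.bone_length / 2.0
    tries = 0
    while len(beads) < params.n_beads and tries < 5000:
        tries += 1
        y = rng.uniform(-half + 8.0, half * 0.25)
        r = rng.uniform(0.0, params.bone_outer_radius
                        - params.cortical_thickness - 3.0)
        th = rng.uniform(0.0, 2 * np.pi)
        p = np.array([r * np.cos(th), y, r * np.sin(th)])
        idx = np.round((p - bone.origin) / bone.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= bone.shape):
            continue
        if bone.voxels[tuple(idx)] <= 0:
            continue
        if beads and np.min(np.linalg.norm(np.array(beads) - p, axis=1)) < 10.0:
            continue
        beads.append(p)
    if len(beads) < params.n_beads:
        raise PhantomError("could not place the requested bead count")
    return np.asarray(beads)


# ---------------------------------------------------------------------------
# Exam simulation
# ---------------------------------------------------------------------------

def _metal_coverage(mesh: SurfaceModel, pose: RigidPose, cam,
                    supersample: int) -> np.ndarray:
    """Fraction of each pixel blocked by the (opaque) posed implant."""
    from .projection import render_silhouette

    s = max(int(supersample), 1)
    fine = render_silhouette(mesh, pose, cam.scaled(float(s))).astype(float)
    rows, cols = cam.image_shape
    fine = fine[:rows * s, :cols * s]
    return fine.reshape(rows, s, cols, s).mean(axis=(1, 3))


def _render_beads(img: np.ndarray, centers: np.ndarray, radius: float,
                  value: float, cam) -> None:
    """Add analytic sphere line integrals (chord length x value) in place."""
    f = cam.focal_point
    rows, cols = cam.image_shape
    for c in centers:
        uv0 = cam.project_to_pixels(c[None, :])[0]
        mag = f[2] / max(f[2] - c[2], 1e-9)
        r_px = radius * mag / cam.pixel_pitch + 2.0
        u0, u1 = int(np.floor(uv0[0] - r_px)), int(np.ceil(uv0[0] + r_px)) + 1
        v0, v1 = int(np.floor(uv0[1] - r_px)), int(np.ceil(uv0[1] + r_px)) + 1
        u0, v0 = max(u0, 0), max(v0, 0)
        u1, v1 = min(u1, cols), min(v1, rows)
        if u0 >= u1 or v0 >= v1:
            continue
        uu, vv = np.meshgrid(np.arange(u0, u1), np.arange(v0, v1))
        uv = np.column_stack([uu.ravel(), vv.ravel()]).astype(float)
        _, dirs = cam.ray_through_pixel(uv)
        w = c - f
        cross = np.cross(np.broadcast_to(w, dirs.shape), dirs)
        d2 = np.einsum("ij,ij->i", cross, cross)
        chord = 2.0 * np.sqrt(np.maximum(radius ** 2 - d2, 0.0))
        img[v0:v1, u0:u1] += (value * chord).reshape(v1 - v0, u1 - u0)


def simulate_exam(scene: PhantomScene, calib: StereoCalibration,
                  offset: RigidPose | None = None,
                  noise: NoiseParams | None = None,
                  seed: int = 0,
                  imposed_um: float = 0.0,
                  axis_world: np.ndarray | None = None,
                  render: bool = True) -> ExamRecord:
    """Simulate one stereo exam of the displaced specimen.

    ``offset`` rigidly displaces the whole specimen (bone + implant + beads)
    from its scene base pose.  With ``render=False`` only the ground truth
    and the exact bead projections are produced (no images).
    """
    offset = offset or RigidPose.identity()
    implant_pose = offset @ scene.implant_pose
    bone_pose = offset @ scene.bone_pose
    bead_world = bone_pose.apply(scene.beads_local)
    obs = {}
    for view in ("left", "right"):
        cam = calib.camera(view)
        obs[view] = cam.project_to_pixels(bead_world)
        if np.any(obs[view] < -0.5) or \
                np.any(obs[view][:, 0] > cam.image_shape[1] - 0.5) or \
                np.any(obs[view][:, 1] > cam.image_shape[0] - 0.5):
            raise PhantomError("specimen projects outside the detector")
    pair = None
    if render:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
        imgs = {}
        for view in ("left", "right"):
            cam = calib.camera(view)
            dirs = _pixel_grid_dirs(cam)
            att = cast_rays(scene.bone, bone_pose, cam.focal_point,
                            dirs).reshape(cam.image_shape)
            _render_beads(att, bead_world, scene.params.bead_radius,
                          scene.params.bead_value, cam)
            t_tissue = np.exp(-att / scene.params.detector_saturation)
            t_metal = 1.0 - _metal_coverage(
                scene.implant, implant_pose, cam,
                scene.params.metal_supersample)
            img = scene.params.display_scale * (1.0 - t_tissue * t_metal)
            if noise is not None and noise.enabled:
                if np.isfinite(noise.photon_scale):
                    img = img + img * rng.normal(0.0, 1.0, img.shape) \
                        / noise.photon_scale
                if noise.gaussian_sd > 0:
                    img = img + rng.normal(0.0, noise.gaussian_sd, img.shape)
            imgs[view] = img
        pair = RadiographPair(imgs["left"], imgs["right"], calib)
    return ExamRecord(pair, implant_pose, bone_pose, bead_world, obs,
                      float(imposed_um), axis_world, seed)


def simulate_series(scene: PhantomScene, calib: StereoCalibration,
                    axis: np.ndarray = (1.0, 0.0, 0.0),
                    displacements_um: tuple = PROTOCOL_DISPLACEMENTS_UM,
                    noise: NoiseParams | None = None,
                    seed: int = 0,
                    axis_tilt_deg: float = 1.5,
                    render: bool = False) -> list:
    """One micrometer displacement series: 5 baseline + 2 x each step.

    ``axis_tilt_deg`` applies a small fixed rotation to the nominal axis,
    emulating the imperfect alignment between micrometer and cage axes that
    makes the per-series axis fit necessary.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    tilt = Rotation.from_euler(
        "xyz", [axis_tilt_deg, axis_tilt_deg, axis_tilt_deg],
        degrees=True).as_matrix()
    axis_world = tilt @ axis
    records = []
    schedule = [0.0] * N_BASELINE
    for d in displacements_um:
        schedule.extend([float(d), float(d)])
    for i, d in enumerate(schedule):
        off = RigidPose(np.eye(3), axis_world * d / 1000.0)
        records.append(simulate_exam(
            scene, calib, off, noise, seed=int(seed * 10007 + i) % (2 ** 31),
            imposed_um=d, axis_world=axis_world, render=render))
    return records


def default_calibration(scale: float = 1.0) -> StereoCalibration:
    """Study-geometry calibration; ``scale`` = 1 is the quarter-size default."""
    shape = (int(552 * scale), int(667 * scale))
    return nominal_stereo_calibration(image_shape=shape,
                                      pixel_pitch=0.64 / scale)
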