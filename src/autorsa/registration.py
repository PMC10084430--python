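"""Two-stage 2D/3D pose registration against calibrated stereoradiographs.

Stage one is a global controlled random search with local mutations (CRS2-LM)
on half-resolution images; stage two refines with Nelder-Mead simplex on
full-resolution images with the dynamic mask active.  Implants (silhouette or
DRR rendering) are registered first; bones are then registered with a fixed
mask excluding the dilated implant silhouettes (the metal and the surgically
removed bone), applied at the global stage and combined with the dynamic mask
at the local stage.

The 6-DOF search space is three translations (mm) and three XYZ Euler
rotations (degrees) relative to the initial pose; model assets are centered
on their centroid so rotations pivot about the model, and 1 mm and 1 degree
are treated as commensurate simplex steps.  The best-seen pose (not the last
simplex centroid) is always returned.  All randomness flows from the config
seed, making every registration bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import Bounds, minimize
from scipy.spatial.transform import Rotation

from .geometry import PinholeCamera, RigidPose
from .models import SurfaceModel, VolumeModel
from .projection import (MaskImage, ProjectionError, RadiographPair,
                         downsample_half, make_dynamic_mask,
                         make_fixed_mask, render_silhouette)
from .similarity import (GradientPair, SimilarityError, ngc, render_virtual,
                         sobel_gradients)


class RegistrationError(RuntimeError):
    """Registration could not be set up or produced no valid evaluation."""


@dataclass
class RegistrationConfig:
    """Tunable schedule of the two-stage registration.

    bounds_mm / bounds_deg
        Half-width of the search box around the initial pose.
    global_budget
        Objective evaluations granted to the CRS2-LM stage (0 skips it).
    population
        CRS population size; default 10 * (dim + 1) = 70.
    local_xatol / local_fatol / local_max_evals
        Nelder-Mead termination: simplex size (mm / deg), objective change,
        and evaluation cap.
    local_step
        Initial simplex edge length, mm / deg.
    dynamic_radius_px / fixed_radius_px
        Mask dilation radii at full resolution (halved at half resolution).
    renderer
        'surface' (silhouette) or 'volume' (DRR) for implant registration.
    intensity_transform
        Preprocessing of the actual images before gradient computation:
        'auto' matches implant projections (silhouette or tone-mapped DRR)
        against the display image and bone DRRs against the log-attenuation
        image (linearizing an exponential detector response); 'none' / 'log'
        force either behavior.
    drr_tone_scale
        If set, virtual DRRs are tone-mapped ``1 - exp(-drr / scale)`` with
        the scale frozen at this fraction of the initial pose's DRR maximum.
        Radiopaque implants saturate the detector, so a tone-mapped DRR
        (flat interior, sharp outline) resembles their radiographic
        appearance far better than the linear line-integral image;
        implant-volume registration defaults to 0.01 (near-opaque), bone
        registration to no tone mapping.
    saturation_exclude
        If set, pixels above this fraction of the crop maximum are excluded
        from the correlation (an automatic high-intensity exclusion mask).
    """

    bounds_mm: float = 5.0
    bounds_deg: float = 5.0
    global_budget: int = 3000
    population: int | None = None
    local_xatol: float = 1e-4
    local_fatol: float = 1e-9
    local_max_evals: int = 400
    local_step: float = 0.5
    seed: int = 0
    dynamic_radius_px: int = 15
    fixed_radius_px: int = 5
    renderer: str = "surface"
    roi_margin_px: int = 8
    intensity_transform: str = "auto"
    drr_tone_scale: float | None = None
    saturation_exclude: float | None = None

    def __post_init__(self) -> None:
        if self.bounds_mm <= 0 or self.bounds_deg <= 0:
            raise ValueError("pose bounds must be positive")
        npop = self.population or 10 * 7
        if self.global_budget and self.global_budget < npop:
            raise ValueError("global budget must cover the population size")


@dataclass
class RegistrationResult:
    """Final pose with objective value and per-stage traces."""

    pose: RigidPose
    objective: float
    initial_objective: float
    traces: dict = field(default_factory=dict)
    converged: bool = True
    model: object = None
    renderer: str = "surface"


def pose_from_params(initial: RigidPose, params: np.ndarray) -> RigidPose:
    """[dx, dy, dz (mm), rx, ry, rz (deg)] applied around the initial pose."""
    p = np.asarray(params, float)
    dR = Rotation.from_euler("xyz", p[3:], degrees=True).as_matrix()
    return RigidPose(dR @ initial.rotation, initial.translation + p[:3])


# ---------------------------------------------------------------------------
# Derivative-free optimizers
# ---------------------------------------------------------------------------

def crs_maximize(f, lower: np.ndarray, upper: np.ndarray, budget: int,
                 rng: np.random.Generator, population: int | None = None,
                 x0: np.ndarray | None = None
                 ) -> tuple[np.ndarray, float, list]:
    """Controlled random search with local mutations (CRS2-LM), maximizing.

    Maintains a population of feasible points; each iteration reflects a
    random simplex anchored at the current best through its centroid, and on
    failure retries a randomized reflection about the best point (the local
    mutation).  Deterministic given ``rng``.
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    d = len(lower)
    n = population or 10 * (d + 1)
    if budget < n:
        raise RegistrationError("global budget smaller than CRS population")
    pts = rng.uniform(lower, upper, (n, d))
    if x0 is not None:
        pts[0] = np.clip(np.asarray(x0, float), lower, upper)
    vals = np.array([f(p) for p in pts])
    if not np.any(np.isfinite(vals)):
        raise RegistrationError("no valid objective evaluation in population")
    evals = n
    trace = [float(np.nanmax(vals))]

    def record() -> None:
        trace.append(max(trace[-1], float(np.nanmax(vals))))

    while evals < budget:
        ibest = int(np.nanargmax(vals))
        iworst = int(np.nanargmin(vals))
        others = rng.choice(n, size=d, replace=False)
        simplex = np.vstack([pts[ibest], pts[others]])
        centroid = simplex[:d].mean(axis=0)
        trial = np.clip(2.0 * centroid - simplex[d], lower, upper)
        v = f(trial)
        evals += 1
        if v > vals[iworst]:
            pts[iworst] = trial
            vals[iworst] = v
        elif evals < budget:
            w = rng.uniform(0.0, 1.0, d)
            mut = np.clip((1.0 + w) * pts[ibest] - w * trial, lower, upper)
            v2 = f(mut)
            evals += 1
            if v2 > vals[iworst]:
                pts[iworst] = mut
                vals[iworst] = v2
        record()
    ibest = int(np.nanargmax(vals))
    return pts[ibest].copy(), float(vals[ibest]), trace


def nelder_mead_maximize(f, x0: np.ndarray, lower: np.ndarray,
                         upper: np.ndarray, step: float, xatol: float,
                         fatol: float, max_evals: int
                         ) -> tuple[np.ndarray, float, list, bool]:
    """Bounded Nelder-Mead refinement returning the best-seen point."""
    x0 = np.clip(np.asarray(x0, float), lower, upper)
    best = {"x": x0.copy(), "v": -np.inf, "lo": np.inf, "hi": -np.inf}
    trace = []

    def neg(p):
        v = f(p)
        if v > best["v"]:
            best["v"] = v
            best["x"] = np.asarray(p, float).copy()
        best["lo"] = min(best["lo"], v)
        best["hi"] = max(best["hi"], v)
        trace.append(best["v"])
        return -v

    simplex = np.vstack([x0] + [x0 + step * e for e in np.eye(len(x0))])
    simplex = np.clip(simplex, lower, upper)
    minimize(neg, x0, method="Nelder-Mead",
             bounds=Bounds(lower, upper),
             options={"initial_simplex": simplex, "xatol": xatol,
                      "fatol": fatol, "maxfev": max_evals, "disp": False})
    # a perfectly flat objective gives the simplex nothing to work with
    converged = best["hi"] > best["lo"]
    return best["x"], best["v"], trace, converged


# ---------------------------------------------------------------------------
# Pose-level optimizer wrappers
# ---------------------------------------------------------------------------

def _bounds(config: RegistrationConfig) -> tuple[np.ndarray, np.ndarray]:
    b = np.array([config.bounds_mm] * 3 + [config.bounds_deg] * 3)
    return -b, b


def optimize_global(objective, initial: RigidPose,
                    config: RegistrationConfig) -> RigidPose:
    """CRS2-LM over the bounded pose box around ``initial`` (half-res stage)."""
    lower, upper = _bounds(config)
    rng = np.random.default_rng(config.seed)
    x, _, _ = crs_maximize(lambda p: objective(pose_from_params(initial, p)),
                           lower, upper, config.global_budget, rng,
                           config.population, x0=np.zeros(6))
    return pose_from_params(initial, x)


def optimize_local(objective, start: RigidPose, config: RegistrationConfig
                   ) -> tuple[RigidPose, bool]:
    """Nelder-Mead refinement from ``start``; returns (pose, converged)."""
    lower, upper = _bounds(config)
    x, _, _, ok = nelder_mead_maximize(
        lambda p: objective(pose_from_params(start, p)),
        np.zeros(6), lower, upper, config.local_step,
        config.local_xatol, config.local_fatol, config.local_max_evals)
    return pose_from_params(start, x), ok


# ---------------------------------------------------------------------------
# Image-based registration
# ---------------------------------------------------------------------------

def _apply_transform(img: np.ndarray, transform: str) -> np.ndarray:
    """Optional detector linearization of an actual image crop.

    'log' treats the image as an inverted-exposure radiograph
    (display = S (1 - exp(-attenuation/s))) and maps it back to a quantity
    proportional to the attenuation line integral, so that DRRs can be
    compared in their native domain.  The display ceiling is taken from the
    crop's maximum; transmissions are floored to keep saturated metal finite.
    """
    if transform == "none":
        return img
    if transform != "log":
        raise ValueError(f"unknown intensity transform {transform!r}")
    ceiling = img.max() * (1.0 + 1e-9) + 1e-12
    trans = np.clip(1.0 - img / ceiling, 1e-4, 1.0)
    return -np.log(trans)


class _ViewContext:
    """Cropped working region of one view with precomputed actual gradients.

    The crop is sized from the model's bounding radius, the pose bounds and
    the mask radius, so every pose inside the search box projects into it;
    restricting the similarity to this region is what makes desk-scale
    registration tractable.
    """

    def __init__(self, cam: PinholeCamera, actual: np.ndarray,
                 center_world: np.ndarray, radius_mm: float,
                 config: RegistrationConfig,
                 transform: str = "none",
                 saturation_exclude: float | None = None) -> None:
        rows, cols = cam.image_shape
        uv = cam.project_to_pixels(center_world[None, :])[0]
        f = cam.focal_point
        mag = f[2] / max(f[2] - center_world[2], 1e-6)
        rad_px = ((radius_mm + config.bounds_mm) * mag / cam.pixel_pitch
                  + config.dynamic_radius_px + config.roi_margin_px)
        r0 = int(np.floor(uv[1] - rad_px)) // 2 * 2
        c0 = int(np.floor(uv[0] - rad_px)) // 2 * 2
        r1 = int(np.ceil(uv[1] + rad_px)) // 2 * 2 + 2
        c1 = int(np.ceil(uv[0] + rad_px)) // 2 * 2 + 2
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, rows // 2 * 2), min(c1, cols // 2 * 2)
        if r1 - r0 < 8 or c1 - c0 < 8:
            raise RegistrationError("model projects outside the image")
        self.cam_full = cam.cropped(r0, c0, r1 - r0, c1 - c0)
        crop = np.asarray(actual, float)[r0:r1, c0:c1]
        self.act_full = _apply_transform(crop, transform)
        self.grad_full = sobel_gradients(self.act_full)
        self.cam_half = self.cam_full.scaled(0.5)
        self.act_half = downsample_half(self.act_full)
        self.grad_half = sobel_gradients(self.act_half)
        # optional exclusion of detector-saturated pixels (radiopaque metal)
        self.sat_full = None
        self.sat_half = None
        if saturation_exclude is not None:
            keep = crop < saturation_exclude * crop.max()
            self.sat_full = MaskImage(keep, "fixed")
            # conservative at half resolution: all four pixels must be kept
            self.sat_half = MaskImage(
                downsample_half(keep.astype(float)) >= 0.999, "fixed")

    def saturation_mask(self, stage: str) -> MaskImage | None:
        return self.sat_half if stage == "half" else self.sat_full

    def cam(self, stage: str) -> PinholeCamera:
        return self.cam_half if stage == "half" else self.cam_full

    def grads(self, stage: str) -> GradientPair:
        return self.grad_half if stage == "half" else self.grad_full


_SILHOUETTE_SUPERSAMPLE = 4


def _render_matching(model, pose: RigidPose, cam: PinholeCamera,
                     renderer: str, tone: float | None = None) -> np.ndarray:
    """Virtual image for similarity scoring.

    Silhouettes are rasterized on an oversampled grid and block-averaged
    into fractional pixel coverage: the soft edge localizes the outline at
    sub-pixel precision, which a hard pixel-center silhouette cannot (4x4
    sub-rays per pixel, the partial-coverage appearance of an opaque part).
    DRRs are optionally tone-mapped with a saturating exposure response;
    ``tone`` is the absolute attenuation scale of that response (held fixed
    across poses so the mapping does not drift with the rendered maximum).
    """
    if renderer == "silhouette":
        s = _SILHOUETTE_SUPERSAMPLE
        fine = render_silhouette(model, pose, cam.scaled(float(s))
                                 ).astype(float)
        rows, cols = cam.image_shape
        return fine[:rows * s, :cols * s].reshape(
            rows, s, cols, s).mean(axis=(1, 3))
    img = render_virtual(model, pose, cam, renderer)
    if tone is not None:
        img = 1.0 - np.exp(-img / tone)
    return img


def _view_score(ctx: _ViewContext, model, pose: RigidPose, renderer: str,
                stage: str, mask: MaskImage | None,
                tone: float | None = None) -> float:
    virt = _render_matching(model, pose, ctx.cam(stage), renderer, tone)
    gv = sobel_gradients(virt)
    ga = ctx.grads(stage)
    sat = ctx.saturation_mask(stage)
    if sat is not None:
        mask = sat if mask is None else mask.combine(sat)
    return 0.5 * (ngc(ga.gx, gv.gx, mask) + ngc(ga.gy, gv.gy, mask))


def _stereo_score(ctxs: dict, model, pose: RigidPose, renderer: str,
                  stage: str, masks: dict,
                  tone: float | None = None) -> float:
    try:
        return float(np.mean([
            _view_score(ctxs[v], model, pose, renderer, stage,
                        masks.get(v), tone)
            for v in ("left", "right")]))
    except (SimilarityError, ProjectionError):
        return -1.0     # degenerate pose inside the search box scores worst


def _projection_support(model, pose: RigidPose, cam: PinholeCamera,
                        renderer: str) -> np.ndarray:
    if renderer == "silhouette":
        return render_silhouette(model, pose, cam)
    return render_virtual(model, pose, cam, "drr") > 0.0


def _run_two_stage(ctxs: dict, model, initial: RigidPose,
                   config: RegistrationConfig, renderer: str,
                   fixed_full: dict, fixed_half: dict,
                   tone: float | None = None) -> RegistrationResult:
    lower, upper = _bounds(config)
    traces = {}

    if tone is not None:
        # freeze the tone-mapping scale from the initial pose's rendering
        ref = max(render_virtual(model, initial, ctxs[v].cam_full, "drr").max()
                  for v in ("left", "right"))
        tone = tone * ref if ref > 0 else None

    # --- stage 1: global CRS at half resolution (fixed mask only) ---------
    if config.global_budget > 0:
        rng = np.random.default_rng(config.seed)
        fg = lambda p: _stereo_score(ctxs, model, pose_from_params(initial, p),  # noqa: E731
                                     renderer, "half", fixed_half, tone)
        xg, _, traces["global"] = crs_maximize(
            fg, lower, upper, config.global_budget, rng, config.population,
            x0=np.zeros(6))
    else:
        xg = np.zeros(6)
    mid = pose_from_params(initial, xg)

    # --- stage 2: dynamic mask from the stage-1 pose, full resolution -----
    masks = {}
    for view in ("left", "right"):
        support = _projection_support(model, mid, ctxs[view].cam_full, renderer)
        dyn = make_dynamic_mask(support, config.dynamic_radius_px)
        mask = dyn if fixed_full.get(view) is None \
            else dyn.combine(fixed_full[view])
        if mask.data.sum() < 16:
            raise RegistrationError(
                "empty masked region: fixed mask excludes the whole ROI")
        masks[view] = mask
    fl = lambda p: _stereo_score(ctxs, model, pose_from_params(initial, p),  # noqa: E731
                                 renderer, "full", masks, tone)
    v_start = fl(xg)
    xl, vbest, traces["local"], ok = nelder_mead_maximize(
        fl, xg, lower, upper, config.local_step, config.local_xatol,
        config.local_fatol, config.local_max_evals)
    return RegistrationResult(pose=pose_from_params(initial, xl),
                              objective=vbest, initial_objective=v_start,
                              traces=traces, converged=ok, model=model,
                              renderer=renderer)


def _make_contexts(pair: RadiographPair, initial: RigidPose, radius_mm: float,
                   config: RegistrationConfig,
                   transform: str = "none",
                   saturation_exclude: float | None = None) -> dict:
    return {view: _ViewContext(pair.calibration.camera(view),
                               pair.image(view), initial.translation,
                               radius_mm, config, transform,
                               saturation_exclude)
            for view in ("left", "right")}


def register_implant(model: SurfaceModel | VolumeModel, pair: RadiographPair,
                     initial: RigidPose, config: RegistrationConfig
                     ) -> RegistrationResult:
    """Register an implant model: global at half resolution without the
    dynamic mask, then Nelder-Mead at full resolution with the dynamic mask
    recomputed once from the stage-one pose."""
    renderer = "silhouette" if config.renderer == "surface" else "drr"
    if isinstance(model, SurfaceModel) and renderer == "drr":
        raise RegistrationError("DRR rendering needs a volumetric model")
    if isinstance(model, VolumeModel) and renderer == "silhouette":
        raise RegistrationError("silhouette rendering needs a surface model")
    transform = config.intensity_transform
    tone = config.drr_tone_scale
    satex = config.saturation_exclude
    if transform == "auto":
        # implants are radiopaque: their radiographic appearance is a
        # saturated region with sharp outline edges, so both renderers are
        # matched against the display image, the DRR after tone mapping
        transform = "none"
        if renderer == "drr" and tone is None:
            tone = 0.01
    ctxs = _make_contexts(pair, initial, model.bounding_radius, config,
                          transform, satex)
    return _run_two_stage(ctxs, model, initial, config, renderer,
                          fixed_full={}, fixed_half={}, tone=tone)


def register_bone(bone: VolumeModel, pair: RadiographPair,
                  implant_results: list, initial: RigidPose,
                  config: RegistrationConfig) -> RegistrationResult:
    """Register a bone volume with the fixed mask built from the already
    registered implants: their dilated silhouettes are excluded at both
    stages (fixed at global, fixed AND dynamic at local)."""
    transform = config.intensity_transform
    if transform == "auto":
        transform = "log"      # bone intensities live in attenuation domain
    ctxs = _make_contexts(pair, initial, bone.bounding_radius, config,
                          transform, config.saturation_exclude)
    fixed_full, fixed_half = {}, {}
    for view in ("left", "right"):
        ctx = ctxs[view]
        excl_full = np.zeros(ctx.cam_full.image_shape, bool)
        excl_half = np.zeros(ctx.cam_half.image_shape, bool)
        for res in implant_results:
            excl_full |= _projection_support(res.model, res.pose,
                                             ctx.cam_full, res.renderer)
            excl_half |= _projection_support(res.model, res.pose,
                                             ctx.cam_half, res.renderer)
        fixed_full[view] = make_fixed_mask(excl_full, config.fixed_radius_px)
        fixed_half[view] = make_fixed_mask(
            excl_half, int(np.ceil(config.fixed_radius_px / 2)))
        if fixed_full[view].data.sum() < 16:
            raise RegistrationError(
                "implant silhouette covers the whole region; bone cannot "
                "be registered")
    cfg = replace(config, renderer="volume")
    return _run_two_stage(ctxs, bone, initial, cfg, "drr",
                          fixed_full, fixed_half)
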