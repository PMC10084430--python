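"""Normalized gradient cross-correlation similarity between projections.

The similarity between an actual radiograph and a virtual projection is the
average over the horizontal and vertical Sobel gradient channels of their
zero-mean normalized cross-correlation (NCC), restricted to an optional
inclusion mask, and averaged over the two stereo views.  NCC is invariant to
affine intensity rescaling of either image, which is why CT intensities and
DRR attenuation sums can be compared without a common intensity scale.

Channel and view averaging use equal weights, so the nesting order of the
means is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import RigidPose
from .models import SurfaceModel, VolumeModel
from .projection import MaskImage, RadiographPair, render_drr, render_silhouette


class SimilarityError(ValueError):
    """Degenerate similarity evaluation (empty mask, zero variance)."""


@dataclass
class GradientPair:
    """Horizontal (gx) and vertical (gy) Sobel responses of one image."""

    gx: np.ndarray
    gy: np.ndarray


def sobel_gradients(image: np.ndarray) -> GradientPair:
    """Standard 3x3 Sobel gradients with reflective border handling.

    On a unit horizontal ramp the interior gx response is 8 (the kernel's
    weight sum), the conventional un-normalized Sobel scaling.
    """
    img = np.asarray(image, float)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise SimilarityError("image must be at least 3x3 for Sobel gradients")
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    return GradientPair(gx, gy)


def ngc(a: np.ndarray, b: np.ndarray, mask: MaskImage | np.ndarray | None = None
        ) -> float:
    """Zero-mean normalized cross-correlation over the masked pixels, in [-1, 1]."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise SimilarityError("image shapes differ")
    if mask is not None:
        m = mask.data if isinstance(mask, MaskImage) else np.asarray(mask, bool)
        if m.shape != a.shape:
            raise SimilarityError("mask shape differs from images")
        a = a[m]
        b = b[m]
    else:
        a = a.ravel()
        b = b.ravel()
    if a.size < 2:
        raise SimilarityError("fewer than 2 pixels in the masked region")
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt(a @ a)
    nb = np.sqrt(b @ b)
    if na <= 0 or nb <= 0:
        raise SimilarityError("zero variance within the masked region")
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))


def gradient_similarity(actual: np.ndarray, virtual: np.ndarray,
                        mask: MaskImage | np.ndarray | None = None) -> float:
    """Mean of the horizontal and vertical gradient NCCs between two images."""
    ga = sobel_gradients(actual)
    gv = sobel_gradients(virtual)
    return 0.5 * (ngc(ga.gx, gv.gx, mask) + ngc(ga.gy, gv.gy, mask))


def render_virtual(model: SurfaceModel | VolumeModel, pose: RigidPose,
                   cam, renderer: str, scale: float = 1.0) -> np.ndarray:
    """Dispatch to silhouette (surface) or DRR (volume) rendering."""
    if renderer == "silhouette":
        return render_silhouette(model, pose, cam, scale).astype(float)
    if renderer == "drr":
        return render_drr(model, pose, cam, scale)
    raise ValueError(f"unknown renderer {renderer!r}")


def stereo_objective(model: SurfaceModel | VolumeModel, pose: RigidPose,
                     actual: RadiographPair,
                     masks: dict | None = None,
                     renderer: str = "drr",
                     scale: float = 1.0,
                     debug_dir: str | None = None) -> float:
    """Mean per-view gradient similarity of a posed model against a pair.

    ``masks`` optionally maps view name to a `MaskImage` at the working
    resolution.  With ``debug_dir`` set, gradient and per-pixel correlation
    images are dumped for inspection.
    """
    scores = []
    for view in ("left", "right"):
        cam = actual.calibration.camera(view)
        act = actual.image(view)
        if scale != 1.0:
            from .projection import downsample_half
            act = downsample_half(act)
        virt = render_virtual(model, pose, cam, renderer, scale)
        mask = None if masks is None else masks.get(view)
        scores.append(gradient_similarity(act, virt, mask))
        if debug_dir is not None:
            _dump_debug(Path(debug_dir), view, act, virt)
    return float(np.mean(scores))


def _dump_debug(outdir: Path, view: str, actual: np.ndarray,
                virtual: np.ndarray) -> None:
    """Write gradient and local-correlation images (visualization only)."""
    import tifffile

    outdir.mkdir(parents=True, exist_ok=True)
    ga = sobel_gradients(actual)
    gv = sobel_gradients(virtual)
    tifffile.imwrite(outdir / f"{view}_actual_gx.tif",
                     ga.gx.astype(np.float32))
    tifffile.imwrite(outdir / f"{view}_virtual_gx.tif",
                     gv.gx.astype(np.float32))
    # per-pixel windowed correlation map of the horizontal gradients
    corr = _local_correlation(ga.gx, gv.gx, 7)
    tifffile.imwrite(outdir / f"{view}_correlation_gx.tif",
                     corr.astype(np.float32))


def _local_correlation(a: np.ndarray, b: np.ndarray, win: int) -> np.ndarray:
    k = np.ones((win, win)) / win ** 2
    conv = lambda x: ndimage.convolve(x, k, mode="reflect")  # noqa: E731
    ma, mb = conv(a), conv(b)
    cov = conv(a * b) - ma * mb
    va = np.maximum(conv(a * a) - ma ** 2, 0)
    vb = np.maximum(conv(b * b) - mb ** 2, 0)
    denom = np.sqrt(va * vb)
    out = np.zeros_like(a)
    ok = denom > 1e-12
    out[ok] = cov[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)
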