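# autorsa

Automated, marker-free radiostereometric analysis (RSA) of joint-implant
migration. RSA quantifies the rigid-body pose of an implant or bone from a
calibrated stereo X-ray pair with sub-millimetre accuracy; it is the
standard tool for detecting early implant loosening. Classical RSA needs
tantalum beads implanted in the bone and manual work per image. This
package implements the automated alternative — 2D/3D rigid image
registration of patient-specific models to the stereoradiographs — next to
the classical marker method, and the statistics that turn per-exam poses
into migration accuracy.

**Who it is for**: researchers validating RSA methodology, and developers
of 2D/3D registration pipelines who need a fully seeded, ground-truthed
test bench.

## Methods

Given a stereo calibration (two pin-hole cameras sharing the calibration
cage frame: focal points **f**ℓ, **f**ᵣ and pixel-to-plane homographies),
a model *M* and a 6-DOF pose *T* = (R, **t**), each method renders a
virtual view per camera and maximizes the similarity

  S(T) = ½ Σ_views ½ [ NCC(∂ₓI, ∂ₓV(T)) + NCC(∂ᵧI, ∂ᵧV(T)) ]

where ∂ₓ, ∂ᵧ are 3×3 Sobel gradients of the actual image *I* and the
virtual projection *V*, and NCC is zero-mean normalized cross-correlation
over a masked region. Optimization is two-stage: a controlled random
search with local mutations (CRS2-LM) at half resolution, then Nelder–Mead
at full resolution with a dynamic region-of-interest mask.

- `surface`: *V* is the mesh silhouette (sub-pixel partial coverage).
- `volume`: *V* is a ray-cast DRR (exact per-voxel intersection lengths)
  of the synthetic volumetric implant (mesh interior filled with value
  3000 at 0.4 mm voxels), tone-mapped to the saturated appearance of
  radiopaque metal.
- `bone`: *V* is the DRR of a CT-style bone volume, matched in
  log-attenuation domain, with a fixed mask excluding the dilated
  silhouettes of the already-registered implants.
- `marker`: beads are detected (circular Hough + centroid refinement),
  triangulated (midpoint of the common ray perpendicular; its length is
  the crossing-line distance), summarized as the marker centroid, and
  rigid-body matched with a 0.35 mm mean-rigid-body-error gate.

Displacement series (5 baselines + 2 exams at each of 15 micrometer steps
from 10 µm to 5 mm) are analyzed as measured-minus-imposed errors after a
median-of-five baseline and a per-series total-least-squares axis fit, and
summarized as mean (SD) and Bland–Altman bias ± 1.96·SD limits of
agreement. A built-in synthetic phantom (asymmetric implant, textured
resected bone, intraosseous beads, two-source geometry at 40°/160 cm)
provides every input with exact ground truth.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

Register all three marker-free methods on a simulated noisy exam and
compare against ground truth:

```python
import numpy as np
from autorsa import (NoiseParams, RegistrationConfig, default_calibration,
                     make_phantom, register_bone, register_implant,
                     simulate_exam)
from autorsa.registration import pose_from_params

scene = make_phantom(seed=7)
calib = default_calibration()
exam = simulate_exam(scene, calib, noise=NoiseParams(), seed=42)

config = dict(bounds_mm=3, bounds_deg=3, global_budget=150, population=35,
              local_max_evals=600, dynamic_radius_px=4, fixed_radius_px=2)
start = pose_from_params(exam.implant_pose, [1, 0, 0, 1, 0, 0])  # 1 mm / 1 deg off

rs = register_implant(scene.implant, exam.pair, start,
                      RegistrationConfig(renderer="surface", **config))
rv = register_implant(scene.implant_volume, exam.pair, start,
                      RegistrationConfig(renderer="volume", **config))
rb = register_bone(scene.bone, exam.pair, [rv], exam.bone_pose,
                   RegistrationConfig(renderer="volume", **config))
for name, res, truth in (("surface", rs, exam.implant_pose),
                         ("volume", rv, exam.implant_pose),
                         ("bone", rb, exam.bone_pose)):
    err = res.pose.translation - truth.translation
    print(f"{name:8s} error mm: {np.round(err, 3)}  objective {res.objective:.3f}")
```

Output:

```
surface  error mm: [-0.     0.     0.001]  objective 0.997
volume   error mm: [-0.06  -0.012  0.061]  objective 0.952
bone     error mm: [ 0.005 -0.006 -0.016]  objective 0.870
```

Each line is the translation error (x, y, z mm) of the recovered pose on
the quarter-scale phantom, followed by the final masked gradient-
correlation score. The silhouette and bone-DRR methods land within
microns-to-tens-of-microns of the truth; the volume method carries the
~half-voxel geometry error of its binary 0.4 mm model, mirroring its
standing relative to the silhouette method in practice.

The command line mirrors the library
(`autorsa phantom/simulate/calibrate/voxelize/render/register/markers/analyze`);
run `autorsa --help`.

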