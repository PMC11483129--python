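# ufiberlab

Depth-resolved quantification of superficial white matter (SWM) U-fiber
density and its association with rhythmic tapping behavior — implemented
end to end on synthetic phantoms and simulated cohorts with known ground
truth.

## The problem

Short-range association fibers (U-fibers) run tangentially just below the
gray/white matter boundary, while long-range projection and commissural
fibers enter the cortex roughly perpendicular to it.  Standard diffusion
MRI summaries mix the two.  This package implements a geometry-driven
decomposition:

1. **Laplace potential.**  Solve ∇²φ = 0 over the white matter shell with
   φ = 0 on the gray/white boundary and φ = 1 on the ventricles.  On the
   concentric-sphere phantom the closed form
   φ(r) = (1/r − 1/b)/(1/a − 1/b) provides an exact oracle.
2. **Laminar streamlines.**  One trajectory per surface vertex follows
   the normalized gradient of φ inward with 0.1 mm Euler steps, truncated
   at 5 mm.  The trajectory arc length is a controlled depth coordinate
   below the cortex.
3. **Fixel AFD decomposition.**  Each voxel's fiber orientation
   distribution (even spherical harmonics, lmax 8) is segmented into
   fixels (direction + apparent fiber density, AFD = the FOD lobe
   integral).  At depths 0, 0.5, 1, 1.5, 2 mm along each streamline,

       total_AFD = Σ fixel AFD
       par_AFD   = AFD of the single fixel parallel to the streamline
                   (axial angle < 45°, else 0)
       tan_AFD   = total_AFD − par_AFD      (the U-fiber proxy)

4. **Behavior.**  A synchronization–continuation tapping task (SCT)
   simulator (linear phase correction + two-level timekeeper/motor model)
   produces event streams scored by four metrics: absolute asynchrony,
   constant error, temporal variability, and lag-1 autocorrelation of
   produced intervals.
5. **Anatomo-behavioral statistics.**  Vertex-wise Pearson correlation
   (SWM_i = β0 + β1·metric), max-extent cluster correction by behavior
   permutation, ROI aggregation, and ridge-regularized CCA between the
   full behavioral matrix and all vertex AFDs, with permutation
   confidence intervals on the loadings.

The synthetic cohort generator plants a known inter-subject correlation ρ
between regional tangential density and asynchrony magnitude, so every
stage is testable by parameter recovery without any external data.

## Worked example

```python
import numpy as np
from ufiberlab import (make_phantom, solve_laplace, gradient_field,
                       trace_streamlines, generate_cohort, sample_cohort,
                       summarize_subject, vertexwise_correlation)

ph = make_phantom()                       # spheres: outer 20 mm, inner 10 mm
field = solve_laplace(ph, tol=1e-7)
grad, _ = gradient_field(field)
streams = trace_streamlines(ph, grad)     # one per surface vertex

fields, sessions, truth = generate_cohort(
    n_subjects=200, rho_planted=-0.6, roi_id=1, phantom=ph, seed=11)
tan = sample_cohort(fields, streams).metric("tan")[:, :, 3]   # 1.5 mm depth

summaries = [summarize_subject(s) for s in sessions]
beh = np.array([np.mean([s.value("auditory", t, "mean_abs_asynchrony")
                         for t in (650.0, 750.0)]) for s in summaries])
res = vertexwise_correlation(tan, beh, depth_mm=1.5)
roi = ph.roi_labels == truth.roi_id
print(f"planted rho = {truth.rho_planted:+.2f}, "
      f"mean vertex r in ROI = {np.nanmean(res.r_map[roi]):+.3f}")
```

Output:

```
planted rho = -0.60, mean vertex r in ROI = -0.584
```

Subjects with denser tangential (U-fiber) AFD in the planted region tap
with asynchronies closer to zero; the vertex-wise correlation recovers
the planted association (slightly attenuated by the per-voxel AFD noise
and behavioral measurement noise).

The full pipeline — including cluster correction, ROI summaries, and the
regularized CCA — runs from a single config:

```bash
ufiberlab demo --out config.yaml
ufiberlab run --config config.yaml
```

which writes every intermediate artifact (NIfTI masks and potential,
GIFTI surface, TCK streamlines, fixel directory, CSV tables) plus a JSON
manifest with per-output hashes; re-running the same config reproduces
bitwise-identical outputs.

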