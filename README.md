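# mvring — automated mitral-valve vortex-ring extraction from 4D-flow MRI

During left-ventricular (LV) filling, the transmitral inflow jet rolls up
into a toroidal vortex ring at the tips of the mitral valve — once during
early diastole (E wave) and once during atrial contraction (A wave).  The
ring's geometry and energetics are candidate markers of diastolic function,
but reading them off time-resolved three-directional phase-contrast MRI
("4D flow") by eye is slow and subjective.  `mvring` extracts the
mitral-valve (MV) vortex ring automatically from a velocity volume series
plus an LV segmentation, tracks it over the cardiac cycle, and quantifies
it — and ships a ground-truthed synthetic vortex-ring phantom for
validating every step.

## Method

Given per-frame velocity volumes **v** (m/s) and binary LV masks, the
pipeline runs four steps inside a bounding box around the LV:

1. **Divergence-free field.** By the Helmholtz–Hodge decomposition,
   v = d + r + h with ∇×d = 0, ∇·r = 0 and h harmonic.  Only the rotational
   part r matters for vortex detection, so r = ∇×Ψ is obtained from the
   curl–curl Poisson problem ∇×∇×Ψ = ∇×v with Ψ|∂Ω = 0 (which makes r
   tangential to the box), discretized with second-order finite differences
   and solved by minimum-norm least squares (LSMR).
2. **Vortex candidates.** Q = ½(‖Ω‖² − ‖S‖²) is computed from r (Ω spin,
   S strain-rate tensor); voxels with Q > 0 are vortical.  The Q series is
   smoothed (spatial Gaussian + median, cyclic temporal Gaussian), masked,
   and thresholded with frame-specific thresholds
   thr_Q,i = (1/N) Σₙ Q_i(r_Qn^max) built from the per-frame Q-maxima
   locations.  The first principal component w₁ of the thresholded Q series
   scores each supra-threshold region with a candidate factor
   f_c = Σ w₁ / d_max; at most two candidates per frame survive.
3. **Core tracing and tracking.** From the maximum-Q point of a candidate,
   a predictor–corrector scheme grows the core line: predictor along the
   local vorticity direction, corrector to the Q maximum on the
   perpendicular plane (pattern search).  Closed lines are tori; open lines
   are classified as U- or bracket-shaped by their turning angle.  Tracing
   starts at the two peaks of the max-Q curve and membership propagates
   frame-to-frame only while centroid displacement and major-axis change
   stay small.
4. **Region growing.** Streamlines seeded at core voxels and their
   26-neighborhood are integrated on r until Q ≤ 0; traversed voxels form
   the ring region, pruned by iteratively removing voxels with fewer than
   eight 26-neighbors.

Per detected frame, six parameters are reported: volume (mL), maximum
(95th-percentile) and mean vorticity magnitude (s⁻¹), absolute (mJ) and
volume-normalized (J/m³) kinetic energy at blood density ρ = 1060 kg/m³,
angle α of the ring plane to the LV long axis, and the circularity index
CI = short/long fitted core axis.  Segmentation-sensitivity experiments
(slice subsampling, static end-diastolic mask, one-voxel erosion/dilation)
and agreement statistics (Cohen's κ, Dice) are built in.

## Worked example

The synthetic phantom provides a fully ground-truthed dataset at the
acquisition scale of a clinical protocol (64 × 64 × 40 voxels at
1.8 × 2.5 × 4 mm³, 30 cardiac frames): a Biot–Savart vortex ring
(R = 16 mm, Gaussian core a = 4 mm) just below the base of an ellipsoidal
LV, pulsed over an E window (frames 3–8) and an A window (frames 14–19),
contaminated with a random gradient (rotation-free) field and Gaussian
velocity noise.

```python
import numpy as np
from mvring.io import RunConfig
from mvring.pipeline import extract
from mvring.synthetic import default_phantom

velocity, masks, truth = default_phantom(seed=1)
result = extract(velocity, masks, RunConfig(seed=1))

print(np.flatnonzero(result.presence(30)))
# [ 3  4  5  6  7  8 14 15 16 17 18 19]   <- matches truth.present exactly

from mvring.params import peak_summaries
peaks = peak_summaries(result.params)
print({k: round(peaks["E"][k], 2) for k in ("vol", "vort_mean", "ekin_abs", "alpha", "ci")})
# {'vol': 7.16, 'vort_mean': 183.4, 'ekin_abs': 0.9, 'alpha': 89.39, 'ci': 0.97}
```

The detected ring frames coincide with the frames of non-zero ring
amplitude; the E-period peaks read: ring volume 7.16 mL, mean vorticity
183 s⁻¹, kinetic energy 0.9 mJ, ring plane 89.4° to the long axis (truth:
90°, the ring lies in the short-axis plane) and circularity 0.97 (truth: a
perfect circle).  The same run can be driven from the shell:

```bash
mvring simulate --out scratch/phantom --seed 1
mvring extract --velocity 'scratch/phantom/frame*_vx.nii.gz' \
               --mask 'scratch/phantom/mask*.nii.gz' --out scratch/run
mvring experiment erode --velocity ... --mask ... --out scratch/exp
```

## Layout

```
src/mvring/
  types.py      # Grid, series, cores, regions, parameters
  io.py         # NIfTI/CSV/JSON I/O, run configuration
  synthetic.py  # Biot-Savart vortex-ring phantom with analytic truth
  hodge.py      # divergence-free projection (curl-curl, LSMR)
  qcrit.py      # Q fields, smoothing, thresholds, candidates, PCA
  tracing.py    # predictor-corrector core tracing + temporal tracking
  region.py     # streamline region growing + pruning
  params.py     # the six ring parameters and peak summaries
  validation.py # mask perturbations, Dice, Cohen's kappa
  pipeline.py   # end-to-end orchestration
  cli.py        # `mvring` command-line interface
```
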