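# Methods

This note records the models, numerical choices and known limitations of
`mvring`, at the level of detail a maintainer needs to change them safely.

## Units and conventions

Velocities are SI (m/s) internally; cm/s inputs are converted on load.
Lengths and positions are millimeters; derivative quantities use spacing in
meters, so vorticity is s⁻¹ and Q is s⁻².  Voxel indices are 0-based,
voxel centers sit at `origin + index * spacing`, boxes are half-open.
Reported parameters use mL, s⁻¹, mJ, J/m³ and degrees.

## Divergence-free projection

The rotational part r of the velocity field is represented as r = ∇×Ψ and
obtained from ∇×∇×Ψ = ∇×v with all three components of Ψ clamped to zero on
the one-voxel boundary shell of the LV bounding box.  The clamp makes the
normal component of r vanish identically on each box face (the in-face
derivatives of a zero field are zero), i.e. r is tangential to the boundary.

Finite differences are second-order central in the interior and one-sided
second-order at faces; the sparse operator is assembled from 1D difference
matrices via Kronecker products and therefore agrees with
`numpy.gradient(..., edge_order=2)` to machine precision.  Because the 1D
operators act on different axes, they commute exactly, so the discrete curl
of a discrete gradient is exactly zero: gradient-type (rotation-free)
contamination never enters the right-hand side ∇×v and is rejected at
solver precision.

The curl–curl operator is rank-deficient (discrete gradients span its null
space), so the system is solved with LSMR started from zero, which
converges to the minimum-norm least-squares solution; on boxes small enough
for a dense pseudo-inverse, the iterative and dense minimum-norm solutions
agree in their curl to ~1e-12.  The solver operator is assembled once per
box geometry and reused across all cardiac frames (per-frame solves are
independent).  Defaults: relative tolerance 1e-8 for standalone solves,
1e-6 in the pipeline (velocity noise in measured data is orders of
magnitude larger), iteration cap 10× the number of unknowns.

A caveat that matters for validation: on a bounded box, the divergence-free
part *with tangential boundary conditions* differs from the unbounded
divergence-free field by a harmonic correction.  For a vortex ring whose
far field the box crops, that correction is a few percent of the interior
field; it falls below 5% only when the box faces are ≳ 6 ring radii away.
Tests that compare the projection against a known free-space field use such
generous boxes.

## Q analysis

Q = ½(‖Ω‖²_F − ‖S‖²_F) is computed from the divergence-free field.  The Q
series is smoothed in a fixed order — per-frame Gaussian (σ = 1 voxel per
axis), per-frame 3³ median, then a per-voxel temporal Gaussian (σ = 1
frame) with cyclic boundary, since the cardiac cycle is periodic — and the
LV masks are applied afterwards.  The smallest standard kernels were chosen
because the filters only need to suppress voxel noise and single-frame
flicker, not reshape the vortex.

Frame thresholds average, for each frame i, the Q_i values at all N
per-frame argmax locations.  With a single stationary vortex (as in the
phantom) all argmax locations coincide and the threshold degenerates
toward the frame maximum, leaving only small near-peak caps as candidate
regions; with clinical data the maxima wander (atrium, outflow tract) and
the thresholds sit well below the maxima.  The tracer only needs a seed
point inside the ring, so the degeneracy is harmless, but candidate-region
*extent* is not meaningful in the single-vortex setting.

**Vortex-frame window.**  The two largest local maxima of the max-Q curve
separated by ≥ 3 frames define the E and A peaks.  The window is the cyclic
arc between the peaks that avoids the global minimum of the curve (the
quiet systolic phase), extended outward at both ends while the curve stays
above `window_factor` (default 0.5) × the mean threshold.  Frames between
the peaks are always kept: transmitral inflow pauses during diastasis, and
cutting the window there would orphan the A wave.  A curve with a single
local maximum duplicates it as both peaks; a constant positive curve
selects all frames.

**PCA scoring.**  The voxels × vortex-frames matrix of thresholded Q
(per-voxel temporal mean removed) is decomposed by SVD; w₁ is the first
left singular vector, sign-fixed to be non-negative at the global Q
maximum.  Candidate factors f_c = Σ_region w₁ / d_max use the long-axis
projected distance d_max to the w₁ maximum, floored at 1 mm to keep the
ratio finite for regions at the maximum itself.  Candidates with
d_max ≥ 2× the minimum d_max are discarded; the two highest factors
survive.  Components below 5 voxels are dropped as sub-smoothing-scale
debris; 26-connectivity is used throughout because vortex shells are thin
and diagonal-connected at 4 mm slices.

## Core tracing

Trilinear interpolation serves Q and vorticity at sub-voxel positions; the
vorticity used for tracing is the curl of the divergence-free field
(analytically identical to the full field's curl, discretely smoother).
Steps: predictor = current + step × unit vorticity (step = 0.5 × minimum
spacing); corrector maximizes Q by compass pattern search on the plane
through the predictor perpendicular to the vorticity, mesh contracting ×0.5
from 1× to 0.1× the minimum spacing, confined to a 2× maximum-spacing
radius so the search cannot jump to a neighboring vortex.  The corrector
accepts only improvements, so interpolated Q never decreases from predictor
to corrector, and every retained point has Q > 0.

Stopping: a trace closes when the corrector returns within `close_tol`
(= step) of *any* earlier point at least `min_loop_steps` (6) back — the
start point is the special case — and the pre-loop lead-in is trimmed; this
catches rings whose spiral lap narrowly misses the seed.  A trace is stuck
when the step displacement falls below 0.1 × step, when it revisits a prior
point within that tolerance, or when the interpolated vorticity magnitude
is below 1e-12; it also ends on Q ≤ 0 or after 500 steps.  An open forward
trace is continued backward (negated vorticity) and may close by fusing
with the forward line.

Open lines are classified by turning angle, computed as the absolute
cumulative signed turning of the polyline projected on its best-fit plane
(signed turning keeps noise wiggles from accumulating): ≥ 150° is U-shaped;
two open lines whose endpoint pairs face each other within 2× the maximum
spacing and whose combined turning reaches 150° form a bracket.  The U test
precedes the bracket test, mirroring the decision order of the stop-criteria
logic.

**Temporal tracking.**  Tracing seeds at the two max-Q peaks (membership
there requires a recognizable shape), then sweeps outward: E-peak backward
to the window start and forward to the inter-peak minimum; A-peak forward
to the window end and backward to that minimum.  With two traced cores in a
frame (and no bracket), the one whose centroid is nearer the previous
frame's ring survives.  Membership propagates only while the centroid moves
≤ 10 mm and the fitted major axis changes ≤ 50% between consecutive frames
— these two thresholds operationalize the otherwise qualitative "small
distance and small deformation" requirement and are what terminates the
ring when the flow decays into incoherence during diastasis.

## Region growing

Streamlines are seeded at the voxels containing core points plus their
26-neighborhood (inside the mask), and integrated in both directions with
RK4 on the *unit-normalized* divergence-free field — the region is a
geometric object, so arc length, not residence time, parameterizes the
path (step 0.5 × minimum spacing, ≤ 1000 steps per direction).  A
streamline ends when interpolated Q ≤ 0 or it leaves the mask; every voxel
whose cell it enters is marked, and the final region keeps marked voxels
with Q > 0 at their center inside the mask.

Termination deliberately uses the *unsmoothed* Q of the divergence-free
field: the smoothed Q > 0 tube is roughly twice as wide as the
instantaneous vortex (spatial blur plus temporal bleed) and inflates the
region accordingly; the smoothed field is reserved for thresholds,
candidates and tracing, where stability matters more than extent.

Pruning removes, in simultaneous sweeps until fixpoint, every voxel with
fewer than eight occupied 26-neighbors.  Simultaneous sweeps make the
result order-independent; the operation is monotone and idempotent.

## Parameters

Vorticity and kinetic energy use the full, un-decomposed velocity field;
only tracing and region growing use the divergence-free part.  The
"maximum" vorticity is the 95th percentile (linear interpolation between
order statistics) of the per-voxel vorticity magnitudes, robust to single
outlier voxels.  Kinetic energy assumes ρ = 1060 kg/m³;
relative = absolute / region volume, exactly.  α is the angle between the
total-least-squares core plane and the LV long axis, folded into [0°, 90°]
(a ring in the short-axis plane scores 90°).  CI is the ratio of the two
largest principal axis lengths of the core point cloud (axis length = 2 ×
maximum absolute projection, lengths sorted).  The long axis comes from the
configuration or, failing that, the first principal axis of the
end-diastolic mask, oriented from the wider (basal) end to the apex.
Peaks are reported per contiguous membership period, early diastolic first.

## Synthetic phantom

The phantom is a circular vortex filament discretized as a 64-gon,
regularized with the 3D-Gaussian (Winckelmans-type) kernel
q(ρ) = erf(ρ/√2) − ρ√(2/π)e^(−ρ²/2), σ = a/√2, which reproduces a
Lamb–Oseen core of radius a near the filament (peak vorticity Γ/(πa²)) and
is analytically divergence-free because the kernel depends only on the
distance to each segment.  The velocity gradient of every segment
contribution is differentiated in closed form, giving analytic Q, vorticity
and the {Q > 0} truth region without any discretization.

Defaults mirror the clinical acquisition scale: 64 × 64 × 40 voxels at
1.8 × 2.5 × 4 mm³, 30 frames; ring R = 16 mm, a = 4 mm, Γ = 0.02 m²/s
(center-line velocity ≈ 0.6 m/s at peak, transmitral range); E window
frames 3–8, A window frames 14–19 with amplitude sin(πk/(L+1)) ramps (zero
outside), A scaled to 0.7 of E — an E-dominant filling pattern; ellipsoidal
LV (semi-axes 26 × 26 × 40 mm) with the ring 16 mm toward the base, where
the mitral annulus sits; Gaussian velocity noise σ = 0.01 m/s (≈ 1% of a
100 cm/s velocity-encoding range); gradient contamination 0.05 m/s peak,
built as grad of a Gaussian-smoothed (σ = 4 voxels) white-noise scalar so
the true divergence-free part is exactly the clean ring field.  All
randomness flows from one seed.

What the phantom does *not* emulate: chamber-shaped geometry, moving walls
and valve leaflets, the atrial and outflow-tract vortices that make
clinical max-Q curves non-degenerate, voxel-averaged (partial-volume) MRI
sampling, phase noise and velocity aliasing.  Passing the phantom tests
therefore demonstrates the correctness of the numerics and the tracking
logic under realistic scale, noise and contamination — not clinical
performance.

## Known limitations

* At 4 mm slice spacing a 4 mm-core ring is under-resolved along z: the
  central-difference vorticity underestimates the analytic mean over the
  core by ~13% (point-sampled fields; the attenuation shrinks quadratically
  with spacing).  The reported vorticities inherit that bias; comparisons
  between runs at the same resolution are unaffected.
* The frame-threshold rule degenerates when one stationary vortex dominates
  every frame (see above); candidate extent is then nominal.
* Membership tracking is first-order (previous frame only); a single
  dropped frame splits a period.
* Streamline regions are Eulerian (instantaneous, frame-frozen fields);
  no pathline or Lagrangian coherent-structure analysis.
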