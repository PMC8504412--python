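# Methods

## The estimation problem

A cardiac-gated 4D flow acquisition yields, for each of M time frames, a
magnitude volume and three velocity-component volumes. The systolic flow
pulse arrives later at sites deeper in the arterial tree; the delay
between a site at vascular depth `r` (path length along the vessels from
the carotid root, in mm) and the root is `r / PWV`. Over the depth range
visible intracranially (50–300 mm) and physiological PWV (5–15 m/s) the
delays are 3–60 ms — a fraction of one time frame (47.5 ms at 20 frames
per 0.95 s cycle). No single pair of sites can resolve such a shift;
pooling thousands of cross-sections can.

The model treats every cross-section as observing one shared periodic
waveform `V(t)`, delayed by its transit time and corrupted by Gaussian
noise whose variance differs per site. With `V` parametrized by its
values at the frame times and interpolated linearly, maximum likelihood
reduces to weighted least squares over the joint parameter `(PWV, V)`:

    argmin Σ_i W_i Σ_j ( Ṽ(t_j − r_i/PWV; V) − v_ij )²,  W_i = area_i / scaling_i².

The weight model takes the measurement variance of a lumen-averaged,
SD-normalized waveform as proportional to `scaling²/area`: averaging over
a larger ROI suppresses noise linearly in pixel count, and the
normalization multiplies noise by `scaling = 1/SD`. Only the ratio of
weights matters — the argmin is invariant to any global positive
rescaling, which the suite asserts; any further normalization of the
weights is therefore immaterial.

### Assumptions

- One global PWV for the whole tree (no per-territory values).
- Waveform shape is conserved along the tree; only its phase shifts.
  Amplitude differences are removed by the SD normalization.
- Noise is independent Gaussian across sites and frames.
- The cardiac cycle is periodic, so the waveform is extended
  periodically.

## Conventions and numerical choices

**Periodic extension.** Delayed evaluation times `t_j − r/PWV` fall below
`t_1` for proximal frames; since the cycle repeats, `Ṽ` wraps with
period `T`, the segment between `t_M` and `t_1 + T` interpolating
`V(t_M) → V(t_1)`. The convention (and the time origin `t_1 = 0`) is
recorded in every fit's diagnostics. Frame times default to
`t_j = (j−1)·T/M`; `T` is taken from the recorded cardiac period, or
derived as `(t_M − t_1)·M/(M−1)` when only frame times are known.

**Optimizer.** L-BFGS-B over the `M+1` parameters, initial values
`PWV₀ = 10 m/s` and `V₀ =` weighted-mean waveform, stopping at relative
objective change `< 1e−10`, projected gradient `< 1e−8`, or 2000
iterations, with a lower bound of 0.1 m/s on PWV guarding against
non-physical steps. The objective is piecewise smooth (kinks where an
evaluation time crosses a knot); the default gradient is the exact
within-segment analytic gradient, which is orders of magnitude faster in
the Monte-Carlo harnesses. A forward-difference numerical gradient
(relative step 1e−6) is available via `gradient="numerical"` and the
suite asserts the two land on the same minimizer. Estimates are
insensitive to initialization (refits from 40 m/s or a zero waveform
move the estimate by < 0.5% on noisy phantoms); the profiled objective
can in principle be multimodal in PWV, so the fit is a local method and
the grid oracle (`profile_fit_oracle`, exact weighted linear solve for V
at each fixed PWV, ridge 1e−12 on singular normal equations) is exposed
as a safeguard (`--oracle-check`).

**Units.** Distances in mm (converted to m inside the objective), times
in seconds, PWV in m/s, velocities in cm/s, venc in cm/s.

**Normalization.** Waveforms are demeaned and scaled by `1/SD` with the
population SD (divisor M). The choice of divisor cancels in the
normalized waveform and rescales all weights by one constant, to which
the estimator is invariant.

## Imaging chain

- **CD angiogram**: temporal means of magnitude and of each velocity
  component; `θ = π‖v̄‖/venc` clipped to `[0, π/2]`; `CD = m̄ sin θ`.
  Component-wise averaging before taking the norm preserves
  directionality, as in standard PC-MRA practice.
- **Vessel enhancement**: multiscale Hessian eigenvalue filter with
  τ-regularized response (τ = 1), scales {0.5, 1, 1.5, 2} mm spanning
  intracranial artery radii, Gaussian derivatives with physical-unit
  scale normalization, reflected boundaries, response in [0, 1],
  maximum over scales. The threshold (2.5% of the global maximum,
  NaNs excluded) is applied to the filtered volume.
- **Centerline**: topology-preserving 3D thinning; 26-connectivity
  throughout; voxels classified by neighbor count (1 endpoint,
  2 interior, ≥3 junction); branches are maximal junction-free paths;
  dangling branches of < 3 voxels are pruned as thinning artifacts.
  Junction voxels belong to no branch and receive no cross-section; a
  one-voxel margin around junctions additionally avoids mixed-lumen
  ROIs.
- **Cross-sections**: direction from the two branch neighbors of each
  interior voxel; perpendicular plane of half-width 5 mm resampled at
  half-voxel pitch (2× upsampling, trilinear); lumen ROI at 50% of the
  CD peak within a 3 mm search disk, 8-connected component at the plane
  center; ROI-mean velocity vector per frame projected on the vessel
  direction. The waveform sign is oriented along net flow (temporal mean
  positive), which in an arterial tree orients every direction away from
  the root without needing distances first. Results are invariant to the
  arbitrary in-plane basis (asserted by test). The 5 mm half-width and
  3 mm search radius are sized to the largest intracranial arteries and
  are exposed as parameters.
- **Distances**: multi-source Dijkstra over the skeleton adjacency with
  physical Euclidean step lengths; per voxel the minimum over seeds is
  kept (the two carotid seeds of the in vivo setting); unreachable spurs
  are dropped. Cycles (Circle of Willis) are handled naturally by
  shortest paths. `main_routes_only` keeps, for each endpoint above a
  distance percentile (default: top quartile), the shortest path back to
  its seed — a programmatic counterpart of the manual main-routes
  re-extraction used as a robustness control. The pipeline snaps
  user-supplied seeds to the nearest centerline voxel within 5 mm;
  `assign_distances` itself requires exact centerline voxels.

## Phantoms: what they emulate, what they do not

The tabular generator draws depths uniformly from 50–300 mm, applies the
model's delays, adds Gaussian noise (SD 0.3 on unit-SD waveforms in the
reference conditions), and assigns ROI areas decreasing linearly from 12
to 2 mm² with depth to emulate proximal-to-distal caliber loss. In
*knot* mode the template exists only at the frame-time knots and is
interpolated with the estimator's own rule, so noise-free sets are
exactly model-consistent: these sets are generated already normalized
and are not re-standardized, because per-row re-normalization of
fractionally delayed linear interpolants introduces O(1%) row-scale
mismatch that would preclude exact-recovery checks. Noisy and
analytic-mode sets go through the same demean/SD normalization as the
imaging chain.

The volumetric phantom rasterizes a tube tree (default: 57 mm trunk
bifurcating into two ~60 mm arms, radii 2.4/1.8 mm, depths to ~117 mm in
a 48×48×180 grid at 0.69 mm) with plug flow along the local axis
following the template delayed by depth/PWV, bright lumen magnitude and
dim background, and velocities kept below venc (110 cm/s). Plug flow
isolates the delay signal the method exploits; an optional noise SD adds
Gaussian velocity noise.

Not modeled: k-space undersampling, phase wrapping/aliasing, eddy-current
phase offsets, gating jitter, sub-voxel partial volume beyond trilinear
sampling, parabolic profiles (available but not default). Passing tests
therefore demonstrate correctness of the algorithmic chain and its
statistical behavior under the stated noise model, not robustness to
MRI physics artifacts.

### Known systematic effects measured on the phantoms

- Voxelized skeleton paths overestimate true arc length (staircase
  effect): on the Y-tree the distance-vs-depth slope is ≈ 1.11, which
  propagates into a proportional PWV overestimate (the end-to-end
  estimate lands ≈ 13% high, within the 15% discretization budget).
- ROI pixels at the lumen edge mix lumen and background velocity
  (partial volume), attenuating the raw waveform by a uniform factor
  (≈ 9% on a 2.4 mm tube). The attenuation is multiplicative, so the SD
  normalization removes it; the suite asserts the shape error after
  rescaling stays below 2% of range.

## Problem sizes used in the test and acceptance harnesses

Exact recovery uses N = 200 noise-free sections; oracle agreement, 20
noisy fixtures of N = 200 against a 4–40 m/s grid at 0.1 m/s; noise
recovery, 100 replicates of N = 500 at each true PWV in
{6, 8, 10, 12, 16} m/s with refits from alternative initializations;
split-half consistency, 30 subjects of N = 300 with true PWV ~ U(7, 14);
group comparison, 50 repetitions of two 10-subject groups (centers 8 and
11 m/s, between-subject SD 1.5, N = 200 per subject, exact Wilcoxon
rank-sum for combined n ≤ 20). These sizes are scaled-down analogues of
an in vivo study (which sees thousands of cross-sections per subject)
chosen so the whole harness runs in minutes on one CPU.

## Limitations

- A single global PWV is estimated; regional stiffening is averaged out.
- Kissing vessels create false junctions that corrupt distal distances;
  no automatic correction is attempted (the main-routes control mitigates
  it, and the induced distance error is small when parallel branches are
  of similar caliber).
- The left/right minimum-distance rule can attribute an anterior branch
  to the contralateral carotid; with approximate left–right symmetry the
  distance error is small.
- The delay span across the intracranial tree is a fraction of a frame;
  identifiability rests on the distance spread, which the estimator
  checks (and reports in diagnostics) before fitting.
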