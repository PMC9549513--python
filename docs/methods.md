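# Methods

## The interpolation model

The cardiac surface is approximated by a triangular mesh {V, F} with n
vertices (coordinates in mm). LAT observations (ms) are scattered points
near the surface. The pipeline is:

1. **Snapping.** Each observation is assigned to its Euclidean-nearest
   vertex; observations colliding on a vertex are merged by the arithmetic
   mean (unbiased, order-independent); nearest-vertex ties break to the
   lowest index so the result is deterministic.
2. **Anomaly rejection.** An observation is discarded when its value
   differs from the mean of its up-to-5 nearest co-observations within
   5 mm by strictly more than 30 ms. The rule is evaluated in a single
   pass against the original set (no cascade — removing one outlier never
   triggers removal of its neighbours), neighbours are found in Euclidean
   3-space among observation locations, and an observation with no
   neighbour in range is kept. "5 nearest within 5 mm" is read as k-NN
   restricted to a radius; since distances are sorted, this equals a
   radius ball capped at 5.
3. **Graph construction.** Vertices sharing a face are adjacent. Edge
   weights are the classic cotangent discretisation
   w_ij = ½ Σ cot(opposite angle) over the 1–2 incident faces; any
   non-positive weight (obtuse configurations) is clamped to a floor of
   1e-6 so every retained weight is strictly positive and L = D − W is a
   symmetric PSD M-matrix with exact zero row sums. The clamped cotangent
   construction was chosen over an intrinsic-Delaunay Laplacian: it has
   the identical interface and the same guaranteed properties (positivity,
   symmetry, locality), at a fraction of the implementation surface.
4. **Observation-driven pruning.** The surface is quantized by
   nearest-labeled-vertex assignment (Euclidean, consistent with the
   metric radius used in step 2; ties to the lowest labeled index), and
   every edge whose quantized endpoint values differ by **≥** 50 ms is
   removed (inclusive threshold). Surviving edges keep their cotangent
   weights; the diagonal is recomputed so row sums stay zero. No
   re-triangulation is attempted.
5. **Solve.** f\* = (M_l + αM_u + βL)⁻¹ f_s via sparse LU factorisation of
   the SPD system (never an explicit inverse — O(n) memory on mesh
   graphs); the ∞-norm residual is checked against 1e-8 · ‖f_s‖∞ and
   reported in the results object. α > 0 makes the smallest eigenvalue of
   the system matrix at least min(1, α), so the solve cannot fail on a
   well-formed Laplacian.

Defaults α = 1e-5, β = 1e-2 are the cross-validated operating point of the
method; the defaults are global rather than per-map. Raising β well above
1e-2 changes results little (the signal is already smooth at that scale),
while lowering it toward 1e-5 consistently hurts: with little Dirichlet
coupling, unlabeled vertices are pulled toward zero by the Tikhonov term.

## Spectral reading

With α = β = 1 the closed form becomes U (I + Λ)⁻¹ Uᵀ f_s where
L = U Λ Uᵀ — a first-order low-pass graph filter with gain 1/(1+λ) at
graph frequency λ. `spectral_interpolate` implements the general
U ĥ(Λ) Uᵀ f_s path by dense eigendecomposition; it is a diagnostic device
intended for n ≲ 2000 and is verified to agree with the sparse solver to
1e-6 relative in that regime. The production path is always the direct
solve.

## Gaussian-process baseline

A zero-mean GP with covariance k(x, x′) = Σ_ℓ exp(−‖x − x′‖²/(2ℓ²)),
ℓ ∈ {0.01, 0.1, 1}, observation jitter 1e-8 on the diagonal, and duplicate
training locations merged by mean. The length scales are unitless, so
coordinates are rescaled by the bounding-box diagonal of the combined
train/query cloud before the kernel is applied — on raw millimetre
coordinates all three kernels would be effectively zero between distinct
points. This scaling choice is the one genuinely open decision in the
baseline and is flagged here; disable with `rescale=False`.

## Mean Delta-E

LAT → colour uses the embedded 256-entry viridis table (bit-stable, no
plotting dependency): position (v − s_min)/(s_max − s_min) clamped to
[0, 1], then linear interpolation between adjacent table entries.
Colour → CIELAB uses the standard sRGB transfer function and D65 white.
ΔE₀₀ implements the full CIEDE2000 formula (chroma compensation G, hue
rotation R_T, compensations S_L/S_C/S_H) with k_L = k_C = k_H = 1, verified
against the published 34-pair test suite to 1e-4 and against an independent
colorimetry library on random pairs.

Because out-of-range values clamp to the endpoints, narrowing
[s_min, s_max] automatically zeroes the contribution of points whose
estimate and truth both lie outside on the same side — the intended
restricted-range reading. MDE is invariant to shifting both signals and
the range jointly. The cross-validation harness fixes the range to the
ground-truth observation min/max of the map, and scores on the held-out
test observations (not on all vertices), so repetitions and methods are
comparable.

NMSE is defined as Σ(est − truth)² / Σ(truth − mean truth)² — residual sum
of squares over the centred total sum of squares; a constant truth is
rejected rather than silently returning infinity. Other normalisations of
"NMSE" exist; comparisons across codebases should check the denominator.

## Sub-sampling protocol

Values are shifted nonnegative (only when negatives exist), the density
peak is x′ = x_min + λ₁·x_avg with λ₁ = 0.5, raw scores
r_i = λ₂(d_max − d_i) + 1 with λ₂ = 0.25 per ms, integer repetitions
f_i = floor(r_i) ≥ 1, probabilities p_i = f_i/Σf_i. floor preserves the
minimum of 1, hence no observation ever has vanishing probability.
Subsets are drawn **without replacement** — each successive draw is
proportional to the repetition counts of the still-available observations.
Uniform sampling of the repetition list with duplicates discarded would
bias the realised subset size; distinct indices are what an interpolation
consumer needs, so the protocol draws them directly. This is an
interpretive choice and is noted as such.

## Synthetic study maps

The generator emulates clinical electroanatomic maps at desk scale:
icosphere/ellipsoid/cylinder meshes (default icosphere subdivision 4:
2562 vertices, 25 mm radius — vertex spacing ≈ 3 mm, comparable to mapped
chambers), focal activation as Dijkstra geodesic distance from a focus
divided by a conduction velocity of 0.8 mm/ms, Gaussian observation noise
of 3 ms, and the map shifted so its minimum sits at −150 ms (LAT is
negative relative to a late reference in typical PVC maps). Observations
are field values at 300 random distinct vertices with 0.5 mm coordinate
jitter so snapping is exercised. The early-meets-late regime adds a
≥ 50 ms jump (default 250 ms) on one side of a plane through the mesh,
guaranteeing adjacent-vertex discontinuities that trigger edge pruning.

What the generator does **not** reproduce: anisotropic conduction and
fibre orientation, scar/block geometry, spatially correlated annotation
error, catheter-trajectory-ordered acquisition, and real chamber anatomy.
Passing tests therefore demonstrate the mechanics and the qualitative
behaviour of the method (error decreasing with observations, pruning
helping on discontinuities), not clinical-grade accuracy figures.

Dijkstra over edge lengths approximates geodesics from above; on these
mesh densities the bias is a few percent and irrelevant for generating
plausible fields.

## Evaluation harness

Pre-processing runs once per map; each repetition draws m training
observations via the sub-sampling protocol (per-repetition seed =
base + repetition index), every method consumes the identical training
subset, and MDE/NMSE are scored on the complement. Problem sizes used in
the packaged experiments — 2562 vertices, 300 observations, 25 repetitions
for the m-sweep (m = 50/100/200) and 20 for the pruning comparison at
m = 100 — keep a full run in seconds while leaving Monte-Carlo noise well
below the effect sizes being demonstrated. Results serialise to JSON
(sorted keys) and a per-repetition CSV; fixed seeds give byte-identical
output.

## Known limitations

- The cotangent floor (1e-6) is a pragmatic positivity guarantee, not an
  intrinsic remeshing; very poor triangulations will distort weights.
- Pruning can disconnect unlabeled islands; the Tikhonov term then pulls
  them toward 0 ms rather than leaving the solve singular. Interpret
  estimates in pruned-off unlabeled regions with care.
- The spectral path is dense and intended for diagnostics only.
- MDE weights all evaluated points equally; errors near the earliest
  activation are clinically more consequential but are not up-weighted.
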