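# Methods

This note documents the models, conventions, parameter choices and known
limitations of `rtdic`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Image model and conversion filters

A single-shot DIC image of a specimen intensity field *I* is modeled as
`g = −I + ∂I/∂d`, the inverted image plus the directional derivative
along the prism's shear axis `d = (cos θ, sin θ)`, θ = 45° by default
(configurable). All filters are complex coefficient grids on the standard
DFT frequencies, applied as FFT → multiply → inverse FFT per 2D plane
(the shear lies in-plane, so 3D+t stacks convert plane by plane).

* Hilbert transform: `H = −i·sgn(ω·d)`; removes shadows but has a hard
  frequency-domain edge (ringing) and is blind to shear-aligned features.
* First-order Riesz transform: `H = −i (ω·d)/|ω|`; the smooth directional
  version, which integrates the gradient term of `g`.
* Second-order Riesz transform: `H = −(ω·d)²/|ω|²`; real and even, it
  passes and inverts the features whose spectral energy lies along `d` —
  combined with the `−I` term of `g`, those emerge positive.
* Composite: `[R1(θ) + R2(θ+90°)] · HP(|ω|)` with the Gaussian high-pass
  `HP = 1 − exp(−|ω|²/2σ_hp²)`, σ_hp = 0.01 cycles/px (1/50 of Nyquist).
  The high-pass removes DC and slowly varying illumination shading; a
  quadrant-scale bias field changes the output by ≈1% RMS (tested).

Numerical details: the zero bin sits at the array origin; on even-sized
grids the Nyquist rows/columns fold +½ and −½ cycles/px onto one bin, so
every filter is projected onto its Hermitian part (odd filters are zeroed
on those lines), guaranteeing real output to machine precision. Borders
are mirror-padded by 25% per side before the FFT and cropped after
(padding mode selectable). All filters satisfy |H| ≤ 1.

Why the conversion cannot be perfect: for a spectral component at
frequency f with angle cosine c = ω̂·d, the restored coefficient is
`c·sin(2πf) + (1−c²)` (real part) plus a quadrature term `c − (1−c²)
sin(2πf)` that displaces ridges. The quadrature vanishes nowhere for a
single-shot acquisition; it is small exactly where the DIC gradient term
carries contrast, i.e. for local spatial frequencies roughly in the
0.1–0.4 cycles/px band. The grating validation chart therefore uses a
spoke period of ~5 px at mid-radius (128² image, 64 spokes); on it the
composite reaches a matched-area Jaccard overlap of ≈0.77 against the
ground truth, versus ≈0.48 for the Hilbert variant. Charts dominated by
coarser structure restore visibly but with lower overlap — a property of
single-shot DIC conversion, not of this implementation.

## Preprocessing

* Range expansion: one global linear map of the whole sequence to
  [0, 4095] (12-bit), rejecting constant input.
* XY drift: symmetric phase-only correlation (cross-spectrum whitened by
  its magnitude) per plane, quadratic 3-point subpixel peak fit, averaged
  along Z per frame; cumulative drift removed by Fourier resampling and
  recorded in `meta['drift']`. Low-confidence frames are interpolated
  from neighbours.
* Z-position correction: per interior plane, the axial offset δ ∈ [−0.5,
  +0.5] spacings minimizing the MSD between the plane and the symmetric
  four-point Lagrange cubic through z±1, z±2 evaluated at z+δ (bounded
  scalar minimization). The symmetric stencil puts the minimum at δ = 0
  for a regular stack; an offset is accepted only when it improves the
  objective by more than 10⁻⁵ of the plane's variance — near intensity
  extrema along z the problem is ill-conditioned and δ = 0 is retained.
  The two planes nearest each border are left untouched. The method
  presumes intensity varying smoothly on the plane-spacing scale.
* Smoothing: separable Gaussian along x, y and time only (never z),
  reflect boundary, so total intensity is conserved.
* Isotropic resampling: cubic-spline interpolation along Z by an integer
  factor (default 4; 250 nm spacing → 62.5 nm, matching 64.5 nm XY).
* Deconvolution: Richardson–Lucy (scikit-image) with a user-supplied,
  normalized PSF; zero iterations is the identity. PSF generation is out
  of scope; tests use synthetic Gaussian PSFs.

## Structure tensor

Gradients by Gaussian derivative at the inner scale σ_in; the tensor is
`S = G_σout ∗ (∇I∇Iᵀ)` and the polarity vector `P = G_σout ∗ ∇I`.
Eigenvalues are sorted λ1 ≥ λ2 ≥ λ3 ≥ 0; e3 (smallest eigenvalue) is the
fiber axis. The outer scale is the structure diameter of interest —
about 0.6 µm for filopodium-scale protrusions; σ_in defaults to σ_out/3.

Certainty indices (forms chosen to reproduce the qualitative anatomy —
high Ca on fiber trunks, Ct maxima at tips — and exposed as parameters):

* fiber certainty `Ca = (λ2 − λ3)/(λ1 + ε)` with ε = 10⁻³·max λ1;
* tip certainty `Ct = |ep·e3| · min(λp/λ̄p, 1) · Ca`, zero where the
  region's mean polarity magnitude λ̄p vanishes.

The ±e3 ambiguity is resolved by pointing the axis away from the centroid
of a user-supplied base region (adequate for radially arranged
protrusions; strongly re-curving fibers would need orientation
propagation, a known limitation). Retrograde tracing integrates −ê with
trilinear interpolation at ≤0.5 voxel steps; a voxel is tractable when
the path reaches the base region with fiber certainty above threshold.

2D signed curvature: the fiber tangent (eigenvector of the smaller
eigenvalue) is oriented outward from a reference center (t̂·r̂ ≥ 0; nearly
tangential fibers, |t̂·r̂| ≤ 0.05, are masked rather than inherited from
neighbours — the simpler rule suffices for radial/spiral geometries), and
κ = t̂·(t_x∇t_y − t_y∇t_x), reported in rad/mm. Positive = the tangent
rotates clockwise on screen while moving outward. Mirroring the image
negates the field exactly.

## Optical flow

Dimension-agnostic Horn–Schunck: Jacobi iteration of
`u ← ū − I(I·ū + I_t)/(α² + |∇I|²)` with the 2·d-neighbour mean ū,
central differences of the two-frame average, Neumann boundaries.
Defaults: α = 0.1 (intensities normalized to ~unit range give voxel-scale
gradients of ~0.1, so α = 1 would over-regularize), 200 iterations per
level or RMS update < 10⁻⁶. Coarse-to-fine: Gaussian σ = 1 pre-smooth,
**2× block-mean decimation** and block-aligned (grid_mode) linear
upsampling — block averaging, unlike strided sampling, is equivariant
under mirroring, which the chirality-parity guarantee requires — with 3
warp/re-estimate passes per level (the target frame is warped back by the
current estimate). `five_frame_flowset` runs four such flows from the
center frame to t±1 and t±2. Identical frames give exactly zero flow.

Measured on a textured ball (48³): 1- and 6-voxel translations recover
within ~5%; frame swap negates the flow exactly; one Jacobi iteration
matches a brute-force loop oracle to 10⁻¹².

## Kinematics and chirality signs

Stencils (d± single-frame, D± double-frame displacements, all on the
center-frame grid, converted to µm by the voxel pitch):

    v = [8(d⁺ − d⁻) − (D⁺ − D⁻)] / 12Δt        (five-point first derivative)
    a = (d⁺ + d⁻) / Δt²
    j = (D⁺ − 2d⁺ + 2d⁻ − D⁻) / 2Δt³
    ω = v × a / |v|²                            (Frenet angular velocity)

Each is exact on cubic polynomial paths; the five-point velocity removes
the O(Δt²) curvature bias of the plain central difference. The Frenet
triad is T = v/|v|, B = v×a/|v×a|, N = B×T. Voxels below the speed floor
(0.2 voxel/frame) or with |v×a| at numerical zero are masked, never
NaN-propagated; masked voxels are excluded from statistics.

Coordinate frame (the chirality convention, pinned throughout): x right,
y **down** (display), z away from the objective — right-handed. Positive
in-plane rotation (x toward y) is clockwise on screen; for an axis ê
oriented base→tip or centroid→outward, ω·ê > 0 is right-screw rotation.
Axial velocity v·ê > 0 is extension, < 0 retraction.

Projections: local (tensor fiber axis), chordal (unit chord from a
tracked basal point), orbital (fiber direction at the base), radial (from
the intensity-weighted centroid, restricted to tip-certainty voxels).
2D pixel-wise motility uses the same stencils with the scalar rate
`(v_x a_y − v_y a_x)/|v|²` and signed curvature `rate/|v|`.

Intrinsic attenuation of axial spin: a voxel at radius ρ on a structure
spinning at Ω while retracting at v_r follows a helix whose Frenet rate
projects onto the axis as `Ω/(1 + (v_r/ρΩ)²)`. For a 0.25 µm-radius
filopodium spinning at 0.03 rad/s under 0.02 µm/s retraction this is only
≈0.12·Ω — below the flow noise floor at 50 nm voxels — so the *sign* of
the spin is recoverable there but its magnitude is not; the quantitative
spin-recovery and parity validations therefore run at 0.1 rad/s, where
the projected signal dominates. This attenuation is a property of the
v×a/|v|² estimator itself, not of the implementation.

## Tracking and statistics

Converted 2D movies are smoothed, thresholded by Otsu, seeded by h-maxima
(h = 5–10% of the dynamic range) and split by watershed on the inverted
intensity; centroids are intensity-weighted. Linking is greedy
nearest-neighbour on flow-predicted centroids under a gate of 2× the
median per-step displacement; unmatched detections start tracks and
unmatched tracks terminate (no gap closing — a disappearance ends the
track and a new one begins). Per-step headings come from atan2 in display
coordinates; Δφ is wrapped to (−180°, 180°], clockwise positive; steps
below 0.5 µm contribute no heading. Per-track outputs: mean angular
velocity (deg/min), signed curvature (mean Δφ_rad/step length, rad/mm),
cumulative angle. Contact state: a particle's mask dilated by 2 px
intersecting another particle's mask.

Statistics are two-tier, as the motility analyses require: each trial's
large sample is summarized as mean ± s.d. with a two-sided Wilcoxon
signed-rank test against zero median (zero differences dropped, normal
approximation for n > 25); trial means are then tested with a two-sided
one-sample t-test against zero, reported as mean ± s.e.m. Both tests are
scipy implementations behind this interface. On null (zero-bias) walker
data the across-trial test rejects at ≈5% for nominal α = 5% over 500
replicate suites (tested).

## Synthetic phantoms: what they emulate and what they do not

* **Radial grating** `0.5(1 + cos Nφ)` (even N): orientation-dense chart
  for rotation coverage; its DIC rendering uses the same forward model
  the filters invert.
* **Helical blob**: isotropic Gaussian sampled at voxel centers moving on
  `(r cos Ωt, r sin Ωt, hΩt/2π)`, rotated into a requested axis, with
  closed-form v, a, j, ω (verified against dense finite differences to
  <0.1%). Validation conditions: r = 1 µm, Ω = 0.05 rad/s, Δt = 8 s,
  100 nm voxels, 48³ — chosen so the per-frame turn Ω·Δt = 0.4 rad makes
  the centripetal displacement (≈1.6 voxels) clearly exceed the flow
  noise floor; a much smaller turn leaves the acceleration signal
  unmeasurable for *any* flow estimator at this resolution.
* **Filopodium**: radial-Gaussian cylinder with sigmoid ends anchored at
  the grid-symmetric base, length shrinking at the retraction speed; an
  axial intensity texture treadmills toward the base at the same speed
  (the retrograde-flow appearance of real filopodia) and an m = 1
  azimuthal texture rotates right-screw at the axial spin (m = 1 keeps
  rotation unambiguous up to π per frame).
* **2D walkers**: headings evolve `φ += ω0Δt + N(0, σ²)`; constant speed;
  specular border reflection (flagged); excluded-volume contact: pairs
  closer than 4 cell-σ are pushed apart and flagged, providing the
  ground-truth encounter schedule. Cells render as Gaussian blobs,
  optionally through the DIC forward model. Defaults: 50 walkers,
  10 µm/min, ω0 = +0.8°/min, 10° heading noise per 30 s step, 5 µm cell
  σ, 2.58 µm pixels — amoeboid-migration scale conditions. The
  end-to-end tracking validation uses a 1.3 mm arena for 40 min
  (80 frames), a low density at which identity-preserving tracking is
  the expected outcome; the null calibration uses 500 suites of 8 trials
  × 12 walkers on ground-truth tracks (rendering 4000 movies would add
  nothing to a test of the statistics tier).
* Not emulated: optics (PSF, polarization, halo), photon/camera noise
  (additive Gaussian noise is available but off by default), cell
  division/merging, non-rigid amoeboid shape change. Passing these tests
  shows the *analysis chain* is correct and chirality-sign-faithful on
  resolvable motion; it does not certify performance on low-SNR or
  strongly deforming real data.

## Known limitations

* Single-shot conversion keeps a quadrature artifact (see above); for
  rotation-invariant restoration a multi-shot inverse-transform
  acquisition is required and out of scope.
* Optical flow needs textured intensity; on featureless smooth blobs the
  tangential component is filled in by regularization only, and speeds
  are biased low by O(10%) near support edges.
* The v×a/|v|² angular velocity attenuates spin on steeply translating
  structures (formula above) and is undefined for straight motion.
* Greedy linking has no global assignment or gap closing; at high cell
  density identity errors grow.
* Tangent orientation for the 2D curvature masks near-tangential fibers
  instead of propagating orientation from neighbours.
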