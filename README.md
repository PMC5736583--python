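# rtdic

Single-shot DIC microscopy produces shadow-cast images: the specimen
appears as its optical-path gradient along the prism's shear axis, summed
with an inverted absorption term. That rendering defeats intensity-based
3D reconstruction and voxel-wise analysis. `rtdic` converts such images
into *self-luminous* intensity images with one frequency-domain filter,
and then quantifies chirality-signed cell motility — the right-screw spin
of growth-cone filopodia, the clockwise migration bias of amoeboid cells —
with a voxel-based computational kinematic pipeline.

The package is aimed at quantitative microscopists and cell biologists who
have (or simulate) DIC time-lapse data and want signed, unit-bearing
motility numbers rather than renderings.

## The method

**Conversion.** With shear direction d = (cos θ, sin θ) (θ = 45° by
default), a DIC image of specimen *I* is modeled as `g = −I + ∂I/∂d`.
The composite filter

    H(ω) = [ −i (ω·d)/|ω|  −  (ω·d⊥)²/|ω|² ] · (1 − exp(−|ω|²/2σ_hp²))

(first-order Riesz transform along the shear axis, second-order Riesz
transform along the orthogonal axis, Gaussian high-pass that removes DC
and shading bias) maps `g` back to a positive-ridge image of *I* at every
feature orientation. Plain Hilbert-transform filtering, by contrast, is
blind to features oriented along the shear axis.

**Kinematics.** Dense 3D Horn–Schunck optical flow (coarse-to-fine
Gaussian pyramids) yields, per voxel, the four displacement fields of the
five-frame scheme: single- and double-frame, forward and backward. From
these the stencil

    v = [8(d⁺ − d⁻) − (D⁺ − D⁻)] / 12Δt,   a = (d⁺ + d⁻)/Δt²,
    j = (D⁺ − 2d⁺ + 2d⁻ − D⁻)/2Δt³,        ω = v × a / |v|²

gives velocity, acceleration, jerk and the Frenet angular velocity, all
exact on cubic paths. Signed projections follow: onto the structure-tensor
fiber axis (oriented base→tip; positive axial velocity = extension,
positive axial angular velocity = right-screw), onto chordal/orbital axes
of tracked points, and onto the radial axis from the intensity-weighted
centroid. In 2D, the scalar rate `(v_x a_y − v_y a_x)/|v|²` is positive
for clockwise rotation on screen (y down), and `rate/|v|` is the signed
path curvature. Cell-scale analysis segments converted movies by
watershed, links centroids with flow assistance and reduces each track to
a mean angular velocity (deg/min) and signed curvature (rad/mm). The whole
pipeline is mirror-equivariant: flipping the input image flips every
chirality-signed output exactly.

Everything is validated on synthetic phantoms with analytic ground truth
(`rtdic.synth`): a radial grating with its DIC rendering, a blob on a 3D
helix, a retracting/spinning filopodium and 2D walkers with a clockwise
heading bias.

## Worked example

```bash
python examples/helical_kinematics.py
```

```
voxels on the moving blob: 429
recovered |omega| = 0.0584 rad/s (ground truth 0.05 rad/s)
recovered |v|     = 0.0396 um/s (ground truth 0.050 um/s)
```

A Gaussian blob orbits a 1 µm circle at Ω = 0.05 rad/s; flow plus the
five-frame stencil recover the orbital angular speed within ~17% and the
speed within ~20%, from image data alone. Other examples convert the
grating chart (`convert_dic_image.py`: composite Jaccard overlap 0.766 vs
0.480 for the Hilbert transform), measure filopodium retraction and spin
(`filopodium_axes.py`: −0.018 µm/s recovered for a −0.020 µm/s phantom,
spin sign +1 = right-screw), track biased walkers (`track_walkers.py`) and
sign neurite curvature (`neurite_curvature.py`).

## Conventions (chirality depends on these)

Arrays are `(t, z, y, x)`; vector components are ordered `(x, y, z)`.
The display frame has x right, **y down**, z away from the objective
(right-handed). Positive in-plane rotation = clockwise on screen; positive
axial angular velocity = right-screw about the reference axis. Public
outputs are in µm, s, deg or rad; voxel units are internal only.
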