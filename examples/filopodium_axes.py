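"""Axial velocity and right-screw spin of a retracting filopodium.

Generates a filopodium-like cylinder phantom (retracting at 0.02 µm/s,
spinning right-screw at 0.1 rad/s about its base→tip axis), estimates
the fiber direction with the structure tensor, and projects the
voxel-wise kinematics onto the tip-oriented local axis.  Negative axial
velocity means retraction; positive axial angular velocity means
right-screw rotation.
"""

import numpy as np

from rtdic import (SynthSpec, derive_kinematics, filopodium_phantom,
                   five_frame_flowset, local_axis_projection)
from rtdic.tensor import certainties, compute_tensor, orient_to_tip

spec = SynthSpec(shape=(56, 40, 40), pitch=0.05, dt=4.0, n_frames=5,
                 filo_length=2.0, filo_radius=0.25,
                 retraction_speed=0.02, axial_spin=0.1)
movie, truth = filopodium_phantom(spec)

flows = five_frame_flowset(movie.data, alpha=0.05, n_iter=300)
kin = derive_kinematics(flows, spec.dt, spec.pitch,
                        intensity=movie.data[2], tau_intensity_frac=0.3)

tensor = certainties(compute_tensor(movie.data[2], 2.0, 5.0))
base = np.zeros(movie.data[2].shape, bool)
base[:6] = True                       # growth-cone body below the volume
tip_axis = orient_to_tip(tensor, base)
proj = local_axis_projection(kin, tip_axis)

core = proj.valid & (movie.data[2] > 0.5 * movie.data[2].max())
spin_sel = proj.meta["valid_omega"] & (tensor.ca > 0.3)
print(f"mean axial velocity  = {proj.axial_velocity[core].mean():+.4f} um/s"
      f"  (ground truth {truth.axial_velocity:+.3f}; negative = retraction)")
print(f"mean axial spin sign = "
      f"{np.sign(proj.axial_angular_velocity[spin_sel].mean()):+.0f}"
      f"  (ground truth +1 = right-screw about base->tip)")
print("Mirroring the movie (x -> -x) flips the spin sign exactly; the")
print("retraction speed is unchanged.  That parity is the package's")
print("chirality guarantee.")
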