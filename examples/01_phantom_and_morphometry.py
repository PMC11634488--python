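"""Build a one-muscle Dixon phantom and measure its volume and MFI profile.

The phantom is an ellipsoid 'gluteus medius' with a designed linear fat
fraction rising from 0.1 proximally to 0.3 distally. Because the geometry is
analytic, the printed volume can be compared with (4/3)*pi*a*b*c and the
recovered profile with the designed line.
"""
import numpy as np

from hipmorph import (
    MFIProfile,
    MuscleShape,
    PhantomSpec,
    generate_phantom,
    mfi_profile,
    muscle_volume,
)

shape = MuscleShape(
    label=1, muscle="Gmed", side="L", primitive="ellipsoid",
    center_mm=(36.0, 30.0, 45.0), semi_axes_mm=(20.0, 15.0, 30.0),
)
spec = PhantomSpec(
    grid_shape=(48, 40, 60), voxel_size_mm=(1.5, 1.5, 1.5),
    muscles=[shape], mfi_profiles={1: MFIProfile("linear", (0.1, 0.3))},
)
dixon, mask = generate_phantom(spec)

rec = muscle_volume(mask, 1)
analytic = 4 / 3 * np.pi * 20 * 15 * 30
print(f"rasterized volume : {rec.volume_mm3:9.1f} mm^3")
print(f"analytic volume   : {analytic:9.1f} mm^3")
print(f"relative error    : {abs(rec.volume_mm3 - analytic) / analytic:9.5f}")

prof = mfi_profile(dixon, mask, 1)
expected = 0.1 + 0.2 * np.linspace(0, 1, 101)
print(f"profile nodes     : {len(prof.nodes)} (proximal 0% -> distal 100%)")
print(f"MFI at 0/50/100%  : {prof.nodes[0]:.3f} {prof.nodes[50]:.3f} {prof.nodes[100]:.3f}")
print(f"max node error    : {np.abs(prof.nodes - expected).max():.2e}")
# The volume error reflects voxelisation only; the profile error shows the
# 101-node spline normalisation recovering the designed fat gradient.
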