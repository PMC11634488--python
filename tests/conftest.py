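import numpy as np
import pytest

from hipmorph.phantom import (
    MFIProfile,
    MuscleShape,
    PhantomSpec,
    generate_phantom,
)


def single_muscle_spec(
    profile: MFIProfile,
    primitive: str = "ellipsoid",
    semi_axes=(20.0, 15.0, 30.0),
    voxel: float = 1.5,
    grid=(48, 40, 60),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """One Gmed-labelled primitive centred in a small grid."""
    extent = [g * voxel for g in grid]
    shape = MuscleShape(
        label=1, muscle="Gmed", side="L", primitive=primitive,
        center_mm=tuple(e / 2 for e in extent), semi_axes_mm=semi_axes,
    )
    return PhantomSpec(
        grid_shape=grid, voxel_size_mm=(voxel,) * 3,
        muscles=[shape], mfi_profiles={1: profile},
        noise_sd=noise_sd, seed=seed,
    )


@pytest.fixture(scope="session")
def linear_profile_phantom():
    """Noise-free ellipsoid with designed linear MFI 0.1 -> 0.3."""
    spec = single_muscle_spec(MFIProfile("linear", (0.1, 0.3)))
    dixon, mask = generate_phantom(spec)
    return spec, dixon, mask


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20241029)
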