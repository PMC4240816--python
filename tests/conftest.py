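import numpy as np
import pytest

from pvmra import (
    ImageVolume,
    PhantomSpec,
    ReconConfig,
    VesselSpec,
    default_phantom_spec,
    generate_pattern,
    make_coil_maps,
    make_pv_phantom,
    simulate_acquisition,
)


def fine_tube_spec(edge_width_mm: float, spacing_mm: float = 0.3) -> PhantomSpec:
    """Single straight tube rendered finely enough that the voxel box-average
    does not widen the 20-80% transition of the linear edge."""
    return PhantomSpec(
        shape=(8, 96, 96),
        spacing_mm=spacing_mm,
        vessels=[
            VesselSpec.straight("tube", (14.4, 14.4), radius_mm=6.0, edge_width_mm=edge_width_mm)
        ],
        blob=None,
        noise_sigma=0.0,
        contour_margin_mm=1.5,
        contour_vertices=180,
    )


def coarse_tube_spec(edge_width_mm: float = 2.0) -> PhantomSpec:
    """Single tube on the study's 1.5 mm grid (small in-plane extent)."""
    return PhantomSpec(
        shape=(8, 48, 48),
        spacing_mm=1.5,
        vessels=[
            VesselSpec.straight("tube", (36.0, 36.0), radius_mm=6.0, edge_width_mm=edge_width_mm)
        ],
        blob=None,
        noise_sigma=0.0,
    )


@pytest.fixture(scope="session")
def slab_phantom():
    """Default four-vessel slab phantom with ground-truth contours."""
    vol, contours = make_pv_phantom(default_phantom_spec("slab"))
    return vol, contours


@pytest.fixture(scope="session")
def slab_acquisition(slab_phantom):
    """Undersampled (R=5) six-coil noisy acquisition of the default phantom."""
    vol, contours = slab_phantom
    coils = make_coil_maps(vol.shape, 6, seed=11)
    pattern = generate_pattern(vol.shape[1], vol.shape[2], 5.0, (32, 19), seed=7)
    k = simulate_acquisition(vol, coils, pattern, noise_sigma=1.0, seed=3)
    return vol, contours, coils, pattern, k


@pytest.fixture(scope="session")
def slab_cs_recon(slab_acquisition):
    """CS and zero-filled reconstructions of the slab acquisition."""
    from pvmra.recon import combine_coils, cs_reconstruct, zero_filled_recon

    vol, contours, coils, pattern, k = slab_acquisition
    zf = np.abs(combine_coils(zero_filled_recon(k), coils, mode="b1"))
    cs = cs_reconstruct(k, coils, ReconConfig(patch_mode="slice"))
    return vol, contours, ImageVolume(zf, vol.spacing_mm), cs
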