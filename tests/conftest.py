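import numpy as np
import pytest

from lesionctx import phantoms as ph


@pytest.fixture(scope="session")
def default_phantom():
    """Canonical phantom: tumor 8 mm from pleura, vessel 5 mm away, adhesion."""
    spec = ph.standard_spec(
        pleura_distance_mm=8.0,
        tumor_radius_mm=7.0,
        vessel_distance_mm=5.0,
        vessel_caliber_mm=3.0,
        adhesion_radius_mm=3.0,
        seed=0,
    )
    vol, intensity = ph.generate_phantom(spec)
    return spec, vol, intensity


@pytest.fixture(scope="session")
def juxtapleural_phantom():
    """Tumor touching-distance (1 mm) from the pleura, no adhesion."""
    spec = ph.standard_spec(
        pleura_distance_mm=0.5, tumor_radius_mm=7.0, vessel_distance_mm=6.0, seed=1
    )
    vol, _ = ph.generate_phantom(spec, with_intensity=False)
    return vol


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free 60-case cohort with the default planted risk structure."""
    return ph.sample_cohort(60, seed=42)


def brute_force_min_distance(mask_a, mask_b, spacing):
    """O(|A| |B|) all-pairs minimum voxel-center distance (oracle)."""
    a = np.argwhere(mask_a) * np.asarray(spacing)
    b = np.argwhere(mask_b) * np.asarray(spacing)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def brute_force_sdf(mask, spacing):
    """Oracle signed distance: +min distance to mask voxels outside, -min
    distance to background voxels inside."""
    sp = np.asarray(spacing)
    inside = np.argwhere(mask) * sp
    outside = np.argwhere(~mask) * sp
    coords = np.indices(mask.shape).reshape(3, -1).T * sp
    sdf = np.empty(mask.shape)
    flat = mask.ravel()
    for i, p in enumerate(coords):
        if flat[i]:
            d = np.sqrt(((outside - p) ** 2).sum(axis=1).min())
            sdf.ravel()[i] = -d
        else:
            d = np.sqrt(((inside - p) ** 2).sum(axis=1).min())
            sdf.ravel()[i] = d
    return sdf
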