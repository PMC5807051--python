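"""Shared fixtures: small synthetic colonies reused across test modules.

Session scope keeps the suite fast — tests must not mutate these.
"""

import numpy as np
import pytest

import micropattern as mp


@pytest.fixture(scope="session")
def noise_free_colony():
    """500 μm colony, uniform marker, no noise; clean stack retained."""
    spec = mp.SyntheticColonySpec(
        diameter_um=500.0, seed=3, noise=mp.NoiseModel.off(),
        marker_models=[mp.MarkerDomainModel("m", "uniform", level_inside=7000.0,
                                            level_outside=7000.0)],
    )
    grid, truth = mp.generate_colony(spec)
    return spec, grid, truth


@pytest.fixture(scope="session")
def noise_free_mask(noise_free_colony):
    _, grid, _ = noise_free_colony
    return mp.classify_nuclei(grid)


@pytest.fixture(scope="session")
def noisy_colony():
    """500 μm colony, uniform marker, default acquisition noise."""
    spec = mp.SyntheticColonySpec(
        diameter_um=500.0, seed=4,
        marker_models=[mp.MarkerDomainModel("m", "uniform")],
    )
    grid, truth = mp.generate_colony(spec)
    return spec, grid, truth


@pytest.fixture(scope="session")
def noisy_mask(noisy_colony):
    _, grid, _ = noisy_colony
    return mp.classify_nuclei(grid)


@pytest.fixture()
def disc_mask():
    """Synthetic perfectly symmetric disc probability mask.

    100 μm radius disc on a 128×128 grid at 2 μm spacing, 8 z-planes,
    centered exactly at the grid center (128 μm, 128 μm).
    """
    n = 128
    spacing = (2.0, 2.0, 1.0)
    xs = (np.arange(n) + 0.5) * spacing[0] - n * spacing[0] / 2
    r = np.hypot(xs[:, None], xs[None, :])
    disc = (r <= 100.0).astype(float)
    prob = np.broadcast_to(disc, (8, n, n)).copy()
    return mp.NuclearMask(prob, voxel_spacing_um=spacing)


def brute_force_profile(grid, mask, center_um, bin_width_um, fitted_radius_um):
    """Independent per-voxel enumeration oracle for radial binning."""
    dx, dy, dz = grid.voxel_spacing_um
    n_bins = int(np.ceil(fitted_radius_um / bin_width_um))
    sums = {ch: np.zeros(n_bins) for ch in grid.channel_names}
    counts = np.zeros(n_bins, dtype=int)
    binary = mask.binary
    nz, ny, nx = grid.spatial_shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not binary[z, y, x]:
                    continue
                r = np.hypot((x + 0.5) * dx - center_um[0], (y + 0.5) * dy - center_um[1])
                if r > fitted_radius_um:
                    continue
                b = min(int(r // bin_width_um), n_bins - 1)
                counts[b] += 1
                for ch in grid.channel_names:
                    sums[ch][b] += float(grid.channel(ch)[z, y, x])
    means = {
        ch: np.where(counts > 0, sums[ch] / np.maximum(counts, 1), np.nan)
        for ch in grid.channel_names
    }
    return means, counts
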