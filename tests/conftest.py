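"""Shared phantom builders for the test suite."""

import numpy as np
import pytest

from dbsnet import NetworkSpec, PhantomSpec, RegionSpec


def null_phantom(n_subjects=50, grid=(12, 12, 12), n_timepoints=124, seed=0):
    """All-noise phantom: one pure-noise seed region, no latent networks."""
    return PhantomSpec(
        grid_shape=grid,
        n_subjects=n_subjects,
        n_timepoints=n_timepoints,
        regions=[RegionSpec("seed", [(0, 0, z) for z in range(4)], {})],
        networks=[],
        rng_seed=seed,
    )


def cube(corner, size=3):
    x, y, z = corner
    return [(x + i, y + j, z + k)
            for i in range(size) for j in range(size) for k in range(size)]


def three_seed_phantom(n_subjects=100, grid=(14, 14, 14), seed=0,
                       common_loading=1.0, seed_loading=3.0):
    """Three seed regions on separate networks plus one shared territory.

    Each 27-voxel seed drives its own latent network strongly (the seed mean
    time course is essentially the latent); the 'common' cube loads on all
    three with ``common_loading``, giving population seed-to-common
    correlation a / sqrt(3 a^2 + 1) (= 0.5 at a = 1, noise sd 1).
    """
    gx, gy, gz = grid
    networks = [NetworkSpec(f"net_{t}") for t in ("A", "B", "C")]
    regions = [
        RegionSpec("seedA", cube((1, 1, 1)), {"net_A": seed_loading}),
        RegionSpec("seedB", cube((gx - 4, 1, 1)), {"net_B": seed_loading}),
        RegionSpec("seedC", cube((1, gy - 4, 1)), {"net_C": seed_loading}),
        RegionSpec("common", cube((gx // 2 - 1, gy // 2 - 1, gz - 4)),
                   {"net_A": common_loading, "net_B": common_loading,
                    "net_C": common_loading}),
    ]
    return PhantomSpec(grid_shape=grid, n_subjects=n_subjects,
                       regions=regions, networks=networks, rng_seed=seed)


def hub_phantom(n_networks=5, n_subjects=20, seed=0, hub_loading=1.0,
                spoke_loading=1.5):
    """One connector region loading on every latent network, spokes on one each."""
    networks = [NetworkSpec(f"net{i}") for i in range(n_networks)]
    regions = [
        RegionSpec("hub", [(x, y, 0) for x in range(2) for y in range(4)],
                   {f"net{i}": hub_loading for i in range(n_networks)})
    ]
    for i in range(n_networks):
        regions.append(
            RegionSpec(f"spoke{i}",
                       [(x, y, i + 1) for x in range(2) for y in range(4)],
                       {f"net{i}": spoke_loading})
        )
    return PhantomSpec(grid_shape=(8, 8, n_networks + 2), n_subjects=n_subjects,
                       regions=regions, networks=networks, rng_seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
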