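import numpy as np
import pytest

from lsmseg.synth import add_nuclei_channel, make_foam


def sphere_sdf(shape, radius):
    """Exact signed distance to a centred sphere (negative inside)."""
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    centre = [(n - 1) / 2.0 for n in shape]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, centre)))
    return r - radius


def radius_from_volume(phi):
    """Equivalent-sphere radius of the interior of a level-set field."""
    vol = int((phi < 0).sum())
    return (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)


@pytest.fixture(scope="session")
def small_foam():
    """6-cell foam ball at 64^3 with bright outer wall (shared, read-only)."""
    return make_foam(
        shape=(64, 64, 64), n_cells=6, rho_outer=1.0, atten_k=0.0,
        noise_sigma=2.0, seed=11, min_cell_voxels=200,
    )


@pytest.fixture(scope="session")
def dim_foam():
    """8-cell foam with dim outer wall and z attenuation (the L1 pathology)."""
    return make_foam(
        shape=(96, 96, 96), n_cells=8, rho_outer=0.3, atten_k=0.4,
        noise_sigma=2.0, seed=3,
    )


@pytest.fixture(scope="session")
def nuclei_foam():
    """Small two-channel foam: 12 cells, one without nuclear signal."""
    tis = make_foam(
        shape=(72, 72, 72), n_cells=12, rho_outer=1.0, atten_k=0.0,
        noise_sigma=2.0, seed=21, min_cell_voxels=200,
    )
    return add_nuclei_channel(
        tis, ratio_mean=0.17, ratio_sd=0.04, target_corr=0.6,
        missing_fraction=0.1, seed=22,
    )
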