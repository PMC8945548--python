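import numpy as np
import pytest

from braintensor import (
    GrayordinateDataset,
    SynthConfig,
    generate_dataset,
    normalize_timeseries,
)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Desk-scale study conditions shrunk for fast unit tests."""
    return SynthConfig(
        n_cortical_vertices=300,
        n_subcortical_voxels=100,
        grid_dims=(5, 5, 4),
        n_timepoints=120,
        n_subjects=8,
        n_networks=4,
        network_magnitudes=(6.0, 4.0, 3.0, 2.0),
        snr=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


def make_dataset(rng, v=30, t=20, s=3, n_sub=8, grid=(2, 2, 2)):
    """Tiny hand-rolled dataset with normalized random rows."""
    subjects = [normalize_timeseries(rng.standard_normal((v, t))) for _ in range(s)]
    coords = np.stack(
        np.meshgrid(*[np.arange(d) for d in grid], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    return GrayordinateDataset(
        subjects=subjects,
        cortical_index=np.arange(v - n_sub),
        subcortical_index=np.arange(v - n_sub, v),
        subcortical_grid_coords=coords[:n_sub],
        grid_dims=grid,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_orthogonal(rng, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))
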