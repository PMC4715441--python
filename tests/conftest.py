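import numpy as np
import pytest

import hullmass as hm


@pytest.fixture(scope="session")
def pigeons() -> hm.CalibrationDataset:
    return hm.load_pigeon_fixture()


@pytest.fixture(scope="session")
def dodo_volumes():
    return hm.load_dodo_fixture()


@pytest.fixture(scope="session")
def eviscerated_model(pigeons) -> hm.CalibrationModel:
    return hm.fit_loglog_ols(hm.subset_by_preparation(pigeons, "eviscerated"))


@pytest.fixture(scope="session")
def combined_model(pigeons) -> hm.CalibrationModel:
    return hm.fit_loglog_ols(hm.subset_by_preparation(pigeons, "combined"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160111)


@pytest.fixture()
def unit_cube() -> hm.PointSet:
    corners = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    return hm.PointSet(label="cube", points=corners)


def random_cloud(rng: np.random.Generator, n: int = 50, scale: float = 10.0) -> np.ndarray:
    """A generic full-rank 3D point cloud for property tests."""
    return rng.standard_normal((n, 3)) * scale


def monte_carlo_volume(
    hull: hm.ConvexPolytope, rng: np.random.Generator, n_samples: int = 200_000
) -> float:
    """Independent rejection-sampling containment oracle for hull volume."""
    lo = hull.vertices.min(axis=0)
    hi = hull.vertices.max(axis=0)
    samples = rng.uniform(lo, hi, size=(n_samples, 3))
    inside = hull.contains(samples)
    box = float(np.prod(hi - lo))
    return box * inside.mean()
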