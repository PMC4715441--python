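"""Synthetic skeletons and calibration datasets with exact ground truth.

Two generator families back the test suite end to end:

* geometric — point clouds sampled on convex polytopes of analytically
  known volume (cuboids, regular tetrahedra, and octahedral ellipsoid
  approximations), posed with random rigid motions. Every polytope vertex
  is included in the cloud and interior jitter points are convex
  combinations of the vertices, so the generating polytope is exactly the
  hull of the cloud and its analytic volume is exact ground truth.

* statistical — calibration datasets drawn from the allometric model
  M = 10^(a + b·log10 V + ε) with ε either i.i.d. Gaussian on the log10
  scale or multivariate normal with a Brownian-motion covariance on a
  supplied phylogeny.

Ground-truth volumes come from closed-form shape formulas, never from the
hull machinery under test. All generators are pure functions of their
specification and seed.

The packaged reference fixtures — the 20-specimen extant pigeon
calibration table and the three composite dodo skeleton hull volumes — are
loaded from CSVs shipped with the package. One typographical slip in the
source table (a minus-feet volume printed as "7,4691" alongside a
with-feet volume of 77,882) is shipped already corrected to 74,691 mm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .calibration import CalibrationDataset, Specimen, brownian_covariance
from .errors import InvalidSpec
from .geometry import HullVolumeTable, PointSet, SkeletonSegments

SHAPES = ("cuboid", "tetrahedron", "ellipsoid")

#: with-feet / minus-feet volume ratio used when synthesizing specimen rows
_FEET_RATIO = 1.03


def _base_shape(shape: str, size: tuple[float, ...]) -> tuple[np.ndarray, float]:
    """Vertices and analytic volume of a canonical convex polytope."""
    if shape == "cuboid":
        a, b, c = size
        grid = np.array([[x, y, z] for x in (0, a) for y in (0, b) for z in (0, c)], dtype=float)
        return grid, a * b * c
    if shape == "tetrahedron":
        (edge,) = size if len(size) == 1 else (size[0],)
        # regular tetrahedron inscribed in alternating cube corners
        s = edge / math.sqrt(2.0)
        verts = np.array([[0, 0, 0], [s, s, 0], [s, 0, s], [0, s, s]], dtype=float)
        return verts, edge**3 / (6.0 * math.sqrt(2.0))
    if shape == "ellipsoid":
        # inscribed octahedron: the ground truth is the octahedron's volume
        a, b, c = size
        verts = np.array(
            [[a, 0, 0], [-a, 0, 0], [0, b, 0], [0, -b, 0], [0, 0, c], [0, 0, -c]], dtype=float
        )
        return verts, 4.0 * a * b * c / 3.0
    raise InvalidSpec(f"unknown shape {shape!r}; expected one of {SHAPES}")


@dataclass(frozen=True)
class SegmentShapeSpec:
    """One synthetic segment: shape family, size parameters (mm), point count."""

    label: str
    shape: str = "cuboid"
    size: tuple[float, ...] = (10.0, 10.0, 10.0)
    n_points: int = 40
    is_foot: bool = False

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise InvalidSpec(f"unknown shape {self.shape!r}")
        if any(s <= 0 for s in self.size):
            raise InvalidSpec(f"segment {self.label!r}: sizes must be positive")
        if self.n_points < 1:
            raise InvalidSpec("n_points must be >= 1")


@dataclass(frozen=True)
class SyntheticSkeletonSpec:
    """A synthetic skeleton: posed segments plus an interior-jitter amplitude.

    ``jitter`` in (0, 1] scales interior points' spread about the segment
    centroid; because interior points are convex combinations of the
    vertices, no jitter value can push a point outside its generating
    polytope, so hull volumes stay exact.
    """

    specimen_id: str = "synthetic"
    segments: tuple[SegmentShapeSpec, ...] = (SegmentShapeSpec(label="trunk"),)
    jitter: float = 1.0
    pose: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.jitter <= 1:
            raise InvalidSpec("jitter must lie in (0, 1]")
        labels = [s.label for s in self.segments]
        if len(set(labels)) != len(labels):
            raise InvalidSpec("segment labels must be unique")


def make_synthetic_skeleton(
    spec: SyntheticSkeletonSpec,
) -> tuple[SkeletonSegments, HullVolumeTable]:
    """Generate a skeleton point cloud and its exact hull-volume table."""
    rng = np.random.default_rng(spec.seed)
    segments: dict[str, PointSet] = {}
    volumes: dict[str, float] = {}
    feet = set()
    for seg in spec.segments:
        verts, vol = _base_shape(seg.shape, seg.size)
        n_interior = max(0, seg.n_points - verts.shape[0])
        centroid = verts.mean(axis=0)
        if n_interior:
            weights = rng.dirichlet(np.ones(verts.shape[0]), size=n_interior)
            combos = weights @ verts
            interior = centroid + spec.jitter * (combos - centroid)
            cloud = np.vstack([verts, interior])
        else:
            cloud = verts
        if spec.pose:
            rot = Rotation.random(random_state=rng).as_matrix()
            shift = rng.uniform(-100.0, 100.0, size=3)
            cloud = cloud @ rot.T + shift
        segments[seg.label] = PointSet(label=seg.label, points=cloud)
        volumes[seg.label] = vol
        if seg.is_foot:
            feet.add(seg.label)
    skeleton = SkeletonSegments(
        specimen_id=spec.specimen_id, segments=segments, feet_labels=frozenset(feet)
    )
    truth = HullVolumeTable(
        specimen_id=spec.specimen_id, volumes=volumes, feet_labels=frozenset(feet)
    )
    return skeleton, truth


@dataclass(frozen=True)
class SyntheticCalibrationSpec:
    """Parameters of a simulated mass–volume calibration dataset.

    ``sigma`` is the residual SD of log10 mass; ``x_range`` is the span of
    log10 volume (mm³). Defaults mirror the extant-pigeon calibration
    regime: 13 specimens spanning roughly 47,000–1,400,000 mm³ with the
    eviscerated-fit coefficients and residual scale.
    """

    n: int = 13
    a: float = -2.31
    b: float = 0.90
    sigma: float = 0.065
    x_range: tuple[float, float] = (4.6, 6.2)
    preparation: str = "eviscerated"
    seed: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise InvalidSpec("n must be >= 3")
        if self.sigma < 0:
            raise InvalidSpec("sigma must be >= 0")
        if not self.x_range[1] > self.x_range[0]:
            raise InvalidSpec("x_range must be non-degenerate")


def _specimen_rows(
    species: list[str], x: np.ndarray, log_mass: np.ndarray, preparation: str
) -> list[Specimen]:
    rows = []
    for name, xi, lm in zip(species, x, log_mass):
        v_minus = 10.0**xi
        rows.append(
            Specimen(
                species=name,
                common_name=name,
                mass_g=10.0**lm,
                preparation=preparation,
                ch_vol_mm3=v_minus * _FEET_RATIO,
                ch_vol_minus_feet_mm3=v_minus,
            )
        )
    return rows


def make_calibration_dataset(spec: SyntheticCalibrationSpec) -> CalibrationDataset:
    """Draw a dataset from M = 10^(a + b·x + ε), ε ~ N(0, σ²), x uniform."""
    rng = np.random.default_rng(spec.seed)
    x = rng.uniform(spec.x_range[0], spec.x_range[1], size=spec.n)
    eps = rng.normal(0.0, spec.sigma, size=spec.n) if spec.sigma > 0 else np.zeros(spec.n)
    log_mass = spec.a + spec.b * x + eps
    species = [f"synthsp_{i:03d}" for i in range(spec.n)]
    subset = "combined" if spec.preparation == "intact" else spec.preparation
    return CalibrationDataset(
        _specimen_rows(species, x, log_mass, spec.preparation),
        subset_tag=subset,
        predictor_variant="minus_feet",
    )


def make_brownian_dataset(
    tree: dendropy.Tree,
    a: float,
    b: float,
    sigma2: float,
    seed: int = 0,
    x_range: tuple[float, float] = (4.6, 6.2),
) -> CalibrationDataset:
    """Dataset whose residuals are Brownian-correlated on a phylogeny.

    One specimen per tip; residuals are multivariate normal with covariance
    σ²·C(tree), C from :func:`brownian_covariance`.
    """
    species = [leaf.taxon.label.strip() for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(species) < 3:
        raise InvalidSpec("tree must have at least 3 labelled tips")
    if sigma2 < 0:
        raise InvalidSpec("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], size=len(species))
    if sigma2 > 0:
        C = brownian_covariance(tree, species)
        L = np.linalg.cholesky(sigma2 * C + 1e-12 * np.eye(len(species)))
        eps = L @ rng.standard_normal(len(species))
    else:
        eps = np.zeros(len(species))
    log_mass = a + b * x + eps
    return CalibrationDataset(
        _specimen_rows(species, x, log_mass, "eviscerated"),
        subset_tag="eviscerated",
        predictor_variant="minus_feet",
    )


def _data_path(name: str):
    return resources.files("hullmass.data").joinpath(name)


def load_pigeon_fixture() -> CalibrationDataset:
    """The packaged 20-specimen extant pigeon calibration table."""
    with resources.as_file(_data_path("pigeons.csv")) as p:
        df = pd.read_csv(p)
    return CalibrationDataset.from_frame(df, subset_tag="combined", predictor_variant="minus_feet")


def load_dodo_fixture() -> pd.DataFrame:
    """Hull volumes of the three composite dodo skeletons (mm³)."""
    with resources.as_file(_data_path("dodo.csv")) as p:
        return pd.read_csv(p)
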