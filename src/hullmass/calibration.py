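"""Allometric calibration of body mass against convex-hull volume.

Body mass M (g) is modelled against skeletal hull volume V (mm³) on
log10–log10 axes,

    log10 M = a + b · log10 V + ε,

fitted by ordinary least squares, and — to account for the shared ancestry
of the calibration species — by generalized least squares with residual
covariance proportional to shared branch lengths under a Brownian-motion
model on a phylogeny (PGLS). Because the fitted line is used predictively,
type-I regression is used throughout rather than reduced major axis.

The intercept is unit-bound: masses must be grams and volumes mm³.
Calibration specimens carry a preparation state ("eviscerated" carcasses
have had the internal organs removed; "intact" ones have not), and fits are
run per preparation subset and per predictor variant (whole-body hull volume
with or without the foot segments).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .errors import (
    InputError,
    InsufficientData,
    MissingTip,
    NonPositiveValue,
    SingularCovariance,
    UnknownTag,
)

PREPARATIONS = ("intact", "eviscerated")
SUBSET_TAGS = ("eviscerated", "intact", "combined")
VARIANTS = ("with_feet", "minus_feet")

#: number of free parameters in a simple-regression Gaussian likelihood
_K_PARAMS = 3  # intercept, slope, residual variance


@dataclass(frozen=True)
class Specimen:
    """One calibration carcass: species, mass and whole-body hull volumes."""

    species: str
    common_name: str
    mass_g: float
    preparation: str
    ch_vol_mm3: float
    ch_vol_minus_feet_mm3: float

    def __post_init__(self):
        if self.preparation not in PREPARATIONS:
            raise ValueError(f"preparation must be one of {PREPARATIONS}, got {self.preparation!r}")
        if not self.mass_g > 0:
            raise ValueError(f"{self.species}: mass must be positive")
        if not 0 < self.ch_vol_minus_feet_mm3 <= self.ch_vol_mm3:
            raise ValueError(
                f"{self.species}: need 0 < minus-feet volume <= with-feet volume"
            )


@dataclass
class CalibrationDataset:
    """A set of calibration specimens with a subset tag and predictor variant."""

    specimens: list[Specimen]
    subset_tag: str = "combined"
    predictor_variant: str = "minus_feet"

    def __post_init__(self):
        if self.subset_tag not in SUBSET_TAGS:
            raise UnknownTag(f"subset tag must be one of {SUBSET_TAGS}")
        if self.predictor_variant not in VARIANTS:
            raise ValueError(f"predictor variant must be one of {VARIANTS}")
        names = [s.species for s in self.specimens]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique within a dataset")

    @property
    def n(self) -> int:
        return len(self.specimens)

    @property
    def species(self) -> list[str]:
        return [s.species for s in self.specimens]

    def masses(self) -> np.ndarray:
        return np.array([s.mass_g for s in self.specimens], dtype=float)

    def volumes(self, variant: str | None = None) -> np.ndarray:
        variant = variant or self.predictor_variant
        if variant == "with_feet":
            return np.array([s.ch_vol_mm3 for s in self.specimens], dtype=float)
        if variant == "minus_feet":
            return np.array([s.ch_vol_minus_feet_mm3 for s in self.specimens], dtype=float)
        raise ValueError(f"unknown variant {variant!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.specimens])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, subset_tag: str = "combined", predictor_variant: str = "minus_feet"
    ) -> "CalibrationDataset":
        required = [
            "species",
            "common_name",
            "mass_g",
            "preparation",
            "ch_vol_mm3",
            "ch_vol_minus_feet_mm3",
        ]
        missing = set(required) - set(df.columns)
        if missing:
            raise InputError(f"specimen table missing columns: {sorted(missing)}")
        specimens = [
            Specimen(
                species=str(r.species).strip(),
                common_name=str(r.common_name),
                mass_g=float(r.mass_g),
                preparation=str(r.preparation).strip().lower(),
                ch_vol_mm3=float(r.ch_vol_mm3),
                ch_vol_minus_feet_mm3=float(r.ch_vol_minus_feet_mm3),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(specimens, subset_tag=subset_tag, predictor_variant=predictor_variant)

    @classmethod
    def from_csv(
        cls, path: str | Path, subset_tag: str = "combined", predictor_variant: str = "minus_feet"
    ) -> "CalibrationDataset":
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise InputError(f"could not read specimen CSV {path}: {exc}") from exc
        return cls.from_frame(df, subset_tag=subset_tag, predictor_variant=predictor_variant)


def subset_by_preparation(
    data: CalibrationDataset | list[Specimen], tag: str, predictor_variant: str | None = None
) -> CalibrationDataset:
    """Filter specimens by carcass preparation ("combined" keeps all)."""
    if tag not in SUBSET_TAGS:
        raise UnknownTag(f"unknown subset tag {tag!r}; expected one of {SUBSET_TAGS}")
    if isinstance(data, CalibrationDataset):
        specimens = data.specimens
        variant = predictor_variant or data.predictor_variant
    else:
        specimens = list(data)
        variant = predictor_variant or "minus_feet"
    if tag != "combined":
        specimens = [s for s in specimens if s.preparation == tag]
    return CalibrationDataset(specimens, subset_tag=tag, predictor_variant=variant)


@dataclass
class CalibrationModel:
    """A fitted log10–log10 mass–volume regression and its summary statistics.

    Carries everything needed to issue predictions with intervals without
    refitting: coefficients, sample size, predictor mean and sum of squares,
    residual SSE/MSE, coefficient standard errors, and the covariance
    structure used ("iid" for OLS, "brownian" for PGLS). For PGLS the stored
    mean/Sxx/SSE are the C⁻¹-weighted analogues, so the same interval
    formulas apply.
    """

    model_id: str
    a: float
    b: float
    n: int
    mean_x: float
    sxx: float
    sse: float
    mse: float
    r2: float
    se_a: float
    se_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    aic: float
    covariance: str = "iid"
    subset_tag: str = "combined"
    predictor_variant: str = "minus_feet"
    level: float = 0.95

    def __post_init__(self):
        if not -1e-12 <= self.r2 <= 1 + 1e-12:
            raise ValueError(f"r2 out of range: {self.r2}")
        if self.mse < 0:
            raise ValueError("MSE must be non-negative")
        if not self.sxx > 0:
            raise ValueError("Sxx must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci_a"] = list(d["ci_a"])
        d["ci_b"] = list(d["ci_b"])
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        d = dict(d)
        d["ci_a"] = tuple(d["ci_a"])
        d["ci_b"] = tuple(d["ci_b"])
        return cls(**d)

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def _design(data: CalibrationDataset) -> tuple[np.ndarray, np.ndarray]:
    masses = data.masses()
    vols = data.volumes()
    if np.any(masses <= 0) or np.any(vols <= 0):
        raise NonPositiveValue("all masses and volumes must be positive for log transforms")
    return np.log10(vols), np.log10(masses)


def _gaussian_aic(n: int, sse_w: float, logdet_c: float = 0.0) -> float:
    """AIC from the full Gaussian log-likelihood at the ML variance SSE/n.

    Returns -inf for a perfect fit (SSE = 0), a defined sentinel for
    noiseless synthetic data.
    """
    if sse_w <= 0:
        return float("-inf")
    sigma2 = sse_w / n
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet_c + n)
    return -2.0 * loglik + 2 * _K_PARAMS


def fit_loglog_ols(data: CalibrationDataset, level: float = 0.95) -> CalibrationModel:
    """Ordinary least squares fit of log10 mass on log10 hull volume."""
    if data.n < 3:
        raise InsufficientData(f"need at least 3 specimens, got {data.n}")
    x, y = _design(data)
    n = data.n
    xbar = float(x.mean())
    ybar = float(y.mean())
    sxx = float(((x - xbar) ** 2).sum())
    if sxx <= 0:
        raise InsufficientData("predictor has zero spread")
    sxy = float(((x - xbar) * (y - ybar)).sum())
    syy = float(((y - ybar) ** 2).sum())
    b = sxy / sxx
    a = ybar - b * xbar
    resid = y - (a + b * x)
    sse = float(resid @ resid)
    # snap exactly-collinear data to SSE = 0 so the noiseless path is well defined
    if sse <= 1e-24 * max(syy, 1.0):
        sse = 0.0
    mse = sse / (n - 2)
    r2 = 1.0 - sse / syy if syy > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    se_b = math.sqrt(mse / sxx)
    se_a = math.sqrt(mse * (1.0 / n + xbar**2 / sxx))
    tq = float(stats.t.ppf(0.5 + level / 2.0, n - 2))
    model = CalibrationModel(
        model_id=f"{data.subset_tag}_{data.predictor_variant}_ols",
        a=a,
        b=b,
        n=n,
        mean_x=xbar,
        sxx=sxx,
        sse=sse,
        mse=mse,
        r2=r2,
        se_a=se_a,
        se_b=se_b,
        ci_a=(a - tq * se_a, a + tq * se_a),
        ci_b=(b - tq * se_b, b + tq * se_b),
        aic=_gaussian_aic(n, sse),
        covariance="iid",
        subset_tag=data.subset_tag,
        predictor_variant=data.predictor_variant,
        level=level,
    )
    return model


def coefficient_ci(
    model: CalibrationModel, level: float = 0.95
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Symmetric t confidence intervals for (intercept, slope)."""
    if model.n < 3:
        raise InsufficientData("confidence intervals need n >= 3")
    tq = float(stats.t.ppf(0.5 + level / 2.0, model.n - 2))
    ci_a = (model.a - tq * model.se_a, model.a + tq * model.se_a)
    ci_b = (model.b - tq * model.se_b, model.b + tq * model.se_b)
    return ci_a, ci_b


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; underscores in labels are preserved."""
    p = Path(source)
    kwargs = dict(schema="newick", preserve_underscores=True)
    try:
        if p.exists():
            return dendropy.Tree.get(path=str(p), **kwargs)
        return dendropy.Tree.get(data=str(source), **kwargs)
    except Exception as exc:
        raise InputError(f"could not parse Newick tree: {exc}") from exc


def brownian_covariance(
    tree: dendropy.Tree, species_order: list[str], default_length: float = 1.0
) -> np.ndarray:
    """Brownian-motion covariance of tip values on a rooted tree.

    Entry (i, j) is the branch length shared by tips i and j, i.e. the depth
    of their most recent common ancestor below the root; the diagonal holds
    root-to-tip distances. Edges without a stated length get
    ``default_length`` (the convention here sets every branch to 1).
    """
    root = tree.seed_node
    depth: dict[int, float] = {id(root): 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        length = node.edge.length if node.edge.length is not None else default_length
        depth[id(node)] = depth[id(node.parent_node)] + float(length)

    leaf_by_label: dict[str, dendropy.Node] = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None:
            leaf_by_label[leaf.taxon.label.strip()] = leaf

    ancestors: list[dict[int, float]] = []
    tips: list[dendropy.Node] = []
    for name in species_order:
        key = name.strip()
        if key not in leaf_by_label:
            raise MissingTip(f"species {name!r} has no matching tip in the tree")
        leaf = leaf_by_label[key]
        path: dict[int, float] = {}
        node = leaf
        while node is not None:
            path[id(node)] = depth[id(node)]
            node = node.parent_node
        tips.append(leaf)
        ancestors.append(path)

    n = len(species_order)
    cov = np.zeros((n, n))
    for i in range(n):
        cov[i, i] = depth[id(tips[i])]
        for j in range(i + 1, n):
            shared = max(
                d for node_id, d in ancestors[i].items() if node_id in ancestors[j]
            )
            cov[i, j] = cov[j, i] = shared
    return cov


def fit_pgls(
    data: CalibrationDataset, tree: dendropy.Tree, level: float = 0.95
) -> CalibrationModel:
    """Phylogenetic GLS fit under a Brownian-motion covariance.

    Estimates (XᵀC⁻¹X)⁻¹XᵀC⁻¹y with C from :func:`brownian_covariance`.
    With C = I this reproduces OLS exactly. Summary statistics are the
    C⁻¹-weighted analogues of their OLS counterparts, and the AIC uses the
    full Gaussian likelihood including the log-determinant of C, so OLS and
    PGLS fits on the same data are directly comparable.
    """
    if data.n < 3:
        raise InsufficientData(f"need at least 3 specimens, got {data.n}")
    x, y = _design(data)
    n = data.n
    C = brownian_covariance(tree, data.species)
    try:
        cho = scipy.linalg.cho_factor(C)
    except scipy.linalg.LinAlgError as exc:
        raise SingularCovariance(f"Brownian covariance is not positive definite: {exc}") from exc
    logdet_c = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))

    X = np.column_stack([np.ones(n), x])
    Ci_X = scipy.linalg.cho_solve(cho, X)
    Ci_y = scipy.linalg.cho_solve(cho, y)
    XtCiX = X.T @ Ci_X
    beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    a, b = float(beta[0]), float(beta[1])

    resid = y - X @ beta
    Ci_r = scipy.linalg.cho_solve(cho, resid)
    sse = float(resid @ Ci_r)
    if sse <= 1e-24 * max(float(y @ scipy.linalg.cho_solve(cho, y)), 1.0):
        sse = 0.0
    mse = sse / (n - 2)

    ones = np.ones(n)
    Ci_1 = scipy.linalg.cho_solve(cho, ones)
    w_tot = float(ones @ Ci_1)
    xbar = float(x @ Ci_1) / w_tot
    ybar = float(y @ Ci_1) / w_tot
    dx = x - xbar
    dy = y - ybar
    sxx = float(dx @ scipy.linalg.cho_solve(cho, dx))
    syy = float(dy @ scipy.linalg.cho_solve(cho, dy))
    r2 = 1.0 - sse / syy if syy > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)

    cov_beta = mse * np.linalg.inv(XtCiX)
    se_a = math.sqrt(cov_beta[0, 0])
    se_b = math.sqrt(cov_beta[1, 1])
    tq = float(stats.t.ppf(0.5 + level / 2.0, n - 2))
    return CalibrationModel(
        model_id=f"{data.subset_tag}_{data.predictor_variant}_pgls",
        a=a,
        b=b,
        n=n,
        mean_x=xbar,
        sxx=sxx,
        sse=sse,
        mse=mse,
        r2=r2,
        se_a=se_a,
        se_b=se_b,
        ci_a=(a - tq * se_a, a + tq * se_a),
        ci_b=(b - tq * se_b, b + tq * se_b),
        aic=_gaussian_aic(n, sse, logdet_c),
        covariance="brownian",
        subset_tag=data.subset_tag,
        predictor_variant=data.predictor_variant,
        level=level,
    )


def aic(model: CalibrationModel) -> float:
    """Akaike Information Criterion of a fitted model (stored at fit time)."""
    return model.aic


def summary_table(models: list[CalibrationModel]) -> pd.DataFrame:
    """One row per model: coefficients, CIs, r², MSE and AIC."""
    rows = []
    for m in models:
        rows.append(
            {
                "model": m.model_id,
                "subset": m.subset_tag,
                "variant": m.predictor_variant,
                "covariance": m.covariance,
                "n": m.n,
                "a": m.a,
                "a_ci_low": m.ci_a[0],
                "a_ci_high": m.ci_a[1],
                "b": m.b,
                "b_ci_low": m.ci_b[0],
                "b_ci_high": m.ci_b[1],
                "r2": m.r2,
                "mse": m.mse,
                "aic": m.aic,
            }
        )
    return pd.DataFrame(rows)
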