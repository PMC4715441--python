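"""Fossil body-mass prediction from convex-hull volume.

Given a fitted log10–log10 calibration, a fossil hull volume V (mm³) yields

    point mass      M = 10^(a + b·log10 V)
    corrected mass  M · e^(MSE/2)

where the multiplicative factor e^(MSE/2) corrects the downward bias
introduced by back-transforming a log-linear model into a power function
(MSE is the residual mean square on the log10 scale). The 95% prediction
interval is computed on the log10 scale with the usual new-observation
standard error,

    ŷ ± t(1−α/2, n−2) · √(MSE · (1 + 1/n + (x₀ − x̄)²/Sxx)),

back-transformed, and scaled by the same correction factor so that the
interval stays symmetric about the corrected estimate in log space.

Two further quantities bracket the estimate from below and above:

* a density floor — hull volume × whole-carcass density is a hard lower
  bound on mass, because the true body volume cannot be smaller than the
  skeleton's hull volume (default density 648 kg/m³, the literature value
  for an intact feathered pigeon);
* a viscera correction — predictions from an eviscerated calibration are
  multiplied by 1.33 to approximate live mass, the organ-mass fraction
  quantified in extant rock doves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationModel
from .errors import InputError, InsufficientData, NonPositiveValue, VariantMismatch

DEFAULT_DENSITY_KG_M3 = 648.0
DEFAULT_VISCERA_FACTOR = 1.33

#: grams per (mm³ × kg/m³)
_G_PER_MM3_KG_M3 = 1e-6


@dataclass(frozen=True)
class MassEstimate:
    """A back-transformed mass prediction with its prediction interval."""

    ch_vol_mm3: float
    model_id: str
    point_mass_g: float
    corrected_mass_g: float
    pi_low_g: float
    pi_high_g: float
    level: float

    def __post_init__(self):
        if not (self.pi_low_g <= self.point_mass_g <= self.pi_high_g):
            raise ValueError("prediction interval must bracket the point estimate")
        if self.corrected_mass_g < self.point_mass_g:
            raise ValueError("smearing-corrected mass cannot be below the point estimate")
        if min(self.point_mass_g, self.pi_low_g) <= 0:
            raise ValueError("masses must be positive")


def prediction_interval(
    model: CalibrationModel, ch_vol: float, level: float = 0.95
) -> tuple[float, float]:
    """95% (by default) prediction interval for the mass at one hull volume.

    Bounds are back-transformed to grams and carry the e^(MSE/2) correction
    applied to the point estimate, preserving log-scale symmetry.
    """
    if not ch_vol > 0:
        raise NonPositiveValue("hull volume must be positive")
    if model.n < 3:
        raise InsufficientData("prediction intervals need n >= 3")
    if not model.sxx > 0:
        raise InsufficientData("prediction intervals need Sxx > 0")
    x0 = np.log10(ch_vol)
    yhat = model.a + model.b * x0
    se = np.sqrt(model.mse * (1.0 + 1.0 / model.n + (x0 - model.mean_x) ** 2 / model.sxx))
    tq = float(stats.t.ppf(0.5 + level / 2.0, model.n - 2))
    smear = np.exp(model.mse / 2.0)
    low = 10.0 ** (yhat - tq * se) * smear
    high = 10.0 ** (yhat + tq * se) * smear
    return float(low), float(high)


def predict_mass(model: CalibrationModel, ch_vol: float, level: float = 0.95) -> MassEstimate:
    """Point estimate, smearing-corrected estimate and PI at one hull volume."""
    if not ch_vol > 0:
        raise NonPositiveValue("hull volume must be positive")
    x0 = np.log10(ch_vol)
    point = float(10.0 ** (model.a + model.b * x0))
    corrected = point * float(np.exp(model.mse / 2.0))
    low, high = prediction_interval(model, ch_vol, level=level)
    return MassEstimate(
        ch_vol_mm3=float(ch_vol),
        model_id=model.model_id,
        point_mass_g=point,
        corrected_mass_g=corrected,
        pi_low_g=low,
        pi_high_g=high,
        level=level,
    )


def density_floor(ch_vol: float, density: float = DEFAULT_DENSITY_KG_M3) -> float:
    """Hard lower bound on mass (g): hull volume (mm³) × density (kg/m³)."""
    if not (ch_vol > 0 and density > 0):
        raise NonPositiveValue("hull volume and density must be positive")
    return float(ch_vol * density * _G_PER_MM3_KG_M3)


def viscera_correction(mass: float, factor: float = DEFAULT_VISCERA_FACTOR) -> float:
    """Scale an eviscerated-mass estimate up to approximate live mass."""
    if not mass > 0:
        raise NonPositiveValue("mass must be positive")
    if factor < 1:
        raise ValueError("viscera factor must be >= 1")
    return float(mass * factor)


def apply_external_model(
    a: float,
    b: float,
    ch_vol: float,
    *,
    n: int | None = None,
    mean_x: float | None = None,
    sxx: float | None = None,
    mse: float | None = None,
    level: float = 0.95,
    model_id: str = "external",
    predictor_variant: str = "with_feet",
):
    """Predict from externally published coefficients.

    With only (a, b) the return value is the bare point mass in grams,
    10^(a + b·log10 V). When the full calibration statistics (n, x̄, Sxx,
    MSE) are also supplied, the result is a full :class:`MassEstimate`,
    identical to :func:`predict_mass` on an equivalent model.
    """
    if not ch_vol > 0:
        raise NonPositiveValue("hull volume must be positive")
    stats_given = [n, mean_x, sxx, mse]
    if any(v is None for v in stats_given):
        if not all(v is None for v in stats_given):
            raise InputError("supply all of n, mean_x, sxx, mse or none of them")
        return float(10.0 ** (a + b * np.log10(ch_vol)))
    model = CalibrationModel(
        model_id=model_id,
        a=a,
        b=b,
        n=int(n),
        mean_x=float(mean_x),
        sxx=float(sxx),
        sse=float(mse) * (int(n) - 2),
        mse=float(mse),
        r2=0.0,
        se_a=float("nan"),
        se_b=float("nan"),
        ci_a=(a, a),
        ci_b=(b, b),
        aic=float("nan"),
        covariance="iid",
        subset_tag="combined",
        predictor_variant=predictor_variant,
        level=level,
    )
    return predict_mass(model, ch_vol, level=level)


def read_fossil_csv(path: str | Path) -> pd.DataFrame:
    """Fossil volume table: specimen,ch_vol_mm3,ch_vol_minus_feet_mm3."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"could not read fossil CSV {path}: {exc}") from exc
    required = {"specimen", "ch_vol_mm3", "ch_vol_minus_feet_mm3"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"fossil table missing columns: {sorted(missing)}")
    return df


def predict_fossils(
    model: CalibrationModel,
    fossils: pd.DataFrame,
    level: float = 0.95,
    density: float = DEFAULT_DENSITY_KG_M3,
    viscera_factor: float = DEFAULT_VISCERA_FACTOR,
) -> pd.DataFrame:
    """Per-fossil prediction report mirroring a mass-table layout.

    The predictor column is chosen by the model's ``predictor_variant``
    (pigeon-calibrated models use minus-feet volumes; external ground-bird
    coefficients use with-feet volumes); supplying a table without that
    column is a hard error rather than a silent substitution. The density
    floor always uses the full with-feet hull volume.
    """
    col = "ch_vol_minus_feet_mm3" if model.predictor_variant == "minus_feet" else "ch_vol_mm3"
    if col not in fossils.columns:
        raise VariantMismatch(
            f"model predicts from {model.predictor_variant!r} volumes but column {col!r} is absent"
        )
    rows = []
    for r in fossils.itertuples(index=False):
        vol = float(getattr(r, col))
        est = predict_mass(model, vol, level=level)
        floor_vol = float(getattr(r, "ch_vol_mm3", vol))
        rows.append(
            {
                "specimen": r.specimen,
                "model": model.model_id,
                "ch_vol_used_mm3": vol,
                "point_mass_g": est.point_mass_g,
                "corrected_mass_g": est.corrected_mass_g,
                "pi_low_g": est.pi_low_g,
                "pi_high_g": est.pi_high_g,
                "level": level,
                "density_floor_g": density_floor(floor_vol, density),
                "viscera_mass_g": viscera_correction(est.corrected_mass_g, viscera_factor),
                "viscera_pi_low_g": viscera_correction(est.pi_low_g, viscera_factor),
                "viscera_pi_high_g": viscera_correction(est.pi_high_g, viscera_factor),
            }
        )
    return pd.DataFrame(rows)


def round_report(report: pd.DataFrame) -> pd.DataFrame:
    """Presentation rounding: grams to integers, with kg columns to 0.1 kg."""
    out = report.copy()
    gram_cols = [c for c in out.columns if c.endswith("_g")]
    for c in gram_cols:
        out[c.replace("_g", "_kg")] = (out[c] / 1000.0).round(1)
        out[c] = out[c].round(0).astype(int)
    return out
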