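"""Closed-form log BCF predictors and regulatory screening rules.

Two families of predictors live here:

* the IAM-based multiple-linear-regression models fitted on the
  120-compound training set (MLR1–MLR3), with their published
  coefficients, standard errors and validation statistics; and
* the classical log Kow-based compendium used in regulatory screening —
  six historical linear regressions, four non-linear forms, the
  Technical Guidance Document (TGD) piecewise model, the Meylan and
  US EPA (EPI Suite BCFBAF) piecewise models with ionic/non-ionic
  branches, the CAESAR combination rule and a quantum-descriptor model.

All predictors are pure functions of their inputs.  Regulatory
bioaccumulation categories: BCF < 1000 not significant, 1000–5000
bioaccumulative, > 5000 highly bioaccumulative.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

from .compound_data import CompoundRecord


class Category(str, enum.Enum):
    """Regulatory bioaccumulation category."""

    NOT_SIGNIFICANT = "not_significant"
    BIOACCUMULATIVE = "bioaccumulative"
    HIGHLY_BIOACCUMULATIVE = "highly_bioaccumulative"


@dataclass(frozen=True)
class LinearModel:
    """Intercept + named linear coefficients, with optional fit metadata."""

    name: str
    intercept: float
    coefficients: dict[str, float]
    coefficient_se: dict[str, float] | None = None
    intercept_se: float | None = None
    n_train: int | None = None
    stats: dict[str, float] = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return list(self.coefficients)

    def evaluate(self, values: Mapping[str, float]) -> float:
        total = self.intercept
        for var, coef in self.coefficients.items():
            if var not in values:
                raise KeyError(f"model {self.name!r} requires variable {var!r}")
            total += coef * float(values[var])
        return total


@dataclass(frozen=True)
class BcfPrediction:
    """One model's prediction plus screening metadata."""

    model_name: str
    log_bcf: float
    category: Category
    ad_warnings: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# IAM retention models (fitted on the 120-compound training set)
# --------------------------------------------------------------------------

MLR1 = LinearModel(
    name="MLR1",
    intercept=0.18,
    coefficients={"log_kw_iam": 0.70},
    coefficient_se={"log_kw_iam": 0.03},
    intercept_se=0.06,
    n_train=120,
    stats={
        "r2": 0.80, "r2_adj": 0.80, "rmsecv": 0.30, "rmsep_ext": 0.45,
        "rmsep_vivo": 0.35, "r2_vivo": 0.74, "F": 470.5,
    },
)

MLR2 = LinearModel(
    name="MLR2",
    intercept=0.27,
    coefficients={"log_kw_iam": 0.71, "TPSA": -0.0043, "F_Csp3": 0.24, "HD": -0.089},
    coefficient_se={"log_kw_iam": 0.03, "TPSA": 0.0009, "F_Csp3": 0.06, "HD": 0.036},
    intercept_se=0.06,
    n_train=120,
    stats={
        "r2": 0.87, "r2_adj": 0.87, "rmsecv": 0.25, "rmsep_ext": 0.42,
        "rmsep_vivo": 0.27, "r2_vivo": 0.83, "F": 198.4,
    },
)

MLR3 = LinearModel(
    name="MLR3",
    intercept=0.14,
    coefficients={
        "log_kw_iam": 0.74, "TPSA": -0.0037, "F_Csp3": 0.35,
        "HD": -0.16, "FRB": -0.026, "DipH": 0.29,
    },
    coefficient_se={
        "log_kw_iam": 0.03, "TPSA": 0.0011, "F_Csp3": 0.07,
        "HD": 0.04, "FRB": 0.011, "DipH": 0.08,
    },
    intercept_se=0.06,
    n_train=120,
    stats={
        "r2": 0.89, "r2_adj": 0.88, "rmsecv": 0.17, "rmsep_ext": 0.45,
        "rmsep_vivo": 0.27, "r2_vivo": 0.83, "F": 147.3,
    },
)

MLR_MODELS: dict[str, LinearModel] = {"mlr1": MLR1, "mlr2": MLR2, "mlr3": MLR3}


def predict_mlr(model: LinearModel, record: CompoundRecord) -> float:
    """Evaluate a fitted linear model on one compound.

    Raises a named error when the record lacks a required variable.
    """
    values: dict[str, float] = {}
    for var in model.coefficients:
        if var == "log_kw_iam":
            if record.log_kw_iam is None:
                raise KeyError(
                    f"compound {record.id!r} is missing log_kw_iam required by "
                    f"{model.name}"
                )
            values[var] = record.log_kw_iam
        else:
            values[var] = record.descriptor(var)
    return model.evaluate(values)


# --------------------------------------------------------------------------
# Classical log Kow compendium
# --------------------------------------------------------------------------

#: Historical linear log BCF = a·log Kow + b regressions.
KOW_LINEAR: dict[str, tuple[float, float]] = {
    "eq1": (0.542, 0.124),
    "eq2": (0.85, -0.70),
    "eq3": (1.0, -1.32),
    "eq4": (0.94, -1.00),
    "eq5": (0.516, 0.576),
    "eq6": (0.80, -0.52),
}


def predict_kow_linear(variant: str, log_kow: float) -> float:
    """Evaluate one of the six historical linear log Kow regressions."""
    try:
        slope, intercept = KOW_LINEAR[variant]
    except KeyError:
        raise ValueError(
            f"unknown linear variant {variant!r}; choose from {sorted(KOW_LINEAR)}"
        ) from None
    return slope * log_kow + intercept


def predict_kow_nonlinear(
    variant: str,
    log_kow: float,
    molar_volume: float | None = None,
    eq8_log_form: bool = True,
) -> float:
    """Evaluate one of the non-linear log Kow models.

    ``eq7``  quadratic; ``eq8`` bilinear-type with a Kow-dependent
    correction (the logarithmic reading is the default; the literally
    printed product form is available with ``eq8_log_form=False``);
    ``eq9`` quartic polynomial; ``eq10`` quadratic with a molar-volume
    term (requires ``molar_volume``).
    """
    L = log_kow
    if variant == "eq7":
        return -0.164 * L**2 + 2.069 * L - 2.592
    if variant == "eq8":
        correction = 6.8e-7 * 10.0**L + 1.0
        if eq8_log_form:
            return 0.910 * L - 1.975 * math.log10(correction) - 0.786
        return 0.910 * L - 1.975 * correction - 0.786
    if variant == "eq9":
        return 0.0069 * L**4 - 0.185 * L**3 + 1.55 * L**2 - 4.18 * L + 4.79
    if variant == "eq10":
        if molar_volume is None:
            raise ValueError("eq10 requires molar_volume")
        return 3.036 * L - 0.197 * L**2 - 0.808 * molar_volume
    raise ValueError(
        f"unknown nonlinear variant {variant!r}; choose from eq7, eq8, eq9, eq10"
    )


def predict_tgd(log_kow: float) -> float:
    """Technical Guidance Document piecewise log Kow → log BCF model.

    Constant 0.15 below log Kow 1, linear on [1, 6], quadratic on
    (6, 10), constant 2.68 at and above 10; the branches meet at the
    breakpoints.
    """
    L = log_kow
    if L < 1.0:
        return 0.15
    if L <= 6.0:
        return 0.85 * L - 0.70
    if L < 10.0:
        return -0.20 * L**2 + 2.74 * L - 4.72
    return 2.68


def predict_meylan(
    log_kow: float,
    ionic: bool = False,
    sum_F: float = 0.0,
    scheme: str = "meylan",
) -> float:
    """Meylan or US EPA (EPI Suite BCFBAF) piecewise screening model.

    Non-ionic compounds follow a rising mid-range regression plus the
    correction-factor sum ΣF_i, a falling branch above log Kow 7 and
    the constant 0.50 outside (1, 10.5].  Ionic compounds use a step
    function of log Kow whose band edges differ slightly between the
    two schemes.  Abutting printed ranges are resolved with the lower
    branch closed at its upper endpoint.
    """
    if scheme not in ("meylan", "us_epa"):
        raise ValueError(f"unknown scheme {scheme!r}; choose 'meylan' or 'us_epa'")
    L = log_kow
    if ionic:
        upper_175 = 7.0 if scheme == "meylan" else 8.0
        if L < 5.0 or L > 9.0:
            return 0.50
        if L <= 6.0:
            return 0.75
        if L <= upper_175:
            return 1.75
        return 1.00
    if L < 1.0 or L > 10.5:
        return 0.50
    if L <= 7.0:
        if scheme == "meylan":
            return 0.77 * L - 0.70 + sum_F
        return 0.6598 * L - 0.333 + sum_F
    if scheme == "meylan":
        return -1.37 * L + 14.4 + sum_F
    return -0.49 * L + 7.554 + sum_F


def caesar_combine(log_kow: float, bcf_a: float, bcf_b: float) -> float:
    """Combine CAESAR sub-model outputs log BCF_A and log BCF_B.

    The sub-models themselves are external inputs; only the published
    log Kow-dependent combination rule is applied here.
    """
    mean = 0.5 * (bcf_a + bcf_b)
    if log_kow <= 1.355:
        return 0.936 * mean - 0.123
    if log_kow <= 2.410:
        return 0.996 * min(bcf_a, bcf_b)
    return 1.052 * mean


def predict_quantum(mw: float, e_t: float, e_homo: float, e_lumo: float) -> float:
    """Quantum-descriptor BCF model (Mw in g/mol, E_T in hartree, orbital
    energies in eV).  Returned on the scale the source prints (unlabeled)."""
    return 0.00250 * mw - 0.0724 * e_t - 0.214 * e_homo - 0.892 * e_lumo - 2.58


# --------------------------------------------------------------------------
# Screening
# --------------------------------------------------------------------------

def categorize(log_bcf: float) -> Category:
    """Regulatory category from log BCF (thresholds on BCF = 10^log_bcf;
    both boundaries belong to the middle category)."""
    bcf = 10.0**log_bcf
    if bcf < 1000.0:
        return Category.NOT_SIGNIFICANT
    if bcf <= 5000.0:
        return Category.BIOACCUMULATIVE
    return Category.HIGHLY_BIOACCUMULATIVE


def applicability_flags(
    record: CompoundRecord, extrapolated_log_kw: bool = False
) -> list[str]:
    """Applicability-domain warnings for the IAM models.

    Above log Kow ≈ 7 IAM retention times become too long for log kw^IAM
    to be measured, so predictions there are outside the models'
    domain; extrapolated (rather than directly measured) log kw^IAM is
    flagged as a mild quality caveat.
    """
    flags: list[str] = []
    log_kow = record.descriptors.get("logKow")
    if log_kow is not None and log_kow > 7.0:
        flags.append("logKow_above_7")
    if extrapolated_log_kw:
        flags.append("extrapolated_logkw")
    return flags


def predict_with_screening(
    model: LinearModel,
    record: CompoundRecord,
    extrapolated_log_kw: bool = False,
) -> BcfPrediction:
    """Predict log BCF with an IAM model and attach category + AD flags."""
    log_bcf = predict_mlr(model, record)
    return BcfPrediction(
        model_name=model.name,
        log_bcf=log_bcf,
        category=categorize(log_bcf),
        ad_warnings=tuple(applicability_flags(record, extrapolated_log_kw)),
    )
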