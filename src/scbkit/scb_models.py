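"""Scleral-Conjunctival Bilirubin (SCB) prediction models.

Two linear models map sclera chromaticity to an SCB value in umol/L:

* ``SCB_JECI = m * JECI + n``  -- simple regression on the Jaundice Eye
  Colour Index, a one-dimensional yellowness proxy;
* ``SCB_xy = p * x + q * y + r`` -- multiple regression on both free
  chromaticity coordinates (z is redundant since x + y + z = 1).

Both are fit by ordinary least squares against total serum bilirubin
(TSB).  Model quality is reported as Pearson correlation with TSB and as
leave-one-out cross-validated RMSE, which is the honest generalization
error for cohorts of this size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .colorimetry import Chromaticity, jeci as _jeci

__all__ = [
    "SubjectRecord",
    "SCBJECIModel",
    "SCBXYModel",
    "FitReport",
    "fit_scb_jeci",
    "fit_scb_xy",
    "predict_scb",
    "pearson_r",
    "loocv_rmse",
]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: estimated sclera chromaticity, JECI and measured TSB."""

    subject_id: str
    chromaticity: Chromaticity
    jeci: float
    tsb: float

    def __post_init__(self) -> None:
        if self.tsb < 0:
            raise ValueError("TSB must be non-negative")
        if abs(self.jeci - _jeci(self.chromaticity)) > 1e-9:
            raise ValueError("jeci field inconsistent with chromaticity")

    @classmethod
    def from_chromaticity(
        cls, subject_id: str, chromaticity: Chromaticity, tsb: float
    ) -> "SubjectRecord":
        return cls(subject_id, chromaticity, _jeci(chromaticity), tsb)


@dataclass(frozen=True)
class SCBJECIModel:
    """SCB = m * JECI + n; m in umol/L per JECI unit, n in umol/L."""

    m: float
    n: float

    def predict(self, jeci_value: float) -> float:
        return self.m * jeci_value + self.n

    def to_dict(self) -> dict:
        return {"family": "jeci", "m": self.m, "n": self.n}


@dataclass(frozen=True)
class SCBXYModel:
    """SCB = p * x + q * y + r_intercept, in umol/L."""

    p: float
    q: float
    r_intercept: float

    def predict(self, x: float, y: float) -> float:
        return self.p * x + self.q * y + self.r_intercept

    def to_dict(self) -> dict:
        return {"family": "xy", "p": self.p, "q": self.q, "r": self.r_intercept}


@dataclass(frozen=True)
class FitReport:
    """A fitted SCB model with its association and cross-validation stats."""

    model: Union[SCBJECIModel, SCBXYModel]
    pearson_r: float
    pearson_p: float
    loocv_rmse: float
    n: int

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "loocv_rmse_umol_per_L": self.loocv_rmse,
            "n": self.n,
        }


def pearson_r(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with the exact two-sided t-test p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in input")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def _records_arrays(records: Sequence[SubjectRecord]):
    x = np.array([r.chromaticity.x for r in records])
    y = np.array([r.chromaticity.y for r in records])
    j = np.array([r.jeci for r in records])
    tsb = np.array([r.tsb for r in records])
    return x, y, j, tsb


def _fit_jeci_coeffs(j: np.ndarray, tsb: np.ndarray) -> SCBJECIModel:
    if np.ptp(j) == 0:
        raise ValueError("degenerate predictor: all JECI values equal")
    res = stats.linregress(j, tsb)
    return SCBJECIModel(m=float(res.slope), n=float(res.intercept))


def _fit_xy_coeffs(x: np.ndarray, y: np.ndarray, tsb: np.ndarray) -> SCBXYModel:
    A = np.column_stack([x, y, np.ones_like(x)])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("rank-deficient design: x and y chromaticity are collinear")
    coef, *_ = np.linalg.lstsq(A, tsb, rcond=None)
    return SCBXYModel(p=float(coef[0]), q=float(coef[1]), r_intercept=float(coef[2]))


def fit_scb_jeci(records: Sequence[SubjectRecord]) -> FitReport:
    """OLS fit of TSB on JECI, with Pearson r and LOOCV RMSE."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    _, _, j, tsb = _records_arrays(records)
    model = _fit_jeci_coeffs(j, tsb)
    r, p = pearson_r(j, tsb)
    rmse = loocv_rmse(records, "jeci") if len(records) >= 4 else float("nan")
    return FitReport(model=model, pearson_r=r, pearson_p=p, loocv_rmse=rmse, n=len(records))


def fit_scb_xy(records: Sequence[SubjectRecord]) -> FitReport:
    """OLS fit of TSB on (x, y, 1), with Pearson r (of predictions vs TSB)
    and LOOCV RMSE.

    With two predictors the reported correlation is between the in-sample
    model predictions and TSB (the multiple correlation coefficient).
    """
    if len(records) < 4:
        raise ValueError("need at least 4 records")
    x, y, _, tsb = _records_arrays(records)
    model = _fit_xy_coeffs(x, y, tsb)
    pred = model.p * x + model.q * y + model.r_intercept
    r, p = pearson_r(pred, tsb)
    rmse = loocv_rmse(records, "xy") if len(records) >= 5 else float("nan")
    return FitReport(model=model, pearson_r=r, pearson_p=p, loocv_rmse=rmse, n=len(records))


def predict_scb(
    model: Union[SCBJECIModel, SCBXYModel], chrom: Chromaticity
) -> float:
    """Evaluate a fitted SCB model at a chromaticity.

    Extreme chromaticities can produce negative SCB; the value is reported
    as-is (with a warning) rather than truncated, so that agreement and
    ROC analyses downstream see the raw model output.
    """
    if isinstance(model, SCBJECIModel):
        scb = model.predict(_jeci(chrom))
    elif isinstance(model, SCBXYModel):
        scb = model.predict(chrom.x, chrom.y)
    else:
        raise TypeError(f"unknown model type {type(model)!r}")
    if scb < 0:
        warnings.warn("negative SCB prediction (extreme chromaticity)", stacklevel=2)
    return float(scb)


def loocv_rmse(
    records: Sequence[SubjectRecord],
    model_family: Literal["jeci", "xy"],
) -> float:
    """Leave-one-out RMSE of TSB prediction, in umol/L.

    Each subject's TSB is predicted from a model fit on the other n-1
    subjects; the RMSE is over those held-out errors.
    """
    n = len(records)
    min_n = 4 if model_family == "jeci" else 5
    if n < min_n:
        raise ValueError(f"need at least {min_n} records for {model_family} LOOCV")
    x, y, j, tsb = _records_arrays(records)
    errors = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        if model_family == "jeci":
            m = _fit_jeci_coeffs(j[keep], tsb[keep])
            pred = m.predict(j[i])
        else:
            m = _fit_xy_coeffs(x[keep], y[keep], tsb[keep])
            pred = m.predict(x[i], y[i])
        errors[i] = pred - tsb[i]
    return float(np.sqrt(np.mean(errors**2)))
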