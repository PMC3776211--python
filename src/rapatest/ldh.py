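"""Lactate-dehydrogenase (LDH) cell-number assay.

Cell numbers in cultured lymphocytes are estimated from LDH release: lysed
cultures are read as absorbance at 490 nm, which is directly proportional to
the number of cells in the well.  A calibration curve fitted to LDH-positive
standards converts absorbance to cells; triplicate wells are aggregated with
a coefficient-of-variation quality gate (pass requires CV < 10%).
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Condition",
    "CalibrationCurve",
    "LDHMeasurement",
    "CellCount",
    "QCStatus",
    "fit_calibration",
    "aggregate_triplicates",
    "absorbance_to_cells",
]

#: CV threshold for the triplicate quality gate (pass requires CV strictly below).
QC_CV_THRESHOLD = 0.10


class Condition(str, enum.Enum):
    """Culture condition an LDH well belongs to."""

    SEED = "seed"
    UNTREATED_72H = "untreated_72h"
    RAPAMYCIN_72H = "rapamycin_72h"


class QCStatus(str, enum.Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_ASSESSABLE = "not_assessable"


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line ``absorbance = slope * cells + intercept``.

    The intercept is retained (not forced through zero) because blank wells
    carry background absorbance.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")
        if self.n_points < 2:
            raise ValueError("calibration requires at least 2 points")


@dataclass
class LDHMeasurement:
    """Replicate absorbances for one culture condition."""

    condition: Condition
    absorbances: list[float]
    mean: float = field(init=False)
    cv: float | None = field(init=False)
    qc: QCStatus = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.absorbances, dtype=float)
        if arr.size < 1:
            raise ValueError("at least one replicate absorbance is required")
        if np.any(arr < 0):
            raise ValueError("absorbances must be non-negative")
        self.mean, self.cv, self.qc = aggregate_triplicates(self.absorbances)


@dataclass(frozen=True)
class CellCount:
    """Continuous cell-number estimate for one well/condition."""

    value: float
    condition: Condition
    qc: QCStatus = QCStatus.PASS
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("cell count cannot be negative")


def fit_calibration(standards) -> CalibrationCurve:
    """Fit the absorbance-vs-cells calibration line by unweighted OLS.

    Parameters
    ----------
    standards : sequence of (cell_count, absorbance) pairs
        At least two distinct cell counts are required.
    """
    pts = np.asarray(list(standards), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (cells, absorbance) calibration points")
    cells, absorb = pts[:, 0], pts[:, 1]
    if np.any(absorb < 0):
        raise ValueError("negative absorbance in calibration standards")
    if np.unique(cells).size < 2:
        raise ValueError("calibration design is singular: all cell counts identical")

    design = np.column_stack([cells, np.ones_like(cells)])
    (slope, intercept), *_ = np.linalg.lstsq(design, absorb, rcond=None)
    fitted = design @ np.array([slope, intercept])
    ss_res = float(np.sum((absorb - fitted) ** 2))
    ss_tot = float(np.sum((absorb - absorb.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CalibrationCurve(slope=float(slope), intercept=float(intercept),
                            r_squared=r2, n_points=pts.shape[0])


def aggregate_triplicates(raw) -> tuple[float, float | None, QCStatus]:
    """Aggregate replicate absorbances into (mean, CV, QC status).

    CV = sample SD / mean.  QC passes only when CV < 0.10 (strict); a single
    replicate has no CV and is flagged ``not_assessable``; a zero mean with
    nonzero spread makes CV undefined and fails QC.  Flagged wells are never
    dropped here — the flag propagates.
    """
    arr = np.asarray(list(raw), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicates supplied")
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, None, QCStatus.NOT_ASSESSABLE
    sd = float(arr.std(ddof=1))
    if mean == 0:
        if sd == 0:
            return mean, 0.0, QCStatus.PASS
        return mean, None, QCStatus.FAIL
    cv = sd / mean
    status = QCStatus.PASS if cv < QC_CV_THRESHOLD else QCStatus.FAIL
    return mean, cv, status


def absorbance_to_cells(measurement: LDHMeasurement, curve: CalibrationCurve,
                        *, allow_qc_fail: bool = False) -> CellCount:
    """Invert the calibration line: cells = (mean absorbance − intercept)/slope.

    Estimates below zero are clipped to 0 with a warning (physical lower
    bound).  QC-failed measurements are refused unless ``allow_qc_fail``.
    """
    if measurement.qc is QCStatus.FAIL and not allow_qc_fail:
        raise ValueError(
            f"measurement for {measurement.condition.value} failed triplicate QC "
            f"(cv={measurement.cv}); pass allow_qc_fail=True to override"
        )
    cells = (measurement.mean - curve.intercept) / curve.slope
    clipped = False
    if cells < 0:
        warnings.warn(
            f"negative cell estimate ({cells:.1f}) clipped to 0 for "
            f"{measurement.condition.value}", stacklevel=2)
        cells, clipped = 0.0, True
    return CellCount(value=float(cells), condition=measurement.condition,
                     qc=measurement.qc, clipped=clipped)
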