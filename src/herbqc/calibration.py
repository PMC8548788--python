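"""External-standard calibration and relative correction factors (RCF).

The single-marker method (QAMS) quantifies several analytes from one
calibrated marker compound. Its central quantity is the relative correction
factor

    f_si = f_s / f_i = (A_s / C_s) / (A_i / C_i)

the ratio of the marker's detector response factor to an analyte's response
factor, measured from (peak area, concentration) pairs of standard
solutions. This module fits ordinary-least-squares calibration curves
(area = a * conc + b), computes response factors and RCFs, and summarises
RCF robustness (mean and RSD) across instrument conditions such as flow
rate and column temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear detector response of one compound: area = slope * conc + intercept.

    Concentrations are in ug/ml, areas in mAU*min. ``linear_range`` is the
    (low, high) concentration span over which the fit was established;
    predictions outside it are extrapolations and are flagged downstream.
    """

    compound: str
    slope: float
    intercept: float
    r_squared: float = 1.0
    linear_range: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"{self.compound}: slope must be positive, got {self.slope}")
        lo, hi = self.linear_range
        if not lo < hi:
            raise ValueError(f"{self.compound}: invalid linear range {self.linear_range}")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"{self.compound}: r_squared outside [0, 1]")

    def predict(self, conc_ug_ml: float) -> float:
        """Predicted peak area at a concentration (linear, may extrapolate)."""
        return self.slope * conc_ug_ml + self.intercept

    def invert(self, area: float) -> float:
        """Concentration (ug/ml) at which the curve gives ``area``."""
        return (area - self.intercept) / self.slope

    def in_range(self, conc_ug_ml: float) -> bool:
        lo, hi = self.linear_range
        return lo <= conc_ug_ml <= hi


@dataclass(frozen=True)
class ResponseFactor:
    """Detector response per concentration, f = A / C (area per mg/ml)."""

    compound: str
    f: float
    flagged: bool = False


def fit_curve(concentrations, areas, compound: str = "") -> CalibrationCurve:
    """Fit an ordinary-least-squares line area = a*conc + b.

    Requires at least 3 points with at least 2 distinct concentrations.
    ``r_squared`` is the squared Pearson correlation of the fit and
    ``linear_range`` the span of the fitted concentrations.
    """
    conc = np.asarray(concentrations, dtype=float)
    area = np.asarray(areas, dtype=float)
    if conc.shape != area.shape or conc.ndim != 1:
        raise ValueError("concentrations and areas must be 1-d and equal length")
    if conc.size < 3:
        raise ValueError(f"need >= 3 calibration points, got {conc.size}")
    if np.unique(conc).size < 2:
        raise ValueError("degenerate design: all concentrations identical")
    res = stats.linregress(conc, area)
    return CalibrationCurve(
        compound=compound,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        linear_range=(float(conc.min()), float(conc.max())),
    )


def response_factor(area: float, concentration_mg_ml: float, compound: str = "") -> ResponseFactor:
    """Response factor f = A / C with C in mg/ml.

    A zero area yields f = 0 and is flagged (a missing peak cannot carry a
    meaningful response factor).
    """
    if concentration_mg_ml <= 0:
        raise ValueError(f"concentration must be > 0, got {concentration_mg_ml}")
    if area < 0:
        raise ValueError(f"area must be >= 0, got {area}")
    return ResponseFactor(compound=compound, f=area / concentration_mg_ml, flagged=area == 0)


def rcf(f_s: ResponseFactor | float, f_i: ResponseFactor | float) -> float:
    """Relative correction factor f_si = f_s / f_i (dimensionless).

    ``f_s`` is the marker's response factor, ``f_i`` the analyte's.
    Swapping the arguments inverts the result.
    """
    fs = f_s.f if isinstance(f_s, ResponseFactor) else float(f_s)
    fi = f_i.f if isinstance(f_i, ResponseFactor) else float(f_i)
    if fs <= 0 or fi <= 0:
        raise ValueError(f"response factors must be > 0, got f_s={fs}, f_i={fi}")
    return fs / fi


def rcf_robustness(table: pd.DataFrame, condition_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    """Per-analyte mean and RSD% of RCFs measured under several conditions.

    ``table`` holds one row per instrument condition and one column per
    analyte (extra condition-describing columns may be named in
    ``condition_cols`` and are ignored). RSD uses the sample (n-1) standard
    deviation, the analytical-chemistry convention.

    Returns a frame with rows ``mean`` and ``rsd_percent``.
    """
    values = table.drop(columns=list(condition_cols), errors="ignore")
    values = values.select_dtypes(include=[np.number])
    if values.empty:
        raise ValueError("no analyte columns found")
    if len(values) < 2:
        raise ValueError("need >= 2 conditions per analyte")
    if (values <= 0).any().any():
        raise ValueError("RCF values must be positive")
    mean = values.mean(axis=0)
    rsd = 100.0 * values.std(axis=0, ddof=1) / mean
    return pd.DataFrame({"mean": mean, "rsd_percent": rsd}).T


@dataclass
class RCFRecord:
    """One RCF measurement under one instrument condition."""

    analyte: str
    f_si: float
    flow_rate_ml_min: float | None = None
    column_temp_c: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.f_si <= 0:
            raise ValueError(f"f_si must be > 0, got {self.f_si}")


def records_to_table(records: list[RCFRecord]) -> pd.DataFrame:
    """Pivot a list of RCFRecord into a condition x analyte table."""
    rows = [
        {
            "flow_rate_ml_min": r.flow_rate_ml_min,
            "column_temp_c": r.column_temp_c,
            "analyte": r.analyte,
            "f_si": r.f_si,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows)
    return frame.pivot_table(
        index=["flow_rate_ml_min", "column_temp_c"], columns="analyte", values="f_si"
    ).reset_index()
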