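"""Content determination by ESM and QAMS, and method-agreement statistics.

ESM (external standard method) inverts each compound's own calibration
curve; QAMS (quantitative analysis of multi-components by single marker)
derives every analyte concentration from the marker peak via

    C_i = f_si * C_s * A_i / A_s

where A_s, C_s are the marker's peak area and concentration in the sample
and f_si the relative correction factor. Both land on the content scale
(mg per g dry material) through the extraction dilution. The two methods
are compared per cell by the relative error RE = (QAMS - ESM)/ESM * 100%
and per compound by Pearson correlation and a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationCurve
from .synthetic_data import Dilution


@dataclass
class ContentValue:
    """A single content determination with its quality flag (or None)."""

    value: float
    flag: str | None = None


def esm_content(area: float, curve: CalibrationCurve, dilution: Dilution) -> ContentValue:
    """External-standard content: invert the curve, convert to mg/g.

    The implied concentration x = (A - b)/a (ug/ml) becomes
    content = x * volume_ml / (1000 * mass_g). Negative x is clipped to 0
    and flagged; x outside the curve's linear range is flagged.
    """
    if area < 0:
        raise ValueError(f"area must be >= 0, got {area}")
    x = curve.invert(area)
    if x < 0:
        return ContentValue(0.0, "negative_concentration")
    flag = None if curve.in_range(x) else "outside_linear_range"
    return ContentValue(dilution.conc_to_content(x), flag)


def qams_content(
    a_i: float, a_s: float, c_s_mg_ml: float, f_si: float, dilution: Dilution
) -> float:
    """Single-marker content of an analyte, mg/g.

    ``a_i``/``a_s`` are analyte and marker peak areas from the same
    injection, ``c_s_mg_ml`` the marker concentration in the extract and
    ``f_si`` the relative correction factor.
    """
    if a_s <= 0:
        raise ValueError("marker peak area must be positive (marker peak missing?)")
    if c_s_mg_ml <= 0 or f_si <= 0:
        raise ValueError("marker concentration and f_si must be positive")
    if a_i < 0:
        raise ValueError(f"analyte area must be >= 0, got {a_i}")
    c_i = f_si * c_s_mg_ml * a_i / a_s  # mg/ml
    return c_i * dilution.volume_ml / dilution.mass_g


def relative_error(qams: float, esm: float) -> float:
    """RE = (QAMS - ESM) / ESM * 100 (percent)."""
    if esm <= 0:
        raise ValueError("ESM content must be positive to form a relative error")
    return 100.0 * (qams - esm) / esm


def pair_rsd(esm: float, qams: float) -> float:
    """RSD% of the two-method pair (n=2, sample sd), the per-cell spread."""
    pair = np.array([esm, qams], dtype=float)
    m = pair.mean()
    if m <= 0:
        raise ValueError("pair mean must be positive")
    return float(100.0 * pair.std(ddof=1) / m)


@dataclass
class AgreementStats:
    """Per-compound ESM-vs-QAMS agreement."""

    pearson_r: float  # NaN when a column is constant
    t_statistic: float  # NaN when all differences are 0
    p_value: float
    note: str = ""


def method_agreement(esm_col, qams_col) -> AgreementStats:
    """Pearson correlation and two-sided paired t-test between the methods.

    Zero-variance inputs make the correlation undefined: it is reported as
    NaN with a note, never silently as 1. All-zero differences likewise
    yield an undefined t statistic, reported as "no difference".
    """
    e = np.asarray(esm_col, dtype=float)
    q = np.asarray(qams_col, dtype=float)
    if e.shape != q.shape or e.ndim != 1:
        raise ValueError("columns must be 1-d and equal length")
    if e.size < 3:
        raise ValueError("need at least 3 paired values")
    note = ""
    if e.std() == 0 or q.std() == 0:
        r = float("nan")
        note = "correlation undefined (zero-variance column)"
    else:
        r = float(stats.pearsonr(e, q).statistic)
    diff = q - e
    if np.allclose(diff, 0):
        return AgreementStats(pearson_r=r, t_statistic=float("nan"), p_value=1.0,
                              note=(note + "; " if note else "") + "no difference")
    t = stats.ttest_rel(q, e)
    return AgreementStats(pearson_r=r, t_statistic=float(t.statistic), p_value=float(t.pvalue), note=note)


def summarize_contents(cm: pd.DataFrame) -> pd.DataFrame:
    """Per-column mean/min/max of a content matrix (4 dp on the mean scale)."""
    if cm.empty:
        raise ValueError("empty content matrix")
    return pd.DataFrame({"mean": cm.mean(), "min": cm.min(), "max": cm.max()}).T


def agreement_table(esm: pd.DataFrame, qams: pd.DataFrame) -> pd.DataFrame:
    """Cell-wise RE% and pair-RSD% plus per-compound agreement statistics.

    ``esm`` and ``qams`` are batch x compound content frames over the same
    analytes (the marker, quantified by ESM only, is not included).
    Returns a per-compound frame with mean |RE|, max |RE|, pearson_r,
    t_statistic and p_value.
    """
    if not esm.columns.equals(qams.columns) or not esm.index.equals(qams.index):
        raise ValueError("ESM and QAMS frames must share index and columns")
    out = {}
    for col in esm.columns:
        ok = esm[col] > 0  # absent/zero cells carry no relative error
        re = 100.0 * (qams[col][ok] - esm[col][ok]) / esm[col][ok]
        ag = method_agreement(esm[col][ok], qams[col][ok])
        out[col] = {
            "mean_abs_re": float(re.abs().mean()),
            "max_abs_re": float(re.abs().max()),
            "pearson_r": ag.pearson_r,
            "t_statistic": ag.t_statistic,
            "p_value": ag.p_value,
        }
    return pd.DataFrame(out).T


@dataclass
class ValidationReport:
    """RSDs of the replicate designs and spike-recovery summaries, per compound."""

    precision_rsd: pd.Series
    stability_rsd: pd.Series
    repeatability_rsd: pd.Series
    recovery_mean_percent: pd.Series
    recovery_rsd: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precision_rsd": self.precision_rsd,
                "stability_rsd": self.stability_rsd,
                "repeatability_rsd": self.repeatability_rsd,
                "recovery_mean_percent": self.recovery_mean_percent,
                "recovery_rsd": self.recovery_rsd,
            }
        )


def _rsd(frame: pd.DataFrame) -> pd.Series:
    if len(frame) < 2:
        raise ValueError("need >= 2 replicates per set")
    mean = frame.mean(axis=0)
    if (mean <= 0).any():
        raise ValueError("replicate means must be positive")
    return 100.0 * frame.std(axis=0, ddof=1) / mean


def validation_stats(
    precision: pd.DataFrame,
    stability: pd.DataFrame,
    repeatability: pd.DataFrame,
    recovery: pd.DataFrame,
) -> ValidationReport:
    """Validation statistics: RSD = 100*sd/mean per compound per replicate
    set, and recovery% = 100*(found - base)/added per spiked record,
    averaged per compound (with its RSD)."""
    if (recovery["added_mg_g"] <= 0).any():
        raise ValueError("spike records must have added > 0")
    rec = recovery.assign(
        recovery_percent=100.0 * (recovery["found_mg_g"] - recovery["base_mg_g"]) / recovery["added_mg_g"]
    )
    by = rec.groupby("compound")["recovery_percent"]
    return ValidationReport(
        precision_rsd=_rsd(precision),
        stability_rsd=_rsd(stability),
        repeatability_rsd=_rsd(repeatability),
        recovery_mean_percent=by.mean(),
        recovery_rsd=100.0 * by.std(ddof=1) / by.mean(),
    )
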