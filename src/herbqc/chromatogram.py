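"""Chromatogram I/O, baseline correction, peak detection and integration.

A chromatogram is a sampled detector trace: a strictly increasing time grid
(minutes) with intensities (mAU). Peaks are integrated trapezoidally with a
local linear baseline between the peak bounds; areas are in mAU*min.
Detected peaks are matched to reference retention times and assembled into
the sample x common-peak area matrix that all downstream statistics use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

log = logging.getLogger(__name__)

TIME_COL = "time_min"
INTENSITY_COL = "intensity_mAU"


@dataclass
class Chromatogram:
    time: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must be 1-d arrays of equal length")
        if self.time.size < 2:
            raise ValueError("chromatogram needs at least 2 points")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValueError("time grid must be strictly increasing")
        if steps.max() / steps.min() >= 1.5:
            raise ValueError("time grid too irregular (max/min step ratio >= 1.5)")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class Peak:
    """A detected peak; bounds delimit the integration window (minutes)."""

    apex_time: float
    left_bound: float
    right_bound: float
    height: float
    area: float = 0.0
    assigned_compound: str | None = None

    def __post_init__(self) -> None:
        if not self.left_bound < self.apex_time < self.right_bound:
            raise ValueError("peak bounds must bracket the apex")
        if self.height <= 0:
            raise ValueError("peak height must be positive")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


@dataclass
class PeakTable:
    """Sample x common-peak area matrix with per-column retention metadata."""

    areas: pd.DataFrame  # rows: sample ids; columns: peak labels
    retention_times: pd.Series  # per column, minutes
    compounds: pd.Series  # per column, compound name or "" if unidentified

    def __post_init__(self) -> None:
        if self.areas.isna().any().any():
            raise ValueError("peak table has missing cells")
        rts = self.retention_times.to_numpy()
        if np.any(np.diff(rts) <= 0):
            raise ValueError("peak table columns must be ordered by retention time")


def read_chromatogram(path) -> Chromatogram:
    """Read a two-column delimited chromatogram (header time_min, intensity_mAU)."""
    frame = pd.read_csv(path)
    missing = {TIME_COL, INTENSITY_COL} - set(frame.columns)
    if missing:
        raise ValueError(
            f"{path}: missing expected columns {sorted(missing)}; "
            f"header must contain '{TIME_COL}' and '{INTENSITY_COL}'"
        )
    frame = frame[[TIME_COL, INTENSITY_COL]].apply(pd.to_numeric, errors="raise")
    from pathlib import Path

    return Chromatogram(
        time=frame[TIME_COL].to_numpy(),
        intensity=frame[INTENSITY_COL].to_numpy(),
        sample_id=Path(path).stem,
    )


def write_chromatogram(c: Chromatogram, path) -> None:
    pd.DataFrame({TIME_COL: c.time, INTENSITY_COL: c.intensity}).to_csv(
        path, index=False, float_format="%.9g"
    )


def baseline_correct(c: Chromatogram, n_windows: int = 20, percentile: float = 10.0) -> Chromatogram:
    """Subtract a piecewise-linear baseline anchored in peak-free regions.

    The trace is split into ``n_windows`` equal time windows; in each, the
    anchor is the grid point at the window's ``percentile``-th intensity
    (a low quantile sits on the baseline as long as peaks occupy less than
    1 - percentile/100 of the window). The anchors are joined by linear
    interpolation and subtracted. A flat trace and a pure linear ramp both
    map to ~0 everywhere.
    """
    edges = np.linspace(c.time[0], c.time[-1], n_windows + 1)
    anchor_t, anchor_y = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (c.time >= lo) & (c.time <= hi)
        if mask.sum() < 2:
            continue
        y = c.intensity[mask]
        t = c.time[mask]
        cutoff = np.percentile(y, percentile)
        idx = int(np.argmin(np.abs(y - cutoff)))
        anchor_t.append(t[idx])
        anchor_y.append(y[idx])
    anchor_t = np.asarray(anchor_t)
    anchor_y = np.asarray(anchor_y)
    baseline = np.interp(c.time, anchor_t, anchor_y)
    # linear extrapolation beyond the outermost anchors (np.interp holds flat,
    # which would leave a ramp residual at the trace edges)
    if anchor_t.size >= 2:
        left = c.time < anchor_t[0]
        slope = (anchor_y[1] - anchor_y[0]) / (anchor_t[1] - anchor_t[0])
        baseline[left] = anchor_y[0] + slope * (c.time[left] - anchor_t[0])
        right = c.time > anchor_t[-1]
        slope = (anchor_y[-1] - anchor_y[-2]) / (anchor_t[-1] - anchor_t[-2])
        baseline[right] = anchor_y[-1] + slope * (c.time[right] - anchor_t[-1])
    return Chromatogram(
        time=c.time.copy(),
        intensity=c.intensity - baseline,
        sample_id=c.sample_id,
        metadata={**c.metadata, "baseline_corrected": True},
    )


def _bound(intensity: np.ndarray, apex: int, direction: int, floor: float) -> int:
    """Walk from the apex until the signal drops below ``floor`` or turns up."""
    i = apex
    n = intensity.size
    while 0 < i < n - 1:
        j = i + direction
        if intensity[j] <= floor:
            return j
        if intensity[j] > intensity[i]:  # valley: neighbour rises again
            return i
        i = j
    return i


def detect_peaks(
    c: Chromatogram,
    min_height: float = 1.0,
    min_prominence: float = 0.5,
    bound_frac: float = 1e-3,
) -> list[Peak]:
    """Detect local maxima above height/prominence thresholds.

    Expects a baseline-corrected trace. Bounds are placed where the signal
    falls below ``bound_frac`` of the peak height or at the nearest valley,
    whichever comes first. Deterministic; returns peaks ordered by apex time.
    """
    idx, _ = find_peaks(c.intensity, height=min_height, prominence=min_prominence)
    peaks = []
    for apex in idx:
        h = c.intensity[apex]
        floor = bound_frac * h
        left = _bound(c.intensity, apex, -1, floor)
        right = _bound(c.intensity, apex, +1, floor)
        if not left < apex < right:
            continue
        p = Peak(
            apex_time=float(c.time[apex]),
            left_bound=float(c.time[left]),
            right_bound=float(c.time[right]),
            height=float(h),
        )
        p.area = integrate_peak(c, p)
        peaks.append(p)
    return peaks


def integrate_peak(c: Chromatogram, p: Peak) -> float:
    """Trapezoidal area between the bounds minus the local linear baseline.

    The chord between the signal values at the two bounds is subtracted,
    standard practice for rider baselines; the result is clipped at 0.
    """
    if p.left_bound < c.time[0] or p.right_bound > c.time[-1]:
        raise ValueError("peak bounds outside the time grid")
    mask = (c.time >= p.left_bound) & (c.time <= p.right_bound)
    t = c.time[mask]
    y = c.intensity[mask]
    if t.size < 2:
        raise ValueError("integration window contains fewer than 2 points")
    chord = np.interp(t, [t[0], t[-1]], [y[0], y[-1]])
    area = float(np.trapezoid(y - chord, t))
    return max(area, 0.0)


@dataclass
class PeakAssignment:
    """Result of matching detected peaks to reference retention times."""

    matched: dict[int, Peak]  # reference index -> claimed peak
    unmatched_references: list[int]
    unclaimed_peaks: list[Peak]


def match_peaks(peaks: list[Peak], reference_rts, tolerance: float = 0.2) -> PeakAssignment:
    """Greedy nearest-first assignment of peaks to reference retention times.

    Each reference claims the nearest unclaimed peak within ``tolerance``
    minutes. Conflicts are resolved by smaller time difference, then by
    earlier reference index (and logged).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    refs = np.asarray(reference_rts, dtype=float)
    candidates = []
    for ri, rt in enumerate(refs):
        for pi, p in enumerate(peaks):
            d = abs(p.apex_time - rt)
            if d <= tolerance:
                candidates.append((d, ri, pi))
    candidates.sort()
    matched: dict[int, Peak] = {}
    used: set[int] = set()
    for d, ri, pi in candidates:
        if ri in matched or pi in used:
            if ri not in matched:
                log.debug("reference %d lost peak at %.3f to a closer reference", ri, peaks[pi].apex_time)
            continue
        matched[ri] = peaks[pi]
        used.add(pi)
    unmatched = [ri for ri in range(refs.size) if ri not in matched]
    unclaimed = [p for pi, p in enumerate(peaks) if pi not in used]
    return PeakAssignment(matched=matched, unmatched_references=unmatched, unclaimed_peaks=unclaimed)


def build_peak_table(
    samples: list[tuple[Chromatogram, list[Peak]]],
    reference_rts,
    compound_names: list[str] | None = None,
    tolerance: float = 0.2,
    min_fraction: float = 1.0,
) -> PeakTable:
    """Assemble the sample x common-peak area matrix.

    A reference position is a *common peak* when it is matched in at least
    ``min_fraction`` of the samples (default: all of them, the usual
    fingerprint convention). References matched in fewer samples are dropped
    and logged. Raises if no common peak remains.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    refs = np.asarray(reference_rts, dtype=float)
    order = np.argsort(refs)
    refs = refs[order]
    if compound_names is not None:
        names = [compound_names[i] for i in order]
    else:
        names = [""] * refs.size

    rows = {}
    hit_count = np.zeros(refs.size, dtype=int)
    for chrom, peaks in samples:
        assign = match_peaks(peaks, refs, tolerance=tolerance)
        areas = np.full(refs.size, np.nan)
        for ri, p in assign.matched.items():
            areas[ri] = p.area
            hit_count[ri] += 1
        rows[chrom.sample_id] = areas

    need = int(np.ceil(min_fraction * len(samples)))
    common = hit_count >= need
    for ri in np.flatnonzero(~common):
        log.info(
            "reference peak at %.2f min present in %d/%d samples; excluded from common set",
            refs[ri], hit_count[ri], len(samples),
        )
    if not common.any():
        raise ValueError("no common peaks across samples")

    labels = [f"P{i + 1}" for i in range(refs.size)]
    frame = pd.DataFrame(rows, index=labels).T
    frame = frame.loc[:, common]
    frame = frame.dropna(axis=0)  # samples that miss a common peak are rejected
    dropped = set(rows) - set(frame.index)
    for sid in sorted(dropped):
        log.warning("sample %s missing a common peak; excluded from the peak table", sid)
    return PeakTable(
        areas=frame,
        retention_times=pd.Series(refs[common], index=frame.columns),
        compounds=pd.Series(np.array(names)[common], index=frame.columns),
    )
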