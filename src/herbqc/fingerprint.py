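"""Chromatographic fingerprint similarity.

A batch's fingerprint is its full baseline-corrected trace. Batches are
resampled onto a common fine grid and compared with a designated reference
profile (one good batch, or the point-wise mean profile) by the congruence
(cosine) coefficient or the Pearson correlation. For non-negative traces
both lie in [0, 1]; batches below a similarity threshold are flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chromatogram import Chromatogram

DEFAULT_GRID_STEP = 0.01  # minutes; well below peak width
DEFAULT_THRESHOLD = 0.82  # conventional acceptance bar for batch similarity


def resample_to_grid(c: Chromatogram, grid) -> np.ndarray:
    """Linear interpolation of the trace onto a common time grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if grid.min() < c.time[0] or grid.max() > c.time[-1]:
        raise ValueError("grid extends outside the chromatogram's time span")
    return np.interp(grid, c.time, c.intensity)


def similarity(x, y, method: str = "cosine") -> float:
    """Similarity of two equal-length profiles.

    cosine: sum(xy) / (||x|| ||y||) (the congruence coefficient);
    pearson: the same after centering each vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("profiles must be 1-d, equal length and >= 2 points")
    if method == "pearson":
        x = x - x.mean()
        y = y - y.mean()
    elif method != "cosine":
        raise ValueError(f"unknown method {method!r}")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm profile: similarity undefined")
    return float(x @ y / (nx * ny))


def common_grid(samples: list[Chromatogram], step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Intersection of time spans, sampled at ``step`` minutes."""
    lo = max(c.time[0] for c in samples)
    hi = min(c.time[-1] for c in samples)
    if hi <= lo:
        raise ValueError("samples have no overlapping time span")
    return np.arange(lo, hi + step / 2, step)


def reference_profile(
    samples: list[Chromatogram],
    reference_id: str | None = None,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, str]:
    """The reference vector: a designated batch, or the mean profile.

    Returns (grid, reference vector, reference label).
    """
    if grid is None:
        grid = common_grid(samples)
    if reference_id is None:
        ref = np.mean([resample_to_grid(c, grid) for c in samples], axis=0)
        return grid, ref, "mean"
    for c in samples:
        if c.sample_id == reference_id:
            return grid, resample_to_grid(c, grid), reference_id
    raise KeyError(f"unknown reference id {reference_id!r}")


def similarity_report(
    samples: list[Chromatogram],
    reference_id: str | None = None,
    method: str = "cosine",
    threshold: float = DEFAULT_THRESHOLD,
    grid_step: float = DEFAULT_GRID_STEP,
) -> pd.DataFrame:
    """Per-batch similarity to the reference, flagging values below threshold.

    Returns a frame indexed by sample id with columns ``similarity`` and
    ``below_threshold``; ``.attrs`` records the method and reference.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    grid = common_grid(samples, step=grid_step)
    grid, ref, ref_label = reference_profile(samples, reference_id, grid)
    rows = {
        c.sample_id: similarity(resample_to_grid(c, grid), ref, method=method)
        for c in samples
    }
    frame = pd.DataFrame({"similarity": pd.Series(rows)})
    frame["below_threshold"] = frame["similarity"] < threshold
    frame.attrs.update({"method": method, "reference": ref_label, "threshold": threshold})
    return frame
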