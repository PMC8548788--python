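"""Range analysis of an L9(3^4) orthogonal extraction-optimisation design.

Nine runs cover four factors (solid-liquid ratio, solvent concentration,
extraction time, column temperature) at three levels each, every level
appearing exactly three times. For each factor, k[level] is the mean
response over the runs at that level and the range R = max(k) - min(k)
ranks factor importance; the best level per factor is argmax k.

Because published tables often compute R from 3-dp-rounded level means, a
report-only rounded-k variant of R is emitted alongside the raw one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class OrthogonalDesign:
    """Runs x factors level table plus the per-run response."""

    levels: pd.DataFrame  # one column per factor, level labels (any hashable)
    response: pd.Series

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.response):
            raise ValueError("levels and response must have equal length")
        for factor in self.levels.columns:
            counts = self.levels[factor].value_counts()
            if counts.nunique() != 1:
                raise ValueError(f"unbalanced design: factor {factor!r} levels {dict(counts)}")

    @property
    def factors(self) -> list[str]:
        return list(self.levels.columns)


def from_frame(frame: pd.DataFrame, response: str = "total", ignore: tuple[str, ...] = ("run",)) -> OrthogonalDesign:
    """Build a design from a flat table with a response column."""
    levels = frame.drop(columns=[response, *[c for c in ignore if c in frame.columns]])
    return OrthogonalDesign(levels=levels, response=frame[response].astype(float))


@dataclass
class RangeAnalysis:
    k: pd.DataFrame  # rows k1..k3 (levels in per-factor sorted order) x factors
    level_labels: pd.DataFrame  # the level label behind each k cell
    r: pd.Series  # per-factor range from raw k
    r_rounded: pd.Series  # per-factor range from 3-dp-rounded k (report-only)
    grand_mean: float
    design: OrthogonalDesign


def range_analysis(design: OrthogonalDesign, round_dp: int = 3) -> RangeAnalysis:
    """Level means k and ranges R per factor.

    Rows k1..kL follow each factor's own level order (sorted labels).
    ``r`` is computed from unrounded level means; ``r_rounded`` from level
    means rounded to ``round_dp`` decimals, matching common report style.
    """
    k_cols, label_cols = {}, {}
    n_levels = None
    for factor in design.factors:
        means = design.response.groupby(design.levels[factor]).mean().sort_index()
        if n_levels is None:
            n_levels = len(means)
        k_cols[factor] = means.to_numpy()
        label_cols[factor] = list(means.index)
    rows = [f"k{i + 1}" for i in range(n_levels)]
    k = pd.DataFrame(k_cols, index=rows)
    labels = pd.DataFrame(label_cols, index=rows)
    r = k.max(axis=0) - k.min(axis=0)
    kr = k.round(round_dp)
    return RangeAnalysis(
        k=k,
        level_labels=labels,
        r=r,
        r_rounded=kr.max(axis=0) - kr.min(axis=0),
        grand_mean=float(design.response.mean()),
        design=design,
    )


def rank_factors(ra: RangeAnalysis) -> list[str]:
    """Factors in descending order of range R; ties keep design column order."""
    order = sorted(
        range(len(ra.r)), key=lambda i: (-ra.r.iloc[i], i)
    )
    return [ra.r.index[i] for i in order]


def best_levels(ra: RangeAnalysis) -> pd.DataFrame:
    """The level with the largest mean response per factor.

    Ties pick the first level by index order and are flagged ``ambiguous``.
    """
    rows = {}
    for factor in ra.k.columns:
        col = ra.k[factor]
        best_row = col.idxmax()
        ambiguous = (col == col.max()).sum() > 1
        rows[factor] = {
            "level": ra.level_labels.loc[best_row, factor],
            "k": float(col.max()),
            "ambiguous": ambiguous,
        }
    return pd.DataFrame(rows).T
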