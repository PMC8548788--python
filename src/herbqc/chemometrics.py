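"""Multivariate chemometrics: clustering, factor analysis, quality scoring.

Batches are rows, quantified components are columns. The workflow is the
one standard in herbal quality evaluation:

* hierarchical clustering in two modes — a heatmap-style mode (per-feature
  z-scores, 1 - Pearson distance between batches, average linkage) and a
  squared-Euclidean between-groups (average linkage) mode on raw contents;
* sampling-adequacy gatekeepers — the Kaiser-Meyer-Olkin statistic and
  Bartlett's test of sphericity on the correlation matrix;
* principal-component factor extraction (loadings = eigenvector * sqrt(λ)),
  varimax rotation with Kaiser normalization, regression-method factor
  scores, and a composite quality score

      F = (w1*F1 + ... + wk*Fk) / (w1 + ... + wk)

  weighted by each rotated factor's variance contribution, from which the
  batches are ranked (1 = best, competition ranking).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

_MODES = ("similarity-heatmap", "squared-euclidean")


def _as_frame(data) -> pd.DataFrame:
    frame = pd.DataFrame(data)
    if frame.isna().any().any():
        raise ValueError("data contains missing values")
    return frame.astype(float)


def standardize(data) -> pd.DataFrame:
    """Column z-scores with the sample (n-1) standard deviation."""
    frame = _as_frame(data)
    sd = frame.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant columns cannot be standardized: {bad}")
    return (frame - frame.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# Hierarchical clustering


@dataclass
class HCATree:
    """Agglomerative merge history (scipy linkage matrix) plus settings."""

    merges: np.ndarray  # scipy (n-1) x 4 linkage matrix
    labels: list  # leaf labels, row order of the input
    mode: str
    distance: str
    linkage_method: str = "average"

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels (1..k) at ``n_clusters`` clusters."""
        assignment = fcluster(self.merges, t=n_clusters, criterion="maxclust")
        return pd.Series(assignment, index=self.labels, name="cluster")


def hca(data, mode: str = "squared-euclidean") -> HCATree:
    """Cluster batches hierarchically.

    ``similarity-heatmap``: per-feature standardization, distance
    1 - Pearson correlation between batch profiles, average linkage
    (undefined for a constant batch row, which raises).
    ``squared-euclidean``: squared Euclidean distance on the raw feature
    values with between-groups average linkage.

    Deterministic; scipy breaks distance ties by index order.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    frame = _as_frame(data)
    if len(frame) < 2:
        raise ValueError("need at least 2 rows to cluster")
    if mode == "similarity-heatmap":
        raw_sd = frame.std(axis=1, ddof=0)
        if (raw_sd == 0).any():
            bad = list(raw_sd.index[raw_sd == 0])
            raise ValueError(f"constant rows have undefined correlation: {bad}")
        z = standardize(frame)
        row_sd = z.std(axis=1, ddof=1)
        if (row_sd == 0).any():
            bad = list(row_sd.index[row_sd == 0])
            raise ValueError(f"constant rows have undefined correlation: {bad}")
        dist = pdist(z.to_numpy(), metric="correlation")
        distance = "1 - pearson"
    else:
        dist = pdist(frame.to_numpy(), metric="sqeuclidean")
        distance = "squared euclidean"
    merges = linkage(dist, method="average")
    return HCATree(merges=merges, labels=list(frame.index), mode=mode, distance=distance)


# ---------------------------------------------------------------------------
# Sampling adequacy


@dataclass
class AdequacyStats:
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


def _correlation_matrix(data) -> tuple[np.ndarray, int]:
    frame = standardize(data)
    n = len(frame)
    r = np.corrcoef(frame.to_numpy(), rowvar=False)
    return r, n


def kmo(data, max_condition: float = 1e10) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over off-diagonal elements,
    where q_ij are the anti-image partial correlations obtained from the
    inverse correlation matrix, q_ij = -s_ij / sqrt(s_ii s_jj).
    Raises on (near-)singular correlation matrices rather than returning a
    number from an unstable inverse.
    """
    r, _ = _correlation_matrix(data)
    p = r.shape[0]
    if p < 2:
        raise ValueError("KMO needs at least 2 variables")
    if np.linalg.cond(r) > max_condition:
        raise ValueError("correlation matrix is singular or near-singular")
    s = np.linalg.inv(r)
    d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    q = -s / d
    off = ~np.eye(p, dtype=bool)
    r2 = np.sum(r[off] ** 2)
    q2 = np.sum(q[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett(data) -> AdequacyStats:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), df = p(p-1)/2. The returned
    object carries a NaN KMO slot when computed alone; use
    :func:`adequacy` for both at once.
    """
    r, n = _correlation_matrix(data)
    p = r.shape[0]
    if p < 2:
        raise ValueError("need at least 2 variables")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than variables ({p})")
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return AdequacyStats(kmo=float("nan"), bartlett_chi2=float(chi2), bartlett_df=df, bartlett_p=pval)


def adequacy(data) -> AdequacyStats:
    """KMO and Bartlett sphericity in one object."""
    b = bartlett(data)
    return AdequacyStats(kmo=kmo(data), bartlett_chi2=b.bartlett_chi2,
                         bartlett_df=b.bartlett_df, bartlett_p=b.bartlett_p)


# ---------------------------------------------------------------------------
# Factor analysis


def _fix_columns(loadings: np.ndarray) -> np.ndarray:
    """Deterministic column convention: largest-|loading| element positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


@dataclass
class FactorModel:
    """Principal-component factor model of a batch x component matrix."""

    eigenvalues: np.ndarray  # all p eigenvalues of the correlation matrix
    variance_table: pd.DataFrame  # initial / extraction / rotation sums
    loadings: pd.DataFrame  # unrotated, p x k
    rotated_loadings: pd.DataFrame  # after varimax, p x k
    score_coefficients: pd.DataFrame  # regression-method, p x k
    scores: pd.DataFrame  # n x k factor scores
    contributions: np.ndarray  # rotation % of variance per retained factor
    composite: pd.Series  # composite quality score F per batch
    ranking: pd.Series  # 1 = best
    rotation_iterations: int = 0
    retain_threshold: float = 0.8
    feature_names: list[str] = field(default_factory=list)


def extract_factors(data, retain_threshold: float = 0.8) -> tuple[np.ndarray, pd.DataFrame]:
    """Eigendecomposition of the correlation matrix; retain λ > threshold.

    Returns (all eigenvalues descending, unrotated loadings of the retained
    factors). Loadings are eigenvector * sqrt(λ). Raises when no factor
    clears the threshold.
    """
    frame = _as_frame(data)
    z = standardize(frame)
    r = np.corrcoef(z.to_numpy(), rowvar=False)
    vals, vecs = np.linalg.eigh(r)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    keep = vals > retain_threshold
    if not keep.any():
        raise ValueError(f"no eigenvalue exceeds the retention threshold {retain_threshold}")
    k = int(keep.sum())
    load = vecs[:, :k] * np.sqrt(vals[:k])
    load = _fix_columns(load)
    cols = [f"F{j + 1}" for j in range(k)]
    return vals, pd.DataFrame(load, index=frame.columns, columns=cols)


def varimax(
    loadings,
    kaiser_normalize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, int]:
    """Varimax rotation (orthogonal, optionally Kaiser row-normalized).

    Maximizes the variance of squared loadings per factor; communalities
    (row sums of squared loadings) are preserved exactly. Columns are
    re-ordered by explained variance and signed so the largest-|loading|
    element is positive, making the result deterministic. A single-factor
    input is returned unchanged (logged).

    Returns (rotated loadings, iterations used).
    """
    frame = pd.DataFrame(loadings).astype(float)
    x = frame.to_numpy()
    p, k = x.shape
    if k == 1:
        log.info("varimax: single factor, rotation is a no-op")
        return frame.copy(), 0
    h = np.sqrt((x**2).sum(axis=1))
    if kaiser_normalize:
        if (h == 0).any():
            raise ValueError("zero-communality row cannot be Kaiser-normalized")
        x = x / h[:, None]
    rot = np.eye(k)
    d = 0.0
    iters = 0
    for iters in range(1, max_iter + 1):
        lam = x @ rot
        u, s, vt = np.linalg.svd(
            x.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    lam = x @ rot
    if kaiser_normalize:
        lam = lam * h[:, None]
    # order factors by explained variance, then fix signs
    order = np.argsort(-(lam**2).sum(axis=0))
    lam = _fix_columns(lam[:, order])
    return pd.DataFrame(lam, index=frame.index, columns=frame.columns), iters


def score_coefficients(data, rotated_loadings: pd.DataFrame) -> pd.DataFrame:
    """Regression-method component score coefficients, B = R^-1 Λ."""
    z = standardize(data)
    r = np.corrcoef(z.to_numpy(), rowvar=False)
    coef = np.linalg.solve(r, rotated_loadings.to_numpy())
    return pd.DataFrame(coef, index=rotated_loadings.index, columns=rotated_loadings.columns)


def factor_scores(data, coefficients: pd.DataFrame) -> pd.DataFrame:
    """Factor scores = standardized data x score-coefficient matrix."""
    z = standardize(data)
    if list(z.columns) != list(coefficients.index):
        raise ValueError("score coefficients do not conform to the data columns")
    return pd.DataFrame(
        z.to_numpy() @ coefficients.to_numpy(), index=z.index, columns=coefficients.columns
    )


def composite_score(scores, contributions) -> pd.Series:
    """Contribution-weighted composite F = sum(w_j F_j) / sum(w_j)."""
    w = np.asarray(contributions, dtype=float)
    if (w <= 0).any():
        raise ValueError("contributions must be positive")
    frame = pd.DataFrame(scores).astype(float)
    if frame.shape[1] != w.size:
        raise ValueError("one contribution weight per factor is required")
    return pd.Series(frame.to_numpy() @ w / w.sum(), index=frame.index, name="F")


def rank_samples(f_values) -> pd.Series:
    """Competition ranking of composite scores, 1 = best (highest F).

    Ties share the smaller rank and the next rank is skipped (1, 1, 3).
    """
    s = pd.Series(f_values, dtype=float)
    return s.rank(method="min", ascending=False).astype(int).rename("ranking")


def factor_analysis(data, retain_threshold: float = 0.8) -> FactorModel:
    """Full pipeline: extract, rotate, score, weight, rank.

    The composite weights are the rotation variance contributions (% of
    total variance explained by each rotated factor).
    """
    frame = _as_frame(data)
    p = frame.shape[1]
    vals, load = extract_factors(frame, retain_threshold=retain_threshold)
    rotated, iters = varimax(load)
    k = rotated.shape[1]

    pct = 100.0 * vals / p
    cum = np.cumsum(pct)
    rot_total = (rotated.to_numpy() ** 2).sum(axis=0)
    rot_pct = 100.0 * rot_total / p
    table = pd.DataFrame(
        {
            "eigenvalue": vals,
            "pct_variance": pct,
            "cum_pct": cum,
        },
        index=pd.RangeIndex(1, p + 1, name="component"),
    )
    table["extraction_total"] = np.where(np.arange(p) < k, vals, np.nan)
    table["extraction_pct"] = np.where(np.arange(p) < k, pct, np.nan)
    table["extraction_cum"] = np.where(np.arange(p) < k, cum, np.nan)
    table["rotation_total"] = np.concatenate([rot_total, np.full(p - k, np.nan)])
    table["rotation_pct"] = np.concatenate([rot_pct, np.full(p - k, np.nan)])
    table["rotation_cum"] = np.concatenate([np.cumsum(rot_pct), np.full(p - k, np.nan)])

    coef = score_coefficients(frame, rotated)
    scores = factor_scores(frame, coef)
    composite = composite_score(scores, rot_pct)
    return FactorModel(
        eigenvalues=vals,
        variance_table=table,
        loadings=load,
        rotated_loadings=rotated,
        score_coefficients=coef,
        scores=scores,
        contributions=rot_pct,
        composite=composite,
        ranking=rank_samples(composite),
        rotation_iterations=iters,
        retain_threshold=retain_threshold,
        feature_names=list(frame.columns),
    )
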