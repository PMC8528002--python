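"""Trait-scapes: standardised PCA of the trait table and centroid metrics.

A trait-scape is the 2-D principal-component projection of the
standardised (z-scored) wells x traits matrix.  Group (strain or
strain x environment) centroids are arithmetic means of PC1/PC2 scores;
phenotype shifts between centroids are summarised by their Euclidean
distance and direction in degrees from the horizontal (PC1 axis),
quadrant-resolved via the two-argument arctangent.  Correspondence
between two trait-scapes is the r-squared of a regression of all
pairwise centroid distances in one on those in the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .core_io import TraitTable
from .errors import DecompositionError, InvalidInputError

__all__ = [
    "TraitScape",
    "ShiftMetric",
    "CorrelationMatrix",
    "standardize",
    "pca",
    "centroids",
    "shift_metric",
    "traitscape_correspondence",
    "trait_correlation_matrix",
]


@dataclass
class TraitScape:
    """Standardised-PCA result: scores, loadings, % variance per component."""

    scores: pd.DataFrame  # rows x components, columns PC1..PCk
    loadings: pd.DataFrame  # traits x components
    var_explained: np.ndarray  # percentages, nonincreasing, sum 100

    def __post_init__(self) -> None:
        self.var_explained = np.asarray(self.var_explained, dtype=float)
        if not math.isclose(float(self.var_explained.sum()), 100.0, abs_tol=1e-6):
            raise InvalidInputError("var_explained must sum to 100%")


@dataclass(frozen=True)
class ShiftMetric:
    """Distance and direction (degrees from horizontal) between centroids.

    ``direction_deg`` is None for a zero-length shift, whose angle is
    undefined.
    """

    distance: float
    direction_deg: float | None


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided p and significance mask."""

    r: pd.DataFrame
    p: pd.DataFrame
    shown: pd.DataFrame  # True where p < alpha (and r is defined)
    alpha: float


def standardize(table: TraitTable | pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, sample sd 1, n-1 denominator).

    Puts all traits on a common scale before ordination; a zero-variance
    column cannot be standardised and is reported by name.
    """
    m = table.trait_matrix() if isinstance(table, TraitTable) else pd.DataFrame(table).dropna()
    if len(m) < 2:
        raise InvalidInputError("standardisation needs >= 2 complete rows")
    sd = m.std(axis=0, ddof=1)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise InvalidInputError(f"zero-variance column(s): {dead}")
    return (m - m.mean(axis=0)) / sd


def pca(z: pd.DataFrame) -> TraitScape:
    """Principal components of a standardised matrix via SVD.

    Sign convention: the largest-magnitude loading of each component is
    positive, so plots are reproducible.  Variance-explained percentages
    sum to 100 over the retained (nonzero) components.
    """
    x = np.asarray(z, dtype=float)
    n, p = x.shape
    if n < 2:
        raise InvalidInputError("PCA needs >= 2 rows")
    u, s, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    if not np.any(s > 1e-12 * max(s.max(initial=0.0), 1.0)):
        raise DecompositionError("zero-rank input: no variance to decompose")
    keep = s > 1e-12 * s[0]
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s
    var = s**2
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return TraitScape(
        scores=pd.DataFrame(scores, index=z.index, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=z.columns, columns=comp_names),
        var_explained=100.0 * var / var.sum(),
    )


def centroids(scape: TraitScape, grouping) -> dict[str, tuple[float, float]]:
    """Group means of (PC1, PC2) scores — the multivariate mean phenotypes."""
    g = pd.Series(list(grouping), index=scape.scores.index)
    if g.isna().any():
        raise InvalidInputError("every row must be assigned a group")
    out: dict[str, tuple[float, float]] = {}
    for name, idx in g.groupby(g).groups.items():
        sub = scape.scores.loc[idx]
        if len(sub) == 0:
            raise InvalidInputError(f"empty group {name!r}")
        out[name] = (float(sub["PC1"].mean()), float(sub["PC2"].mean()))
    return out


def shift_metric(c1: tuple[float, float], c2: tuple[float, float]) -> ShiftMetric:
    """Euclidean distance and quadrant-resolved angle between two centroids.

    The angle is atan2(dy, dx) in degrees, reported in (-180, 180]; a
    zero shift has no defined direction (None).
    """
    dx = c2[0] - c1[0]
    dy = c2[1] - c1[1]
    distance = math.hypot(dx, dy)
    if distance == 0.0:
        return ShiftMetric(distance=0.0, direction_deg=None)
    deg = math.degrees(math.atan2(dy, dx))
    if deg <= -180.0:
        deg += 360.0
    return ShiftMetric(distance=distance, direction_deg=deg)


def _pairwise_centroid_distances(
    cents: dict[str, tuple[float, float]], groups: list[str]
) -> np.ndarray:
    pts = np.array([cents[g] for g in groups], dtype=float)
    return pdist(pts)


def traitscape_correspondence(
    scape_a: TraitScape,
    scape_b: TraitScape,
    grouping_a,
    grouping_b,
) -> dict[str, float]:
    """Regression of scape_b's pairwise centroid distances on scape_a's.

    Measures whether two trait-scapes (e.g. plate-grown vs flask-grown
    cultures) preserve the between-group geometry: r^2 = 1 under any
    similarity transform.  Needs >= 3 shared groups (>= 3 distances).
    """
    ca = centroids(scape_a, grouping_a)
    cb = centroids(scape_b, grouping_b)
    shared = sorted(set(ca) & set(cb))
    if len(shared) < 3:
        raise InvalidInputError(f"need >= 3 shared groups, got {len(shared)}")
    da = _pairwise_centroid_distances(ca, shared)
    db = _pairwise_centroid_distances(cb, shared)
    res = stats.linregress(da, db)
    return {
        "r_squared": float(res.rvalue**2),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "n_distances": len(da),
    }


def trait_correlation_matrix(
    table: TraitTable | pd.DataFrame, alpha: float = 0.05
) -> CorrelationMatrix:
    """Pairwise Pearson r with t-distribution p; entries masked at p >= alpha.

    Mirrors the significance-masked correlation plots used to read trait
    trade-offs off the assembled table.  Constant columns have undefined
    correlations: r is NaN and the pair is never shown.
    """
    m = table.trait_matrix() if isinstance(table, TraitTable) else pd.DataFrame(table).dropna()
    n = len(m)
    if n < 3:
        raise InvalidInputError("need >= 3 complete rows for correlation tests")
    cols = list(m.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    shown = pd.DataFrame(np.eye(k, dtype=bool), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = m[cols[i]], m[cols[j]]
            if xi.std(ddof=1) == 0 or xj.std(ddof=1) == 0:
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(xi, xj)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
            ok = np.isfinite(pij) and pij < alpha
            shown.iloc[i, j] = shown.iloc[j, i] = ok
    return CorrelationMatrix(r=r, p=p, shown=shown, alpha=alpha)
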