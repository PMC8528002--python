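"""Permutational multivariate ANOVA (PERMANOVA) from first principles.

The pseudo-F statistic partitions sums of squared Euclidean distances of
the standardised trait data within and between groups, computed in the
Gower-centred inner-product form: G = J A J with A = -d^2 / 2 and J the
centring matrix.  For a projection H onto a design's column space,
SS(model) = tr(H G) and SS(residual) = tr(G) - tr(H G); on a single
variable this reduces exactly to the classical one-way ANOVA F.

p-values come from free permutation of rows, p = (#{F* >= F} + 1) /
(n_permutations + 1), so the smallest attainable p is 1/(n_perm + 1).
Two-factor designs use sequential (Type I) sums of squares with the same
permutation scheme per term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, InvalidInputError

__all__ = [
    "PermanovaResult",
    "euclidean_distance_matrix",
    "permanova",
    "permanova_two_factor",
    "pairwise_permanova",
    "bh_adjust",
]


@dataclass(frozen=True)
class PermanovaResult:
    """One PERMANOVA term: pseudo-F, permutation p, degrees of freedom."""

    pseudo_f: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    seed: int | None = None


def euclidean_distance_matrix(x) -> np.ndarray:
    """Symmetric pairwise Euclidean distance matrix of a rows x traits array."""
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or len(a) < 2:
        raise InvalidInputError("need a 2-D array with >= 2 rows")
    sq = np.sum(a**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (a @ a.T), 0.0)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def _gower_centre(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * np.asarray(dist, dtype=float) ** 2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection onto the column space of x, and its rank."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(initial=0.0), 1.0)
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def _design(groups: np.ndarray) -> np.ndarray:
    """Intercept + dummy columns for a single factor."""
    levels = pd.unique(groups)
    x = np.column_stack(
        [np.ones(len(groups))] + [(groups == lv).astype(float) for lv in levels[:-1]]
    )
    return x


def _check_dist(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidInputError("distance matrix must be square")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise InvalidInputError("distance matrix must be symmetric with zero diagonal")
    return d


def permanova(
    dist: np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    F = (SS_between / df_between) / (SS_within / df_within) with the sums
    of squares read off the Gower-centred matrix; the p-value is from
    free permutation of group labels.
    """
    d = _check_dist(dist)
    g = np.asarray(list(groups))
    n = len(d)
    if len(g) != n:
        raise InvalidInputError("groups must match the distance matrix size")
    levels, counts = np.unique(g, return_counts=True)
    k = len(levels)
    if k < 2:
        raise InvalidDesignError("need >= 2 groups")
    if not np.any(counts >= 2):
        raise InvalidDesignError("at least one group needs >= 2 members")
    df_between = k - 1
    df_within = n - k
    if df_within < 1:
        raise InvalidDesignError("no residual degrees of freedom")

    gmat = _gower_centre(d)
    ss_total = float(np.trace(gmat))
    h, _ = _hat(_design(g))

    def pseudo_f(perm_g: np.ndarray) -> tuple[float, float, float]:
        hp, _ = _hat(_design(perm_g))
        ss_b = float(np.sum(hp * gmat))  # tr(H G), H symmetric
        ss_w = ss_total - ss_b
        return (ss_b / df_between) / (ss_w / df_within), ss_b, ss_w

    f_obs, ss_b, ss_w = pseudo_f(g)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        f_perm, _, _ = pseudo_f(g[rng.permutation(n)])
        if f_perm >= f_obs:
            exceed += 1
    return PermanovaResult(
        pseudo_f=f_obs,
        p_value=(exceed + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
        df_between=df_between,
        df_within=df_within,
        ss_between=ss_b,
        ss_within=ss_w,
        seed=seed,
    )


def permanova_two_factor(
    dist: np.ndarray,
    factor_a,
    factor_b,
    n_permutations: int = 999,
    seed: int | None = None,
) -> dict[str, PermanovaResult]:
    """Two-factor PERMANOVA with interaction, sequential (Type I) SS.

    Terms are added in the order A, B, A x B; each term's SS is the
    increase in tr(H G) as its columns enter the design.  The p-value of
    every term comes from the same free permutation of observations.  A
    factor wholly aliased with the other (identical partition with > 1
    level) raises a design error; a constant factor collapses its term
    (0 df) and the remaining terms equal the one-way analysis.
    """
    d = _check_dist(dist)
    n = len(d)
    a = np.asarray(list(factor_a))
    b = np.asarray(list(factor_b))
    if len(a) != n or len(b) != n:
        raise InvalidInputError("factors must match the distance matrix size")
    gmat = _gower_centre(d)
    ss_total = float(np.trace(gmat))

    def designs(av: np.ndarray, bv: np.ndarray):
        xa = _design(av)
        lb = pd.unique(bv)
        xb_cols = [(bv == lv).astype(float) for lv in lb[:-1]]
        xab = np.column_stack([xa] + xb_cols) if xb_cols else xa
        inter = np.char.add(np.char.add(av.astype(str), ":"), bv.astype(str))
        li = pd.unique(inter)
        xi_cols = [(inter == lv).astype(float) for lv in li[:-1]]
        xfull = np.column_stack([xab] + xi_cols) if xi_cols else xab
        return xa, xab, xfull

    def term_stats(av, bv):
        xa, xab, xfull = designs(av, bv)
        ha, ra = _hat(xa)
        hab, rab = _hat(xab)
        hf, rf = _hat(xfull)
        tr_a = float(np.sum(ha * gmat))
        tr_ab = float(np.sum(hab * gmat))
        tr_f = float(np.sum(hf * gmat))
        df = {"A": ra - 1, "B": rab - ra, "A:B": rf - rab}
        ss = {"A": tr_a, "B": tr_ab - tr_a, "A:B": tr_f - tr_ab}
        df_res = n - rf
        ss_res = ss_total - tr_f
        return ss, df, ss_res, df_res

    ss, df, ss_res, df_res = term_stats(a, b)
    if len(pd.unique(b)) > 1 and df["B"] == 0:
        raise InvalidDesignError("factor_b is aliased with factor_a")
    if df_res < 1:
        raise InvalidDesignError("no residual degrees of freedom (need replication)")

    def f_of(ss_t: float, df_t: int, ss_r: float, df_r: int) -> float:
        if df_t == 0:
            return float("nan")
        return (ss_t / df_t) / (ss_r / df_r)

    f_obs = {t: f_of(ss[t], df[t], ss_res, df_res) for t in ("A", "B", "A:B")}
    exceed = {t: 0 for t in f_obs}
    rng = np.random.default_rng(seed)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        ss_p, df_p, ss_res_p, df_res_p = term_stats(a[perm], b[perm])
        for t in f_obs:
            if df[t] == 0:
                continue
            f_p = f_of(ss_p[t], df_p[t], ss_res_p, df_res_p)
            if f_p >= f_obs[t]:
                exceed[t] += 1
    out = {}
    for t in ("A", "B", "A:B"):
        out[t] = PermanovaResult(
            pseudo_f=f_obs[t],
            p_value=(exceed[t] + 1) / (n_permutations + 1) if df[t] else float("nan"),
            n_permutations=n_permutations,
            df_between=df[t],
            df_within=df_res,
            ss_between=ss[t],
            ss_within=ss_res,
            seed=seed,
        )
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def pairwise_permanova(
    dist: np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    p_adjust: str = "none",
) -> pd.DataFrame:
    """PERMANOVA on every group pair's distance submatrix.

    Returns one row per pair with pseudo-F, raw p, and (optionally)
    Benjamini-Hochberg adjusted p.  The default reports raw p-values.
    """
    if p_adjust not in ("none", "bh"):
        raise InvalidInputError("p_adjust must be 'none' or 'bh'")
    d = _check_dist(dist)
    g = np.asarray(list(groups))
    levels = sorted(pd.unique(g).tolist())
    if len(levels) < 2:
        raise InvalidDesignError("need >= 2 groups")
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    children = ss.spawn(len(levels) * (len(levels) - 1) // 2)
    rows = []
    idx = 0
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            mask = (g == levels[i]) | (g == levels[j])
            sub = d[np.ix_(mask, mask)]
            res = permanova(
                sub, g[mask], n_permutations=n_permutations,
                seed=int(children[idx].generate_state(1)[0] % (2**31)),
            )
            rows.append(
                {
                    "group_1": levels[i],
                    "group_2": levels[j],
                    "pseudo_f": res.pseudo_f,
                    "p_value": res.p_value,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "n_permutations": res.n_permutations,
                }
            )
            idx += 1
    table = pd.DataFrame(rows)
    if p_adjust == "bh":
        table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    return table
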