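"""Permutation-based multivariate inference on distance matrices.

PERMANOVA (pseudo-F on Gower-centered squared distances), the partial Mantel
test, distance-based variation partitioning over the soil-type / pH /
chemical-concentration blocks, BIOENV-style exhaustive covariate-subset
selection, min-max normalization, and Tukey HSD group comparison.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .containers import DistanceMatrix

__all__ = [
    "minmax_normalize",
    "permanova",
    "partial_mantel",
    "variation_partition",
    "bioenv",
    "tukey_hsd",
    "PermutationTestResult",
    "VariationPartition",
]


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_perm: int
    r_squared: float | None = None
    df: tuple[int, int] | None = None


@dataclass
class VariationPartition:
    """Venn fractions of community variance over explanatory blocks.

    ``fractions`` maps frozensets of block names to the variance fraction
    unique to that intersection region (inclusion-exclusion on unadjusted
    R-squared); ``residual`` is the unexplained remainder. ``p_unique``
    carries partial-Mantel significance of each block's unique fraction.
    """

    fractions: dict[frozenset, float]
    residual: float
    r2_full: float
    p_unique: dict[str, float] = field(default_factory=dict)
    n_negative_eigenvalues: int = 0

    def unique(self, block: str) -> float:
        return self.fractions[frozenset([block])]


def minmax_normalize(v: np.ndarray | pd.Series) -> np.ndarray:
    """Scale a covariate onto [0, 1]; a constant vector maps to zeros."""
    arr = np.asarray(v, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        warnings.warn("constant vector in min-max normalization; returning zeros")
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    means = a.mean(axis=0)
    return a - means[None, :] - means[:, None] + a.mean()


def _factor_f_stat(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float, int, int]:
    """Pseudo-F, R^2 and dfs for a single-factor grouping from squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        if ng > 1:
            sub = d2[np.ix_(mask, mask)]
            ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    if df_w <= 0 or ss_within <= 0:
        raise ValueError("within-group sum of squares is degenerate")
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, ss_between / ss_total, df_b, df_w


def permanova(
    d: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> PermutationTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``grouping`` is either a 1-D factor (categorical labels per sample) or a
    2-D design matrix of covariates (model df = its column count). The
    p-value counts permuted pseudo-F values >= the observed one under free
    permutation of sample labels: p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    With ``exact`` every distinct label assignment is enumerated instead
    (small n only) and p = #{F >= F_obs} / #assignments, the identity
    included.
    """
    n = len(d.ids)
    rng = np.random.default_rng(seed)
    grouping = np.asarray(grouping)
    if grouping.shape[0] != n:
        raise ValueError("grouping length must match the number of samples")

    if grouping.ndim == 1:
        levels, codes = np.unique(grouping, return_inverse=True)
        if len(levels) < 2:
            raise ValueError("need >= 2 groups")
        d2 = d.data**2
        f_obs, r2, df_b, df_w = _factor_f_stat(d2, codes, len(levels))
        if exact:
            if n > 10:
                raise ValueError("exact enumeration limited to n <= 10")
            assignments = {tuple(p) for p in itertools.permutations(codes)}
            count = sum(
                _factor_f_stat(d2, np.array(a), len(levels))[0] >= f_obs - 1e-12
                for a in assignments
            )
            return PermutationTestResult(
                statistic=float(f_obs), p_value=count / len(assignments),
                n_perm=len(assignments), r_squared=float(r2), df=(df_b, df_w),
            )
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            f_perm, _, _, _ = _factor_f_stat(d2, codes[perm], len(levels))
            if f_perm >= f_obs:
                count += 1
    else:
        # design-matrix form: McArdle & Anderson hat-matrix formulation
        x = np.column_stack([np.ones(n), grouping.astype(float)])
        h = x @ np.linalg.pinv(x)
        g = _gower_center(d.data)
        df_b = int(np.round(np.trace(h))) - 1
        df_w = n - df_b - 1
        tr_total = np.trace(g)

        def fstat(gmat: np.ndarray) -> tuple[float, float]:
            ss_b = np.trace(h @ gmat)
            ss_w = np.trace(gmat) - ss_b
            return (ss_b / df_b) / (ss_w / df_w), ss_b / tr_total

        f_obs, r2 = fstat(g)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            f_perm, _ = fstat(g[np.ix_(perm, perm)])
            if f_perm >= f_obs:
                count += 1

    p = (1 + count) / (1 + n_perm)
    return PermutationTestResult(
        statistic=float(f_obs), p_value=float(p), n_perm=n_perm,
        r_squared=float(r2), df=(df_b, df_w),
    )


def _offdiag(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    return d[np.triu_indices(n, 1)]


def partial_mantel(
    dA: DistanceMatrix,
    dB: DistanceMatrix,
    dC: DistanceMatrix,
    n_perm: int = 999,
    method: str = "spearman",
    seed: int = 0,
) -> PermutationTestResult:
    """Partial Mantel correlation of dA with dB controlling for dC.

    Off-diagonal vectors are (rank-transformed for Spearman) residualized
    against dC; significance comes from jointly permuting dA's rows and
    columns. One-sided p for positive association, the Mantel convention.
    """
    if not (dA.ids == dB.ids == dC.ids):
        raise ValueError("distance matrices must share sample ids and order")
    n = len(dA.ids)
    if n < 5:
        raise ValueError("need >= 5 samples")
    rng = np.random.default_rng(seed)

    def vec(d: np.ndarray) -> np.ndarray:
        v = _offdiag(d)
        if method == "spearman":
            v = stats.rankdata(v)
        return v

    b = vec(dB.data)
    c = vec(dC.data)
    r_bc = np.corrcoef(b, c)[0, 1]
    if abs(r_bc) >= 1 - 1e-12:
        raise ValueError("control matrix is perfectly collinear with dB")

    def partial_r(a_mat: np.ndarray) -> float:
        a = vec(a_mat)
        r_ab = np.corrcoef(a, b)[0, 1]
        r_ac = np.corrcoef(a, c)[0, 1]
        return (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))

    r_obs = partial_r(dA.data)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if partial_r(dA.data[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermutationTestResult(statistic=float(r_obs), p_value=float(p), n_perm=n_perm)


def _pcoa_scores(d: np.ndarray) -> tuple[np.ndarray, int]:
    """Principal-coordinate scores of a distance matrix.

    Negative-eigenvalue axes are dropped (their count reported), the
    standard dbRDA treatment of non-Euclidean dissimilarities.
    """
    g = _gower_center(d)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > max(1e-10, 1e-8 * abs(vals).max())
    n_neg = int((vals < -max(1e-10, 1e-8 * abs(vals).max())).sum())
    return vecs[:, keep] * np.sqrt(vals[keep]), n_neg


def _r2_multiresponse(y: np.ndarray, x: np.ndarray) -> float:
    """Fraction of total variance of multivariate y explained by [1, x]."""
    xx = np.column_stack([np.ones(len(y)), x])
    yc = y - y.mean(axis=0)
    beta, *_ = np.linalg.lstsq(xx, yc, rcond=None)
    fitted = xx @ beta
    return float((fitted**2).sum() / (yc**2).sum())


def variation_partition(
    d: DistanceMatrix,
    blocks: dict[str, pd.DataFrame | np.ndarray],
    n_perm: int = 999,
    seed: int = 0,
    test_unique: bool = True,
) -> VariationPartition:
    """Variation partitioning of a community distance matrix over blocks.

    Each block (e.g. ST = soil-type dummies, pH, CONC = Ca/Fe covariates) is
    an explanatory table over the same samples. R-squared of every block
    combination is obtained by regressing the principal coordinates of ``d``
    on the combined covariates (distance-based redundancy analysis); unique
    and shared Venn fractions follow by inclusion-exclusion on unadjusted
    R-squared, so fractions plus residual sum to one. Significance of each
    unique fraction comes from a partial Mantel test of ``d`` against the
    block's covariate distances, controlling for the other blocks combined.
    """
    names = list(blocks)
    if not 1 <= len(names) <= 3:
        raise ValueError("variation_partition supports 1-3 blocks")
    mats = {}
    for name, b in blocks.items():
        arr = np.asarray(b, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != len(d.ids):
            raise ValueError(f"block {name!r} rows != number of samples")
        mats[name] = arr

    y, n_neg = _pcoa_scores(d.data)

    r2: dict[frozenset, float] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            x = np.column_stack([mats[c] for c in combo])
            r2[frozenset(combo)] = _r2_multiresponse(y, x)

    # solve for the Venn regions: region(S) = variance in exactly the blocks of S
    regions = [frozenset(c) for r in range(1, len(names) + 1) for c in itertools.combinations(names, r)]
    a = np.zeros((len(regions), len(regions)))
    b_vec = np.zeros(len(regions))
    for i, combo in enumerate(regions):
        b_vec[i] = r2[combo]
        for j, region in enumerate(regions):
            if region & combo:
                a[i, j] = 1.0
    frac_values = np.linalg.solve(a, b_vec)
    fractions = {region: float(v) for region, v in zip(regions, frac_values)}
    full = r2[frozenset(names)]

    p_unique: dict[str, float] = {}
    if test_unique and len(names) >= 2:
        for name in names:
            others = [mats[o] for o in names if o != name]
            d_block = DistanceMatrix(
                squareform(pdist(stats.zscore(mats[name], axis=0, ddof=0))), d.ids
            )
            d_ctrl = DistanceMatrix(
                squareform(pdist(stats.zscore(np.column_stack(others), axis=0, ddof=0))),
                d.ids,
            )
            try:
                p_unique[name] = partial_mantel(
                    d, d_block, d_ctrl, n_perm=n_perm, seed=seed
                ).p_value
            except ValueError:
                p_unique[name] = float("nan")

    return VariationPartition(
        fractions=fractions,
        residual=float(1.0 - full),
        r2_full=float(full),
        p_unique=p_unique,
        n_negative_eigenvalues=n_neg,
    )


def bioenv(
    d: DistanceMatrix,
    env: pd.DataFrame,
    method: str = "spearman",
) -> tuple[tuple[str, ...], float]:
    """Exhaustive search for the covariate subset best matching ``d``.

    For every non-empty subset of (z-scored) covariates, the Euclidean
    distance matrix is correlated (Spearman by default) with ``d``'s
    off-diagonal vector; the subset with the highest correlation wins, ties
    going to the smaller subset.
    """
    if env.shape[1] > 15:
        raise ValueError("exhaustive subset search limited to 15 covariates")
    if env.shape[0] != len(d.ids):
        raise ValueError("env rows must match samples")
    target = _offdiag(d.data)
    scaled = stats.zscore(env.to_numpy(dtype=float), axis=0, ddof=0)
    best: tuple[tuple[str, ...], float] | None = None
    cols = list(env.columns)
    for r in range(1, len(cols) + 1):
        for combo in itertools.combinations(range(len(cols)), r):
            dv = pdist(scaled[:, list(combo)])
            if method == "spearman":
                rho = stats.spearmanr(dv, target).statistic
            else:
                rho = np.corrcoef(dv, target)[0, 1]
            if best is None or rho > best[1] + 1e-12:
                best = (tuple(cols[i] for i in combo), float(rho))
    assert best is not None
    return best


def tukey_hsd(values: np.ndarray | pd.Series, groups) -> pd.DataFrame:
    """Tukey honestly-significant-difference pairwise comparisons.

    Returns one row per group pair with the mean difference and the
    family-wise adjusted p-value (studentized range distribution).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [g for g in pd.unique(groups)]
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs n >= 2")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance everywhere")
    res = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            rows.append(
                {
                    "group_a": levels[i],
                    "group_b": levels[j],
                    "mean_diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)
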