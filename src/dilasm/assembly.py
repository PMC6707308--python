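"""Phylogenetic null-model inference of community-assembly processes.

The observed statistic is the abundance-weighted between-community mean
nearest taxon distance (betaMNTD): for each taxon in one community, the
patristic distance to its closest relative in the other community, averaged
with abundance weights, symmetrized over both directions. The null model
shuffles taxon labels across the full patristic matrix (all taxa in the
table's pool) and recomputes betaMNTD; the z-score of the observation
against 999 such shuffles is the beta nearest taxon index (betaNTI).

|betaNTI| < 2 is read as stochastic assembly, betaNTI > +2 as variable
selection (more phylogenetic turnover than expected), betaNTI < -2 as
homogeneous selection (less turnover than expected).
"""

from __future__ import annotations

import itertools
import math
import warnings

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .containers import AssemblyResult, CommunityMatrix, SampleDesign
from .trees import patristic_distances

__all__ = [
    "beta_mntd",
    "null_bmntd_distribution",
    "beta_nti",
    "classify_assembly",
    "within_treatment_bnti",
    "bnti_diversity_correlation",
]

VARIABLE_SELECTION = "variable_selection"
HOMOGENEOUS_SELECTION = "homogeneous_selection"
STOCHASTIC = "stochastic"


def _bmntd_from_indices(
    pd_values: np.ndarray,
    xi: np.ndarray,
    wx: np.ndarray,
    yi: np.ndarray,
    wy: np.ndarray,
) -> float:
    sub = pd_values[np.ix_(xi, yi)]
    return 0.5 * (float(wx @ sub.min(axis=1)) + float(wy @ sub.min(axis=0)))


def _null_draws(
    pd_values: np.ndarray,
    perms: np.ndarray,
    xi: np.ndarray,
    wx: np.ndarray,
    yi: np.ndarray,
    wy: np.ndarray,
    max_elements: int = 4_000_000,
) -> np.ndarray:
    """betaMNTD for one pair under every tip permutation, chunk-vectorized."""
    n_null = perms.shape[0]
    out = np.empty(n_null)
    per_perm = max(1, len(xi) * len(yi))
    chunk = max(1, min(n_null, max_elements // per_perm))
    for start in range(0, n_null, chunk):
        p = perms[start : start + chunk]
        rows = p[:, xi]  # (c, |x|)
        cols = p[:, yi]  # (c, |y|)
        sub = pd_values[rows[:, :, None], cols[:, None, :]]  # (c, |x|, |y|)
        out[start : start + chunk] = 0.5 * (
            sub.min(axis=2) @ wx + sub.min(axis=1) @ wy
        )
    return out


def beta_mntd(pd_matrix: pd.DataFrame, x: pd.Series, y: pd.Series) -> float:
    """Abundance-weighted betaMNTD between two communities.

    ``x`` and ``y`` are abundance vectors indexed by taxon id; taxa shared by
    both communities contribute a nearest-taxon distance of zero (their own
    counterpart sits in the other community).
    """
    taxa = list(pd_matrix.index)
    pos = {t: i for i, t in enumerate(taxa)}
    values = pd_matrix.to_numpy()

    def support(vec: pd.Series) -> tuple[np.ndarray, np.ndarray]:
        v = vec[vec > 0]
        missing = [t for t in v.index if t not in pos]
        if missing:
            raise ValueError(f"taxa absent from patristic matrix: {missing[:5]}")
        if v.empty:
            raise ValueError("empty community support")
        idx = np.array([pos[t] for t in v.index])
        w = v.to_numpy(dtype=float)
        return idx, w / w.sum()

    xi, wx = support(x)
    yi, wy = support(y)
    return _bmntd_from_indices(values, xi, wx, yi, wy)


def null_bmntd_distribution(
    pd_matrix: pd.DataFrame,
    x: pd.Series,
    y: pd.Series,
    n_null: int = 999,
    seed: int = 0,
    return_samples: bool = False,
) -> tuple[float, float, np.ndarray | None]:
    """Moments of betaMNTD under the tip-label shuffle null for one pair.

    Each draw permutes taxon identities over the full patristic index set
    and recomputes betaMNTD for the pair. Deterministic given ``seed``.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(pd_matrix.index)
    perms = np.array([rng.permutation(n) for _ in range(n_null)])
    values = pd_matrix.to_numpy()
    pos = {t: i for i, t in enumerate(pd_matrix.index)}
    xi = np.array([pos[t] for t in x[x > 0].index])
    yi = np.array([pos[t] for t in y[y > 0].index])
    wx = x[x > 0].to_numpy(dtype=float)
    wy = y[y > 0].to_numpy(dtype=float)
    wx, wy = wx / wx.sum(), wy / wy.sum()
    draws = _null_draws(values, perms, xi, wx, yi, wy)
    mean, sd = float(draws.mean()), float(draws.std(ddof=1))
    if sd <= 1e-12:
        warnings.warn("degenerate null distribution (sd = 0); betaNTI undefined")
    return mean, sd, draws if return_samples else None


def classify_assembly(bnti: float) -> str:
    """Map a betaNTI z-score onto its assembly-process label.

    Strictly above +2: variable selection; strictly below -2: homogeneous
    selection; otherwise (including exactly +/-2) stochastic. NaN yields
    ``"undefined"``.
    """
    if math.isnan(bnti):
        return "undefined"
    if bnti > 2.0:
        return VARIABLE_SELECTION
    if bnti < -2.0:
        return HOMOGENEOUS_SELECTION
    return STOCHASTIC


def beta_nti(
    tree: dendropy.Tree,
    m: CommunityMatrix,
    pairs: list[tuple[str, str]] | None = None,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> list[AssemblyResult]:
    """betaNTI for a set of sample pairs of one community table.

    The taxon pool is the set of taxa present anywhere in the table. One
    shared set of ``n_null`` tip permutations is drawn up front and reused
    for every pair, making pairwise z-scores comparable within a run and
    the whole run reproducible from ``seed``.
    """
    rel = m.to_relative()
    pool = rel.table.index[rel.table.sum(axis=1) > 0]
    table = rel.table.loc[pool]
    pdm = patristic_distances(tree)
    missing = [t for t in pool if t not in pdm.index]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:10]}")
    pdm = pdm.loc[pool, pool]
    values = pdm.to_numpy()
    n_pool = len(pool)

    if pairs is None:
        pairs = list(itertools.combinations(m.samples, 2))

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n_pool) for _ in range(n_null)])

    pos = {t: i for i, t in enumerate(pool)}
    supports = {}
    for s in {s for p in pairs for s in p}:
        col = table[s]
        colp = col[col > 0]
        if weighted:
            w = colp.to_numpy(dtype=float)
        else:
            w = np.ones(len(colp))
        supports[s] = (np.array([pos[t] for t in colp.index]), w / w.sum())

    results = []
    for a, b in pairs:
        xi, wx = supports[a]
        yi, wy = supports[b]
        obs = _bmntd_from_indices(values, xi, wx, yi, wy)
        draws = _null_draws(values, perms, xi, wx, yi, wy)
        mean, sd = float(draws.mean()), float(draws.std(ddof=1))
        if sd <= 1e-12:
            bnti = float("nan")
        else:
            bnti = (obs - mean) / sd
        results.append(
            AssemblyResult(
                pair=(a, b),
                bmntd_obs=obs,
                null_mean=mean,
                null_sd=sd,
                n_null=n_null,
                bnti=bnti,
                label=classify_assembly(bnti),
            )
        )
    return results


def results_to_frame(results: list[AssemblyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_a": r.pair[0],
                "sample_b": r.pair[1],
                "bmntd": r.bmntd_obs,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "bnti": r.bnti,
                "label": r.label,
            }
            for r in results
        ]
    )


def within_treatment_bnti(
    results: list[AssemblyResult],
    design: list[SampleDesign],
    include_subsample_pairs: bool = False,
) -> pd.DataFrame:
    """Group pairwise betaNTI values by (soil, pH, dilution) treatment.

    Only pairs whose two samples share a treatment are kept. By default,
    pairs of subsamples from the same microcosm (pseudo-replicates) are
    excluded; groups with fewer than one usable pair are skipped.
    Returns one row per pair with treatment columns, plus group medians
    accessible via ``groupby``.
    """
    by_id = {s.sample_id: s for s in design}
    rows = []
    for r in results:
        a, b = r.pair
        if a not in by_id or b not in by_id:
            continue
        sa, sb = by_id[a], by_id[b]
        if sa.treatment != sb.treatment:
            continue
        same_microcosm = sa.replicate == sb.replicate and sa.treatment == sb.treatment
        if same_microcosm and sa.subsample != sb.subsample and not include_subsample_pairs:
            continue
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "soil": sa.soil_type,
                "pH": sa.ph_level,
                "lg_dil": sa.lg_dil,
                "bnti": r.bnti,
                "label": r.label,
            }
        )
    return pd.DataFrame(rows)


def treatment_medians(grouped: pd.DataFrame) -> pd.DataFrame:
    """Median betaNTI and process counts per treatment cell."""
    if grouped.empty:
        return pd.DataFrame()
    out = (
        grouped.groupby(["soil", "pH", "lg_dil"])
        .agg(
            median_bnti=("bnti", "median"),
            n_pairs=("bnti", "size"),
            frac_variable=("label", lambda s: (s == VARIABLE_SELECTION).mean()),
            frac_homogeneous=("label", lambda s: (s == HOMOGENEOUS_SELECTION).mean()),
            frac_stochastic=("label", lambda s: (s == STOCHASTIC).mean()),
        )
        .reset_index()
    )
    return out


def bnti_diversity_correlation(
    results: list[AssemblyResult], shannon_per_sample: pd.Series
) -> tuple[float, float, float]:
    """Spearman correlation between |betaNTI| and Shannon diversity.

    Each pair's diversity is the mean Shannon index of its two samples.
    Returns (rho, rho squared, two-sided p).
    """
    xs, ys = [], []
    for r in results:
        a, b = r.pair
        if a in shannon_per_sample.index and b in shannon_per_sample.index and not math.isnan(r.bnti):
            xs.append(abs(r.bnti))
            ys.append(0.5 * (shannon_per_sample[a] + shannon_per_sample[b]))
    if len(xs) < 4:
        raise ValueError("need >= 4 pairs with matched diversity values")
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(rho**2), float(p)
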