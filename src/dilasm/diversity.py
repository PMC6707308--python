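"""Alpha-diversity, taxonomic and phylogenetic beta-diversity, ordination.

Implements the diversity arithmetic of the analysis: rarefaction to a common
read depth, the Shannon index (natural log), Bray-Curtis dissimilarity,
weighted UniFrac on a rooted branch-length tree, and non-metric
multidimensional scaling by majorization (SMACOF) with isotonic regression
on the dissimilarity ranks (Kruskal stress-1).
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .containers import CommunityMatrix, DistanceMatrix, Ordination
from .trees import branch_structure, patristic_distances, tip_depths

__all__ = [
    "rarefy",
    "shannon",
    "shannon_per_sample",
    "bray_curtis",
    "weighted_unifrac",
    "patristic_distances",
    "nmds",
]


def rarefy(
    m: CommunityMatrix,
    depth: int,
    seed: int = 0,
    drop_empty: bool = False,
) -> CommunityMatrix:
    """Subsample every sample column without replacement to exactly ``depth`` reads.

    Each column is one multivariate-hypergeometric draw (a single rarefaction
    at the stated depth, with the seed recorded by the caller). Columns below
    ``depth`` raise, naming the offending sample. All-zero taxon rows are
    retained unless ``drop_empty``.
    """
    if m.mode != "counts":
        raise ValueError("rarefaction requires a counts-mode table")
    counts = m.table.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction requires integer counts")
    counts = counts.astype(np.int64)
    short = m.table.columns[counts.sum(axis=0) < depth].tolist()
    if short:
        raise ValueError(f"samples below rarefaction depth {depth}: {short}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    result = CommunityMatrix(
        pd.DataFrame(out, index=m.table.index, columns=m.table.columns), mode="counts"
    )
    return result.drop_empty_taxa() if drop_empty else result


def shannon(column: np.ndarray | pd.Series, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log by default)."""
    p = np.asarray(column, dtype=float)
    if p.ndim != 1:
        raise ValueError("shannon expects a single abundance vector")
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise ValueError("Shannon diversity undefined for an all-zero sample")
    p = p[p > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def shannon_per_sample(m: CommunityMatrix, base: float | None = None) -> pd.Series:
    """Shannon index for every sample column."""
    return pd.Series(
        {s: shannon(m.table[s].to_numpy(), base=base) for s in m.samples}, name="shannon"
    )


def bray_curtis(m: CommunityMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    Columns are normalized to relative abundances first, so sequencing-depth
    differences do not masquerade as community turnover.
    """
    if len(m.samples) < 2:
        raise ValueError("need >= 2 samples")
    rel = m.to_relative().table.to_numpy().T
    d = squareform(pdist(rel, metric="braycurtis"))
    return DistanceMatrix(d, m.samples)


def weighted_unifrac(
    tree: dendropy.Tree, m: CommunityMatrix, normalized: bool = True
) -> DistanceMatrix:
    """Abundance-weighted UniFrac between all sample pairs.

    Raw form: sum over branches of branch_length * |p_A - p_B| where p_X is
    the fraction of community X's abundance descending from the branch. The
    normalized form divides by sum over tips of depth_tip * (p_A + p_B),
    the maximum attainable raw value, so results lie in [0, 1].
    """
    if len(m.samples) < 2:
        raise ValueError("need >= 2 samples")
    lengths, incidence, tips = branch_structure(tree)
    tip_index = {t: i for i, t in enumerate(tips)}
    present = m.table.index[m.table.sum(axis=1) > 0]
    missing = [t for t in present if t not in tip_index]
    if missing:
        raise ValueError(f"abundant taxa missing from tree: {missing[:10]}")

    rel = m.to_relative().table
    p = np.zeros((len(tips), len(m.samples)))
    for t in rel.index:
        if t in tip_index:
            p[tip_index[t]] = rel.loc[t].to_numpy()
    branch_mass = incidence @ p  # branches x samples
    n = len(m.samples)
    d = np.zeros((n, n))
    depth_map = tip_depths(tree)
    depths = np.array([depth_map[t] for t in tips])
    tipmass = depths @ p  # per-sample abundance-weighted depth
    for a in range(n):
        diff = np.abs(branch_mass[:, a, None] - branch_mass[:, a + 1 :])
        raw = lengths @ diff
        if normalized:
            denom = tipmass[a] + tipmass[a + 1 :]
            with np.errstate(invalid="ignore", divide="ignore"):
                raw = np.where(denom > 0, raw / denom, 0.0)
        d[a, a + 1 :] = raw
    d = d + d.T
    return DistanceMatrix(d, m.samples)


def _stress1(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom <= 0:
        return 0.0
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 50,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1.

    Each start alternates (i) isotonic regression of the configuration
    distances on the observed dissimilarities (ties share one fitted value,
    Kruskal's secondary approach) and (ii) a Guttman transform toward the
    fitted disparities. A start stops when stress-1 improves by less than
    ``tol`` or would increase; the best of ``n_starts`` random starts is
    returned.
    """
    n = len(d.ids)
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    delta = d.condensed()
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    best_stress = np.inf
    best_coords = None
    best_converged = False
    for _ in range(n_starts):
        x = rng.normal(size=(n, k))
        prev = np.inf
        converged = False
        coords_prev = x
        for _ in range(max_iter):
            dist = squareform(pdist(x))
            dvec = dist[iu]
            dhat = iso.fit_transform(delta, dvec)
            s = _stress1(dvec, dhat)
            if s > prev:  # majorization of the normalized stress can overshoot
                x = coords_prev
                s = prev
                converged = True
                break
            if prev - s < tol:
                prev = s
                converged = True
                break
            prev = s
            coords_prev = x
            # Guttman transform toward the disparities
            full_dhat = np.zeros((n, n))
            full_dhat[iu] = dhat
            full_dhat = full_dhat + full_dhat.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, full_dhat / dist, 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = (b @ x) / n
            x = x - x.mean(axis=0)
        if prev < best_stress:
            best_stress = prev
            best_coords = x
            best_converged = converged
    coords = pd.DataFrame(
        best_coords, index=d.ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    if not best_converged:
        warnings.warn("NMDS did not converge; returning best configuration found")
    return Ordination(
        coordinates=coords,
        stress=float(best_stress),
        n_starts_used=n_starts,
        converged=bool(best_converged),
    )
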