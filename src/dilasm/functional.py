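"""Functional-category profiles and indicator analysis of the gene table.

FG_RA is a category's share of a sample's reads; FG_Div its detected-gene
richness. Per-gene dilution trends are Spearman correlations of relative
abundance against the dilution exponent with BH-FDR control; IndVal scores
(sqrt of specificity x fidelity) flag genes indicative of sample groups,
with significance by group-label permutation in the style of multipatt.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FunctionalCatalog, SampleDesign

__all__ = [
    "category_relative_abundance",
    "category_gene_richness",
    "zscore_matrix",
    "gene_dilution_trends",
    "indval",
    "function_assembly_correlations",
]


def _check_gene_table(g: pd.DataFrame) -> None:
    if g.index.has_duplicates:
        raise ValueError("duplicate gene ids")
    if (g.to_numpy() < 0).any():
        raise ValueError("negative gene counts")


def category_relative_abundance(g: pd.DataFrame, cat: FunctionalCatalog) -> pd.DataFrame:
    """Per-sample share of reads belonging to each functional category.

    Share = reads of the category's genes / total reads of the sample
    (including unclassified genes, which are excluded from categories with
    a warning).
    """
    _check_gene_table(g)
    totals = g.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero-read samples: {bad}")
    unknown = [gene for gene in g.index if gene not in cat.gene_to_category]
    if unknown:
        warnings.warn(f"{len(unknown)} genes without category excluded from FG_RA")
    membership = pd.Series(
        {gene: cat.gene_to_category.get(gene) for gene in g.index}, name="category"
    )
    grouped = g.groupby(membership).sum()
    fg_ra = grouped / totals
    return fg_ra.reindex(cat.categories, fill_value=0.0)


def category_gene_richness(
    g: pd.DataFrame, cat: FunctionalCatalog, detection_threshold: int = 1
) -> pd.DataFrame:
    """Number of detected genes (reads >= threshold) per category and sample."""
    _check_gene_table(g)
    detected = (g >= detection_threshold).astype(int)
    membership = pd.Series(
        {gene: cat.gene_to_category.get(gene) for gene in g.index}, name="category"
    )
    richness = detected.groupby(membership).sum()
    return richness.reindex(cat.categories, fill_value=0)


def zscore_matrix(x: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score (remove mean, divide by population SD).

    Constant rows are emitted as zeros with a warning, matching the
    heatmap-normalization convention.
    """
    arr = x.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant rows z-scored to zeros")
    sd = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame((arr - mean) / sd, index=x.index, columns=x.columns)


def gene_dilution_trends(
    g: pd.DataFrame,
    design: list[SampleDesign] | pd.DataFrame,
    cat: FunctionalCatalog | None = None,
    alpha: float = 0.05,
    fdr: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Spearman trend of each gene's relative abundance against lg_dil.

    Returns a per-gene frame (rho, p, q, class in {increased, decreased, ns})
    and, when a catalog is supplied, per-category fractions of significantly
    increased/decreased genes.
    """
    _check_gene_table(g)
    if isinstance(design, pd.DataFrame):
        lg = design["lg_dil"]
    else:
        lg = pd.Series({s.sample_id: s.lg_dil for s in design})
    lg = lg.reindex(g.columns)
    if lg.isna().any():
        raise ValueError("samples missing from design")
    if lg.nunique() < 3:
        raise ValueError("need >= 3 distinct lg_dil levels")
    rel = g / g.sum(axis=0)
    x = lg.to_numpy(dtype=float)

    rows = []
    for gene in g.index:
        y = rel.loc[gene].to_numpy(dtype=float)
        if np.all(y == 0) or np.ptp(y) == 0:
            rows.append({"gene": gene, "rho": np.nan, "p": np.nan, "class": "ns"})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"gene": gene, "rho": rho, "p": p, "class": None})
    out = pd.DataFrame(rows).set_index("gene")

    valid = out["p"].notna()
    if fdr:
        q = np.full(len(out), np.nan)
        if valid.any():
            q[valid.to_numpy()] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
        out["q"] = q
        crit = out["q"]
    else:
        out["q"] = out["p"]
        crit = out["p"]
    sig = valid & (crit < alpha)
    out.loc[sig & (out["rho"] > 0), "class"] = "increased"
    out.loc[sig & (out["rho"] < 0), "class"] = "decreased"
    out["class"] = out["class"].fillna("ns")

    per_cat = None
    if cat is not None:
        rows = []
        for c in cat.categories:
            genes = [x_ for x_ in cat.genes_in(c) if x_ in out.index]
            if not genes:
                continue
            sub = out.loc[genes, "class"]
            rows.append(
                {
                    "category": c,
                    "fungp": cat.category_to_fungp[c],
                    "n_genes": len(genes),
                    "frac_increased": float((sub == "increased").mean()),
                    "frac_decreased": float((sub == "decreased").mean()),
                }
            )
        per_cat = pd.DataFrame(rows)
    return out, per_cat


def _indval_stats(
    abundance: np.ndarray, presence: np.ndarray, codes: np.ndarray,
    combos: list[tuple[int, ...]],
) -> np.ndarray:
    """IndVal statistic of one gene for every candidate group combination."""
    n_groups = codes.max() + 1
    group_means = np.array([abundance[codes == g].mean() for g in range(n_groups)])
    total = group_means.sum()
    out = np.zeros(len(combos))
    if total <= 0:
        return out
    for i, combo in enumerate(combos):
        mask = np.isin(codes, combo)
        # specificity: combination's group-equalized mean abundance over the
        # sum of base-group means; fidelity: occurrence within the combination
        spec = (sum(group_means[list(combo)]) / len(combo)) / total
        fid = presence[mask].mean()
        out[i] = np.sqrt(max(spec, 0.0) * fid)
    return out


def indval(
    g: pd.DataFrame,
    grouping,
    with_combinations: bool = True,
    n_perm: int = 999,
    seed: int = 0,
    squared: bool = False,
) -> pd.DataFrame:
    """Indicator-value analysis of every gene against a sample grouping.

    For gene k and group combination c: specificity A is c's (group-
    equalized) mean abundance over the summed base-group means; fidelity B
    is the fraction of c's samples where the gene is present. The statistic
    is sqrt(A x B) (or A x B with ``squared``). The best combination
    (excluding the trivial all-groups union) is reported per gene; p-values
    permute sample group labels and compare the permuted best statistic.
    """
    _check_gene_table(g)
    grouping = np.asarray(grouping)
    if grouping.shape[0] != g.shape[1]:
        raise ValueError("grouping length must match sample count")
    levels, codes = np.unique(grouping, return_inverse=True)
    n_groups = len(levels)
    if n_groups < 2:
        raise ValueError("need >= 2 groups")
    max_size = n_groups - 1 if with_combinations else 1
    combos: list[tuple[int, ...]] = []
    for r in range(1, max_size + 1):
        combos.extend(itertools.combinations(range(n_groups), r))

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(len(codes)) for _ in range(n_perm)]

    rows = []
    abund = g.to_numpy(dtype=float)
    presence = abund > 0
    for gi, gene in enumerate(g.index):
        if not presence[gi].any():
            continue
        obs_all = _indval_stats(abund[gi], presence[gi], codes, combos)
        if squared:
            obs_all = obs_all**2
        best_i = int(np.argmax(obs_all))
        obs = obs_all[best_i]
        count = 0
        for perm in perms:
            perm_stats = _indval_stats(abund[gi], presence[gi], codes[perm], combos)
            if squared:
                perm_stats = perm_stats**2
            if perm_stats.max() >= obs - 1e-12:
                count += 1
        rows.append(
            {
                "gene": gene,
                "best_group": "+".join(str(levels[i]) for i in combos[best_i]),
                "stat": float(obs),
                "p": (1 + count) / (1 + n_perm),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def function_assembly_correlations(
    shannon_per_sample: pd.Series,
    abs_bnti_per_sample: pd.Series,
    fg_ra: pd.DataFrame,
    fg_div: pd.DataFrame,
    cat: FunctionalCatalog | None = None,
) -> pd.DataFrame:
    """Spearman grid linking diversity and assembly strength to function.

    For every category: correlations of FG_RA and FG_Div with the Shannon
    index and with |betaNTI| (the latter mapped to samples beforehand, e.g.
    by within-treatment medians). Cells with fewer than 4 matched values or
    a constant profile are NaN.
    """
    rows = []
    for cname in fg_ra.index:
        row: dict = {"category": cname}
        if cat is not None:
            row["fungp"] = cat.category_to_fungp.get(cname)
        for label, profile in (("FG_RA", fg_ra), ("FG_Div", fg_div)):
            for pred_name, pred in (("shannon", shannon_per_sample), ("abs_bnti", abs_bnti_per_sample)):
                common = profile.columns.intersection(pred.index)
                ys = profile.loc[cname, common].to_numpy(dtype=float)
                xs = pred.reindex(common).to_numpy(dtype=float)
                ok = ~(np.isnan(xs) | np.isnan(ys))
                if ok.sum() < 4 or np.ptp(ys[ok]) == 0 or np.ptp(xs[ok]) == 0:
                    rho, p = np.nan, np.nan
                else:
                    rho, p = stats.spearmanr(xs[ok], ys[ok])
                row[f"rho_{pred_name}_{label}"] = rho
                row[f"p_{pred_name}_{label}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")
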