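"""Self-contained benchmark experiments for validating the pipeline.

Each benchmark fixes a generator configuration in one known assembly regime
and measures how well the analysis recovers it. Problem sizes are desk-scale
versions of the full factorial design (pools of a few hundred to ~1500 taxa,
one sequenced subsample per microcosm); the measured quantities are the ones
the analysis reports on real data.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from . import assembly, diversity, functional, mvstats
from .containers import CommunityMatrix
from .synthetic import ExperimentConfig, generate_experiment, sample_reads
from .trees import build_phylogeny

__all__ = [
    "regime_config",
    "regime_median_bnti",
    "neutral_calibration",
    "gradient_config",
    "diversity_assembly_correlation",
    "vpa_dilution_trend",
    "functional_group_signs",
    "fig4d_sign_grid",
]


def regime_config(regime: str, seed: int) -> ExperimentConfig:
    """A single-soil experiment whose every treatment sits in one regime.

    ``homogeneous``: micro-environmental pH heterogeneity switched off, so
    each treatment applies one uniform strong filter. ``variable``: flat
    microsite SD of 2 pH units, so replicate microcosms of a treatment are
    filtered toward different optima. ``neutral``: selection off (smaller
    pool; membership turnover comes from dilution alone).
    """
    common = dict(
        soils=("red",),
        ph_levels=(4.5, 5.5, 6.5, 7.5, 8.5),
        dilutions=(1, 7),
        replicates=6,
        subsamples=1,
        include_untreated=False,
        n_black=10,
        overlap=0.0,
        seed=seed,
    )
    if regime == "homogeneous":
        return ExperimentConfig(
            n_taxa=2000, n_red=1500, otu_depth=12000,
            microsite_sd_neutral=0.05, microsite_sd_extreme=0.05, **common,
        )
    if regime == "variable":
        return ExperimentConfig(
            n_taxa=2000, n_red=1500, otu_depth=12000,
            microsite_sd_neutral=2.0, microsite_sd_extreme=2.0, **common,
        )
    if regime == "neutral":
        common["dilutions"] = (1, 10)
        return ExperimentConfig(
            n_taxa=400, n_red=300, otu_depth=6000,
            selection_strength=0.0, **common,
        )
    raise ValueError(f"unknown regime {regime!r}")


def regime_median_bnti(regime: str, seed: int, n_null: int = 199) -> float:
    """Median within-treatment betaNTI at the high-dilution level.

    The experiment's low-dilution samples stay in the table so the null
    model's taxon pool spans the full pH gradient.
    """
    cfg = regime_config(regime, seed)
    exp = generate_experiment(cfg)
    high = max(cfg.dilutions)
    groups: dict = {}
    for s in exp.design:
        if s.lg_dil == high:
            groups.setdefault(s.treatment, []).append(s.sample_id)
    pairs = [p for mem in groups.values() for p in itertools.combinations(mem, 2)]
    res = assembly.beta_nti(exp.tree, exp.otu_table, pairs, n_null=n_null, seed=seed + 1)
    grouped = assembly.within_treatment_bnti(res, exp.design)
    return float(grouped.groupby("pH")["bnti"].median().median())


def neutral_calibration(
    seed: int,
    n_tips: int = 500,
    depth: int = 600,
    n_samples: int = 21,
    n_null: int = 999,
) -> dict:
    """betaNTI z-score calibration under its own tip-shuffle null.

    Communities are independent multinomial draws from one even taxon pool
    on a random pure-birth tree — phylogeny and membership are exchangeable,
    so betaNTI should behave like a standard z-score. The default sizes
    keep sample supports large enough that the finite-sample skew of the
    nearest-taxon statistic does not shift the z-score mean.
    """
    tree = build_phylogeny(n_tips, 1.0, seed=seed)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    rel = pd.Series(1.0 / n_tips, index=tips)
    cols = {
        f"s{i}": sample_reads(rel, depth, seed=seed * 1000 + i) for i in range(n_samples)
    }
    m = CommunityMatrix(pd.DataFrame(cols), mode="counts").drop_empty_taxa()
    pairs = list(itertools.combinations(m.samples, 2))
    res = assembly.beta_nti(tree, m, pairs, n_null=n_null, seed=seed + 1)
    z = np.array([r.bnti for r in res])
    return {
        "mean": float(z.mean()),
        "sd": float(z.std()),
        "rate_gt2": float((np.abs(z) > 2).mean()),
        "n_pairs": len(z),
    }


def gradient_config(seed: int, soils: str = "both") -> ExperimentConfig:
    """Desk-scale version of the full two-soil dilution x pH gradient."""
    if soils == "both":
        return ExperimentConfig(
            replicates=4, subsamples=1, n_taxa=1600, n_black=800, n_red=800,
            overlap=0.5, otu_depth=8000, seed=seed,
        )
    return ExperimentConfig(
        soils=("red",), replicates=3, subsamples=1, n_taxa=1100, n_black=10,
        n_red=800, overlap=0.0, otu_depth=8000, seed=seed,
    )


def diversity_assembly_correlation(seed: int, n_null: int = 99) -> dict:
    """Spearman correlation of |betaNTI| with Shannon diversity on the gradient."""
    cfg = gradient_config(seed, soils="both")
    exp = generate_experiment(cfg)
    rare = diversity.rarefy(exp.otu_table, 6000, seed=seed + 1)
    sh = diversity.shannon_per_sample(rare)
    groups: dict = {}
    for s in exp.design:
        groups.setdefault(s.treatment, []).append(s.sample_id)
    pairs = [p for mem in groups.values() for p in itertools.combinations(mem, 2)]
    res = assembly.beta_nti(exp.tree, rare, pairs, n_null=n_null, seed=seed + 2)
    rho, r2, p = assembly.bnti_diversity_correlation(res, sh)
    return {"rho": rho, "rho_squared": r2, "p": p, "n_pairs": len(pairs)}


def vpa_dilution_trend(seed: int) -> dict:
    """Unique ST and pH variance fractions per treated dilution level.

    The pH block enters as factor dummies (the community's pH response is
    unimodal, so a single linear pH column would miss it).
    """
    cfg = gradient_config(seed, soils="both")
    cfg.replicates = 3
    exp = generate_experiment(cfg)
    meta = exp.metadata
    rare = diversity.rarefy(exp.otu_table, 6000, seed=seed + 1)
    wu = diversity.weighted_unifrac(exp.tree, rare)
    st_frac, ph_frac = {}, {}
    for dil in sorted(d for d in meta["lg_dil"].unique() if d > 0):
        samples = meta.index[meta["lg_dil"] == dil].tolist()
        sub = wu.subset(samples)
        st = pd.get_dummies(meta.loc[samples, "soil"], drop_first=True).to_numpy(float)
        ph = pd.get_dummies(meta.loc[samples, "pH"].astype(str), drop_first=True).to_numpy(float)
        conc = np.column_stack(
            [mvstats.minmax_normalize(meta.loc[samples, c]) for c in ("Ca", "Fe", "SO4")]
        )
        vp = mvstats.variation_partition(
            sub, {"ST": st, "pH": ph, "CONC": conc}, test_unique=False
        )
        st_frac[int(dil)] = vp.unique("ST")
        ph_frac[int(dil)] = vp.unique("pH")
    return {"ST": st_frac, "pH": ph_frac}


def functional_group_signs(seed: int) -> dict:
    """Dilution trends of FG_RA and FG_Div per functional group.

    Returns Spearman correlations with lg_dil of the summed FunGp relative
    abundance and the mean per-category gene richness, plus the relative
    FG_Div decline amplitude from dilution 1 to the deepest dilution.
    """
    cfg = gradient_config(seed, soils="red")
    exp = generate_experiment(cfg)
    lg = exp.metadata["lg_dil"]
    fungp = pd.Series(exp.catalog.category_to_fungp)
    fg_ra = functional.category_relative_abundance(exp.gene_table, exp.catalog)
    fg_div = functional.category_gene_richness(exp.gene_table, exp.catalog)
    out: dict = {}
    for grp in ("FunGp1", "FunGp2"):
        cats = fungp.index[fungp == grp]
        ra = fg_ra.loc[cats].sum()
        dv = fg_div.loc[cats].mean()
        out[f"{grp}_ra_rho"] = float(stats.spearmanr(lg.to_numpy(), ra.to_numpy()).statistic)
        out[f"{grp}_div_rho"] = float(stats.spearmanr(lg.to_numpy(), dv.to_numpy()).statistic)
        by_dil = pd.Series(dv.to_numpy(), index=lg.to_numpy()).groupby(level=0).mean()
        deepest = by_dil.index.max()
        out[f"{grp}_div_amplitude"] = float(
            (by_dil[1] - by_dil[deepest]) / max(by_dil[1], 1e-9)
        )
    return out


def fig4d_sign_grid(seed: int, n_null: int = 99) -> dict:
    """Sign structure of the diversity/assembly vs function correlation grid.

    Checks the reported contrast: FunGp1 relative abundance correlates
    positively with Shannon diversity and negatively with |betaNTI|;
    FunGp2 relative abundance shows the opposite signs. Four replicates per
    treatment keep the within-treatment median |betaNTI| (the per-sample
    assembly covariate) reasonably stable.
    """
    cfg = gradient_config(seed, soils="red")
    cfg.replicates = 4
    exp = generate_experiment(cfg)
    rare = diversity.rarefy(exp.otu_table, 6000, seed=seed + 1)
    sh = diversity.shannon_per_sample(rare)
    groups: dict = {}
    for s in exp.design:
        groups.setdefault(s.treatment, []).append(s.sample_id)
    pairs = [p for mem in groups.values() for p in itertools.combinations(mem, 2)]
    res = assembly.beta_nti(exp.tree, rare, pairs, n_null=n_null, seed=seed + 2)
    grouped = assembly.within_treatment_bnti(res, exp.design)
    med = grouped.groupby(["soil", "pH", "lg_dil"])["bnti"].median().abs()
    abs_bnti = pd.Series(
        {
            s.sample_id: med.get((s.soil_type, s.ph_level, s.lg_dil), np.nan)
            for s in exp.design
        }
    )
    fg_ra = functional.category_relative_abundance(exp.gene_table, exp.catalog)
    fg_div = functional.category_gene_richness(exp.gene_table, exp.catalog)
    # group-level profiles: the figure's qualitative contrast is between the
    # two functional groups, and group FG_RA shares are complementary
    fungp = pd.Series(exp.catalog.category_to_fungp)
    group_ra = fg_ra.groupby(fungp).sum()
    group_div = fg_div.groupby(fungp).mean()
    out = {}
    for grp in ("FunGp1", "FunGp2"):
        for label, profile in (("ra", group_ra), ("div", group_div)):
            for pred_name, pred in (("shannon", sh), ("absbnti", abs_bnti)):
                common = profile.columns.intersection(pred.index)
                ys = profile.loc[grp, common].to_numpy(dtype=float)
                xs = pred.reindex(common).to_numpy(dtype=float)
                ok = ~(np.isnan(xs) | np.isnan(ys))
                rho = stats.spearmanr(xs[ok], ys[ok]).statistic
                out[f"{grp.lower()}_{label}_{pred_name}"] = float(rho)
    return out
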