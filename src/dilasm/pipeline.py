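"""Stage orchestration: simulate -> diversity -> assembly -> multivariate -> function.

``run_pipeline`` executes the stages in dependency order into an append-only
output directory, logging every stage's seed and parameters, and returns a
report mirroring the study's result tables (diversity summaries, ordination,
variance partitioning per dilution level, assembly-process classification,
and functional-group trend grids).
"""

from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assembly, diversity, functional, io, mvstats
from .containers import CommunityMatrix, SampleDesign
from .synthetic import ExperimentConfig, generate_experiment

logger = logging.getLogger("dilasm")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "simulate_to_dir"]


@dataclass
class PipelineConfig:
    """Pipeline-level knobs around the generator config."""

    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    rarefaction_depth: int = 11020
    n_null: int = 999
    n_perm: int = 999
    nmds_starts: int = 20
    max_bnti_pairs_per_treatment: int | None = None
    seed: int = 0


@dataclass
class RunReport:
    shannon_summary: pd.DataFrame
    nmds_stress: float
    nmds_coordinates: pd.DataFrame
    unifrac_tukey: pd.DataFrame
    vpa_by_dilution: pd.DataFrame
    bnti_treatments: pd.DataFrame
    bnti_shannon: dict
    gene_trends: pd.DataFrame
    fig4_grid: pd.DataFrame
    n_microcosms: int
    n_samples: int


def simulate_to_dir(config: ExperimentConfig, out_dir: str) -> None:
    """Run the generator and write all canonical files into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    exp = generate_experiment(config)
    io.write_community(exp.otu_table, os.path.join(out_dir, "otu_table.tsv"))
    exp.gene_table.rename_axis("gene").to_csv(
        os.path.join(out_dir, "gene_table.tsv"), sep="\t"
    )
    io.write_catalog(exp.catalog, os.path.join(out_dir, "catalog.tsv"))
    io.write_metadata(exp.design, os.path.join(out_dir, "metadata.tsv"))
    io.write_tree(exp.tree, os.path.join(out_dir, "tree.nwk"))
    exp.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)


def _within_treatment_pairs(
    design: list[SampleDesign], cap: int | None, rng: np.random.Generator
) -> list[tuple[str, str]]:
    groups: dict = {}
    for s in design:
        groups.setdefault(s.treatment, []).append(s)
    pairs = []
    for members in groups.values():
        cand = [
            (a.sample_id, b.sample_id)
            for a, b in itertools.combinations(members, 2)
            if a.replicate != b.replicate  # skip same-microcosm pseudo-replicates
        ]
        if cap is not None and len(cand) > cap:
            idx = rng.choice(len(cand), size=cap, replace=False)
            cand = [cand[i] for i in idx]
        pairs.extend(cand)
    return pairs


def run_pipeline(config: PipelineConfig, out_dir: str | None = None) -> RunReport:
    """Execute the full analysis on one simulated experiment."""
    ss = np.random.SeedSequence(config.seed)
    s_sim, s_rare, s_nmds, s_bnti, s_perm, s_pairs = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(6)
    )
    exp_config = config.experiment
    exp_config.seed = s_sim
    exp = generate_experiment(exp_config)
    if out_dir:
        simulate_to_dir(exp_config, out_dir)

    meta = exp.metadata
    depth = min(config.rarefaction_depth, int(exp.otu_table.table.sum(axis=0).min()))
    rare = diversity.rarefy(exp.otu_table, depth, seed=s_rare)
    logger.info("rarefied %d samples to %d reads", len(rare.samples), depth)

    sh = diversity.shannon_per_sample(rare)
    shannon_summary = (
        pd.DataFrame({"shannon": sh})
        .join(meta[["soil", "pH", "lg_dil"]])
        .groupby(["soil", "pH", "lg_dil"])["shannon"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )

    bc = diversity.bray_curtis(rare)
    ord_res = diversity.nmds(bc, k=2, n_starts=config.nmds_starts, seed=s_nmds)

    wu = diversity.weighted_unifrac(exp.tree, rare)
    # within-soil, across-pH UniFrac distances grouped by dilution level
    rows = []
    ids = wu.ids
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ma, mb = meta.loc[a], meta.loc[b]
            if ma["soil"] == mb["soil"] and ma["lg_dil"] == mb["lg_dil"] and ma["pH"] != mb["pH"]:
                rows.append({"lg_dil": ma["lg_dil"], "dist": wu[a, b]})
    unidf = pd.DataFrame(rows)
    if unidf["lg_dil"].nunique() >= 2:
        unifrac_tukey = mvstats.tukey_hsd(unidf["dist"], unidf["lg_dil"])
    else:
        unifrac_tukey = pd.DataFrame()

    # VPA per dilution level over ST / pH / CONC blocks
    vpa_rows = []
    for dil in sorted(meta["lg_dil"].unique()):
        samples = meta.index[meta["lg_dil"] == dil].tolist()
        if len(samples) < 8 or meta.loc[samples, "soil"].nunique() < 2:
            continue
        sub = wu.subset(samples)
        st = pd.get_dummies(meta.loc[samples, "soil"], drop_first=True).to_numpy(float)
        ph = meta.loc[samples, "pH"].to_numpy(float)[:, None]
        conc = np.column_stack(
            [mvstats.minmax_normalize(meta.loc[samples, c]) for c in ("Ca", "Fe", "SO4")]
        )
        if ph.std() == 0:
            continue
        vp = mvstats.variation_partition(
            sub, {"ST": st, "pH": ph, "CONC": conc}, n_perm=config.n_perm, seed=s_perm,
            test_unique=False,
        )
        vpa_rows.append(
            {
                "lg_dil": dil,
                "ST": vp.unique("ST"),
                "pH": vp.unique("pH"),
                "CONC": vp.unique("CONC"),
                "residual": vp.residual,
            }
        )
    vpa_by_dilution = pd.DataFrame(vpa_rows)

    pair_rng = np.random.default_rng(s_pairs)
    pairs = _within_treatment_pairs(exp.design, config.max_bnti_pairs_per_treatment, pair_rng)
    results = assembly.beta_nti(exp.tree, rare, pairs, n_null=config.n_null, seed=s_bnti)
    grouped = assembly.within_treatment_bnti(results, exp.design)
    bnti_treatments = assembly.treatment_medians(grouped)
    rho, r2, p = assembly.bnti_diversity_correlation(results, sh)
    bnti_shannon = {"rho": rho, "rho_squared": r2, "p": p}

    # |betaNTI| mapped to samples via within-treatment medians
    med = grouped.groupby(["soil", "pH", "lg_dil"])["bnti"].median().abs()
    abs_bnti = pd.Series(
        {
            s.sample_id: med.get((s.soil_type, s.ph_level, s.lg_dil), np.nan)
            for s in exp.design
        }
    )

    fg_ra = functional.category_relative_abundance(exp.gene_table, exp.catalog)
    fg_div = functional.category_gene_richness(exp.gene_table, exp.catalog)
    _, per_cat = functional.gene_dilution_trends(exp.gene_table, exp.design, exp.catalog)
    fig4_grid = functional.function_assembly_correlations(sh, abs_bnti, fg_ra, fg_div, exp.catalog)

    report = RunReport(
        shannon_summary=shannon_summary,
        nmds_stress=ord_res.stress,
        nmds_coordinates=ord_res.coordinates,
        unifrac_tukey=unifrac_tukey,
        vpa_by_dilution=vpa_by_dilution,
        bnti_treatments=bnti_treatments,
        bnti_shannon=bnti_shannon,
        gene_trends=per_cat if per_cat is not None else pd.DataFrame(),
        fig4_grid=fig4_grid,
        n_microcosms=exp_config.n_microcosms,
        n_samples=exp_config.n_samples,
    )

    if out_dir:
        report.shannon_summary.to_csv(os.path.join(out_dir, "shannon_summary.tsv"), sep="\t", index=False)
        report.nmds_coordinates.rename_axis("sample_id").to_csv(os.path.join(out_dir, "nmds.tsv"), sep="\t")
        report.vpa_by_dilution.to_csv(os.path.join(out_dir, "vpa.tsv"), sep="\t", index=False)
        assembly.results_to_frame(results).to_csv(os.path.join(out_dir, "bnti.tsv"), sep="\t", index=False)
        report.bnti_treatments.to_csv(os.path.join(out_dir, "bnti_treatments.tsv"), sep="\t", index=False)
        report.gene_trends.to_csv(os.path.join(out_dir, "gene_trends.tsv"), sep="\t", index=False)
        report.fig4_grid.to_csv(os.path.join(out_dir, "fig4d_grid.tsv"), sep="\t")
        with open(os.path.join(out_dir, "run.json"), "w") as fh:
            json.dump(
                {
                    "seed": config.seed,
                    "rarefaction_depth": depth,
                    "n_null": config.n_null,
                    "n_perm": config.n_perm,
                    "nmds_stress": report.nmds_stress,
                    "bnti_shannon": bnti_shannon,
                    "n_microcosms": report.n_microcosms,
                    "n_samples": report.n_samples,
                },
                fh,
                indent=2,
            )
    return report
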