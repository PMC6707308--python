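"""Synthetic dilution-to-extinction microcosm experiments.

Emulates the statistical structure of a 2-soil x 5-pH x 4-dilution microcosm
design: two regional species pools with partial overlap drawn from one shared
phylogeny, lognormal inoculum abundances spanning many orders of magnitude,
Poisson dilution that loses rare taxa first, Gaussian pH-niche filtering of a
phylogenetically conserved (Brownian-motion) pH optimum with per-microcosm
micro-environmental pH jitter, multinomial read sampling, and a functional
gene catalog in which specialized categories sit on narrow (and rare) clades
while broad categories spread over most taxa.

All stages are deterministic given the master seed; child seeds are spawned
from one :class:`numpy.random.SeedSequence` in a fixed documented order
(tree, traits, pools, genes, covariates, then one child per microcosm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

from .containers import (
    CommunityMatrix,
    FunctionalCatalog,
    RegionalPool,
    SampleDesign,
    SyntheticExperiment,
)
from .trees import assign_ph_optima, build_phylogeny, clades_by_size

__all__ = [
    "build_phylogeny",
    "assign_ph_optima",
    "build_regional_pools",
    "dilute_inoculum",
    "incubate",
    "sample_reads",
    "assign_gene_content",
    "synthesize_gene_table",
    "generate_experiment",
    "ExperimentConfig",
    "NEUTRAL",
    "VARIABLE",
    "HOMOGENEOUS",
]

NEUTRAL = "neutral"
VARIABLE = "variable_selection"
HOMOGENEOUS = "homogeneous_selection"


def build_regional_pools(
    tree: dendropy.Tree,
    n_black: int,
    n_red: int,
    overlap: float,
    lognormal_mu: float = 15.0,
    lognormal_sigma: float = 6.0,
    seed: int = 0,
    ph_optima: dict[str, float] | None = None,
    niche_breadth: float = 0.8,
    exclusive_rarity: float = 1.0,
) -> tuple[RegionalPool, RegionalPool]:
    """Two regional pools with a controlled membership overlap fraction.

    ``overlap`` is the fraction of the smaller pool shared between soils;
    abundances (expected inoculum cell densities) are i.i.d. lognormal and
    drawn independently per pool, so shared taxa differ in abundance
    between soils. ``exclusive_rarity`` < 1 down-scales the abundance of
    pool-exclusive members (cosmopolitan taxa abundant, endemics rare), so
    dilution progressively erases the soil-of-origin signature.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be in [0, 1]")
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    n_shared = int(round(overlap * min(n_black, n_red)))
    needed = n_black + n_red - n_shared
    if needed > len(tips):
        raise ValueError(
            f"pools need {needed} distinct taxa but the tree has {len(tips)} tips"
        )
    rng = np.random.default_rng(seed)
    # soil-of-origin affinity evolves on the tree (early burst), so each
    # soil's endemics form clades rather than a random scatter of tips
    affinity = assign_ph_optima(
        tree, root_value=0.0, bm_rate=1.0, seed=int(rng.integers(2**31)), rate_decay=0.5
    )
    ranked = sorted(tips, key=lambda t: affinity[t], reverse=True)
    nb_only, nr_only = n_black - n_shared, n_red - n_shared
    only_black = ranked[:nb_only]
    only_red = ranked[len(ranked) - nr_only :] if nr_only else []
    middle = ranked[nb_only : len(ranked) - nr_only or None]
    shared_idx = rng.choice(len(middle), size=n_shared, replace=False)
    shared = [middle[i] for i in sorted(shared_idx)]

    if ph_optima is None:
        ph_optima = assign_ph_optima(tree, seed=seed + 1)

    shared_set = set(shared)

    def make(soil: str, members: list[str]) -> RegionalPool:
        abund = rng.lognormal(lognormal_mu, lognormal_sigma, size=len(members))
        scale = np.array([1.0 if t in shared_set else exclusive_rarity for t in members])
        return RegionalPool(
            soil_type=soil,
            taxon_abundance=dict(zip(members, abund * scale)),
            ph_optimum={t: ph_optima[t] for t in members},
            niche_breadth=niche_breadth,
        )

    return make("black", shared + only_black), make("red", shared + only_red)


def dilute_inoculum(
    pool: RegionalPool,
    lg_dil: int,
    inoculum_volume_factor: float = 1.0,
    seed: int = 0,
) -> dict[str, int]:
    """Poisson cell sampling of a 10^-lg_dil suspension.

    Each taxon's cell count is Poisson with mean
    abundance * 10^-lg_dil * volume_factor; taxa drawing zero cells are
    absent, so rarer taxa are lost first. An all-zero draw is a legitimate
    (empty) inoculum; callers decide how to handle it.
    """
    if lg_dil < 1:
        raise ValueError("lg_dil must be >= 1; untreated soils bypass dilution")
    if inoculum_volume_factor <= 0:
        raise ValueError("inoculum_volume_factor must be positive")
    rng = np.random.default_rng(seed)
    members = pool.members
    lam = np.array([pool.taxon_abundance[t] for t in members]) * 10.0 ** (-lg_dil)
    lam = lam * inoculum_volume_factor
    # Poisson draws overflow for huge means; those taxa are certainly present
    # and their exact cell count only matters proportionally
    draws = np.where(
        lam < 1e12,
        rng.poisson(np.minimum(lam, 1e12)),
        np.round(lam),
    )
    return {t: int(c) for t, c in zip(members, draws) if c > 0}


def incubate(
    inoculum: dict[str, float],
    ph_optima: dict[str, float],
    ph_level: float,
    selection_strength: float = 1.0,
    microsite_sd: float = 0.0,
    niche_breadth: float = 0.8,
    seed: int = 0,
) -> pd.Series:
    """Grow an inoculum to carrying capacity under pH-niche selection.

    The microcosm's effective pH is the target pH plus one Normal(0,
    microsite_sd) micro-environmental perturbation drawn per microcosm.
    Taxon fitness is a Gaussian pH kernel raised to ``selection_strength``;
    the final community is the fitness-weighted inoculum, normalized to
    relative abundances. ``selection_strength = 0`` reproduces the inoculum
    proportions exactly (neutral growth).
    """
    if not inoculum:
        raise ValueError("cannot incubate an empty inoculum")
    rng = np.random.default_rng(seed)
    ph_eff = ph_level + (rng.normal(0.0, microsite_sd) if microsite_sd > 0 else 0.0)
    taxa = list(inoculum)
    a = np.array([inoculum[t] for t in taxa], dtype=float)
    opt = np.array([ph_optima[t] for t in taxa])
    log_w = -((ph_eff - opt) ** 2) / (2.0 * niche_breadth**2) * selection_strength
    log_mass = np.log(a) + log_w
    log_mass -= log_mass.max()
    mass = np.exp(log_mass)
    return pd.Series(mass / mass.sum(), index=taxa)


def sample_reads(community: pd.Series, depth: int, seed: int = 0) -> pd.Series:
    """One multinomial sequencing draw of ``depth`` reads."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    p = community.to_numpy(dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("community abundances must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, p / p.sum())
    return pd.Series(counts, index=community.index)


def assign_gene_content(
    tree: dendropy.Tree,
    n_specialized: int = 5,
    n_broad: int = 5,
    specialized_clade_frac: float = 0.05,
    broad_taxon_frac: float = 0.3,
    genes_per_category: int = 30,
    seed: int = 0,
    specialized_copy_number: float = 5.0,
) -> tuple[FunctionalCatalog, pd.DataFrame]:
    """Build the gene catalog and the gene x taxon incidence matrix.

    Every specialized category's genes live on one monophyletic clade of
    roughly ``specialized_clade_frac`` of the tips (the closest-sized clade
    is used when no exact match exists); each carrier contributes
    ``specialized_copy_number`` distinct mappable variants per gene family
    (specialized pathways recruit more reads per carrier genome). Every broad gene is carried by an
    independent random sample of all tips, phylogenetically scattered, with
    a per-gene carrier fraction jittered around ``broad_taxon_frac`` (gene
    variants within a broad category differ in host range).
    """
    if not 0 < specialized_clade_frac < broad_taxon_frac <= 1:
        raise ValueError("need 0 < specialized_clade_frac < broad_taxon_frac <= 1")
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    tip_index = {t: i for i, t in enumerate(tips)}
    rng = np.random.default_rng(seed)
    target = max(2, int(round(specialized_clade_frac * len(tips))))
    clades = clades_by_size(tree)
    # candidate clades within 50% of the target size; widen to nearest sizes
    candidates = [c for size, c in clades if abs(size - target) <= max(1, target // 2)]
    if len(candidates) < n_specialized:
        ranked = sorted(clades, key=lambda sc: abs(sc[0] - target))
        candidates = [c for _, c in ranked[: max(n_specialized, len(candidates))]]
    picked = rng.choice(len(candidates), size=n_specialized, replace=len(candidates) < n_specialized)

    gene_to_category: dict[str, str] = {}
    category_to_fungp: dict[str, str] = {}
    rows = []
    gene_names = []
    for ci in range(n_specialized):
        cname = f"spec_{ci + 1:02d}"
        category_to_fungp[cname] = "FunGp1"
        clade = candidates[picked[ci]]
        row = np.zeros(len(tips))
        row[[tip_index[t] for t in clade]] = specialized_copy_number
        for gi in range(genes_per_category):
            gname = f"{cname}_g{gi + 1:03d}"
            gene_to_category[gname] = cname
            gene_names.append(gname)
            rows.append(row.copy())
    for ci in range(n_broad):
        cname = f"broad_{ci + 1:02d}"
        category_to_fungp[cname] = "FunGp2"
        for gi in range(genes_per_category):
            gname = f"{cname}_g{gi + 1:03d}"
            gene_to_category[gname] = cname
            gene_names.append(gname)
            # host-range heterogeneity shrinks toward the boundaries so that
            # broad_taxon_frac = 1 still means every taxon carries the gene
            jitter = 1.8 * broad_taxon_frac * (1.0 - broad_taxon_frac)
            frac = broad_taxon_frac + rng.uniform(-jitter, jitter)
            n_carriers = int(np.clip(round(frac * len(tips)), 1, len(tips)))
            row = np.zeros(len(tips))
            row[rng.choice(len(tips), size=n_carriers, replace=False)] = 1.0
            rows.append(row)

    catalog = FunctionalCatalog(gene_to_category, category_to_fungp)
    incidence = pd.DataFrame(np.array(rows), index=gene_names, columns=tips)
    return catalog, incidence


def synthesize_gene_table(
    otu_table: CommunityMatrix,
    incidence: pd.DataFrame,
    depth: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate metagenomic gene counts from taxon abundances.

    Per sample, a gene's expected read share is proportional to the summed
    relative abundance of its carrier taxa; counts are one multinomial draw
    of ``depth`` reads per sample.
    """
    missing = [t for t in otu_table.taxa if t not in incidence.columns]
    if missing:
        raise ValueError(f"taxa without gene incidence: {missing[:5]}")
    rel = otu_table.to_relative().table
    inc = incidence[rel.index].to_numpy(dtype=float)  # genes x taxa
    shares = inc @ rel.to_numpy()  # genes x samples
    rng = np.random.default_rng(seed)
    out = np.zeros_like(shares, dtype=np.int64)
    for j in range(shares.shape[1]):
        total = shares[:, j].sum()
        if total > 0:
            out[:, j] = rng.multinomial(depth, shares[:, j] / total)
    return pd.DataFrame(out, index=incidence.index, columns=rel.columns)


@dataclass
class ExperimentConfig:
    """All generator parameters of one synthetic experiment.

    Defaults reproduce the full factorial design: (5 pH x 4 dilutions x
    2 soils + 2 untreated) x 6 replicates = 252 microcosms, 2 sequenced
    subsamples each.
    """

    # design
    soils: tuple[str, ...] = ("black", "red")
    ph_levels: tuple[float, ...] = (4.5, 5.5, 6.5, 7.5, 8.5)
    dilutions: tuple[int, ...] = (1, 4, 7, 10)
    replicates: int = 6
    subsamples: int = 2
    include_untreated: bool = True
    source_ph: dict = field(default_factory=lambda: {"black": 8.0, "red": 5.3})
    # phylogeny & pools
    n_taxa: int = 2000
    birth_rate: float = 1.0
    ph_root: float = 6.5
    bm_rate: float = 3.6
    # early-burst trait decay: niche guilds coincide with deep clades
    trait_rate_decay: float = 0.6
    n_black: int = 1200
    n_red: int = 1200
    overlap: float = 0.5
    pool_exclusive_rarity: float = 0.05
    lognormal_mu: float = 17.8
    lognormal_sigma: float = 5.0
    inoculum_volume_factor: float = 100.0
    # 16 weeks of regrowth to carrying capacity largely erases initial
    # cell-count differences among survivors: final abundance enters the
    # selection step as inoculum**growth_compression
    growth_compression: float = 0.15
    # demographic stochasticity / founder effects during regrowth: one
    # lognormal factor exp(N(0, growth_noise_sd)) per taxon per microcosm
    growth_noise_sd: float = 0.8
    # selection
    niche_breadth: float = 0.5
    selection_strength: float = 6.0
    # regrowth from a 10^-d inoculum takes ~d more generations, and fitness
    # compounds per generation: the effective selection exponent is
    # selection_strength * (base + (1-base) * lg_dil / 10)
    selection_dilution_base: float = 0.02
    selection_dilution_power: float = 1.5
    microsite_sd_neutral: float = 0.45
    microsite_sd_extreme: float = 0.05
    ph_center: float = 6.5
    ph_window: float = 1.0
    variable_sd_threshold: float = 0.3
    # sequencing
    otu_depth: int = 12000
    gene_depth: int = 10000
    # genes
    n_specialized: int = 5
    n_broad: int = 5
    specialized_clade_frac: float = 0.05
    broad_taxon_frac: float = 0.3
    genes_per_category: int = 30
    specialized_copy_number: float = 5.0
    specialized_rarity: float = 0.02
    # master seed
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_taxa < 2:
            problems.append("n_taxa must be >= 2")
        if not self.soils:
            problems.append("soils must be non-empty")
        if self.replicates < 1:
            problems.append("replicates must be >= 1")
        if self.subsamples < 1:
            problems.append("subsamples must be >= 1")
        if any(d < 1 for d in self.dilutions):
            problems.append("dilutions must be >= 1 (0 is reserved for untreated)")
        if not 0 <= self.overlap <= 1:
            problems.append("overlap must be in [0, 1]")
        if self.include_untreated and any(s not in self.source_ph for s in self.soils):
            problems.append("source_ph must cover every soil when untreated included")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    @property
    def n_microcosms(self) -> int:
        n_untreated = len(self.soils) if self.include_untreated else 0
        return (
            len(self.ph_levels) * len(self.dilutions) * len(self.soils) + n_untreated
        ) * self.replicates

    @property
    def n_samples(self) -> int:
        return self.n_microcosms * self.subsamples

    def effective_selection(self, lg_dil: int) -> float:
        """Selection exponent after regrowth from a 10^-lg_dil inoculum."""
        base = self.selection_dilution_base
        ramp = (lg_dil / 10.0) ** self.selection_dilution_power
        return self.selection_strength * (base + (1.0 - base) * ramp)

    def microsite_sd(self, ph: float) -> float:
        """Micro-environmental pH heterogeneity as a function of target pH.

        Large near neutral pH (variable-selection regime) and near zero at
        the extremes (homogeneous-selection regime): a Gaussian bump of
        width ``ph_window`` centered on ``ph_center``.
        """
        bump = np.exp(-((ph - self.ph_center) ** 2) / (2.0 * self.ph_window**2))
        return float(
            self.microsite_sd_extreme
            + (self.microsite_sd_neutral - self.microsite_sd_extreme) * bump
        )

    def regime(self, ph: float) -> str:
        if self.selection_strength == 0:
            return NEUTRAL
        return VARIABLE if self.microsite_sd(ph) >= self.variable_sd_threshold else HOMOGENEOUS

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for section in ("design", "pools", "selection", "sequencing", "genes"):
            flat.update(raw.pop(section, {}) or {})
        flat.update(raw)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("soils", "ph_levels", "dilutions"):
            if key in flat:
                flat[key] = tuple(flat[key])
        return cls(**flat)


def _covariates(ph: float, rng: np.random.Generator) -> dict[str, float]:
    """Ca/Fe/SO4 concentrations implied by the pH amendment, plus noise.

    CaO raises pH (Ca tracks the target pH), FeSO4 lowers it (Fe and SO4
    track its inverse); arbitrary concentration units on [0, ~1].
    """
    ca = 0.2 + 0.8 * (ph - 4.5) / 4.0 + rng.normal(0, 0.03)
    fe = 0.2 + 0.8 * (8.5 - ph) / 4.0 + rng.normal(0, 0.03)
    so4 = 0.9 * fe + rng.normal(0, 0.03)
    return {"Ca": float(ca), "Fe": float(fe), "SO4": float(so4)}


def enumerate_design(config: ExperimentConfig) -> list[dict]:
    """The microcosm-level factorial design (before subsampling)."""
    cells = []
    for soil in config.soils:
        for ph in config.ph_levels:
            for dil in config.dilutions:
                for rep in range(1, config.replicates + 1):
                    cells.append(
                        {"soil": soil, "ph": float(ph), "lg_dil": int(dil), "replicate": rep}
                    )
        if config.include_untreated:
            for rep in range(1, config.replicates + 1):
                cells.append(
                    {
                        "soil": soil,
                        "ph": float(config.source_ph[soil]),
                        "lg_dil": 0,
                        "replicate": rep,
                    }
                )
    return cells


def generate_experiment(config: ExperimentConfig) -> SyntheticExperiment:
    """Simulate a complete microcosm experiment per the config.

    Pipeline per microcosm: dilute the soil's regional pool (untreated
    controls use the pool directly), incubate under the pH regime, then draw
    ``subsamples`` independent read profiles. Gene tables follow from the
    carrier incidence of the catalog. Deterministic given ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seed_tree, seed_traits, seed_pools, seed_genes, seed_cov, seed_cells = ss.spawn(6)

    tree = build_phylogeny(
        config.n_taxa, config.birth_rate, seed=int(seed_tree.generate_state(1)[0] % 2**31)
    )
    ph_optima = assign_ph_optima(
        tree,
        root_value=config.ph_root,
        bm_rate=config.bm_rate,
        seed=int(seed_traits.generate_state(1)[0] % 2**31),
        rate_decay=config.trait_rate_decay,
    )
    black, red = build_regional_pools(
        tree,
        config.n_black,
        config.n_red,
        config.overlap,
        config.lognormal_mu,
        config.lognormal_sigma,
        seed=int(seed_pools.generate_state(1)[0] % 2**31),
        ph_optima=ph_optima,
        niche_breadth=config.niche_breadth,
        exclusive_rarity=config.pool_exclusive_rarity,
    )
    pools = {"black": black, "red": red}
    catalog, incidence = assign_gene_content(
        tree,
        config.n_specialized,
        config.n_broad,
        config.specialized_clade_frac,
        config.broad_taxon_frac,
        config.genes_per_category,
        seed=int(seed_genes.generate_state(1)[0] % 2**31),
        specialized_copy_number=config.specialized_copy_number,
    )
    # specialized functions live in the rare tail: down-scale the inoculum
    # abundance of every specialized clade's members
    specialized_taxa = set()
    for cname, fungp in catalog.category_to_fungp.items():
        if fungp == "FunGp1":
            genes = catalog.genes_in(cname)
            carriers = incidence.loc[genes[0]]
            specialized_taxa.update(carriers.index[carriers > 0])
    for pool in pools.values():
        for t in pool.taxon_abundance:
            if t in specialized_taxa:
                pool.taxon_abundance[t] *= config.specialized_rarity

    cells = enumerate_design(config)
    cell_seeds = seed_cells.spawn(len(cells))
    cov_rng = np.random.default_rng(seed_cov.generate_state(1)[0] % 2**31)

    design: list[SampleDesign] = []
    columns: dict[str, pd.Series] = {}
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    for cell, cell_ss in zip(cells, cell_seeds):
        soil, ph, dil, rep = cell["soil"], cell["ph"], cell["lg_dil"], cell["replicate"]
        pool = pools[soil]
        sub_seeds = cell_ss.spawn(3 + config.subsamples)
        s_dil = int(sub_seeds[0].generate_state(1)[0] % 2**31)
        s_inc = int(sub_seeds[1].generate_state(1)[0] % 2**31)
        s_noise = int(sub_seeds[2].generate_state(1)[0] % 2**31)
        if dil == 0:
            inoculum = {t: a for t, a in pool.taxon_abundance.items()}
        else:
            inoculum = dilute_inoculum(
                pool, dil, config.inoculum_volume_factor, seed=s_dil
            )
            attempt = 1
            while not inoculum and attempt <= 10:  # empty inocula are re-drawn
                inoculum = dilute_inoculum(
                    pool, dil, config.inoculum_volume_factor, seed=s_dil + attempt
                )
                attempt += 1
            if not inoculum:
                raise RuntimeError(
                    f"persistent empty inoculum for {soil} pH {ph} dilution {dil}"
                )
        noise_rng = np.random.default_rng(s_noise)
        noise = np.exp(noise_rng.normal(0.0, config.growth_noise_sd, size=len(inoculum)))
        regrown = {
            t: float(c) ** config.growth_compression * n
            for (t, c), n in zip(inoculum.items(), noise)
        }
        community = incubate(
            regrown,
            pool.ph_optimum,
            ph,
            selection_strength=config.effective_selection(dil),
            microsite_sd=config.microsite_sd(ph) if dil > 0 else config.microsite_sd_extreme,
            niche_breadth=config.niche_breadth,
            seed=s_inc,
        )
        covs = _covariates(ph, cov_rng)
        for sub in range(1, config.subsamples + 1):
            s_reads = int(sub_seeds[2 + sub].generate_state(1)[0] % 2**31)
            reads = sample_reads(community, config.otu_depth, seed=s_reads)
            sid = f"{soil[0].upper()}_pH{ph:g}_D{dil}_R{rep}_S{sub}"
            columns[sid] = reads
            design.append(
                SampleDesign(
                    sample_id=sid,
                    soil_type=soil,
                    ph_level=ph,
                    lg_dil=dil,
                    replicate=rep,
                    subsample=sub,
                    covariates=covs,
                )
            )

    otu = pd.DataFrame(0, index=tips, columns=list(columns), dtype=np.int64)
    for sid, reads in columns.items():
        otu.loc[reads.index, sid] = reads.to_numpy()
    otu_table = CommunityMatrix(otu, mode="counts")

    gene_seed = int(seed_genes.generate_state(2)[1] % 2**31)
    gene_table = synthesize_gene_table(otu_table, incidence, config.gene_depth, seed=gene_seed)

    truth = (
        pd.DataFrame(
            [
                {
                    "soil": c["soil"],
                    "pH": c["ph"],
                    "lg_dil": c["lg_dil"],
                    "regime": config.regime(c["ph"]),
                }
                for c in cells
            ]
        )
        .drop_duplicates(["soil", "pH", "lg_dil"])
        .reset_index(drop=True)
    )

    return SyntheticExperiment(
        tree=tree,
        design=design,
        otu_table=otu_table,
        gene_table=gene_table,
        catalog=catalog,
        truth=truth,
    )
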