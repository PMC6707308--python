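"""Generator unit tests: phylogeny, traits, pools, dilution, growth, genes, design."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from dilasm.containers import RegionalPool
from dilasm.synthetic import (
    ExperimentConfig,
    assign_gene_content,
    build_phylogeny,
    build_regional_pools,
    dilute_inoculum,
    generate_experiment,
    incubate,
    sample_reads,
    synthesize_gene_table,
)
from dilasm.trees import assign_ph_optima, patristic_distances, tip_depths, write_newick


class TestBuildPhylogeny:
    def test_smallest_tree(self):
        tree = build_phylogeny(2, 1.0, seed=1)
        tips = list(tree.leaf_node_iter())
        assert len(tips) == 2
        depths = list(tip_depths(tree).values())
        assert depths[0] == pytest.approx(depths[1], abs=1e-9)

    def test_deterministic_newick(self):
        a = write_newick(build_phylogeny(100, 1.0, seed=7))
        b = write_newick(build_phylogeny(100, 1.0, seed=7))
        assert a == b
        c = write_newick(build_phylogeny(100, 1.0, seed=8))
        assert a != c

    def test_ultrametric_by_traversal(self):
        tree = build_phylogeny(50, 1.0, seed=3)
        depths = np.array(list(tip_depths(tree).values()))
        assert np.sum(depths) == pytest.approx(50 * depths[0], abs=1e-6)

    def test_tip_labels_unique_and_padded(self):
        tree = build_phylogeny(12, 2.0, seed=0)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        assert len(set(labels)) == 12
        assert all(lab.startswith("OTU_") for lab in labels)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            build_phylogeny(1, 1.0, seed=0)


class TestPhOptima:
    def test_zero_rate_collapses_to_root(self, toy_tree):
        opt = assign_ph_optima(toy_tree, root_value=6.5, bm_rate=0.0, seed=1)
        assert all(v == 6.5 for v in opt.values())

    def test_deterministic(self, toy_tree):
        a = assign_ph_optima(toy_tree, 6.5, 0.5, seed=9)
        b = assign_ph_optima(toy_tree, 6.5, 0.5, seed=9)
        assert a == b

    def test_brownian_variance_scales_with_patristic_distance(self, toy_tree):
        # A and B are at patristic distance 2: Var(opt_A - opt_B) = 2 * rate
        rate = 0.7
        diffs = []
        for seed in range(1000):
            opt = assign_ph_optima(toy_tree, 6.5, rate, seed=seed)
            diffs.append(opt["A"] - opt["B"])
        assert np.var(diffs) == pytest.approx(2 * rate, rel=0.10)


class TestRegionalPools:
    @pytest.fixture(scope="class")
    def tree(self):
        return build_phylogeny(320, 1.0, seed=4)

    def test_full_overlap(self, tree):
        b, r = build_regional_pools(tree, 150, 150, overlap=1.0, seed=1)
        assert set(b.members) == set(r.members)

    def test_disjoint(self, tree):
        b, r = build_regional_pools(tree, 100, 100, overlap=0.0, seed=1)
        assert not set(b.members) & set(r.members)

    def test_half_overlap_count(self, tree):
        b, r = build_regional_pools(tree, 200, 200, overlap=0.5, seed=5)
        shared = set(b.members) & set(r.members)
        assert abs(len(shared) - 100) <= 1

    def test_pool_too_large(self, tree):
        with pytest.raises(ValueError):
            build_regional_pools(tree, 300, 300, overlap=0.0, seed=1)

    def test_exclusive_rarity_scaling(self, tree):
        b, r = build_regional_pools(tree, 150, 150, overlap=0.5, seed=2, exclusive_rarity=1e-6)
        shared = set(b.members) & set(r.members)
        excl = [t for t in b.members if t not in shared]
        med_shared = np.median([b.taxon_abundance[t] for t in shared])
        med_excl = np.median([b.taxon_abundance[t] for t in excl])
        assert med_excl < med_shared * 1e-3


def _single_taxon_pool(abundance: float) -> RegionalPool:
    return RegionalPool("red", {"OTU_1": abundance}, {"OTU_1": 6.5}, 0.8)


class TestDilution:
    def test_poisson_presence_probability(self):
        # mean 1e10 at lg_dil 10 -> Poisson(1): present with prob 1 - exp(-1)
        pool = _single_taxon_pool(1e10)
        present = [bool(dilute_inoculum(pool, 10, 1.0, seed=s)) for s in range(2000)]
        assert np.mean(present) == pytest.approx(1 - np.exp(-1), abs=0.02)

    def test_extinction_limit_gives_empty(self):
        pool = _single_taxon_pool(1.0)
        assert dilute_inoculum(pool, 10, 1.0, seed=0) == {}

    def test_richness_nonincreasing_in_dilution(self):
        rng = np.random.default_rng(0)
        abund = {f"t{i}": a for i, a in enumerate(rng.lognormal(8, 3, 150))}
        pool = RegionalPool("red", abund, {k: 6.5 for k in abund}, 0.8)
        mean_rich = []
        for dil in (1, 4, 7, 10):
            rich = [len(dilute_inoculum(pool, dil, 1.0, seed=s)) for s in range(200)]
            mean_rich.append(np.mean(rich))
        assert all(a > b for a, b in zip(mean_rich, mean_rich[1:]))

    def test_invalid_args(self):
        pool = _single_taxon_pool(10.0)
        with pytest.raises(ValueError):
            dilute_inoculum(pool, 0, 1.0, seed=0)
        with pytest.raises(ValueError):
            dilute_inoculum(pool, 4, -1.0, seed=0)


class TestIncubate:
    def test_neutral_growth_preserves_proportions(self):
        inoc = {"a": 3.0, "b": 1.0}
        out = incubate(inoc, {"a": 4.0, "b": 9.0}, ph_level=7.0, selection_strength=0.0, seed=1)
        assert out["a"] == pytest.approx(0.75)
        assert out["b"] == pytest.approx(0.25)

    def test_single_taxon_normalization(self):
        out = incubate({"a": 5.0}, {"a": 4.0}, ph_level=8.0, selection_strength=3.0, seed=1)
        assert out["a"] == pytest.approx(1.0)

    def test_gaussian_kernel_ratio(self):
        # equal inocula, optima 5 and 8 at pH 5 with sigma 1: ratio exp(0)/exp(-4.5)
        out = incubate(
            {"a": 1.0, "b": 1.0}, {"a": 5.0, "b": 8.0},
            ph_level=5.0, selection_strength=1.0, microsite_sd=0.0, niche_breadth=1.0, seed=1,
        )
        assert out["a"] / out["b"] == pytest.approx(np.exp(4.5), rel=1e-9)

    def test_empty_inoculum_errors(self):
        with pytest.raises(ValueError):
            incubate({}, {}, ph_level=7.0)


class TestSampleReads:
    def test_single_taxon(self):
        out = sample_reads(pd.Series({"a": 1.0}), depth=500, seed=1)
        assert out["a"] == 500

    def test_uniform_counts_within_3sd(self):
        p = pd.Series(0.25, index=list("abcd"))
        out = sample_reads(p, depth=10**6, seed=2)
        sd = np.sqrt(10**6 * 0.25 * 0.75)
        assert (np.abs(out - 250000) < 3 * sd).all()

    def test_deterministic(self):
        p = pd.Series([0.5, 0.3, 0.2], index=list("abc"))
        assert sample_reads(p, 1000, seed=3).equals(sample_reads(p, 1000, seed=3))

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            sample_reads(pd.Series([0.5, 0.3], index=list("ab")), 100, seed=0)


class TestGeneContent:
    @pytest.fixture(scope="class")
    def tree(self):
        return build_phylogeny(120, 1.0, seed=6)

    def test_bookkeeping(self, tree):
        cat, inc = assign_gene_content(tree, 3, 4, 0.08, 0.4, genes_per_category=5, seed=1)
        assert len(cat.categories) == 7
        assert len(cat.gene_to_category) == 35
        assert inc.shape == (35, 120)
        assert set(cat.category_to_fungp.values()) == {"FunGp1", "FunGp2"}

    def test_specialized_carriers_are_monophyletic(self, tree):
        cat, inc = assign_gene_content(tree, 3, 2, 0.08, 0.4, genes_per_category=3, seed=2)
        taxon_ns = tree.taxon_namespace
        for cname, fungp in cat.category_to_fungp.items():
            if fungp != "FunGp1":
                continue
            carriers = set(inc.columns[inc.loc[cat.genes_in(cname)[0]] > 0])
            mrca = tree.mrca(taxa=[t for t in taxon_ns if t.label in carriers])
            clade_tips = {leaf.taxon.label for leaf in mrca.leaf_iter()}
            assert clade_tips == carriers

    def test_broad_frac_one_covers_all_taxa(self, tree):
        cat, inc = assign_gene_content(tree, 1, 2, 0.08, 1.0, genes_per_category=4, seed=3)
        broad_genes = [g for g, c in cat.gene_to_category.items() if c.startswith("broad")]
        assert (inc.loc[broad_genes] > 0).all(axis=None)

    def test_invalid_fracs(self, tree):
        with pytest.raises(ValueError):
            assign_gene_content(tree, 1, 1, 0.5, 0.3, genes_per_category=2, seed=0)


class TestGeneTable:
    def test_expected_shares_and_absent_carriers(self, toy_tree):
        from dilasm.containers import CommunityMatrix

        otu = CommunityMatrix(
            pd.DataFrame({"s1": [10, 10, 0], "s2": [0, 0, 20]}, index=["A", "B", "C"])
        )
        inc = pd.DataFrame(
            {"A": [True, False], "B": [True, False], "C": [False, True]},
            index=["g_all_ab", "g_only_c"],
        )
        g = synthesize_gene_table(otu, inc, depth=1000, seed=1)
        # s1 has no C: gene carried only by C gets zero reads with certainty
        assert g.loc["g_only_c", "s1"] == 0
        assert g.loc["g_all_ab", "s1"] == 1000
        assert g.loc["g_only_c", "s2"] == 1000


class TestDesignEnumeration:
    def test_paper_shaped_design(self):
        cfg = ExperimentConfig()
        assert cfg.n_microcosms == 252
        assert cfg.n_samples == 504

    def test_single_cell_design(self):
        cfg = ExperimentConfig(
            soils=("red",), ph_levels=(6.5,), dilutions=(4,), replicates=1,
            subsamples=1, include_untreated=False,
        )
        assert cfg.n_microcosms == 1

    def test_config_validation_lists_problems(self):
        cfg = ExperimentConfig(replicates=0, dilutions=(0, 4))
        with pytest.raises(ValueError, match="replicates"):
            cfg.validate()

    def test_generate_experiment_reproducible(self):
        cfg = ExperimentConfig(
            soils=("red",), ph_levels=(5.5, 7.5), dilutions=(1, 7), replicates=2,
            subsamples=2, n_taxa=80, n_black=10, n_red=60, overlap=0.0,
            otu_depth=500, gene_depth=500, genes_per_category=4, seed=42,
        )
        e1 = generate_experiment(cfg)
        e2 = generate_experiment(cfg)
        assert e1.otu_table.table.equals(e2.otu_table.table)
        assert e1.gene_table.equals(e2.gene_table)
        assert len(e1.design) == cfg.n_samples
        assert list(e1.otu_table.samples) == list(e1.gene_table.columns)

    def test_truth_labels_cover_every_cell(self):
        cfg = ExperimentConfig(
            soils=("red",), ph_levels=(4.5, 6.5), dilutions=(1,), replicates=1,
            subsamples=1, n_taxa=60, n_black=5, n_red=40, overlap=0.0,
            otu_depth=300, gene_depth=300, genes_per_category=2, seed=1,
        )
        exp = generate_experiment(cfg)
        cells = {(s.soil_type, s.ph_level, s.lg_dil) for s in exp.design}
        truth_cells = set(map(tuple, exp.truth[["soil", "pH", "lg_dil"]].to_numpy()))
        assert cells <= truth_cells
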