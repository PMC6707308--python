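"""Phylogeny construction and tree arithmetic.

Trees are :class:`dendropy.Tree` objects throughout the package. This module
supplies the pure-birth simulator used by the synthetic world, Brownian-motion
trait evolution, and the numeric structures (patristic matrix, branch
incidence) that the diversity and null-model stages consume.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "build_phylogeny",
    "assign_ph_optima",
    "patristic_distances",
    "branch_structure",
    "tip_depths",
    "clades_by_size",
    "parse_newick",
    "write_newick",
]


def build_phylogeny(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Simulate an ultrametric pure-birth (Yule) tree with ``n_taxa`` tips.

    Lineages split at rate ``birth_rate`` each; after the last split every
    extant lineage is extended to the present, so all root-to-tip depths are
    equal. Tips are labeled ``OTU_0001`` .. in left-to-right order.
    Deterministic given ``seed``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    birth_time = {root: 0.0}
    # the stem lineage splits immediately: root has two children at t=0
    active = []
    for _ in range(2):
        child = root.new_child()
        birth_time[child] = 0.0
        active.append(child)

    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(rng.integers(k))
        node.edge.length = t - birth_time[node]
        for _ in range(2):
            child = node.new_child()
            birth_time[child] = t
            active.append(child)
    t += rng.exponential(1.0 / (n_taxa * birth_rate))
    for node in active:
        node.edge.length = t - birth_time[node]
    root.edge.length = None

    width = max(4, len(str(n_taxa)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        taxon = taxon_ns.new_taxon(f"OTU_{i:0{width}d}")
        leaf.taxon = taxon
    return tree


def assign_ph_optima(
    tree: dendropy.Tree,
    root_value: float = 6.5,
    bm_rate: float = 0.5,
    seed: int = 0,
    rate_decay: float = 0.0,
) -> dict[str, float]:
    """Evolve a pH optimum along the tree by Brownian motion.

    Each branch adds an independent Normal(0, bm_rate * branch_length)
    increment, so the variance of the difference between two tips equals
    ``bm_rate`` times their patristic distance.

    With ``rate_decay`` r > 0 the instantaneous rate becomes
    bm_rate * exp(-r * t) at time t since the root (an early-burst model):
    trait divergence concentrates on deep branches, so niche guilds
    coincide with clades. The default r = 0 is time-homogeneous Brownian
    motion.
    """
    if bm_rate < 0:
        raise ValueError("bm_rate must be non-negative")
    if rate_decay < 0:
        raise ValueError("rate_decay must be non-negative")
    rng = np.random.default_rng(seed)
    depth = {tree.seed_node: 0.0}
    value = {tree.seed_node: float(root_value)}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        t0 = depth[node.parent_node]
        depth[node] = t0 + bl
        if rate_decay == 0.0:
            var = bm_rate * bl
        else:
            # integral of bm_rate * exp(-r t) over the branch
            var = bm_rate / rate_decay * (
                np.exp(-rate_decay * t0) - np.exp(-rate_decay * depth[node])
            )
        value[node] = value[node.parent_node] + rng.normal(0.0, np.sqrt(var))
        if node.is_leaf():
            out[node.taxon.label] = value[node]
    return out


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length per tip label."""
    depth = {tree.seed_node: 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            out[node.taxon.label] = depth[node]
    return out


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """All pairwise tip-to-tip path-length sums.

    Computed in one post-order sweep: for each internal node, pairs of tips
    first united there are at distance depth_i + depth_j - 2 * depth(node).
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(tips) < 2:
        raise ValueError("tree must have >= 2 tips")
    idx = {label: i for i, label in enumerate(tips)}
    depth_node = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth_node[node] = depth_node[node.parent_node] + (node.edge.length or 0.0)

    n = len(tips)
    d = np.zeros((n, n))
    depths = np.zeros(n)
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            depths[i] = depth_node[node]
            tipsets[node] = np.array([i])
        else:
            child_sets = [tipsets.pop(c) for c in node.child_nodes()]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    ii = child_sets[a]
                    jj = child_sets[b]
                    dij = depths[ii][:, None] + depths[jj][None, :] - 2.0 * depth_node[node]
                    d[np.ix_(ii, jj)] = dij
                    d[np.ix_(jj, ii)] = dij.T
            tipsets[node] = np.concatenate(child_sets)
    return pd.DataFrame(d, index=tips, columns=tips)


def branch_structure(tree: dendropy.Tree) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Branch lengths and branch x tip descendant incidence.

    Returns ``(lengths, incidence, tips)`` where ``incidence[b, i]`` is 1 if
    tip ``i`` descends from branch ``b``. The root edge is excluded. Used to
    vectorize weighted UniFrac over all sample pairs at once.
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    idx = {label: i for i, label in enumerate(tips)}
    lengths = []
    rows = []
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [idx[node.taxon.label]]
        else:
            merged: list[int] = []
            for c in node.child_nodes():
                merged.extend(tipsets[c])
            tipsets[node] = merged
        if node is tree.seed_node or node.edge.length is None:
            continue
        lengths.append(node.edge.length)
        row = np.zeros(len(tips))
        row[tipsets[node]] = 1.0
        rows.append(row)
    return np.asarray(lengths), np.asarray(rows), tips


def clades_by_size(tree: dendropy.Tree) -> list[tuple[int, list[str]]]:
    """All monophyletic tip sets (proper clades), as (size, labels) pairs."""
    out = []
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [node.taxon.label]
        else:
            merged: list[str] = []
            for c in node.child_nodes():
                merged.extend(tipsets[c])
            tipsets[node] = merged
            if node is not tree.seed_node:
                out.append((len(merged), merged))
    return out


def parse_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string or file path into a rooted tree."""
    if "(" in source:
        data = source
    else:
        with open(source) as fh:
            data = fh.read()
    tree = dendropy.Tree.get(data=data, schema="newick", rooting="force-rooted")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    buf = io.StringIO()
    tree.write(file=buf, schema="newick", suppress_rooting=True)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
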