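"""Community phylogenetic structure: ultrametric forcing, random grafting
of species below genus tips, cophenetic distances, MPD, and its
variance-standardized effect size against a richness-matched random null.

Negative SES values indicate phylogenetic clustering (less pairwise
evolutionary distance than random equal-richness communities); positive
values indicate evenness/overdispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "force_ultrametric",
    "graft_species",
    "cophenetic",
    "mpd",
    "ses_mpd",
    "SESResult",
]


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def force_ultrametric(tree: dendropy.Tree) -> dendropy.Tree:
    """Return a copy with every tip extended to the maximum tip depth.

    Terminal-edge extension: topology and internal branch lengths are
    unchanged; each terminal edge grows by (max depth - tip depth).
    Idempotent on already-ultrametric trees.
    """
    out = tree.clone(depth=1)
    depths = _node_depths(out)
    leaves = [n for n in out.leaf_node_iter()]
    max_depth = max(depths[n] for n in leaves)
    for leaf in leaves:
        extra = max_depth - depths[leaf]
        new_len = (leaf.edge.length or 0.0) + extra
        if new_len < 0:
            raise ValueError(f"negative branch length produced at {leaf}")
        leaf.edge.length = new_len
    return out


def _random_coalescent_subtree(
    species: Sequence[str],
    attach_height: float,
    taxa: dendropy.TaxonNamespace,
    rng: np.random.Generator,
) -> dendropy.Node:
    """Random bifurcating ultrametric subtree over ``species`` with its
    root at ``attach_height`` above the tips: successive random pairwise
    joins at sorted uniform(0, attach_height) heights, final join at the
    attachment height."""
    nodes = []
    heights = {}
    for sp in species:
        nd = dendropy.Node(taxon=taxa.new_taxon(sp))
        heights[id(nd)] = 0.0
        nodes.append(nd)
    n = len(nodes)
    inner = np.sort(rng.uniform(0.0, attach_height, size=n - 2)) if n > 2 else np.array([])
    join_heights = np.append(inner, attach_height)
    for h in join_heights:
        k = len(nodes)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        heights[id(parent)] = float(h)
        for child in (left, right):
            parent.add_child(child)
            child.edge.length = float(h) - heights[id(child)]
        nodes.append(parent)
    return nodes[0]


def graft_species(
    genus_tree: dendropy.Tree,
    species_by_genus: Mapping[str, Sequence[str]],
    rng: np.random.Generator,
) -> dendropy.Tree:
    """Expand genus tips into random bifurcating species subtrees.

    Each genus tip with assigned species is replaced by a random
    coalescent subtree of those species, bound at a uniform random point
    along the genus terminal edge; ultrametricity is preserved. Genus
    tips with no assigned species are kept unchanged. Genera in the
    mapping but absent from the tree are dropped with a warning (their
    species do not appear in the output).
    """
    tree = genus_tree.clone(depth=1)
    # detach from the caller's taxon namespace: relabeling/grafting must not
    # mutate the input tree's shared Taxon objects
    taxa = dendropy.TaxonNamespace()
    tree.taxon_namespace = taxa
    for leaf in tree.leaf_node_iter():
        leaf.taxon = taxa.new_taxon(leaf.taxon.label)
    tip_by_label = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}

    missing = sorted(set(species_by_genus) - set(tip_by_label))
    if missing:
        warnings.warn(
            f"genera not in tree, their species dropped: {missing}",
            stacklevel=2,
        )

    for genus, species in species_by_genus.items():
        species = list(species)
        leaf = tip_by_label.get(genus)
        if leaf is None or not species:
            continue
        if len(species) == 1:
            leaf.taxon.label = species[0]
            continue
        term_len = leaf.edge.length
        if term_len is None or term_len <= 0:
            raise ValueError(f"genus tip {genus!r} has no positive terminal edge")
        attach = float(rng.uniform(0.0, term_len))
        parent = leaf.parent_node
        sub_root = _random_coalescent_subtree(species, attach, taxa, rng)
        parent.remove_child(leaf)
        parent.add_child(sub_root)
        sub_root.edge.length = term_len - attach
    tree.update_taxon_namespace()
    tree.purge_taxon_namespace()
    return tree


def cophenetic(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip-to-tip patristic distance matrix (sum of branch lengths along
    the connecting path), as a labeled symmetric DataFrame.

    Computed as depth_i + depth_j - 2 * depth(MRCA(i, j)) with MRCA depths
    filled in one postorder sweep.
    """
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = sorted(leaf.taxon.label for leaf in leaves)
    index = {lab: i for i, lab in enumerate(labels)}
    if len(index) != len(leaves):
        raise ValueError("duplicate tip labels")
    n = len(labels)
    tip_depth = np.zeros(n)
    for leaf in leaves:
        tip_depth[index[leaf.taxon.label]] = depths[leaf]

    mrca_depth = np.zeros((n, n))
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = np.array([index[node.taxon.label]])
            continue
        child_sets = [below.pop(id(c)) for c in node.child_nodes()]
        d = depths[node]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                mrca_depth[np.ix_(child_sets[a], child_sets[b])] = d
        below[id(node)] = np.concatenate(child_sets)

    mrca_depth = mrca_depth + mrca_depth.T
    dist = tip_depth[:, None] + tip_depth[None, :] - 2.0 * mrca_depth
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=labels, columns=labels)


def mpd(community: Iterable[str], dist: pd.DataFrame) -> float:
    """Mean pairwise patristic distance among the species present
    (presence-based, unweighted). NaN for communities of < 2 species."""
    taxa = sorted(set(community))
    unknown = [t for t in taxa if t not in dist.index]
    if unknown:
        raise KeyError(f"species not in distance matrix: {unknown}")
    k = len(taxa)
    if k < 2:
        return float("nan")
    sub = dist.loc[taxa, taxa].to_numpy()
    return float(sub.sum() / (k * (k - 1)))


@dataclass
class SESResult:
    """Standardized effect size of MPD against a richness-matched null."""

    mpd_obs: float
    null_mean: float
    null_sd: float
    ses: float
    n_null: int
    degenerate_null: bool = False


def ses_mpd(
    community: Iterable[str],
    dist: pd.DataFrame,
    pool: Sequence[str] | None = None,
    n_null: int = 999,
    rng: np.random.Generator | None = None,
) -> SESResult:
    """SES-MPD: (observed MPD - null mean) / null SD.

    The null draws uniform random subsets of ``pool`` (default: all
    species in ``dist``) with the same richness as the community.
    When the null SD is zero (e.g. the community is the entire pool of
    that size with no variation) the SES is reported as 0 with
    ``degenerate_null=True``.
    """
    rng = rng or np.random.default_rng()
    taxa = sorted(set(community))
    k = len(taxa)
    if k < 2:
        return SESResult(float("nan"), float("nan"), float("nan"),
                         float("nan"), n_null, True)
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    pool = list(pool) if pool is not None else list(dist.index)
    if not set(taxa) <= set(pool):
        raise ValueError("community is not a subset of the species pool")

    obs = mpd(taxa, dist)
    dpool = dist.loc[pool, pool].to_numpy()
    p = len(pool)
    # vectorized richness-matched random subsets
    idx = np.argsort(rng.random((n_null, p)), axis=1)[:, :k]
    sub = dpool[idx[:, :, None], idx[:, None, :]]  # (n_null, k, k)
    null_vals = sub.sum(axis=(1, 2)) / (k * (k - 1))
    null_mean = float(null_vals.mean())
    null_sd = float(null_vals.std(ddof=1))
    if null_sd <= 1e-12 * max(abs(null_mean), 1.0):
        return SESResult(obs, null_mean, null_sd, 0.0, n_null, True)
    return SESResult(obs, null_mean, null_sd,
                     (obs - null_mean) / null_sd, n_null, False)
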