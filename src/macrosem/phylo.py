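"""Tip-level phylogenetic metrics on time-calibrated trees.

Implements the equal-splits measure and its reciprocal, the DR tip
speciation-rate statistic (which up-weights recent branching), pendant-edge
tip ages as the evolutionary-time proxy, stochastic grafting of missing taxa
into named clades, and aggregation of metrics over tree replicates and over
the species present in each grid cell.

Trees are handled as :class:`dendropy.Tree` objects with branch lengths in
Myr.  Zero-length edges are rejected at parse time; polytomies are allowed
(the halving rule of the equal-splits sum is applied per split regardless of
its degree).
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_trees",
    "equal_splits",
    "dr_metric",
    "tip_ages",
    "impute_missing_taxa",
    "species_metrics_over_trees",
    "cell_means",
]


def read_trees(path: str, schema: str = "newick") -> list[dendropy.Tree]:
    """Read one or more trees, validating branch lengths.

    Edges with missing or non-positive lengths (other than the root edge)
    raise immediately: downstream metrics divide by path sums.
    """
    trees = dendropy.TreeList.get(path=path, schema=schema, rooting="default-rooted")
    for t_idx, tree in enumerate(trees):
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None or edge.length <= 0:
                raise ValueError(
                    f"tree {t_idx}: edge above "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else 'internal node'!r} "
                    f"has non-positive length {edge.length}"
                )
    return list(trees)


def _leaf_by_label(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def equal_splits(tree: dendropy.Tree, tip: str) -> float:
    """Equal-splits sum for one tip: ES = sum_j l_j (1/2)^(j-1).

    l_1 is the pendant edge and j increases toward the root along the tip's
    path, so recent branches carry the most weight.
    """
    if not tree.is_rooted:
        raise ValueError("equal splits requires a rooted tree")
    leaves = _leaf_by_label(tree)
    if tip not in leaves:
        raise KeyError(f"tip {tip!r} not in tree")
    node = leaves[tip]
    es = 0.0
    weight = 1.0
    while node.parent_node is not None:
        length = node.edge.length
        if length is None or length <= 0:
            raise ValueError(f"non-positive branch length on path of tip {tip!r}")
        es += weight * length
        weight *= 0.5
        node = node.parent_node
    return es


def dr_metric(tree: dendropy.Tree) -> pd.Series:
    """Per-tip DR statistic: the reciprocal of the equal-splits sum (1/Myr)."""
    if not tree.is_rooted:
        raise ValueError("DR requires a rooted tree")
    out = {}
    for leaf in tree.leaf_node_iter():
        node = leaf
        es = 0.0
        weight = 1.0
        while node.parent_node is not None:
            es += weight * node.edge.length
            weight *= 0.5
            node = node.parent_node
        out[leaf.taxon.label] = 1.0 / es
    return pd.Series(out, name="dr").sort_index()


def tip_ages(tree: dendropy.Tree, ultrametric_rtol: float = 1e-6) -> pd.Series:
    """Pendant-edge length per tip (Myr): time since the most recent split.

    Warns (and proceeds) if root-to-tip depths spread by more than
    ``ultrametric_rtol`` relative — imputed trees can carry tiny numerical
    error.
    """
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depths[parent] + (node.edge.length or 0.0)
        depths[node] = d
    leaf_depths = np.array([depths[l] for l in tree.leaf_node_iter()])
    dmax = leaf_depths.max()
    if dmax > 0 and (dmax - leaf_depths.min()) / dmax > ultrametric_rtol:
        logger.warning(
            "tree is not ultrametric (relative depth spread %.2e); "
            "tip ages interpreted as pendant lengths anyway",
            (dmax - leaf_depths.min()) / dmax,
        )
    out = {leaf.taxon.label: float(leaf.edge.length) for leaf in tree.leaf_node_iter()}
    return pd.Series(out, name="tip_age").sort_index()


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[node] = 0.0 if parent is None else depths[parent] + node.edge.length
    return depths


def _mrca(nodes: list[dendropy.Node]) -> dendropy.Node:
    paths = []
    for node in nodes:
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent_node
        paths.append(path[::-1])  # root first
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        cand = paths[0][depth]
        if all(p[depth] is cand for p in paths):
            mrca = cand
        else:
            break
    return mrca


def impute_missing_taxa(
    tree: dendropy.Tree,
    taxonomy: pd.DataFrame,
    n_replicates: int = 100,
    seed: int = 0,
) -> list[dendropy.Tree]:
    """Stochastically graft missing species into their named clades.

    ``taxonomy`` has columns ``species`` and ``clade``; species already in
    the tree anchor their clade, the rest are grafted.  For each missing
    species an attachment edge is drawn with probability proportional to its
    length among the edges of the clade's crown subtree plus its stem edge,
    the attachment time is uniform along that edge, and the new pendant edge
    extends to the present, preserving ultrametricity.  Grafting is
    sequential (earlier grafts of the same clade become attachment
    candidates), in sorted species order, so replicates differ only by their
    random draws.

    This is a simplified stochastic taxon-addition scheme: attachment is
    length-proportional rather than weighted by a fitted birth-death model.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not {"species", "clade"}.issubset(taxonomy.columns):
        raise ValueError("taxonomy must have 'species' and 'clade' columns")
    base_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    tax = taxonomy.set_index("species")["clade"]
    missing = sorted(set(tax.index) - base_labels)
    orphans = [
        sp for sp in missing
        if not any(tax.get(lbl) == tax[sp] for lbl in base_labels)
    ]
    if orphans:
        raise ValueError(
            "no tree representatives for the clades of: " + ", ".join(orphans)
        )
    newick = tree.as_string(schema="newick")
    ss = np.random.SeedSequence(seed)
    replicates = []
    for child_ss in ss.spawn(n_replicates):
        rng = np.random.default_rng(child_ss)
        rep = dendropy.Tree.get(data=newick, schema="newick", rooting="default-rooted")
        depths = _node_depths(rep)
        height = max(depths[l] for l in rep.leaf_node_iter())
        clade_of = dict(tax)
        for sp in missing:
            clade = clade_of[sp]
            members = [
                leaf for leaf in rep.leaf_node_iter()
                if clade_of.get(leaf.taxon.label) == clade
            ]
            mrca = _mrca(members)
            # candidate edges: crown subtree below the MRCA plus its stem
            cand_nodes = [
                nd for nd in mrca.preorder_iter() if nd is not mrca
            ]
            if mrca.parent_node is not None:
                cand_nodes.append(mrca)
            lengths = np.array([nd.edge.length for nd in cand_nodes])
            probs = lengths / lengths.sum()
            pick = cand_nodes[rng.choice(len(cand_nodes), p=probs)]
            parent = pick.parent_node
            d_parent, d_pick = depths[parent], depths[pick]
            u = rng.uniform(d_parent, d_pick)
            parent.remove_child(pick)
            joint = parent.new_child(edge_length=u - d_parent)
            joint.add_child(pick)
            pick.edge.length = d_pick - u
            taxon = rep.taxon_namespace.require_taxon(label=sp)
            joint.new_child(taxon=taxon, edge_length=height - u)
            depths[joint] = u
            depths[joint.child_nodes()[-1]] = height
        replicates.append(rep)
    return replicates


def species_metrics_over_trees(trees: list[dendropy.Tree]) -> pd.DataFrame:
    """Average DR and tip age per species across tree replicates.

    All trees must share the same tip set.  Returns a frame indexed by
    species with columns ``dr``, ``tip_age`` (arithmetic means) and
    ``n_trees``.
    """
    if not trees:
        raise ValueError("no trees supplied")
    ref = set(_leaf_by_label(trees[0]))
    drs, ages = [], []
    for i, tree in enumerate(trees):
        labels = set(_leaf_by_label(tree))
        if labels != ref:
            raise ValueError(f"tree {i} tip set differs from the first tree")
        drs.append(dr_metric(tree))
        ages.append(tip_ages(tree))
    out = pd.DataFrame({
        "dr": pd.concat(drs, axis=1).mean(axis=1),
        "tip_age": pd.concat(ages, axis=1).mean(axis=1),
    })
    out["n_trees"] = len(trees)
    out.index.name = "species"
    return out


def cell_means(pam: pd.DataFrame, tip_metrics: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-cell means of DR and tip age over species present.

    Cells with no species receive NaN (excluded from modelling downstream).
    A species present in the PAM but absent from the metric table raises.
    """
    present = [sp for sp in pam.columns if pam[sp].any()]
    missing = set(present) - set(tip_metrics.index)
    if missing:
        raise KeyError(f"no tip metrics for species present in PAM: {sorted(missing)}")
    occ = pam.to_numpy(dtype=float)
    counts = occ.sum(axis=1)
    dr = tip_metrics.reindex(pam.columns)["dr"].to_numpy()
    age = tip_metrics.reindex(pam.columns)["tip_age"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dr = np.where(counts > 0, occ @ np.nan_to_num(dr) / np.maximum(counts, 1), np.nan)
        mean_age = np.where(counts > 0, occ @ np.nan_to_num(age) / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"mean_dr": mean_dr, "mean_tip_age": mean_age}, index=pam.index
    )
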