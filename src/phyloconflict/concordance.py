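"""Per-node concordance/conflict accounting of gene trees against a
species tree, plus cloud-tree preparation."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import GeneTreeRecord
from .trees import (
    Bipartition,
    Node,
    PhyloTree,
    bipartitions,
    collapse_low_support,
)

logger = logging.getLogger(__name__)

__all__ = ["NodeCounts", "ConcordanceSummary", "map_concordance", "pie_fractions", "prepare_cloud_trees"]


@dataclass
class NodeCounts:
    node_id: str
    bipartition: Bipartition
    n_concordant: int = 0
    n_top_conflict: int = 0
    n_other_conflict: int = 0
    n_uninformative: int = 0
    top_conflict_bipartition: Optional[str] = None

    @property
    def total(self) -> int:
        return (
            self.n_concordant
            + self.n_top_conflict
            + self.n_other_conflict
            + self.n_uninformative
        )


@dataclass
class ConcordanceSummary:
    nodes: dict[str, NodeCounts]
    n_genes: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for node_id, nc in self.nodes.items():
            frac = pie_fractions_for(nc, self.n_genes)
            rows.append(
                dict(
                    node=node_id,
                    bipartition=str(nc.bipartition),
                    n_concordant=nc.n_concordant,
                    n_top_conflict=nc.n_top_conflict,
                    n_other_conflict=nc.n_other_conflict,
                    n_uninformative=nc.n_uninformative,
                    frac_concordant=frac[0],
                    frac_top_conflict=frac[1],
                    frac_other_conflict=frac[2],
                    frac_uninformative=frac[3],
                    top_conflict=nc.top_conflict_bipartition or "",
                )
            )
        return pd.DataFrame(rows)


def species_tree_splits(species: PhyloTree) -> dict[str, Bipartition]:
    """Stable node ids (preorder N1, N2, ...) for nontrivial splits."""
    taxa = frozenset(species.leaf_labels())
    clusters: dict[Node, frozenset] = {}
    for node in species.iter_nodes("postorder"):
        clusters[node] = (
            frozenset([node.label])
            if node.is_leaf
            else frozenset().union(*(clusters[c] for c in node.children))
        )
    out: dict[str, Bipartition] = {}
    seen = set()
    i = 0
    for node in species.iter_nodes("preorder"):
        if node.is_leaf or node is species.root:
            continue
        i += 1
        block = clusters[node]
        if len(block) <= 1 or len(taxa - block) <= 1:
            continue
        bip = Bipartition.make(block, taxa)
        if bip in seen:
            continue
        seen.add(bip)
        out[f"N{i}"] = bip
    return out


def _gene_status(
    species_bip: Bipartition,
    gene_taxa: frozenset,
    gene_bips: set[Bipartition],
) -> tuple[str, Optional[Bipartition]]:
    restricted = species_bip.restricted(gene_taxa)
    if restricted is None or restricted.is_trivial:
        return "uninformative", None
    if restricted in gene_bips:
        return "concordant", None
    conflicting = [b for b in gene_bips if not b.is_compatible_with(restricted)]
    if not conflicting:
        return "uninformative", None
    # representative conflict: closest to the species split, ties broken
    # lexicographically so counting is deterministic
    def score(b: Bipartition):
        d = min(
            len(b.block ^ restricted.block),
            len(b.block ^ restricted.other_block),
        )
        return (d, str(b))

    return "conflict", min(conflicting, key=score)


def map_concordance(
    species: PhyloTree,
    genes: Sequence[GeneTreeRecord],
    support_collapse: float = 50.0,
) -> ConcordanceSummary:
    """PhyParts-style counts per species-tree node.

    A gene counts concordant at a node when (restricted to its taxa) it
    contains the node's split, conflicting when it has an incompatible
    split, and uninformative otherwise; gene-tree edges with support below
    ``support_collapse`` are collapsed first.
    """
    splits = species_tree_splits(species)
    species_taxa = frozenset(species.leaf_labels())
    per_node_status: dict[str, list[tuple[str, Optional[Bipartition]]]] = {
        nid: [] for nid in splits
    }
    for rec in genes:
        gtree = rec.tree
        gene_taxa = frozenset(gtree.leaf_labels())
        extra = gene_taxa - species_taxa
        if extra:
            raise ValueError(f"gene {rec.gene_id!r} has taxa not in species tree: {sorted(extra)}")
        if len(gene_taxa) < 4:
            warnings.warn(
                f"gene {rec.gene_id!r} has < 4 taxa; uninformative everywhere",
                stacklevel=2,
            )
            for nid in splits:
                per_node_status[nid].append(("uninformative", None))
            continue
        collapsed = collapse_low_support(gtree, support_collapse)
        gene_bips = bipartitions(collapsed)
        for nid, sbip in splits.items():
            per_node_status[nid].append(_gene_status(sbip, gene_taxa, gene_bips))

    nodes: dict[str, NodeCounts] = {}
    for nid, sbip in splits.items():
        nc = NodeCounts(node_id=nid, bipartition=sbip)
        conflict_counter: dict[str, int] = {}
        for status, rep in per_node_status[nid]:
            if status == "concordant":
                nc.n_concordant += 1
            elif status == "uninformative":
                nc.n_uninformative += 1
            else:
                key = str(rep)
                conflict_counter[key] = conflict_counter.get(key, 0) + 1
        if conflict_counter:
            top_key, top_n = max(conflict_counter.items(), key=lambda kv: (kv[1], kv[0]))
            nc.top_conflict_bipartition = top_key
            nc.n_top_conflict = top_n
            nc.n_other_conflict = sum(conflict_counter.values()) - top_n
        nodes[nid] = nc
    return ConcordanceSummary(nodes=nodes, n_genes=len(genes))


def pie_fractions_for(nc: NodeCounts, total: int) -> np.ndarray:
    if total <= 0:
        raise ValueError("total gene count must be positive")
    return (
        np.array(
            [nc.n_concordant, nc.n_top_conflict, nc.n_other_conflict, nc.n_uninformative],
            dtype=float,
        )
        / total
    )


def pie_fractions(summary: ConcordanceSummary) -> dict[str, np.ndarray]:
    """Per-node (concordant, top-conflict, other-conflict, uninformative)
    fractions; each vector sums to 1."""
    return {nid: pie_fractions_for(nc, summary.n_genes) for nid, nc in summary.nodes.items()}


def prepare_cloud_trees(
    genes: Sequence[GeneTreeRecord], taxa: Sequence[str]
) -> tuple[list[PhyloTree], list[str]]:
    """Unit-height ultrametric copies of trees covering the full taxon set.

    Node depths are normalized proportionally (depth divided by the
    deepest leaf reachable through the node), a qualitative stand-in for
    time calibration. Returns (scaled trees, excluded gene ids)."""
    want = frozenset(taxa)
    scaled, excluded = [], []
    for rec in genes:
        if frozenset(rec.tree.leaf_labels()) != want:
            excluded.append(rec.gene_id)
            continue
        scaled.append(_proportional_ultrametric(rec.tree))
    if excluded:
        logger.info("cloud trees: excluded %d/%d genes missing taxa", len(excluded), len(genes))
    return scaled, excluded


def _proportional_ultrametric(tree: PhyloTree) -> PhyloTree:
    out = tree.copy()
    depths = out.node_depths()
    # deepest leaf through each node
    max_below: dict[Node, float] = {}
    for node in out.iter_nodes("postorder"):
        if node.is_leaf:
            max_below[node] = depths[node]
        else:
            max_below[node] = max(max_below[c] for c in node.children)
    u: dict[Node, float] = {}
    for node in out.iter_nodes("preorder"):
        if node is out.root:
            u[node] = 0.0
        elif max_below[node] <= 0:
            u[node] = 1.0 if node.is_leaf else u[node.parent]
        else:
            u[node] = depths[node] / max_below[node]
    for node in out.iter_nodes("preorder"):
        if node is not out.root:
            node.length = max(u[node] - u[node.parent], 0.0)
    for leaf in out.leaves():
        # force exact unit height against float drift
        leaf.length = (leaf.length or 0.0) + (1.0 - u[leaf])
    return out
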