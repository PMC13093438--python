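"""Neighbour-joining gene-tree estimation with bootstrap supports.

This is a deliberately simple, tool-free stand-in for per-gene ML tree
inference: Jukes-Cantor distances, scikit-bio's NJ, and nonparametric
bootstrap over alignment columns. It exists so the rest of the pipeline
can be exercised without external binaries; it is not a serious estimator.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .alignment import Alignment
from .records import GeneTreeRecord
from .trees import Bipartition, PhyloTree, bipartitions, parse_newick

logger = logging.getLogger(__name__)

#: distance assigned when the p-distance is saturated (p >= 3/4)
SATURATION_CAP = 5.0

__all__ = ["jc_distance_matrix", "nj_tree", "estimate_gene_tree_nj", "SATURATION_CAP"]


def jc_distance_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise Jukes-Cantor distances from an int-coded alignment matrix.

    Sites where either sequence is missing (-1) are ignored pairwise.
    Saturated pairs (p >= 0.75) get :data:`SATURATION_CAP` with a warning.
    """
    n = mat.shape[0]
    dist = np.zeros((n, n))
    valid = mat >= 0
    saturated = False
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            n_ok = int(both.sum())
            if n_ok == 0:
                d = SATURATION_CAP
                saturated = True
            else:
                p = float((mat[i, both] != mat[j, both]).mean())
                if p >= 0.75:
                    d = SATURATION_CAP
                    saturated = True
                else:
                    d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            dist[i, j] = dist[j, i] = d
    if saturated:
        warnings.warn("saturated JC distances capped", stacklevel=2)
    return dist


def nj_tree(dist: np.ndarray, labels: list[str]) -> PhyloTree:
    import io

    dm = DistanceMatrix(dist, ids=labels)
    buf = io.StringIO()
    _skbio_nj(dm).write(buf)
    tree = parse_newick(buf.getvalue())
    for node in tree.iter_nodes():
        if node.length is not None and node.length < 0:
            node.length = 0.0
        node.support = None
    tree.units = "substitutions"
    return tree


def estimate_gene_tree_nj(
    aln: Alignment,
    n_bootstrap: int = 100,
    seed: int = 0,
    gene_id: str = "gene",
) -> GeneTreeRecord:
    """NJ tree on JC distances with column-bootstrap supports (percent)."""
    if aln.n_taxa < 4:
        raise ValueError("need at least 4 taxa for gene-tree estimation")
    if aln.n_sites < 1:
        raise ValueError("empty alignment")
    labels = aln.labels
    mat = aln.to_int_matrix()
    tree = nj_tree(jc_distance_matrix(mat), labels)

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        counts: Counter[Bipartition] = Counter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_bootstrap):
                cols = rng.integers(0, aln.n_sites, size=aln.n_sites)
                rep = nj_tree(jc_distance_matrix(mat[:, cols]), labels)
                counts.update(bipartitions(rep))
        _annotate_supports(tree, counts, n_bootstrap)

    record = GeneTreeRecord(gene_id=gene_id, tree=tree, alignment_length=aln.n_sites)
    try:
        record.recompute_abs()
    except ValueError:
        record.abs_support = None
    return record


def _annotate_supports(tree: PhyloTree, counts, n_reps: int) -> None:
    taxa = frozenset(tree.leaf_labels())
    clusters: dict = {}
    for node in tree.iter_nodes("postorder"):
        if node.is_leaf:
            clusters[node] = frozenset([node.label])
        else:
            clusters[node] = frozenset().union(*(clusters[c] for c in node.children))
    for node in tree.internal_nodes():
        block = clusters[node]
        if len(block) <= 1 or len(taxa - block) <= 1:
            continue
        bip = Bipartition.make(block, taxa)
        node.support = 100.0 * counts.get(bip, 0) / n_reps
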