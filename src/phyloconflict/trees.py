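"""Phylogenetic tree data model, Newick I/O, bipartition algebra and
Robinson-Foulds distances.

Trees are stored as a light node-linked structure with an optional
tree-level branch-length unit tag (``"coalescent"`` or ``"substitutions"``).
Newick parsing is delegated to :mod:`dendropy`; internal node labels are
interpreted as support values when they are numeric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonSet",
    "Node",
    "PhyloTree",
    "Bipartition",
    "NewickError",
    "parse_newick",
    "parse_newick_list",
    "write_newick",
    "bipartitions",
    "rf_distance",
    "max_rf_distance",
    "average_bootstrap_support",
    "collapse_low_support",
    "root_with_outgroup",
    "restrict_to_taxa",
]


class NewickError(ValueError):
    """Raised for malformed Newick input (names the offending token)."""


@dataclass(frozen=True)
class TaxonSet:
    """Ordered collection of unique taxon labels.

    Order is canonical (lexicographic) so that bipartition encodings are
    stable across trees sharing the same labels.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]):
        labels = list(labels)
        if any(not lbl for lbl in labels):
            raise ValueError("empty taxon label")
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate taxon labels: {dups}")
        object.__setattr__(self, "labels", tuple(sorted(labels)))

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in set(self.labels)

    @property
    def first(self) -> str:
        return self.labels[0]


class Node:
    """Single tree node; ``support`` only meaningful on internal nodes."""

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length}, sup={self.support})"


class PhyloTree:
    """Rooted tree wrapper (a rooted=False tag marks 'interpret unrooted')."""

    def __init__(self, root: Node, units: Optional[str] = None, rooted: bool = True):
        self.root = root
        self.units = units
        self.rooted = rooted
        self._validate()

    def _validate(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate leaf labels: {dups}")
        for node in self.iter_nodes():
            if node.length is not None and node.length < -1e-12:
                raise ValueError(f"negative branch length {node.length} at {node.label}")

    # -- traversal ---------------------------------------------------------
    def iter_nodes(self, order: str = "preorder") -> Iterator[Node]:
        if order == "preorder":
            stack = [self.root]
            while stack:
                node = stack.pop()
                yield node
                stack.extend(reversed(node.children))
        elif order == "postorder":
            yield from self._postorder(self.root)
        else:  # pragma: no cover
            raise ValueError(order)

    def _postorder(self, node: Node) -> Iterator[Node]:
        for child in node.children:
            yield from self._postorder(child)
        yield node

    def leaves(self) -> list[Node]:
        return [n for n in self.iter_nodes("postorder") if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self, include_root: bool = False) -> list[Node]:
        out = [n for n in self.iter_nodes() if not n.is_leaf]
        if not include_root:
            out = [n for n in out if n is not self.root]
        return out

    @property
    def taxon_set(self) -> TaxonSet:
        return TaxonSet(self.leaf_labels())

    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- geometry ----------------------------------------------------------
    def node_depths(self) -> dict[Node, float]:
        """Root-to-node path lengths (missing lengths count as 0)."""
        depths: dict[Node, float] = {self.root: 0.0}
        for node in self.iter_nodes():
            if node is self.root:
                continue
            depths[node] = depths[node.parent] + (node.length or 0.0)
        return depths

    def height(self) -> float:
        depths = self.node_depths()
        return max(depths[leaf] for leaf in self.leaves())

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.iter_nodes() if n is not self.root)

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root), units=self.units, rooted=self.rooted)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.n_leaves()} leaves, units={self.units!r})"


@dataclass(frozen=True)
class Bipartition:
    """A split of a taxon set into two complementary non-empty blocks.

    The canonical key is the block *not* containing the lexicographically
    first taxon, so equal splits compare equal regardless of orientation.
    """

    block: frozenset
    taxa: frozenset = field(compare=False)

    @staticmethod
    def make(block: Iterable[str], taxa: Iterable[str]) -> "Bipartition":
        taxa = frozenset(taxa)
        block = frozenset(block)
        if not block or block == taxa:
            raise ValueError("bipartition blocks must be non-empty")
        if not block <= taxa:
            raise ValueError(f"block not within taxa: {sorted(block - taxa)}")
        anchor = min(taxa)
        if anchor in block:
            block = taxa - block
        return Bipartition(block=block, taxa=taxa)

    @property
    def other_block(self) -> frozenset:
        return self.taxa - self.block

    @property
    def is_trivial(self) -> bool:
        return min(len(self.block), len(self.taxa) - len(self.block)) <= 1

    def is_compatible_with(self, other: "Bipartition") -> bool:
        """Two splits on the same taxa are compatible iff some pairwise
        block intersection is empty."""
        if self.taxa != other.taxa:
            raise ValueError("bipartitions on different taxon sets")
        a, a2 = self.block, self.other_block
        b, b2 = other.block, other.other_block
        return not (a & b) or not (a & b2) or not (a2 & b) or not (a2 & b2)

    def restricted(self, taxa: Iterable[str]) -> Optional["Bipartition"]:
        """Restriction to a taxon subset; None when it degenerates."""
        taxa = frozenset(taxa)
        block = self.block & taxa
        if not block or block == taxa:
            return None
        return Bipartition.make(block, taxa)

    def __str__(self) -> str:
        return ",".join(sorted(self.block)) + " | " + ",".join(sorted(self.other_block))


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy)
# ---------------------------------------------------------------------------

def _from_dendropy(dnode, rescaled_flag: list) -> Node:
    if dnode.is_leaf():
        if dnode.taxon is None or not dnode.taxon.label:
            raise NewickError("leaf without a label")
        node = Node(label=dnode.taxon.label, length=dnode.edge.length)
    else:
        support = None
        label = dnode.label
        if label is not None:
            try:
                support = float(label)
                label = None
            except ValueError:
                support = None
        node = Node(label=label, length=dnode.edge.length, support=support)
        for child in dnode.child_nodes():
            node.add_child(_from_dendropy(child, rescaled_flag))
    return node


def _rescale_fractional_supports(tree: PhyloTree) -> None:
    """Supports in [0,1] are read as proportions and rescaled to [0,100]."""
    supports = [n.support for n in tree.internal_nodes(include_root=True) if n.support is not None]
    if supports and all(0.0 <= s <= 1.0 for s in supports) and any(0.0 < s < 1.0 for s in supports):
        logger.warning("internal supports look fractional; rescaling to [0, 100]")
        for node in tree.internal_nodes(include_root=True):
            if node.support is not None:
                node.support *= 100.0


def parse_newick(text: str, units: Optional[str] = None) -> PhyloTree:
    """Parse a single Newick string into a :class:`PhyloTree`.

    Numeric internal-node labels become support values; fractional support
    scales are normalized to percentages with a logged warning.
    """
    text = text.strip()
    if not text:
        raise NewickError("empty Newick string")
    if text.count("(") != text.count(")"):
        raise NewickError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"Newick parse failure: {exc}") from exc
    root = _from_dendropy(dtree.seed_node, [])
    tree = PhyloTree(root, units=units)
    _rescale_fractional_supports(tree)
    return tree


def parse_newick_list(text: str, units: Optional[str] = None) -> list[PhyloTree]:
    """Parse one tree per non-empty line / semicolon-terminated statement."""
    trees = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            trees.append(parse_newick(chunk + ";", units=units))
    return trees


def _format_length(x: float) -> str:
    s = f"{x:.10g}"
    return s


def write_newick(tree: PhyloTree, include_supports: bool = True) -> str:
    def render(node: Node) -> str:
        if node.is_leaf:
            out = node.label
        else:
            out = "(" + ",".join(render(c) for c in node.children) + ")"
            if include_supports and node.support is not None:
                out += _format_length(node.support)
            elif node.label:
                out += node.label
        if node.length is not None:
            out += ":" + _format_length(node.length)
        return out

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# Bipartition algebra and RF
# ---------------------------------------------------------------------------

def bipartitions(tree: PhyloTree, include_trivial: bool = False) -> set[Bipartition]:
    """Nontrivial bipartitions induced by the tree's internal edges.

    The tree is read unrooted: the two edges meeting at a bifurcating root
    induce the same split and are reported once.
    """
    taxa = frozenset(tree.leaf_labels())
    clusters: dict[Node, frozenset] = {}
    for node in tree.iter_nodes("postorder"):
        if node.is_leaf:
            clusters[node] = frozenset([node.label])
        else:
            clusters[node] = frozenset().union(*(clusters[c] for c in node.children))
    out: set[Bipartition] = set()
    for node in tree.iter_nodes():
        if node is tree.root:
            continue
        block = clusters[node]
        if not block or block == taxa:
            continue
        bip = Bipartition.make(block, taxa)
        if include_trivial or not bip.is_trivial:
            out.add(bip)
    return out


def max_rf_distance(n_leaves: int) -> int:
    return 2 * max(n_leaves - 3, 0)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unweighted Robinson-Foulds distance on unrooted topologies."""
    s1, s2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if s1 != s2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(s1 - s2)} only-in-second={sorted(s2 - s1)}"
        )
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def average_bootstrap_support(tree: PhyloTree) -> float:
    """Mean support over internal nodes that carry a support value."""
    supports = [n.support for n in tree.internal_nodes() if n.support is not None]
    if not supports:
        raise ValueError("no internal node carries a support value; ABS undefined")
    return float(sum(supports)) / len(supports)


def collapse_low_support(tree: PhyloTree, threshold: float) -> PhyloTree:
    """Contract internal edges whose support is below ``threshold``.

    Nodes without a support value are left untouched (no evidence either
    way); threshold 0 is the identity.
    """
    out = tree.copy()
    if threshold <= 0:
        return out
    changed = True
    while changed:
        changed = False
        for node in list(out.iter_nodes("postorder")):
            if node.is_leaf or node is out.root:
                continue
            if node.support is not None and node.support < threshold:
                parent = node.parent
                idx = parent.children.index(node)
                parent.children.pop(idx)
                for i, child in enumerate(node.children):
                    child.parent = parent
                    parent.children.insert(idx + i, child)
                changed = True
    return out


def _cluster_map(tree: PhyloTree) -> dict[Node, frozenset]:
    clusters: dict[Node, frozenset] = {}
    for node in tree.iter_nodes("postorder"):
        if node.is_leaf:
            clusters[node] = frozenset([node.label])
        else:
            clusters[node] = frozenset().union(*(clusters[c] for c in node.children))
    return clusters


def root_with_outgroup(tree: PhyloTree, outgroup: Sequence[str]) -> PhyloTree:
    """Re-root so the root bisects the edge separating outgroup from ingroup."""
    out_set = frozenset(outgroup)
    taxa = frozenset(tree.leaf_labels())
    missing = out_set - taxa
    if missing:
        raise ValueError(f"outgroup taxa absent from tree: {sorted(missing)}")
    if out_set == taxa:
        raise ValueError("outgroup cannot be the whole taxon set")
    work = tree.copy()
    clusters = _cluster_map(work)
    # find edge whose lower cluster is the outgroup or its complement
    target = None
    for node in work.iter_nodes():
        if node is work.root:
            continue
        if clusters[node] == out_set or clusters[node] == taxa - out_set:
            target = node
            break
    if target is None:
        below = [clusters[n] for n in work.iter_nodes() if n is not work.root]
        best = max(
            (c for c in below if c <= out_set),
            key=len,
            default=frozenset(),
        )
        intruders = sorted(out_set - best) if best else sorted(out_set)
        raise ValueError(
            f"outgroup {sorted(out_set)} is not monophyletic (unrooted); "
            f"could not isolate taxa: {intruders}"
        )
    if clusters[target] == taxa - out_set:
        # root already separates; equivalent edge viewed from the other side
        pass
    rerooted = _reroot_on_edge(work, target)
    rerooted.units = tree.units
    return rerooted


def _reroot_on_edge(tree: PhyloTree, node: Node) -> PhyloTree:
    """Place a new root at the midpoint of the edge above ``node``."""
    if node.parent is None:
        return tree
    if node.parent is tree.root and len(tree.root.children) == 2:
        # root already on this edge conceptually; just rebalance
        return tree
    length = node.length if node.length is not None else None
    half = None if length is None else length / 2.0

    # Build path from node's parent up to the old root, then reverse edges.
    new_root = Node()
    old_parent = node.parent
    old_parent.children.remove(node)
    node.parent = None
    node.length = half
    new_root.add_child(node)

    # reverse the chain: old_parent becomes child of new root, etc.
    prev = new_root
    prev_edge_len = half
    prev_edge_sup = node.support
    current = old_parent
    while current is not None:
        nxt = current.parent
        nxt_len = current.length
        nxt_sup = current.support
        current.parent = None
        if nxt is not None:
            nxt.children.remove(current)
        current.length = prev_edge_len
        current.support = prev_edge_sup
        prev.add_child(current)
        prev = current
        prev_edge_len = nxt_len
        prev_edge_sup = nxt_sup
        current = nxt
    # the old root may now be a degree-1 or degree-2 node: suppress it
    _suppress_unifurcations(new_root)
    return PhyloTree(new_root, units=tree.units)


def _suppress_unifurcations(root: Node) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        for child in list(node.children):
            while len(child.children) == 1:
                grand = child.children[0]
                grand.length = (grand.length or 0.0) + (child.length or 0.0)
                if grand.support is None:
                    grand.support = child.support
                idx = node.children.index(child)
                node.children[idx] = grand
                grand.parent = node
                child = grand
            stack.append(child)
    # root itself
    while len(root.children) == 1 and root.children[0].children:
        only = root.children[0]
        root.children = only.children
        for c in root.children:
            c.parent = root


def restrict_to_taxa(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Prune to the given taxa, suppressing resulting unifurcations."""
    keep = frozenset(taxa)
    out = tree.copy()

    def prune(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return node if node.label in keep else None
        kept = []
        for child in node.children:
            sub = prune(child)
            if sub is not None:
                sub.parent = node
                kept.append(sub)
        node.children = kept
        if not kept:
            return None
        if len(kept) == 1:
            only = kept[0]
            only.length = (only.length or 0.0) + (node.length or 0.0)
            only.parent = node.parent
            return only
        return node

    new_root = prune(out.root)
    if new_root is None:
        raise ValueError("no requested taxa present in tree")
    new_root.parent = None
    return PhyloTree(new_root, units=tree.units)
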