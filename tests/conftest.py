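import itertools

import numpy as np
import pytest

from phyloconflict.trees import Node, PhyloTree


def random_binary_tree(labels, rng, with_lengths=True, with_supports=False):
    """Random topology by sequential joins; used as an oracle fixture."""
    nodes = [Node(label=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = Node()
        parent.add_child(b)
        parent.add_child(a)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = PhyloTree(nodes[0])
    if with_lengths:
        for node in tree.iter_nodes():
            if node is not tree.root:
                node.length = float(rng.uniform(0.05, 2.0))
    if with_supports:
        for node in tree.internal_nodes():
            node.support = float(rng.integers(0, 101))
    return tree


def brute_force_bipartitions(tree):
    """Edge-by-edge flood fill on the unrooted adjacency graph."""
    adj = {}
    edges = []
    for node in tree.iter_nodes():
        for child in node.children:
            adj.setdefault(node, []).append(child)
            adj.setdefault(child, []).append(node)
            edges.append((node, child))
    leaves = frozenset(tree.leaf_labels())
    out = set()
    for a, b in edges:
        seen = {b}
        stack = [b]
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if cur is b and nxt is a:
                    continue  # the removed edge
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        side = frozenset(n.label for n in seen if n.is_leaf)
        if 1 < len(side) < len(leaves) - 1:
            anchor = min(leaves)
            block = leaves - side if anchor in side else side
            out.add(block)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def adonis_bundle():
    from phyloconflict.scenarios import make_scenario

    return make_scenario("adonis_like", seed=1)


@pytest.fixture(scope="session")
def rate_artifact_bundle():
    from phyloconflict.scenarios import make_scenario

    return make_scenario("rate_artifact", seed=1)
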