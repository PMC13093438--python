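"""Coalescent and sequence simulation.

Implements the multispecies coalescent (MSC) on a species tree with
branch lengths in coalescent units, an optional single reticulation
(network MSC: each hybrid lineage follows one parental history at
random), GTR+Gamma sequence evolution, and missing-data injection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from .alignment import Alignment
from .trees import Node, PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesTreeModel",
    "HybridEvent",
    "SubstitutionModel",
    "simulate_gene_tree",
    "simulate_network_gene_tree",
    "evolve_sequences",
    "inject_missingness",
]

#: stand-in duration (coalescent units) for terminal branches without lengths
DEFAULT_TERMINAL_BRANCH = 2.0


@dataclass
class SpeciesTreeModel:
    """Rooted species tree with coalescent-unit branch lengths.

    ``theta`` maps a clade (frozenset of leaf labels identifying the branch
    above that clade's MRCA) to a population-size scaler; unnamed branches
    use ``default_theta``. Pair-coalescence rate in a branch is 1/theta_b.
    """

    tree: PhyloTree
    default_theta: float = 1.0
    theta: dict = field(default_factory=dict)
    default_terminal_branch: float = DEFAULT_TERMINAL_BRANCH

    def __post_init__(self):
        if self.tree.units is None:
            self.tree.units = "coalescent"
        if self.tree.units != "coalescent":
            raise ValueError(
                f"species tree for MSC simulation must carry coalescent units, got {self.tree.units!r}"
            )
        for node in self.tree.iter_nodes():
            if node is not self.tree.root and node.length is not None and node.length < 0:
                raise ValueError("negative branch length in species tree")

    def theta_for(self, clade: frozenset) -> float:
        return self.theta.get(clade, self.default_theta)


@dataclass
class HybridEvent:
    """One reticulation: ``hybrid`` traces ``parent1`` with probability
    ``gamma``, else ``parent2``. Attachment is on the parents' pendant
    edges at the given elapsed times above the parent leaves."""

    hybrid: str
    parent1: str
    parent2: str
    gamma: float
    attach_time1: Optional[float] = None
    attach_time2: Optional[float] = None

    def __post_init__(self):
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.parent1 == self.parent2:
            raise ValueError("hybrid parents must be distinct")


class _Lineage:
    __slots__ = ("gnode", "height", "entry_elapsed")

    def __init__(self, gnode: Node, height: float, entry_elapsed: float):
        self.gnode = gnode
        self.height = height  # absolute clock at entry
        self.entry_elapsed = entry_elapsed

    def clock_at(self, elapsed: float) -> float:
        return self.height + (elapsed - self.entry_elapsed)


def _branch_durations(model: SpeciesTreeModel) -> dict:
    dur = {}
    warned = False
    for node in model.tree.iter_nodes():
        if node is model.tree.root:
            continue
        if node.length is None:
            if node.is_leaf:
                dur[node] = model.default_terminal_branch
                if not warned:
                    logger.warning(
                        "terminal branch without length; using default %.3g coalescent units",
                        model.default_terminal_branch,
                    )
                    warned = True
            else:
                dur[node] = 0.0
        else:
            dur[node] = float(node.length)
    return dur


def _coalesce_segment(
    active: list,
    arrivals: list,
    duration: float,
    theta: float,
    rng: np.random.Generator,
    node_heights: dict,
) -> list:
    """Coalesce ``active`` lineages within one population branch.

    ``arrivals`` is a list of (elapsed_time, _Lineage) scheduled entries;
    ``duration`` may be ``inf`` (root branch, coalesce to one lineage).
    """
    arrivals = sorted(arrivals, key=lambda x: x[0])
    elapsed = 0.0
    i = 0
    while True:
        k = len(active)
        rate = k * (k - 1) / 2.0 / theta
        next_arrival = arrivals[i][0] if i < len(arrivals) else math.inf
        wait = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        t_coal = elapsed + wait
        if t_coal < min(next_arrival, duration):
            a_idx, b_idx = rng.choice(k, size=2, replace=False)
            a, b = active[a_idx], active[b_idx]
            parent = Node()
            h = max(a.clock_at(t_coal), b.clock_at(t_coal))
            for child_lin in (a, b):
                child = child_lin.gnode
                child.length = h - node_heights[child]
                parent.add_child(child)
            node_heights[parent] = h
            merged = _Lineage(parent, h, t_coal)
            active = [l for j, l in enumerate(active) if j not in (a_idx, b_idx)]
            active.append(merged)
            elapsed = t_coal
        elif i < len(arrivals) and next_arrival <= duration:
            elapsed = next_arrival
            active.append(arrivals[i][1])
            i += 1
        else:
            # branch exhausted, or fully coalesced in the root branch
            break
    # advance clocks to the branch top
    if duration is not math.inf:
        out = []
        for lin in active:
            out.append(_Lineage(lin.gnode, lin.clock_at(duration), 0.0))
        return out
    return active


def _simulate(
    model: SpeciesTreeModel,
    event: Optional[HybridEvent],
    individuals_per_taxon: Optional[Mapping[str, int]],
    rng: np.random.Generator,
) -> PhyloTree:
    tree = model.tree
    taxa = tree.leaf_labels()
    if event is not None:
        for parent in (event.parent1, event.parent2):
            if parent not in taxa:
                raise ValueError(f"hybrid parent {parent!r} not in species tree")
        if event.hybrid in taxa:
            raise ValueError(
                f"hybrid taxon {event.hybrid!r} must not already be a species-tree leaf"
            )
    individuals_per_taxon = dict(individuals_per_taxon or {})
    dur = _branch_durations(model)

    def make_tips(taxon: str) -> list:
        n = individuals_per_taxon.get(taxon, 1)
        if n < 1:
            raise ValueError(f"need >= 1 individual for taxon {taxon!r}")
        labels = [taxon] if n == 1 else [f"{taxon}_{i}" for i in range(n)]
        tips = []
        for lbl in labels:
            gnode = Node(label=lbl)
            node_heights[gnode] = 0.0
            tips.append(_Lineage(gnode, 0.0, 0.0))
        return tips

    node_heights: dict = {}
    clusters: dict = {}
    scheduled: dict = {}  # species leaf node -> list of (elapsed, lineage)

    if event is not None:
        t1 = event.attach_time1
        t2 = event.attach_time2
        p1_node = next(l for l in tree.leaves() if l.label == event.parent1)
        p2_node = next(l for l in tree.leaves() if l.label == event.parent2)
        if t1 is None:
            t1 = dur[p1_node] / 2.0
        if t2 is None:
            t2 = dur[p2_node] / 2.0
        if t1 > dur[p1_node] or t2 > dur[p2_node]:
            raise ValueError("hybrid attachment time exceeds parental pendant edge")
        stem = min(t1, t2)
        active = make_tips(event.hybrid)
        theta_stem = model.theta_for(frozenset([event.hybrid]))
        active = _coalesce_segment(active, [], stem, theta_stem, rng, node_heights)
        for lin in active:
            if rng.random() < event.gamma:
                scheduled.setdefault(p1_node, []).append((t1, _Lineage(lin.gnode, lin.height, t1)))
            else:
                scheduled.setdefault(p2_node, []).append((t2, _Lineage(lin.gnode, lin.height, t2)))

    passed: dict = {}  # species node -> surviving lineages at its branch top
    post = list(tree.iter_nodes("postorder"))
    for snode in post:
        if snode.is_leaf:
            active = make_tips(snode.label)
            clusters[snode] = frozenset([snode.label])
        else:
            active = []
            for child in snode.children:
                active.extend(passed[child])
            clusters[snode] = frozenset().union(*(clusters[c] for c in snode.children))
        theta_b = model.theta_for(clusters[snode])
        if snode is tree.root:
            active = _coalesce_segment(
                active, [], math.inf, theta_b, rng, node_heights
            )
            root_lineage = active[0]
        else:
            arrivals = scheduled.get(snode, [])
            active = _coalesce_segment(active, arrivals, dur[snode], theta_b, rng, node_heights)
            passed[snode] = active

    root = root_lineage.gnode
    root.length = None
    gtree = PhyloTree(root, units="coalescent")
    return gtree


def simulate_gene_tree(
    model: SpeciesTreeModel,
    individuals_per_taxon: Optional[Mapping[str, int]] = None,
    seed: Union[int, np.random.Generator, None] = None,
) -> PhyloTree:
    """Draw one gene tree under the MSC on ``model``.

    Within each species-tree branch, ``k`` lineages coalesce at rate
    k(k-1)/2 / theta_b; lineages left at the root coalesce above it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _simulate(model, None, individuals_per_taxon, rng)


def simulate_network_gene_tree(
    model: SpeciesTreeModel,
    event: HybridEvent,
    individuals_per_taxon: Optional[Mapping[str, int]] = None,
    seed: Union[int, np.random.Generator, None] = None,
) -> PhyloTree:
    """MSC draw with one reticulation: hybrid lineages coalesce in the
    hybrid stem, then each survivor follows parent1's pendant edge with
    probability gamma, else parent2's."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _simulate(model, event, individuals_per_taxon, rng)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

_BASES = "ACGT"


@dataclass
class SubstitutionModel:
    """GTR+Gamma model, normalized to mean substitution rate 1.

    ``exchangeabilities`` order: AC, AG, AT, CG, CT, GT.
    ``gamma_shape`` of ``None`` (or inf) disables rate variation.
    ``lineage_rate_multipliers`` maps a leaf label to a rate multiplier
    applied to that leaf's pendant branch (rate-heterogeneity artifacts).
    """

    exchangeabilities: Sequence[float] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: Optional[float] = None
    n_categories: int = 4
    lineage_rate_multipliers: dict = field(default_factory=dict)

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_freqs, dtype=float)
        if ex.shape != (6,) or np.any(ex <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        if pi.shape != (4,) or abs(pi.sum() - 1.0) > 1e-9 or np.any(pi <= 0):
            raise ValueError("base frequencies must be 4 positives summing to 1")
        if self.gamma_shape is not None and not (self.gamma_shape > 0):
            raise ValueError("gamma shape must be positive")
        self.exchangeabilities = tuple(ex)
        self.base_freqs = tuple(pi)

    def rate_matrix(self) -> np.ndarray:
        """Normalized GTR rate matrix (rows sum to 0, mean rate 1)."""
        ex = self.exchangeabilities
        pi = np.asarray(self.base_freqs)
        Q = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for rate, (i, j) in zip(ex, pairs):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.sum(pi * np.diag(Q)))
        return Q / mu

    def category_rates(self) -> np.ndarray:
        """Equal-probability discrete-Gamma category rates (mean 1)."""
        a = self.gamma_shape
        if a is None or math.isinf(a):
            return np.array([1.0])
        from scipy.stats import gamma as gamma_dist

        k = self.n_categories
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        # mean within each bin: E[X; X<u] = P(Gamma(a+1) < u) since E[X]=1
        upper_mass = gamma_dist.cdf(edges, a + 1, scale=1.0 / a)
        rates = (upper_mass[1:] - upper_mass[:-1]) * k
        return rates / rates.mean()

    def eigensystem(self):
        """Spectral decomposition of Q via reversibility symmetrization."""
        Q = self.rate_matrix()
        pi = np.asarray(self.base_freqs)
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]  # D^1/2 Q D^-1/2, symmetric for GTR
        vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
        U = vecs / d[:, None]
        Uinv = vecs.T * d[None, :]
        return vals, U, Uinv


def _transition_matrix(eigensystem, t: float) -> np.ndarray:
    vals, U, Uinv = eigensystem
    P = (U * np.exp(vals * t)[None, :]) @ Uinv
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def evolve_sequences(
    gene_tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: Union[int, np.random.Generator, None],
    coal_to_subst: Optional[float] = None,
) -> Alignment:
    """Simulate a site-i.i.d. alignment down ``gene_tree``.

    If the tree carries coalescent units, ``coal_to_subst`` (expected
    substitutions/site per coalescent unit) is required and is applied to
    every branch; substitution-unit trees are used as-is.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if gene_tree.units == "coalescent":
        if coal_to_subst is None:
            raise ValueError(
                "tree is in coalescent units: pass coal_to_subst to rescale"
            )
        scale = float(coal_to_subst)
    else:
        scale = 1.0 if coal_to_subst is None else float(coal_to_subst)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    eig = model.eigensystem()
    rates = model.category_rates()
    k = len(rates)
    pi = np.asarray(model.base_freqs)

    site_cat = rng.integers(0, k, size=n_sites) if k > 1 else np.zeros(n_sites, dtype=int)
    states: dict = {}
    root_states = rng.choice(4, size=n_sites, p=pi)
    states[gene_tree.root] = root_states

    out: dict[str, str] = {}
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    for node in gene_tree.iter_nodes("preorder"):
        if node is gene_tree.root:
            pass
        else:
            t = (node.length or 0.0) * scale
            if node.is_leaf and node.label in model.lineage_rate_multipliers:
                t *= float(model.lineage_rate_multipliers[node.label])
            parent_states = states[node.parent]
            child_states = np.empty(n_sites, dtype=np.int64)
            if t <= 0:
                child_states[:] = parent_states
            else:
                for c in range(k):
                    mask = site_cat == c
                    if not mask.any():
                        continue
                    P = _transition_matrix(eig, t * rates[c])
                    cum = np.cumsum(P, axis=1)
                    u = rng.random(int(mask.sum()))
                    rows = cum[parent_states[mask]]
                    child_states[mask] = (rows < u[:, None]).sum(axis=1)
            states[node] = child_states
        if node.is_leaf:
            out[node.label] = base_arr[states[node]].tobytes().decode()
        # free parent state arrays lazily; trees are small so keep simple
    return Alignment(out)


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

Profile = Union[float, Sequence[float], Callable[[np.random.Generator], float]]


def inject_missingness(
    aln: Alignment,
    column_missing_profile: Profile,
    seed: Union[int, np.random.Generator, None],
) -> tuple[Alignment, list[float]]:
    """Replace random cells by '-' following a per-column missing-fraction
    profile; returns the new alignment and the realized per-column
    missing fraction (sidecar table)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if callable(column_missing_profile):
        draw = column_missing_profile
    elif np.isscalar(column_missing_profile):
        f = float(column_missing_profile)
        draw = lambda r: f  # noqa: E731
    else:
        choices = np.asarray(column_missing_profile, dtype=float)
        draw = lambda r: float(r.choice(choices))  # noqa: E731

    labels = aln.labels
    grid = np.array([list(aln[l]) for l in labels], dtype="U1")
    n_taxa, n_sites = grid.shape
    realized = []
    for j in range(n_sites):
        f = draw(rng)
        if f > 0:
            mask = rng.random(n_taxa) < f
            grid[mask, j] = "-"
        realized.append(float(np.isin(grid[:, j], list("N-?")).mean()))
    rows = {lbl: "".join(grid[i]) for i, lbl in enumerate(labels)}
    return Alignment(rows), realized
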