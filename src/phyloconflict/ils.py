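"""ILS assessment: tree-distance distributions against an MSC null and
node-wise attribution of cyto-nuclear conflicts to coalescent variance."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SpeciesTreeModel, simulate_gene_tree
from .trees import (
    Bipartition,
    PhyloTree,
    bipartitions,
    max_rf_distance,
    restrict_to_taxa,
    rf_distance,
)
from .concordance import species_tree_splits

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceDistribution",
    "DistributionComparison",
    "ConflictAttribution",
    "distance_distribution",
    "compare_distributions",
    "attribute_conflicts",
]


@dataclass
class DistanceDistribution:
    source: str  # "empirical" | "simulated"
    values: list[int]
    reference_id: str
    n_leaves: int

    def __post_init__(self):
        cap = max_rf_distance(self.n_leaves)
        bad = [v for v in self.values if v < 0 or v > cap]
        if bad:
            raise ValueError(f"RF values out of range [0, {cap}]: {bad[:5]}")


def distance_distribution(
    trees: Sequence[PhyloTree],
    reference: PhyloTree,
    source: str = "empirical",
    reference_id: str = "species",
) -> DistanceDistribution:
    """RF distance of each tree to the reference, order-preserving.

    Trees with a leaf subset are compared on the shared taxa (recorded)."""
    ref_taxa = set(reference.leaf_labels())
    values = []
    n_restricted = 0
    for tree in trees:
        taxa = set(tree.leaf_labels())
        if taxa == ref_taxa:
            values.append(rf_distance(tree, reference))
        else:
            shared = taxa & ref_taxa
            if len(shared) < 4:
                raise ValueError("fewer than 4 shared taxa with reference")
            n_restricted += 1
            values.append(
                rf_distance(restrict_to_taxa(tree, shared), restrict_to_taxa(reference, shared))
            )
    if n_restricted:
        logger.info("distance_distribution: %d/%d trees restricted to shared taxa",
                    n_restricted, len(trees))
    return DistanceDistribution(
        source=source,
        values=values,
        reference_id=reference_id,
        n_leaves=len(ref_taxa),
    )


@dataclass
class DistributionComparison:
    bins: np.ndarray
    empirical_hist: np.ndarray
    simulated_hist: np.ndarray
    empirical_mean: float
    simulated_mean: float
    empirical_var: float
    simulated_var: float
    overlap: float
    ks_statistic: float
    ks_pvalue: float
    verdict: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rf": self.bins,
                "empirical": self.empirical_hist,
                "simulated": self.simulated_hist,
            }
        )


def compare_distributions(
    empirical: DistanceDistribution,
    simulated: DistanceDistribution,
    overlap_threshold: float = 0.5,
) -> DistributionComparison:
    """Histogram + moment + overlap + two-sample KS comparison.

    Overlap is the shared-bin coefficient sum(min(p_emp, p_sim)); the
    verdict text calls ILS a plausible primary driver when the overlap
    reaches ``overlap_threshold``.
    """
    if empirical.reference_id != simulated.reference_id:
        raise ValueError("distributions computed against different reference trees")
    if not empirical.values or not simulated.values:
        raise ValueError("cannot compare an empty distance distribution")
    e = np.asarray(empirical.values)
    s = np.asarray(simulated.values)
    top = int(max(e.max(), s.max()))
    bins = np.arange(0, top + 1)
    eh = np.bincount(e, minlength=top + 1) / len(e)
    sh = np.bincount(s, minlength=top + 1) / len(s)
    overlap = float(np.minimum(eh, sh).sum())
    ks = stats.ks_2samp(e, s, method="asymp")
    verdict = (
        "ILS plausible as primary driver"
        if overlap >= overlap_threshold
        else "poor fit to MSC: ILS alone unlikely"
    )
    return DistributionComparison(
        bins=bins,
        empirical_hist=eh,
        simulated_hist=sh,
        empirical_mean=float(e.mean()),
        simulated_mean=float(s.mean()),
        empirical_var=float(e.var(ddof=1)) if len(e) > 1 else 0.0,
        simulated_var=float(s.var(ddof=1)) if len(s) > 1 else 0.0,
        overlap=overlap,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        verdict=verdict,
    )


@dataclass
class ConflictAttribution:
    node_id: str
    bipartition: Bipartition
    fraction: float
    se: float
    n_simulated: int
    verdict: str

    def __post_init__(self):
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction outside [0, 1]")


def attribute_conflicts(
    nuclear_species: SpeciesTreeModel,
    plastid: PhyloTree,
    n_sim: int = 10_000,
    seed: Union[int, np.random.Generator, None] = None,
    ils_threshold: float = 0.05,
) -> list[ConflictAttribution]:
    """For each plastid split conflicting with the nuclear species tree,
    the fraction of MSC-simulated gene trees that contain it.

    A fraction of at least ``ils_threshold`` is reported as ILS-plausible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nuc_tree = nuclear_species.tree
    nuc_taxa = set(nuc_tree.leaf_labels())
    pla_taxa = set(plastid.leaf_labels())
    shared = nuc_taxa & pla_taxa
    if len(shared) < 4:
        raise ValueError("nuclear and plastid trees share fewer than 4 taxa")
    plastid_shared = plastid if pla_taxa == shared else restrict_to_taxa(plastid, shared)
    nuc_shared = nuc_tree if nuc_taxa == shared else restrict_to_taxa(nuc_tree, shared)
    nuclear_bips = bipartitions(nuc_shared)

    conflicts = {
        nid: bip
        for nid, bip in species_tree_splits(plastid_shared).items()
        if bip not in nuclear_bips
    }
    if not conflicts:
        logger.info("plastid topology congruent with nuclear tree: nothing to attribute")
        return []

    hits = {nid: 0 for nid in conflicts}
    restrict = nuc_taxa != shared
    for _ in range(n_sim):
        gtree = simulate_gene_tree(nuclear_species, seed=rng)
        if restrict:
            gtree = restrict_to_taxa(gtree, shared)
        gbips = bipartitions(gtree)
        for nid, bip in conflicts.items():
            if bip in gbips:
                hits[nid] += 1

    out = []
    for nid, bip in conflicts.items():
        f = hits[nid] / n_sim
        se = math.sqrt(f * (1 - f) / n_sim)
        out.append(
            ConflictAttribution(
                node_id=nid,
                bipartition=bip,
                fraction=f,
                se=se,
                n_simulated=n_sim,
                verdict="ILS plausible" if f >= ils_threshold else "ILS implausible",
            )
        )
    return out


def attributions_to_dataframe(attribs: Sequence[ConflictAttribution]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                node=a.node_id,
                bipartition=str(a.bipartition),
                fraction=a.fraction,
                se=a.se,
                n_simulated=a.n_simulated,
                verdict=a.verdict,
            )
            for a in attribs
        ]
    )
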