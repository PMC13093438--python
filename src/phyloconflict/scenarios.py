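"""Self-contained test scenarios: species tree + optional reticulation +
gene trees + alignments + orthogroup occupancy, written as a plain-text
bundle so the full pipeline can run without any external data.

Scenario names:

``adonis_like``
    10 ingroup taxa + outgroup, one extra hybrid taxon with inheritance
    probability gamma = 0.6 between two non-sister parents, a subclade
    with short internal branches (ILS-rich), mild taxon dropout and
    column missingness.
``no_hybrid``
    The same backbone with no reticulation and clean data; used for
    type-I-error calibration.
``rate_artifact``
    No reticulation, but one lineage evolves 5x faster; used to exercise
    long-branch flagging and the null-simulation false-positive filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .alignment import Alignment
from .simulate import (
    HybridEvent,
    SpeciesTreeModel,
    SubstitutionModel,
    evolve_sequences,
    inject_missingness,
    simulate_gene_tree,
    simulate_network_gene_tree,
)
from .trees import PhyloTree, parse_newick, write_newick

SCENARIOS = ("adonis_like", "no_hybrid", "rate_artifact")

#: ultrametric backbone, heights in coalescent units (ILS-rich left clade)
BACKBONE_NEWICK = (
    "((((t1:0.4,t2:0.4):0.6,(t3:0.6,t4:0.6):0.4):5.0,"
    "((t5:1.6,(t6:0.8,t7:0.8):0.8):1.4,"
    "(t8:1.6,(t9:0.8,t10:0.8):0.8):1.4):3.0):4.0,OUT:10.0);"
)

#: the backbone with the hybrid grafted as sister to its majority parent
#: (what a tree-only analysis would estimate for the adonis_like data)
BACKBONE_WITH_HYBRID_NEWICK = (
    "((((t1:0.4,t2:0.4):0.6,(t3:0.6,t4:0.6):0.4):5.0,"
    "(((t5:1.0,hyb:1.0):0.6,(t6:0.8,t7:0.8):0.8):1.4,"
    "(t8:1.6,(t9:0.8,t10:0.8):0.8):1.4):3.0):4.0,OUT:10.0);"
)

OUTGROUP = "OUT"

#: default coalescent-unit -> substitutions/site rescaling
DEFAULT_COAL_TO_SUBST = 0.02

DEFAULT_SUBSTITUTION = dict(
    exchangeabilities=(1.0, 2.5, 1.0, 1.0, 2.5, 1.0),
    base_freqs=(0.3, 0.2, 0.2, 0.3),
    gamma_shape=1.0,
    n_categories=4,
)


@dataclass
class ScenarioBundle:
    """All artifacts of one simulated scenario plus its ground truth."""

    name: str
    seed: int
    species_model: SpeciesTreeModel
    hybrid_event: Optional[HybridEvent]
    substitution_model: SubstitutionModel
    gene_trees: dict[str, PhyloTree]
    alignments: dict[str, Alignment]
    orthogroups: pd.DataFrame  # genes x samples, 0/1
    individual_map: dict[str, str]  # individual -> taxon
    manifest: dict = field(default_factory=dict)

    @property
    def outgroup(self) -> str:
        return self.manifest.get("outgroup", OUTGROUP)

    def write(self, path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "species.nwk").write_text(write_newick(self.species_model.tree) + "\n")
        with open(path / "genetrees.nwk", "w") as fh:
            for gid in sorted(self.gene_trees):
                fh.write(write_newick(self.gene_trees[gid]) + "\n")
        aln_dir = path / "aln"
        aln_dir.mkdir(exist_ok=True)
        for gid in sorted(self.alignments):
            self.alignments[gid].write(aln_dir / f"{gid}.fasta")
        self.orthogroups.to_csv(path / "orthogroups.tsv", sep="\t")
        with open(path / "map.tsv", "w") as fh:
            fh.write("individual\ttaxon\n")
            for ind, taxon in sorted(self.individual_map.items()):
                fh.write(f"{ind}\t{taxon}\n")
        with open(path / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def _scenario_config(name: str) -> dict:
    if name == "adonis_like":
        return dict(
            n_genes=100,
            n_sites=500,
            hybrid=dict(
                hybrid="hyb", parent1="t5", parent2="t8", gamma=0.6,
                attach_time1=1.0, attach_time2=1.0,
            ),
            dropout=0.05,
            missing_profile=(0.0,) * 18 + (0.1, 0.25),
            rate_multipliers={},
        )
    if name == "no_hybrid":
        # many short loci: the invariants test assumes coalescent-
        # independent sites, so the calibration bundle approximates it
        return dict(
            n_genes=800,
            n_sites=50,
            hybrid=None,
            dropout=0.0,
            missing_profile=None,
            rate_multipliers={},
        )
    if name == "rate_artifact":
        # shorter loci keep the linked-site variance inflation of the
        # invariants test small without weakening the homoplasy artifact
        return dict(
            n_genes=400,
            n_sites=125,
            hybrid=None,
            dropout=0.0,
            missing_profile=None,
            rate_multipliers={"t3": 5.0},
        )
    raise ValueError(f"unknown scenario {name!r}; valid names: {list(SCENARIOS)}")


def make_scenario(
    name: str,
    seed: int,
    n_genes: Optional[int] = None,
    n_sites: Optional[int] = None,
    coal_to_subst: float = DEFAULT_COAL_TO_SUBST,
) -> ScenarioBundle:
    """Build a scenario bundle deterministically from ``seed``.

    Per-gene randomness uses hierarchically split streams keyed by
    (seed, gene index, stage) so adding genes never perturbs earlier ones.
    """
    cfg = _scenario_config(name)
    if n_genes is not None:
        cfg["n_genes"] = int(n_genes)
    if n_sites is not None:
        cfg["n_sites"] = int(n_sites)

    species = parse_newick(BACKBONE_NEWICK, units="coalescent")
    model = SpeciesTreeModel(species)
    event = HybridEvent(**cfg["hybrid"]) if cfg["hybrid"] else None
    # the "analysis" species tree is what a tree-only method would infer:
    # with a reticulation present, the hybrid appears as sister to its
    # majority parent
    if event is not None:
        analysis_model = SpeciesTreeModel(
            parse_newick(BACKBONE_WITH_HYBRID_NEWICK, units="coalescent")
        )
    else:
        analysis_model = model
    subst = SubstitutionModel(
        **DEFAULT_SUBSTITUTION, lineage_rate_multipliers=dict(cfg["rate_multipliers"])
    )

    taxa = sorted(species.leaf_labels()) + ([event.hybrid] if event else [])
    ingroup = [t for t in taxa if t != OUTGROUP]

    gene_trees: dict[str, PhyloTree] = {}
    alignments: dict[str, Alignment] = {}
    presence_rows = {}
    for gi in range(cfg["n_genes"]):
        gid = f"gene_{gi:04d}"
        rng_tree = np.random.default_rng([seed, gi, 0])
        rng_seq = np.random.default_rng([seed, gi, 1])
        rng_post = np.random.default_rng([seed, gi, 2])
        if event is not None:
            gtree = simulate_network_gene_tree(model, event, seed=rng_tree)
        else:
            gtree = simulate_gene_tree(model, seed=rng_tree)
        aln = evolve_sequences(
            gtree, subst, cfg["n_sites"], seed=rng_seq, coal_to_subst=coal_to_subst
        )
        keep = list(aln.labels)
        if cfg["dropout"] > 0:
            kept_ingroup = [
                t for t in ingroup if not (rng_post.random() < cfg["dropout"])
            ]
            keep = [OUTGROUP] + kept_ingroup
            if len(keep) < 4:
                keep = list(aln.labels)
            aln = aln.subset([t for t in aln.labels if t in keep])
        if cfg["missing_profile"] is not None:
            aln, _ = inject_missingness(aln, cfg["missing_profile"], seed=rng_post)
        gene_trees[gid] = gtree
        alignments[gid] = aln
        presence_rows[gid] = {t: int(t in aln.rows) for t in taxa}

    orthogroups = pd.DataFrame.from_dict(presence_rows, orient="index")[taxa]
    orthogroups.index.name = "gene"
    individual_map = {t: t for t in taxa}

    manifest = {
        "scenario": name,
        "seed": seed,
        "outgroup": OUTGROUP,
        "n_genes": cfg["n_genes"],
        "n_sites": cfg["n_sites"],
        "coal_to_subst": coal_to_subst,
        "species_tree_true": write_newick(species),
        "species_tree_analysis": write_newick(analysis_model.tree),
        "substitution_model": {
            "exchangeabilities": list(subst.exchangeabilities),
            "base_freqs": list(subst.base_freqs),
            "gamma_shape": subst.gamma_shape,
            "n_categories": subst.n_categories,
            "lineage_rate_multipliers": dict(subst.lineage_rate_multipliers),
        },
        "dropout": cfg["dropout"],
        "missing_profile": list(cfg["missing_profile"]) if cfg["missing_profile"] else None,
    }
    if event is not None:
        manifest["hybrid_event"] = {
            "hybrid": event.hybrid,
            "parent1": event.parent1,
            "parent2": event.parent2,
            "gamma": event.gamma,
            "attach_time1": event.attach_time1,
            "attach_time2": event.attach_time2,
        }

    return ScenarioBundle(
        name=name,
        seed=seed,
        species_model=analysis_model,
        hybrid_event=event,
        substitution_model=subst,
        gene_trees=gene_trees,
        alignments=alignments,
        orthogroups=orthogroups,
        individual_map=individual_map,
        manifest=manifest,
    )
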