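"""End-to-end analysis pipeline: filtering -> concordance -> ILS
assessment -> hybridization scan -> null filtering -> reports.

The pipeline consumes a bundle directory (``species.nwk``,
``genetrees.nwk``, ``aln/*.fasta``, ``orthogroups.tsv``, ``map.tsv``)
and writes TSV/Newick/JSON artifacts plus a manifest into an output
directory. Every stochastic stage derives its stream from the single
config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alignment import Alignment
from .concordance import map_concordance, prepare_cloud_trees
from .filters import (
    OrthogroupTable,
    concatenate_alignments,
    filter_alignment_columns,
    filter_by_abs,
    filter_by_occupancy,
    flag_long_branches,
    partition_by_length,
    partition_table_to_raxml,
    screen_organellar,
)
from .hyde import (
    estimate_lineage_rate_multipliers,
    node_mode,
    null_hypothesis_filter,
    results_to_dataframe,
    scan_triples,
)
from .ils import (
    attribute_conflicts,
    attributions_to_dataframe,
    compare_distributions,
    distance_distribution,
)
from .nj import estimate_gene_tree_nj
from .records import GeneTreeRecord
from .simulate import SpeciesTreeModel, SubstitutionModel, simulate_gene_tree
from .trees import (
    parse_newick,
    parse_newick_list,
    write_newick,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Invalid analysis configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Thresholds, paths and simulation settings for one pipeline run."""

    bundle_dir: str = "."
    output_dir: str = "out"
    plastid_tree: Optional[str] = None
    organelle_reference: Optional[str] = None

    occupancy_fraction: float = 0.70
    column_missing_max: float = 0.20
    length_classes: tuple = (1000, 2000)
    abs_threshold: float = 60.0
    support_collapse: float = 50.0
    long_branch_factor: float = 5.0
    alpha: float = 0.05
    correction: str = "bonferroni"
    null_cutoff: float = 0.05
    ils_threshold: float = 0.05

    n_sim: int = 10_000
    null_replicates: int = 20
    seed: int = 1

    estimate_gene_trees: bool = False
    n_bootstrap: int = 100
    coal_to_subst: float = 0.02
    node_mode_target: Optional[Sequence[str]] = None

    def validate(self) -> None:
        checks = [
            (0 < self.occupancy_fraction <= 1, "occupancy_fraction in (0,1]"),
            (0 <= self.column_missing_max <= 1, "column_missing_max in [0,1]"),
            (0 < self.alpha < 1, "alpha in (0,1)"),
            (self.correction in ("bonferroni", "none"), "correction bonferroni|none"),
            (0 <= self.null_cutoff <= 1, "null_cutoff in [0,1]"),
            (self.n_sim > 0, "n_sim > 0"),
            (self.null_replicates >= 20, "null_replicates >= 20"),
            (tuple(self.length_classes) == tuple(sorted(self.length_classes)),
             "length_classes sorted ascending"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_classes"] = list(self.length_classes)
        if self.node_mode_target is not None:
            d["node_mode_target"] = list(self.node_mode_target)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def load_bundle(bundle_dir) -> dict:
    """Read a bundle directory into memory."""
    bundle = Path(bundle_dir)
    species = parse_newick((bundle / "species.nwk").read_text(), units="coalescent")
    gene_trees = parse_newick_list((bundle / "genetrees.nwk").read_text())
    alignments = {}
    for fa in sorted((bundle / "aln").glob("*.fasta")):
        alignments[fa.stem] = Alignment.read(fa, "fasta")
    orthogroups = OrthogroupTable.read_tsv(bundle / "orthogroups.tsv")
    taxon_map = {}
    for line in (bundle / "map.tsv").read_text().splitlines()[1:]:
        ind, taxon = line.split("\t")
        taxon_map[ind] = taxon
    manifest_path = bundle / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    return dict(
        species=species,
        gene_trees=gene_trees,
        alignments=alignments,
        orthogroups=orthogroups,
        taxon_map=taxon_map,
        manifest=manifest,
        files=sorted(str(p.relative_to(bundle)) for p in bundle.rglob("*") if p.is_file()),
    )


def run_pipeline(config: AnalysisConfig) -> Path:
    """Execute all stages; returns the output directory.

    Any stage failure aborts with :class:`StageError` after writing a
    ``failed/<stage>`` marker; completed artifacts are retained.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        bundle = load_bundle(config.bundle_dir)
        applied_defaults: list[str] = []

        stage = "filter"
        artifacts = _stage_filter(config, bundle, out, applied_defaults)

        stage = "concordance"
        _stage_concordance(config, bundle, artifacts, out)

        stage = "ils"
        _stage_ils(config, bundle, artifacts, out)

        stage = "hyde"
        _stage_hyde(config, bundle, artifacts, out)

        stage = "nullfilter"
        _stage_nullfilter(config, bundle, artifacts, out)

        stage = "report"
        from .report import render_reports

        render_reports(out)

        stage = "manifest"
        bundle_dir = Path(config.bundle_dir)
        manifest = dict(
            version=__version__,
            config=config.to_dict(),
            inputs={f: _sha256(bundle_dir / f) for f in bundle["files"]},
            outputs=sorted(
                str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
            ),
            applied_defaults=applied_defaults,
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / stage).write_text(f"{type(exc).__name__}: {exc}\n")
        raise StageError(stage, exc) from exc
    return out


def _stage_filter(config, bundle, out: Path, applied_defaults: list) -> dict:
    table = filter_by_occupancy(bundle["orthogroups"], config.occupancy_fraction)
    kept_genes = [g for g in table.genes if g in bundle["alignments"]]

    if config.organelle_reference:
        refs = list(Alignment.read(config.organelle_reference, "fasta").rows.values())
        gene_seqs = {
            g: next(iter(bundle["alignments"][g].rows.values())) for g in kept_genes
        }
        kept_map, _, screen_report = screen_organellar(gene_seqs, refs)
        _write_tsv(screen_report, out / "organelle_screen.tsv")
        kept_genes = [g for g in kept_genes if g in kept_map]
    else:
        applied_defaults.append("organelle screen skipped (no reference given)")

    trimmed: dict[str, Alignment] = {}
    trim_rows = []
    for g in kept_genes:
        aln, kept_cols = filter_alignment_columns(
            bundle["alignments"][g], config.column_missing_max
        )
        if aln.n_sites == 0:
            continue
        trimmed[g] = aln
        trim_rows.append((g, bundle["alignments"][g].n_sites, aln.n_sites))
    _write_tsv(
        pd.DataFrame(trim_rows, columns=["gene", "n_sites_raw", "n_sites_trimmed"]),
        out / "column_trim.tsv",
    )

    classes = partition_by_length(trimmed, list(config.length_classes))
    class_rows = [(t, len(g)) for t, g in classes.items()]
    _write_tsv(pd.DataFrame(class_rows, columns=["min_length", "n_genes"]),
               out / "length_classes.tsv")
    # analysis set: the smallest length class (most inclusive)
    analysis = classes[min(classes)] if classes else trimmed

    records: list[GeneTreeRecord] = []
    if config.estimate_gene_trees:
        for gi, g in enumerate(sorted(analysis)):
            rec = estimate_gene_tree_nj(
                analysis[g], n_bootstrap=config.n_bootstrap,
                seed=int(np.random.default_rng([config.seed, 101, gi]).integers(2**31)),
                gene_id=g,
            )
            records.append(rec)
    else:
        name_by_index = sorted(bundle["alignments"])
        for idx, tree in enumerate(bundle["gene_trees"]):
            gid = name_by_index[idx] if idx < len(name_by_index) else f"tree_{idx}"
            if gid not in analysis:
                continue
            rec = GeneTreeRecord(gene_id=gid, tree=tree,
                                 alignment_length=analysis[gid].n_sites)
            try:
                rec.recompute_abs()
            except ValueError:
                rec.abs_support = None
            records.append(rec)

    have_abs = all(r.abs_support is not None for r in records) and records
    if have_abs:
        records = filter_by_abs(records, config.abs_threshold)
    else:
        applied_defaults.append("ABS filter skipped (gene trees carry no supports)")

    flag_rows = []
    for rec in records:
        _, flagged = flag_long_branches(rec, factor=config.long_branch_factor)
        for taxon in flagged:
            flag_rows.append((rec.gene_id, taxon))
    _write_tsv(pd.DataFrame(flag_rows, columns=["gene", "taxon"]),
               out / "long_branches.tsv")

    taxa = sorted({t for a in analysis.values() for t in a.labels})
    supermatrix, partitions = concatenate_alignments(
        {g: analysis[g] for g in sorted(analysis)}, taxa
    )
    supermatrix.write(out / "supermatrix.fasta")
    (out / "partitions.txt").write_text(partition_table_to_raxml(partitions))

    abs_rows = [(r.gene_id, r.abs_support if r.abs_support is not None else float("nan"))
                for r in records]
    _write_tsv(pd.DataFrame(abs_rows, columns=["gene", "abs"]), out / "gene_abs.tsv")
    return dict(
        records=records,
        analysis_alignments=analysis,
        supermatrix=supermatrix,
        taxa=taxa,
    )


def _stage_concordance(config, bundle, artifacts, out: Path) -> None:
    species = bundle["species"]
    records = artifacts["records"]
    summary = map_concordance(species, records, support_collapse=config.support_collapse)
    _write_tsv(summary.to_dataframe(), out / "concordance.tsv")
    (out / "species_for_report.nwk").write_text(write_newick(species) + "\n")
    cloud, excluded = prepare_cloud_trees(records, species.leaf_labels())
    with open(out / "cloud_trees.nwk", "w") as fh:
        for tree in cloud:
            fh.write(write_newick(tree) + "\n")
    (out / "cloud_excluded.txt").write_text("\n".join(excluded) + ("\n" if excluded else ""))
    artifacts["concordance"] = summary


def _stage_ils(config, bundle, artifacts, out: Path) -> None:
    species = bundle["species"]
    model = SpeciesTreeModel(species)
    rng = np.random.default_rng([config.seed, 7])
    simulated = [simulate_gene_tree(model, seed=rng) for _ in range(config.n_sim)]
    emp = distance_distribution(
        [r.tree for r in artifacts["records"]], species, source="empirical"
    )
    sim = distance_distribution(simulated, species, source="simulated")
    comparison = compare_distributions(emp, sim)
    _write_tsv(comparison.to_dataframe(), out / "distance_histogram.tsv")
    summary = pd.DataFrame(
        [dict(
            empirical_mean=comparison.empirical_mean,
            simulated_mean=comparison.simulated_mean,
            empirical_var=comparison.empirical_var,
            simulated_var=comparison.simulated_var,
            overlap=comparison.overlap,
            ks_statistic=comparison.ks_statistic,
            ks_pvalue=comparison.ks_pvalue,
            verdict=comparison.verdict,
        )]
    )
    _write_tsv(summary, out / "distance_comparison.tsv")

    if config.plastid_tree:
        plastid = parse_newick(Path(config.plastid_tree).read_text())
        attribs = attribute_conflicts(
            model, plastid, n_sim=config.n_sim,
            seed=np.random.default_rng([config.seed, 8]),
            ils_threshold=config.ils_threshold,
        )
        _write_tsv(attributions_to_dataframe(attribs), out / "conflict_attribution.tsv")


def _stage_hyde(config, bundle, artifacts, out: Path) -> None:
    manifest = bundle.get("manifest", {})
    outgroup = manifest.get("outgroup", "OUT")
    results = scan_triples(
        artifacts["supermatrix"], bundle["taxon_map"], outgroup,
        alpha=config.alpha, correction=config.correction,
        seed=config.seed,
    )
    _write_tsv(results_to_dataframe(results), out / "hyde_results.tsv")
    artifacts["hyde_results"] = results
    artifacts["outgroup"] = outgroup

    sig = [r for r in results if r.significant and not r.suspect]
    target = config.node_mode_target
    if target is None and sig:
        # default target: the hybrid taxon with most significant tests
        counts: dict[str, int] = {}
        for r in sig:
            counts[r.hybrid] = counts.get(r.hybrid, 0) + 1
        target = [max(counts, key=lambda t: (counts[t], t))]
    if target:
        heat = node_mode(results, bundle["species"], target)
        heat.mean.to_csv(out / "node_mode_gamma.tsv", sep="\t", float_format=FLOAT_FMT)
        heat.count.to_csv(out / "node_mode_count.tsv", sep="\t")
        with open(out / "node_mode_summary.tsv", "w") as fh:
            fh.write("parent\tgamma\n")
            for taxon, txt in heat.parent_summary.items():
                fh.write(f"{taxon}\t{txt}\n")


def _stage_nullfilter(config, bundle, artifacts, out: Path) -> None:
    results = artifacts["hyde_results"]
    sig = [r for r in results if r.significant]
    if not sig:
        _write_tsv(pd.DataFrame(columns=[
            "p1", "hybrid", "p2", "z", "p_value", "gamma_hat",
            "null_rejection_fraction", "verdict"]), out / "null_filter.tsv")
        return
    supermatrix = artifacts["supermatrix"]
    # empirical substitution-unit tree carries any lineage-rate artifacts
    subst_tree = estimate_gene_tree_nj(
        supermatrix, n_bootstrap=0,
        seed=int(np.random.default_rng([config.seed, 9]).integers(2**31)),
        gene_id="supermatrix",
    ).tree
    (out / "supermatrix_nj.nwk").write_text(write_newick(subst_tree) + "\n")
    manifest = bundle.get("manifest", {})
    sm = manifest.get("substitution_model", {})
    model = SubstitutionModel(
        exchangeabilities=tuple(sm.get("exchangeabilities", (1,) * 6)),
        base_freqs=tuple(sm.get("base_freqs", (0.25,) * 4)),
        gamma_shape=sm.get("gamma_shape"),
        n_categories=sm.get("n_categories", 4),
    )
    k = len({t for t in bundle["taxon_map"].values() if t != artifacts["outgroup"]})
    n_tests = k * (k - 1) * (k - 2) // 2 if config.correction == "bonferroni" else 1
    coal_to_subst = manifest.get("coal_to_subst", config.coal_to_subst)
    species_model = SpeciesTreeModel(bundle["species"])
    multipliers = estimate_lineage_rate_multipliers(
        subst_tree, species_model, coal_to_subst
    )
    if multipliers:
        _write_tsv(
            pd.DataFrame(sorted(multipliers.items()),
                         columns=["taxon", "rate_multiplier"]),
            out / "rate_multipliers.tsv",
        )
    gene_sites = [a.n_sites for _, a in sorted(artifacts["analysis_alignments"].items())]
    report = null_hypothesis_filter(
        sig, subst_tree, model, bundle["taxon_map"],
        n_sites=supermatrix.n_sites,
        n_replicates=config.null_replicates,
        seed=int(np.random.default_rng([config.seed, 10]).integers(2**31)),
        alpha=config.alpha,
        correction_tests=n_tests,
        cutoff=config.null_cutoff,
        coalescent_model=species_model,
        gene_sites=gene_sites,
        coal_to_subst=coal_to_subst,
        rate_multipliers=multipliers,
    )
    _write_tsv(report.rows, out / "null_filter.tsv")
    _write_tsv(report.retained(), out / "retained_hybridizations.tsv")
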