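"""SVG figure rendering from pipeline TSV outputs.

Figures are pure views: every number drawn here is read back from the
stage TSVs, never recomputed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .trees import parse_newick

logger = logging.getLogger(__name__)

PIE_COLORS = ["#2b6cb0", "#c53030", "#ed8936", "#a0aec0"]  # conc, top, other, uninf


def render_reports(out_dir) -> list[Path]:
    """Render whatever stage outputs are present; skip the rest."""
    out = Path(out_dir)
    made = []
    for maker, needs in (
        (_concordance_pies, ["concordance.tsv", "..species"]),
        (_distance_histogram, ["distance_histogram.tsv"]),
        (_gamma_heatmap, ["node_mode_gamma.tsv"]),
    ):
        try:
            path = maker(out)
            if path is not None:
                made.append(path)
        except FileNotFoundError as exc:
            logger.warning("report skipped (%s): missing %s", maker.__name__, exc)
    return made


def _tree_layout(tree):
    """Simple rectangular layout: returns x, y per node."""
    xs, ys = {}, {}
    depths = tree.node_depths()
    leaves = tree.leaves()
    for i, leaf in enumerate(leaves):
        ys[leaf] = float(i)
    for node in tree.iter_nodes("postorder"):
        if not node.is_leaf:
            ys[node] = float(np.mean([ys[c] for c in node.children]))
        xs[node] = depths[node]
    return xs, ys


def _concordance_pies(out: Path):
    tsv = out / "concordance.tsv"
    if not tsv.exists():
        raise FileNotFoundError(tsv)
    df = pd.read_csv(tsv, sep="\t")
    species_path = out / "species_for_report.nwk"
    if not species_path.exists():
        # fall back to bundle copy written by the pipeline, else bail
        raise FileNotFoundError(species_path)
    tree = parse_newick(species_path.read_text())
    from .concordance import species_tree_splits

    splits = species_tree_splits(tree)
    by_node = df.set_index("node")
    xs, ys = _tree_layout(tree)
    fig, ax = plt.subplots(figsize=(8, 6))
    for node in tree.iter_nodes():
        if node is tree.root:
            continue
        ax.plot([xs[node.parent], xs[node]], [ys[node], ys[node]], color="k", lw=1)
        ax.plot([xs[node.parent], xs[node.parent]],
                [ys[node.parent], ys[node]], color="k", lw=1)
        if node.is_leaf:
            ax.text(xs[node] + 0.02, ys[node], node.label, va="center", fontsize=8)
    # map internal nodes to split ids
    clusters = {}
    for node in tree.iter_nodes("postorder"):
        clusters[node] = (
            frozenset([node.label]) if node.is_leaf
            else frozenset().union(*(clusters[c] for c in node.children))
        )
    size = max(xs.values()) * 0.035 or 0.05
    for nid, bip in splits.items():
        if nid not in by_node.index:
            continue
        node = next(
            (n for n in tree.iter_nodes()
             if not n.is_leaf and clusters[n] in (bip.block, bip.other_block)),
            None,
        )
        if node is None:
            continue
        row = by_node.loc[nid]
        fracs = [row[f] for f in ("frac_concordant", "frac_top_conflict",
                                  "frac_other_conflict", "frac_uninformative")]
        _draw_pie(ax, xs[node], ys[node], size, fracs)
    ax.set_axis_off()
    path = out / "concordance_pies.svg"
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path


def _draw_pie(ax, x, y, r, fracs):
    start = 90.0
    for frac, color in zip(fracs, PIE_COLORS):
        if frac <= 0:
            continue
        sweep = 360.0 * frac
        wedge = matplotlib.patches.Wedge(
            (x, y), r, start - sweep, start, facecolor=color, edgecolor="k", lw=0.3
        )
        ax.add_patch(wedge)
        start -= sweep


def _distance_histogram(out: Path):
    tsv = out / "distance_histogram.tsv"
    if not tsv.exists():
        raise FileNotFoundError(tsv)
    df = pd.read_csv(tsv, sep="\t")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    width = 0.4
    ax.bar(df["rf"] - width / 2, df["empirical"], width=width,
           label="empirical gene trees", color="#ed8936")
    ax.bar(df["rf"] + width / 2, df["simulated"], width=width,
           label="MSC simulated", color="#2b6cb0")
    ax.set_xlabel("RF distance to species tree")
    ax.set_ylabel("fraction of trees")
    ax.legend(frameon=False)
    path = out / "distance_histogram.svg"
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path


def _gamma_heatmap(out: Path):
    tsv = out / "node_mode_gamma.tsv"
    fig, ax = plt.subplots(figsize=(6, 5))
    if not tsv.exists():
        ax.text(0.5, 0.5, "no significant hybridization tests",
                ha="center", va="center")
        ax.set_axis_off()
        path = out / "gamma_heatmap.svg"
        fig.savefig(path, format="svg")
        plt.close(fig)
        return path
    df = pd.read_csv(tsv, sep="\t", index_col=0)
    data = np.ma.masked_invalid(df.values.astype(float))
    im = ax.imshow(data, cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=90, fontsize=8)
    ax.set_yticks(range(len(df.index)), df.index, fontsize=8)
    ax.set_xlabel("P2")
    ax.set_ylabel("P1")
    fig.colorbar(im, ax=ax, label="mean inheritance probability from P1")
    fig.tight_layout()
    path = out / "gamma_heatmap.svg"
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path
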