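"""Ortholog-set construction filters: occupancy, organellar screening,
column trimming, length classes, mean-bootstrap filtering, long-branch
flagging, and supermatrix concatenation."""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment
from .records import GeneTreeRecord
from .trees import restrict_to_taxa

logger = logging.getLogger(__name__)

__all__ = [
    "OrthogroupTable",
    "GeneTreeRecord",
    "filter_by_occupancy",
    "screen_organellar",
    "filter_alignment_columns",
    "partition_by_length",
    "filter_by_abs",
    "flag_long_branches",
    "concatenate_alignments",
]

_ABSENT_TOKENS = {"", "*", "0", "nan", "na"}


@dataclass
class OrthogroupTable:
    """Gene-by-sample presence table (Proteinortho-like layout)."""

    presence: pd.DataFrame  # bool; index = gene ids, columns = sample ids

    def __post_init__(self):
        self.presence = self.presence.astype(bool)

    @property
    def n_samples(self) -> int:
        return self.presence.shape[1]

    @property
    def n_genes(self) -> int:
        return self.presence.shape[0]

    @property
    def genes(self) -> list[str]:
        return list(self.presence.index)

    def occupancy(self) -> pd.Series:
        return self.presence.sum(axis=1)

    @classmethod
    def read_tsv(cls, path) -> "OrthogroupTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        # drop Proteinortho bookkeeping columns when present
        drop = [c for c in df.columns if c.lower() in {"genes", "alg.-conn.", "species", "# species"}]
        df = df.drop(columns=drop)
        present = df.map(
            lambda v: str(v).strip().lower() not in _ABSENT_TOKENS
        )
        return cls(presence=present)

    def write_tsv(self, path) -> None:
        self.presence.astype(int).to_csv(path, sep="\t")


def filter_by_occupancy(table: OrthogroupTable, min_fraction: float) -> OrthogroupTable:
    """Keep genes present in at least floor(min_fraction * n_samples) samples.

    The floor makes fraction 0.70 of 47 samples reproduce a cutoff of 32.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    if table.n_genes == 0:
        warnings.warn("empty orthogroup table", stacklevel=2)
        return table
    threshold = math.floor(min_fraction * table.n_samples)
    logger.info(
        "occupancy filter: n_samples=%d fraction=%.3g -> threshold=%d samples",
        table.n_samples, min_fraction, threshold,
    )
    keep = table.occupancy() >= threshold
    return OrthogroupTable(presence=table.presence.loc[keep])


def _kmers(seq: str, k: int) -> set[str]:
    seq = seq.upper().replace("-", "").replace("?", "")
    return {seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]}


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def screen_organellar(
    genes: Mapping[str, str],
    organelle_refs: Iterable[str],
    k: int = 21,
    min_shared_frac: float = 0.5,
) -> tuple[dict, dict, pd.DataFrame]:
    """Flag genes that look organelle-derived by exact k-mer containment.

    A gene is removed when the fraction of its k-mers found in any
    reference (either strand) reaches ``min_shared_frac``. Genes shorter
    than ``k`` are kept with a warning.
    """
    if k < 11:
        raise ValueError("k must be >= 11 for a meaningful containment screen")
    refs = list(organelle_refs)
    if not refs:
        raise ValueError("need at least one organelle reference sequence")
    ref_kmers: set[str] = set()
    for ref in refs:
        ref_kmers |= _kmers(ref, k)
        ref_kmers |= _kmers(_revcomp(ref.upper().replace("-", "")), k)

    kept, removed, rows = {}, {}, []
    for gid, seq in genes.items():
        mers = _kmers(seq, k)
        if not mers:
            warnings.warn(f"gene {gid!r} shorter than k={k}; kept unscreened", stacklevel=2)
            kept[gid] = seq
            rows.append((gid, 0, float("nan"), "kept"))
            continue
        shared = len(mers & ref_kmers) / len(mers)
        if shared >= min_shared_frac:
            removed[gid] = seq
            rows.append((gid, len(mers), shared, "removed"))
        else:
            kept[gid] = seq
            rows.append((gid, len(mers), shared, "kept"))
    report = pd.DataFrame(rows, columns=["gene", "n_kmers", "shared_frac", "verdict"])
    return kept, removed, report


def filter_alignment_columns(
    aln: Alignment, max_missing_frac: float = 0.2
) -> tuple[Alignment, list[int]]:
    """Delete columns whose missing fraction is strictly greater than
    ``max_missing_frac``; returns the trimmed alignment and the 0-based
    indices of surviving columns (provenance map)."""
    if not (0 <= max_missing_frac <= 1):
        raise ValueError("max_missing_frac must be in [0, 1]")
    fracs = aln.column_missing_fractions()
    kept = [i for i, f in enumerate(fracs) if f <= max_missing_frac + 1e-12]
    if not kept:
        warnings.warn("all columns removed by missing-data trimming", stacklevel=2)
        return Alignment({lbl: "" for lbl in aln.labels}), []
    return aln.take_columns(kept), kept


def partition_by_length(
    alns: Mapping[str, Alignment], min_lengths: Sequence[int]
) -> dict[int, dict[str, Alignment]]:
    """One (non-disjoint) class per threshold: genes with length >= it."""
    thresholds = list(min_lengths)
    if thresholds != sorted(thresholds):
        raise ValueError("min_lengths must be sorted ascending")
    return {
        t: {gid: a for gid, a in alns.items() if a.n_sites >= t and a.n_sites > 0}
        for t in thresholds
    }


def filter_by_abs(records: Sequence[GeneTreeRecord], threshold: float) -> list[GeneTreeRecord]:
    """Keep records whose ABS strictly exceeds ``threshold``."""
    for rec in records:
        if rec.abs_support is None:
            raise ValueError(f"record {rec.gene_id!r} lacks an ABS value")
    return [rec for rec in records if rec.abs_support > threshold]


def flag_long_branches(
    record: GeneTreeRecord, factor: float = 5.0, prune: bool = False
) -> tuple[Optional[GeneTreeRecord], list[str]]:
    """Flag leaves whose pendant branch exceeds ``factor`` x the median
    pendant branch; optionally prune them. Returns (record, flagged); the
    record is None when pruning leaves fewer than 4 taxa."""
    tree = record.tree
    pendants = {leaf.label: (leaf.length or 0.0) for leaf in tree.leaves()}
    med = float(np.median(list(pendants.values())))
    if med <= 0:
        return record, []
    flagged = sorted(lbl for lbl, ln in pendants.items() if ln > factor * med)
    if not prune or not flagged:
        return record, flagged
    remaining = [lbl for lbl in pendants if lbl not in flagged]
    if len(remaining) < 4:
        warnings.warn(
            f"gene {record.gene_id!r} dropped: fewer than 4 leaves after pruning",
            stacklevel=2,
        )
        return None, flagged
    pruned = restrict_to_taxa(tree, remaining)
    out = GeneTreeRecord(
        gene_id=record.gene_id, tree=pruned, alignment_length=record.alignment_length
    )
    try:
        out.recompute_abs()
    except ValueError:
        out.abs_support = record.abs_support
    return out, flagged


def concatenate_alignments(
    alns: Mapping[str, Alignment] | Sequence[tuple[str, Alignment]],
    taxa: Iterable[str],
) -> tuple[Alignment, pd.DataFrame]:
    """Concatenate gene alignments into a supermatrix over ``taxa``.

    Taxa absent from a gene are padded with '?'. The partition table uses
    1-based inclusive coordinates (RAxML-style)."""
    if not isinstance(alns, Mapping):
        ids = [gid for gid, _ in alns]
        if len(set(ids)) != len(ids):
            dups = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dups}")
        alns = dict(alns)
    taxa = list(taxa)
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    rows = []
    start = 1
    for gid, aln in alns.items():
        L = aln.n_sites
        for t in taxa:
            chunks[t].append(aln[t] if t in aln else "?" * L)
        rows.append((gid, start, start + L - 1))
        start += L
    supermatrix = Alignment({t: "".join(chunks[t]) for t in taxa})
    table = pd.DataFrame(rows, columns=["gene", "start", "end"])
    return supermatrix, table


def partition_table_to_raxml(table: pd.DataFrame) -> str:
    return "".join(
        f"DNA, {row.gene} = {row.start}-{row.end}\n" for row in table.itertuples()
    )
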