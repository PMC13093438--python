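"""Shared per-gene record type."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .trees import PhyloTree, average_bootstrap_support


@dataclass
class GeneTreeRecord:
    """A gene tree bundled with its reliability metadata.

    ``abs_support`` is the mean bootstrap value over internal nodes that
    carry one (the ABS statistic used for gene filtering).
    """

    gene_id: str
    tree: PhyloTree
    abs_support: Optional[float] = None
    alignment_length: Optional[int] = None

    def recompute_abs(self) -> float:
        self.abs_support = average_bootstrap_support(self.tree)
        return self.abs_support
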