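"""Multiple sequence alignment container with FASTA / relaxed-PHYLIP I/O."""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

ALPHABET = set("ACGTN-?")
MISSING = set("N-?")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

__all__ = ["Alignment", "ALPHABET", "MISSING"]


class Alignment:
    """Immutable-ish alignment: taxon label -> equal-length DNA row.

    Alphabet is {A,C,G,T,-,N,?}, case-insensitive on input, stored upper.
    """

    def __init__(self, rows: Mapping[str, str]):
        if not rows:
            raise ValueError("alignment needs at least one row")
        self.rows: dict[str, str] = {}
        length = None
        for label, seq in rows.items():
            seq = str(seq).upper()
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(f"illegal characters in row {label!r}: {sorted(bad)}")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(
                    f"row {label!r} has length {len(seq)}, expected {length}"
                )
            self.rows[label] = seq
        self.n_sites = length or 0

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.n_sites

    def __iter__(self) -> Iterator[str]:
        return iter(self.rows)

    def __contains__(self, label: str) -> bool:
        return label in self.rows

    def __getitem__(self, label: str) -> str:
        return self.rows[label]

    @property
    def labels(self) -> list[str]:
        return list(self.rows)

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    def column(self, i: int) -> str:
        return "".join(seq[i] for seq in self.rows.values())

    def take_columns(self, indices: Iterable[int]) -> "Alignment":
        idx = list(indices)
        return Alignment({lbl: "".join(seq[i] for i in idx) for lbl, seq in self.rows.items()})

    def subset(self, labels: Iterable[str]) -> "Alignment":
        return Alignment({lbl: self.rows[lbl] for lbl in labels})

    def to_int_matrix(self) -> np.ndarray:
        """(n_taxa, n_sites) int8 matrix; A,C,G,T -> 0..3, missing -> -1."""
        lut = np.full(128, -1, dtype=np.int8)
        for base, code in _BASE_INDEX.items():
            lut[ord(base)] = code
        mat = np.empty((self.n_taxa, self.n_sites), dtype=np.int8)
        for i, seq in enumerate(self.rows.values()):
            mat[i] = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
        return mat

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_fasta(cls, source) -> "Alignment":
        handle = io.StringIO(source) if isinstance(source, str) and "\n" in source else source
        records = list(SeqIO.parse(handle, "fasta"))
        if not records:
            raise ValueError("no FASTA records found")
        return cls({rec.id: str(rec.seq) for rec in records})

    @classmethod
    def read(cls, path, fmt: str = "fasta") -> "Alignment":
        fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}[fmt]
        aln = AlignIO.read(str(path), fmt)
        return cls({rec.id: str(rec.seq) for rec in aln})

    def to_fasta(self) -> str:
        out = []
        for label, seq in self.rows.items():
            out.append(f">{label}\n{seq}\n")
        return "".join(out)

    def write(self, path, fmt: str = "fasta") -> None:
        if fmt == "fasta":
            with open(path, "w") as fh:
                fh.write(self.to_fasta())
            return
        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(seq), id=label, description="") for label, seq in self.rows.items()]
        )
        AlignIO.write(msa, str(path), "phylip-relaxed")

    # -- summaries ---------------------------------------------------------
    def column_missing_fractions(self) -> np.ndarray:
        mat = self.to_int_matrix()
        return (mat < 0).mean(axis=0)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({self.n_taxa} taxa x {self.n_sites} sites)"
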