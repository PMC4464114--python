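"""Rectangular multiple-alignment container with FASTA/PHYLIP I/O."""

from __future__ import annotations

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AA_INDEX

__all__ = ["Alignment"]

GAP = "-"


class Alignment:
    """An ordered set of equal-length gapped sequences with unique ids."""

    def __init__(self, ids: list[str], rows: list[str]):
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in number")
        if len(set(ids)) != len(ids):
            raise ValueError("alignment ids must be unique")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError("alignment is not rectangular")
        self.ids = list(ids)
        self.rows = [r.upper() for r in rows]
        self.n_columns = lengths.pop() if lengths else 0

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "Alignment":
        return cls(list(mapping), list(mapping.values()))

    @classmethod
    def read(cls, path, fmt: str = "fasta") -> "Alignment":
        """Read an alignment; ``fmt`` is "fasta" or "phylip" (relaxed)."""
        bio_fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}[fmt]
        msa = AlignIO.read(str(path), bio_fmt)
        return cls([r.id for r in msa], [str(r.seq) for r in msa])

    def write(self, path, fmt: str = "fasta") -> None:
        bio_fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}[fmt]
        msa = MultipleSeqAlignment(
            SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(self.ids, self.rows)
        )
        AlignIO.write(msa, str(path), bio_fmt)

    # -- queries ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def to_dict(self) -> dict[str, str]:
        return dict(zip(self.ids, self.rows))

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def codes(self, order_ids: list[str] | None = None) -> np.ndarray:
        """Integer state matrix (n_seqs, n_cols); gaps/ambiguities are -1."""
        ids = order_ids if order_ids is not None else self.ids
        out = np.empty((len(ids), self.n_columns), dtype=np.int16)
        for i, sid in enumerate(ids):
            row = self.row(sid)
            out[i] = [AA_INDEX.get(ch, -1) for ch in row]
        return out

    def empirical_frequencies(self) -> np.ndarray:
        """Observed amino-acid frequencies across the whole alignment (+F input)."""
        counts = np.zeros(20)
        for row in self.rows:
            for ch in row:
                idx = AA_INDEX.get(ch)
                if idx is not None:
                    counts[idx] += 1
        total = counts.sum()
        if total == 0:
            raise ValueError("alignment contains no standard residues")
        return counts / total

    # -- manipulation -------------------------------------------------------

    def subset(self, ids: list[str]) -> "Alignment":
        return Alignment(list(ids), [self.row(sid) for sid in ids])

    def take_columns(self, indices) -> "Alignment":
        idx = list(indices)
        return Alignment(self.ids, ["".join(row[j] for j in idx) for row in self.rows])

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap resample of columns with replacement."""
        idx = rng.integers(0, self.n_columns, size=self.n_columns)
        return self.take_columns(idx)
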