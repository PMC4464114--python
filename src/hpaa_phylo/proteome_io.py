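"""Proteome input/output and dataset preparation.

This module reads protein and coding-nucleotide FASTA files, reduces each
gene to a single representative peptide (the longest splice variant), and
applies a cross-species reciprocal-homology filter so that downstream
homopolymer statistics are computed only on peptides with credible homologs
in the other species under comparison.

The homology filter mimics a reciprocal BLASTP criterion: a peptide is kept
only if, against each of the other two proteomes, some cross-species pair
involving it reaches a bit score at or above a threshold (default 200) in
both search directions.  The default backend scores pairs by Smith-Waterman
local alignment under BLOSUM62 with affine gaps and converts raw scores to
bits with gapped Karlin-Altschul parameters; a thin adapter to an external
``blastp`` executable is provided for parity runs.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Peptide",
    "CodingSequence",
    "HomologyFilterSettings",
    "read_fasta",
    "write_fasta",
    "select_representatives",
    "reciprocal_homolog_filter",
    "local_alignment_bits",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "BZXUOJ"

_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Peptide:
    """A protein sequence with species and optional gene labels.

    The sequence is stored uppercase; a single trailing stop symbol ``*`` is
    stripped on construction.  Internal stop symbols are invalid.
    """

    id: str
    sequence: str
    species: str = ""
    gene_id: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"peptide {self.id!r} has an empty sequence")
        if "*" in seq:
            raise ValueError(f"peptide {self.id!r} has an internal stop symbol")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame coding nucleotide sequence (reading frame 1).

    Trailing partial codons and a trailing stop codon are trimmed; internal
    stop codons under the standard genetic code are invalid.
    """

    id: str
    nucleotides: str
    species: str = ""

    def __post_init__(self) -> None:
        nt = self.nucleotides.upper().replace("U", "T")
        bad = set(nt) - set("ACGTN")
        if bad:
            raise ValueError(f"coding sequence {self.id!r} has invalid characters {sorted(bad)}")
        nt = nt[: len(nt) - len(nt) % 3]
        if not nt:
            raise ValueError(f"coding sequence {self.id!r} is empty after codon trimming")
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        if codons[-1] in _STOP_CODONS:
            codons = codons[:-1]
        for i, c in enumerate(codons):
            if c in _STOP_CODONS:
                raise ValueError(f"coding sequence {self.id!r} has an internal stop codon at codon {i + 1}")
        object.__setattr__(self, "nucleotides", "".join(codons))

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass
class HomologyFilterSettings:
    """Settings for the reciprocal cross-species homology filter.

    ``lambda_ka`` and ``k_ka`` are gapped Karlin-Altschul parameters used to
    convert raw Smith-Waterman scores S to bit scores via
    ``(lambda_ka * S - ln k_ka) / ln 2``; the defaults correspond to BLOSUM62
    with gap open 11 / extend 1.
    """

    min_bits: float = 200.0
    backend: str = "builtin"
    lambda_ka: float = 0.267
    k_ka: float = 0.041

    def __post_init__(self) -> None:
        if self.min_bits <= 0:
            raise ValueError("min_bits must be positive")
        if self.lambda_ka <= 0 or self.k_ka <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if self.backend not in ("builtin", "external"):
            raise ValueError(f"unknown backend {self.backend!r}")


def read_fasta(path, alphabet: str = "protein", species: str = ""):
    """Read a FASTA file into :class:`Peptide` or :class:`CodingSequence` records.

    Record ids are the first whitespace-delimited token of each header and
    must be unique.  Protein records may carry a single trailing ``*`` (noted
    and stripped); records with internal stops are rejected with a warning
    and the run continues.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        try:
            if alphabet == "protein":
                if raw.endswith("*"):
                    warnings.warn(f"stripped trailing stop symbol from {rec.id!r}")
                records.append(Peptide(id=rec.id, sequence=raw, species=species))
            else:
                records.append(CodingSequence(id=rec.id, nucleotides=raw, species=species))
        except ValueError as exc:
            warnings.warn(f"rejected record {rec.id!r}: {exc}")
    if not records and not seen:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path) -> None:
    """Write peptides or coding sequences to FASTA, one line per sequence."""
    seqrecs = []
    for r in records:
        seq = r.sequence if isinstance(r, Peptide) else r.nucleotides
        seqrecs.append(SeqRecord(Seq(seq), id=r.id, description=""))
    SeqIO.write(seqrecs, str(path), "fasta-2line")


def read_gene_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping peptide_id -> gene_id."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"gene map line without two columns: {line!r}")
            mapping[fields[0]] = fields[1]
    return mapping


def select_representatives(peptides, gene_map: dict[str, str] | None = None):
    """Keep one representative peptide per gene: the longest splice variant.

    Peptides absent from ``gene_map`` form their own single-member gene.
    Ties in length are broken toward the lexicographically smaller peptide
    id, so the result is deterministic under permutation of the input.
    """
    gene_map = gene_map or {}
    best: dict[str, Peptide] = {}
    for p in peptides:
        gene = gene_map.get(p.id, p.id)
        cur = best.get(gene)
        # longest wins; on equal length the lexicographically smaller id wins
        if cur is None or len(p) > len(cur) or (len(p) == len(cur) and p.id < cur.id):
            best[gene] = p
    return sorted(best.values(), key=lambda p: p.id)


_EXTENDED_BLOSUM62 = None


def _extended_blosum62():
    """BLOSUM62 extended so U/O/J score as the matrix minimum (mismatch-like)."""
    global _EXTENDED_BLOSUM62
    if _EXTENDED_BLOSUM62 is None:
        base = substitution_matrices.load("BLOSUM62")
        lowest = float(base.min())
        alphabet = base.alphabet + "UOJ"
        ext = substitution_matrices.Array(alphabet=alphabet, dims=2)
        ext += lowest
        for i, a in enumerate(base.alphabet):
            for j, b in enumerate(base.alphabet):
                ext[a, b] = base[i, j]
        _EXTENDED_BLOSUM62 = ext
    return _EXTENDED_BLOSUM62


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _extended_blosum62()
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def local_alignment_bits(seq1: str, seq2: str, settings: HomologyFilterSettings | None = None) -> float:
    """Bit score of the best Smith-Waterman local alignment of two peptides."""
    settings = settings or HomologyFilterSettings()
    aligner = _make_aligner()
    raw = aligner.score(seq1.upper(), seq2.upper())
    return (settings.lambda_ka * raw - math.log(settings.k_ka)) / math.log(2.0)


def _builtin_pass(query: list[Peptide], target: list[Peptide], settings: HomologyFilterSettings) -> set[str]:
    """Ids in ``query`` with some partner in ``target`` at >= min_bits.

    The builtin scorer is symmetric, so a pair above threshold in one
    direction is above it in both; reciprocity is a single computation.
    """
    aligner = _make_aligner()
    lam, k = settings.lambda_ka, settings.k_ka
    hit: set[str] = set()
    for q in query:
        for t in target:
            raw = aligner.score(q.sequence, t.sequence)
            bits = (lam * raw - math.log(k)) / math.log(2.0)
            if bits >= settings.min_bits:
                hit.add(q.id)
                break
    return hit


def _blastp_pairs(query: list[Peptide], target: list[Peptide], settings: HomologyFilterSettings) -> set[tuple[str, str]]:
    if shutil.which("blastp") is None:
        raise RuntimeError(
            "external backend requested but 'blastp' is not on PATH; "
            "rerun with backend='builtin'"
        )
    with tempfile.TemporaryDirectory() as tmp:
        qpath, tpath = Path(tmp, "q.fa"), Path(tmp, "t.fa")
        write_fasta(query, qpath)
        write_fasta(target, tpath)
        out = subprocess.run(
            [
                "blastp", "-query", str(qpath), "-subject", str(tpath),
                "-seg", "yes", "-soft_masking", "true",
                "-outfmt", "6 qseqid sseqid bitscore",
            ],
            capture_output=True, text=True, check=True,
        ).stdout
    pairs: set[tuple[str, str]] = set()
    for line in out.splitlines():
        q, s, bits = line.split("\t")
        if float(bits) >= settings.min_bits:
            pairs.add((q, s))
    return pairs


def _external_pass(query: list[Peptide], target: list[Peptide], settings: HomologyFilterSettings) -> set[str]:
    forward = _blastp_pairs(query, target, settings)
    backward = _blastp_pairs(target, query, settings)
    return {q for (q, s) in forward if (s, q) in backward}


def reciprocal_homolog_filter(set_a, set_b, set_c, settings: HomologyFilterSettings | None = None):
    """Filter three species' peptide sets by reciprocal cross-species homology.

    A peptide survives iff, for each of the two other sets, at least one
    cross-species pair involving it reaches ``settings.min_bits`` in both
    search directions.  The operation is symmetric in the order of the sets.
    Empty results are reported with a warning rather than an error.
    """
    settings = settings or HomologyFilterSettings()
    sets = [list(set_a), list(set_b), list(set_c)]
    for s in sets:
        if not s:
            raise ValueError("all three peptide sets must be non-empty")
    passer = _builtin_pass if settings.backend == "builtin" else _external_pass
    kept = []
    for i, current in enumerate(sets):
        others = [sets[j] for j in range(3) if j != i]
        surviving_ids = set(p.id for p in current)
        for other in others:
            surviving_ids &= passer(current, other, settings)
        filtered = [p for p in current if p.id in surviving_ids]
        if not filtered:
            warnings.warn(f"reciprocal homolog filter removed every peptide from set {i + 1}")
        kept.append(filtered)
    return tuple(kept)
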