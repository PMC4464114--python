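"""Alignment-sensitivity experiment: tract deletion, aligners, trimming.

The experiment asks how much of the support for a clade — canonically the
exclusive grouping of the two lamprey Emx paralogs — is manufactured by the
multiple-alignment step when convergent homopolymer tracts are present.
Sequences are analysed in two arms (intact, and with the tracts deleted
before alignment), across a grid of aligner choices and column-trimming
stringencies; each cell runs the full exhaustive-ML + RELL pipeline and
records the summed bootstrap probability of the focal clade.

The builtin aligner is a progressive profile-profile aligner (guide tree
from shared k-mer distances, BLOSUM62, affine gaps open 10 / extend 0.5)
so the pipeline runs with no external binaries; thin subprocess adapters to
``mafft``, ``clustalw`` and ``t_coffee`` are used when those programs are
on PATH and fall back to the builtin aligner with a warning otherwise.

Column trimming first removes every gapped column, then drops columns whose
mean pairwise similarity (BLOSUM62 rescaled to [0, 1]) falls below the
threshold ``st``.  This reproduces the semantics "low-similarity columns
are removed as st rises" of TrimAl-style filtering, not its exact score.
"""

from __future__ import annotations

import itertools
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .dup_count import SpeciesAssignment
from .phylo_core import Alignment, SubstitutionModel, Tree, enumerate_topologies
from .phylo_core.topology import ConstraintGroups
from .topology_tests import clade_support, rell_bootstrap, score_topologies

__all__ = [
    "TrimSettings",
    "delete_hpaa",
    "align",
    "builtin_align",
    "trim_columns",
    "sum_of_pairs_score",
    "run_sensitivity_grid",
    "DEFAULT_ST_LEVELS",
]

#: Trimming stringencies used in the headline grid (0 = gap filter only).
DEFAULT_ST_LEVELS = (0.0, 0.00005, 0.0001, 0.0005, 0.001)

GAP = "-"
GAP_OPEN = 10.0
GAP_EXTEND = 0.5


@dataclass(frozen=True)
class TrimSettings:
    """Column-trimming settings: gapped columns always removed, then
    columns with mean pairwise similarity below ``st``."""

    st: float = 0.0

    def __post_init__(self) -> None:
        if self.st < 0:
            raise ValueError("similarity threshold must be non-negative")


def delete_hpaa(sequence: str, spans) -> str:
    """Excise tract spans (0-based ``(start, length)`` pairs or objects with
    ``start``/``length``) from a sequence.

    Spans must lie within the sequence and must not overlap; residues
    outside the spans are preserved in order.
    """
    pairs = []
    for span in spans:
        start = getattr(span, "start", None)
        length = getattr(span, "length", None)
        if start is None:
            start, length = span
        if start < 0 or start + length > len(sequence):
            raise ValueError(f"span ({start}, {length}) outside sequence of length {len(sequence)}")
        pairs.append((int(start), int(length)))
    pairs.sort()
    for (s1, l1), (s2, _) in itertools.pairwise(pairs):
        if s1 + l1 > s2:
            raise ValueError("tract spans overlap")
    out = sequence
    for start, length in reversed(pairs):
        out = out[:start] + out[start + length :]
    return out


# -- builtin progressive aligner -------------------------------------------

_BLOSUM = None


def _blosum():
    global _BLOSUM
    if _BLOSUM is None:
        mat = substitution_matrices.load("BLOSUM62")
        alphabet = mat.alphabet
        lookup = np.full(128, -1, dtype=np.int64)
        for i, ch in enumerate(alphabet):
            lookup[ord(ch)] = i
        _BLOSUM = (np.asarray(mat, dtype=float), lookup, alphabet)
    return _BLOSUM


def _profile_counts(rows: list[str]) -> np.ndarray:
    """Column residue-count matrix (n_cols, n_symbols); gaps excluded."""
    mat, lookup, alphabet = _blosum()
    n_sym = len(alphabet)
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    counts = np.zeros((arr.shape[1], n_sym))
    idx = lookup[arr]
    for j in range(arr.shape[1]):
        col = idx[:, j]
        col = col[col >= 0]
        np.add.at(counts[j], col, 1.0)
    return counts


def _column_scores(counts_a: np.ndarray, counts_b: np.ndarray) -> np.ndarray:
    """Mean pairwise BLOSUM score between profile columns, (n_a, n_b)."""
    mat, _, _ = _blosum()
    na = counts_a.sum(axis=1)
    nb = counts_b.sum(axis=1)
    raw = counts_a @ mat @ counts_b.T
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, raw / np.maximum(denom, 1e-12), 0.0)
    return out


#: Residues treated as hydrophilic for gap-penalty modulation, and the
#: factor applied to the gap-open cost inside hydrophilic stretches.  This
#: reproduces the classic progressive-aligner heuristic of steering gaps
#: into hydrophilic (loop-like, low-complexity) regions — the very
#: behaviour through which homopolymer tracts disturb the alignment of
#: their neighbourhoods.
HYDROPHILIC = set("GPSNDQEKR")
HYDROPHILIC_FACTOR = 0.3
_HYDRO_WINDOW = 5


def _gap_open_modulation(rows: list[str]) -> np.ndarray:
    """Per-column gap-open multipliers for a profile.

    A column lying in a window of ``_HYDRO_WINDOW`` consecutive
    majority-hydrophilic columns has its gap-open cost scaled by
    ``HYDROPHILIC_FACTOR``; elsewhere the multiplier is 1.
    """
    n_cols = len(rows[0])
    hydro = np.zeros(n_cols)
    for j in range(n_cols):
        residues = [r[j] for r in rows if r[j] != GAP]
        if residues:
            hydro[j] = sum(ch in HYDROPHILIC for ch in residues) / len(residues)
    is_hydro = hydro >= 0.5
    mod = np.ones(n_cols)
    run = 0
    for j in range(n_cols):
        run = run + 1 if is_hydro[j] else 0
        if run >= _HYDRO_WINDOW:
            mod[j - run + 1 : j + 1] = HYDROPHILIC_FACTOR
    return mod


def _gotoh_profile_align(rows_a: list[str], rows_b: list[str]) -> list[str]:
    """Global affine-gap alignment of two profiles; returns merged rows.

    Gap-open costs are modulated per column by hydrophilic-stretch
    detection (see :data:`HYDROPHILIC`), as classic progressive aligners
    do; the extension cost is uniform.
    """
    s = _column_scores(_profile_counts(rows_a), _profile_counts(rows_b))
    n, m = s.shape
    # gap costs per gap location: gaps placed in A sit at an A column, gaps
    # placed in B at a B column; both open and extension are cheapened in
    # hydrophilic stretches
    mod_a = _gap_open_modulation(rows_a)
    mod_b = _gap_open_modulation(rows_b)
    open_a, ext_a = GAP_OPEN * mod_a, GAP_EXTEND * mod_a
    open_b, ext_b = GAP_OPEN * mod_b, GAP_EXTEND * mod_b
    neg = -1e30
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in profile B (move down)
    Y = np.full((n + 1, m + 1), neg)  # gap in profile A (move right)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_b[0] - (i - 1) * ext_b[0]
    for j in range(1, m + 1):
        Y[0, j] = -open_a[0] - (j - 1) * ext_a[0]
    js = np.arange(m)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + s[i - 1]
        X[i, 1:] = np.maximum(M[i - 1, 1:] - open_b, X[i - 1, 1:] - ext_b)
        # Y[i, j] = max_{k<j} (M[i, k] - open_a[i-1] - (j-1-k)*ext_a[i-1]);
        # open and extension are constant along a row, so a running maximum
        # of M[i, k] + k*ext gives the whole row at once
        run = np.maximum.accumulate(M[i, :-1] + js * ext_a[i - 1])
        Y[i, 1:] = run - open_a[i - 1] - js * ext_a[i - 1]
    # traceback
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            ops.append("D")
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            ops.append("U")
            state = 0 if M[i - 1, j] - open_b[j - 1] >= X[i - 1, j] - ext_b[j - 1] else 1
            i -= 1
        elif state == 2 and j > 0:
            ops.append("L")
            state = 0 if M[i, j - 1] - open_a[i - 1] >= Y[i, j - 1] - ext_a[i - 1] else 2
            j -= 1
        elif i > 0:
            ops.append("U")
            i -= 1
            state = 1
        else:
            ops.append("L")
            j -= 1
            state = 2
    ops.reverse()
    merged_a = ["" for _ in rows_a]
    merged_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "U"):
            for k, row in enumerate(rows_a):
                merged_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                merged_a[k] += GAP
        if op in ("D", "L"):
            for k, row in enumerate(rows_b):
                merged_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                merged_b[k] += GAP
    return merged_a + merged_b


def _kmer_distance(s1: str, s2: str, k: int = 3) -> float:
    k1 = {s1[i : i + k] for i in range(max(len(s1) - k + 1, 1))}
    k2 = {s2[i : i + k] for i in range(max(len(s2) - k + 1, 1))}
    if not k1 or not k2:
        return 1.0
    return 1.0 - len(k1 & k2) / min(len(k1), len(k2))


def builtin_align(sequences: dict[str, str]) -> Alignment:
    """Progressive profile-profile alignment with a k-mer guide tree.

    Clusters are merged greedily by average-linkage k-mer distance with a
    deterministic tie-break on cluster names, so the output is identical
    across runs.
    """
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("alignment needs at least two sequences")
    clusters: dict[str, tuple[list[str], list[str]]] = {
        sid: ([sid], [sequences[sid]]) for sid in ids
    }
    dist = {
        (a, b): _kmer_distance(sequences[a], sequences[b])
        for a, b in itertools.combinations(sorted(ids), 2)
    }

    def cluster_distance(ca: str, cb: str) -> float:
        members_a = clusters[ca][0]
        members_b = clusters[cb][0]
        vals = [
            dist[(x, y) if x < y else (y, x)] for x in members_a for y in members_b
        ]
        return sum(vals) / len(vals)

    while len(clusters) > 1:
        names = sorted(clusters)
        best = min(
            ((cluster_distance(a, b), (a, b)) for a, b in itertools.combinations(names, 2)),
            key=lambda t: (t[0], t[1]),
        )
        a, b = best[1]
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        merged = _gotoh_profile_align(rows_a, rows_b)
        clusters[min(a, b)] = (ids_a + ids_b, merged)
    merged_ids, merged_rows = next(iter(clusters.values()))
    order = [sid for sid in ids if sid in merged_ids]
    lookup = dict(zip(merged_ids, merged_rows))
    return Alignment(order, [lookup[sid] for sid in order])


_EXTERNAL_BINARIES = {"mafft": "mafft", "clustalw": "clustalw2", "t_coffee": "t_coffee"}


def _external_align(sequences: dict[str, str], program: str) -> Alignment:
    binary = _EXTERNAL_BINARIES[program]
    if shutil.which(binary) is None:
        raise FileNotFoundError(binary)
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp, "in.fa")
        with open(fasta, "w") as fh:
            for sid, seq in sequences.items():
                fh.write(f">{sid}\n{seq}\n")
        if program == "mafft":
            out = subprocess.run(
                ["mafft", "--auto", "--quiet", str(fasta)],
                capture_output=True, text=True, check=True,
            ).stdout
            aligned = Path(tmp, "out.fa")
            aligned.write_text(out)
            aln = Alignment.read(aligned, "fasta")
        elif program == "clustalw":
            outfile = Path(tmp, "out.fa")
            subprocess.run(
                ["clustalw2", f"-INFILE={fasta}", "-OUTPUT=FASTA", f"-OUTFILE={outfile}"],
                capture_output=True, text=True, check=True,
            )
            aln = Alignment.read(outfile, "fasta")
        else:  # t_coffee
            outfile = Path(tmp, "out.fa")
            subprocess.run(
                ["t_coffee", str(fasta), "-output", "fasta_aln", "-outfile", str(outfile), "-quiet"],
                capture_output=True, text=True, check=True,
            )
            aln = Alignment.read(outfile, "fasta")
    # restore input order
    return aln.subset([sid for sid in sequences if sid in aln.ids])


def align(sequences: dict[str, str], aligner: str = "builtin") -> Alignment:
    """Align sequences with the requested aligner.

    ``aligner`` is "builtin" or one of the external adapters "mafft",
    "clustalw", "t_coffee"; a missing external binary falls back to the
    builtin aligner with a warning.  Every input sequence is recoverable
    from its aligned row by removing gaps.
    """
    if aligner == "builtin":
        return builtin_align(sequences)
    if aligner not in ("mafft", "clustalw", "t_coffee"):
        raise ValueError(f"unknown aligner {aligner!r}")
    try:
        return _external_align(sequences, aligner)
    except (FileNotFoundError, subprocess.CalledProcessError) as exc:
        warnings.warn(f"aligner {aligner!r} unavailable ({exc}); falling back to builtin")
        return builtin_align(sequences)


def sum_of_pairs_score(alignment: Alignment, gap_open: float = GAP_OPEN, gap_extend: float = GAP_EXTEND) -> float:
    """Sum-of-pairs score: BLOSUM62 residue pairs minus affine gap costs.

    Pairwise projections skip columns gapped in both rows; each maximal gap
    run in a projection costs open + (len-1) * extend.
    """
    mat, lookup, _ = _blosum()
    total = 0.0
    for r1, r2 in itertools.combinations(alignment.rows, 2):
        in_gap1 = in_gap2 = False
        for a, b in zip(r1, r2):
            if a == GAP and b == GAP:
                continue
            if a == GAP:
                total -= gap_extend if in_gap1 else gap_open
                in_gap1, in_gap2 = True, False
            elif b == GAP:
                total -= gap_extend if in_gap2 else gap_open
                in_gap2, in_gap1 = True, False
            else:
                ia, ib = lookup[ord(a)], lookup[ord(b)]
                if ia >= 0 and ib >= 0:
                    total += mat[ia, ib]
                in_gap1 = in_gap2 = False
    return total


def trim_columns(alignment: Alignment, settings: TrimSettings) -> tuple[Alignment | None, list[int]]:
    """Remove gapped columns, then columns below the similarity threshold.

    Returns the trimmed alignment and the kept column indices (1-based,
    relative to the input).  Returns ``(None, [])`` when nothing survives.
    """
    mat, lookup, _ = _blosum()
    lo, hi = mat.min(), mat.max()
    kept: list[int] = []
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        if GAP in col:
            continue
        if settings.st > 0:
            idx = [lookup[ord(ch)] for ch in col]
            pairs = [
                (mat[a, b] - lo) / (hi - lo)
                for a, b in itertools.combinations(idx, 2)
                if a >= 0 and b >= 0
            ]
            score = sum(pairs) / len(pairs) if pairs else 0.0
            if score < settings.st:
                continue
        kept.append(j)
    if not kept:
        return None, []
    return alignment.take_columns(kept), [j + 1 for j in kept]


def paired_clade_support(
    intact: dict[str, str],
    delta_hpaa: dict[str, str],
    clade,
    model: SubstitutionModel,
    seed: int,
    aligner: str = "builtin",
    st: float = 0.0,
    n_replicates: int = 2000,
    opt_tol: float = 3e-3,
) -> tuple[float, float]:
    """Clade support of one intact/tract-deleted pair at a single grid cell.

    Returns ``(intact_support, delta_support)``; the two arms share the
    model and RELL seed, so any difference comes from the alignment and
    trimming of the tract-bearing data.
    """
    supports = []
    for sequences in (intact, delta_hpaa):
        aln = align(sequences, aligner)
        trimmed, _ = trim_columns(aln, TrimSettings(st=st))
        if trimmed is None:
            raise ValueError("trimming removed every column")
        topologies = enumerate_topologies(sorted(sequences))
        matrix = score_topologies(trimmed, topologies, model, tol=opt_tol)
        bp = rell_bootstrap(matrix, n_replicates=n_replicates, seed=seed)
        supports.append(clade_support(bp, topologies, clade))
    return supports[0], supports[1]


def run_sensitivity_grid(
    intact: dict[str, str],
    delta_hpaa: dict[str, str],
    clade,
    model: SubstitutionModel,
    seed: int,
    aligners: tuple[str, ...] = ("builtin",),
    st_levels: tuple[float, ...] = DEFAULT_ST_LEVELS,
    constraints: ConstraintGroups | None = None,
    n_replicates: int = 2000,
    opt_tol: float = 3e-3,
) -> pd.DataFrame:
    """Run the aligner x trimming x arm grid and collect clade support.

    Every cell runs: align -> trim -> exhaustive topology enumeration ->
    per-topology branch-length optimization and site log-likelihoods ->
    RELL bootstrap -> summed BP of the focal clade.  The substitution model
    and RELL seed are identical across cells, so cells differ only in the
    data-preparation steps.  A failing stage marks the cell failed without
    aborting the rest of the grid.
    """
    clade = frozenset(clade)
    arms = {"intact": intact, "delta_hpaa": delta_hpaa}
    rows = []
    for aligner, st, (arm, sequences) in itertools.product(
        aligners, st_levels, arms.items()
    ):
        record = {
            "aligner": aligner,
            "st": st,
            "arm": arm,
            "clade_support": np.nan,
            "n_sites": 0,
            "failed": False,
        }
        try:
            aln = align(sequences, aligner)
            trimmed, kept = trim_columns(aln, TrimSettings(st=st))
            if trimmed is None:
                raise ValueError("trimming removed every column")
            labels = sorted(sequences)
            topologies = enumerate_topologies(labels, constraints)
            matrix = score_topologies(
                trimmed, topologies, model, tol=opt_tol
            )
            bp = rell_bootstrap(matrix, n_replicates=n_replicates, seed=seed)
            record["clade_support"] = clade_support(bp, topologies, clade)
            record["n_sites"] = trimmed.n_columns
        except Exception as exc:  # noqa: BLE001 - cell isolation is the contract
            warnings.warn(f"grid cell ({aligner}, st={st}, {arm}) failed: {exc}")
            record["failed"] = True
        rows.append(record)
    return pd.DataFrame(rows)
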