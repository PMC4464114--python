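"""Detection and statistics of homopolymeric amino-acid (HPAA) tracts.

An HPAA tract is a maximal run of identical standard residues of length at
least ``min_len`` (default 6, with 8 and 10 used as robustness checks, and
12 as the cut for "long" tracts).  The module computes, per species and per
amino acid, the fraction of peptides that contain a tract, the proportion of
residues lying inside tracts, and the fraction of tracts of length >= 12
among those of length >= 6, together with the chi-square and two-proportion
tests used to compare species.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .proteome_io import STANDARD_AA, Peptide

__all__ = [
    "ScanSettings",
    "HpaaTract",
    "find_hpaa_tracts",
    "peptide_frequency_table",
    "residue_proportion",
    "long_tract_fraction",
    "two_proportion_test",
    "chi_square_homogeneity",
    "summarize_species",
    "tract_table",
]

#: Key used for statistics pooled over all 20 amino acids.
ANY = "any"


@dataclass(frozen=True)
class ScanSettings:
    """Minimum run length defining a tract (>= 2)."""

    min_len: int = 6

    def __post_init__(self) -> None:
        if self.min_len < 2:
            raise ValueError("min_len must be at least 2")


@dataclass(frozen=True)
class HpaaTract:
    """A maximal identical-residue run: 0-based start, length in residues."""

    peptide_id: str
    amino_acid: str
    start: int
    length: int

    @property
    def end(self) -> int:
        """0-based exclusive end offset."""
        return self.start + self.length

    @property
    def start_1based(self) -> int:
        return self.start + 1


def find_hpaa_tracts(sequence: str, settings: ScanSettings | None = None, peptide_id: str = "") -> list[HpaaTract]:
    """All maximal runs of identical standard residues with length >= min_len.

    Ambiguity characters (B, Z, X, J) and the rare residues U/O terminate
    runs and never form tracts themselves.  Returned tracts are ordered left
    to right and are non-overlapping by construction (runs are maximal).
    """
    settings = settings or ScanSettings()
    tracts = []
    pos = 0
    for aa, group in itertools.groupby(sequence):
        n = sum(1 for _ in group)
        if n >= settings.min_len and aa in STANDARD_AA:
            tracts.append(HpaaTract(peptide_id=peptide_id, amino_acid=aa, start=pos, length=n))
        pos += n
    return tracts


def _scan_all(peptides: list[Peptide], settings: ScanSettings) -> list[HpaaTract]:
    out: list[HpaaTract] = []
    for p in peptides:
        out.extend(find_hpaa_tracts(p.sequence, settings, peptide_id=p.id))
    return out


def tract_table(peptides: list[Peptide], settings: ScanSettings | None = None) -> pd.DataFrame:
    """Per-tract table with 1-based inclusive coordinates, for TSV export."""
    settings = settings or ScanSettings()
    rows = [
        {
            "peptide_id": t.peptide_id,
            "amino_acid": t.amino_acid,
            "start_1based": t.start_1based,
            "length": t.length,
        }
        for t in _scan_all(peptides, settings)
    ]
    return pd.DataFrame(rows, columns=["peptide_id", "amino_acid", "start_1based", "length"])


def peptide_frequency_table(peptides: list[Peptide], settings: ScanSettings | None = None) -> pd.Series:
    """Fraction of peptides containing >= 1 tract, per amino acid plus ``"any"``.

    A peptide with tracts of several amino acids counts once toward each of
    those amino acids but only once toward the pooled ``"any"`` entry.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("peptide set is empty")
    settings = settings or ScanSettings()
    n = len(peptides)
    counts = dict.fromkeys(STANDARD_AA, 0)
    n_any = 0
    for p in peptides:
        aas = {t.amino_acid for t in find_hpaa_tracts(p.sequence, settings)}
        for aa in aas:
            counts[aa] += 1
        if aas:
            n_any += 1
    freq = {aa: counts[aa] / n for aa in STANDARD_AA}
    freq[ANY] = n_any / n
    return pd.Series(freq, name="peptide_frequency")


def residue_proportion(peptides: list[Peptide], settings: ScanSettings | None = None) -> pd.Series:
    """Proportion of residues lying inside tracts, per amino acid and in total.

    Both the per-amino-acid and pooled values are taken over the total
    residue count of the set, so the ``"any"`` entry equals the sum of the
    per-amino-acid entries.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("peptide set is empty")
    settings = settings or ScanSettings()
    total = sum(len(p) for p in peptides)
    in_tract = dict.fromkeys(STANDARD_AA, 0)
    for t in _scan_all(peptides, settings):
        in_tract[t.amino_acid] += t.length
    prop = {aa: in_tract[aa] / total for aa in STANDARD_AA}
    prop[ANY] = sum(in_tract.values()) / total
    return pd.Series(prop, name="residue_proportion")


def long_tract_fraction(
    peptides: list[Peptide],
    settings: ScanSettings | None = None,
    amino_acid: str | None = None,
    long_cut: int = 12,
) -> float:
    """Fraction of tracts of length >= ``long_cut`` among tracts >= min_len.

    Returns NaN (an explicit "undefined" marker, never 0) when the set has
    no qualifying tract at all.
    """
    settings = settings or ScanSettings()
    tracts = _scan_all(list(peptides), settings)
    if amino_acid is not None:
        tracts = [t for t in tracts if t.amino_acid == amino_acid]
    if not tracts:
        return math.nan
    n_long = sum(1 for t in tracts if t.length >= long_cut)
    return n_long / len(tracts)


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-tailed pooled-variance z test for equality of two proportions.

    No continuity correction is applied.  Returns ``(z, p)``; when both
    samples have identical proportions (including the both-zero case) the
    statistic is 0 and p is 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    denom = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if denom == 0.0:
        return 0.0, 1.0
    z = (p1 - p2) / math.sqrt(denom)
    p = 2.0 * stats.norm.sf(abs(z))
    return z, min(p, 1.0)


def chi_square_homogeneity(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity on a k x 2 count table.

    Rows are groups (e.g. species), columns are success/failure counts.
    No continuity correction; df = k - 1.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("expected a k x 2 table")
    if np.any(table.sum(axis=1) <= 0):
        raise ValueError("all row sums must be positive")
    if np.any(table.sum(axis=0) == 0):
        raise ValueError("a column total of zero leaves the statistic undefined")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


@dataclass
class HpaaSummary:
    """Per-species HPAA summary statistics across the 20 amino acids."""

    species: str
    n_peptides: int
    n_residues: int
    peptide_frequency: pd.Series
    residue_proportion: pd.Series
    n_tracts: pd.Series
    n_long_tracts: pd.Series
    long_tract_fraction: pd.Series

    def to_frame(self) -> pd.DataFrame:
        """Matrix of the summary metrics (rows: amino acids plus ``"any"``)."""
        return pd.DataFrame(
            {
                "peptide_frequency": self.peptide_frequency,
                "residue_proportion": self.residue_proportion,
                "n_tracts": self.n_tracts,
                "n_long_tracts": self.n_long_tracts,
                "long_tract_fraction": self.long_tract_fraction,
            }
        )


def summarize_species(
    species: str,
    peptides: list[Peptide],
    settings: ScanSettings | None = None,
    long_cut: int = 12,
) -> HpaaSummary:
    """Full per-species summary: frequencies, proportions and long-tract stats."""
    peptides = list(peptides)
    settings = settings or ScanSettings()
    tracts = _scan_all(peptides, settings)
    keys = list(STANDARD_AA) + [ANY]
    n_tr = dict.fromkeys(keys, 0)
    n_long = dict.fromkeys(keys, 0)
    for t in tracts:
        for key in (t.amino_acid, ANY):
            n_tr[key] += 1
            if t.length >= long_cut:
                n_long[key] += 1
    frac = {k: (n_long[k] / n_tr[k] if n_tr[k] else math.nan) for k in keys}
    return HpaaSummary(
        species=species,
        n_peptides=len(peptides),
        n_residues=sum(len(p) for p in peptides),
        peptide_frequency=peptide_frequency_table(peptides, settings),
        residue_proportion=residue_proportion(peptides, settings),
        n_tracts=pd.Series(n_tr, name="n_tracts"),
        n_long_tracts=pd.Series(n_long, name="n_long_tracts"),
        long_tract_fraction=pd.Series(frac, name="long_tract_fraction"),
    )
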