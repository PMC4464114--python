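"""Synonymous substitution rates by Nei-Gojobori (1986) counting.

For each codon, each position contributes a synonymous-site fraction equal
to the proportion of its three possible nucleotide changes that leave the
amino acid unchanged; sites are averaged between the two sequences.
Differences between codon pairs are classified by averaging over all
orderings of the single-step mutational pathways.  The raw proportion
``ps = Sd / S`` is corrected for multiple hits with the Jukes-Cantor
formula ``Ks = -(3/4) ln(1 - (4/3) ps)``; pairs beyond the correction
domain are flagged as saturated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

__all__ = ["PairwiseKs", "ks_ng86"]

_BASES = "ACGT"
_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class PairwiseKs:
    """Ks result: synonymous sites S, differences Sd, corrected rate.

    ``ks`` is NaN and ``saturated`` True when ps >= 3/4, where the
    Jukes-Cantor correction is undefined.
    """

    ks: float
    s_sites: float
    s_diffs: float
    saturated: bool = False
    method: str = "NG86"


def _synonymous_site_fraction(codon: str) -> float:
    """Number of synonymous sites (0..3) of one codon."""
    aa = _CODON_TABLE.get(codon)
    if aa is None:
        raise ValueError(f"cannot count sites of stop or ambiguous codon {codon!r}")
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TABLE.get(mutant) == aa:
                syn += 1.0 / 3.0
    return syn


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, averaged over mutation orders.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all orders are used regardless (a documented fallback for rare
    codon pairs).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
                break
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        if not blocked:
            results.append((syn, nonsyn))
    if not results:
        for order in permutations(diff_pos):
            cur = c1
            syn = nonsyn = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if _CODON_TABLE.get(cur) == _CODON_TABLE.get(nxt):
                    syn += 1.0
                else:
                    nonsyn += 1.0
                cur = nxt
            results.append((syn, nonsyn))
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


def ks_ng86(cds1, cds2) -> PairwiseKs:
    """Nei-Gojobori Ks between two equal-length, gap-free, in-frame CDSs.

    Accepts raw strings or objects with a ``nucleotides`` attribute.  Codons
    containing N in either sequence are skipped.
    """
    nt1 = getattr(cds1, "nucleotides", cds1).upper()
    nt2 = getattr(cds2, "nucleotides", cds2).upper()
    if len(nt1) != len(nt2):
        raise ValueError("coding sequences must be aligned to equal length")
    if "-" in nt1 or "-" in nt2:
        raise ValueError("gapped codon alignments are not supported; strip gap codons first")
    if len(nt1) % 3:
        raise ValueError("length must be a multiple of 3")
    s_sites = 0.0
    s_diffs = 0.0
    for i in range(0, len(nt1), 3):
        c1, c2 = nt1[i : i + 3], nt2[i : i + 3]
        if "N" in c1 or "N" in c2:
            continue
        if c1 in _STOPS or c2 in _STOPS:
            raise ValueError(f"stop codon inside the alignment at codon {i // 3 + 1}")
        s_sites += (_synonymous_site_fraction(c1) + _synonymous_site_fraction(c2)) / 2.0
        sd, _ = _pathway_differences(c1, c2)
        s_diffs += sd
    if s_sites == 0.0:
        raise ValueError("no synonymous sites in the alignment")
    ps = s_diffs / s_sites
    if ps >= 0.75:
        return PairwiseKs(ks=math.nan, s_sites=s_sites, s_diffs=s_diffs, saturated=True)
    ks = -0.75 * math.log(1.0 - 4.0 * ps / 3.0)
    return PairwiseKs(ks=ks, s_sites=s_sites, s_diffs=s_diffs)
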