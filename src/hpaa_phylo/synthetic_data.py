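"""Synthetic data with known ground truth for the whole pipeline.

Three generators:

* ``generate_proteome`` — peptides drawn i.i.d. from a residue frequency
  vector, with homopolymer tracts inserted at controlled per-amino-acid
  probabilities and geometric lengths; emulates the genome-wide scan input
  where every true tract is known.
* ``simulate_protein_evolution`` — sequences evolved along a tree with
  branch lengths under the amino-acid substitution model with discrete-gamma
  site rates (no indels).
* ``make_scenario`` — a six-leaf gene family (three gnathostome subtype
  OTUs, two cyclostome paralogs, one outgroup) evolved under one of two
  duplication-timing histories: both paralog-creating duplications on the
  stem before the cyclostome-gnathostome split, or independent duplications
  inside each lineage.  Convergent homopolymer tracts can be injected into
  chosen leaves after simulation, mimicking lineage-specific tract
  expansion by replication slippage.

One master seed derives independent per-stage streams, so every replicate
is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dup_count import (
    CYCLOSTOME,
    GNATHOSTOME,
    OUTGROUP,
    DupCounts,
    SpeciesAssignment,
    topology_counts,
)
from .phylo_core import SubstitutionModel, Tree
from .phylo_core.model import AA_ORDER
from .proteome_io import Peptide

__all__ = [
    "ProteomeSpec",
    "HpaaInjection",
    "ScenarioSpec",
    "ScenarioResult",
    "generate_proteome",
    "simulate_protein_evolution",
    "make_scenario",
]


@dataclass(frozen=True)
class ProteomeSpec:
    """Parameters of a synthetic proteome with controlled tract statistics."""

    n_peptides: int = 1000
    min_length: int = 150
    max_length: int = 450
    residue_frequencies: dict[str, float] | None = None  # default: uniform over 20
    tract_probabilities: dict[str, float] = field(default_factory=dict)
    tract_min_length: int = 6
    tract_geometric_p: float = 0.5
    species: str = "synthetic"
    seed: int = 0

    def frequency_vector(self) -> np.ndarray:
        if self.residue_frequencies is None:
            return np.full(20, 0.05)
        freqs = np.array([self.residue_frequencies.get(aa, 0.0) for aa in AA_ORDER])
        total = freqs.sum()
        if total <= 0:
            raise ValueError("residue frequencies must have positive sum")
        return freqs / total


def generate_proteome(spec: ProteomeSpec) -> tuple[list[Peptide], pd.DataFrame]:
    """Generate peptides plus a truth table of every inserted tract.

    Tract insertion is per peptide and per amino acid: with the configured
    probability a single tract of geometric length (floored at
    ``tract_min_length``) is inserted at a uniform position.  Positions in
    the truth table are 0-based offsets in the final sequence; an inserted
    tract abutting an identical chance residue may be detected as a longer
    run by the scanner.
    """
    for aa, p in spec.tract_probabilities.items():
        if aa not in AA_ORDER:
            raise ValueError(f"unknown amino acid {aa!r}")
        if not 0.0 <= p <= 1.0:
            raise ValueError("tract probabilities must lie in [0, 1]")
    if spec.tract_min_length > spec.min_length:
        raise ValueError("tract length floor exceeds the minimum peptide length")
    rng = np.random.default_rng(spec.seed)
    freqs = spec.frequency_vector()
    letters = np.frombuffer(AA_ORDER.encode(), dtype="S1")
    peptides = []
    truth_rows = []
    for i in range(spec.n_peptides):
        pid = f"{spec.species}_{i:05d}"
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        seq = b"".join(rng.choice(letters, size=length, p=freqs)).decode()
        # plan insertions in original coordinates, apply right to left
        plans = []
        for aa in AA_ORDER:
            p = spec.tract_probabilities.get(aa, 0.0)
            if p and rng.random() < p:
                tract_len = spec.tract_min_length + int(rng.geometric(spec.tract_geometric_p)) - 1
                pos = int(rng.integers(0, length + 1))
                plans.append((pos, aa, tract_len))
        for pos, aa, tract_len in sorted(plans, reverse=True):
            seq = seq[:pos] + aa * tract_len + seq[pos:]
        offset = 0
        for pos, aa, tract_len in sorted(plans):
            truth_rows.append(
                {"peptide_id": pid, "amino_acid": aa, "start": pos + offset, "length": tract_len}
            )
            offset += tract_len
        peptides.append(Peptide(id=pid, sequence=seq, species=spec.species))
    truth = pd.DataFrame(truth_rows, columns=["peptide_id", "amino_acid", "start", "length"])
    return peptides, truth


def simulate_protein_evolution(
    tree: Tree, model: SubstitutionModel, length: int, seed: int | None = None
) -> dict[str, str]:
    """Evolve sequences down a tree; returns leaf label -> sequence.

    The root sequence is drawn from the stationary frequencies; each site
    evolves independently with a fixed gamma-category rate shared along the
    whole tree (plus a zero-rate class when the model has +I).  No indels.
    """
    if length < 1:
        raise ValueError("length must be at least 1")
    for node in tree.edges():
        if node.length is None or node.length < 0:
            raise ValueError("every branch needs a non-negative length")
    rng = np.random.default_rng(seed)
    rates = model.variable_rates()
    weights = model.variable_weights()
    if model.p_inv:
        rates = np.concatenate([[0.0], rates])
        weights = np.concatenate([[model.p_inv], weights])
    site_cat = rng.choice(rates.size, size=length, p=weights / weights.sum())
    pi = model.frequencies
    root_states = rng.choice(20, size=length, p=pi)

    sequences: dict[str, str] = {}

    def descend(node, states: np.ndarray) -> None:
        for child in node.children:
            pmats = model.transition_matrices(np.array([child.length]), rates)[0]
            cum = np.cumsum(pmats, axis=2)  # (C, 20, 20)
            u = rng.random(length)
            child_states = np.empty(length, dtype=np.int64)
            for c in range(rates.size):
                mask = site_cat == c
                if not mask.any():
                    continue
                rows = cum[c][states[mask]]  # (k, 20)
                child_states[mask] = (u[mask, None] > rows).sum(axis=1)
            if child.is_leaf:
                sequences[child.label] = "".join(AA_ORDER[s] for s in child_states)
            else:
                descend(child, child_states)

    descend(tree.root, root_states)
    return sequences


@dataclass(frozen=True)
class HpaaInjection:
    """One convergent tract insertion: leaf, amino acid, length, 0-based position."""

    leaf: str
    amino_acid: str
    length: int
    position: int


@dataclass(frozen=True)
class ScenarioSpec:
    """A duplication-timing scenario for the six-OTU gene family.

    ``before_split`` places both paralog-creating duplications on the stem
    lineage before the cyclostome-gnathostome split (the shared-origin
    history); ``independent`` places duplications separately inside the
    gnathostome and cyclostome lineages (the convergence history).  Node
    depths are in expected substitutions per site; defaults keep every
    internal branch at 0.08 or longer.
    """

    scenario: str = "before_split"
    sequence_length: int = 300
    alpha: float = 0.5
    ncat: int = 4
    outgroup_depth: float = 1.0
    split_depth: float = 0.5
    injections: tuple[HpaaInjection, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("before_split", "independent"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 < self.split_depth < self.outgroup_depth:
            raise ValueError("depths must satisfy 0 < split < outgroup")
        for inj in self.injections:
            if inj.position > self.sequence_length:
                raise ValueError("injection position beyond sequence length")
            if inj.amino_acid not in AA_ORDER:
                raise ValueError(f"unknown amino acid {inj.amino_acid!r}")

    def true_tree_newick(self) -> str:
        s, o = self.split_depth, self.outgroup_depth
        if self.scenario == "before_split":
            d1 = s + 0.3 * (o - s)   # first duplication above the split
            d2 = s + 0.6 * (o - s)   # second duplication, still on the stem
            return (
                f"((((g1:{s:g},cA:{s:g}):{d1 - s:g},(g2:{s:g},cB:{s:g}):{d1 - s:g})"
                f":{d2 - d1:g},g3:{d2:g}):{o - d2:g},out:{o:g});"
            )
        g1d = 0.56 * s   # younger gnathostome duplication
        g2d = 0.84 * s   # older gnathostome duplication
        cd = 0.6 * s     # cyclostome duplication
        return (
            f"((((g1:{g1d:g},g3:{g1d:g}):{g2d - g1d:g},g2:{g2d:g}):{s - g2d:g},"
            f"(cA:{cd:g},cB:{cd:g}):{s - cd:g}):{o - s:g},out:{o:g});"
        )


DEFAULT_ASSIGNMENT = SpeciesAssignment(
    {
        "g1": GNATHOSTOME,
        "g2": GNATHOSTOME,
        "g3": GNATHOSTOME,
        "cA": CYCLOSTOME,
        "cB": CYCLOSTOME,
        "out": OUTGROUP,
    }
)


@dataclass
class ScenarioResult:
    """Simulated gene family with its generating truth."""

    spec: ScenarioSpec
    tree: Tree
    sequences: dict[str, str]
    assignment: SpeciesAssignment
    truth_counts: DupCounts
    injection_table: pd.DataFrame

    def intact_sequences(self) -> dict[str, str]:
        return dict(self.sequences)

    def delta_hpaa_sequences(self) -> dict[str, str]:
        """Sequences with every injected tract excised (the control arm)."""
        out = dict(self._pre_injection)
        return out

    _pre_injection: dict[str, str] = field(default_factory=dict)


def make_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Simulate a gene family under the chosen duplication-timing history."""
    tree = Tree.from_newick(spec.true_tree_newick())
    model = SubstitutionModel(alpha=spec.alpha, ncat=spec.ncat)
    master = np.random.default_rng(spec.seed)
    sim_seed = int(master.integers(2**31))
    sequences = simulate_protein_evolution(tree, model, spec.sequence_length, seed=sim_seed)
    pre_injection = dict(sequences)

    rows = []
    by_leaf: dict[str, list[HpaaInjection]] = {}
    for inj in spec.injections:
        if inj.leaf not in sequences:
            raise ValueError(f"injection names unknown leaf {inj.leaf!r}")
        by_leaf.setdefault(inj.leaf, []).append(inj)
    for leaf, injections in by_leaf.items():
        seq = sequences[leaf]
        for inj in sorted(injections, key=lambda i: i.position, reverse=True):
            seq = seq[: inj.position] + inj.amino_acid * inj.length + seq[inj.position :]
        offset = 0
        for inj in sorted(injections, key=lambda i: i.position):
            rows.append(
                {
                    "leaf": leaf,
                    "amino_acid": inj.amino_acid,
                    "start": inj.position + offset,
                    "length": inj.length,
                }
            )
            offset += inj.length
        sequences[leaf] = seq

    truth = topology_counts(tree, DEFAULT_ASSIGNMENT, mode="outgroup")
    result = ScenarioResult(
        spec=spec,
        tree=tree,
        sequences=sequences,
        assignment=DEFAULT_ASSIGNMENT,
        truth_counts=truth,
        injection_table=pd.DataFrame(rows, columns=["leaf", "amino_acid", "start", "length"]),
    )
    result._pre_injection = pre_injection
    return result


def scenario_duplication_counts(
    spec: ScenarioSpec,
    rell_replicates: int = 2000,
    rell_seed: int | None = None,
    opt_tol: float = 3e-3,
    max_sweeps: int = 6,
) -> tuple[DupCounts, "ScenarioResult"]:
    """Full pipeline on one simulated replicate: BP-weighted duplication counts.

    Simulates the gene family, enumerates all 105 six-OTU topologies,
    optimizes branch lengths and collects per-site log-likelihoods for each,
    runs the RELL bootstrap, and returns the BP-weighted counts together
    with the simulated replicate.  ``rell_seed`` defaults to a stream
    derived from the scenario seed.
    """
    from .phylo_core import Alignment, enumerate_topologies
    from .topology_tests import rell_bootstrap, score_topologies

    result = make_scenario(spec)
    alignment = Alignment.from_dict(result.sequences)
    model = SubstitutionModel(alpha=spec.alpha, ncat=spec.ncat)
    topologies = enumerate_topologies(sorted(result.sequences))
    matrix = score_topologies(
        alignment, topologies, model, tol=opt_tol, max_sweeps=max_sweeps
    )
    if rell_seed is None:
        rell_seed = int(np.random.default_rng(spec.seed + 1).integers(2**31))
    bp = rell_bootstrap(matrix, n_replicates=rell_replicates, seed=rell_seed)
    from .dup_count import probabilistic_counts

    counts = probabilistic_counts(topologies, bp, result.assignment)
    return counts, result


def convergent_cyclostome_injections(
    tract_length: int = 20, positions: tuple[int, int] = (5, 35)
) -> tuple[HpaaInjection, ...]:
    """Convergent poly-A and poly-Q tracts in both cyclostome paralogs.

    Mirrors the observed situation where both lamprey Emx paralogs carry
    alanine and glutamine tracts in the N-terminal domain, close to the
    start of the protein, while no other lineage has them.
    """
    a_pos, q_pos = positions
    return tuple(
        HpaaInjection(leaf, aa, tract_length, pos)
        for leaf in ("cA", "cB")
        for aa, pos in (("A", a_pos), ("Q", q_pos))
    )
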