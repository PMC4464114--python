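# Methods

This note documents the models, algorithms, default parameters and known
limitations of `hpaa-phylo`. It is the package's scientific reference; the
README gives the quick tour.

## Problem setting

Lamprey proteins carry homopolymeric amino-acid (HPAA) tracts — maximal
runs of one residue, canonically polyalanine and polyglutamine — at
unusually high frequency. When two ancient paralogs of a gene family
independently accumulate similar tracts, multiple-alignment programs can
couple the two sequences through those low-complexity regions, and the
resulting misalignment can manufacture phylogenetic support for an
"exclusive grouping" of the two paralogs, i.e. for a spurious
lineage-specific duplication. The package provides the machinery to
quantify tract statistics genome-wide, to evaluate all candidate gene-tree
topologies by maximum likelihood with resampling support, to convert
topology support into expected duplication counts relative to the
cyclostome–gnathostome split, and to measure the alignment artifact
directly in a controlled synthetic setting.

## Sequence handling and homology filtering (`proteome_io`)

Peptides are uppercased; one trailing `*` is stripped; internal stops are
invalid. One representative (longest) splice variant per gene is kept,
with lexicographic id as tie-break so the choice is order-independent.

The cross-species reciprocal-homology filter keeps a peptide only if, for
each of the other two species, some cross-species pair involving it
reaches a bit score of at least `min_bits` (default 200) in both search
directions. The builtin backend scores pairs by Smith–Waterman local
alignment (BLOSUM62, gap open 11 / extend 1 via biopython's
`PairwiseAligner`, where the open score applies to the first gap residue)
and converts raw scores to bits with gapped Karlin–Altschul parameters
`lambda = 0.267`, `k = 0.041`. Because the scorer is symmetric,
reciprocity reduces to a single computation per pair. The `external`
backend shells out to `blastp` (with `-seg yes -soft_masking true`) when
available. Ambiguity letters (B, Z, X) score as in BLOSUM62; U, O and J
score at the matrix minimum.

## HPAA scanning (`hpaa_scan`)

A tract is a *maximal* run of one standard residue with length at least
`min_len` (default 6; 8 and 10 serve as robustness checks; 12 is the cut
for "long" tracts). A length-8 run is one tract of length 8, never several
overlapping length-6 tracts. Ambiguity characters terminate runs and never
form tracts. Coordinates are 0-based half-open internally and 1-based
inclusive in exported tables.

Per species the module reports, for each amino acid and pooled over all
twenty ("any"):

* peptide frequency — fraction of peptides containing at least one tract
  (a peptide with tracts of several amino acids counts once per amino acid
  but only once in "any");
* residue proportion — residues inside tracts over all residues;
* long-tract fraction — tracts of length ≥ 12 among tracts ≥ 6, reported
  as NaN (undefined), never 0, when the denominator is empty.

Species are compared with a pooled-variance two-proportion z test and a
Pearson chi-square homogeneity test on k×2 tables, both without
continuity correction (large-sample usage).

## Substitution model and likelihoods (`phylo_core`)

The amino-acid model is JTT: exchangeabilities `s_ij` and stationary
frequencies `pi` combine to rates `q_ij = s_ij pi_j`, scaled to one
expected substitution per unit branch length. Optional terms:

* **+G** — Yang's discrete gamma with `ncat` (default 4) equal-probability
  categories, each represented by its conditional mean; rates average
  exactly 1 and increase with category index. Default shape `alpha = 0.5`
  for simulations; fit by bounded search on the log scale when estimated.
* **+I** — a zero-rate class with proportion `p_inv`; variable-class rates
  are rescaled by `1/(1 - p_inv)` so the overall mean rate remains 1.
* **+F** — empirical alignment-wide frequencies with a small pseudocount.

Per-site log-likelihoods come from Felsenstein pruning, vectorized over
sites and rate categories, with per-site rescaling and alignment-column
pattern compression. Gaps and ambiguity codes are missing data (partial
likelihood 1 over all states); no column is dropped by the engine itself —
column filtering is the alignment-sensitivity stage's job. The transition
matrices are computed from one symmetric eigendecomposition of the
generator, which also underlies the optimizers below. Likelihoods are
invariant under rerooting and leaf order (reversibility), which the test
suite asserts.

Branch lengths are bounded to [1e-8, 20]. Two optimizers are provided:

* `optimize` — coordinate-wise bounded Brent per branch, iterated to a
  log-likelihood tolerance of 1e-6; the reference, contract-level
  optimizer (monotone in logL).
* `optimize_fast` — the pipeline optimizer used when a hundred topologies
  must be scored per replicate. Each sweep computes inside ("down") and
  outside ("up") partial likelihoods once, projects each edge into the
  generator's eigenbasis, and line-searches the edge length on a
  multiplicative grid (span 8, 11 points) with one parabolic refinement in
  log-length; partials are held fixed within a sweep and an exact full
  evaluation guards every sweep (roll back and stop if it ever fails to
  improve). Default stopping tolerance 1e-4. On test problems it reaches
  the Brent optimum to within ~0.05 logL at roughly a tenth of the cost;
  its per-edge likelihoods agree with the exact pruning evaluation to
  machine precision at fixed lengths.

Exhaustive topology sets are produced by stepwise leaf insertion, giving
the (2n−5)!! unrooted binary topologies (3, 15, 105, 945 for n = 4..7);
constraint groups collapse a set of sequence ids into one OTU whose inner
topology is frozen and re-expanded in the output. Enumeration beyond 9
OTUs requires an explicit override.

Companion methods: neighbor joining with a deterministic smallest-label
tie-break and three-point terminal branch lengths; Kimura-corrected
protein distances `d = −ln(1 − p − p²/5)` with an infinity marker beyond
the correction domain; nonparametric bootstrap support over bipartitions
(0–100 scale); and Nei–Gojobori (1986) Ks with equal-pathway averaging
(pathways through stops excluded) and Jukes–Cantor correction, flagged as
saturated at `ps ≥ 3/4`.

## Topology tests (`topology_tests`)

RELL resamples site columns multinomially (default 10,000 replicates, seed
mandatory) and never re-optimizes branch lengths; the bootstrap
probability of a topology is the fraction of replicates in which it
attains the maximal resampled total, with exact ties split equally, so BPs
sum to 1. The one-sided Kishino–Hasegawa test centers the resampled
log-likelihood difference to the ML topology empirically and reports the
upper-tail probability at the observed difference; the
Shimodaira–Hasegawa test centers every topology's resampled totals and
compares against the simultaneous maximum. Both tests share one resample
matrix, which makes `SH p ≥ KH p` an identity rather than a tendency, and
the ML topology reports exactly 1.00 in both by the usual convention. The
standard error attached to each ΔlogL is the KH site-wise estimate
`sqrt(n · var(per-site differences))`.

Clade support for a leaf set is the summed BP of topologies in which the
set forms a bipartition of the unrooted tree — the statistic used
throughout the sensitivity experiment.

## Duplication counting (`dup_count`)

The species tree is fixed as `(outgroup, (cyclostome, gnathostome))`. Each
enumerated topology is rooted on the outgroup edge (always possible when
the outgroup is one collapsed OTU), the outgroup is removed, and the
ingroup tree is reconciled by LCA mapping: a node is a duplication exactly
when it maps to the same species-tree node as at least one child.
Duplications at the cyclostome–gnathostome ancestor count toward N_bef,
inside the gnathostome lineage toward N_aft, inside the cyclostome lineage
toward N_cyc; in this mode N_unk = 0 per topology. BP-weighted sums over
the exhaustive topology set give the probabilistic (expected) counts.

An optional rooting-agnostic mode reconciles the full tree under every
branch rooting, restricts attention to rootings with the minimal total
duplication count, credits each timing class with its minimum over those
rootings, and books the remainder as N_unk (timing unresolved). This is a
documented best-effort reconstruction of "unknown-timing" counting; it has
not been validated against the original implementation of that column and
should be treated as indicative.

## Alignment sensitivity (`align_sensitivity`)

`delete_hpaa` excises non-overlapping tract spans right to left. The
experiment grid crosses aligner × trimming stringency × arm (intact vs
tract-deleted), runs the full enumerate → optimize → RELL → clade-support
pipeline in every cell with one model and one RELL seed, and records the
support for the focal clade plus the retained-site count; a failing cell
is marked failed without aborting the grid.

The builtin aligner is a deliberately plain progressive aligner: guide
clustering by average-linkage shared-3-mer distance with deterministic
name tie-breaks, profile–profile global alignment under BLOSUM62 with
affine gaps (open 10 / extend 0.5), and — like the classic progressive
aligners whose behaviour the experiment studies — position-specific gap
costs: inside a run of five or more majority-hydrophilic columns
(`G P S N D Q E K R`), open and extension costs are scaled by 0.3, which
steers gaps into loop-like, low-complexity neighbourhoods. This is the
documented mechanism by which homopolymer tracts disturb alignment of
their flanks: the cheap gap sites near a polyglutamine tract pull the
compensating gaps of tract-free sequences away from the tract itself, so
tract and flank residues of the two tract-bearing sequences end up aligned
against non-homologous residues in columns that survive gap filtering.
Adapters for `mafft`, `clustalw` and `t_coffee` shell out when the binary
exists and fall back to the builtin aligner with a warning.

Trimming first removes every column containing a gap, then (for `st` > 0)
columns whose mean pairwise BLOSUM62 similarity, rescaled to [0, 1], falls
below `st`. This reproduces the semantics "low-similarity columns are
removed as the threshold rises", not any external tool's exact score;
absolute retained-site counts are therefore only approximate, and the five
grid levels (0, 0.00005, 0.0001, 0.0005, 0.001) are nominal stringencies.

## Synthetic data (`synthetic_data`)

The generator is the package's ground-truth instrument; its defaults *are*
the study conditions of the tests.

**Proteomes.** Peptides are i.i.d. draws from a residue-frequency vector
(default uniform 0.05), lengths uniform on [150, 450]. Per peptide and per
amino acid, a tract is inserted with the configured probability at a
uniform position, with geometric length floored at 6 (p = 0.5). Every
insertion is recorded in a truth table; an inserted tract that abuts a
chance identical residue may be detected as a longer run, which the
calibration tests tolerate by testing per-amino-acid peptide frequencies
(insertion probability) rather than exact tract lengths. Chance-run rates
in tract-free proteomes follow the i.i.d. formula
`E[#runs ≥ L] = q^L (1 + (n−L)(1−q))` per sequence.

**Gene families.** Six leaves — three gnathostome subtype OTUs (g1, g2,
g3), two cyclostome paralogs (cA, cB), one outgroup — evolve under
JTT+G4 (alpha 0.5, length 300, no indels) along one of two histories, with
the outgroup at depth 1.0 and the cyclostome–gnathostome split at 0.5
substitutions/site:

* `before_split` — both paralog-creating duplications on the stem (depths
  0.65 and 0.8), so cA pairs with g1 and cB with g2 by speciation; true
  counts N_bef = 2, N_cyc = 0.
* `independent` — duplications inside each lineage (gnathostome at 0.28
  and 0.42, cyclostome at 0.30); true counts N_bef = 0, N_aft = 2,
  N_cyc = 1.

All internal branches are at least 0.08 substitutions/site, long enough
for the 300-site pipeline to recover the generating history in the large
majority of replicates while leaving a realistic spread of BP over
topologies. One master seed drives per-stage substreams, so replicates are
bit-reproducible.

**Tract injection.** HPAA tracts are inserted into designated leaves after
substitution simulation (insertion, not substitution — mimicking expansion
by replication slippage), with fixed per-plan lengths for determinism. The
default convergent plan places a 20-residue polyalanine at position 5 and
a 20-residue polyglutamine at position 35 of both cyclostome paralogs,
mirroring the N-terminal location and size of the tracts observed in the
real lamprey Emx proteins.

What the generator does *not* emulate: indel evolution in the background
sequences, GC/codon-usage bias, among-lineage composition bias, and rate
variation across lineages. Passing tests on this generator therefore show
that the pipeline machinery is correct and that the tract-convergence
mechanism operates as described; they do not certify behaviour on real
proteomes, where alignment difficulty is compounded by indels and
composition bias.

## Numerical and design choices

* Branch-length bounds [1e-8, 20]; optimizer tolerances as above; the
  pipeline helpers (`scenario_duplication_counts`, the sensitivity grid)
  default to `tol = 3e-3` with at most 6 sweeps, which changes individual
  topology log-likelihoods by well under 0.5 and leaves their ranking on
  test problems unchanged.
* RELL replicates: 10,000 for reported tables; 2,000–5,000 inside
  replicated simulation studies, where the replicate-level Monte-Carlo
  error is dominated by simulation variance.
* Exact resampling ties split equally; NJ criterion ties break toward the
  lexicographically smallest cluster-name pair; representative-isoform
  ties break toward the smaller peptide id.
* Degenerate inputs: empty peptide sets raise; zero-length alignments
  raise; tract statistics with empty denominators return NaN; protein
  distances beyond the Kimura domain return infinity; Ks beyond the
  Jukes–Cantor domain is flagged saturated.
* The scenario-recovery and artifact experiments use 50 and 30 replicates
  respectively in the test suite, and moderately smaller replicate counts
  in the acceptance script; both sizes are stated in the scripts
  themselves.

## Known limitations

* Only JTT (+G/+I/+F) is implemented; no model selection across matrices.
* No heuristic tree search: topology sets must be exhaustively enumerable
  after constraint collapsing (≤ 9 OTUs).
* The builtin aligner is intentionally naive; it is a study instrument for
  alignment-induced artifacts, not a general-purpose aligner.
* The rooting-agnostic N_unk is a best-effort definition (see above).
* Ks is NG86 with Jukes–Cantor correction; no codon-model or
  maximum-likelihood Ks.
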