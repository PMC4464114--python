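"""Tests for the likelihood engine, enumeration, NJ, distances and Ks."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from hpaa_phylo.phylo_core import (
    Alignment,
    SubstitutionModel,
    Tree,
    TreeLikelihood,
    bootstrap_support,
    discretize_gamma,
    enumerate_topologies,
    ks_ng86,
    n_unrooted_topologies,
    nj_tree,
    optimize_branch_lengths,
    protein_distance,
    site_log_likelihoods,
)
from hpaa_phylo.phylo_core.model import AA_INDEX, AA_ORDER
from hpaa_phylo.phylo_core.topology import ConstraintGroups

from conftest import random_alignment


class TestDiscretizeGamma:
    def test_single_category_is_unit_rate(self):
        assert discretize_gamma(0.7, 1).tolist() == [1.0]

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.17, 5.0])
    def test_rates_average_to_one_and_increase(self, alpha):
        rates = discretize_gamma(alpha, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(rates) > 0)

    def test_matches_quadrature_oracle(self):
        # conditional means of equal-probability bins by adaptive quadrature
        alpha, ncat = 0.5, 4
        cuts = gamma_dist.ppf(np.arange(1, ncat) / ncat, a=alpha, scale=1 / alpha)
        bounds = [0.0, *cuts, np.inf]
        expected = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mass, _ = quad(lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1 / alpha), lo, hi)
            expected.append(mass * ncat)
        assert discretize_gamma(alpha, ncat) == pytest.approx(expected, rel=1e-6)

    def test_invalid_alpha_errors(self):
        with pytest.raises(ValueError):
            discretize_gamma(0.0, 4)


def brute_force_site_logl(alignment, lengths, model):
    """Exhaustive sum over both internal states of ((A,B),C,D) per site."""
    ta, tb, tc, td, t5 = lengths
    rates = model.variable_rates()
    weights = model.variable_weights()
    pi = model.frequencies
    codes = alignment.codes(["A", "B", "C", "D"])
    out = []
    for s in range(codes.shape[1]):
        a, b, c, d = codes[:, s]
        total = 0.0
        for r, w in zip(rates, weights):
            mats = {
                t: model.transition_matrices(np.array([t]), np.array([r]))[0, 0]
                for t in (ta, tb, tc, td, t5)
            }
            sub = 0.0
            for x in range(20):
                for y in range(20):
                    sub += (
                        pi[x]
                        * mats[tc][x, c]
                        * mats[td][x, d]
                        * mats[t5][x, y]
                        * mats[ta][y, a]
                        * mats[tb][y, b]
                    )
            total += w * sub
        out.append(math.log(total))
    return np.array(out)


class TestPruning:
    def test_identical_sequences_zero_branches_give_log_pi(self, jtt_g4):
        aln = Alignment.from_dict({"a": "MKV", "b": "MKV"})
        tree = Tree.from_newick("(a:0.00000001,b:0.00000001);")
        sl = site_log_likelihoods(aln, tree, jtt_g4)
        expected = [math.log(jtt_g4.frequencies[AA_INDEX[ch]]) for ch in "MKV"]
        assert sl == pytest.approx(expected, abs=1e-6)

    def test_matches_brute_force_state_sum(self, rng, jtt_g4):
        for _ in range(5):
            aln = random_alignment(rng, ["A", "B", "C", "D"], 10)
            lengths = rng.uniform(0.05, 1.0, 5)
            ta, tb, tc, td, t5 = lengths
            tree = Tree.from_newick(f"((A:{ta},B:{tb}):{t5},C:{tc},D:{td});")
            assert site_log_likelihoods(aln, tree, jtt_g4) == pytest.approx(
                brute_force_site_logl(aln, lengths, jtt_g4), abs=1e-8
            )

    def test_invariant_under_rerooting_and_leaf_order(self, rng, jtt_g4):
        aln = random_alignment(rng, ["A", "B", "C", "D"], 20)
        tree = Tree.from_newick("((A:0.2,B:0.3):0.15,C:0.25,D:0.1);")
        ref = site_log_likelihoods(aln, tree, jtt_g4)
        for clade in [frozenset({"C"}), frozenset({"A", "B"}), frozenset({"A"})]:
            rerooted = tree.rerooted_on_edge(clade)
            assert site_log_likelihoods(aln, rerooted, jtt_g4) == pytest.approx(ref, abs=1e-8)
        shuffled = Alignment(aln.ids[::-1], aln.rows[::-1])
        assert site_log_likelihoods(shuffled, tree, jtt_g4) == pytest.approx(ref, abs=1e-10)

    def test_gap_and_ambiguity_treated_as_missing(self, jtt_g4):
        aln1 = Alignment.from_dict({"a": "M-X", "b": "MKV"})
        tree = Tree.from_newick("(a:0.1,b:0.1);")
        sl = site_log_likelihoods(aln1, tree, jtt_g4)
        # a site that is missing in one sequence reduces to the other's marginal
        only_b = [math.log(jtt_g4.frequencies[AA_INDEX[ch]]) for ch in "KV"]
        assert sl[1:] == pytest.approx(only_b, abs=1e-10)

    def test_plus_i_model_mixes_invariant_class(self):
        model = SubstitutionModel(alpha=0.5, ncat=4, p_inv=0.3)
        aln = Alignment.from_dict({"a": "MM", "b": "MK"})
        tree = Tree.from_newick("(a:0.2,b:0.2);")
        sl = site_log_likelihoods(aln, tree, model)
        # constant site gains from the invariant class, variable site cannot
        pi_m = model.frequencies[AA_INDEX["M"]]
        assert math.exp(sl[0]) > 0.3 * pi_m
        assert np.isfinite(sl).all()

    def test_id_mismatch_errors(self, jtt_g4):
        aln = Alignment.from_dict({"a": "M", "z": "M"})
        tree = Tree.from_newick("(a:0.1,b:0.1);")
        with pytest.raises(ValueError, match="leaves"):
            site_log_likelihoods(aln, tree, jtt_g4)


class TestBranchOptimization:
    def test_identical_sequences_shrink_to_lower_bound(self, jtt_g4):
        aln = Alignment.from_dict({"a": "MKVLYRA" * 4, "b": "MKVLYRA" * 4})
        tree = Tree.from_newick("(a:0.3,b:0.3);")
        fitted, _ = optimize_branch_lengths(aln, tree, jtt_g4)
        assert sum(n.length for n in fitted.edges()) < 1e-4

    def test_two_taxon_length_matches_grid_search_oracle(self, rng, jtt_g4):
        anc = "".join(rng.choice(list(AA_ORDER), 150))
        p = jtt_g4.transition_matrices(np.array([0.4]), np.ones(1))[0, 0]
        der = "".join(AA_ORDER[rng.choice(20, p=p[AA_INDEX[ch]])] for ch in anc)
        aln = Alignment.from_dict({"a": anc, "b": der})
        fitted, logl = optimize_branch_lengths(aln, Tree.from_newick("(a:0.1,b:0.1);"), jtt_g4)
        total = sum(n.length for n in fitted.edges())
        grid = np.linspace(0.01, 2.0, 400)
        scores = [
            TreeLikelihood(aln, Tree.from_newick(f"(a:{g / 2},b:{g / 2});"), jtt_g4).log_likelihood()
            for g in grid
        ]
        best = grid[int(np.argmax(scores))]
        assert total == pytest.approx(best, abs=1e-2)
        assert logl >= max(scores) - 1e-6

    def test_logl_never_decreases_and_fast_matches_exact(self, rng, jtt_g4):
        aln = random_alignment(rng, ["A", "B", "C", "D"], 40)
        tree = Tree.from_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        engine = TreeLikelihood(aln, tree.copy(), jtt_g4)
        start = engine.log_likelihood()
        exact = engine.optimize()
        assert exact >= start
        fast_engine = TreeLikelihood(aln, tree.copy(), jtt_g4)
        fast = fast_engine.optimize_fast()
        assert fast >= start
        assert fast == pytest.approx(exact, abs=0.05)


class TestEnumeration:
    @pytest.mark.parametrize("n, count", [(4, 3), (5, 15), (6, 105), (7, 945)])
    def test_double_factorial_counts(self, n, count):
        labels = [f"t{i}" for i in range(n)]
        topologies = enumerate_topologies(labels)
        assert len(topologies) == count == n_unrooted_topologies(n)
        splits = {frozenset(map(frozenset, t.bipartitions())) for t in topologies}
        assert len(splits) == count  # all topologies distinct

    def test_constraint_groups_expanded_verbatim(self):
        constraints = ConstraintGroups({"g1": "((m,h),f)"})
        topologies = enumerate_topologies(["g1", "cA", "cB", "out"], constraints)
        assert len(topologies) == 3
        for t in topologies:
            assert {"m", "h", "f", "cA", "cB", "out"} == set(t.leaf_names())
            assert t.has_bipartition({"m", "h", "f"})

    def test_guard_refuses_large_inputs_unless_forced(self):
        labels = [f"t{i}" for i in range(10)]
        with pytest.raises(ValueError, match="force"):
            enumerate_topologies(labels)

    def test_too_few_otus_error(self):
        with pytest.raises(ValueError):
            enumerate_topologies(["a", "b"])


class TestNeighborJoining:
    def test_three_taxa_solves_three_point_equations(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(d, ["a", "b", "c"])
        lengths = {n.label: n.length for n in tree.root.children}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_matrix_recovers_tree_and_lengths(self):
        # distances from ((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07) are additive
        true = Tree.from_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07);")
        labels = ["A", "B", "C", "D"]
        paths = {
            ("A", "B"): 0.3,
            ("A", "C"): 0.1 + 0.05 + 0.07 + 0.3,
            ("A", "D"): 0.1 + 0.05 + 0.07 + 0.15,
            ("B", "C"): 0.2 + 0.05 + 0.07 + 0.3,
            ("B", "D"): 0.2 + 0.05 + 0.07 + 0.15,
            ("C", "D"): 0.45,
        }
        d = np.zeros((4, 4))
        for (u, v), val in paths.items():
            i, j = labels.index(u), labels.index(v)
            d[i, j] = d[j, i] = val
        tree = nj_tree(d, labels)
        assert tree.bipartitions() == true.bipartitions()
        total = sum(n.length for n in tree.edges())
        assert total == pytest.approx(sum(paths[k] for k in [("A", "B"), ("C", "D")]) + 0.12)

    def test_equal_distances_resolved_by_deterministic_tie_break(self):
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        t1 = nj_tree(d, ["a", "b", "c", "d"])
        t2 = nj_tree(d, ["a", "b", "c", "d"])
        assert t1.to_newick() == t2.to_newick()
        assert t1.has_bipartition({"a", "b"})  # smallest label pair joined first

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d, ["a", "b"])

    def test_random_additive_trees_roundtrip(self, rng):
        import dendropy

        for _ in range(5):
            labels = [f"t{i}" for i in range(6)]
            topo = enumerate_topologies(labels)[rng.integers(105)]
            for node in topo.edges():
                node.length = float(rng.uniform(0.05, 0.5))
            dt = dendropy.Tree.get(data=topo.to_newick(), schema="newick")
            pdm = dt.phylogenetic_distance_matrix()
            tax = {x.label: x for x in dt.taxon_namespace}
            d = np.array(
                [[0.0 if u == v else pdm.distance(tax[u], tax[v]) for v in labels] for u in labels]
            )
            recovered = nj_tree(d, labels)
            assert recovered.bipartitions() == topo.bipartitions()


class TestProteinDistance:
    def test_identical_sequences_are_zero(self):
        assert protein_distance("MKV", "MKV") == 0.0

    def test_kimura_correction_closed_form(self):
        # p = 0.1 -> -ln(1 - 0.1 - 0.01/5)
        s1 = "A" * 90 + "C" * 10
        s2 = "A" * 90 + "D" * 10
        assert protein_distance(s1, s2) == pytest.approx(-math.log(1 - 0.1 - 0.01 / 5))

    def test_saturation_marker_beyond_domain(self):
        s1 = "A" * 50
        s2 = "C" * 50
        assert protein_distance(s1, s2) == math.inf

    def test_gapped_columns_excluded(self):
        assert protein_distance("MK-V", "MKAV") == 0.0

    def test_no_shared_columns_errors(self):
        with pytest.raises(ValueError, match="shared"):
            protein_distance("M-", "-M")


class TestBootstrap:
    def test_fixed_seed_is_deterministic(self, rng):
        base = list("MKVLYRAEDSWHQPGITFCN" * 3)
        seqs = {}
        for sid in ("A", "B", "C", "D", "E"):
            mutant = base.copy()
            for j in rng.choice(len(base), 12, replace=False):
                mutant[j] = AA_ORDER[rng.integers(20)]
            seqs[sid] = "".join(mutant)
        aln = Alignment.from_dict(seqs)
        _, s1 = bootstrap_support(aln, n_replicates=30, seed=5)
        _, s2 = bootstrap_support(aln, n_replicates=30, seed=5)
        assert s1 == s2

    def test_unanimous_signal_gives_full_support(self):
        # A,B identical; C,D identical; ten separating sites -> every
        # resampled replicate recovers the AB|CD split
        base = "MKVLYRAEDSWHQPGITFCN" * 2
        other = "W" * 10 + base[10:]
        aln = Alignment.from_dict({"A": base, "B": base, "C": other, "D": other})
        tree, support = bootstrap_support(aln, n_replicates=50, seed=1)
        split = next(iter(tree.bipartitions()))
        assert support[split] == 100.0

    def test_replicate_count_validated(self, rng):
        aln = random_alignment(rng, ["A", "B", "C", "D"], 10)
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_replicates=0, seed=1)


class TestKsNG86:
    def test_identical_cds_is_zero(self):
        r = ks_ng86("ATGGCTAAA", "ATGGCTAAA")
        assert r.ks == 0.0 and not r.saturated

    def test_fourfold_glycine_hand_oracle(self):
        # GGT/GGC differ at one 4-fold degenerate site: S=3, Sd=1,
        # Ks = -(3/4) ln(1 - (4/3)(1/3))
        r = ks_ng86("GGTGGTGGT", "GGCGGTGGT")
        assert r.s_sites == pytest.approx(3.0)
        assert r.s_diffs == pytest.approx(1.0)
        assert r.ks == pytest.approx(-0.75 * math.log(1 - 4 / 9), abs=1e-6)

    def test_symmetry(self, rng):
        codons = ["ATG", "GCT", "GCC", "AAA", "AAG", "GGC", "GGT", "TTT", "CAG"]
        c1 = "".join(rng.choice(codons, 40))
        c2 = "".join(np.where(rng.random(40) < 0.2, rng.choice(codons, 40), list(map("".join, zip(*[iter(c1)] * 3)))))
        fwd, back = ks_ng86(c1, c2), ks_ng86(c2, c1)
        assert fwd.s_sites == pytest.approx(back.s_sites)
        assert fwd.s_diffs == pytest.approx(back.s_diffs)
        assert fwd.ks == pytest.approx(back.ks, nan_ok=True)

    def test_saturation_marker(self):
        # every codon differs at its 4-fold third position -> ps = 1
        c1 = "GGT" * 10
        c2 = "GGC" * 10
        r = ks_ng86(c1, "GGA" * 10)
        r2 = ks_ng86(c1, c2)
        assert r.saturated and math.isnan(r.ks)
        assert r2.saturated and math.isnan(r2.ks)

    def test_unaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            ks_ng86("ATGGCT", "ATG")
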