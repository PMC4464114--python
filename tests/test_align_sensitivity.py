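"""Tests for tract deletion, the builtin aligner, trimming and the grid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpaa_phylo.align_sensitivity import (
    TrimSettings,
    align,
    builtin_align,
    delete_hpaa,
    run_sensitivity_grid,
    sum_of_pairs_score,
    trim_columns,
)
from hpaa_phylo.hpaa_scan import ScanSettings, find_hpaa_tracts
from hpaa_phylo.phylo_core import Alignment, SubstitutionModel
from hpaa_phylo.phylo_core.model import AA_ORDER


class TestDeleteHpaa:
    def test_removes_both_tracts(self):
        seq = "MAAAAAAKQQQQQQQQ"
        tracts = find_hpaa_tracts(seq, ScanSettings(6))
        assert delete_hpaa(seq, tracts) == "MK"

    def test_empty_span_list_is_identity(self):
        assert delete_hpaa("MKV", []) == "MKV"

    def test_accepts_plain_start_length_pairs(self):
        assert delete_hpaa("ABCDEF", [(1, 2), (4, 1)]) == "ADF"

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            delete_hpaa("ABCDEF", [(1, 3), (2, 2)])

    def test_out_of_bounds_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            delete_hpaa("ABC", [(2, 5)])

    @given(
        st.text(alphabet=AA_ORDER, min_size=5, max_size=40),
        st.integers(min_value=0, max_value=4),
        st.integers(min_value=1, max_value=5),
    )
    @settings(max_examples=100, deadline=None)
    def test_length_conservation(self, seq, start, length):
        if start + length > len(seq):
            return
        out = delete_hpaa(seq, [(start, length)])
        assert len(out) + length == len(seq)
        assert out == seq[:start] + seq[start + length:]


class TestBuiltinAligner:
    def test_identical_sequences_align_gap_free(self):
        aln = builtin_align({"a": "MKVLYRAEDS", "b": "MKVLYRAEDS"})
        assert aln.rows[0] == aln.rows[1] == "MKVLYRAEDS"

    def test_single_deletion_recovered_by_degapping(self):
        aln = align({"a": "ACDEFG", "b": "ACEFG"}, "builtin")
        assert aln.degapped("a") == "ACDEFG"
        assert aln.degapped("b") == "ACEFG"
        assert aln.n_columns == 6

    def test_every_input_recoverable_from_rows(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice(list(AA_ORDER), rng.integers(40, 60)))
            for i in range(5)
        }
        aln = builtin_align(seqs)
        for sid, seq in seqs.items():
            assert aln.degapped(sid) == seq

    def test_score_beats_left_justified_stacking(self, rng):
        base = "".join(rng.choice(list(AA_ORDER), 50))
        seqs = {
            "a": base,
            "b": base[:20] + base[25:],       # internal deletion
            "c": base[2:48],                   # truncated
        }
        aligned = builtin_align(seqs)
        width = max(len(s) for s in seqs.values())
        stacked = Alignment(
            list(seqs), [s + "-" * (width - len(s)) for s in seqs.values()]
        )
        assert sum_of_pairs_score(aligned) >= sum_of_pairs_score(stacked)

    def test_deterministic_across_runs(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list(AA_ORDER), 30)) for i in range(4)}
        assert builtin_align(seqs).rows == builtin_align(seqs).rows

    def test_unknown_aligner_rejected(self):
        with pytest.raises(ValueError, match="unknown aligner"):
            align({"a": "MKV", "b": "MKV"}, "muscle")

    def test_missing_binary_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="falling back"):
            aln = align({"a": "MKVLYR", "b": "MKVLYR"}, "t_coffee")
        assert aln.degapped("a") == "MKVLYR"


class TestTrimColumns:
    def test_gapped_column_removed_regardless_of_threshold(self):
        aln = Alignment.from_dict({"a": "MK-V", "b": "MKAV"})
        trimmed, kept = trim_columns(aln, TrimSettings(st=0.0))
        assert kept == [1, 2, 4]
        assert trimmed.rows == ["MKV", "MKV"]

    def test_st_zero_keeps_all_gap_free_columns(self):
        aln = Alignment.from_dict({"a": "MKVW", "b": "ADEF"})
        trimmed, kept = trim_columns(aln, TrimSettings(st=0.0))
        assert kept == [1, 2, 3, 4]

    def test_conserved_column_survives_every_threshold(self):
        aln = Alignment.from_dict({"a": "WADE", "b": "WDEA", "c": "WEAD"})
        for st in (0.0, 0.00005, 0.0001, 0.0005, 0.001):
            trimmed, kept = trim_columns(aln, TrimSettings(st=st))
            assert 1 in kept  # the all-W column

    def test_raising_st_never_increases_kept_columns(self, rng):
        aln = Alignment.from_dict(
            {f"s{i}": "".join(rng.choice(list(AA_ORDER), 60)) for i in range(4)}
        )
        previous = None
        for st in (0.0, 0.1, 0.3, 0.5, 0.8):
            _, kept = trim_columns(aln, TrimSettings(st=st))
            if previous is not None:
                assert len(kept) <= previous
            assert kept == sorted(kept)
            previous = len(kept)

    def test_everything_removed_gives_marker(self):
        aln = Alignment.from_dict({"a": "M-", "b": "-M"})
        trimmed, kept = trim_columns(aln, TrimSettings(st=0.0))
        assert trimmed is None and kept == []


class TestSensitivityGrid:
    def test_grid_shape_and_determinism(self, rng, jtt_g4):
        # a 4-OTU family keeps the per-cell exhaustive scan small
        base = "".join(rng.choice(list(AA_ORDER), 120))

        def mutate(seq, n):
            out = list(seq)
            for j in rng.choice(len(out), n, replace=False):
                out[j] = AA_ORDER[rng.integers(20)]
            return "".join(out)

        intact = {
            "cA": mutate(base, 30) + "Q" * 10,
            "cB": mutate(base, 30) + "Q" * 10,
            "g1": mutate(base, 25),
            "out": mutate(base, 45),
        }
        delta = {k: (v[:-10] if k in ("cA", "cB") else v) for k, v in intact.items()}
        grid = run_sensitivity_grid(
            intact, delta, clade={"cA", "cB"}, model=jtt_g4, seed=7,
            aligners=("builtin",), st_levels=(0.0, 0.001), n_replicates=500,
        )
        assert len(grid) == 4  # 1 aligner x 2 st x 2 arms
        assert set(grid["arm"]) == {"intact", "delta_hpaa"}
        assert not grid["failed"].any()
        assert ((grid["clade_support"] >= 0) & (grid["clade_support"] <= 1)).all()
        assert (grid["n_sites"] > 0).all()
        rerun = run_sensitivity_grid(
            intact, delta, clade={"cA", "cB"}, model=jtt_g4, seed=7,
            aligners=("builtin",), st_levels=(0.0, 0.001), n_replicates=500,
        )
        assert grid.equals(rerun)

    def test_convergent_tracts_inflate_support_when_untrimmed(self, jtt_g4):
        """Without column trimming, the injected tract columns carry data for
        the two cyclostome paralogs only, and the naive alignment's handling
        of them inflates support for their exclusive grouping relative to
        the matched tract-deleted control."""
        from hpaa_phylo.phylo_core import enumerate_topologies
        from hpaa_phylo.synthetic_data import (
            ScenarioSpec,
            convergent_cyclostome_injections,
            make_scenario,
        )
        from hpaa_phylo.topology_tests import clade_support, rell_bootstrap, score_topologies

        def support(seqs, seed):
            aln = align(seqs, "builtin")
            topologies = enumerate_topologies(sorted(seqs))
            matrix = score_topologies(aln, topologies, jtt_g4, tol=3e-3, max_sweeps=6)
            bp = rell_bootstrap(matrix, n_replicates=3000, seed=seed)
            return clade_support(bp, topologies, {"cA", "cB"})

        n = 12
        hits = 0
        for seed in range(n):
            result = make_scenario(
                ScenarioSpec(
                    scenario="before_split", seed=seed,
                    injections=convergent_cyclostome_injections(),
                )
            )
            intact = support(result.intact_sequences(), seed + 1000)
            delta = support(result.delta_hpaa_sequences(), seed + 1000)
            hits += intact >= delta
        assert hits >= 0.8 * n, f"support inflated in only {hits}/{n} pairs"

    def test_identical_arms_give_identical_support(self, rng, jtt_g4):
        seqs = {
            sid: "".join(rng.choice(list(AA_ORDER), 80))
            for sid in ("cA", "cB", "g1", "out")
        }
        grid = run_sensitivity_grid(
            seqs, dict(seqs), clade={"cA", "cB"}, model=jtt_g4, seed=3,
            aligners=("builtin",), st_levels=(0.0,), n_replicates=400,
        )
        by_arm = grid.set_index("arm")["clade_support"]
        assert by_arm["intact"] == pytest.approx(by_arm["delta_hpaa"], abs=1e-12)
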