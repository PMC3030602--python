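import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirpath.data_model import Pathway, TimePoint, Universe
from mirpath.differential import ModulatedSet
from mirpath.enrichment import (
    PermutationConfig,
    count_target_pairs,
    hypergeom_pvalue,
    overlap_summary,
    permutation_pvalue,
    run_pathway_analysis,
    stouffer_combine,
)


def _preds(edges, db="microcosm"):
    df = pd.DataFrame(edges, columns=["mirna_id", "gene_id"])
    df["p_value"] = 0.01
    df["source_db"] = db
    return df


class TestCountTargetPairs:
    def test_direct_count(self):
        n = count_target_pairs(
            {"G1", "G2"}, {"M1"}, _preds([("M1", "G1"), ("M1", "G2"), ("M1", "G3")])
        )
        assert n == 2

    def test_empty_modulated(self):
        assert count_target_pairs({"G1"}, set(), _preds([("M1", "G1")])) == 0

    def test_per_pair_counting(self):
        n = count_target_pairs(
            {"G1"}, {"M1", "M2"}, _preds([("M1", "G1"), ("M2", "G1")])
        )
        assert n == 2

    def test_duplicate_edges_count_once(self):
        df = pd.concat([_preds([("M1", "G1")]), _preds([("M1", "G1")])])
        assert count_target_pairs({"G1"}, {"M1"}, df) == 1


class TestPermutationPvalue:
    def test_observed_zero_gives_one(self):
        p, obs = permutation_pvalue(
            {"G1"}, {"M1"}, {"M1", "M2"}, _preds([("M2", "G1")]),
            PermutationConfig(100, seed=0),
        )
        assert obs == 0
        assert p == 1.0

    def test_modulated_equals_universe(self):
        p, obs = permutation_pvalue(
            {"G1"}, {"M1", "M2"}, {"M1", "M2"}, _preds([("M1", "G1")]),
            PermutationConfig(100, seed=0),
        )
        assert p == 1.0

    def test_modulated_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue({"G1"}, {"MX"}, {"M1"}, _preds([]), PermutationConfig(10, 0))

    def test_matches_exhaustive_enumeration(self):
        # universe of 5 miRNAs, 2 modulated: all C(5,2) = 10 subsets enumerable
        universe = [f"M{i}" for i in range(5)]
        edges = [("M0", "G1"), ("M0", "G2"), ("M1", "G1"), ("M3", "G2")]
        pathway = {"G1", "G2"}
        modulated = {"M0", "M3"}
        preds = _preds(edges)
        degree = {m: sum(1 for e in edges if e[0] == m and e[1] in pathway)
                  for m in universe}
        observed = sum(degree[m] for m in modulated)
        tail = [
            sum(degree[m] for m in subset) >= observed
            for subset in itertools.combinations(universe, 2)
        ]
        exact = sum(tail) / len(tail)
        n_trials = 10000
        p, obs = permutation_pvalue(
            pathway, modulated, universe, preds, PermutationConfig(n_trials, seed=3)
        )
        assert obs == observed
        se = math.sqrt(exact * (1 - exact) / n_trials)
        assert abs(p - exact) <= 3 * se


class TestHypergeomPvalue:
    def test_zero_overlap_gives_one(self):
        universe = {f"G{i}" for i in range(10)}
        assert hypergeom_pvalue({"G0"}, {"G5"}, universe) == 1.0

    def test_closed_form_example(self):
        # universe 10, modulated 4, pathway 3, overlap 2 -> 40/120 = 1/3
        universe = [f"G{i}" for i in range(10)]
        modulated = universe[:4]
        pathway = ["G0", "G1", "G9"]
        p = hypergeom_pvalue(pathway, modulated, universe)
        assert p == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_pathway_outside_universe_warns(self):
        with pytest.warns(RuntimeWarning):
            p = hypergeom_pvalue({"GX"}, {"G0"}, {f"G{i}" for i in range(5)})
        assert p == 1.0

    def test_fully_modulated_universe(self):
        universe = {f"G{i}" for i in range(6)}
        assert hypergeom_pvalue({"G0", "G1"}, universe, universe) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_mass_summation(self, seed):
        rng = np.random.default_rng(seed)
        n_universe = int(rng.integers(20, 51))
        universe = [f"G{i}" for i in range(n_universe)]
        modulated = list(rng.choice(universe, size=int(rng.integers(3, 15)), replace=False))
        pathway = list(rng.choice(universe, size=int(rng.integers(3, 15)), replace=False))
        K, n = len(modulated), len(pathway)
        k_obs = len(set(pathway) & set(modulated))

        def brute(k):
            num = sum(
                math.comb(K, j) * math.comb(n_universe - K, n - j)
                for j in range(k, min(K, n) + 1)
                if n - j <= n_universe - K
            )
            return num / math.comb(n_universe, n)

        p = hypergeom_pvalue(pathway, modulated, universe)
        assert p == pytest.approx(brute(k_obs), rel=1e-10)


class TestStoufferCombine:
    def test_neutral_point(self):
        assert stouffer_combine(0.5, 0.5) == pytest.approx(0.5)

    def test_antisymmetry(self):
        for p in (0.01, 0.1, 0.3, 0.49):
            assert stouffer_combine(p, 1 - p) == pytest.approx(0.5, abs=1e-12)

    def test_argument_symmetry(self):
        assert stouffer_combine(0.01, 0.2) == pytest.approx(stouffer_combine(0.2, 0.01))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stouffer_combine(-0.1, 0.5)
        with pytest.raises(ValueError):
            stouffer_combine(0.5, 1.1)

    @given(st.floats(0.001, 0.999))
    def test_evidence_accumulation(self, p):
        combined = stouffer_combine(p, p)
        if p < 0.5:
            assert combined < p
        elif p > 0.5:
            assert combined > p

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.98))
    def test_monotone_in_each_component(self, p1, p2):
        assert stouffer_combine(p1, p2) <= stouffer_combine(p1, p2 + 0.01) + 1e-12


class TestRunPathwayAnalysis:
    def _empty_sets(self):
        mir = {
            tp: ModulatedSet(tp, frozenset(), frozenset(), "mirna")
            for tp in TimePoint
        }
        gen = {
            tp: ModulatedSet(tp, frozenset(), frozenset(), "mrna")
            for tp in TimePoint
        }
        return mir, gen

    def test_no_modulation_selects_nothing(self, desk_study):
        mir, gen = self._empty_sets()
        results, selections = run_pathway_analysis(
            desk_study.pathways,
            mir,
            gen,
            {"microcosm": desk_study.predictions["microcosm"]},
            desk_study.universe,
            PermutationConfig(100, seed=0),
        )
        assert all(len(v) == 0 for v in selections.values())
        assert (results["p_combined"] >= 0.5).all()

    def test_reproducible_bit_for_bit(self, desk_study):
        from mirpath.differential import (
            call_modulated_genes_both_pools,
            call_modulated_mirnas,
        )
        from mirpath.normalization import normalize_probe_signals, summarize_mirnas

        tp = TimePoint.ST
        mir = {
            tp: call_modulated_mirnas(
                summarize_mirnas(
                    normalize_probe_signals(desk_study.probe_signals[tp]), tp
                )
            )
        }
        gen = {tp: call_modulated_genes_both_pools(desk_study.mrna_ratios[tp], tp)}
        args = (
            desk_study.pathways,
            mir,
            gen,
            {"microcosm": desk_study.predictions["microcosm"]},
            desk_study.universe,
        )
        r1, s1 = run_pathway_analysis(*args, PermutationConfig(300, seed=9))
        r2, s2 = run_pathway_analysis(*args, PermutationConfig(300, seed=9))
        pd.testing.assert_frame_equal(r1, r2)
        assert s1 == s2

    def test_planted_pathway_selected_and_trials_stable(self, desk_study):
        from mirpath.differential import (
            call_modulated_genes_both_pools,
            call_modulated_mirnas,
        )
        from mirpath.normalization import normalize_probe_signals, summarize_mirnas

        tp = TimePoint.ST
        mir = {
            tp: call_modulated_mirnas(
                summarize_mirnas(
                    normalize_probe_signals(desk_study.probe_signals[tp]), tp
                )
            )
        }
        gen = {tp: call_modulated_genes_both_pools(desk_study.mrna_ratios[tp], tp)}
        planted = desk_study.truth["planted_pathways"][0]
        selected = {}
        for trials in (500, 1000):
            _, sel = run_pathway_analysis(
                desk_study.pathways,
                mir,
                gen,
                {"microcosm": desk_study.predictions["microcosm"]},
                desk_study.universe,
                PermutationConfig(trials, seed=21),
            )
            selected[trials] = sel[("ST", "microcosm")]
            assert planted in selected[trials]
        assert selected[500] == selected[1000]


class TestOverlapSummary:
    def test_example_partition(self):
        out = overlap_summary({"ST": {"A", "B"}, "IT": {"B", "C"}, "LT": {"B"}})
        assert out["exactly_1"] == 2
        assert out["exactly_2"] == 0
        assert out["exactly_3"] == 1
        assert out["all_timepoints"] == ["B"]
        assert out["exactly_1"] + out["exactly_2"] + out["exactly_3"] == out["union"]

    def test_disjoint_sets(self):
        out = overlap_summary({"ST": {"A"}, "IT": {"B"}, "LT": {"C"}})
        assert out["exactly_1"] == 3 and out["exactly_3"] == 0

    def test_identical_sets(self):
        out = overlap_summary({"ST": {"A", "B"}, "IT": {"A", "B"}, "LT": {"A", "B"}})
        assert out["exactly_3"] == 2 and out["union"] == 2
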