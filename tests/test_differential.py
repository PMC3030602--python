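import numpy as np
import pandas as pd
import pytest

from mirpath.data_model import MiRnaMeasurement, TimePoint
from mirpath.differential import (
    call_modulated_genes,
    call_modulated_genes_both_pools,
    call_modulated_mirnas,
    recurrent_mirnas,
)
from mirpath.synthetic_data import fixture_measurements


def _m(mirna, fi, p, tp=TimePoint.ST):
    return MiRnaMeasurement(mirna, tp, fi, p)


def _probes(rows):
    """rows: (gene, probe, pool1, pool2)"""
    return pd.DataFrame(
        rows, columns=["gene_id", "probe_id", "log_ratio_pool1", "log_ratio_pool2"]
    )


class TestCallModulatedMirnas:
    def test_example_calls(self):
        s = call_modulated_mirnas(
            [_m("mmu-miR-146b", 1.91, 0.003), _m("mmu-miR-x", 1.4, 0.001)]
        )
        assert s.up == {"mmu-miR-146b"}
        assert not s.down

    @pytest.mark.parametrize(
        "fi,p,expected",
        [
            (1.5, 0.005, "up"),  # fold bound inclusive
            (1 / 1.5, 0.005, "down"),
            (1.5, 0.01, None),  # p bound strict
            (1.49, 0.001, None),
            (0.67, 0.001, None),  # just above 1/1.5
        ],
    )
    def test_threshold_edges(self, fi, p, expected):
        s = call_modulated_mirnas([_m("m", fi, p)])
        if expected is None:
            assert not s.members
        else:
            assert s.direction("m") == expected

    def test_table2_st_block_counts(self):
        s = call_modulated_mirnas(fixture_measurements(TimePoint.ST))
        assert len(s.up) == 11
        assert len(s.down) == 9

    def test_mixed_timepoints_rejected(self):
        with pytest.raises(ValueError):
            call_modulated_mirnas(
                [_m("a", 2.0, 0.001), _m("b", 2.0, 0.001, TimePoint.IT)]
            )

    def test_raising_fc_min_is_monotone(self):
        rng = np.random.default_rng(0)
        ms = [
            _m(f"m{i}", float(2.0 ** rng.normal(0, 1)), float(rng.uniform(0, 0.02)))
            for i in range(100)
        ]
        prev = call_modulated_mirnas(ms, fc_min=1.2)
        for fc in (1.5, 2.0, 3.0):
            cur = call_modulated_mirnas(ms, fc_min=fc)
            assert cur.up <= prev.up and cur.down <= prev.down
            prev = cur

    def test_fi_inversion_swaps_directions(self):
        rng = np.random.default_rng(1)
        ms = [
            _m(f"m{i}", float(2.0 ** rng.normal(0, 1)), float(rng.uniform(0, 0.02)))
            for i in range(50)
        ]
        inv = [_m(m.mirna_id, 1.0 / m.fold_induction, m.p_value) for m in ms]
        a = call_modulated_mirnas(ms)
        b = call_modulated_mirnas(inv)
        assert a.up == b.down and a.down == b.up


class TestCallModulatedGenes:
    def test_single_probe_up(self):
        s = call_modulated_genes(_probes([("G1", "p1", 0.7, 0.7)]), TimePoint.ST)
        assert s.up == {"G1"}

    def test_inconsistent_probes_excluded(self):
        s = call_modulated_genes(
            _probes([("G1", "p1", 0.8, 0.8), ("G1", "p2", -0.1, -0.1)]), TimePoint.ST
        )
        assert not s.members

    def test_one_passing_probe_with_agreeing_sign(self):
        s = call_modulated_genes(
            _probes([("G1", "p1", 0.65, 0.65), ("G1", "p2", 0.2, 0.2)]), TimePoint.ST
        )
        assert s.up == {"G1"}

    def test_threshold_is_strict(self):
        s = call_modulated_genes(_probes([("G1", "p1", 0.6, 0.6)]), TimePoint.ST)
        assert not s.members

    def test_down_direction(self):
        s = call_modulated_genes(_probes([("G1", "p1", -0.9, -0.5)]), TimePoint.ST)
        assert s.down == {"G1"}


class TestCallModulatedGenesBothPools:
    def test_both_pools_pass(self):
        s = call_modulated_genes_both_pools(
            _probes([("G1", "p1", 0.7, 0.9)]), TimePoint.ST
        )
        assert s.up == {"G1"}

    def test_second_pool_below_threshold_excluded(self):
        s = call_modulated_genes_both_pools(
            _probes([("G1", "p1", 0.7, 0.3)]), TimePoint.ST
        )
        assert not s.members

    def test_exactly_point_six_passes_both_pools(self):
        # log2(1.5) = 0.58496, so 0.6 clears the strict bound in each pool
        s = call_modulated_genes_both_pools(
            _probes([("G1", "p1", 0.6, 0.6)]), TimePoint.ST
        )
        assert s.up == {"G1"}

    def test_symmetric_down_call(self):
        s = call_modulated_genes_both_pools(
            _probes([("G1", "p1", -0.7, -0.9)]), TimePoint.ST
        )
        assert s.down == {"G1"}


class TestRecurrentMirnas:
    @pytest.fixture()
    def fixture_sets(self):
        return [
            call_modulated_mirnas(fixture_measurements(tp))
            for tp in (TimePoint.ST, TimePoint.IT, TimePoint.LT)
        ]

    def test_all_three_timepoints_is_unique(self, fixture_sets):
        rec = recurrent_mirnas(fixture_sets, k=3)
        assert list(rec.index) == ["mmu-miR-146b"]
        assert (rec.loc["mmu-miR-146b", [c for c in rec.columns if c.endswith("direction")]] == "up").all()

    def test_k2_matches_recurrence_table(self, fixture_sets, fixtures):
        rec = recurrent_mirnas(fixture_sets, k=2)
        assert len(rec) == 13
        assert set(rec.index) == set(fixtures.table3["mirna_id"])

    def test_k1_is_union(self, fixture_sets):
        rec = recurrent_mirnas(fixture_sets, k=1)
        union = set().union(*(s.members for s in fixture_sets))
        assert set(rec.index) == union

    def test_empty_sets(self):
        from mirpath.differential import ModulatedSet

        sets = [
            ModulatedSet(tp, frozenset(), frozenset(), "mirna")
            for tp in (TimePoint.ST, TimePoint.IT, TimePoint.LT)
        ]
        assert recurrent_mirnas(sets, k=2).empty

    def test_duplicate_timepoints_rejected(self, fixture_sets):
        with pytest.raises(ValueError):
            recurrent_mirnas([fixture_sets[0], fixture_sets[0]], k=2)
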