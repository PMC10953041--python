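"""Event classification, dating, reconciliation and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleorange.dec import AncestralRangeTable
from paleorange.events import (
    EventRecord,
    classify_cladogenetic_event,
    events_from_ancestral_table,
    extract_anagenetic_events,
    summarize_events,
)
from paleorange.trees import DatedTree

from conftest import make_geo


class TestClassify:
    @pytest.mark.parametrize("parent,left,right,want", [
        (0b11, 0b01, 0b10, "vicariance"),
        (0b11, 0b11, 0b01, "subset_sympatry"),
        (0b01, 0b01, 0b01, "sympatry"),
        (0b111, 0b001, 0b110, "vicariance"),
        (0b111, 0b111, 0b010, "subset_sympatry"),
        (0b01, 0b01, 0b10, "anagenetic-adjusted"),
        (0b11, 0b11, 0b11, "anagenetic-adjusted"),
    ])
    def test_examples(self, parent, left, right, want):
        assert classify_cladogenetic_event(parent, left, right) == want

    def test_null_rejected(self):
        with pytest.raises(ValueError):
            classify_cladogenetic_event(0, 0b01, 0b01)


@pytest.fixture
def geo_snap():
    """B reachable from A only in the older half of the tiling."""
    linked = [[1, 1], [1, 1]]
    split = [[1, 0], [0, 1]]
    return make_geo([linked, split], [100.0, 50.0, 0.0], 2)


class TestAnagenetic:
    def test_single_gain_at_midpoint(self, geo2):
        evs = extract_anagenetic_events(0b01, 0b11, 7, 0.0, 20.0, geo2)
        assert len(evs) == 1
        ev = evs[0]
        assert ev.event_type == "dispersal"
        assert ev.gained_area == 1
        assert ev.source_areas == frozenset({0})
        assert ev.time == pytest.approx(10.0)

    def test_multi_source_out_of_counting(self, geo3_complete):
        # gaining B from {A,C}: one into-count, one out-of per source area
        evs = extract_anagenetic_events(0b101, 0b111, 3, 0.0, 30.0,
                                        geo3_complete)
        assert len(evs) == 1
        assert evs[0].source_areas == frozenset({0, 2})
        summary = summarize_events(evs, geo3_complete)
        assert summary.dispersal_into["B"] == 1
        assert summary.dispersal_out_of["A"] == 1
        assert summary.dispersal_out_of["C"] == 1

    def test_loss_is_extirpation(self, geo2):
        evs = extract_anagenetic_events(0b11, 0b01, 2, 10.0, 30.0, geo2)
        assert len(evs) == 1
        assert evs[0].event_type == "extirpation"
        assert evs[0].lost_area == 1
        assert evs[0].time == pytest.approx(20.0)

    def test_impossible_midpoint_snaps_older(self, geo_snap):
        # branch spans 80-20 Ma; midpoint 50 falls in the split slice
        # where A-B dispersal is impossible, so the event snaps into
        # the 80-50 Ma sub-interval
        evs = extract_anagenetic_events(0b01, 0b11, 1, 20.0, 80.0, geo_snap)
        ev = evs[0]
        assert "snapped" in ev.flags
        assert ev.time == pytest.approx(65.0)  # midpoint of [50, 80]
        assert geo_snap.slices[ev.slice_index].older_bound == 100.0

    def test_impossible_everywhere_flagged(self, geo_snap):
        evs = extract_anagenetic_events(0b01, 0b11, 1, 0.0, 40.0, geo_snap)
        assert "unconstrained" in evs[0].flags
        assert evs[0].time == pytest.approx(20.0)

    def test_times_inside_branch(self, geo_snap):
        evs = extract_anagenetic_events(0b01, 0b11, 1, 20.0, 80.0, geo_snap)
        for ev in evs:
            assert 20.0 <= ev.time <= 80.0


def _table_from_best(tree, geo, best_by_label_or_index):
    """Degenerate ancestral table with probability-1 best ranges."""
    ranked = {}
    for node in tree.postorder():
        key = node.label if node.label in best_by_label_or_index else node.index
        ranked[node.index] = [(best_by_label_or_index[key], 1.0)]
    eq = {i: {r[0][0]} for i, r in ranked.items()}
    return AncestralRangeTable(tree, geo, ranked, eq)


class TestReconciliation:
    def test_clean_vicariance_no_anagenesis(self, geo2):
        tree = DatedTree.from_newick("(A:10,B:10);")
        table = _table_from_best(tree, geo2, {
            "A": 0b01, "B": 0b10, tree.root.index: 0b11})
        evs = events_from_ancestral_table(tree, table, geo2)
        kinds = [e.event_type for e in evs]
        assert kinds == ["vicariance"]

    def test_chain_gain_and_loss_on_terminal_branch(self, geo2):
        # root {A} -> child {A} -> grandchild tip {B}: the B tip branch
        # must carry one dispersal into B and one extirpation of A
        tree = DatedTree.from_newick("((G:5,H:5):5,C:10);")
        table = _table_from_best(tree, geo2, {
            "G": 0b01, "H": 0b10, "C": 0b01,
            tree.tip_by_label("G").parent.index: 0b01,
            tree.root.index: 0b01,
        })
        evs = events_from_ancestral_table(tree, table, geo2)
        anag = [e for e in evs if e.event_type in ("dispersal", "extirpation")]
        assert len(anag) == 2
        by_type = {e.event_type: e for e in anag}
        assert by_type["dispersal"].gained_area == 1
        assert by_type["extirpation"].lost_area == 0
        assert all(e.node_index == tree.tip_by_label("H").index for e in anag)

    def test_subset_sympatry_emitted(self, geo2):
        tree = DatedTree.from_newick("(A:10,B:10);")
        table = _table_from_best(tree, geo2, {
            "A": 0b11, "B": 0b01, tree.root.index: 0b11})
        evs = events_from_ancestral_table(tree, table, geo2)
        assert [e.event_type for e in evs] == ["subset_sympatry"]


class TestSummaries:
    def test_counting_matches_oneliner_oracle(self, geo3_complete):
        rng = np.random.default_rng(11)
        events = []
        for _ in range(200):
            kind = rng.choice(["dispersal", "extirpation", "vicariance"])
            if kind == "dispersal":
                gained = int(rng.integers(3))
                sources = frozenset(
                    int(a) for a in rng.choice(3, size=rng.integers(1, 3),
                                               replace=False))
                events.append(EventRecord("dispersal", 0, 10.0, 0,
                                          gained_area=gained,
                                          source_areas=sources))
            elif kind == "extirpation":
                events.append(EventRecord("extirpation", 0,
                                          float(rng.uniform(0, 50)), 0,
                                          lost_area=int(rng.integers(3))))
            else:
                events.append(EventRecord("vicariance", 0, 10.0, 0))
        s = summarize_events(events, geo3_complete)
        assert s.n_vicariance == sum(
            1 for e in events if e.event_type == "vicariance")
        assert sum(s.dispersal_into.values()) == sum(
            1 for e in events if e.event_type == "dispersal")
        assert sum(s.dispersal_out_of.values()) == sum(
            len(e.source_areas) for e in events if e.event_type == "dispersal")
        assert sum(s.extirpation.values()) == sum(
            1 for e in events if e.event_type == "extirpation")

    def test_out_of_total_geq_into_total(self, geo3_complete):
        evs = [
            EventRecord("dispersal", 0, 1.0, 0, gained_area=0,
                        source_areas=frozenset({1, 2})),
            EventRecord("dispersal", 0, 1.0, 0, gained_area=1,
                        source_areas=frozenset({0})),
        ]
        s = summarize_events(evs, geo3_complete)
        assert sum(s.dispersal_out_of.values()) >= sum(s.dispersal_into.values())

    def test_latitude_class_aggregation(self):
        geo = make_geo([np.ones((2, 2), int)], [50.0, 0.0], 2, high=("A",))
        evs = [
            EventRecord("dispersal", 0, 1.0, 0, gained_area=0,
                        source_areas=frozenset({1})),
            EventRecord("extirpation", 0, 1.0, 0, lost_area=1),
        ]
        s = summarize_events(evs, geo)
        assert s.by_class["high"]["dispersal_into"] == 1
        assert s.by_class["low"]["dispersal_out_of"] == 1
        assert s.by_class["low"]["extirpation"] == 1
        # high + low aggregates equal the per-area sums
        for key in ("dispersal_into", "dispersal_out_of", "extirpation"):
            total = s.by_class["high"][key] + s.by_class["low"][key]
            assert total == sum(getattr(s, key).values())

    def test_extirpation_time_bins(self, geo2):
        evs = [
            EventRecord("extirpation", 0, 30.0, 0, lost_area=0),
            EventRecord("extirpation", 0, 30.0, 0, lost_area=1),
        ]
        s = summarize_events(evs, geo2)
        assert s.extirpations_per_bin["Cenozoic"] == 2
        evs.append(EventRecord("extirpation", 0, 80.0, 0, lost_area=0))
        geo100 = make_geo([np.ones((2, 2), int)], [100.0, 0.0], 2)
        s2 = summarize_events(evs, geo100)
        assert s2.extirpations_per_bin["Mesozoic+Paleozoic"] == 1

    @settings(max_examples=30, deadline=None)
    @given(perm=st.permutations(range(6)), cut=st.integers(0, 6))
    def test_permutation_invariant_and_additive(self, perm, cut):
        geo2 = make_geo([np.ones((2, 2), int)], [50.0, 0.0], 2)
        base = [
            EventRecord("dispersal", i, 5.0, 0, gained_area=i % 2,
                        source_areas=frozenset({(i + 1) % 2}))
            if i % 3 else
            EventRecord("extirpation", i, 5.0, 0, lost_area=i % 2)
            for i in range(6)
        ]
        shuffled = [base[i] for i in perm]
        s1 = summarize_events(base, geo2)
        s2 = summarize_events(shuffled, geo2)
        assert s1 == s2
        sa = summarize_events(base[:cut], geo2)
        sb = summarize_events(base[cut:], geo2)
        assert sa.n_dispersal + sb.n_dispersal == s1.n_dispersal
        for code in s1.dispersal_into:
            assert (sa.dispersal_into[code] + sb.dispersal_into[code]
                    == s1.dispersal_into[code])
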