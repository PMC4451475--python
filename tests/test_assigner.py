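"""CSSS formation, sequential linking, recognition and mapping."""

import numpy as np
import pytest

from conftest import csss_from_truth
from smftnmr.assigner import (
    build_csss,
    evaluate_assignment,
    form_chains,
    join_chains_over_gaps,
    link_csss,
    map_chains,
    recognize_aa,
    recover_gap_shifts,
    score_link,
    true_positions,
)
from smftnmr.fixing_catalog import get_variant, list_variants
from smftnmr.peak_analysis import PickedPeak2D
from smftnmr.shift_synth import generate_shift_table

SEQ20 = "MDSKAVERLTFNGQHWIYCE"


@pytest.fixture(scope="module")
def table20():
    return generate_shift_table(SEQ20, seed=6, ensure_pair_separation=(0.1, 0.2))


@pytest.fixture(scope="module")
def cssss20(table20):
    return [csss_from_truth(table20, i) for i in range(2, len(SEQ20))]


def synthetic_picks(table, i):
    """Ideal picked-peak lists for every variant of basis residue i."""
    picks = {}
    for e in ("basis4d", "habcab5d", "hn5d"):
        for v in list_variants(e):
            plist = []
            for t in v.templates:
                (xk, xo), (yk, yo) = t.slots()
                x, y = table.get(i + xo, xk), table.get(i + yo, yk)
                if x is None or y is None:
                    continue
                sign = t.expected_sign(table.sequence, i)
                plist.append(PickedPeak2D(x_ppm=x, y_ppm=y, intensity=sign * 1000.0))
            picks[v.id] = plist
    return picks


class TestBuildCSSS:
    def test_complete_internal_residue_fills_18_slots(self, table20):
        i = 10
        c = build_csss_from(table20, i)
        assert c.n_filled() == 18

    def test_glycine_leaves_beta_slots_empty(self, table20):
        i = 13  # G
        c = build_csss_from(table20, i)
        assert c.get("CB", 0) is None and c.get("HB", 0) is None
        assert c.get("CA", 0) == pytest.approx(table20.get(13, "CA"))

    def test_lone_ambiguous_aliphatic_peak_dropped(self, table20):
        i = 10
        picks = synthetic_picks(table20, i)
        # keep only the beta peak of a serine-like residue: its (HB, CB)
        # statistics also fit an alpha pair, so no slot may be guessed
        picks["2i"] = [PickedPeak2D(x_ppm=3.87, y_ppm=63.8, intensity=900.0)]
        picks["2iii"] = []
        bp = csss_from_truth(table20, i).basis
        c = build_csss(bp, picks)
        assert c.get("CA", 0) is None and c.get("CB", 0) is None

    def test_slot_sources_are_own_planes_only(self, table20):
        c = build_csss_from(table20, 10)
        assert all(s.source == "basis" or s.source in
                   {v.id for e in ("basis4d", "habcab5d", "hn5d") for v in list_variants(e)}
                   for s in c.slots.values())


def build_csss_from(table, i):
    bp = csss_from_truth(table, i).basis
    return build_csss(bp, synthetic_picks(table, i))


class TestLinking:
    def test_complete_data_gives_exact_successor_graph(self, cssss20):
        g = link_csss(cssss20)
        expected = {(f"t{i:03d}", f"t{i + 1:03d}") for i in range(2, len(SEQ20) - 1)}
        assert set(g.edges) == expected

    def test_unrelated_spin_systems_not_linked(self, table20):
        other = generate_shift_table("WWWHHHCCC", seed=99)
        a = csss_from_truth(table20, 5)
        b = csss_from_truth(other, 5, bid="x005")
        s = score_link(a, b)
        assert s is None or s[0] < 2

    def test_three_pair_link_score(self, cssss20):
        s = score_link(cssss20[3], cssss20[4])
        assert s is not None and s[0] == 3  # all three shared CO-N pairs match

    def test_chains_single_path(self, cssss20):
        g = link_csss(cssss20)
        for c in cssss20:
            g.nodes[c.id]["csss"] = c
        chains = form_chains(g)
        assert len(chains) == 1 and len(chains[0]) == len(cssss20)

    def test_empty_graph_gives_singletons(self, cssss20):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(c.id for c in cssss20[:4])
        chains = form_chains(g)
        assert sorted(len(c) for c in chains) == [1, 1, 1, 1]

    def test_branch_point_terminates_chains(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_edges_from([("a", "c"), ("b", "c"), ("c", "d")])
        chains = form_chains(g)
        by_first = {tuple(ch.members) for ch in chains}
        # two in-edges at c: neither a->c nor b->c may be followed
        assert ("a", "c") not in [m for ch in chains for m in zip(ch.members, ch.members[1:])]
        assert {("c", "d")} == {m for ch in chains for m in zip(ch.members, ch.members[1:])}


class TestGapRecovery:
    def test_deleted_basis_peak_bridged_and_recovered(self, table20, cssss20):
        missing = 10
        remaining = [c for c in cssss20 if c.id != f"t{missing:03d}"]
        g = link_csss(remaining)
        for c in remaining:
            g.nodes[c.id]["csss"] = c
        chains = form_chains(g)
        assert sorted(len(c) for c in chains) == [missing - 2, len(SEQ20) - 1 - missing]
        joined = join_chains_over_gaps(chains)
        assert len(joined) == 1 and len(joined[0]) == len(cssss20)
        gap = joined[0].members[missing - 2]
        for kind in ("CO", "N", "CA", "CB", "HA", "HB", "HN"):
            assert gap.shifts[kind] == pytest.approx(table20.get(missing, kind), abs=1e-9)

    def test_recover_gap_shifts_all_seven_nuclei(self, table20, cssss20):
        a, b = cssss20[3], cssss20[5]  # i = 5 and i = 7, bridging residue 6
        rec = recover_gap_shifts(a, b)
        assert set(rec) == {"CO", "N", "CA", "CB", "HA", "HB", "HN"}

    def test_distant_chains_not_joined(self, table20, cssss20):
        remaining = [c for c in cssss20 if c.id not in ("t010", "t011")]  # 2-residue gap
        g = link_csss(remaining)
        for c in remaining:
            g.nodes[c.id]["csss"] = c
        chains = join_chains_over_gaps(form_chains(g))
        assert len(chains) == 2


class TestRecognizeAA:
    def test_glycine_from_ca_without_cb(self, table20):
        c = csss_from_truth(table20, 13)  # G at 13
        cand_im1, cand_i = recognize_aa(c)
        assert cand_i == {"G"}

    def test_alanine_excludes_ser_thr(self, table20):
        c = csss_from_truth(table20, 5)  # A at 5
        _, cand = recognize_aa(c)
        assert "A" in cand and not cand & {"S", "T"}

    def test_no_information_admits_all_twenty(self, table20):
        c = csss_from_truth(table20, 5)
        for kind in ("CA", "CB", "HA", "HB"):
            c.slots.pop((kind, 0), None)
        _, cand = recognize_aa(c)
        assert len(cand) == 20


class TestMapping:
    def test_complete_twenty_mer_maps_exactly(self, table20, cssss20):
        g = link_csss(cssss20)
        for c in cssss20:
            g.nodes[c.id]["csss"] = c
        chains = form_chains(g)
        assignment = map_chains(chains, SEQ20)
        assert assignment.positions == {f"t{i:03d}": i for i in range(2, len(SEQ20))}
        report = evaluate_assignment(assignment, cssss20, table20)
        total = report[report["nucleus"] == "total"].iloc[0]
        assert total["pct_correct"] == 100.0 and total["pct_incorrect"] == 0.0

    def test_ambiguous_chain_left_unassigned(self):
        t = generate_shift_table("AAAAAAAA", seed=3)
        c = csss_from_truth(t, 4)
        from smftnmr.assigner import Chain

        assignment = map_chains([Chain(id=0, members=[c])], t.sequence)
        assert assignment.positions == {}
        assert assignment.unassigned_chains == {0: "ambiguous"}

    def test_single_member_chain_with_unique_position_assigned(self):
        t = generate_shift_table("AAGAA", seed=3)
        c = csss_from_truth(t, 3)  # the lone glycine pins the position
        from smftnmr.assigner import Chain

        assignment = map_chains([Chain(id=0, members=[c])], t.sequence)
        assert assignment.positions == {"t003": 3}
        assert assignment.chain_of["t003"] == (0, 1)

    def test_degenerate_repeat_confuses_mapping(self):
        # two identical windows: a chain spanning only the repeated motif
        # cannot be placed uniquely
        t = generate_shift_table("MKAVLSKAVLS", seed=8)
        c = csss_from_truth(t, 3)  # A in 'KAVL' ... also fits position 8
        from smftnmr.assigner import Chain

        assignment = map_chains([Chain(id=0, members=[c])], t.sequence)
        assert assignment.unassigned_chains.get(0) == "ambiguous"

    def test_conflicting_double_placement_blocks_later_chain(self, table20, cssss20):
        from smftnmr.assigner import Chain

        long_chain = Chain(id=0, members=list(cssss20[2:8]))
        overlapping = Chain(id=1, members=[cssss20[4]])
        assignment = map_chains([long_chain, overlapping], SEQ20)
        assert all(cssss20[k].id in assignment.positions for k in range(2, 8))
        assert assignment.unassigned_chains.get(1) in ("conflict", "ambiguous")

    def test_true_positions_identifies_ground_truth(self, table20, cssss20):
        tp = true_positions(cssss20, table20)
        assert tp == {f"t{i:03d}": i for i in range(2, len(SEQ20))}
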