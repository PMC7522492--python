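"""Strategy classification: role summaries, labels, and oracle agreement."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectogenesis import (
    NP,
    PN,
    XNOR,
    XOR_FIRST,
    XOR_SECOND,
    Policy,
    StrategyAssignment,
    SynapseRecord,
    assign_all,
    classify_strategy,
    load_catalog,
    role_summary,
)
from connectogenesis.first_mover import ClassificationError


def _catalog(births):
    return load_catalog(
        pd.DataFrame(
            {"name": list(births), "birth_time": list(births.values())}
        )
    )


def _records(edges):
    return [SynapseRecord(p, q, "stable") for p, q in edges]


class TestRoleSummary:
    def test_partitions_by_role(self):
        cat = _catalog({"X": 300.0, "A": 320.0, "B": 295.0})
        recs = _records([("X", "A"), ("B", "X")])
        s = role_summary("X", recs, cat)
        assert s.pre_role_deltas == (-20.0,)  # X presynaptic to younger A
        assert s.post_role_deltas == (-5.0,)  # older B presynaptic to X
        assert s.mean_delta_all == -12.5

    def test_components_split_by_sign(self):
        cat = _catalog({"X": 300.0, "A": 320.0, "B": 290.0})
        recs = _records([("X", "A"), ("X", "B")])  # deltas -20, +10
        s = role_summary("X", recs, cat)
        assert s.neg_component == -20
        assert s.pos_component == 10

    def test_all_negative_leaves_pos_component_absent(self):
        cat = _catalog({"X": 300.0, "A": 320.0})
        s = role_summary("X", _records([("X", "A")]), cat)
        assert s.pos_component is None

    def test_isolated_cell_is_an_error(self):
        cat = _catalog({"X": 300.0, "A": 320.0})
        with pytest.raises(ClassificationError, match="no incident"):
            role_summary("X", [], cat)

    @given(
        deltas=st.lists(
            st.integers(min_value=-50, max_value=50), min_size=1, max_size=20
        ),
        split=st.integers(min_value=0, max_value=20),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_partition(self, deltas, split):
        # cell X at 400; encode each delta through a dedicated partner
        split = min(split, len(deltas))
        births = {"X": 400.0}
        edges = []
        for i, d in enumerate(deltas):
            name = f"P{i}"
            if i < split:  # X presynaptic: delta = 400 - birth(partner)
                births[name] = 400.0 - d
                edges.append(("X", name))
            else:  # X postsynaptic: delta = birth(partner) - 400
                births[name] = 400.0 + d
                edges.append((name, "X"))
        if any(b < 0 or b > 800 for b in births.values()):
            return
        s = role_summary("X", _records(edges), _catalog(births))
        assert sorted(s.pre_role_deltas) == sorted(map(float, deltas[:split]))
        assert sorted(s.post_role_deltas) == sorted(
            map(float, deltas[split:])
        )


class TestClassifyStrategy:
    def test_fully_conforming_cell_is_np_xnor(self):
        cat = _catalog({"X": 300.0, "OLD": 280.0, "YNG": 350.0})
        recs = _records([("OLD", "X"), ("X", "YNG")])
        a = classify_strategy(role_summary("X", recs, cat))
        assert a.labels == {NP, XNOR}

    def test_positive_mean_is_pure_pn(self):
        cat = _catalog({"X": 350.0, "OLD": 300.0})
        a = classify_strategy(role_summary("X", _records([("X", "OLD")]),
                                           cat))
        assert a.labels == {PN}

    def test_xor_first_keeps_an_older_postsynaptic_partner(self):
        # all presynaptic partners older; one postsynaptic partner older too
        cat = _catalog(
            {"X": 300.0, "O1": 250.0, "O2": 260.0, "Y": 380.0}
        )
        recs = _records([("O1", "X"), ("X", "O2"), ("X", "Y")])
        a = classify_strategy(role_summary("X", recs, cat))
        assert a.labels == {NP, XOR_FIRST}

    def test_xor_second_keeps_a_younger_presynaptic_partner(self):
        cat = _catalog(
            {"X": 300.0, "O1": 220.0, "Y1": 340.0, "Y2": 380.0}
        )
        recs = _records([("O1", "X"), ("Y1", "X"), ("X", "Y2")])
        a = classify_strategy(role_summary("X", recs, cat))
        assert a.labels == {NP, XOR_SECOND}

    def test_tie_resolved_by_policy(self):
        cat = _catalog({"X": 300.0, "A": 280.0, "B": 320.0})
        recs = _records([("X", "A"), ("X", "B")])  # deltas +20 and -20
        s = role_summary("X", recs, cat)
        assert s.mean_delta_all == 0
        assert classify_strategy(s).labels >= {NP}
        assert classify_strategy(s, Policy(tie_label=PN)).labels == {PN}

    def test_simultaneous_partner_ignored_by_universal_tests(self):
        # partner born the same minute is neither earlier nor later
        cat = _catalog({"X": 300.0, "TWIN": 300.0, "OLD": 280.0,
                        "YNG": 330.0})
        recs = _records([("OLD", "X"), ("X", "YNG"), ("TWIN", "X")])
        a = classify_strategy(role_summary("X", recs, cat))
        assert a.labels == {NP, XNOR}

    def test_assignment_invariants_enforced(self):
        with pytest.raises(ClassificationError):
            StrategyAssignment(cell="X", labels=frozenset({PN, NP}))
        with pytest.raises(ClassificationError):
            StrategyAssignment(
                cell="X", labels=frozenset({NP, XOR_FIRST, XNOR})
            )
        with pytest.raises(ClassificationError):
            StrategyAssignment(cell="X", labels=frozenset())


class TestAssignAll:
    def test_single_edge_network(self):
        # both endpoints of an old->young connection see the same negative
        # delta, so both classify as maximally conforming N-P cells
        cat = _catalog({"OLD": 280.0, "YNG": 350.0})
        out = assign_all(_records([("OLD", "YNG")]), cat)
        assert out["OLD"].labels == {NP, XNOR}
        assert out["YNG"].labels == {NP, XNOR}

    def test_single_edge_young_presynaptic_gives_pn(self):
        cat = _catalog({"OLD": 280.0, "YNG": 350.0})
        out = assign_all(_records([("YNG", "OLD")]), cat)
        assert out["OLD"].labels == {PN}
        assert out["YNG"].labels == {PN}

    def test_record_order_invariance(self):
        cat = _catalog(
            {"A": 280.0, "B": 300.0, "C": 320.0, "D": 350.0}
        )
        edges = [("A", "B"), ("B", "C"), ("D", "B"), ("C", "A")]
        for perm in itertools.permutations(edges):
            out = assign_all(_records(list(perm)), cat)
            assert out == assign_all(_records(edges), cat)


class TestOracleEquivalence:
    """Classification agrees with brute-force evaluation of the strategy
    definitions on exhaustively enumerated micro-networks."""

    def test_exhaustive_three_cell_tables(self, strategy_oracle):
        names = ["A", "B", "C"]
        pairs = [(p, q) for p in names for q in names if p != q]
        for births_tuple in itertools.product([0.0, 1.0, 2.0], repeat=3):
            births = dict(zip(names, births_tuple))
            cat = _catalog(births)
            for mask in range(1, 2 ** len(pairs)):
                edges = [pairs[i] for i in range(len(pairs))
                         if mask >> i & 1]
                got = assign_all(_records(edges), cat)
                for cell in {p for e in edges for p in e}:
                    assert got[cell].labels == strategy_oracle(
                        cell, edges, births
                    ), (births, edges, cell)

    def test_random_tables_up_to_six_cells(self, strategy_oracle):
        import numpy as np

        rng = np.random.default_rng(2026)
        for _ in range(400):
            n = int(rng.integers(4, 7))
            names = [f"C{i}" for i in range(n)]
            births = {
                c: float(rng.integers(0, 3)) for c in names
            }
            cat = _catalog(births)
            pairs = [(p, q) for p in names for q in names if p != q]
            k = int(rng.integers(1, len(pairs) + 1))
            idx = rng.choice(len(pairs), size=k, replace=False)
            edges = [pairs[i] for i in idx]
            got = assign_all(_records(edges), cat)
            for cell in {p for e in edges for p in e}:
                assert got[cell].labels == strategy_oracle(
                    cell, edges, births
                ), (births, edges, cell)
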