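"""Catalog loading, snapshots, family counts and birth-burst detection."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectogenesis import (
    burst_histogram,
    expand_pairs,
    family_counts,
    fixtures,
    load_catalog,
    parse_family,
    snapshot,
    snapshot_diff,
)
from connectogenesis.cell_catalog import CatalogError, parse_laterality


class TestLoadCatalog:
    def test_founder_cell_row(self):
        cat = load_catalog(
            pd.DataFrame({"name": ["RMEV"], "birth_time": [265]})
        )
        rec = cat["RMEV"]
        assert rec.birth_time == 265
        assert rec.family == "RME"
        assert rec.laterality == "unpaired"

    def test_empty_table_gives_empty_catalog(self):
        cat = load_catalog(pd.DataFrame({"name": [], "birth_time": []}))
        assert len(cat) == 0

    def test_printed_strategy_classes_number_53(self):
        classes = sorted(fixtures().all_strategy_cells)
        assert len(classes) == 53
        cat = load_catalog(
            pd.DataFrame(
                {"name": classes, "birth_time": [300.0] * len(classes)}
            )
        )
        assert len(cat) == 53

    @pytest.mark.parametrize(
        "frame, match",
        [
            (
                pd.DataFrame(
                    {"name": ["A", "A"], "birth_time": [1.0, 2.0]}
                ),
                "duplicate",
            ),
            (
                pd.DataFrame({"name": ["A"], "birth_time": [-3.0]}),
                "negative",
            ),
            (
                pd.DataFrame({"name": ["A"], "birth_time": [None]}),
                "missing",
            ),
        ],
    )
    def test_invalid_rows_are_hard_errors(self, frame, match):
        with pytest.raises(CatalogError, match=match):
            load_catalog(frame)

    def test_explicit_family_column_wins(self):
        cat = load_catalog(
            pd.DataFrame(
                {"name": ["AV01"], "birth_time": [350.0], "family": ["AV"]}
            )
        )
        assert cat["AV01"].family == "AV"

    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "cells.tsv"
        path.write_text("name\tbirth_time\nRMEV\t265\nADFL\t280\n")
        cat = load_catalog(path)
        assert cat.birth_time("ADFL") == 280


class TestNameParsing:
    @pytest.mark.parametrize(
        "name, family",
        [
            ("RMEV", "RME"),
            ("AVDL", "AV"),
            ("IL2DL", "IL2"),
            ("IL1VR", "IL1"),
            ("URYDL", "UR"),  # via the override table
            ("ADFL", "ADF"),
        ],
    )
    def test_family_stripping(self, name, family):
        assert parse_family(name) == family

    @pytest.mark.parametrize(
        "name, lat",
        [("ADFL", "left"), ("ADFR", "right"), ("RMEV", "unpaired"),
         ("AUA", "class")],
    )
    def test_laterality_heuristic(self, name, lat):
        assert parse_laterality(name) == lat

    def test_pair_expansion(self):
        assert expand_pairs(["AWC"]) == ["AWCL", "AWCR"]
        assert expand_pairs(["IL2L/R"]) == ["IL2L", "IL2R"]
        assert expand_pairs(["RMEV"], unpaired={"RMEV"}) == ["RMEV"]
        # the eight P-N classes of the NSY-5 subnetwork expand to 16 cells
        assert len(expand_pairs(fixtures().nsy5_pn_classes)) == 16


class TestSnapshots:
    def test_265_min_snapshot_contains_only_founder(self, small_catalog):
        assert snapshot(small_catalog, 265).members == {"RMEV"}

    def test_280_min_snapshot_has_five_neurons(self, small_catalog):
        assert len(snapshot(small_catalog, 280)) == 5

    def test_time_zero_is_empty(self, small_catalog):
        assert snapshot(small_catalog, 0).members == frozenset()

    def test_diff_equals_filter(self, small_catalog):
        assert snapshot_diff(small_catalog, 265, 280) == {
            "ADFL", "ADFR", "AWBL", "AWBR",
        }
        assert snapshot_diff(small_catalog, 270, 275) == frozenset()

    def test_diff_requires_ordered_times(self, small_catalog):
        with pytest.raises(CatalogError):
            snapshot_diff(small_catalog, 300, 300)

    @given(
        births=st.lists(
            st.floats(min_value=0, max_value=800), min_size=1, max_size=30
        ),
        t1=st.floats(min_value=0, max_value=800),
        t2=st.floats(min_value=0, max_value=800),
    )
    @settings(max_examples=60, deadline=None)
    def test_snapshot_monotone_and_diff_partition(self, births, t1, t2):
        cat = load_catalog(
            pd.DataFrame(
                {
                    "name": [f"C{i}" for i in range(len(births))],
                    "birth_time": births,
                }
            )
        )
        lo, hi = sorted((t1, t2))
        early = snapshot(cat, lo).members
        late = snapshot(cat, hi).members
        assert early <= late
        if lo < hi:
            diff = snapshot_diff(cat, lo, hi)
            assert diff | early == late
            assert not diff & early


class TestFamilyCounts:
    def test_published_family_table(self):
        counts = fixtures().family_counts_300_400
        assert sum(counts.values()) == 87
        assert counts["AV"] == 14
        assert counts["RI"] == 9
        assert counts["RM"] == 7
        assert counts["UR"] == 6

    def test_synthetic_catalog_reproduces_family_table(self):
        # one synthetic cell per published (family, index); birth at 350 so
        # the 300->400 snapshot difference recovers the full cohort
        counts = fixtures().family_counts_300_400
        rows = [
            (f"{fam}{i:02d}", 350.0, fam)
            for fam, n in counts.items()
            for i in range(n)
        ]
        cat = load_catalog(
            pd.DataFrame(rows, columns=["name", "birth_time", "family"])
        )
        born = snapshot_diff(cat, 300, 400)
        assert len(born) == 87
        assert family_counts(born, catalog=cat) == counts

    def test_single_cell(self):
        assert family_counts(["ADFL"]) == {"ADF": 1}

    def test_counts_conserve_total_on_planted_prefixes(self):
        names = [f"QQ{s}" for s in ("L", "R")] + ["ZZV", "ZZD", "YXA"]
        counts = family_counts(names)
        assert sum(counts.values()) == len(names)
        assert counts["QQ"] == 2
        assert counts["ZZ"] == 2


class TestBurstHistogram:
    def test_single_time_single_burst(self):
        h = burst_histogram([100.0], bin_width=8)
        assert h.counts == (1,)
        assert h.bursts == ((96.0, 104.0),)

    def test_empty_input(self):
        h = burst_histogram([])
        assert h.total == 0
        assert h.bursts == ()

    def test_three_burst_schedule_with_quiescent_window(self):
        # births in three separated windows, none in 345-365
        times = (
            [212 + i for i in range(0, 44, 4)]
            + [286 + i for i in range(0, 56, 4)]
            + [368 + i for i in range(0, 28, 4)]
        )
        h = burst_histogram(times, bin_width=8)
        assert len(h.bursts) == 3
        gap_start, gap_end = h.bursts[1][1], h.bursts[2][0]
        assert gap_start <= 345 and gap_end >= 365

    @given(
        times=st.lists(
            st.floats(min_value=0, max_value=800),
            min_size=1,
            max_size=200,
        ),
        width=st.sampled_from([1.0, 4.0, 8.0, 16.0]),
    )
    @settings(max_examples=60, deadline=None)
    def test_counts_conserve_and_match_bruteforce(self, times, width):
        h = burst_histogram(times, bin_width=width)
        assert h.total == len(times)
        for lo, hi, count in zip(h.bin_edges, h.bin_edges[1:], h.counts):
            assert count == sum(1 for t in times if lo <= t < hi)
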