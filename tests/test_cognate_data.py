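"""Cognate-matrix ingestion, validation, filtering, and partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lexiphylo import cognate_data as cd
from lexiphylo.cognate_data import (CognateMatrix, CognateSet,
                                    CognateParseError, CognateSchemaError,
                                    EmptyResultError, MISSING,
                                    partition_by_meaning_size)


def build_matrix(doculects, cognates, cells):
    """cognates: list of (id, meaning, sub) triples; cells: list of rows."""
    return CognateMatrix(
        doculects=list(doculects),
        cognate_sets=[CognateSet(*c) for c in cognates],
        cells=np.array(cells, dtype=np.int8))


@pytest.fixture
def small_matrix():
    return build_matrix(
        ["A", "B", "C"],
        [("hand_1", "hand", False), ("hand_2", "hand", False),
         ("hand_2a", "hand", True), ("eye_1", "eye", False),
         ("eye_2", "eye", False)],
        [[1, 0, 0, 1, 0],
         [0, 1, 1, MISSING, MISSING],
         [1, 0, 0, 0, 1]])


class TestNexusIO:
    def test_two_by_two_block_is_transcribed_directly(self, tmp_path):
        text = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=2 NCHAR=2;
FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
CHARSTATELABELS
    1 hand_1,
    2 eye_1;
MATRIX
A  01
B  1?
;
END;
BEGIN SETS;
CHARSET hand = 1;
CHARSET eye = 2;
END;
"""
        path = tmp_path / "two.nex"
        path.write_text(text)
        m = cd.read_cognate_matrix(str(path))
        assert m.doculects == ["A", "B"]
        assert m.cells.tolist() == [[0, 1], [1, MISSING]]

    def test_empty_character_block_is_a_schema_error(self, tmp_path):
        text = "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=0;\nMATRIX\n;\nEND;\n"
        path = tmp_path / "empty.nex"
        path.write_text(text)
        with pytest.raises(CognateSchemaError):
            cd.read_cognate_matrix(str(path))

    def test_unknown_symbol_names_row_and_column(self, tmp_path):
        text = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=2 NCHAR=2;
CHARSTATELABELS
    1 hand_1, 2 hand_2;
MATRIX
A  0X
B  11
;
END;
BEGIN SETS;
CHARSET hand = 1 2;
END;
"""
        path = tmp_path / "bad.nex"
        path.write_text(text)
        with pytest.raises(CognateParseError, match="'A'.*column 2"):
            cd.read_cognate_matrix(str(path))

    def test_column_without_meaning_charset_is_a_schema_error(self, tmp_path):
        text = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=2 NCHAR=2;
CHARSTATELABELS
    1 hand_1, 2 hand_2;
MATRIX
A  01
B  11
;
END;
BEGIN SETS;
CHARSET hand = 1;
END;
"""
        path = tmp_path / "nomeaning.nex"
        path.write_text(text)
        with pytest.raises(CognateSchemaError, match="meaning"):
            cd.read_cognate_matrix(str(path))

    def test_nexus_round_trip_is_cell_exact(self, small_matrix, tmp_path):
        path = tmp_path / "m.nex"
        cd.write_cognate_matrix(small_matrix, str(path))
        back = cd.read_cognate_matrix(str(path))
        assert back.doculects == small_matrix.doculects
        assert [c.id for c in back.cognate_sets] == \
            [c.id for c in small_matrix.cognate_sets]
        assert [c.subcognate for c in back.cognate_sets] == \
            [c.subcognate for c in small_matrix.cognate_sets]
        assert (back.cells == small_matrix.cells).all()

    def test_long_table_round_trip_is_cell_exact(self, small_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        cd.write_cognate_matrix(small_matrix, str(path), "long_table")
        back = cd.read_cognate_matrix(str(path), "long_table")
        assert back.doculects == small_matrix.doculects
        assert [c.meaning for c in back.cognate_sets] == \
            [c.meaning for c in small_matrix.cognate_sets]
        assert (back.cells == small_matrix.cells).all()


class TestValidation:
    def test_partial_meaning_coding_is_rejected(self):
        m = build_matrix(["A", "B"],
                         [("m_1", "m", False), ("m_2", "m", False)],
                         [[1, MISSING], [0, 1]])
        with pytest.raises(CognateSchemaError, match="meaning-level"):
            m.validate()

    def test_meaning_level_missingness_is_accepted(self, small_matrix):
        small_matrix.validate()


class TestDropSubcognates:
    def test_flagged_column_is_removed(self, small_matrix):
        out = small_matrix.drop_subcognates()
        assert [c.id for c in out.cognate_sets] == \
            ["hand_1", "hand_2", "eye_1", "eye_2"]
        assert out.doculects == small_matrix.doculects

    def test_no_subcognates_is_identity(self, small_matrix):
        once = small_matrix.drop_subcognates()
        twice = once.drop_subcognates()
        assert (once.cells == twice.cells).all()
        assert once.cognate_sets == twice.cognate_sets

    def test_meaning_vanishes_when_all_its_cognates_are_sub(self):
        m = build_matrix(["A", "B"],
                         [("x_1", "x", True), ("y_1", "y", False)],
                         [[1, 0], [0, 1]])
        out = m.drop_subcognates()
        assert out.meanings == ["y"]


class TestFilterDoculects:
    def test_strict_less_than_boundary(self):
        cells = np.zeros((3, 100), dtype=np.int8)
        cells[0, :100] = 1
        cells[1, :80] = 1
        cells[2, :79] = 1
        m = build_matrix(["hi", "mid", "lo"],
                         [(f"m_{j}", "m", False) for j in range(100)], cells)
        out, _ = m.filter_doculects(80)
        assert out.doculects == ["hi", "mid"]

    def test_threshold_one_keeps_everyone_with_a_present_cell(self, small_matrix):
        out, emptied = small_matrix.filter_doculects(1)
        assert out.doculects == small_matrix.doculects
        assert emptied == []

    def test_unreachable_threshold_raises_empty_result(self, small_matrix):
        max_count = int((small_matrix.cells == 1).sum(axis=1).max())
        with pytest.raises(EmptyResultError):
            small_matrix.filter_doculects(max_count + 1)

    def test_emptied_columns_are_reported_not_dropped(self):
        # only A carries x_2; dropping A leaves the column all-absent
        m = build_matrix(["A", "B"],
                         [("x_1", "x", False), ("x_2", "x", False),
                          ("y_1", "y", False)],
                         [[0, 1, 0], [1, 0, 1]])
        out, emptied = m.filter_doculects(2)
        assert out.doculects == ["B"]
        assert emptied == ["x_2"]
        assert out.n_cognates == 3


class TestPartition:
    def test_paper_style_bins(self):
        sizes = {"a": 3, "b": 10, "c": 11, "d": 25}
        cognates = [(f"{m}_{j}", m, False)
                    for m, k in sizes.items() for j in range(k)]
        n = len(cognates)
        mat = build_matrix(["X", "Y"], cognates, np.ones((2, n), dtype=np.int8))
        scheme = partition_by_meaning_size(mat, 10)
        assert scheme.bins["1-10"] == {"a", "b"}
        assert scheme.bins["11-20"] == {"c"}
        assert scheme.bins["21-30"] == {"d"}

    def test_huge_width_gives_single_bin(self):
        mat = build_matrix(["X", "Y"],
                           [("a_1", "a", False), ("b_1", "b", False)],
                           [[1, 0], [0, 1]])
        scheme = partition_by_meaning_size(mat, 1000)
        assert len(scheme.bins) == 1

    def test_width_one_bins_by_exact_count(self):
        sizes = {"a": 1, "b": 2, "c": 2, "d": 4}
        cognates = [(f"{m}_{j}", m, False)
                    for m, k in sizes.items() for j in range(k)]
        mat = build_matrix(["X", "Y"], cognates,
                           np.ones((2, len(cognates)), dtype=np.int8))
        scheme = partition_by_meaning_size(mat, 1)
        assert scheme.bins == {"1-1": frozenset({"a"}),
                               "2-2": frozenset({"b", "c"}),
                               "4-4": frozenset({"d"})}

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(sizes=st.lists(st.integers(1, 40), min_size=1, max_size=12),
           width=st.integers(1, 15))
    def test_bins_partition_the_meanings(self, sizes, width):
        cognates = [(f"m{i}_{j}", f"m{i}", False)
                    for i, k in enumerate(sizes) for j in range(k)]
        mat = build_matrix(["X", "Y"], cognates,
                           np.ones((2, len(cognates)), dtype=np.int8))
        scheme = partition_by_meaning_size(mat, width)
        union = set()
        total = 0
        for members in scheme.bins.values():
            total += len(members)
            union |= members
        assert union == set(mat.meanings)
        assert total == len(mat.meanings)  # disjoint + exhaustive


class TestFrequencies:
    def test_direct_count_excluding_missing(self):
        cells = np.zeros((4, 5), dtype=np.int8)
        cells[0, 0] = cells[1, 1] = 1          # 2 present
        cells[2, :] = [MISSING] * 5            # won't validate per-meaning; fine here
        m = build_matrix(["A", "B", "C", "D"],
                         [(f"m_{j}", "m", False) for j in range(5)], cells)
        f0, f1 = m.empirical_state_frequencies()
        assert f0 == pytest.approx(13 / 15)
        assert f1 == pytest.approx(2 / 15)

    def test_all_present_boundary(self):
        m = build_matrix(["A", "B"], [("m_1", "m", False)], [[1], [1]])
        assert m.empirical_state_frequencies() == (0.0, 1.0)

    def test_duplication_invariance(self, small_matrix):
        doubled = CognateMatrix(
            doculects=small_matrix.doculects,
            cognate_sets=[CognateSet(c.id + "_copy", c.meaning + "2", c.subcognate)
                          for c in small_matrix.cognate_sets]
            + list(small_matrix.cognate_sets),
            cells=np.hstack([small_matrix.cells, small_matrix.cells]))
        assert doubled.empirical_state_frequencies() == \
            small_matrix.empirical_state_frequencies()

    def test_all_missing_is_an_error(self):
        m = build_matrix(["A", "B"], [("m_1", "m", False)],
                         [[MISSING], [MISSING]])
        with pytest.raises(CognateSchemaError):
            m.empirical_state_frequencies()
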