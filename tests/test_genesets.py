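"""Gene-set parsing, canonicalization, overlaps and coverage."""

from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocultrx.exceptions import ValidationError
from cocultrx.genesets import (
    GeneSet,
    canonicalize,
    coverage_fraction,
    overlap,
    overlap_from_counts,
    overlap_matrix,
    read_gene_sets,
    read_universe,
    restrict_to_universe,
    set_difference,
)
from cocultrx.synthetic_data import reference_overlap_sets

from .conftest import make_set


class TestGmtIO:
    def test_parses_and_canonicalizes(self, gmt_file):
        sets = read_gene_sets(gmt_file)
        assert [s.name for s in sets] == ["COLONOCYTE", "ENTEROCYTE"]
        # "MUC2" and "muc2" collapse to one symbol after canonicalization
        assert sets[0].genes == frozenset({"MUC2", "TFF3"})
        assert sets[0].source == "COPE"

    def test_empty_file_rejected(self, tmp_path):
        empty = tmp_path / "empty.gmt"
        empty.write_text("")
        with pytest.raises(ValidationError):
            read_gene_sets(empty)

    @pytest.mark.parametrize(
        "content",
        [
            "NAME_ONLY\n",                  # missing description + symbols
            "NAME\tdesc\n",                 # no symbols
            "NAME\tdesc\t \t \n",           # only blank symbols
            "A\td\tX\nA\td\tY\n",           # duplicate name
        ],
    )
    def test_malformed_records_rejected(self, tmp_path, content):
        bad = tmp_path / "bad.gmt"
        bad.write_text(content)
        with pytest.raises(ValidationError):
            read_gene_sets(bad)

    def test_error_names_the_line(self, tmp_path):
        bad = tmp_path / "bad.gmt"
        bad.write_text("OK\td\tX\nBROKEN\td\n")
        with pytest.raises(ValidationError, match=":2"):
            read_gene_sets(bad)

    def test_universe_roundtrip(self, tmp_path):
        path = tmp_path / "u.txt"
        path.write_text("a\nB\n b \n\n")
        uni = read_universe(path)
        assert uni.genes == frozenset({"A", "B"})
        assert uni.size == 2


@given(st.text(min_size=1, max_size=20))
@settings(deadline=None, max_examples=50)
def test_canonicalization_idempotent(symbol):
    once = canonicalize(symbol)
    assert canonicalize(once) == once


class TestOverlap:
    def test_reference_cells_from_counts(self):
        r = overlap_from_counts("A", "B", 579, 1371, 79)
        assert (r.freq_a, r.freq_b) == (13.6, 5.8)
        r = overlap_from_counts("C", "E", 103, 142, 50)
        assert (r.freq_a, r.freq_b) == (48.5, 35.2)

    def test_identity_overlap(self):
        a = make_set("A", range(10))
        r = overlap(a, GeneSet("B", a.genes))
        assert r.common == 10 and r.freq_a == r.freq_b == 100.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            overlap_from_counts("A", "B", 0, 5, 0)

    def test_count_exceeding_size_rejected(self):
        with pytest.raises(ValidationError):
            overlap_from_counts("A", "B", 5, 5, 6)

    @given(
        st.sets(st.integers(0, 40), min_size=1, max_size=20),
        st.sets(st.integers(0, 40), min_size=1, max_size=20),
    )
    @settings(deadline=None, max_examples=50)
    def test_symmetry_and_frequency_identity(self, ia, ib):
        a, b = make_set("A", ia), make_set("B", ib)
        r = overlap(a, b)
        assert r.common == overlap(b, a).common == len(ia & ib)
        # before rounding: freq_a * |A| == freq_b * |B| == 100*common
        assert abs(100.0 * r.common / a.size - r.freq_a) <= 0.05
        assert abs(100.0 * r.common / b.size - r.freq_b) <= 0.05


class TestOverlapMatrix:
    def test_matches_brute_force_on_random_sets(self):
        rnd = random.Random(7)
        sets = [
            make_set(f"S{i}", rnd.sample(range(30), rnd.randint(3, 20)))
            for i in range(3)
        ]
        om = overlap_matrix(sets)
        for a, b in itertools.combinations(sets, 2):
            assert om.cell(a.name, b.name).common == len(a.genes & b.genes)
            assert om.cell(b.name, a.name).common == len(a.genes & b.genes)

    def test_disjoint_sets(self):
        om = overlap_matrix([make_set("A", range(5)), make_set("B", range(10, 15))])
        cell = om.cell("A", "B")
        assert cell.common == 0 and cell.freq_a == 0.0

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValidationError):
            overlap_matrix([make_set("A", range(5)), make_set("A", range(3))])

    def test_formatted_cells_mirror_published_layout(self):
        om = overlap_matrix([make_set("A", range(6)), make_set("B", range(3, 12))])
        fmt = om.to_formatted()
        assert fmt.loc["A", "B"] == "50.0 (3)"
        assert fmt.loc["A", "A"] == ""

    def test_triple_intersection_bounded_by_pairwise(self):
        rnd = random.Random(13)
        for _ in range(20):
            sets = [make_set(f"S{i}", rnd.sample(range(25), 10)) for i in range(3)]
            triple = len(sets[0].genes & sets[1].genes & sets[2].genes)
            pairwise = [
                len(x.genes & y.genes)
                for x, y in itertools.combinations(sets, 2)
            ]
            assert triple <= min(pairwise)


class TestSetDifference:
    def test_difference_and_provenance(self):
        a = GeneSet("A", frozenset({"CD36", "EGF"}))
        b = GeneSet("B", frozenset({"EGF"}))
        d = set_difference(a, b)
        assert d.genes == frozenset({"CD36"})
        assert d.name == "A_minus_B"

    def test_self_difference_empty(self):
        a = make_set("A", range(5))
        assert set_difference(a, a).genes == frozenset()

    def test_recovers_planted_specific_genes(self):
        # enterocyte-like vs colonocyte-like pair sharing a planted core
        shared = set(range(50))
        specific = set(range(100, 130))
        entero = make_set("ENTERO", shared | specific)
        colono = make_set("COLONO", shared | set(range(200, 220)))
        diff = set_difference(entero, colono)
        assert diff.genes == frozenset(f"G{i:03d}" for i in specific)


class TestCoverage:
    def test_full_and_zero_coverage(self):
        d = make_set("D", range(10))
        assert coverage_fraction(d, [make_set("P", range(20))]) == 100.0
        assert coverage_fraction(d, [make_set("P", range(50, 60))]) == 0.0

    def test_empty_pathway_collection_warns_and_returns_zero(self, caplog):
        d = make_set("D", range(10))
        with caplog.at_level("WARNING"):
            assert coverage_fraction(d, []) == 0.0
        assert "empty pathway" in caplog.text


class TestUniverseRestriction:
    def test_outside_genes_dropped_and_logged(self, small_universe, caplog):
        gs = GeneSet("S", frozenset({"G001", "G002", "NOT_THERE"}))
        with caplog.at_level("WARNING"):
            restricted = restrict_to_universe(gs, small_universe)
        assert restricted.genes == frozenset({"G001", "G002"})
        assert "1 of 3" in caplog.text

    def test_fully_outside_set_rejected(self, small_universe):
        gs = GeneSet("S", frozenset({"NOPE"}))
        with pytest.raises(ValidationError):
            restrict_to_universe(gs, small_universe)


class TestReferenceSetsRealization:
    def test_sizes_and_pairwise_counts_match_fixture(self, fixtures):
        universe, sets = reference_overlap_sets()
        assert universe.size == 7000
        sizes = dict(zip(fixtures.datasets_info["name"], fixtures.datasets_info["size"]))
        by_name = {s.name: s for s in sets}
        for name, size in sizes.items():
            assert by_name[name].size == size
        for _, row in fixtures.overlaps.iterrows():
            a, b = by_name[row["name_a"]], by_name[row["name_b"]]
            assert len(a.genes & b.genes) == row["common"]
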