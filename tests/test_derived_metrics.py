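"""Authority, self-citation, concordance and research-group detection."""

from __future__ import annotations

import itertools
import random

import pytest

from citenet.citation_matching import CitationEdge
from citenet.derived_metrics import (
    AuthorityTable,
    article_group_membership,
    authority_band,
    build_authority_table,
    coauthorship_groups,
    concordance,
    is_self_citation,
    path_authority,
)
from citenet.records_io import effective_publication_date

from conftest import make_attrs, make_record


class TestAuthorityTable:
    def _toy(self):
        # author "bernard,a" on P1 (2003) and P2 (2006); P1 cited in 2004
        # and 2005, P2 cited in 2007
        records = [
            make_record("P1", authors=("bernard,a",), epub="2003-01"),
            make_record("P2", authors=("bernard,a", "dumont,x"), epub="2006-01"),
            make_record("X", authors=("x,x",), epub="2004-06"),
            make_record("Y", authors=("y,y",), epub="2005-06"),
            make_record("Z", authors=("z,z",), epub="2007-06"),
        ]
        edges = {
            CitationEdge("X", "P1", "doi"),
            CitationEdge("Y", "P1", "doi"),
            CitationEdge("Z", "P2", "doi"),
        }
        return records, edges

    def test_cumulative_counts_by_citing_year(self):
        records, edges = self._toy()
        table = build_authority_table(records, edges)
        assert [table.value("bernard,a", y) for y in (2003, 2004, 2005, 2006, 2007)] \
            == [0, 1, 2, 2, 3]

    def test_uncited_author_has_zero_authority_everywhere(self):
        records, edges = self._toy()
        table = build_authority_table(records, edges)
        assert all(table.value("dumont,x", y) == 0 for y in range(2003, 2007))
        assert table.value("dumont,x", 2007) == 1  # co-author of P2

    def test_monotone_in_year_and_equals_exhaustive_recount(self, paper_net):
        table = paper_net.authority
        by_id = {r.article_id: r for r in paper_net.records}
        lo, hi = table.year_range
        for author in table.authors:
            values = [table.value(author, y) for y in range(lo, hi + 1)]
            assert values == sorted(values)
        # brute-force recount for every (author, year)
        for author in table.authors:
            for year in (lo, (lo + hi) // 2, hi):
                expected = sum(
                    1
                    for e in paper_net.edges
                    if author in by_id[e.cited_id].authors
                    and effective_publication_date(by_id[e.citing_id]).year <= year
                )
                assert table.value(author, year) == expected


class TestPathAuthority:
    def test_maximum_over_cited_authors(self):
        table = AuthorityTable(
            {"a,a": [2001] * 5, "b,b": [2001] * 12}, (2000, 2010)
        )
        cited = make_record("C", authors=("a,a", "b,b"), epub="2000-01")
        citing = make_record("G", authors=("z,z",), epub="2005-01")
        assert path_authority(cited, citing, table) == 12
        assert authority_band(12) == "medium"

    def test_author_order_invariance(self):
        table = AuthorityTable({"a,a": [2001] * 3, "b,b": [2001] * 7}, (2000, 2010))
        citing = make_record("G", epub="2005-01")
        for authors in itertools.permutations(("a,a", "b,b")):
            cited = make_record("C", authors=authors, epub="2000-01")
            assert path_authority(cited, citing, table) == 7

    @pytest.mark.parametrize(
        "value, band",
        [(0, "low"), (5, "low"), (6, "medium"), (50, "medium"), (51, "high")],
    )
    def test_bands(self, value, band):
        assert authority_band(value) == band


class TestSelfCitation:
    def test_shared_author_key(self):
        a = make_record("A", authors=("bernard,a", "x,x"), epub="2003-01")
        b = make_record("B", authors=("bernard,a",), epub="2005-01")
        assert is_self_citation(a, b) and is_self_citation(b, a)

    def test_disjoint_authors(self):
        a = make_record("A", authors=("bernard,a",), epub="2003-01")
        b = make_record("B", authors=("michel,o",), epub="2005-01")
        assert not is_self_citation(a, b)

    def test_same_surname_different_initial_is_not_shared(self):
        a = make_record("A", authors=("bernard,a",), epub="2003-01")
        b = make_record("B", authors=("bernard,c",), epub="2005-01")
        assert not is_self_citation(a, b)


class TestConcordance:
    def test_same_conclusion_is_concordant(self):
        a = make_record("A", epub="2003-01", attributes=make_attrs())
        b = make_record("B", epub="2005-01", attributes=make_attrs())
        assert concordance(a, b, "authors_conclusion") is True

    def test_different_conclusion_is_discordant(self):
        a = make_record("A", epub="2003-01", attributes=make_attrs())
        b = make_record("B", epub="2005-01",
                        attributes=make_attrs(authors_conclusion="negative"))
        assert concordance(a, b, "authors_conclusion") is False

    def test_not_applicable_propagates_to_undefined(self):
        narrative = make_attrs(
            article_type="narrative", study_design="commentary",
            sample_size=None, data_based_conclusion="not-applicable",
            study_quality="not-rated",
        )
        a = make_record("A", epub="2003-01", attributes=narrative)
        b = make_record("B", epub="2005-01", attributes=make_attrs())
        assert concordance(a, b, "data_based_conclusion") is None

    def test_unknown_attribute_rejected(self):
        a = make_record("A", epub="2003-01", attributes=make_attrs())
        with pytest.raises(ValueError, match="concordance"):
            concordance(a, a, "journal")


class TestResearchGroups:
    def _triads(self):
        g1, g2 = ("a,a", "b,b", "c,c"), ("d,d", "e,e", "f,f")
        records = []
        for i in range(3):  # each triad co-publishes three times
            records.append(make_record(f"G1{i}", authors=g1, epub=f"200{i + 1}-01"))
            records.append(make_record(f"G2{i}", authors=g2, epub=f"200{i + 1}-06"))
        return records, g1, g2

    def test_two_disjoint_triads_give_two_groups(self):
        records, g1, g2 = self._triads()
        groups = coauthorship_groups(records)
        assert len(groups) == 2
        assert {frozenset(g1), frozenset(g2)} == {g.members for g in groups}

    def test_authors_below_publication_threshold_excluded(self):
        records, *_ = self._triads()
        assert coauthorship_groups(records, min_publications=4) == []

    def test_membership_codes(self):
        records, g1, g2 = self._triads()
        groups = coauthorship_groups(records)
        both = make_record("MIX", authors=("a,a", "d,d"), epub="2009-01")
        neither = make_record("OUT", authors=("z,z",), epub="2009-01")
        assert article_group_membership(records[0], groups) in ({1}, {2})
        assert article_group_membership(both, groups) == {1, 2}
        assert article_group_membership(neither, groups) == set()

    def test_matches_union_find_on_random_instances(self):
        rng = random.Random(99)
        for _ in range(20):
            n_authors = rng.randint(4, 20)
            pool = [f"a{i},a" for i in range(n_authors)]
            records = [
                make_record(
                    f"R{j}",
                    authors=tuple(rng.sample(pool, rng.randint(1, min(4, n_authors)))),
                    epub="2005-01",
                )
                for j in range(rng.randint(3, 15))
            ]
            groups = coauthorship_groups(records, min_publications=2)
            # union-find oracle
            counts = {}
            for r in records:
                for a in set(r.authors):
                    counts[a] = counts.get(a, 0) + 1
            keep = {a for a, c in counts.items() if c >= 2}
            parent = {a: a for a in keep}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for r in records:
                authors = [a for a in set(r.authors) if a in keep]
                for a, b in zip(authors, authors[1:]):
                    parent[find(a)] = find(b)
            comps = {}
            for a in keep:
                comps.setdefault(find(a), set()).add(a)
            expected = {frozenset(c) for c in comps.values() if len(c) >= 2}
            assert {g.members for g in groups} == expected

    def test_fixture_recovers_planted_communities(self, paper_net):
        groups = coauthorship_groups(paper_net.records)
        assert len(groups) == 2
        planted = paper_net.truth.author_communities
        for g in groups:
            communities = {planted[a] for a in g.members if a in planted}
            assert len(communities) == 1  # no mixing across planted communities
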