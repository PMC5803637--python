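"""Per-path determinants: authority, self-citation, concordance, co-authorship.

*Within-network authority* of an author in year y is the cumulative number
of within-network citations (realized edges) to any publication that author
contributed to, counting citing articles published in or before y.  A cited
article's authority on a given path is the maximum over its authors in the
citing article's publication year — authority grows over time, so the same
cited article carries different authority on paths from different citing
years.

*Self-citation* is a citation between two articles sharing at least one
(normalized) author.  *Concordance* asks whether cited and citing articles
carry the same value of a coded attribute.  Research groups are the
connected components of the co-authorship graph restricted to authors with
at least three in-network publications.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .citation_matching import CitationEdge
from .path_builder import CitationPath, PathDataset
from .records_io import ArticleRecord, effective_publication_date

#: coded attributes for which cited/citing concordance is defined
CONCORDANCE_ATTRIBUTES = (
    "authors_conclusion",
    "data_based_conclusion",
    "article_type",
    "study_quality",
    "specificity",
    "funding",
    "conclusive_title",
)

#: attribute values that carry no information for concordance
_NA_VALUES = {"not-applicable", "not-rated"}

#: authority bands as reported in the characteristics table
AUTHORITY_BANDS = (("low", 0, 5), ("medium", 6, 50), ("high", 51, None))


class AuthorityTable:
    """Cumulative within-network citation counts per (author, year).

    Stored as per-author sorted lists of citing-article publication years;
    a lookup counts events in or before the query year, so counts are
    non-decreasing in year by construction.
    """

    def __init__(self, events: dict[str, list[int]], year_range: tuple[int, int]):
        self._events = {a: sorted(ys) for a, ys in events.items()}
        self.year_range = year_range

    def value(self, author: str, year: int) -> int:
        years = self._events.get(author)
        if not years:
            return 0
        return bisect.bisect_right(years, year)

    @property
    def authors(self) -> list[str]:
        return sorted(self._events)

    def entries(self) -> pd.DataFrame:
        """Long-format (author, year, authority) table over the network years."""
        lo, hi = self.year_range
        rows = [
            {"author": a, "year": y, "authority": self.value(a, y)}
            for a in self.authors
            for y in range(lo, hi + 1)
        ]
        return pd.DataFrame(rows, columns=["author", "year", "authority"])

    def to_csv(self, path: str | Path) -> None:
        self.entries().to_csv(path, index=False)


def build_authority_table(
    records: Sequence[ArticleRecord], edges: Iterable[CitationEdge]
) -> AuthorityTable:
    """Count within-network citations accumulated by each author per year.

    Each realized edge contributes one citation, dated by the citing
    article's publication year (inclusive: citations published in year y
    count toward authority in year y), to every author of the cited article.
    """
    by_id = {r.article_id: r for r in records}
    events: dict[str, list[int]] = {}
    for edge in edges:
        citing_year = effective_publication_date(by_id[edge.citing_id]).year
        for author in set(by_id[edge.cited_id].authors):
            events.setdefault(author, []).append(citing_year)
    years = [effective_publication_date(r).year for r in records]
    return AuthorityTable(events, (min(years), max(years)))


def authority_band(value: int) -> str:
    if value < 0:
        raise ValueError("authority must be non-negative")
    for name, lo, hi in AUTHORITY_BANDS:
        if hi is None or lo <= value <= hi:
            if value >= lo:
                return name
    raise AssertionError("unreachable")


def path_authority(
    cited: ArticleRecord, citing: ArticleRecord, table: AuthorityTable
) -> int:
    """Highest authority among the cited article's authors in the citing year."""
    year = effective_publication_date(citing).year
    return max(table.value(a, year) for a in cited.authors)


def is_self_citation(cited: ArticleRecord, citing: ArticleRecord) -> bool:
    """True iff the two articles share at least one author (by name key)."""
    return bool(set(cited.authors) & set(citing.authors))


def concordance(
    cited: ArticleRecord, citing: ArticleRecord, attribute: str
) -> bool | None:
    """Whether cited and citing articles carry the same attribute value.

    Returns None (undefined) when either side's value is not applicable
    (e.g. data-based conclusion of a narrative article) or not rated.
    """
    if attribute not in CONCORDANCE_ATTRIBUTES:
        raise ValueError(
            f"no concordance defined for attribute {attribute!r}; "
            f"choose one of {CONCORDANCE_ATTRIBUTES}"
        )
    if cited.attributes is None or citing.attributes is None:
        raise ValueError("concordance requires merged coded attributes")
    a = getattr(cited.attributes, attribute)
    b = getattr(citing.attributes, attribute)
    if a in _NA_VALUES or b in _NA_VALUES:
        return None
    return a == b


def annotate_paths(
    dataset: PathDataset,
    records: Sequence[ArticleRecord],
    table: AuthorityTable,
    concordance_attributes: Sequence[str] = CONCORDANCE_ATTRIBUTES,
) -> PathDataset:
    """Fill self-citation, authority and concordance on every path (in place)."""
    by_id = {r.article_id: r for r in records}
    have_attrs = all(r.attributes is not None for r in records)
    for path in dataset.paths:
        cited = by_id[path.cited_id]
        citing = by_id[path.citing_id]
        path.self_citation = is_self_citation(cited, citing)
        path.authority_value = path_authority(cited, citing, table)
        path.authority_band = authority_band(path.authority_value)
        if have_attrs:
            path.concordance = {
                attr: concordance(cited, citing, attr)
                for attr in concordance_attributes
            }
    return dataset


# --------------------------------------------------------------------------
# Co-authorship groups
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ResearchGroup:
    group_id: int
    members: frozenset[str]


def coauthorship_graph(
    records: Sequence[ArticleRecord], min_publications: int = 3
) -> nx.Graph:
    """Co-authorship graph over authors with >= min_publications articles."""
    counts: dict[str, int] = {}
    for rec in records:
        for author in set(rec.authors):
            counts[author] = counts.get(author, 0) + 1
    keep = {a for a, c in counts.items() if c >= min_publications}
    graph = nx.Graph()
    for author in sorted(keep):
        graph.add_node(author, publications=counts[author])
    for rec in records:
        authors = sorted(set(rec.authors) & keep)
        for i, a in enumerate(authors):
            for b in authors[i + 1:]:
                graph.add_edge(a, b)
    return graph


def coauthorship_groups(
    records: Sequence[ArticleRecord], min_publications: int = 3
) -> list[ResearchGroup]:
    """Research groups: connected components (size >= 2) of the graph above.

    Groups are numbered 1..k in order of their lexicographically smallest
    member, which makes the ids deterministic.
    """
    graph = coauthorship_graph(records, min_publications)
    components = [c for c in nx.connected_components(graph) if len(c) >= 2]
    components.sort(key=lambda c: min(c))
    return [
        ResearchGroup(group_id=i + 1, members=frozenset(c))
        for i, c in enumerate(components)
    ]


def article_group_membership(
    record: ArticleRecord, groups: Sequence[ResearchGroup]
) -> set[int]:
    """Ids of all groups whose members intersect the article's author set."""
    authors = set(record.authors)
    return {g.group_id for g in groups if authors & g.members}


def coauthorship_to_graphml(
    records: Sequence[ArticleRecord], path: str | Path, min_publications: int = 3
) -> None:
    nx.write_graphml(coauthorship_graph(records, min_publications), path)
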