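"""Link reference lists to in-network articles (two-tier matching).

A reference is linked to a candidate article by DOI when both sides carry
one; a reference that did not match by DOI falls back to the composite key
of five components — first author's surname, first author's first initial,
publication year, volume number, and first page number — all of which must
match exactly after normalization.  No fuzzy matching is attempted, and a
reference that two distinct candidates would claim raises an error rather
than picking one arbitrarily.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .records_io import ArticleRecord, ReferenceEntry

MatchKey = tuple[str, str, int, str, str]


class AmbiguousMatchError(ValueError):
    """A reference matches two or more distinct candidate articles."""


@dataclass(frozen=True, order=True)
class CitationEdge:
    """One realized citation: *citing_id*'s reference list contains *cited_id*."""

    citing_id: str
    cited_id: str
    matched_by: str = "doi"  # "doi" | "composite-key"

    def __post_init__(self) -> None:
        if self.citing_id == self.cited_id:
            raise ValueError(f"self-loop edge on {self.citing_id}")


def normalize_page(page: str | None) -> str | None:
    """First-page normalization: strip leading zeros from all-digit pages.

    Electronic article numbers ("e0123") are compared verbatim.
    """
    if page is None:
        return None
    page = page.strip()
    if page.isdigit():
        return page.lstrip("0") or "0"
    return page


def record_match_year(record: ArticleRecord) -> int:
    """Year a database export prints for a cited record: print year, else epub."""
    date = record.print_date if record.print_date is not None else record.epub_date
    assert date is not None  # guaranteed by ArticleRecord invariant
    return date.year


def record_composite_key(record: ArticleRecord) -> MatchKey:
    first = record.authors[0]  # "surname,f"
    surname, _, initial = first.partition(",")
    return (
        surname,
        initial,
        record_match_year(record),
        (record.volume or "").strip(),
        normalize_page(record.first_page) or "",
    )


def reference_composite_key(ref: ReferenceEntry) -> MatchKey:
    return (
        ref.first_author_surname,
        ref.first_author_initial,
        int(ref.year),
        (ref.volume or "").strip(),
        normalize_page(ref.first_page) or "",
    )


def _build_indexes(
    candidates: Sequence[ArticleRecord],
) -> tuple[dict[str, list[str]], dict[MatchKey, list[str]]]:
    by_doi: dict[str, list[str]] = {}
    by_key: dict[MatchKey, list[str]] = {}
    for rec in candidates:
        if rec.doi:
            by_doi.setdefault(rec.doi, []).append(rec.article_id)
        by_key.setdefault(record_composite_key(rec), []).append(rec.article_id)
    return by_doi, by_key


def _lookup(ids: list[str] | None, ref: ReferenceEntry, tier: str) -> str | None:
    if not ids:
        return None
    if len(ids) > 1:
        raise AmbiguousMatchError(
            f"reference {ref!r} matches multiple candidates by {tier}: {sorted(ids)}"
        )
    return ids[0]


def match_reference(
    ref: ReferenceEntry, candidates: Sequence[ArticleRecord]
) -> tuple[str | None, str | None]:
    """Match one reference entry against candidate records.

    Returns ``(article_id, matched_by)`` or ``(None, None)``.  A DOI match
    short-circuits: it is never re-tested against the composite key.
    """
    by_doi, by_key = _build_indexes(candidates)
    if ref.doi:
        hit = _lookup(by_doi.get(ref.doi), ref, "doi")
        if hit is not None:
            return hit, "doi"
    hit = _lookup(by_key.get(reference_composite_key(ref)), ref, "composite-key")
    if hit is not None:
        return hit, "composite-key"
    return None, None


def build_citation_edges(records: Sequence[ArticleRecord]) -> set[CitationEdge]:
    """Link every article's reference list against the whole network.

    Duplicate matches within one reference list collapse to a single edge;
    a reference resolving to the citing article itself is ignored (an
    article cannot cite itself).
    """
    by_doi, by_key = _build_indexes(records)
    edges: dict[tuple[str, str], CitationEdge] = {}
    for rec in records:
        for ref in rec.references:
            try:
                cited = None
                matched_by = None
                if ref.doi:
                    cited = _lookup(by_doi.get(ref.doi), ref, "doi")
                    if cited is not None:
                        matched_by = "doi"
                if cited is None:
                    cited = _lookup(
                        by_key.get(reference_composite_key(ref)), ref, "composite-key"
                    )
                    matched_by = "composite-key" if cited is not None else None
            except AmbiguousMatchError as exc:
                raise AmbiguousMatchError(
                    f"while matching references of {rec.article_id}: {exc}"
                ) from exc
            if cited is None or cited == rec.article_id:
                continue
            key = (rec.article_id, cited)
            if key not in edges:
                edges[key] = CitationEdge(rec.article_id, cited, matched_by)
    return set(edges.values())


# --------------------------------------------------------------------------
# Exports
# --------------------------------------------------------------------------


def edges_to_tsv(edges: Iterable[CitationEdge], path: str | Path) -> None:
    lines = ["citing_id\tcited_id\n"]
    for e in sorted(edges):
        lines.append(f"{e.citing_id}\t{e.cited_id}\n")
    Path(path).write_text("".join(lines))


def edges_to_graphml(edges: Iterable[CitationEdge], path: str | Path) -> None:
    graph = nx.DiGraph()
    for e in sorted(edges):
        graph.add_edge(e.citing_id, e.cited_id, matched_by=e.matched_by)
    nx.write_graphml(graph, path)
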