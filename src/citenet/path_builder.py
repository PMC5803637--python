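"""Enumerate potential citation paths — the unit of analysis.

A potential citation path is an ordered pair (cited, citing) such that the
cited article was published strictly before the citing article's submission:
its *time to citation* (years from the cited article's publication date to
the citing article's submission date) is positive.  The dependent variable
of the downstream models is whether such a path was *realized*, i.e. whether
the citing article's reference list actually contains the cited article.

A realized citation whose time to citation is not positive (the citing
authors saw the cited manuscript before it was published, which happens
within research groups) is not a potential citation; it is excluded from the
dataset and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .citation_matching import CitationEdge
from .records_io import (
    ArticleRecord,
    effective_publication_date,
    resolve_submission_date,
)


@dataclass
class CitationPath:
    """One potential citation with its derived covariates.

    The derived determinants (self-citation, authority, concordance) start
    unset and are filled in by :mod:`citenet.derived_metrics`.
    """

    citing_id: str
    cited_id: str
    realized: bool
    time_to_citation: float  # years, months/12, > 0
    self_citation: bool | None = None
    authority_value: int | None = None
    authority_band: str | None = None
    concordance: dict[str, bool | None] = field(default_factory=dict)


@dataclass(frozen=True)
class ExcludedEdge:
    edge: CitationEdge
    reason: str


@dataclass
class PathDataset:
    paths: list[CitationPath]
    excluded_edges: list[ExcludedEdge]

    @property
    def n_realized(self) -> int:
        return sum(p.realized for p in self.paths)


def time_to_citation(cited: ArticleRecord, citing: ArticleRecord) -> float:
    """Years from the cited article's publication to the citing submission.

    Computed in whole months and divided by 12; may be zero or negative —
    the caller applies the strict positivity filter.
    """
    submission, _ = resolve_submission_date(citing)
    published = effective_publication_date(cited)
    return (submission - published).n / 12.0


def enumerate_paths(
    records: Sequence[ArticleRecord], edges: set[CitationEdge]
) -> PathDataset:
    """Enumerate every potential citation path and flag the realized ones.

    Every ordered pair with strictly positive time to citation becomes a
    path; realized edges that fail the time filter are excluded with reason
    ``"forward citation"``.  Output ordering is deterministic (sorted by
    citing then cited id) and independent of the input record order.
    """
    realized_pairs = {(e.citing_id, e.cited_id): e for e in edges}
    ordered = sorted(records, key=lambda r: r.article_id)
    paths: list[CitationPath] = []
    excluded: list[ExcludedEdge] = []
    seen_pairs: set[tuple[str, str]] = set()
    for citing in ordered:
        for cited in ordered:
            if citing.article_id == cited.article_id:
                continue
            pair = (citing.article_id, cited.article_id)
            seen_pairs.add(pair)
            ttc = time_to_citation(cited, citing)
            edge = realized_pairs.get(pair)
            if ttc > 0:
                paths.append(
                    CitationPath(
                        citing_id=citing.article_id,
                        cited_id=cited.article_id,
                        realized=edge is not None,
                        time_to_citation=ttc,
                    )
                )
            elif edge is not None:
                excluded.append(ExcludedEdge(edge, "forward citation"))
    stray = [e for p, e in realized_pairs.items() if p not in seen_pairs]
    for e in sorted(stray):
        excluded.append(ExcludedEdge(e, "endpoint not in record collection"))
    return PathDataset(paths=paths, excluded_edges=excluded)


def paths_to_frame(dataset: PathDataset) -> pd.DataFrame:
    """Materialize the path dataset as a flat table (one row per path)."""
    rows = []
    for p in dataset.paths:
        row = {
            "citing_id": p.citing_id,
            "cited_id": p.cited_id,
            "realized": int(p.realized),
            "time_to_citation": p.time_to_citation,
            "self_citation": p.self_citation,
            "authority_value": p.authority_value,
            "authority_band": p.authority_band,
        }
        for attr, flag in p.concordance.items():
            row[f"conc_{attr}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)


def export_paths(dataset: PathDataset, path: str | Path) -> None:
    paths_to_frame(dataset).to_csv(path, index=False)


def export_excluded(dataset: PathDataset, path: str | Path) -> None:
    rows = [
        {
            "citing_id": x.edge.citing_id,
            "cited_id": x.edge.cited_id,
            "matched_by": x.edge.matched_by,
            "reason": x.reason,
        }
        for x in dataset.excluded_edges
    ]
    pd.DataFrame(rows, columns=["citing_id", "cited_id", "matched_by", "reason"]).to_csv(
        path, index=False
    )
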