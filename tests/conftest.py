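"""Shared fixtures: toy record builders and the frozen synthetic network."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from citenet import (
    annotate_paths,
    build_authority_table,
    build_citation_edges,
    covariate_frame,
    enumerate_paths,
)
from citenet.records_io import ArticleRecord, CodedAttributes
from citenet.synthetic_network import PAPER_LIKE_CONFIG, generate_network


def make_attrs(**overrides) -> CodedAttributes:
    """A valid empirical cross-sectional attribute set, overridable per test."""
    base = dict(
        authors_conclusion="positive",
        data_based_conclusion="negative",
        article_type="empirical",
        study_design="cross-sectional",
        sample_size=500,
        study_quality="fair",
        specificity=4,
        language_english=True,
        conclusive_title=False,
        funding="non-profit",
        n_authors=3,
        n_affiliations=1,
        n_references=30,
        journal_impact_factor=2.5,
        corr_gender="male",
        corr_country="belgium",
        corr_affiliation="university",
    )
    base.update(overrides)
    if base["article_type"] == "narrative":
        base.setdefault("study_design", "narrative-review")
    return CodedAttributes(**base)


def make_record(
    article_id: str,
    authors=("bernard,a",),
    epub: str | None = None,
    print_date: str | None = None,
    submission: str | None = None,
    references=(),
    attributes: CodedAttributes | None = None,
    **fields,
) -> ArticleRecord:
    def _p(x):
        return pd.Period(x, freq="M") if x else None

    rec = ArticleRecord(
        article_id=article_id,
        title=fields.pop("title", f"Title {article_id}"),
        authors=list(authors),
        doi=fields.pop("doi", None),
        epub_date=_p(epub),
        print_date=_p(print_date),
        submission_date=_p(submission),
        journal=fields.pop("journal", "J Test"),
        volume=fields.pop("volume", None),
        first_page=fields.pop("first_page", None),
        references=list(references),
        attributes=attributes,
    )
    assert not fields, f"unknown fields {fields}"
    return rec


@dataclass
class NetworkBundle:
    records: list
    sheet: dict
    truth: object
    edges: set
    dataset: object
    authority: object
    frame: pd.DataFrame


@pytest.fixture(scope="session")
def paper_net() -> NetworkBundle:
    """The frozen 36-article synthetic network, fully processed."""
    records, sheet, truth = generate_network(PAPER_LIKE_CONFIG)
    edges = build_citation_edges(records)
    dataset = enumerate_paths(records, edges)
    authority = build_authority_table(records, edges)
    annotate_paths(dataset, records, authority)
    frame = covariate_frame(dataset, records)
    return NetworkBundle(records, sheet, truth, edges, dataset, authority, frame)
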