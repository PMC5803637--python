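"""Generate synthetic citation networks with known ground truth.

The generator emulates the statistical structure of a small claim-specific
citation network: articles with year-month publication/submission dates,
author lists drawn from a pool with optional co-authorship communities
(which create self-citation opportunities), manually-coded attributes drawn
from configurable marginals, and citation decisions drawn from a logistic
model with a per-citing-article normal random intercept,

    P(realized) = logistic(intercept + b_citing + sum_k coef_k * x_k),
    b_citing ~ Normal(0, random_intercept_sd^2).

Realized citations are written back into the citing articles' reference
lists in the exact text format the record reader consumes, with DOIs present
at a configurable rate and composite keys always complete — so the matching
stage can be tested for perfect recovery.  Random streams are split per
sub-process (dates, authors, attributes, realization, reference formatting)
so that changing one marginal does not perturb the others under a fixed
master seed; identical seeds give identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from .citation_matching import record_match_year
from .records_io import (
    ArticleRecord,
    CodedAttributes,
    ReferenceEntry,
    effective_publication_date,
    resolve_submission_date,
    write_extraction_sheet,
    write_records,
)

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

#: attribute marginals mirroring the published characteristics of a small
#: (36-article) chlorination-and-asthma network
DEFAULT_MARGINALS: dict[str, dict] = {
    "article_type": {"narrative": 14 / 36, "empirical": 22 / 36},
    "narrative_design": {"narrative-review": 11 / 14, "commentary": 3 / 14},
    "empirical_design": {
        "cross-sectional": 13 / 22,
        "cohort": 3 / 22,
        "pre-experimental": 2 / 22,
        "multiple-designs": 1 / 22,
        "ecological": 1 / 22,
        "meta-analysis": 1 / 22,
        "case-study": 1 / 22,
    },
    "authors_conclusion": {"positive": 16 / 36, "negative": 10 / 36, "mixed": 10 / 36},
    "data_based_conclusion": {"positive": 6 / 22, "negative": 16 / 22},
    "sample_size_band": {"low": 6 / 22, "medium": 8 / 22, "high": 8 / 22},
    "study_quality": {"fair": 9 / 13, "poor": 4 / 13},
    "specificity": {1: 5 / 36, 2: 7 / 36, 3: 9 / 36, 4: 11 / 36, 5: 4 / 36},
    "language_english": {True: 33 / 36, False: 3 / 36},
    "conclusive_title": {True: 11 / 36, False: 25 / 36},
    "funding": {
        "non-profit": 15 / 36,
        "for-profit": 1 / 36,
        "both": 5 / 36,
        "not-reported": 15 / 36,
    },
    "n_affiliations_band": {"1": 15 / 36, "2": 10 / 36, "3+": 11 / 36},
    "impact_factor_band": {"0-2": 10 / 36, "2-4": 13 / 36, "4+": 13 / 36},
    "corr_gender": {"male": 24 / 36, "female": 12 / 36},
    "corr_country": {
        "belgium": 12 / 36,
        "italy": 5 / 36,
        "spain": 4 / 36,
        "usa": 3 / 36,
        "uk": 3 / 36,
        "germany": 2 / 36,
        "france": 2 / 36,
        "netherlands": 1 / 36,
        "norway": 1 / 36,
        "sweden": 1 / 36,
        "croatia": 1 / 36,
        "canada": 1 / 36,
    },
    "corr_affiliation": {
        "university": 27 / 36,
        "government": 2 / 36,
        "industry": 1 / 36,
        "other": 6 / 36,
    },
}


@dataclass
class SyntheticConfig:
    """Generative parameters for one synthetic citation network."""

    n_articles: int = 36
    year_range: tuple[int, int] = (2002, 2015)
    author_pool_size: int = 60
    authors_per_article: tuple[int, int] = (1, 8)  # uniform integer bounds
    group_structure: tuple[int, ...] | None = None  # author-community sizes
    community_article_probs: tuple[float, ...] | None = None
    attribute_marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    random_intercept_sd: float = 0.0
    doi_coverage: float = 1.0
    n_noise_references: tuple[int, int] = (5, 30)  # out-of-network refs per article
    seed: int = 0

    def validate(self) -> None:
        if self.n_articles < 2:
            raise ValueError("need at least 2 articles")
        if not 0.0 <= self.doi_coverage <= 1.0:
            raise ValueError("doi_coverage must lie in [0, 1]")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be non-negative")
        lo, hi = self.authors_per_article
        if lo < 1 or hi < lo:
            raise ValueError("authors_per_article bounds must satisfy 1 <= lo <= hi")
        if hi > self.author_pool_size:
            raise ValueError("authors_per_article exceeds the author pool")
        if self.group_structure is not None:
            if sum(self.group_structure) > self.author_pool_size:
                raise ValueError("group_structure exceeds the author pool")
            if self.community_article_probs is not None:
                if len(self.community_article_probs) != len(self.group_structure):
                    raise ValueError("one article probability per community required")
                if sum(self.community_article_probs) > 1 + 1e-9:
                    raise ValueError("community article probabilities exceed 1")
        for name, marg in self.attribute_marginals.items():
            total = sum(marg.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"marginal {name!r} sums to {total}, not 1")
        for key in self.coefficients:
            if key not in PATH_COVARIATES:
                raise ValueError(
                    f"unknown coefficient {key!r}; known: {sorted(PATH_COVARIATES)}"
                )


@dataclass
class GroundTruth:
    """What the generator knows: planted edges, predictors, memberships."""

    planted_edges: set[tuple[str, str]]  # (citing_id, cited_id)
    linear_predictors: dict[tuple[str, str], float]  # keyed (citing_id, cited_id)
    random_intercepts: dict[str, float]
    article_communities: dict[str, int | None]
    author_communities: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_edges": sorted(list(e) for e in self.planted_edges),
            "linear_predictors": {
                f"{k[0]}->{k[1]}": v for k, v in sorted(self.linear_predictors.items())
            },
            "random_intercepts": self.random_intercepts,
            "article_communities": self.article_communities,
            "author_communities": self.author_communities,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# Path covariates the realization model understands
# --------------------------------------------------------------------------


def _x_self_citation(cited: ArticleRecord, citing: ArticleRecord) -> float:
    return float(bool(set(cited.authors) & set(citing.authors)))


def _x_empirical(cited: ArticleRecord, citing: ArticleRecord) -> float:
    return float(cited.attributes.article_type == "empirical")


def _x_conclusion_positive(cited: ArticleRecord, citing: ArticleRecord) -> float:
    return float(cited.attributes.authors_conclusion == "positive")


def _x_time_to_citation(cited: ArticleRecord, citing: ArticleRecord) -> float:
    submission, _ = resolve_submission_date(citing)
    return (submission - effective_publication_date(cited)).n / 12.0


def _x_specificity(cited: ArticleRecord, citing: ArticleRecord) -> float:
    return float(cited.attributes.specificity)


def _x_concordant_conclusion(cited: ArticleRecord, citing: ArticleRecord) -> float:
    return float(
        cited.attributes.authors_conclusion == citing.attributes.authors_conclusion
    )


PATH_COVARIATES: dict[str, Callable[[ArticleRecord, ArticleRecord], float]] = {
    "self_citation": _x_self_citation,
    "empirical": _x_empirical,
    "conclusion_positive": _x_conclusion_positive,
    "time_to_citation": _x_time_to_citation,
    "specificity": _x_specificity,
    "concordant_conclusion": _x_concordant_conclusion,
}


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _surname(i: int) -> str:
    return "au" + _LETTERS[i // 26 % 26] + _LETTERS[i % 26]


def _author_key(i: int) -> str:
    return f"{_surname(i)},{_LETTERS[i % 26]}"


def _draw(rng: np.random.Generator, marginal: dict):
    cats = list(marginal)
    probs = np.array([marginal[c] for c in cats], dtype=float)
    return cats[rng.choice(len(cats), p=probs / probs.sum())]


def _draw_attributes(
    rng: np.random.Generator, marg: dict, n_authors: int
) -> CodedAttributes:
    article_type = _draw(rng, marg["article_type"])
    if article_type == "narrative":
        design = _draw(rng, marg["narrative_design"])
        sample_size = None
        dbc = "not-applicable"
        quality = "not-rated"
    else:
        design = _draw(rng, marg["empirical_design"])
        band = _draw(rng, marg["sample_size_band"])
        sample_size = int(
            rng.integers(1, 200) if band == "low"
            else rng.integers(200, 2000) if band == "medium"
            else rng.integers(2000, 20000)
        )
        dbc = _draw(rng, marg["data_based_conclusion"])
        quality = (
            _draw(rng, marg["study_quality"])
            if design == "cross-sectional"
            else "not-rated"
        )
    aff_band = _draw(rng, marg["n_affiliations_band"])
    n_aff = {"1": 1, "2": 2}.get(aff_band, int(rng.integers(3, 7)))
    if_band = _draw(rng, marg["impact_factor_band"])
    jif = float(
        rng.uniform(0.3, 2.0) if if_band == "0-2"
        else rng.uniform(2.0, 4.0) if if_band == "2-4"
        else rng.uniform(4.0, 12.0)
    )
    return CodedAttributes(
        authors_conclusion=_draw(rng, marg["authors_conclusion"]),
        data_based_conclusion=dbc,
        article_type=article_type,
        study_design=design,
        sample_size=sample_size,
        study_quality=quality,
        specificity=int(_draw(rng, marg["specificity"])),
        language_english=bool(_draw(rng, marg["language_english"])),
        conclusive_title=bool(_draw(rng, marg["conclusive_title"])),
        funding=_draw(rng, marg["funding"]),
        n_authors=n_authors,
        n_affiliations=n_aff,
        n_references=0,  # patched once the reference list is assembled
        journal_impact_factor=round(jif, 2),
        corr_gender=_draw(rng, marg["corr_gender"]),
        corr_country=_draw(rng, marg["corr_country"]),
        corr_affiliation=_draw(rng, marg["corr_affiliation"]),
    )


def generate_network(
    config: SyntheticConfig,
) -> tuple[list[ArticleRecord], dict[str, CodedAttributes], GroundTruth]:
    """Generate a full synthetic network with its ground truth.

    Returns ``(records, extraction_sheet, truth)``; records carry their
    attributes already merged, and the sheet dict holds the same attributes
    keyed by article id for writing to disk.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_dates = np.random.default_rng(streams[0])
    rng_authors = np.random.default_rng(streams[1])
    rng_attrs = np.random.default_rng(streams[2])
    rng_real = np.random.default_rng(streams[3])
    rng_refs = np.random.default_rng(streams[4])

    n = config.n_articles
    y0, y1 = config.year_range
    n_months = (y1 - y0 + 1) * 12

    # author communities
    author_communities: dict[str, int] = {}
    blocks: list[list[str]] = []
    cursor = 0
    if config.group_structure:
        for gi, size in enumerate(config.group_structure):
            block = [_author_key(cursor + j) for j in range(size)]
            for a in block:
                author_communities[a] = gi + 1
            blocks.append(block)
            cursor += size
    background = [
        _author_key(cursor + j)
        for j in range(config.author_pool_size - cursor)
    ]

    # article community assignment
    if config.group_structure:
        if config.community_article_probs is not None:
            probs = list(config.community_article_probs)
        else:
            share = 0.6 / len(config.group_structure)
            probs = [share] * len(config.group_structure)
        probs = probs + [1.0 - sum(probs)]
        communities = rng_authors.choice(
            len(probs), size=n, p=np.array(probs) / sum(probs)
        )
        communities = [int(c) + 1 if c < len(blocks) else None for c in communities]
    else:
        communities = [None] * n

    records: list[ArticleRecord] = []
    sheet: dict[str, CodedAttributes] = {}
    background_use: dict[str, int] = {}
    lo_a, hi_a = config.authors_per_article
    import pandas as pd

    for i in range(n):
        article_id = f"A{i + 1:03d}"
        month = int(rng_dates.integers(0, n_months))
        epub = pd.Period(year=y0 + month // 12, month=month % 12 + 1, freq="M")
        prnt = epub + int(rng_dates.integers(0, 4))
        has_print = rng_dates.random() < 0.9
        has_submission = rng_dates.random() < 0.7
        submission = epub - 7 if has_submission else None

        k = int(rng_authors.integers(lo_a, hi_a + 1))
        if communities[i]:
            pool = blocks[communities[i] - 1]
        else:
            # background teams are transient: an author outside the planted
            # communities appears in at most two articles, so no incidental
            # third research group can cross the publication threshold
            pool = [a for a in background if background_use.get(a, 0) < 2] or background
        k = min(k, len(pool))
        authors = [str(a) for a in rng_authors.choice(pool, size=k, replace=False)]
        if not communities[i]:
            for a in authors:
                background_use[a] = background_use.get(a, 0) + 1

        attrs = _draw_attributes(rng_attrs, config.attribute_marginals, n_authors=k)
        rec = ArticleRecord(
            article_id=article_id,
            title=f"Synthetic article {article_id}",
            authors=authors,
            doi=f"10.5555/synth.{article_id.lower()}",
            epub_date=epub,
            print_date=prnt if has_print else None,
            submission_date=submission,
            journal=f"Journal {i % 7 + 1}",
            volume=str(10 + i),
            first_page=str(100 + 10 * i),
        )
        rec.attributes = attrs
        records.append(rec)
        sheet[article_id] = attrs

    # realization model over potential paths
    b = {
        r.article_id: float(rng_real.normal(0.0, config.random_intercept_sd))
        for r in records
    }
    planted: set[tuple[str, str]] = set()
    predictors: dict[tuple[str, str], float] = {}
    for citing in records:
        for cited in records:
            if citing.article_id == cited.article_id:
                continue
            submission, _ = resolve_submission_date(citing)
            ttc = (submission - effective_publication_date(cited)).n
            if ttc <= 0:
                continue
            lp = config.intercept + b[citing.article_id]
            for key, coef in config.coefficients.items():
                lp += coef * PATH_COVARIATES[key](cited, citing)
            predictors[(citing.article_id, cited.article_id)] = lp
            if rng_real.random() < expit(lp):
                planted.add((citing.article_id, cited.article_id))

    # reference lists: planted citations (complete composite keys, DOIs at
    # the configured coverage) plus out-of-network noise references
    by_id = {r.article_id: r for r in records}
    lo_n, hi_n = config.n_noise_references
    noise_counter = 0
    for rec in records:
        refs: list[ReferenceEntry] = []
        cited_ids = sorted(c for (g, c) in planted if g == rec.article_id)
        for cid in cited_ids:
            cited = by_id[cid]
            surname, _, initial = cited.authors[0].partition(",")
            refs.append(
                ReferenceEntry(
                    first_author_surname=surname,
                    first_author_initial=initial,
                    year=record_match_year(cited),
                    journal=cited.journal,
                    volume=cited.volume,
                    first_page=cited.first_page,
                    doi=cited.doi if rng_refs.random() < config.doi_coverage else None,
                )
            )
        for _ in range(int(rng_refs.integers(lo_n, hi_n + 1))):
            noise_counter += 1
            refs.append(
                ReferenceEntry(
                    first_author_surname="ext" + _LETTERS[noise_counter % 26]
                    + _LETTERS[noise_counter // 26 % 26],
                    first_author_initial=_LETTERS[noise_counter % 26],
                    year=int(rng_refs.integers(1980, y1 + 1)),
                    journal="External Journal",
                    volume=str(900 + noise_counter),
                    first_page=str(5000 + noise_counter),
                    doi=None,
                )
            )
        rec.references = refs
        rec.attributes.n_references = len(refs)
        rec.validate()

    truth = GroundTruth(
        planted_edges=planted,
        linear_predictors=predictors,
        random_intercepts=b,
        article_communities={
            r.article_id: communities[i] for i, r in enumerate(records)
        },
        author_communities=author_communities,
    )
    return records, sheet, truth


def write_inputs(
    records: Sequence[ArticleRecord],
    sheet: dict[str, CodedAttributes],
    outdir: str | Path,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write generated inputs in the formats the record reader consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.tsv",
        "sheet": outdir / "extraction_sheet.csv",
    }
    write_records(records, paths["records"], format="tabular")
    write_extraction_sheet(sheet, paths["sheet"])
    if truth is not None:
        paths["truth"] = outdir / "ground_truth.json"
        truth.to_json(paths["truth"])
    return paths


def config_to_json(config: SyntheticConfig, path: str | Path) -> None:
    payload = asdict(config)
    payload["attribute_marginals"] = {
        k: {str(c): p for c, p in v.items()}
        for k, v in payload["attribute_marginals"].items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# Canonical fixtures
# --------------------------------------------------------------------------

#: 36-article fixture emulating the published network's scale: two planted
#: co-authorship communities (12/9/15 article split), attribute marginals
#: from the characteristics table, and an overall realized fraction near
#: one third.  Frozen seed — the fixture is a constant of the test suite.
PAPER_LIKE_CONFIG = SyntheticConfig(
    n_articles=36,
    year_range=(2002, 2015),
    author_pool_size=100,
    authors_per_article=(1, 8),
    group_structure=(6, 5),
    community_article_probs=(12 / 36, 9 / 36),
    coefficients={
        "self_citation": math.log(4.6),
        "empirical": math.log(4.2),
        "conclusion_positive": math.log(1.4),
    },
    intercept=-2.0,
    random_intercept_sd=0.5,
    doi_coverage=0.8,
    seed=170402,
)


def paper_like_fixture() -> tuple[list[ArticleRecord], dict[str, CodedAttributes]]:
    """The frozen 36-article synthetic network used throughout the tests."""
    records, sheet, _ = generate_network(PAPER_LIKE_CONFIG)
    return records, sheet


def recovery_config(
    seed: int,
    random_intercept_sd: float = 0.0,
    n_articles: int = 45,
    log_or: float = math.log(5.0),
) -> SyntheticConfig:
    """Config for self-citation parameter-recovery experiments (~1000 paths)."""
    return SyntheticConfig(
        n_articles=n_articles,
        year_range=(2000, 2015),
        author_pool_size=80,
        authors_per_article=(1, 6),
        group_structure=(8, 8),
        community_article_probs=(0.35, 0.35),
        coefficients={"self_citation": log_or},
        intercept=-1.2,
        random_intercept_sd=random_intercept_sd,
        doi_coverage=0.8,
        seed=seed,
    )
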