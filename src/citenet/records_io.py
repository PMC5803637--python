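"""Read, validate and merge bibliographic records and coded extraction sheets.

The unit of input is one *in-network article*: its bibliographic fields
(identifiers, author list, dates, journal, volume, first page, DOI) plus the
raw reference list as exported by a bibliographic database, and a manually
coded attribute sheet (study outcome, article type, sample size, quality,
specificity, funding, corresponding-author metadata, ...).

Dates are carried at year-month resolution and all date arithmetic is in
whole calendar months; `pandas.Period` with monthly frequency is the internal
representation.  Author identity uses a deterministic name key
``"surname,f"`` (lower-cased, diacritics folded to ASCII, single first
initial) because both reference matching and self-citation detection need an
exact, reproducible key.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

# --------------------------------------------------------------------------
# Closed vocabularies for the coded extraction sheet.  Unknown values fail
# fast rather than being coerced.
# --------------------------------------------------------------------------

AUTHORS_CONCLUSION = frozenset({"positive", "negative", "mixed"})
DATA_BASED_CONCLUSION = frozenset({"positive", "negative", "mixed", "not-applicable"})
ARTICLE_TYPE = frozenset({"narrative", "empirical"})
STUDY_DESIGN = frozenset(
    {
        "narrative-review",
        "commentary",
        "cohort",
        "cross-sectional",
        "pre-experimental",
        "multiple-designs",
        "ecological",
        "meta-analysis",
        "case-study",
    }
)
NARRATIVE_DESIGNS = frozenset({"narrative-review", "commentary"})
STUDY_QUALITY = frozenset({"good", "fair", "poor", "not-rated"})
FUNDING = frozenset({"non-profit", "for-profit", "both", "not-reported"})
CORR_GENDER = frozenset({"male", "female"})
CORR_AFFILIATION = frozenset({"university", "government", "industry", "other"})

#: columns required in a record table (tab-separated or CSV, one row/article)
RECORD_COLUMNS = (
    "article_id",
    "title",
    "authors",
    "doi",
    "epub_date",
    "print_date",
    "submission_date",
    "journal",
    "volume",
    "first_page",
    "cited_references",
)

#: columns required in the coded extraction sheet (CSV, one row/article)
SHEET_COLUMNS = (
    "article_id",
    "authors_conclusion",
    "data_based_conclusion",
    "article_type",
    "study_design",
    "sample_size",
    "study_quality",
    "specificity",
    "language_english",
    "conclusive_title",
    "funding",
    "n_authors",
    "n_affiliations",
    "n_references",
    "journal_impact_factor",
    "corr_gender",
    "corr_country",
    "corr_affiliation",
)

#: months from submission to publication used to impute missing submission
#: dates (the network-wide average turnaround).
SUBMISSION_LAG_MONTHS = 7

_NAME_KEY_RE = re.compile(r"^[a-z][a-z' \-]*,[a-z]$")


class RecordsError(ValueError):
    """Base class for record-table and extraction-sheet errors."""


class SchemaError(RecordsError):
    """A required column is missing from an input file."""


class RecordValidationError(RecordsError):
    """A record violates an invariant; the message names the article_id."""


class MergeError(RecordsError):
    """Record table and extraction sheet do not match one-to-one."""


class AmbiguityError(RecordsError):
    """Conflicting findings at the same validity rank."""


# --------------------------------------------------------------------------
# Normalization helpers
# --------------------------------------------------------------------------


def fold_ascii(text: str) -> str:
    """Fold diacritics to plain ASCII (``"Müller"`` -> ``"Muller"``)."""
    return unicodedata.normalize("NFKD", text).encode("ascii", "ignore").decode()


def normalize_author(name: str) -> str:
    """Build the deterministic author name key ``"surname,f"``.

    Accepts ``"Surname, First"`` / ``"Surname, F."`` forms, or a plain
    ``"First Surname"`` form (last token taken as the surname).
    """
    text = fold_ascii(name).strip().lower()
    if not text:
        raise RecordsError("empty author name")
    if "," in text:
        surname, _, rest = text.partition(",")
    else:
        tokens = text.split()
        surname = tokens[-1]
        rest = tokens[0] if len(tokens) > 1 else ""
    surname = re.sub(r"[^a-z' \-]", "", surname).strip()
    initial = next((ch for ch in rest if ch.isalpha()), "")
    if not surname or not initial:
        raise RecordsError(f"cannot normalize author name {name!r}")
    return f"{surname},{initial}"


def normalize_doi(doi: str | None) -> str | None:
    """Lower-case a DOI and strip resolver/``doi:`` prefixes; None stays None."""
    if doi is None:
        return None
    text = doi.strip().lower()
    for prefix in ("https://doi.org/", "http://doi.org/", "https://dx.doi.org/", "doi:"):
        if text.startswith(prefix):
            text = text[len(prefix):]
    return text or None


def parse_month(text: str | None) -> pd.Period | None:
    """Parse ``"YYYY-MM"`` into a monthly Period; blank/None -> None."""
    if text is None:
        return None
    if isinstance(text, pd.Period):
        return text.asfreq("M")
    text = str(text).strip()
    if not text:
        return None
    if not re.match(r"^\d{4}-\d{1,2}$", text):
        raise RecordsError(f"unparseable year-month date {text!r}")
    period = pd.Period(text, freq="M")
    if not 1 <= period.month <= 12:  # pragma: no cover - Period rejects these
        raise RecordsError(f"unparseable year-month date {text!r}")
    return period


def format_month(period: pd.Period | None) -> str:
    return "" if period is None else f"{period.year:04d}-{period.month:02d}"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceEntry:
    """One parsed entry of an article's reference list.

    Only the fields used by the two-tier matching algorithm are kept: the
    DOI (when the export carries one) and the five composite-key components
    — first author's surname and first initial, publication year, volume,
    and first page.
    """

    first_author_surname: str
    first_author_initial: str
    year: int
    journal: str | None = None
    volume: str | None = None
    first_page: str | None = None
    doi: str | None = None

    def __post_init__(self) -> None:
        if not self.first_author_surname:
            raise RecordsError("reference entry with empty surname")
        if not 1000 <= int(self.year) <= 9999:
            raise RecordsError(f"implausible reference year {self.year!r}")


@dataclass
class CodedAttributes:
    """Manually coded per-article attributes from the extraction sheet."""

    authors_conclusion: str
    data_based_conclusion: str
    article_type: str
    study_design: str
    sample_size: int | None
    study_quality: str
    specificity: int
    language_english: bool
    conclusive_title: bool
    funding: str
    n_authors: int
    n_affiliations: int
    n_references: int
    journal_impact_factor: float
    corr_gender: str
    corr_country: str
    corr_affiliation: str

    def validate(self, article_id: str = "?") -> None:
        def _check(value, vocab, name):
            if value not in vocab:
                raise RecordValidationError(
                    f"{article_id}: {name}={value!r} not in {sorted(vocab)}"
                )

        _check(self.authors_conclusion, AUTHORS_CONCLUSION, "authors_conclusion")
        _check(self.data_based_conclusion, DATA_BASED_CONCLUSION, "data_based_conclusion")
        _check(self.article_type, ARTICLE_TYPE, "article_type")
        _check(self.study_design, STUDY_DESIGN, "study_design")
        _check(self.study_quality, STUDY_QUALITY, "study_quality")
        _check(self.funding, FUNDING, "funding")
        _check(self.corr_gender, CORR_GENDER, "corr_gender")
        _check(self.corr_affiliation, CORR_AFFILIATION, "corr_affiliation")
        if self.specificity not in (1, 2, 3, 4, 5):
            raise RecordValidationError(
                f"{article_id}: specificity={self.specificity!r} outside 1-5"
            )
        if self.sample_size is not None and self.sample_size < 0:
            raise RecordValidationError(f"{article_id}: negative sample_size")
        if self.article_type == "narrative":
            if self.sample_size is not None:
                raise RecordValidationError(
                    f"{article_id}: narrative article with a sample size"
                )
            if self.data_based_conclusion != "not-applicable":
                raise RecordValidationError(
                    f"{article_id}: narrative article must code "
                    "data_based_conclusion=not-applicable"
                )
            if self.study_design not in NARRATIVE_DESIGNS:
                raise RecordValidationError(
                    f"{article_id}: narrative article with design {self.study_design!r}"
                )
        elif self.study_design in NARRATIVE_DESIGNS:
            raise RecordValidationError(
                f"{article_id}: empirical article with narrative design"
            )
        if self.study_design != "cross-sectional" and self.study_quality != "not-rated":
            raise RecordValidationError(
                f"{article_id}: study_quality rated for non-cross-sectional design"
            )
        if self.n_authors < 1 or self.n_affiliations < 1:
            raise RecordValidationError(f"{article_id}: author/affiliation counts < 1")
        if self.n_references < 0 or self.journal_impact_factor < 0:
            raise RecordValidationError(f"{article_id}: negative count attribute")


@dataclass
class ArticleRecord:
    """One in-network article: bibliographic fields plus coded attributes."""

    article_id: str
    title: str
    authors: list[str]
    doi: str | None
    epub_date: pd.Period | None
    print_date: pd.Period | None
    submission_date: pd.Period | None
    journal: str
    volume: str | None
    first_page: str | None
    references: list[ReferenceEntry] = field(default_factory=list)
    attributes: CodedAttributes | None = None

    def validate(self) -> None:
        if not self.article_id:
            raise RecordValidationError("record with empty article_id")
        if self.epub_date is None and self.print_date is None:
            raise RecordValidationError(
                f"{self.article_id}: neither epub_date nor print_date present"
            )
        if not self.authors:
            raise RecordValidationError(f"{self.article_id}: empty author list")
        for key in self.authors:
            if not _NAME_KEY_RE.match(key):
                raise RecordValidationError(
                    f"{self.article_id}: author key {key!r} violates the "
                    "normalization grammar 'surname,f'"
                )
        if self.attributes is not None:
            self.attributes.validate(self.article_id)


# --------------------------------------------------------------------------
# Reference-string parsing
#
# The cited-references cell holds ";"-separated strings of the form
#   "surname, initial, year, journal, Vvolume, Ppage, DOI doi"
# with trailing elements optional.
# --------------------------------------------------------------------------


def parse_reference(text: str) -> ReferenceEntry:
    parts = [p.strip() for p in text.split(",")]
    if len(parts) < 3:
        raise RecordsError(f"reference string too short: {text!r}")
    surname = fold_ascii(parts[0]).lower()
    initial = fold_ascii(parts[1]).lower()[:1]
    try:
        year = int(parts[2])
    except ValueError as exc:
        raise RecordsError(f"bad year in reference {text!r}") from exc
    journal = volume = page = doi = None
    for token in parts[3:]:
        if not token:
            continue
        if re.match(r"^V\S", token):
            volume = token[1:]
        elif re.match(r"^P\S", token):
            page = token[1:]
        elif token.upper().startswith("DOI "):
            doi = normalize_doi(token[4:])
        elif journal is None:
            journal = token
    return ReferenceEntry(
        first_author_surname=surname,
        first_author_initial=initial,
        year=year,
        journal=journal,
        volume=volume,
        first_page=page,
        doi=doi,
    )


def format_reference(ref: ReferenceEntry) -> str:
    parts = [ref.first_author_surname, ref.first_author_initial, str(ref.year)]
    if ref.journal:
        parts.append(ref.journal)
    if ref.volume:
        parts.append(f"V{ref.volume}")
    if ref.first_page:
        parts.append(f"P{ref.first_page}")
    if ref.doi:
        parts.append(f"DOI {ref.doi}")
    return ", ".join(parts)


# --------------------------------------------------------------------------
# Record-table I/O
# --------------------------------------------------------------------------


def _read_table(path: str | Path, fmt: str) -> pd.DataFrame:
    if fmt not in ("tabular", "csv"):
        raise RecordsError(f"unknown format {fmt!r} (use 'tabular' or 'csv')")
    sep = "\t" if fmt == "tabular" else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_records(path: str | Path, format: str = "tabular") -> list[ArticleRecord]:
    """Read a bibliographic record table into validated ArticleRecords."""
    frame = _read_table(path, format)
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"record table missing required column(s): {missing}")
    records: list[ArticleRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        article_id = row["article_id"].strip()
        if article_id in seen:
            raise RecordValidationError(f"duplicate article_id {article_id!r}")
        seen.add(article_id)
        try:
            epub = parse_month(row["epub_date"])
            prnt = parse_month(row["print_date"])
            subm = parse_month(row["submission_date"])
        except RecordsError as exc:
            raise RecordValidationError(f"{article_id}: {exc}") from exc
        authors = [
            normalize_author(a)
            for a in row["authors"].split(";")
            if a.strip()
        ]
        refs = [
            parse_reference(r)
            for r in row["cited_references"].split(";")
            if r.strip()
        ]
        record = ArticleRecord(
            article_id=article_id,
            title=row["title"],
            authors=authors,
            doi=normalize_doi(row["doi"]) if row["doi"].strip() else None,
            epub_date=epub,
            print_date=prnt,
            submission_date=subm,
            journal=row["journal"],
            volume=row["volume"].strip() or None,
            first_page=row["first_page"].strip() or None,
            references=refs,
        )
        record.validate()
        records.append(record)
    return records


def write_records(
    records: Iterable[ArticleRecord], path: str | Path, format: str = "tabular"
) -> None:
    """Write records in the same layout `read_records` consumes (round-trip)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "article_id": rec.article_id,
                "title": rec.title,
                "authors": "; ".join(rec.authors),
                "doi": rec.doi or "",
                "epub_date": format_month(rec.epub_date),
                "print_date": format_month(rec.print_date),
                "submission_date": format_month(rec.submission_date),
                "journal": rec.journal,
                "volume": rec.volume or "",
                "first_page": rec.first_page or "",
                "cited_references": "; ".join(format_reference(r) for r in rec.references),
            }
        )
    sep = "\t" if format == "tabular" else ","
    pd.DataFrame(rows, columns=list(RECORD_COLUMNS)).to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------------
# Extraction-sheet I/O and merge
# --------------------------------------------------------------------------

_TRUTHY = {"yes", "true", "1"}
_FALSY = {"no", "false", "0"}


def _parse_flag(value: str, name: str, article_id: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise RecordValidationError(f"{article_id}: {name}={value!r} is not yes/no")


def read_extraction_sheet(path: str | Path) -> dict[str, CodedAttributes]:
    """Read the coded extraction sheet; returns attributes keyed by article_id."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SHEET_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"extraction sheet missing required column(s): {missing}")
    out: dict[str, CodedAttributes] = {}
    for _, row in frame.iterrows():
        aid = row["article_id"].strip()
        if aid in out:
            raise RecordValidationError(f"duplicate article_id {aid!r} in sheet")
        sample = row["sample_size"].strip()
        attrs = CodedAttributes(
            authors_conclusion=row["authors_conclusion"].strip(),
            data_based_conclusion=row["data_based_conclusion"].strip(),
            article_type=row["article_type"].strip(),
            study_design=row["study_design"].strip(),
            sample_size=int(sample) if sample else None,
            study_quality=row["study_quality"].strip(),
            specificity=int(row["specificity"]),
            language_english=_parse_flag(row["language_english"], "language_english", aid),
            conclusive_title=_parse_flag(row["conclusive_title"], "conclusive_title", aid),
            funding=row["funding"].strip(),
            n_authors=int(row["n_authors"]),
            n_affiliations=int(row["n_affiliations"]),
            n_references=int(row["n_references"]),
            journal_impact_factor=float(row["journal_impact_factor"]),
            corr_gender=row["corr_gender"].strip(),
            corr_country=row["corr_country"].strip().lower(),
            corr_affiliation=row["corr_affiliation"].strip(),
        )
        attrs.validate(aid)
        out[aid] = attrs
    return out


def write_extraction_sheet(
    attributes: dict[str, CodedAttributes], path: str | Path
) -> None:
    rows = []
    for aid, a in attributes.items():
        rows.append(
            {
                "article_id": aid,
                "authors_conclusion": a.authors_conclusion,
                "data_based_conclusion": a.data_based_conclusion,
                "article_type": a.article_type,
                "study_design": a.study_design,
                "sample_size": "" if a.sample_size is None else a.sample_size,
                "study_quality": a.study_quality,
                "specificity": a.specificity,
                "language_english": "yes" if a.language_english else "no",
                "conclusive_title": "yes" if a.conclusive_title else "no",
                "funding": a.funding,
                "n_authors": a.n_authors,
                "n_affiliations": a.n_affiliations,
                "n_references": a.n_references,
                "journal_impact_factor": a.journal_impact_factor,
                "corr_gender": a.corr_gender,
                "corr_country": a.corr_country,
                "corr_affiliation": a.corr_affiliation,
            }
        )
    pd.DataFrame(rows, columns=list(SHEET_COLUMNS)).to_csv(path, index=False)


def merge_extraction_sheet(
    records: Sequence[ArticleRecord], sheet: str | Path
) -> list[ArticleRecord]:
    """One-to-one merge of the coded sheet onto the record collection."""
    attributes = read_extraction_sheet(sheet)
    record_ids = {r.article_id for r in records}
    orphans_sheet = sorted(set(attributes) - record_ids)
    orphans_records = sorted(record_ids - set(attributes))
    if orphans_sheet or orphans_records:
        raise MergeError(
            "record table and extraction sheet do not match one-to-one; "
            f"sheet-only ids: {orphans_sheet}; record-only ids: {orphans_records}"
        )
    return [replace(rec, attributes=attributes[rec.article_id]) for rec in records]


# --------------------------------------------------------------------------
# Date resolution
# --------------------------------------------------------------------------


def effective_publication_date(record: ArticleRecord) -> pd.Period:
    """Earlier of the electronic and print publication dates."""
    dates = [d for d in (record.epub_date, record.print_date) if d is not None]
    if not dates:
        raise RecordValidationError(f"{record.article_id}: no publication date")
    return min(dates)


def resolve_submission_date(record: ArticleRecord) -> tuple[pd.Period, bool]:
    """Recorded submission date, or publication minus the 7-month average lag.

    Returns ``(date, imputed)`` where *imputed* is True when the date was
    estimated from the publication date.
    """
    if record.submission_date is not None:
        return record.submission_date, False
    return effective_publication_date(record) - SUBMISSION_LAG_MONTHS, True


# --------------------------------------------------------------------------
# Study-outcome coding
# --------------------------------------------------------------------------

#: asthma-assessment validity ranks, in decreasing validity
VALIDITY_RANKS = {
    1: "physician's assessment",
    2: "self-assessment",
    3: "asthma symptoms",
    4: "lung tests",
    5: "blood tests",
}


def resolve_data_based_conclusion(
    findings: Sequence[tuple[int, str]]
) -> str:
    """Resolve contradictory findings by the most valid asthma assessment.

    *findings* is a list of ``(validity_rank, direction)`` pairs where rank 1
    is the most valid assessment (physician's diagnosis) and rank 5 the least
    (blood tests); direction is ``"positive"`` when a statistically
    significant positive association was reported, else ``"negative"``.
    The direction of the lowest-ranked (most valid) finding wins.
    """
    if not findings:
        raise RecordsError("no findings to resolve")
    for rank, direction in findings:
        if rank not in VALIDITY_RANKS:
            raise RecordsError(f"validity rank {rank!r} outside 1-5")
        if direction not in ("positive", "negative"):
            raise RecordsError(f"finding direction {direction!r} invalid")
    best = min(rank for rank, _ in findings)
    directions = {d for r, d in findings if r == best}
    if len(directions) > 1:
        raise AmbiguityError(
            f"conflicting directions at validity rank {best}: cannot resolve"
        )
    return directions.pop()
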