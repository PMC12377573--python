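"""Coder output and rating ingestion, validation and filtering.

One *annotation record* is the set of concept codes (a "code set") that one
coder — human, software, or the gold-standard panel — assigned to one
free-text diagnosis line.  The gold standard is represented as an ordinary
coder (conventionally ``GS``) so every comparison uses the same machinery.

Before any comparison, code sets are restricted to the Clinical-Finding-like
subhierarchy (qualifier, procedure and other out-of-hierarchy codes are
removed), and items where either compared coder is left with an empty set are
excluded from that pairwise comparison.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

SINGLE_FINDING = "single-finding"
MULTI_FINDING = "multi-finding"


class AnnotationError(Exception):
    """Base class for annotation ingestion failures."""


class AnnotationFormatError(AnnotationError):
    """A row of an annotation or rating file could not be parsed."""


class DuplicateRecordError(AnnotationError):
    """Two rows share the same (item_id, coder_id)."""


class Rating(enum.Enum):
    """Three-level qualitative judgement of how well a code set captures intent."""

    GOOD = "good"
    ACCEPTABLE = "acceptable"
    NOT_ACCEPTABLE = "not_acceptable"

    @property
    def label(self) -> str:
        return {
            Rating.GOOD: "Good",
            Rating.ACCEPTABLE: "Acceptable",
            Rating.NOT_ACCEPTABLE: "Not acceptable",
        }[self]


RATING_ORDER = (Rating.GOOD, Rating.ACCEPTABLE, Rating.NOT_ACCEPTABLE)


@dataclass(frozen=True)
class AnnotationRecord:
    """One coder's code set for one free-text diagnosis line."""

    item_id: str
    coder_id: str
    code_set: frozenset[str]
    text: str = ""


@dataclass(frozen=True)
class QualitativeRating:
    item_id: str
    coder_id: str
    rating: Rating


# -- readers ---------------------------------------------------------------


def _parse_codes(cell: str, lineno: int) -> frozenset[str]:
    tokens = [t.strip() for t in cell.split("|")] if cell.strip() else []
    codes = set()
    for tok in tokens:
        if not tok:
            continue
        if not tok.isdigit():
            raise AnnotationFormatError(
                f"line {lineno}: malformed code token {tok!r} (expected digits)"
            )
        codes.add(tok)
    return frozenset(codes)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read annotation records from a CSV with header item_id,coder_id,text,codes.

    The ``codes`` cell holds pipe-separated concept codes; an empty cell
    yields an empty code set (kept, and flagged invalid at comparison time).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"item_id", "coder_id", "codes"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationFormatError(f"{path}: missing columns {sorted(missing)}")
    records: list[AnnotationRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        key = (row.item_id, row.coder_id)
        if key in seen:
            raise DuplicateRecordError(
                f"{path}, line {lineno}: duplicate record for item "
                f"{row.item_id!r}, coder {row.coder_id!r}"
            )
        seen.add(key)
        records.append(
            AnnotationRecord(
                item_id=row.item_id,
                coder_id=row.coder_id,
                text=getattr(row, "text", ""),
                code_set=_parse_codes(row.codes, lineno),
            )
        )
    return records


def read_ratings(path: str | Path) -> list[QualitativeRating]:
    """Read qualitative ratings from a CSV with header item_id,coder_id,rating.

    Ratings are spelled ``good``, ``acceptable`` or ``not_acceptable``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"item_id", "coder_id", "rating"} - set(df.columns)
    if missing:
        raise AnnotationFormatError(f"{path}: missing columns {sorted(missing)}")
    ratings = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rating = Rating(row.rating.strip().lower())
        except ValueError:
            raise AnnotationFormatError(
                f"{path}, line {i + 2}: unknown rating label {row.rating!r}"
            ) from None
        ratings.append(
            QualitativeRating(item_id=row.item_id, coder_id=row.coder_id, rating=rating)
        )
    return ratings


def read_blocklist(path: str | Path) -> set[str]:
    """Read excluded item_ids, one per line; blank lines and # comments ignored."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def apply_blocklist(
    records: Iterable[AnnotationRecord], blocked: set[str]
) -> list[AnnotationRecord]:
    return [r for r in records if r.item_id not in blocked]


# -- filtering and validation ----------------------------------------------


def filter_clinical_findings(
    record: AnnotationRecord,
    graph: OntologyGraph,
    finding_root: str,
    strict: bool = False,
) -> AnnotationRecord:
    """Restrict a record's code set to descendants of ``finding_root``.

    Codes outside the finding subhierarchy (qualifiers, procedures, ...) are
    removed.  Codes absent from the loaded ontology altogether are dropped
    with a warning — real annotation files reference retired codes — unless
    ``strict``, in which case they raise.
    """
    findings = graph.descendants_of(finding_root)
    unknown = {c for c in record.code_set if c not in graph}
    if unknown:
        msg = (
            f"item {record.item_id!r} coder {record.coder_id!r}: codes "
            f"{sorted(unknown)} absent from ontology"
        )
        if strict:
            raise AnnotationError(msg)
        logger.warning("%s; dropped", msg)
    return replace(record, code_set=frozenset(record.code_set & findings))


def filter_records(
    records: Iterable[AnnotationRecord],
    graph: OntologyGraph,
    finding_root: str,
    strict: bool = False,
) -> list[AnnotationRecord]:
    """Apply :func:`filter_clinical_findings` to every record."""
    return [filter_clinical_findings(r, graph, finding_root, strict) for r in records]


@dataclass
class PairExclusions:
    """Usable item ids for one coder pair plus exclusion counts by reason."""

    item_ids: list[str]
    excluded: dict[str, int] = field(default_factory=dict)


def exclude_invalid_pairs(
    records_x: Iterable[AnnotationRecord],
    records_y: Iterable[AnnotationRecord],
) -> PairExclusions:
    """Item ids where *both* coders provided a non-empty (valid) code set.

    Items covered by only one coder, or where either filtered code set is
    empty, are excluded; counts per reason are reported.
    """
    by_x = {r.item_id: r for r in records_x}
    by_y = {r.item_id: r for r in records_y}
    usable: list[str] = []
    excluded = {"only_one_coder": 0, "invalid_code_set": 0}
    for item in sorted(by_x.keys() | by_y.keys()):
        rx, ry = by_x.get(item), by_y.get(item)
        if rx is None or ry is None:
            excluded["only_one_coder"] += 1
        elif not rx.code_set or not ry.code_set:
            excluded["invalid_code_set"] += 1
        else:
            usable.append(item)
    return PairExclusions(item_ids=usable, excluded=excluded)


def classify_arity(set_x: frozenset[str], set_y: frozenset[str]) -> str:
    """Stratify a coder pair's item: single-finding iff both sets are singletons."""
    if not set_x or not set_y:
        raise ValueError("classify_arity requires two non-empty code sets")
    return SINGLE_FINDING if len(set_x) == 1 and len(set_y) == 1 else MULTI_FINDING


def records_by_coder(
    records: Iterable[AnnotationRecord],
) -> dict[str, list[AnnotationRecord]]:
    out: dict[str, list[AnnotationRecord]] = {}
    for r in records:
        out.setdefault(r.coder_id, []).append(r)
    return out


def write_annotations(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    """Write records in the same CSV layout :func:`read_annotations` consumes."""
    df = pd.DataFrame(
        {
            "item_id": [r.item_id for r in records],
            "coder_id": [r.coder_id for r in records],
            "text": [r.text for r in records],
            "codes": ["|".join(sorted(r.code_set)) for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_ratings(ratings: Sequence[QualitativeRating], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "item_id": [r.item_id for r in ratings],
            "coder_id": [r.coder_id for r in ratings],
            "rating": [r.rating.value for r in ratings],
        }
    )
    df.to_csv(path, index=False)
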