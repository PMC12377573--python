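"""Stratified agreement tables, micro-averages, and rating concordance.

Every comparison is between two coders (one of which may be a gold-standard
reference) over the items where both provided a valid code set.  Items are
stratified into single-finding (both code sets are singletons) and
multi-finding, and each table reports cumulative distance-band percentages
exact / <=1 / <=2 / <=3 on the 0-100 scale, so percentages are non-decreasing
left to right within a row.  Items with an unreachable distance fall only in
the >3 residual (100 - pct_le3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations import (
    MULTI_FINDING,
    RATING_ORDER,
    SINGLE_FINDING,
    AnnotationRecord,
    PairExclusions,
    QualitativeRating,
    Rating,
    classify_arity,
    exclude_invalid_pairs,
)
from .metrics import code_set_distance, distance_band
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

STRATA = ("All", SINGLE_FINDING, MULTI_FINDING)

PCT_COLUMNS = ("pct_exact", "pct_le1", "pct_le2", "pct_le3")


class EmptyComparisonError(Exception):
    """Two coders share no usable items."""


@dataclass(frozen=True)
class ItemComparison:
    """Distance outcome for one item between one coder pair."""

    item_id: str
    coder_x: str
    coder_y: str
    n_x: int
    n_y: int
    stratum: str
    value: float  # average-minimum distance, may be inf
    band: str
    exact: bool


@dataclass(frozen=True)
class AgreementRow:
    """One stratum's cumulative band percentages (0-100; NaN when n = 0)."""

    stratum: str
    n_items: int
    pct_exact: float
    pct_le1: float
    pct_le2: float
    pct_le3: float


@dataclass
class AgreementTable:
    label: str
    rows: list[AgreementRow]
    exclusions: dict[str, int]

    def row(self, stratum: str) -> AgreementRow:
        for r in self.rows:
            if r.stratum == stratum:
                return r
        raise KeyError(stratum)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stratum": r.stratum,
                    "n_items": r.n_items,
                    "pct_exact": r.pct_exact,
                    "pct_le1": r.pct_le1,
                    "pct_le2": r.pct_le2,
                    "pct_le3": r.pct_le3,
                }
                for r in self.rows
            ]
        )


def compare_coders(
    records: Iterable[AnnotationRecord],
    coder_x: str,
    coder_y: str,
    graph: OntologyGraph,
    direction: str = "symmetric",
) -> tuple[list[ItemComparison], PairExclusions]:
    """Per-item distance outcomes for one coder pair over their usable items.

    ``records`` must already be Clinical-Finding filtered; items where either
    coder's set is empty or missing are excluded (counts reported).
    """
    rx = [r for r in records if r.coder_id == coder_x]
    ry = [r for r in records if r.coder_id == coder_y]
    pairs = exclude_invalid_pairs(rx, ry)
    by_x = {r.item_id: r for r in rx}
    by_y = {r.item_id: r for r in ry}
    comparisons = []
    for item in pairs.item_ids:
        sx, sy = by_x[item].code_set, by_y[item].code_set
        result = code_set_distance(sx, sy, graph, direction=direction)
        comparisons.append(
            ItemComparison(
                item_id=item,
                coder_x=coder_x,
                coder_y=coder_y,
                n_x=len(sx),
                n_y=len(sy),
                stratum=classify_arity(sx, sy),
                value=result.value,
                band=distance_band(result),
                exact=result.exact_match,
            )
        )
    return comparisons, pairs


def _tabulate(
    comparisons: Sequence[ItemComparison],
    label: str,
    exclusions: dict[str, int],
) -> AgreementTable:
    rows = []
    for stratum in STRATA:
        subset = (
            comparisons
            if stratum == "All"
            else [c for c in comparisons if c.stratum == stratum]
        )
        n = len(subset)
        if n == 0:
            rows.append(
                AgreementRow(stratum, 0, math.nan, math.nan, math.nan, math.nan)
            )
            continue
        pct = lambda k: 100.0 * k / n  # noqa: E731
        rows.append(
            AgreementRow(
                stratum=stratum,
                n_items=n,
                pct_exact=pct(sum(c.exact for c in subset)),
                pct_le1=pct(sum(c.value <= 1 for c in subset)),
                pct_le2=pct(sum(c.value <= 2 for c in subset)),
                pct_le3=pct(sum(c.value <= 3 for c in subset)),
            )
        )
    return AgreementTable(label=label, rows=rows, exclusions=exclusions)


def pairwise_agreement(
    records: Iterable[AnnotationRecord],
    coder_x: str,
    coder_y: str,
    graph: OntologyGraph,
    direction: str = "symmetric",
) -> AgreementTable:
    """Stratified cumulative band percentages for one coder pair."""
    comparisons, pairs = compare_coders(records, coder_x, coder_y, graph, direction)
    return _tabulate(comparisons, f"{coder_x} vs {coder_y}", pairs.excluded)


def micro_average(
    records: Iterable[AnnotationRecord],
    coder_ids: Sequence[str],
    reference: str,
    graph: OntologyGraph,
    direction: str = "symmetric",
) -> AgreementTable:
    """Micro-averaged agreement of several coders against one reference.

    Per-item outcomes are pooled across all (coder, item) comparisons before
    percentages are computed — count-level pooling, not a mean of per-coder
    percentages — so coders with more usable items carry more weight.
    """
    records = list(records)
    pooled: list[ItemComparison] = []
    excluded: dict[str, int] = {}
    for coder in coder_ids:
        comparisons, pairs = compare_coders(records, coder, reference, graph, direction)
        pooled.extend(comparisons)
        for reason, k in pairs.excluded.items():
            excluded[reason] = excluded.get(reason, 0) + k
    label = f"micro-average {'/'.join(coder_ids)} vs {reference}"
    return _tabulate(pooled, label, excluded)


# -- qualitative ratings -----------------------------------------------------


def qualitative_summary(
    ratings: Iterable[QualitativeRating], coder_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-coder percentages of Good / Acceptable / cumulative / Not acceptable.

    Cumulative is Good + Acceptable.  Coders with no rated items get an NaN
    row with n = 0.
    """
    by_coder: dict[str, list[Rating]] = {c: [] for c in coder_ids}
    for r in ratings:
        if r.coder_id in by_coder:
            by_coder[r.coder_id].append(r.rating)
    rows = []
    for coder in coder_ids:
        rated = by_coder[coder]
        n = len(rated)
        if n == 0:
            rows.append(
                {
                    "coder": coder,
                    "n_items": 0,
                    "pct_good": math.nan,
                    "pct_acceptable": math.nan,
                    "pct_good_or_acceptable": math.nan,
                    "pct_not_acceptable": math.nan,
                }
            )
            continue
        good = 100.0 * sum(r is Rating.GOOD for r in rated) / n
        acc = 100.0 * sum(r is Rating.ACCEPTABLE for r in rated) / n
        not_acc = 100.0 * sum(r is Rating.NOT_ACCEPTABLE for r in rated) / n
        rows.append(
            {
                "coder": coder,
                "n_items": n,
                "pct_good": good,
                "pct_acceptable": acc,
                "pct_good_or_acceptable": good + acc,
                "pct_not_acceptable": not_acc,
            }
        )
    return pd.DataFrame(rows)


def distance_vs_rating(
    records: Iterable[AnnotationRecord],
    ratings: Iterable[QualitativeRating],
    reference: str,
    graph: OntologyGraph,
    direction: str = "symmetric",
) -> pd.DataFrame:
    """Concordance between graph distance to the reference and panel ratings.

    Each (coder, item) pair with both a usable distance to the reference and
    a rating is one observation; coders are pooled.  Rows are the three
    rating levels, columns the cumulative band percentages, so a monotone
    association shows as higher exact/<=k percentages for better ratings.
    """
    records = list(records)
    rated = {
        (r.coder_id, r.item_id): r.rating
        for r in ratings
        if r.coder_id != reference
    }
    coders = sorted({c for c, _ in rated})
    outcomes: dict[Rating, list[ItemComparison]] = {lvl: [] for lvl in RATING_ORDER}
    n_missing = 0
    for coder in coders:
        comparisons, _ = compare_coders(records, coder, reference, graph, direction)
        by_item = {c.item_id: c for c in comparisons}
        for (rc, item), rating in rated.items():
            if rc != coder:
                continue
            comp = by_item.get(item)
            if comp is None:
                n_missing += 1
                continue
            outcomes[rating].append(comp)
    if n_missing:
        logger.info(
            "distance_vs_rating: %d rated (coder, item) pairs had no usable "
            "distance to %s and were excluded",
            n_missing,
            reference,
        )
    rows = []
    for level in RATING_ORDER:
        subset = outcomes[level]
        n = len(subset)
        row: dict[str, object] = {"rating": level.label, "n_items": n}
        if n == 0:
            row.update({c: math.nan for c in PCT_COLUMNS})
            row["mean_distance"] = math.nan
        else:
            row["pct_exact"] = 100.0 * sum(c.exact for c in subset) / n
            row["pct_le1"] = 100.0 * sum(c.value <= 1 for c in subset) / n
            row["pct_le2"] = 100.0 * sum(c.value <= 2 for c in subset) / n
            row["pct_le3"] = 100.0 * sum(c.value <= 3 for c in subset) / n
            finite = [c.value for c in subset if math.isfinite(c.value)]
            row["mean_distance"] = (
                sum(finite) / len(finite) if finite else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


# -- cross-coder concordance -------------------------------------------------


def cross_coder_concordance(
    records: Iterable[AnnotationRecord],
    coder_x: str,
    coder_y: str,
    reference: str,
    graph: OntologyGraph,
    ratings: Iterable[QualitativeRating] | None = None,
    direction: str = "symmetric",
) -> pd.DataFrame:
    """Contingency of two coders' outcomes against the same reference.

    Answers whether the same items are "easy" or "difficult" for both coders.
    Without ratings the table is a 2x2 of exact vs not-exact matches to the
    reference; with ratings it is a rating-level x rating-level table.  Rows
    are coder_x outcomes, columns coder_y outcomes, with Total margins.
    """
    records = list(records)
    cx, _ = compare_coders(records, coder_x, reference, graph, direction)
    cy, _ = compare_coders(records, coder_y, reference, graph, direction)
    by_x = {c.item_id: c for c in cx}
    by_y = {c.item_id: c for c in cy}
    shared = sorted(by_x.keys() & by_y.keys())
    if ratings is not None:
        rmap: dict[tuple[str, str], Rating] = {
            (r.coder_id, r.item_id): r.rating for r in ratings
        }
        labels = [lvl.label for lvl in RATING_ORDER]
        outcome_x = {
            i: rmap[(coder_x, i)].label for i in shared if (coder_x, i) in rmap
        }
        outcome_y = {
            i: rmap[(coder_y, i)].label for i in shared if (coder_y, i) in rmap
        }
        shared = [i for i in shared if i in outcome_x and i in outcome_y]
    else:
        labels = ["exact", "not exact"]
        outcome_x = {i: "exact" if by_x[i].exact else "not exact" for i in shared}
        outcome_y = {i: "exact" if by_y[i].exact else "not exact" for i in shared}
    if not shared:
        raise EmptyComparisonError(
            f"coders {coder_x!r} and {coder_y!r} share no usable items "
            f"against {reference!r}"
        )
    table = pd.DataFrame(0, index=labels, columns=labels)
    for item in shared:
        table.loc[outcome_x[item], outcome_y[item]] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    table.index.name = coder_x
    table.columns.name = coder_y
    return table
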