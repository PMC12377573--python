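"""Set-to-set ontology distance and distance-band classification.

The core similarity between two code sets is the *average minimum distance*:
for every code in either set, take the shortest-path distance to its closest
code in the opposite set, and average those minima over all |X| + |Y| codes.
A code with an exact counterpart in the other set contributes 0.  The metric
deliberately pairs each code with its nearest counterpart rather than
penalising the number of distinct findings an item describes.

Distances are banded as exact / <=1 / <=2 / <=3 / >3; band percentages are
reported cumulatively (an exact match also counts within <=1, <=2 and <=3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .ontology import UNREACHABLE, OntologyGraph

EXACT = "exact"
LE1 = "le1"
LE2 = "le2"
LE3 = "le3"
GT3 = "gt3"

#: Band labels in increasing-distance order.
BANDS = (EXACT, LE1, LE2, LE3, GT3)

#: Supported symmetrisation modes for :func:`code_set_distance`.
DIRECTIONS = ("symmetric", "x_to_y")


@dataclass(frozen=True)
class SetDistanceResult:
    """Average-minimum distance between two code sets.

    Attributes
    ----------
    value
        The averaged per-code minima; ``math.inf`` when any code has no
        finite path to the opposite set.
    per_code_minima
        ``{"x": {code: min distance to set_y}, "y": {code: min distance to
        set_x}}`` (the ``"y"`` side is empty in ``x_to_y`` mode).
    exact_match
        True iff the two sets are identical (set identity, not value == 0,
        to stay robust on pathological graphs).
    """

    value: float
    per_code_minima: dict[str, dict[str, float]]
    exact_match: bool


def _minima(
    sources: frozenset[str], targets: frozenset[str], graph: OntologyGraph
) -> dict[str, float]:
    out: dict[str, float] = {}
    for code in sources:
        dist = graph.distances_from(code)
        out[code] = min(dist.get(t, UNREACHABLE) for t in targets)
    return out


def code_set_distance(
    set_x: frozenset[str] | set[str],
    set_y: frozenset[str] | set[str],
    graph: OntologyGraph,
    direction: str = "symmetric",
) -> SetDistanceResult:
    """Average minimum shortest-path distance between two code sets.

    In the default ``symmetric`` mode the minima of both directions (each x
    against set_y, each y against set_x) are pooled before averaging, so both
    over-coding and under-coding raise the distance.  ``x_to_y`` averages the
    x-side minima only.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    set_x, set_y = frozenset(set_x), frozenset(set_y)
    if not set_x or not set_y:
        raise ValueError("code_set_distance requires two non-empty code sets")
    minima_x = _minima(set_x, set_y, graph)
    minima_y = _minima(set_y, set_x, graph) if direction == "symmetric" else {}
    values = list(minima_x.values()) + list(minima_y.values())
    value = UNREACHABLE if any(math.isinf(v) for v in values) else sum(values) / len(values)
    return SetDistanceResult(
        value=value,
        per_code_minima={"x": minima_x, "y": minima_y},
        exact_match=set_x == set_y,
    )


def distance_band(result: SetDistanceResult) -> str:
    """Classify a set-distance result into exact / <=1 / <=2 / <=3 / >3."""
    if result.exact_match:
        return EXACT
    v = result.value
    if math.isinf(v):
        return GT3
    if v <= 1:
        return LE1
    if v <= 2:
        return LE2
    if v <= 3:
        return LE3
    return GT3
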