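"""Synthetic ontologies, gold standards, simulated coders and ratings.

Real clinical-coding studies hinge on a licensed terminology and on
confidential annotation data, neither of which can ship with an evaluation
toolkit.  This module generates inputs with the same statistical structure so
every analysis stage is exercisable end to end:

* a single-rooted DAG of coded concepts standing in for a Clinical-Finding
  subhierarchy;
* a gold standard whose items are mostly single-finding, with a configurable
  multi-finding fraction (default 1/8, i.e. seven single-finding items per
  multi-finding one);
* coders that deviate from gold by exact reproduction, ancestor/descendant
  drift along is-a edges, omission, spurious addition, or outright invalid
  (empty) code sets;
* panel-style ratings whose Good/Acceptable/Not-acceptable probabilities
  depend monotonically on the realised distance to gold.

All generators are bit-reproducible given (parameters, seed); one study-level
seed fans out to fixed per-component substreams, so adding a coder never
perturbs the gold standard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotations import (
    AnnotationRecord,
    QualitativeRating,
    Rating,
    write_annotations,
    write_ratings,
)
from .ontology import OntologyGraph

GOLD_CODER = "GS"


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    """Independent, order-stable substream of a study-level seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


@dataclass(frozen=True)
class CoderErrorModel:
    """Probabilities governing how a simulated coder deviates from gold.

    Parameters
    ----------
    p_exact
        Probability each gold code is reproduced verbatim.
    drift_geom
        When exact reproduction fails, the code is replaced by the endpoint
        of a random walk over undirected is-a edges; the walk continues with
        this probability after each step (geometric length >= 1).  The
        endpoint is resampled if it coincides with the original code, so a
        drifted code is always a genuine deviation.
    p_omit
        Probability a code is dropped; applied only to multi-code sets and
        never allowed to empty the set.
    p_add
        Probability a spurious code, uniform over the finding subhierarchy,
        is appended to the set.
    p_invalid
        Probability the whole item gets an empty (invalid) code set.
    """

    p_exact: float = 1.0
    drift_geom: float = 0.0
    p_omit: float = 0.0
    p_add: float = 0.0
    p_invalid: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_exact", "drift_geom", "p_omit", "p_add", "p_invalid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class RatingModel:
    """Distance-conditioned distribution over the three rating levels.

    A cumulative-logit model: P(Good) = sigmoid(c_good - slope * d) and
    P(Good or Acceptable) = sigmoid(c_acceptable - slope * d) with
    c_acceptable > c_good, so with positive slope the probability of a better
    rating decreases monotonically with distance.  Unreachable distances are
    treated as ``unreachable_distance`` edges.
    """

    c_good: float = 2.0
    c_acceptable: float = 4.5
    slope: float = 1.2
    unreachable_distance: float = 10.0

    def __post_init__(self) -> None:
        if self.c_acceptable <= self.c_good:
            raise ValueError("c_acceptable must exceed c_good")

    def probabilities(self, distance: float) -> tuple[float, float, float]:
        """(P(Good), P(Acceptable), P(Not acceptable)) at a given distance."""
        d = self.unreachable_distance if math.isinf(distance) else distance
        p_good = _sigmoid(self.c_good - self.slope * d)
        p_cum = _sigmoid(self.c_acceptable - self.slope * d)
        return p_good, p_cum - p_good, 1.0 - p_cum

    @classmethod
    def always(cls, rating: Rating) -> "DegenerateRatingModel":
        return DegenerateRatingModel(rating=rating)

    @classmethod
    def good_iff_exact(cls) -> "StepRatingModel":
        return StepRatingModel()


@dataclass(frozen=True)
class DegenerateRatingModel(RatingModel):
    """Always emits the same rating, regardless of distance."""

    rating: Rating = Rating.GOOD

    def probabilities(self, distance: float) -> tuple[float, float, float]:
        return tuple(1.0 if lvl is self.rating else 0.0 for lvl in (
            Rating.GOOD, Rating.ACCEPTABLE, Rating.NOT_ACCEPTABLE
        ))  # type: ignore[return-value]


@dataclass(frozen=True)
class StepRatingModel(RatingModel):
    """Good iff distance 0, Acceptable iff <= 3, Not acceptable beyond."""

    def probabilities(self, distance: float) -> tuple[float, float, float]:
        if distance == 0:
            return (1.0, 0.0, 0.0)
        if distance <= 3:
            return (0.0, 1.0, 0.0)
        return (0.0, 0.0, 1.0)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# -- generators --------------------------------------------------------------


def generate_ontology(
    n_concepts: int, max_parents: int = 2, seed: int = 0
) -> OntologyGraph:
    """Random single-rooted DAG of SCTID-style coded concepts.

    Concept 0 is the root; every later concept attaches to 1..max_parents
    parents drawn uniformly from earlier concepts, which guarantees
    acyclicity and a single root.  With ``max_parents=1`` the result is a
    tree with ``n_concepts - 1`` edges.
    """
    if n_concepts < 1:
        raise ValueError("n_concepts must be >= 1")
    rng = _rng(seed, 0)
    codes = [str(10_000_000 + i) for i in range(n_concepts)]
    edges: list[tuple[str, str]] = []
    for i in range(1, n_concepts):
        k = int(rng.integers(1, max_parents + 1))
        parents = rng.choice(i, size=min(k, i), replace=False)
        edges.extend((codes[i], codes[int(p)]) for p in sorted(parents))
    return OntologyGraph(edges, concepts=codes)


def generate_gold_standard(
    graph: OntologyGraph,
    n_items: int,
    multi_fraction: float = 0.125,
    multi_size_range: tuple[int, int] = (2, 3),
    seed: int = 0,
    finding_root: str | None = None,
) -> list[AnnotationRecord]:
    """Gold-standard code sets drawn uniformly from a finding subhierarchy.

    Each item is multi-finding with probability ``multi_fraction`` (default
    1/8: seven single-finding items per multi-finding one, the imbalance
    typical of diagnosis lists); multi-finding items draw k codes without
    replacement, k uniform over ``multi_size_range``.
    """
    if finding_root is None:
        roots = graph.roots
        if len(roots) != 1:
            raise ValueError(
                "finding_root must be given when the graph has multiple roots"
            )
        (finding_root,) = roots
    pool = sorted(graph.descendants_of(finding_root))
    lo, hi = multi_size_range
    if hi > len(pool):
        raise ValueError(
            f"multi-finding size {hi} exceeds the {len(pool)}-code subhierarchy"
        )
    rng = _rng(seed, 1)
    width = max(4, len(str(n_items)))
    records = []
    for i in range(n_items):
        k = int(rng.integers(lo, hi + 1)) if rng.random() < multi_fraction else 1
        codes = rng.choice(len(pool), size=k, replace=False)
        records.append(
            AnnotationRecord(
                item_id=f"{i + 1:0{width}d}",
                coder_id=GOLD_CODER,
                text=f"synthetic diagnosis {i + 1}",
                code_set=frozenset(pool[int(c)] for c in codes),
            )
        )
    return records


def _drift(code: str, graph: OntologyGraph, rng: np.random.Generator, cont: float) -> str:
    """Endpoint of a geometric-length random walk over undirected is-a edges.

    Resampled (up to a bound) so the endpoint differs from the start; if every
    attempt returns home, a uniform neighbour is taken instead.
    """
    for _ in range(16):
        current = code
        while True:
            nbrs = graph.neighbors(current)
            current = nbrs[int(rng.integers(len(nbrs)))]
            if rng.random() >= cont:
                break
        if current != code:
            return current
    nbrs = graph.neighbors(code)
    return nbrs[int(rng.integers(len(nbrs)))]


def simulate_coder(
    gold: Sequence[AnnotationRecord],
    graph: OntologyGraph,
    model: CoderErrorModel,
    coder_id: str,
    seed: int = 0,
    finding_root: str | None = None,
) -> list[AnnotationRecord]:
    """Simulate one coder's annotations as noisy copies of the gold standard.

    Per item: with ``p_invalid`` the code set is empty; otherwise each gold
    code is kept with ``p_exact`` or replaced by a drifted neighbour, then
    omissions (multi-code sets only, never emptying) and spurious additions
    are applied.  Output records reuse the gold item_ids and texts.
    """
    if finding_root is None:
        roots = graph.roots
        finding_root = next(iter(roots)) if len(roots) == 1 else None
    pool = (
        sorted(graph.descendants_of(finding_root))
        if finding_root is not None
        else sorted(graph.codes)
    )
    # substream keyed by a stable hash of the coder label
    key = sum(ord(ch) * 31**i for i, ch in enumerate(coder_id)) % (2**31)
    rng = _rng(seed, 2, key)
    out = []
    for record in gold:
        if rng.random() < model.p_invalid:
            codes: set[str] = set()
        else:
            codes = set()
            for code in sorted(record.code_set):
                if rng.random() < model.p_exact:
                    codes.add(code)
                else:
                    codes.add(_drift(code, graph, rng, model.drift_geom))
            if len(codes) > 1 and model.p_omit > 0:
                kept = {c for c in sorted(codes) if rng.random() >= model.p_omit}
                if not kept:
                    kept = {sorted(codes)[int(rng.integers(len(codes)))]}
                codes = kept
            if rng.random() < model.p_add:
                extras = [c for c in pool if c not in codes]
                if extras:
                    codes.add(extras[int(rng.integers(len(extras)))])
        out.append(
            AnnotationRecord(
                item_id=record.item_id,
                coder_id=coder_id,
                text=record.text,
                code_set=frozenset(codes),
            )
        )
    return out


def simulate_ratings(
    distances: Iterable[tuple[str, str, float]],
    model: RatingModel,
    seed: int = 0,
) -> list[QualitativeRating]:
    """Sample one rating per (item_id, coder_id, distance) observation."""
    rng = _rng(seed, 3)
    levels = (Rating.GOOD, Rating.ACCEPTABLE, Rating.NOT_ACCEPTABLE)
    out = []
    for item_id, coder_id, d in distances:
        probs = np.asarray(model.probabilities(d), dtype=float)
        probs = probs / probs.sum()
        choice = int(rng.choice(3, p=probs))
        out.append(
            QualitativeRating(item_id=item_id, coder_id=coder_id, rating=levels[choice])
        )
    return out


# -- study-level orchestration ------------------------------------------------

#: Illustrative study-shaped defaults: ~700 items, 1/8 multi-finding, two
#: human-like coders and one software-like coder whose exact-match rates on
#: single codes bracket typical human/automated coding performance.
PAPER_LIKE = {
    "n_concepts": 500,
    "max_parents": 2,
    "n_items": 708,
    "multi_fraction": 0.125,
    "multi_size_range": (2, 3),
    "coders": {
        "A": CoderErrorModel(p_exact=0.86, drift_geom=0.4, p_omit=0.10, p_add=0.04, p_invalid=0.02),
        "B": CoderErrorModel(p_exact=0.89, drift_geom=0.4, p_omit=0.08, p_add=0.03, p_invalid=0.02),
        "COMP": CoderErrorModel(p_exact=0.77, drift_geom=0.5, p_omit=0.12, p_add=0.10, p_invalid=0.04),
    },
    "rating_model": RatingModel(),
}


@dataclass
class SimulatedStudy:
    graph: OntologyGraph
    records: list[AnnotationRecord]  # gold + all coders
    ratings: list[QualitativeRating]
    finding_root: str


def simulate_study(
    seed: int = 0,
    n_concepts: int = 500,
    max_parents: int = 2,
    n_items: int = 708,
    multi_fraction: float = 0.125,
    multi_size_range: tuple[int, int] = (2, 3),
    coders: Mapping[str, CoderErrorModel] | None = None,
    rating_model: RatingModel | None = None,
) -> SimulatedStudy:
    """Generate a full synthetic study: ontology, gold, coders and ratings."""
    # local import: agreement depends on metrics only, no cycle with simulate
    from .agreement import compare_coders

    if coders is None:
        coders = PAPER_LIKE["coders"]
    if rating_model is None:
        rating_model = PAPER_LIKE["rating_model"]
    graph = generate_ontology(n_concepts, max_parents=max_parents, seed=seed)
    (finding_root,) = graph.roots
    gold = generate_gold_standard(
        graph,
        n_items,
        multi_fraction=multi_fraction,
        multi_size_range=multi_size_range,
        seed=seed,
    )
    records = list(gold)
    for coder_id, model in coders.items():
        records.extend(simulate_coder(gold, graph, model, coder_id, seed=seed))
    distances = []
    for coder_id in coders:
        comparisons, _ = compare_coders(records, coder_id, GOLD_CODER, graph)
        distances.extend((c.item_id, c.coder_x, c.value) for c in comparisons)
    ratings = simulate_ratings(distances, rating_model, seed=seed)
    return SimulatedStudy(
        graph=graph, records=records, ratings=ratings, finding_root=finding_root
    )


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated study as the text formats the evaluate pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology": out / "ontology_edges.tsv",
        "annotations": out / "annotations.csv",
        "ratings": out / "ratings.csv",
    }
    with paths["ontology"].open("w", encoding="utf-8") as fh:
        fh.write("child_code\tparent_code\n")
        for child, parent in sorted(study.graph.edges):
            fh.write(f"{child}\t{parent}\n")
    write_annotations(study.records, paths["annotations"])
    write_ratings(study.ratings, paths["ratings"])
    return paths
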