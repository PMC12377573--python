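"""Hand-checkable worked-example fixtures shipped as pipeline-format files.

The fixtures double as documentation of the input formats: each one is stored
as exactly the edge-list / annotations CSV text the pipeline consumes, plus
frozen expected values that the metrics must reproduce.

``tendinitis``
    A shoulder-tendinitis vs fractured-clavicle comparison.  The subsumption
    chain "disorder of tendon of shoulder region" > "tendinitis and/or
    tenosynovitis of the shoulder region" > "shoulder tendinitis" gives a
    pairwise distance of 2; the clavicle-fracture code appears in both sets
    and contributes 0; the average-minimum set distance is therefore 1.  The
    printed fragment leaves the two branches disconnected, so both are
    attached to a synthetic Clinical-Finding-style root via chains of 4 hops
    on distinct branches — long enough that no attachment path shortcuts any
    expected distance.

``anxiety``
    A two-code annotation ("Anxiety and depression" -> anxiety finding +
    depressive disorder) exercising the annotations reader round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from ..annotations import AnnotationRecord, read_annotations
from ..ontology import OntologyGraph, load_edge_list

#: Synthetic root standing in for the Clinical Finding subhierarchy root.
FIXTURE_FINDING_ROOT = "404684003"


@dataclass
class PaperFixture:
    """A worked example: mini-ontology, code sets and frozen expectations."""

    name: str
    graph: OntologyGraph | None
    code_sets: dict[str, frozenset[str]]
    records: list[AnnotationRecord]
    expectations: dict[str, float | int]
    note: str = ""


def _data_path(filename: str):
    return resources.files(__package__) / filename


def _load_tendinitis() -> PaperFixture:
    with resources.as_file(_data_path("tendinitis_edges.tsv")) as p:
        graph = load_edge_list(p)
    set1 = frozenset({"202852009", "58150001"})  # shoulder tendinitis + clavicle #
    set2 = frozenset({"76318008", "58150001"})  # broader tendon disorder + clavicle #
    return PaperFixture(
        name="tendinitis",
        graph=graph,
        code_sets={"set1": set1, "set2": set2},
        records=[],
        expectations={
            # chain: 76318008 -> 239955008 -> 202852009, two subsumption hops
            "pair_distance_76318008_202852009": 2,
            # 58150001 has an exact counterpart in the other set
            "min_distance_58150001": 0,
            # mean of per-code minima (2, 0, 2, 0) over the two sets
            "set_distance": 1,
        },
        note=(
            "Worked example comparing code sets for 'left shoulder tendonitis "
            "and a fractured clavicle': one coder chose the specific shoulder "
            "tendinitis code, the other its grandparent disorder-of-tendon "
            "code; both coded the clavicle fracture identically."
        ),
    )


def _load_anxiety() -> PaperFixture:
    with resources.as_file(_data_path("anxiety_annotations.csv")) as p:
        records = read_annotations(p)
    return PaperFixture(
        name="anxiety",
        graph=None,
        code_sets={"gold": records[0].code_set},
        records=records,
        expectations={"n_codes": 2},
        note=(
            "'Anxiety and depression' is a multi-finding item coded with two "
            "separate concepts: anxiety (finding) 48694002 and depressive "
            "disorder 35489007."
        ),
    )


_REGISTRY = {
    "tendinitis": _load_tendinitis,
    "anxiety": _load_anxiety,
}


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def load_fixture(name: str) -> PaperFixture:
    """Load a registered worked-example fixture by name."""
    try:
        loader = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {fixture_names()}"
        ) from None
    return loader()
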