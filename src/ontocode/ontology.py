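"""Is-a concept hierarchy: construction, descendant closure and graph distance.

The ontology is a directed acyclic graph of coded concepts whose edges point
from child to parent ("is-a" / subsumption).  All code-to-code distances used
by the evaluation metrics are shortest-path lengths over the *undirected*
view of this graph, so a hop to a parent and a hop to a child both cost 1.

Concepts that lie in different connected components have no defined distance;
such pairs yield the :data:`UNREACHABLE` sentinel (``math.inf``) rather than
an arbitrary large number, and downstream code routes them to the residual
(>3) distance band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel distance for concept pairs in different connected components.
UNREACHABLE = math.inf

#: SNOMED CT relationship type identifier for the is-a (subsumption) relation.
ISA_TYPE_ID = "116680003"

#: SNOMED CT code of the Clinical Finding subhierarchy root.
CLINICAL_FINDING_ROOT = "404684003"

_RF2_REQUIRED_COLUMNS = {"active", "sourceId", "destinationId", "typeId"}


class OntologyError(Exception):
    """Base class for ontology construction and lookup failures."""


class CycleError(OntologyError):
    """The child->parent edge set contains a directed cycle."""


class UnknownCodeError(OntologyError, KeyError):
    """A concept code was requested that is not present in the graph."""


class OntologyFormatError(OntologyError):
    """An ontology input file does not follow the expected layout."""


@dataclass(frozen=True)
class Concept:
    """A coded concept: an identifier plus an optional preferred label."""

    code: str
    term: str = ""


class OntologyGraph:
    """Directed acyclic is-a hierarchy over coded concepts.

    Parameters
    ----------
    edges
        Iterable of ``(child_code, parent_code)`` pairs.
    concepts
        Optional extra codes (possibly isolated) and/or terms.  Mapping of
        code -> term, or an iterable of codes.

    Raises
    ------
    CycleError
        If the child->parent digraph is not acyclic.
    OntologyError
        If the graph would contain no concepts.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        concepts: Mapping[str, str] | Iterable[str] | None = None,
    ) -> None:
        g = nx.DiGraph()
        terms: dict[str, str] = {}
        if concepts is not None:
            if isinstance(concepts, Mapping):
                terms = {str(c): str(t) for c, t in concepts.items()}
                g.add_nodes_from(terms)
            else:
                g.add_nodes_from(str(c) for c in concepts)
        for child, parent in edges:
            child, parent = str(child), str(parent)
            if not child or not parent:
                raise OntologyFormatError("empty concept code in edge list")
            g.add_edge(child, parent)
        if len(g) == 0:
            raise OntologyError("an ontology must contain at least one concept")
        if not nx.is_directed_acyclic_graph(g):
            member = nx.find_cycle(g)[0][0]
            raise CycleError(f"is-a hierarchy contains a cycle involving {member!r}")
        self._graph = g
        self._terms = terms
        self._undirected = g.to_undirected(as_view=True)
        self._dist_cache: dict[str, dict[str, int]] = {}

    # -- basic queries ----------------------------------------------------

    def __contains__(self, code: str) -> bool:
        return code in self._graph

    def __len__(self) -> int:
        return len(self._graph)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    @property
    def codes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def roots(self) -> set[str]:
        """Codes with no parent (no outgoing is-a edge)."""
        return {n for n in self._graph.nodes if self._graph.out_degree(n) == 0}

    @property
    def edges(self) -> set[tuple[str, str]]:
        """The (child, parent) edge set."""
        return set(self._graph.edges)

    def concept(self, code: str) -> Concept:
        self._require(code)
        return Concept(code=code, term=self._terms.get(code, ""))

    def concepts(self) -> list[Concept]:
        return [self.concept(c) for c in sorted(self._graph.nodes)]

    def _require(self, code: str) -> None:
        if code not in self._graph:
            raise UnknownCodeError(f"unknown concept code {code!r}")

    # -- hierarchy queries ------------------------------------------------

    def neighbors(self, code: str) -> list[str]:
        """Codes one undirected is-a edge away (parents and children), sorted."""
        self._require(code)
        return sorted(self._undirected[code])

    def descendants_of(self, root_code: str) -> set[str]:
        """All codes subsumed by ``root_code``, including the root itself."""
        self._require(root_code)
        return nx.ancestors(self._graph, root_code) | {root_code}

    def distances_from(self, code: str) -> Mapping[str, int]:
        """Undirected shortest-path lengths from ``code`` to every reachable code.

        Results are cached per source code; the graph is immutable after
        construction so the cache never invalidates.
        """
        self._require(code)
        cached = self._dist_cache.get(code)
        if cached is None:
            cached = dict(
                nx.single_source_shortest_path_length(self._undirected, code)
            )
            self._dist_cache[code] = cached
        return cached

    def shortest_path_distance(self, a: str, b: str) -> float:
        """Undirected shortest-path length between two codes.

        Returns ``0`` for identical codes and :data:`UNREACHABLE` when the
        codes lie in different connected components.
        """
        self._require(a)
        self._require(b)
        return self.distances_from(a).get(b, UNREACHABLE)


# -- readers ---------------------------------------------------------------


def load_edge_list(path: str | Path) -> OntologyGraph:
    """Load an ontology from a delimited child/parent edge-list file.

    The file is UTF-8 text with a header naming at least ``child_code`` and
    ``parent_code`` (optionally ``child_term``), tab- or comma-delimited.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise OntologyFormatError(f"{path}: empty edge-list file")
    sep = "\t" if "\t" in lines[0] else ","
    header = [h.strip() for h in lines[0].split(sep)]
    try:
        i_child = header.index("child_code")
        i_parent = header.index("parent_code")
    except ValueError:
        raise OntologyFormatError(
            f"{path}: header must name child_code and parent_code; got {header}"
        ) from None
    i_term = header.index("child_term") if "child_term" in header else None

    edges: list[tuple[str, str]] = []
    terms: dict[str, str] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) <= max(i_child, i_parent):
            raise OntologyFormatError(f"{path}, line {lineno}: too few columns")
        child, parent = fields[i_child], fields[i_parent]
        if not child or not parent:
            raise OntologyFormatError(
                f"{path}, line {lineno}: empty child_code or parent_code"
            )
        edges.append((child, parent))
        if i_term is not None and len(fields) > i_term and fields[i_term]:
            terms[child] = fields[i_term]
    return OntologyGraph(edges, concepts=terms)


def load_rf2_relationships(
    path: str | Path, active_only: bool = True
) -> OntologyGraph:
    """Load an ontology from an RF2 Relationship *snapshot* file.

    Only rows whose ``typeId`` is the is-a relationship (116680003) become
    edges (``sourceId`` = child, ``destinationId`` = parent); other
    relationship types contribute their concepts as isolated nodes only.
    With ``active_only``, inactive rows are likewise kept as concepts but
    contribute no edge.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = _RF2_REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise OntologyFormatError(
            f"{path}: missing required RF2 columns {sorted(missing)}"
        )
    concepts = set(df["sourceId"]) | set(df["destinationId"])
    mask = df["typeId"] == ISA_TYPE_ID
    if active_only:
        mask &= df["active"] == "1"
    isa = df.loc[mask]
    edges = list(zip(isa["sourceId"], isa["destinationId"]))
    logger.info(
        "RF2 %s: %d rows, %d is-a edges, %d concepts", path.name, len(df), len(edges), len(concepts)
    )
    return OntologyGraph(edges, concepts=concepts)
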