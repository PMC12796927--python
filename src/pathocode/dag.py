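"""Constraint DAG over observed annotation sequences.

The DAG is built from historical, rule-filtered code series.  Each
root-to-EOS path, read as a sequence of terms, is a series that (a) passes
the minimal Palga validity rules, (b) uses only thesaurus units, and (c)
chains only successions observed in the training annotations.  During
constrained decoding the DAG answers "which units may follow this prefix",
which is what masks the scorer's candidate set.

Nodes are keyed by ``(phase, term, dedup_index)`` where *phase* is the state
of the series rule machine when the unit was inserted (TOPOGRAPHY,
PROCEDURE, DIAGNOSIS, or POST for anything after the first diagnosis).
Phase-keying lets a term shared between contexts (e.g. a laterality such as
*links* following either *huid* or *pleura*) be a single multi-parent node,
while preventing category structure from leaking across rule states.  Edges
never decrease the phase, so cycles can only arise within a phase; when an
observed succession would close such a cycle the successor is duplicated
with an incremented ``dedup_index`` instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .codes import (
    DIAGNOSIS_CATEGORIES,
    Annotation,
    CodeSeries,
    Thesaurus,
    parse_annotation,
    validate_series,
)

EOS = "</s>"
SERIES_SEP = "<sep>"

PHASE_TOPO = "TOPOGRAPHY"
PHASE_PROC = "PROCEDURE"
PHASE_DIAG = "DIAGNOSIS"
PHASE_POST = "POST"

_ROOT_KEY = ("ROOT", "", 0)

NodeKey = tuple[str, str, int]


class UnreachablePrefixError(KeyError):
    """Raised when a prefix cannot be traversed from the DAG root."""


class DeadEndError(RuntimeError):
    """A constrained decode reached a node with no continuation and no EOS.

    Cannot occur on DAGs built by :func:`build_dag`; signals a corrupted DAG.
    """


@dataclass(frozen=True)
class RuleProfile:
    """Rule configuration used both to filter insertions and to define what
    counts as a valid path.

    ``report_type`` "C" waives the procedure requirement (the cytology rule);
    ``require_procedure`` overrides that derivation when set.  ``eos_after``
    is the set of categories after which a series may end — the default "M"
    (morphology only) follows annotation practice; widen to MDEF to allow
    ending on any diagnosis-category unit.

    ``require_terminal_diagnosis`` additionally filters out series whose
    final unit is not in ``eos_after``.  Such series cannot be root-to-EOS
    paths (EOS is only valid after a diagnosis unit), so inserting them
    would leave dead-end leaves the decoder could never finish from; with
    the filter on, every inserted series is generatable and constrained
    decoding can always terminate.
    """

    report_type: str = "T"
    require_procedure: bool | None = None
    eos_after: frozenset[str] = frozenset("M")
    series_sep: bool = False
    require_terminal_diagnosis: bool = True

    @property
    def procedure_required(self) -> bool:
        if self.require_procedure is not None:
            return self.require_procedure
        return self.report_type != "C"

    def to_dict(self) -> dict:
        return {
            "report_type": self.report_type,
            "require_procedure": self.require_procedure,
            "eos_after": sorted(self.eos_after),
            "series_sep": self.series_sep,
            "require_terminal_diagnosis": self.require_terminal_diagnosis,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleProfile":
        return cls(
            report_type=d["report_type"],
            require_procedure=d["require_procedure"],
            eos_after=frozenset(d["eos_after"]),
            series_sep=d["series_sep"],
            require_terminal_diagnosis=d.get("require_terminal_diagnosis", True),
        )


def _advance(state: str, category: str) -> str:
    if state == PHASE_TOPO and category == "T":
        return PHASE_TOPO
    if state in (PHASE_TOPO, PHASE_PROC) and category == "P":
        return PHASE_PROC
    if state in (PHASE_TOPO, PHASE_PROC) and category in DIAGNOSIS_CATEGORIES:
        return PHASE_DIAG
    return PHASE_POST


class AnnotationDAG:
    """Rooted multi-parent DAG of observed valid continuations."""

    def __init__(self, profile: RuleProfile | None = None):
        self.profile = profile or RuleProfile()
        self.graph = nx.DiGraph()
        self.graph.add_node(_ROOT_KEY, term=None, category=None, phase="ROOT",
                            eos_allowed=False, series_sep=False)
        self.source_count = 0
        self.rejected_count = 0

    # -- construction -------------------------------------------------------

    def _same_phase_reachable(self, start: NodeKey, target: NodeKey) -> bool:
        phase = start[0]
        stack = [start]
        seen = set()
        while stack:
            node = stack.pop()
            if node == target:
                return True
            if node in seen:
                continue
            seen.add(node)
            stack.extend(k for k in self.graph.successors(node) if k[0] == phase)
        return False

    def _child_for(self, parent: NodeKey, phase: str, term: str, category: str) -> NodeKey:
        for k in self.graph.successors(parent):
            if k[0] == phase and k[1] == term:
                return k
        dedup = 0
        while True:
            key = (phase, term, dedup)
            if key not in self.graph:
                self.graph.add_node(key, term=term, category=category, phase=phase,
                                    eos_allowed=False, series_sep=False)
                break
            # reuse an existing node unless linking it would close a cycle
            if phase != parent[0] or not self._same_phase_reachable(key, parent):
                break
            dedup += 1
        self.graph.add_edge(parent, key)
        return key

    def insert_series(self, series: CodeSeries) -> NodeKey | None:
        """Insert one rule-checked series; returns the final node, or None
        (incrementing ``rejected_count``) when the series fails the rules."""
        result = validate_series(series, self.profile.report_type,
                                 require_procedure=self.profile.require_procedure)
        if not result.valid:
            self.rejected_count += 1
            return None
        if self.profile.require_terminal_diagnosis:
            last = series.units[-1].primary_category
            if last not in self.profile.eos_after:
                self.rejected_count += 1
                return None
        cur = _ROOT_KEY
        state = PHASE_TOPO
        for unit in series.units:
            category = unit.primary_category
            phase = _advance(state, category)
            cur = self._child_for(cur, phase, unit.term, category)
            for c in unit.part_categories:
                state = _advance(state, c)
            if category in self.profile.eos_after:
                self.graph.nodes[cur]["eos_allowed"] = True
        self.source_count += 1
        return cur

    def insert_annotation(self, annotation: Annotation) -> None:
        prev_end: NodeKey | None = None
        for series in annotation.series:
            end = self.insert_series(series)
            if self.profile.series_sep and prev_end is not None and end is not None:
                self.graph.nodes[prev_end]["series_sep"] = True
            prev_end = end

    # -- queries -------------------------------------------------------------

    @property
    def root(self) -> NodeKey:
        return _ROOT_KEY

    def node_count(self) -> int:
        return self.graph.number_of_nodes() - 1  # excluding the virtual root

    def _step(self, node: NodeKey, term: str) -> NodeKey:
        for k in self.graph.successors(node):
            if k[1] == term:
                return k
        raise UnreachablePrefixError(f"no child {term!r} under node {node!r}")

    def traverse(self, prefix: Sequence[str]) -> NodeKey:
        """Walk a term sequence (possibly containing SERIES_SEP) from root."""
        cur = _ROOT_KEY
        for term in prefix:
            if term == SERIES_SEP:
                if not (self.profile.series_sep and self.graph.nodes[cur]["series_sep"]):
                    raise UnreachablePrefixError("series separator not allowed here")
                cur = _ROOT_KEY
                continue
            cur = self._step(cur, term)
        return cur

    def valid_continuations(self, prefix: Sequence[str]) -> set[str]:
        """Terms (plus EOS / SERIES_SEP specials) that may follow ``prefix``."""
        node = self.traverse(prefix)
        out = {k[1] for k in self.graph.successors(node)}
        attrs = self.graph.nodes[node]
        if attrs["eos_allowed"]:
            out.add(EOS)
        if self.profile.series_sep and attrs["series_sep"]:
            out.add(SERIES_SEP)
        return out

    def is_generatable(self, sequence: Sequence[str]) -> bool:
        """True iff ``sequence`` is a root path whose final node allows EOS
        (with any embedded series separators taken at permitted nodes)."""
        if not sequence:
            return False
        try:
            node = self.traverse(sequence)
        except UnreachablePrefixError:
            return False
        if node == _ROOT_KEY:  # ended on a separator
            return False
        return bool(self.graph.nodes[node]["eos_allowed"])

    def enumerate_paths(self, max_count: int = 10000) -> list[tuple[str, ...]]:
        """Depth-first enumeration of root-to-EOS term sequences, children in
        insertion order, truncated at ``max_count``."""
        out: list[tuple[str, ...]] = []

        def dfs(node: NodeKey, path: list[str]) -> bool:
            if node != _ROOT_KEY and self.graph.nodes[node]["eos_allowed"]:
                out.append(tuple(path))
                if len(out) >= max_count:
                    return False
            for child in self.graph.successors(node):
                path.append(child[1])
                ok = dfs(child, path)
                path.pop()
                if not ok:
                    return False
            return True

        dfs(_ROOT_KEY, [])
        return out

    # -- serialization -------------------------------------------------------

    def to_json(self) -> dict:
        nodes = []
        for key, attrs in self.graph.nodes(data=True):
            if key == _ROOT_KEY:
                continue
            nodes.append({
                "key": list(key),
                "term": attrs["term"],
                "category": attrs["category"],
                "eos_allowed": attrs["eos_allowed"],
                "series_sep": attrs["series_sep"],
            })
        edges = [[list(u), list(v)] for u, v in self.graph.edges()]
        return {
            "format": "pathocode-dag/1",
            "profile": self.profile.to_dict(),
            "source_count": self.source_count,
            "rejected_count": self.rejected_count,
            "nodes": nodes,
            "edges": edges,
        }

    @classmethod
    def from_json(cls, data: dict) -> "AnnotationDAG":
        dag = cls(RuleProfile.from_dict(data["profile"]))
        for n in data["nodes"]:
            key = tuple(n["key"])
            dag.graph.add_node(key, term=n["term"], category=n["category"],
                               phase=key[0], eos_allowed=n["eos_allowed"],
                               series_sep=n["series_sep"])
        for u, v in data["edges"]:
            dag.graph.add_edge(tuple(u), tuple(v))
        dag.source_count = data["source_count"]
        dag.rejected_count = data["rejected_count"]
        return dag

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, ensure_ascii=False, indent=1)

    @classmethod
    def load(cls, path) -> "AnnotationDAG":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


def build_dag(
    annotations: Iterable[Annotation | str],
    thesaurus: Thesaurus | None = None,
    profile: RuleProfile | None = None,
) -> AnnotationDAG:
    """Build the constraint DAG from historical annotations.

    Annotations may be :class:`Annotation` objects or raw Table-1 dialect
    strings (parsed against ``thesaurus``).  Series failing the rule profile
    — including series with terms the thesaurus cannot resolve — are counted
    in ``rejected_count`` and skipped, never raised.
    """
    dag = AnnotationDAG(profile)
    for ann in annotations:
        if isinstance(ann, str):
            ann = parse_annotation(ann, thesaurus)
        dag.insert_annotation(ann)
    return dag


def valid_continuations(dag: AnnotationDAG, prefix: Sequence[str]) -> set[str]:
    return dag.valid_continuations(prefix)


def is_generatable(dag: AnnotationDAG, sequence: Sequence[str]) -> bool:
    return dag.is_generatable(sequence)


def enumerate_paths(dag: AnnotationDAG, max_count: int = 10000) -> list[tuple[str, ...]]:
    return dag.enumerate_paths(max_count)
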