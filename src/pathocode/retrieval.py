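"""Case-based retrieval evaluation.

Annotations exist so that code queries against the pathology archive
retrieve the right patients.  This module runs simple code queries — a
disjunction of conjunctive clauses, each clause a set of codes/terms that
must co-occur within one code series — over annotated reports, compares the
patient/report sets retrieved from the original annotations (O) versus a
model's annotations (M), and offers a heuristic classifier for why a
patient retrievable from the original codes was missed by a model.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .codes import Annotation, CodeSeries, ReportRecord, Thesaurus, _normalize_term

#: miss-reason taxonomy (heuristic proxy for a manual audit)
ABSENCE_OF_RELEVANT_INFORMATION = "ABSENCE_OF_RELEVANT_INFORMATION"
ESSENTIAL_CODE_NOT_RECOGNIZED = "ESSENTIAL_CODE_NOT_RECOGNIZED"
WRONG_CODES = "WRONG_CODES"
NO_CODES = "NO_CODES"
MISS_REASONS = (ABSENCE_OF_RELEVANT_INFORMATION, ESSENTIAL_CODE_NOT_RECOGNIZED,
                WRONG_CODES, NO_CODES)


class NotAMissError(ValueError):
    """The report actually matches the query under the model annotation."""


@dataclass(frozen=True)
class CodeQuery:
    """Disjunction of conjunctive clauses over codes or terms.

    A series matches a clause iff it contains every clause member (order
    free); a report matches iff any of its series matches any clause.  With
    ``across_series`` a clause may collect its members from the whole
    annotation instead of a single series.
    """

    name: str
    clauses: tuple[frozenset[str], ...]
    across_series: bool = False

    def __post_init__(self):
        if not self.clauses or any(not c for c in self.clauses):
            raise ValueError("query needs >=1 clause, each non-empty")

    @classmethod
    def from_json(cls, obj: dict) -> "CodeQuery":
        return cls(
            name=obj["name"],
            clauses=tuple(frozenset(c) for c in obj["clauses"]),
            across_series=bool(obj.get("across_series", False)),
        )

    def to_json(self) -> dict:
        return {"name": self.name, "clauses": [sorted(c) for c in self.clauses],
                "across_series": self.across_series}


def load_queries(path) -> list[CodeQuery]:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    return [CodeQuery.from_json(obj) for obj in data]


def _series_keys(series: CodeSeries) -> set[str]:
    keys: set[str] = set()
    for u in series.units:
        keys.add(_normalize_term(u.term))
        if u.code is not None:
            keys.add(u.code.raw)
            keys.update(u.code.parts)
    return keys


def _matches(query: CodeQuery, annotation: Annotation) -> bool:
    if annotation.is_empty:
        return False
    if query.across_series:
        pooled: set[str] = set()
        for s in annotation.series:
            pooled |= _series_keys(s)
        scopes = [pooled]
    else:
        scopes = [_series_keys(s) for s in annotation.series]
    for scope in scopes:
        for clause in query.clauses:
            if all(m in scope or _normalize_term(m) in scope for m in clause):
                return True
    return False


@dataclass(frozen=True)
class QueryHits:
    report_ids: frozenset[str]
    patient_ids: frozenset[str]


def run_query(
    query: CodeQuery,
    reports: Sequence[tuple[ReportRecord, Annotation]],
) -> QueryHits:
    """Matched report and patient ids; a patient is retrieved iff the query
    hits at least one of their reports."""
    rids, pids = set(), set()
    for record, annotation in reports:
        if _matches(query, annotation):
            rids.add(record.report_id)
            pids.add(record.patient_id)
    return QueryHits(frozenset(rids), frozenset(pids))


@dataclass(frozen=True)
class RetrievalResult:
    """Patient- and report-level O/M set algebra for one query and system."""

    query_name: str
    system: str
    patients_O: frozenset[str]
    patients_M: frozenset[str]
    reports_O: frozenset[str]
    reports_M: frozenset[str]

    @property
    def patients_O_only(self) -> frozenset[str]:
        return self.patients_O - self.patients_M

    @property
    def patients_M_only(self) -> frozenset[str]:
        return self.patients_M - self.patients_O

    @property
    def patients_both(self) -> frozenset[str]:
        return self.patients_O & self.patients_M

    @property
    def reports_O_only(self) -> frozenset[str]:
        return self.reports_O - self.reports_M

    @property
    def reports_M_only(self) -> frozenset[str]:
        return self.reports_M - self.reports_O

    @property
    def reports_both(self) -> frozenset[str]:
        return self.reports_O & self.reports_M

    def counts(self) -> dict[str, int]:
        return {
            "patients_O": len(self.patients_O),
            "patients_M": len(self.patients_M),
            "patients_O_only": len(self.patients_O_only),
            "patients_M_only": len(self.patients_M_only),
            "patients_both": len(self.patients_both),
            "reports_O": len(self.reports_O),
            "reports_M": len(self.reports_M),
            "reports_O_only": len(self.reports_O_only),
            "reports_M_only": len(self.reports_M_only),
            "reports_both": len(self.reports_both),
        }


def compare_retrieval(
    reports: Sequence[ReportRecord],
    original: Mapping[str, Annotation],
    model: Mapping[str, Annotation],
    query: CodeQuery,
    system: str = "model",
) -> RetrievalResult:
    """Run ``query`` against both annotation sets covering the same reports."""
    missing = {r.report_id for r in reports} - set(original) | \
              {r.report_id for r in reports} - set(model)
    if missing:
        raise KeyError(f"annotations missing for reports: {sorted(missing)[:5]}")
    hits_o = run_query(query, [(r, original[r.report_id]) for r in reports])
    hits_m = run_query(query, [(r, model[r.report_id]) for r in reports])
    return RetrievalResult(
        query_name=query.name,
        system=system,
        patients_O=hits_o.patient_ids,
        patients_M=hits_m.patient_ids,
        reports_O=hits_o.report_ids,
        reports_M=hits_m.report_ids,
    )


def _query_surface_forms(query: CodeQuery, thesaurus: Thesaurus | None) -> set[str]:
    forms: set[str] = set()
    for clause in query.clauses:
        for m in clause:
            forms.add(_normalize_term(m))
            if thesaurus is not None:
                entry = thesaurus.get(m) or thesaurus.lookup_term(m)
                if entry is not None:
                    forms.add(_normalize_term(entry.term))
    return {f for f in forms if f}


def classify_miss(
    report: ReportRecord,
    model_annotation: Annotation,
    query: CodeQuery,
    reference_annotation: Annotation,
    thesaurus: Thesaurus | None = None,
    overlap_threshold: float = 0.5,
) -> str:
    """Heuristic reason why a model's annotation fails a query the original
    annotation satisfied.

    Proxy rules, applied in order: NO_CODES for an empty model output;
    ABSENCE_OF_RELEVANT_INFORMATION when no query code/term (nor its
    thesaurus display form) occurs in the conclusion text;
    ESSENTIAL_CODE_NOT_RECOGNIZED when the model output overlaps the
    reference in at least ``overlap_threshold`` of its units yet lacks a
    query-required code; WRONG_CODES otherwise.  This stands in for a manual
    audit and makes no claim of reproducing one.
    """
    if _matches(query, model_annotation):
        raise NotAMissError(f"report {report.report_id} matches {query.name}")
    if model_annotation.is_empty:
        return NO_CODES
    conclusion = _normalize_term(report.conclusion)
    if not any(f in conclusion for f in _query_surface_forms(query, thesaurus)):
        return ABSENCE_OF_RELEVANT_INFORMATION
    model_terms = Counter(_normalize_term(t) for t in model_annotation.all_terms())
    ref_terms = Counter(_normalize_term(t) for t in reference_annotation.all_terms())
    overlap = sum((model_terms & ref_terms).values())
    if model_terms and overlap / sum(model_terms.values()) >= overlap_threshold:
        return ESSENTIAL_CODE_NOT_RECOGNIZED
    return WRONG_CODES


def tally_miss_reasons(
    reports: Sequence[ReportRecord],
    original: Mapping[str, Annotation],
    model: Mapping[str, Annotation],
    query: CodeQuery,
    thesaurus: Thesaurus | None = None,
    max_audit: int | None = None,
) -> Counter:
    """Audit the reports retrievable from the original annotations but not
    the model's, tallying one reason per miss (up to ``max_audit`` reports)."""
    result = compare_retrieval(reports, original, model, query)
    missed = sorted(result.reports_O_only)
    if max_audit is not None:
        missed = missed[:max_audit]
    by_id = {r.report_id: r for r in reports}
    tally: Counter = Counter()
    for rid in missed:
        tally[classify_miss(by_id[rid], model[rid], query, original[rid], thesaurus)] += 1
    return tally
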