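"""Data model for Palga-style codes, code series, annotations, and reports.

The Palga thesaurus assigns each pathology concept a code starting with a
category letter — T (topography), P (procedure), or one of the diagnosis
categories M (morphology), D (disease), E (etiology), F (function) — followed
by uppercase letters and digits, e.g. ``T96000`` (thyroid) or ``M80903``
(basal cell carcinoma).  Combination codes concatenate several atomic codes
into one raw string, e.g. ``T96000P11100`` (thyroidectomy).

A *code series* is an ordered sequence of such codes summarizing one
diagnosis: at least one topography, then at least one procedure (optional in
cytology reports), then at least one diagnosis code; further codes may follow
unrestricted.  An *annotation* is one or more series attached to a report,
serialized with ``*`` between terms and a newline between series.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

CATEGORY_LETTERS = frozenset("TPMDEF")
DIAGNOSIS_CATEGORIES = frozenset("MDEF")

#: violation codes reported by :func:`validate_series`
MISSING_TOPOGRAPHY = "MISSING_TOPOGRAPHY"
MISSING_PROCEDURE = "MISSING_PROCEDURE"
MISSING_DIAGNOSIS = "MISSING_DIAGNOSIS"
ORDER_VIOLATION = "ORDER_VIOLATION"
MALFORMED_CODE = "MALFORMED_CODE"
EMPTY_SERIES = "EMPTY_SERIES"

_PART_RE = re.compile(r"^[TPMDEF][A-Z0-9]+$")


class AnnotationError(ValueError):
    """Base class for parsing/validation errors; ``code`` is a violation code."""

    code = "ANNOTATION_ERROR"


class MalformedCodeError(AnnotationError):
    code = MALFORMED_CODE


class UnknownCodeError(AnnotationError):
    code = "UNKNOWN_CODE"


class EmptySeriesError(AnnotationError):
    code = EMPTY_SERIES


def _normalize_term(term: str) -> str:
    return " ".join(term.split()).casefold()


@dataclass(frozen=True)
class ThesaurusEntry:
    code: str
    term: str
    categories: str  # category letter per atomic part, e.g. "T" or "TP"


class Thesaurus:
    """Table mapping Palga codes to display terms and category letters.

    Terms are matched case-insensitively with whitespace normalized, which
    tolerates dictation artifacts in report annotations.
    """

    def __init__(self, entries: Iterable[ThesaurusEntry] = ()):
        self._by_code: dict[str, ThesaurusEntry] = {}
        self._by_term: dict[str, ThesaurusEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: ThesaurusEntry) -> None:
        self._by_code[entry.code] = entry
        self._by_term[_normalize_term(entry.term)] = entry

    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __iter__(self) -> Iterator[ThesaurusEntry]:
        return iter(self._by_code.values())

    def get(self, code: str) -> ThesaurusEntry | None:
        return self._by_code.get(code)

    def is_atomic(self, code: str) -> bool:
        e = self._by_code.get(code)
        return e is not None and len(e.categories) == 1

    def lookup_term(self, term: str) -> ThesaurusEntry | None:
        return self._by_term.get(_normalize_term(term))

    def terms(self) -> list[str]:
        return [e.term for e in self._by_code.values()]

    @classmethod
    def from_tsv(cls, path) -> "Thesaurus":
        th = cls()
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                th.add(ThesaurusEntry(
                    code=fields[idx["code"]],
                    term=fields[idx["term"]],
                    categories=fields[idx["category_letters"]],
                ))
        return th

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("code\tterm\tcategory_letters\n")
            for e in self._by_code.values():
                fh.write(f"{e.code}\t{e.term}\t{e.categories}\n")


@dataclass(frozen=True)
class PalgaCode:
    """A thesaurus code, possibly a combination of atomic parts.

    ``parts`` concatenate exactly to ``raw``; ``categories`` holds the
    category letter of each part in order.  The *primary* category — the one
    used by the series rules — is that of the first part.
    """

    raw: str
    categories: tuple[str, ...]
    parts: tuple[str, ...]
    term: str | None = None

    @property
    def primary_category(self) -> str:
        return self.categories[0]

    @property
    def is_combination(self) -> bool:
        return len(self.parts) > 1


def _starts_known_part(raw: str, i: int, thesaurus: Thesaurus | None) -> bool:
    if raw[i] not in CATEGORY_LETTERS:
        return False
    if thesaurus is None:
        return True
    return any(thesaurus.is_atomic(raw[i:end]) for end in range(i + 2, len(raw) + 1))


def _split_parts(raw: str, thesaurus: Thesaurus | None) -> list[str]:
    parts: list[str] = []
    pos, n = 0, len(raw)
    while pos < n:
        part = None
        if thesaurus is not None:
            # greedy: the longest thesaurus-known atomic code starting here
            for end in range(n, pos + 1, -1):
                if thesaurus.is_atomic(raw[pos:end]):
                    part = raw[pos:end]
                    break
        if part is None:
            end = pos + 1
            while end < n and (end - pos < 2 or not _starts_known_part(raw, end, thesaurus)):
                end += 1
            part = raw[pos:end]
        if not _PART_RE.match(part):
            raise MalformedCodeError(f"malformed code part {part!r} in {raw!r}")
        parts.append(part)
        pos += len(part)
    return parts


def parse_code(raw: str, thesaurus: Thesaurus | None = None, *, strict: bool = False) -> PalgaCode:
    """Parse a raw code string into a :class:`PalgaCode`.

    Combination codes are split greedily left-to-right at boundaries that
    begin a thesaurus-known atomic code; without a thesaurus, at every
    category letter starting a maximal ``[TPMDEF][A-Z0-9]+`` run.

    Raises :class:`MalformedCodeError` on residues that cannot form a
    well-formed part, and :class:`UnknownCodeError` in strict mode when a
    part is absent from the thesaurus.
    """
    if not raw:
        raise MalformedCodeError("empty code")
    parts = _split_parts(raw, thesaurus)
    if strict and thesaurus is not None:
        for p in parts:
            if p not in thesaurus:
                raise UnknownCodeError(f"code part {p!r} not in thesaurus")
    term = None
    if thesaurus is not None:
        entry = thesaurus.get(raw)
        if entry is not None:
            term = entry.term
    return PalgaCode(
        raw=raw,
        categories=tuple(p[0] for p in parts),
        parts=tuple(parts),
        term=term,
    )


@dataclass(frozen=True)
class AnnotationUnit:
    """One term of a code series with its resolved code (None if unresolved)."""

    term: str
    code: PalgaCode | None = None

    @property
    def primary_category(self) -> str | None:
        return self.code.primary_category if self.code is not None else None

    @property
    def part_categories(self) -> tuple[str, ...]:
        return self.code.categories if self.code is not None else ()


@dataclass(frozen=True)
class CodeSeries:
    units: tuple[AnnotationUnit, ...]

    def __post_init__(self):
        if not isinstance(self.units, tuple):
            object.__setattr__(self, "units", tuple(self.units))

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(u.term for u in self.units)

    @property
    def categories(self) -> tuple[str | None, ...]:
        """Primary category per unit (None where the code is unresolved)."""
        return tuple(u.primary_category for u in self.units)

    def serialize(self) -> str:
        return "*".join(self.terms)

    def __len__(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class Annotation:
    series: tuple[CodeSeries, ...]

    def __post_init__(self):
        if not isinstance(self.series, tuple):
            object.__setattr__(self, "series", tuple(self.series))

    def serialize(self) -> str:
        return "\n".join(s.serialize() for s in self.series)

    def all_terms(self) -> list[str]:
        return [t for s in self.series for t in s.terms]

    def __len__(self) -> int:
        return len(self.series)

    @property
    def is_empty(self) -> bool:
        return len(self.series) == 0


@dataclass(frozen=True)
class ReportRecord:
    report_id: str
    patient_id: str
    report_type: str  # T (histology), C (cytology), S (autopsy)
    year: int
    conclusion: str
    reference: Annotation | None = None

    def __post_init__(self):
        if self.report_type not in ("T", "C", "S"):
            raise ValueError(f"report_type must be T/C/S, got {self.report_type!r}")

    @property
    def length_chars(self) -> int:
        return len(self.conclusion)


@dataclass(frozen=True)
class ValidationResult:
    valid: bool
    violations: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.valid


def make_unit(term: str, thesaurus: Thesaurus | None, *, strict: bool = False) -> AnnotationUnit:
    code = None
    if thesaurus is not None:
        entry = thesaurus.lookup_term(term)
        if entry is not None:
            code = parse_code(entry.code, thesaurus)
        elif strict:
            raise UnknownCodeError(f"term {term!r} not in thesaurus")
    return AnnotationUnit(term=term, code=code)


def validate_series(
    series: CodeSeries,
    report_type: str = "T",
    *,
    require_procedure: bool | None = None,
    diagnosis_categories: frozenset[str] = DIAGNOSIS_CATEGORIES,
) -> ValidationResult:
    """Check the minimal Palga requirements on one code series.

    A series is valid iff it contains at least one topography, at least one
    procedure (waived for cytology, report_type ``"C"``), at least one
    diagnosis-category code, and the *first occurrences* of these respect the
    order topography < procedure < diagnosis.  Codes after the first
    diagnosis are unrestricted.  Combination codes satisfy every category
    they contain, their internal part order contributing to the order check.
    """
    if require_procedure is None:
        require_procedure = report_type != "C"
    violations: list[str] = []
    if len(series) == 0:
        return ValidationResult(False, (EMPTY_SERIES,))

    flat: list[str] = []
    for u in series.units:
        if u.code is None:
            if MALFORMED_CODE not in violations:
                violations.append(MALFORMED_CODE)
            continue
        flat.extend(u.code.categories)

    def first(pred) -> int | None:
        for i, c in enumerate(flat):
            if pred(c):
                return i
        return None

    ft = first(lambda c: c == "T")
    fp = first(lambda c: c == "P")
    fd = first(lambda c: c in diagnosis_categories)

    if ft is None:
        violations.append(MISSING_TOPOGRAPHY)
    if require_procedure and fp is None:
        violations.append(MISSING_PROCEDURE)
    if fd is None:
        violations.append(MISSING_DIAGNOSIS)

    if not violations:
        if require_procedure:
            ordered = ft < fp < fd
        else:
            # P waived: only T-before-diagnosis is mandatory, but a procedure
            # appearing before the first diagnosis must still follow a topography
            ordered = ft < fd and (fp is None or fp > fd or ft < fp)
        if not ordered:
            violations.append(ORDER_VIOLATION)

    return ValidationResult(not violations, tuple(violations))


def parse_series(line: str, thesaurus: Thesaurus | None = None, *, strict: bool = False) -> CodeSeries:
    terms = [t.strip() for t in line.split("*")]
    terms = [t for t in terms if t]
    if not terms:
        raise EmptySeriesError(f"series line {line!r} has no terms")
    return CodeSeries(tuple(make_unit(t, thesaurus, strict=strict) for t in terms))


def parse_annotation(text: str, thesaurus: Thesaurus | None = None, *, strict: bool = False) -> Annotation:
    """Parse the asterisk/newline annotation dialect into an :class:`Annotation`.

    Terms are split on ``*`` within a line; each non-empty line is one code
    series.  A line consisting only of separators raises
    :class:`EmptySeriesError`.
    """
    if not text.strip():
        raise EmptySeriesError("empty annotation text")
    series = []
    for line in text.split("\n"):
        if not line.strip():
            continue
        series.append(parse_series(line, thesaurus, strict=strict))
    return Annotation(tuple(series))


def serialize_annotation(annotation: Annotation) -> str:
    return annotation.serialize()


# ---------------------------------------------------------------------------
# file formats: thesaurus TSV (above), reports JSONL, annotations TSV

def load_reports_jsonl(path, thesaurus: Thesaurus | None = None) -> list[ReportRecord]:
    """Read report records from JSONL with fields report_id, patient_id,
    type, year, conclusion, annotation (Table-1 dialect string)."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            ref = None
            ann_text = obj.get("annotation")
            if ann_text:
                ref = parse_annotation(ann_text, thesaurus)
            records.append(ReportRecord(
                report_id=str(obj["report_id"]),
                patient_id=str(obj["patient_id"]),
                report_type=obj["type"],
                year=int(obj["year"]),
                conclusion=obj["conclusion"],
                reference=ref,
            ))
    return records


def write_reports_jsonl(path, records: Iterable[ReportRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            obj = {
                "report_id": r.report_id,
                "patient_id": r.patient_id,
                "type": r.report_type,
                "year": r.year,
                "conclusion": r.conclusion,
                "annotation": r.reference.serialize() if r.reference else "",
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def load_annotations_tsv(path, thesaurus: Thesaurus | None = None) -> dict[str, Annotation]:
    """Read a two-column TSV (report_id, annotation); newlines inside an
    annotation are encoded as ``\\n`` escapes."""
    out: dict[str, Annotation] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            if not line.rstrip("\n"):
                continue
            report_id, text = line.rstrip("\n").split("\t", 1)
            text = text.replace("\\n", "\n")
            out[report_id] = parse_annotation(text, thesaurus) if text.strip() else Annotation(())
    return out


def write_annotations_tsv(path, annotations: Mapping[str, Annotation]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("report_id\tannotation\n")
        for rid, ann in annotations.items():
            fh.write(f"{rid}\t{ann.serialize().replace(chr(10), chr(92) + 'n')}\n")
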