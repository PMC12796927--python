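"""Seeded generator of thesauri, rule-conformant annotated report corpora,
patients, and query fixtures.

The generator emulates the statistical shape of a national pathology
archive, not its language: a heavy-tailed (Zipf-like) code usage
distribution, three report types with distinct conclusion-length and
codes-per-annotation distributions (histology T, cytology C, autopsy S),
multi-series annotations, patients owning several reports, and optional
reference-annotation noise.  Conclusion texts are synthetic filler tokens
with the annotation's terms embedded, which is all the lexical toy scorer
needs.  Every clean (and noised) annotation passes the series validity
rules by construction, and all output is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .codes import (
    Annotation,
    AnnotationUnit,
    CodeSeries,
    ReportRecord,
    Thesaurus,
    ThesaurusEntry,
    parse_code,
    validate_series,
)
from .retrieval import CodeQuery, run_query

#: per-type conclusion length in tokens: median and interquartile range
DEFAULT_LENGTHS = {"T": (15, 9, 26), "C": (11, 7, 17), "S": (124, 65, 207)}
#: per-type codes per annotation: median and interquartile range
DEFAULT_CODES = {"T": (4, 3, 5), "C": (4, 3, 5), "S": (4, 3, 8)}
#: report type mix (histology-heavy, as in archive practice)
DEFAULT_TYPE_MIX = {"T": 0.587, "C": 0.188, "S": 0.225}

#: Zipf exponent calibrated once so that, at the default vocabulary sizes and
#: a 10,000-report corpus, the 5 most frequent codes carry ~26% and the top
#: 20 ~49% of all code occurrences (the documented skew of archive codes)
DEFAULT_ZIPF_EXPONENT = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    n_topography: int = 80
    n_procedure: int = 40
    n_morphology: int = 120
    n_disease: int = 20
    n_etiology: int = 10
    n_function: int = 10
    combination_fraction: float = 0.04
    zipf_exponent: float = DEFAULT_ZIPF_EXPONENT
    n_reports: Mapping[str, int] = field(
        default_factory=lambda: {"T": 587, "C": 188, "S": 225})
    lengths: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTHS))
    codes_per_annotation: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CODES))
    multi_series_rate: float = 0.2
    procedure_omit_rate_cytology: float = 0.3
    combination_use_rate: float = 0.05
    term_embed_rate: float = 0.8
    noise_rate: float = 0.1
    mean_reports_per_patient: float = 2.0
    chars_per_token: float = 7.0
    n_queries: int = 5
    start_year: int = 2013
    end_year: int = 2023

    def __post_init__(self):
        for name in ("n_topography", "n_procedure", "n_morphology",
                     "n_disease", "n_etiology", "n_function"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("multi_series_rate", "noise_rate", "term_embed_rate",
                     "procedure_omit_rate_cytology", "combination_use_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")


# ---------------------------------------------------------------------------
# thesaurus generation

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


def _make_term(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        n_words = 2 if rng.random() < 0.10 else 1
        words = []
        for _ in range(n_words):
            n_syll = int(rng.integers(2, 5))
            word = "".join(
                _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
                for _ in range(n_syll)
            )
            words.append(word)
        term = " ".join(words)
        if term not in used:
            used.add(term)
            return term


def _make_code(rng: np.random.Generator, letter: str, used: set[str]) -> str:
    while True:
        code = letter + "".join(str(rng.integers(10)) for _ in range(5))
        if code not in used:
            used.add(code)
            return code


class SyntheticThesaurus(Thesaurus):
    """Thesaurus with per-code Zipf base sampling weights."""

    def __init__(self):
        super().__init__()
        self.weights: dict[str, float] = {}

    def codes_by_category(self, letter: str) -> list[str]:
        return [e.code for e in self if e.categories == letter]


def generate_thesaurus(config: GeneratorConfig, seed: int = 0) -> SyntheticThesaurus:
    """Emit unique codes per category with pronounceable synthetic terms and
    Zipf base weights; a small fraction are combination codes."""
    rng = np.random.default_rng(seed)
    th = SyntheticThesaurus()
    used_terms: set[str] = set()
    used_codes: set[str] = set()
    category_counts = {
        "T": config.n_topography, "P": config.n_procedure,
        "M": config.n_morphology, "D": config.n_disease,
        "E": config.n_etiology, "F": config.n_function,
    }
    for letter, count in category_counts.items():
        for rank in range(count):
            code = _make_code(rng, letter, used_codes)
            term = _make_term(rng, used_terms)
            th.add(ThesaurusEntry(code=code, term=term, categories=letter))
            th.weights[code] = 1.0 / (rank + 1) ** config.zipf_exponent
    # combination codes: concatenated topography+procedure entries
    n_combo = int(round(config.combination_fraction * len(th)))
    t_codes = th.codes_by_category("T")
    p_codes = th.codes_by_category("P")
    for _ in range(n_combo):
        t = t_codes[int(rng.integers(min(10, len(t_codes))))]
        p = p_codes[int(rng.integers(min(10, len(p_codes))))]
        combo = t + p
        if combo in th:
            continue
        term = _make_term(rng, used_terms)
        th.add(ThesaurusEntry(code=combo, term=term, categories="TP"))
        th.weights[combo] = min(th.weights[t], th.weights[p]) * 0.5
    return th


# ---------------------------------------------------------------------------
# corpus generation

@dataclass(frozen=True)
class NoiseEdit:
    report_id: str
    kind: str  # drop_unit | substitute_diagnosis | drop_series
    detail: str


@dataclass
class SyntheticCorpus:
    config: GeneratorConfig
    thesaurus: SyntheticThesaurus
    reports: list[ReportRecord]
    patients: dict[str, list[str]]  # patient id -> report ids
    clean_annotations: dict[str, Annotation]
    noised_annotations: dict[str, Annotation]
    noise_log: list[NoiseEdit]
    queries: list[tuple[CodeQuery, frozenset[str]]]  # query, true patient ids


class _CodeSampler:
    def __init__(self, thesaurus: SyntheticThesaurus, rng: np.random.Generator):
        self._rng = rng
        self._by_cat: dict[str, tuple[list[str], np.ndarray]] = {}
        for letter in "TPMDEF":
            codes = [e.code for e in thesaurus if e.categories == letter]
            w = np.array([thesaurus.weights[c] for c in codes])
            self._by_cat[letter] = (codes, w / w.sum())
        combos = [e.code for e in thesaurus if len(e.categories) > 1]
        if combos:
            w = np.array([thesaurus.weights[c] for c in combos])
            self._by_cat["combo"] = (combos, w / w.sum())
        self._th = thesaurus

    def draw(self, category: str) -> AnnotationUnit:
        codes, p = self._by_cat[category]
        code = codes[int(self._rng.choice(len(codes), p=p))]
        parsed = parse_code(code, self._th)
        return AnnotationUnit(term=parsed.term, code=parsed)

    def sibling(self, unit: AnnotationUnit) -> AnnotationUnit | None:
        """A different unit of the same primary category."""
        cat = unit.primary_category
        codes, p = self._by_cat[cat]
        if len(codes) < 2:
            return None
        for _ in range(20):
            cand = self.draw(cat)
            if cand.code.raw != unit.code.raw:
                return cand
        return None

    @property
    def has_combos(self) -> bool:
        return "combo" in self._by_cat


def _lognormal_int(rng: np.random.Generator, median: float, q1: float, q3: float,
                   minimum: int = 1) -> int:
    mu = math.log(median)
    sigma = (math.log(q3) - math.log(q1)) / (2 * 0.6745)
    return max(minimum, int(round(float(rng.lognormal(mu, sigma)))))


_POST_CATEGORIES = ["T", "M", "D", "E", "F", "P"]
_POST_WEIGHTS = np.array([0.30, 0.40, 0.12, 0.06, 0.06, 0.06])


def _generate_series(sampler: _CodeSampler, rng: np.random.Generator,
                     report_type: str, config: GeneratorConfig) -> CodeSeries:
    med, q1, q3 = config.codes_per_annotation[report_type]
    k = _lognormal_int(rng, med, q1, q3, minimum=3)
    omit_p = report_type == "C" and rng.random() < config.procedure_omit_rate_cytology

    units: list[AnnotationUnit] = []
    if not omit_p and sampler.has_combos and rng.random() < config.combination_use_rate:
        units.append(sampler.draw("combo"))  # combined topography+procedure opener
    else:
        units.append(sampler.draw("T"))
        if rng.random() < 0.25:  # secondary leading topography
            units.append(sampler.draw("T"))
        if not omit_p:
            units.append(sampler.draw("P"))
    units.append(sampler.draw("M"))
    while len(units) < k:
        cat = _POST_CATEGORIES[int(rng.choice(len(_POST_CATEGORIES), p=_POST_WEIGHTS))]
        units.append(sampler.draw(cat))
    if units[-1].primary_category != "M":
        # annotation practice: a series closes on the morphology it asserts,
        # which is also what lets the DAG terminate the sequence there
        units[-1] = sampler.draw("M")
    return CodeSeries(tuple(units))


def _conclusion_text(rng: np.random.Generator, annotation: Annotation,
                     report_type: str, config: GeneratorConfig,
                     filler: list[str]) -> str:
    med, q1, q3 = config.lengths[report_type]
    target = _lognormal_int(rng, med, q1, q3, minimum=3)
    embedded: list[str] = []
    for term in annotation.all_terms():
        if rng.random() < config.term_embed_rate:
            embedded.append(term)
    tokens: list[str] = []
    for t in embedded:
        tokens.extend(t.split())
    n_filler = max(0, target - len(tokens))
    tokens.extend(filler[int(rng.integers(len(filler)))] for _ in range(n_filler))
    perm = rng.permutation(len(tokens))
    return " ".join(tokens[i] for i in perm)


def generate_corpus(thesaurus: SyntheticThesaurus, config: GeneratorConfig,
                    seed: int = 0) -> SyntheticCorpus:
    """Generate the full synthetic study corpus.

    Per report: a type-dependent number of rule-conformant code series with
    Zipf-weighted codes, a filler conclusion embedding the annotation's
    terms, and a patient assignment; plus planted code queries with their
    ground-truth patient sets computed from the clean annotations.
    """
    rng = np.random.default_rng(seed)
    sampler = _CodeSampler(thesaurus, rng)
    filler_used: set[str] = set(thesaurus.terms())
    filler = [_make_term(rng, filler_used) for _ in range(120)]

    reports: list[ReportRecord] = []
    clean: dict[str, Annotation] = {}
    rid = 0
    for rtype in ("T", "C", "S"):
        for _ in range(config.n_reports.get(rtype, 0)):
            n_series = 1
            while rng.random() < config.multi_series_rate:
                n_series += 1
            ann = Annotation(tuple(
                _generate_series(sampler, rng, rtype, config) for _ in range(n_series)))
            report_id = f"r{rid:06d}"
            rid += 1
            conclusion = _conclusion_text(rng, ann, rtype, config, filler)
            reports.append(ReportRecord(
                report_id=report_id,
                patient_id="",  # assigned below
                report_type=rtype,
                year=int(rng.integers(config.start_year, config.end_year + 1)),
                conclusion=conclusion,
                reference=ann,
            ))
            clean[report_id] = ann

    # partition reports over patients
    order = rng.permutation(len(reports))
    patients: dict[str, list[str]] = {}
    pos = 0
    pid = 0
    lam = max(0.0, config.mean_reports_per_patient - 1.0)
    while pos < len(reports):
        size = 1 + int(rng.poisson(lam))
        patient_id = f"p{pid:05d}"
        pid += 1
        member_idx = [int(i) for i in order[pos:pos + size]]
        patients[patient_id] = [reports[i].report_id for i in member_idx]
        for i in member_idx:
            reports[i] = replace(reports[i], patient_id=patient_id)
        pos += size

    # reference noise
    noised, noise_log = inject_noise(
        clean, config.noise_rate, seed=int(rng.integers(2 ** 31)),
        sampler=sampler, report_types={r.report_id: r.report_type for r in reports})

    # planted queries: a topography+morphology pair co-occurring in a series
    queries: list[tuple[CodeQuery, frozenset[str]]] = []
    pairs = [(r, s) for r in reports for s in r.reference.series]
    for qi in range(config.n_queries):
        for _ in range(50):
            _, series = pairs[int(rng.integers(len(pairs)))]
            t_terms = [u.term for u in series.units if u.primary_category == "T"]
            m_terms = [u.term for u in series.units if u.primary_category == "M"]
            if t_terms and m_terms:
                clause = frozenset({t_terms[0], m_terms[0]})
                if len(clause) == 2:
                    query = CodeQuery(name=f"q{qi}", clauses=(clause,))
                    truth = run_query(query, [(r, clean[r.report_id]) for r in reports])
                    queries.append((query, truth.patient_ids))
                    break

    return SyntheticCorpus(
        config=config,
        thesaurus=thesaurus,
        reports=reports,
        patients=patients,
        clean_annotations=clean,
        noised_annotations=noised,
        noise_log=noise_log,
        queries=queries,
    )


def generate(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticCorpus:
    """Convenience: thesaurus plus corpus from one seed."""
    config = config or GeneratorConfig()
    thesaurus = generate_thesaurus(config, seed=seed)
    return generate_corpus(thesaurus, config, seed=seed + 1)


# ---------------------------------------------------------------------------
# noise injection

def inject_noise(
    annotations: Mapping[str, Annotation],
    noise_rate: float,
    seed: int,
    sampler: _CodeSampler | None = None,
    thesaurus: SyntheticThesaurus | None = None,
    report_types: Mapping[str, str] | None = None,
) -> tuple[dict[str, Annotation], list[NoiseEdit]]:
    """Independently, with probability ``noise_rate`` per annotation, apply
    one validity-preserving edit: drop a non-mandatory unit, substitute a
    diagnosis unit by a same-category sibling, or drop an extra series.

    Emulates references that are partially complete or correct while keeping
    every noised annotation rule-valid.  Returns the noised annotations and
    an edit log.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must be in [0, 1]")
    if sampler is None:
        if thesaurus is None:
            raise ValueError("need a sampler or a thesaurus")
        sampler = _CodeSampler(thesaurus, np.random.default_rng(seed))
    rng = np.random.default_rng(seed)
    report_types = report_types or {}
    out: dict[str, Annotation] = {}
    log: list[NoiseEdit] = []
    for rid, ann in annotations.items():
        if rng.random() >= noise_rate:
            out[rid] = ann
            continue
        rtype = report_types.get(rid, "T")
        edited, edit = _apply_one_edit(ann, rid, rtype, sampler, rng)
        out[rid] = edited
        if edit is not None:
            log.append(edit)
    return out, log


def _droppable_indices(series: CodeSeries, rtype: str) -> list[int]:
    out = []
    for i in range(len(series)):
        rest = CodeSeries(series.units[:i] + series.units[i + 1:])
        if len(rest) and validate_series(rest, rtype).valid:
            out.append(i)
    return out


def _apply_one_edit(ann: Annotation, rid: str, rtype: str,
                    sampler: _CodeSampler, rng: np.random.Generator
                    ) -> tuple[Annotation, NoiseEdit | None]:
    kinds = ["substitute_diagnosis"]
    drop_units = [
        (si, _droppable_indices(s, rtype)) for si, s in enumerate(ann.series)
    ]
    drop_units = [(si, idxs) for si, idxs in drop_units if idxs]
    if drop_units:
        kinds.append("drop_unit")
    if len(ann.series) > 1:
        kinds.append("drop_series")
    kind = kinds[int(rng.integers(len(kinds)))]

    if kind == "drop_series":
        si = int(rng.integers(len(ann.series)))
        edited = Annotation(ann.series[:si] + ann.series[si + 1:])
        return edited, NoiseEdit(rid, kind, f"series {si}")

    if kind == "drop_unit":
        si, idxs = drop_units[int(rng.integers(len(drop_units)))]
        ui = idxs[int(rng.integers(len(idxs)))]
        series = ann.series[si]
        new_series = CodeSeries(series.units[:ui] + series.units[ui + 1:])
        edited = Annotation(ann.series[:si] + (new_series,) + ann.series[si + 1:])
        return edited, NoiseEdit(rid, kind, f"series {si} unit {ui} ({series.units[ui].term})")

    # substitute a diagnosis unit by a same-category sibling
    candidates = [
        (si, ui) for si, s in enumerate(ann.series)
        for ui, u in enumerate(s.units)
        if u.primary_category in ("M", "D", "E", "F")
    ]
    si, ui = candidates[int(rng.integers(len(candidates)))]
    series = ann.series[si]
    sib = sampler.sibling(series.units[ui])
    if sib is None:
        return ann, None
    new_units = series.units[:ui] + (sib,) + series.units[ui + 1:]
    edited = Annotation(ann.series[:si] + (CodeSeries(new_units),) + ann.series[si + 1:])
    return edited, NoiseEdit(
        rid, "substitute_diagnosis", f"series {si} unit {ui} ({series.units[ui].term} -> {sib.term})")
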