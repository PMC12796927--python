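"""Greedy and diverse beam-search generation with optional DAG masking.

The decoder is model-agnostic: any :class:`Scorer` producing log-scores over
candidate next units given (source text, generated prefix) can drive it.
With a constraint DAG attached, units outside the DAG's valid continuations
are masked to minus infinity before top-k selection, so every emitted series
is guaranteed to be a known-valid root-to-EOS path — no hallucinated codes,
no rule violations, only historically observed successions, and termination
only after a diagnosis unit.

Default decoding parameters follow the study conditions: beam search with
6 beams, 2 beam groups, a diversity penalty of 0.3, and a maximum output
length of 128 units.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

from .codes import Annotation, ReportRecord, Thesaurus
from .dag import EOS, SERIES_SEP, AnnotationDAG, DeadEndError

NEG_INF = float("-inf")
_BOS = "<s>"


class Scorer(Protocol):
    """Contract for pluggable next-unit scorers.

    Implementations must be deterministic given (source, prefix) and their
    own fixed state, and must return finite scores for at least one unit.
    """

    def vocabulary(self) -> list[str]: ...

    def score_next(self, source: str, prefix: Sequence[str]) -> Mapping[str, float]: ...


@dataclass(frozen=True)
class DecodeParams:
    num_beams: int = 6
    num_groups: int = 2
    diversity_penalty: float = 0.3
    max_length: int = 128
    mode: str = "beam"  # "beam" or "greedy"
    constrained: bool = True

    def __post_init__(self):
        if self.mode not in ("beam", "greedy"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        if self.diversity_penalty < 0:
            raise ValueError("diversity_penalty must be non-negative")
        if self.mode == "beam" and self.num_beams % self.num_groups:
            raise ValueError("num_beams must be divisible by num_groups")


@dataclass(frozen=True)
class DecodeResult:
    sequence: tuple[str, ...]  # terms with EOS/SERIES_SEP stripped
    raw_sequence: tuple[str, ...]  # terms incl. SERIES_SEP markers
    score: float  # total log-score
    normalized_score: float  # mean log-score per emitted decision
    finished: bool  # ended on EOS (True) vs length cap (False)
    beam_rank: int = 0

    def annotation_string(self) -> str:
        """Render as the asterisk/newline annotation dialect."""
        series: list[list[str]] = [[]]
        for t in self.raw_sequence:
            if t == SERIES_SEP:
                series.append([])
            else:
                series[-1].append(t)
        return "\n".join("*".join(s) for s in series if s)


@dataclass
class _Beam:
    terms: tuple[str, ...]
    total: float
    finished: bool = False
    decisions: int = 0  # scored steps, incl. the EOS step when taken

    @property
    def normalized(self) -> float:
        return self.total / self.decisions if self.decisions else NEG_INF


def _allowed_units(dag: AnnotationDAG, prefix: Sequence[str]) -> set[str]:
    allowed = dag.valid_continuations(prefix)
    if not allowed:
        raise DeadEndError(f"no valid continuation after prefix {list(prefix)!r}")
    return allowed


def _finalize(beams: list[_Beam]) -> list[DecodeResult]:
    def strip(seq: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(t for t in seq if t != SERIES_SEP)

    beams = sorted(beams, key=lambda b: (-b.normalized, b.terms))
    return [
        DecodeResult(
            sequence=strip(b.terms),
            raw_sequence=b.terms,
            score=b.total,
            normalized_score=b.normalized,
            finished=b.finished,
            beam_rank=rank,
        )
        for rank, b in enumerate(beams)
    ]


def decode(
    source: str,
    scorer: Scorer,
    params: DecodeParams | None = None,
    dag: AnnotationDAG | None = None,
) -> list[DecodeResult]:
    """Generate ranked annotation sequences for one source text.

    Beam mode implements group-wise diverse beam search: at each step the
    expansions of all alive beams form one shared candidate pool; beams are
    selected in ``num_groups`` sequential blocks, and a candidate's selection
    score is penalized by ``diversity_penalty`` for every time its unit was
    already chosen at this step by an earlier block (Hamming diversity).
    With a zero penalty this reduces exactly to plain beam search.  The
    accumulated beam score is the raw log-score; the penalty steers selection
    only.  Results are ranked by length-normalized total score (mean
    log-score per decision), ties broken lexicographically.
    """
    params = params or DecodeParams()
    if params.constrained and dag is None:
        raise ValueError("constrained decoding requires a DAG")
    if params.mode == "greedy":
        return _greedy(source, scorer, params, dag)
    return _beam(source, scorer, params, dag)


def _candidate_scores(
    source: str,
    scorer: Scorer,
    prefix: tuple[str, ...],
    params: DecodeParams,
    dag: AnnotationDAG | None,
) -> dict[str, float]:
    scores = dict(scorer.score_next(source, prefix))
    if params.constrained:
        allowed = _allowed_units(dag, prefix)
        # hard mask: anything outside the DAG's continuations is unreachable
        return {u: scores.get(u, -1e9) for u in allowed}
    return {u: s for u, s in scores.items() if s > NEG_INF}


def _greedy(source, scorer, params, dag) -> list[DecodeResult]:
    beam = _Beam(terms=(), total=0.0)
    for _ in range(params.max_length):
        cands = _candidate_scores(source, scorer, beam.terms, params, dag)
        unit = min(cands, key=lambda u: (-cands[u], u))  # lexicographic tie-break
        beam.total += cands[unit]
        beam.decisions += 1
        if unit == EOS:
            beam.finished = True
            break
        beam.terms = beam.terms + (unit,)
    return _finalize([beam])


def _beam(source, scorer, params, dag) -> list[DecodeResult]:
    beams_per_group = params.num_beams // params.num_groups
    alive = [_Beam(terms=(), total=0.0)]
    done: list[_Beam] = []

    for _ in range(params.max_length):
        if not alive:
            break
        # shared candidate pool over all alive beams
        pool: list[tuple[float, tuple[str, ...], int, str]] = []
        for bi, b in enumerate(alive):
            for u, s in _candidate_scores(source, scorer, b.terms, params, dag).items():
                pool.append((b.total + s, b.terms + ((u,) if u != EOS else (EOS,)), bi, u))

        taken: set[int] = set()
        step_units: Counter[str] = Counter()
        next_alive: list[_Beam] = []
        for _g in range(params.num_groups):
            ranked = sorted(
                (i for i in range(len(pool)) if i not in taken),
                key=lambda i: (
                    -(pool[i][0] - params.diversity_penalty * step_units[pool[i][3]]),
                    pool[i][1],
                ),
            )
            for i in ranked[:beams_per_group]:
                taken.add(i)
                total, _seq, bi, u = pool[i]
                step_units[u] += 1
                parent = alive[bi]
                if u == EOS:
                    done.append(_Beam(terms=parent.terms, total=total, finished=True,
                                      decisions=parent.decisions + 1))
                else:
                    next_alive.append(_Beam(terms=parent.terms + (u,), total=total,
                                            decisions=parent.decisions + 1))
        alive = next_alive

    done.extend(alive)  # length-capped beams compete unfinished
    return _finalize(done)


# ---------------------------------------------------------------------------
# toy scorers — desk-scale stand-ins for a fine-tuned seq2seq model


class UniformScorer:
    """Equal log-score over the whole vocabulary (including EOS)."""

    def __init__(self, vocab: Iterable[str]):
        self._vocab = sorted(set(vocab) | {EOS})
        self._score = -math.log(len(self._vocab))

    def vocabulary(self) -> list[str]:
        return list(self._vocab)

    def score_next(self, source: str, prefix: Sequence[str]) -> dict[str, float]:
        return {u: self._score for u in self._vocab}


class BigramScorer:
    """Add-one-smoothed bigram log-probabilities over annotation units.

    Estimated from the reference annotations of a corpus: each code series
    contributes transitions BOS -> u1 -> ... -> un -> EOS.
    """

    def __init__(self, corpus: Iterable[ReportRecord] | Iterable[Annotation],
                 vocab: Iterable[str] | None = None):
        annotations = [
            r.reference if isinstance(r, ReportRecord) else r
            for r in corpus
        ]
        annotations = [a for a in annotations if a is not None]
        if not annotations:
            raise ValueError("bigram scorer needs a non-empty annotated corpus")
        self._counts: Counter[tuple[str, str]] = Counter()
        self._context: Counter[str] = Counter()
        units: set[str] = set(vocab) if vocab is not None else set()
        for ann in annotations:
            for series in ann.series:
                prev = _BOS
                for term in series.terms:
                    units.add(term)
                    self._counts[(prev, term)] += 1
                    self._context[prev] += 1
                    prev = term
                self._counts[(prev, EOS)] += 1
                self._context[prev] += 1
        self._vocab = sorted(units | {EOS})
        self._v = len(self._vocab)

    def vocabulary(self) -> list[str]:
        return list(self._vocab)

    def score_pair(self, prev: str, unit: str) -> float:
        c = self._counts[(prev, unit)]
        return math.log((c + 1) / (self._context[prev] + self._v))

    def score_next(self, source: str, prefix: Sequence[str]) -> dict[str, float]:
        prev = prefix[-1] if prefix else _BOS
        if prev == SERIES_SEP:
            prev = _BOS
        return {u: self.score_pair(prev, u) for u in self._vocab}


class LexicalScorer:
    """Bigram scores plus a bonus for units whose term occurs in the source.

    The bonus rewards case-insensitive substring presence of the term in the
    conclusion text, a crude stand-in for encoder attention.  The default of
    6 log-units is deliberately larger than the spread of the Zipf prior so
    that source evidence, when present, outweighs marginal code frequency.
    A coverage condition pays the bonus only for terms not yet generated,
    so one mention in the source does not reward endless repetition.
    """

    def __init__(self, bigram: BigramScorer, bonus: float = 6.0):
        self._bigram = bigram
        self._bonus = bonus

    def vocabulary(self) -> list[str]:
        return self._bigram.vocabulary()

    def score_next(self, source: str, prefix: Sequence[str]) -> dict[str, float]:
        base = self._bigram.score_next(source, prefix)
        low = source.casefold()
        used = set(prefix)
        return {
            u: s + (self._bonus
                    if u != EOS and u not in used and u.casefold() in low
                    else 0.0)
            for u, s in base.items()
        }


class AdversarialScorer:
    """Seeded random fixed preference per unit, independent of context.

    Test plumbing: left unconstrained it happily emits rule-violating unit
    orders, which is what demonstrates the necessity of the DAG mask.
    """

    def __init__(self, vocab: Iterable[str], seed: int = 0, eos_score: float = -6.0):
        rng = np.random.default_rng(seed)
        self._vocab = sorted(set(vocab) | {EOS})
        prefs = rng.uniform(-5.0, 0.0, size=len(self._vocab))
        self._scores = dict(zip(self._vocab, prefs.tolist()))
        self._scores[EOS] = eos_score

    def vocabulary(self) -> list[str]:
        return list(self._vocab)

    def score_next(self, source: str, prefix: Sequence[str]) -> dict[str, float]:
        if len(prefix) >= 3:  # let unconstrained runs terminate
            out = dict(self._scores)
            out[EOS] = 0.0
            return out
        return dict(self._scores)


def toy_scorers(corpus: Sequence[ReportRecord], thesaurus: Thesaurus | None = None,
                lexical_bonus: float = 6.0) -> dict[str, object]:
    """Build the three standard toy scorers from an annotated corpus."""
    vocab = thesaurus.terms() if thesaurus is not None else None
    bigram = BigramScorer(corpus, vocab=vocab)
    uniform = UniformScorer(bigram.vocabulary())
    lexical = LexicalScorer(bigram, bonus=lexical_bonus)
    return {"uniform": uniform, "bigram": bigram, "lexical": lexical}
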