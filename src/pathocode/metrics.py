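"""Quantitative evaluation: corpus BLEU, paired bootstrap significance,
per-code precision/recall/F1, frequency binning, subgroup stratification,
and auxiliary word/character error rates.

BLEU is computed on annotation strings after replacing the ``*`` and newline
separators with single spaces, so tokens are terms and the words of
multi-word terms.  The algorithm is the standard corpus BLEU-4: per-segment
clipped n-gram counts summed over the corpus, exponential smoothing for
zero numerators, multiplicative brevity penalty, reported on the 0-100
scale.  Statistical comparison between systems uses a two-sided paired
bootstrap over evaluation items with percentile confidence intervals.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .codes import Annotation, ReportRecord

#: inclusive conclusion-length bins (characters) used for stratification
LENGTH_BINS: tuple[tuple[int, int | None], ...] = ((0, 80), (81, 200), (201, 400), (401, None))
REPORT_TYPES = ("T", "C", "S")


class LengthMismatchError(ValueError):
    pass


class EmptyCorpusError(ValueError):
    pass


def tokenize(annotation_string: str) -> list[str]:
    """Map an annotation string to BLEU/WER tokens: separators to spaces,
    then whitespace split."""
    return annotation_string.replace("*", " ").replace("\n", " ").split()


# ---------------------------------------------------------------------------
# BLEU

def _check(hypotheses: Sequence[str], references: Sequence[str]) -> None:
    if len(hypotheses) != len(references):
        raise LengthMismatchError(
            f"{len(hypotheses)} hypotheses vs {len(references)} references")
    if len(hypotheses) == 0:
        raise EmptyCorpusError("empty corpus")


def bleu_stats(hypotheses: Sequence[str], references: Sequence[str]) -> np.ndarray:
    """Per-item sufficient statistics, shape (n, 10):
    clipped matches 1..4-gram, hypothesis n-gram totals 1..4, hyp len, ref len.

    Corpus BLEU is a function of the column sums, which is what makes
    bootstrap resampling cheap.
    """
    _check(hypotheses, references)
    out = np.zeros((len(hypotheses), 10), dtype=np.int64)
    for i, (hyp, ref) in enumerate(zip(hypotheses, references)):
        h, r = tokenize(hyp), tokenize(ref)
        for n in range(1, 5):
            hc = Counter(tuple(h[j:j + n]) for j in range(len(h) - n + 1))
            rc = Counter(tuple(r[j:j + n]) for j in range(len(r) - n + 1))
            out[i, n - 1] = sum(min(c, rc[g]) for g, c in hc.items())
            out[i, 3 + n] = max(len(h) - n + 1, 0)
        out[i, 8] = len(h)
        out[i, 9] = len(r)
    return out


def bleu_from_stats(agg: np.ndarray) -> float:
    """Corpus BLEU-4 from summed statistics (exponential smoothing)."""
    correct = agg[0:4]
    total = agg[4:8]
    hyp_len, ref_len = float(agg[8]), float(agg[9])
    if hyp_len == 0:
        return 0.0
    log_sum = 0.0
    smooth = 1.0
    for n in range(4):
        if total[n] == 0:
            return 0.0
        if correct[n] == 0:
            smooth *= 2.0
            p = 100.0 / (smooth * total[n])
        else:
            p = 100.0 * correct[n] / total[n]
        log_sum += math.log(p)
    bp = 1.0 if hyp_len >= ref_len else math.exp(1.0 - ref_len / hyp_len)
    return bp * math.exp(log_sum / 4.0)


def corpus_bleu(hypotheses: Sequence[str], references: Sequence[str]) -> float:
    """Corpus BLEU on the 0-100 scale for aligned annotation strings."""
    return bleu_from_stats(bleu_stats(hypotheses, references).sum(axis=0))


# ---------------------------------------------------------------------------
# paired bootstrap

@dataclass(frozen=True)
class BleuReport:
    bleu: float
    ci_halfwidth: float
    n_items: int


@dataclass(frozen=True)
class ComparisonResult:
    """System-vs-reference BLEU comparison.

    ``direction`` is "+" for a significant increase of the system over the
    reference, "-" for a decrease, "n.s." otherwise (at level ``alpha``).
    """

    reference: BleuReport
    system: BleuReport
    p_value: float
    direction: str
    alpha: float = 0.05


def paired_bootstrap(
    hyp_reference: Sequence[str],
    hyp_system: Sequence[str],
    references: Sequence[str],
    n_resamples: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided paired bootstrap comparing a system against a reference
    system on the same items.

    Item indices are resampled with replacement ``n_resamples`` times; BLEU
    is recomputed for both systems per resample.  The CI half-width is half
    the 2.5-97.5 percentile range of each system's bootstrap distribution.
    The p-value is the fraction of resamples whose BLEU difference
    contradicts the full-data sign, doubled and capped at 1.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    _check(hyp_reference, references)
    _check(hyp_system, references)

    stats_a = bleu_stats(hyp_reference, references)
    stats_b = bleu_stats(hyp_system, references)
    n = len(references)
    full_a = bleu_from_stats(stats_a.sum(axis=0))
    full_b = bleu_from_stats(stats_b.sum(axis=0))
    delta = full_b - full_a

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_resamples, n))
    boot_a = np.array([bleu_from_stats(stats_a[row].sum(axis=0)) for row in idx])
    boot_b = np.array([bleu_from_stats(stats_b[row].sum(axis=0)) for row in idx])

    def halfwidth(boot: np.ndarray) -> float:
        lo, hi = np.percentile(boot, [2.5, 97.5])
        return float(hi - lo) / 2.0

    if delta == 0.0:
        p = 1.0
    else:
        contradict = np.sign(boot_b - boot_a) != np.sign(delta)
        p = min(1.0, 2.0 * float(np.mean(contradict)))
    direction = "n.s."
    if p < alpha:
        direction = "+" if delta > 0 else "-"

    return ComparisonResult(
        reference=BleuReport(full_a, halfwidth(boot_a), n),
        system=BleuReport(full_b, halfwidth(boot_b), n),
        p_value=p,
        direction=direction,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# per-code precision / recall / F1

@dataclass(frozen=True)
class CodeScore:
    code: str
    support: int
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def _annotation_multiset(ann: Annotation, use_codes: bool) -> Counter:
    if not use_codes:
        return Counter(ann.all_terms())
    out: Counter = Counter()
    for s in ann.series:
        for u in s.units:
            out[u.code.raw if u.code is not None else u.term] += 1
    return out


def per_code_scores(
    predictions: Sequence[Annotation],
    references: Sequence[Annotation],
    *,
    use_codes: bool = False,
) -> list[CodeScore]:
    """Micro-averaged per-code counts over aligned report pairs.

    Prediction and reference are reduced to term multisets pooled over all
    series of a report; per code, tp is the clipped overlap and fp/fn the
    one-sided surpluses.  With ``use_codes`` the raw code strings resolved
    through the thesaurus are counted instead of terms.
    """
    if len(predictions) != len(references):
        raise LengthMismatchError(
            f"{len(predictions)} predictions vs {len(references)} references")
    tp: Counter = Counter()
    fp: Counter = Counter()
    fn: Counter = Counter()
    support: Counter = Counter()
    for pred, ref in zip(predictions, references):
        pc = _annotation_multiset(pred, use_codes)
        rc = _annotation_multiset(ref, use_codes)
        for code in set(pc) | set(rc):
            p, r = pc[code], rc[code]
            tp[code] += min(p, r)
            fp[code] += max(0, p - r)
            fn[code] += max(0, r - p)
            support[code] += r
    codes = sorted(set(tp) | set(fp) | set(fn), key=lambda c: (-support[c], c))
    return [CodeScore(c, support[c], tp[c], fp[c], fn[c]) for c in codes]


@dataclass(frozen=True)
class FrequencyBin:
    index: int
    n_codes: int
    total_support: int
    mean_support: float
    mean_f1: float


def frequency_binned_f1(scores: Sequence[CodeScore], n_bins: int = 20) -> list[FrequencyBin]:
    """Bin codes by cumulative frequency share and average F1 per bin.

    Codes are sorted by descending support; bin boundaries fall at equal
    increments of cumulative support (each bin carries ~1/n_bins of all
    reference occurrences), a code landing exactly on a boundary going to
    the earlier bin.  Returns the unweighted mean F1 and mean support per
    populated bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    ranked = sorted(scores, key=lambda s: (-s.support, s.code))
    total = sum(s.support for s in ranked)
    if total == 0:
        return []
    target = total / n_bins
    members: dict[int, list[CodeScore]] = {}
    cum = 0
    for s in ranked:
        cum += s.support
        b = min(n_bins - 1, math.ceil(cum / target) - 1)
        members.setdefault(b, []).append(s)
    out = []
    for b in sorted(members):
        group = members[b]
        sup = sum(s.support for s in group)
        out.append(FrequencyBin(
            index=b,
            n_codes=len(group),
            total_support=sup,
            mean_support=sup / len(group),
            mean_f1=sum(s.f1 for s in group) / len(group),
        ))
    return out


# ---------------------------------------------------------------------------
# subgroup stratification

def length_bin(length_chars: int) -> str:
    for lo, hi in LENGTH_BINS:
        if length_chars >= lo and (hi is None or length_chars <= hi):
            return bin_label((lo, hi))
    raise ValueError(f"negative length {length_chars}")


def bin_label(bin_: tuple[int, int | None]) -> str:
    lo, hi = bin_
    return f"{lo}-{hi}" if hi is not None else f"{lo}+"


@dataclass(frozen=True)
class SubgroupRow:
    report_type: str
    length_bin: str
    count: int
    comparisons: Mapping[str, ComparisonResult]  # system name -> vs reference


def subgroup_analysis(
    corpus: Sequence[ReportRecord],
    predictions: Mapping[str, Sequence[str]],
    reference_system: str,
    n_resamples: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[SubgroupRow]:
    """Per (report type x length bin) paired-bootstrap comparison of every
    system against ``reference_system``.

    Bins partition conclusion character counts inclusively: [0,80], [81,200],
    [201,400], [401,inf).  Empty cells are reported with count 0 and no
    statistics.  Rows appear for all 3 types x 4 bins.
    """
    if reference_system not in predictions:
        raise KeyError(f"reference system {reference_system!r} not among predictions")
    refs = [r.reference.serialize() if r.reference else "" for r in corpus]
    rows = []
    for rtype in REPORT_TYPES:
        for bin_ in LENGTH_BINS:
            label = bin_label(bin_)
            idx = [i for i, r in enumerate(corpus)
                   if r.report_type == rtype and length_bin(r.length_chars) == label]
            comparisons: dict[str, ComparisonResult] = {}
            if idx:
                cell_refs = [refs[i] for i in idx]
                ref_hyps = [predictions[reference_system][i] for i in idx]
                for name, hyps in predictions.items():
                    if name == reference_system:
                        continue
                    comparisons[name] = paired_bootstrap(
                        ref_hyps, [hyps[i] for i in idx], cell_refs,
                        n_resamples=n_resamples, seed=seed, alpha=alpha)
            rows.append(SubgroupRow(rtype, label, len(idx), comparisons))
    return rows


# ---------------------------------------------------------------------------
# word / character error rates

def _alignment_counts(ref: Sequence, hyp: Sequence) -> tuple[int, int, int, int]:
    """Levenshtein alignment counts (hits, substitutions, deletions,
    insertions) between a reference and a hypothesis sequence."""
    n, m = len(ref), len(hyp)
    # full dp table with backtracking; annotation strings are short
    dp = np.zeros((n + 1, m + 1), dtype=np.int32)
    dp[:, 0] = np.arange(n + 1)
    dp[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j] = min(dp[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1]),
                           dp[i - 1, j] + 1, dp[i, j - 1] + 1)
    i, j = n, m
    hits = subs = dels = ins = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i, j] == dp[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1]):
            if ref[i - 1] == hyp[j - 1]:
                hits += 1
            else:
                subs += 1
            i, j = i - 1, j - 1
        elif i > 0 and dp[i, j] == dp[i - 1, j] + 1:
            dels += 1
            i -= 1
        else:
            ins += 1
            j -= 1
    return hits, subs, dels, ins


def error_rate_metrics(hypotheses: Sequence[str], references: Sequence[str]) -> dict[str, float]:
    """WER, CER, MER, WIL, WIP over aligned annotation strings.

    Word-level metrics use the same term tokenization as BLEU; CER runs on
    raw characters of the space-joined token strings.  Counts are pooled
    over the corpus before the rates are formed, and WIP = 1 - WIL.
    """
    _check(hypotheses, references)
    H = S = D = I = 0
    cS = cD = cI = cN = 0
    for hyp, ref in zip(hypotheses, references):
        ht, rt = tokenize(hyp), tokenize(ref)
        h, s, d, i = _alignment_counts(rt, ht)
        H, S, D, I = H + h, S + s, D + d, I + i
        hs, rs = " ".join(ht), " ".join(rt)
        _, s, d, i = _alignment_counts(list(rs), list(hs))
        cS, cD, cI, cN = cS + s, cD + d, cI + i, cN + len(rs)
    ref_words = H + S + D
    hyp_words = H + S + I
    wer = (S + D + I) / ref_words if ref_words else 0.0
    cer = (cS + cD + cI) / cN if cN else 0.0
    mer = (S + D + I) / (H + S + D + I) if H + S + D + I else 0.0
    wip = (H / ref_words) * (H / hyp_words) if ref_words and hyp_words else 0.0
    wil = 1.0 - wip
    return {"wer": wer, "cer": cer, "mer": mer, "wil": wil, "wip": wip}
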