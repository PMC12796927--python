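"""BLEU, bootstrap, per-code F1, frequency binning, and error rates."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

import pathocode as pc
from pathocode.metrics import (
    EmptyCorpusError,
    FrequencyBin,
    LengthMismatchError,
    bleu_stats,
    frequency_binned_f1,
    length_bin,
    subgroup_analysis,
    tokenize,
)


# --- independent naive BLEU oracle (written straight from the definition,
# no shared code with the implementation's sufficient-statistics path) ------

def naive_corpus_bleu(hyps, refs) -> float:
    num = [0] * 4
    den = [0] * 4
    hyp_len = ref_len = 0
    for hyp, ref in zip(hyps, refs):
        h = hyp.replace("*", " ").replace("\n", " ").split()
        r = ref.replace("*", " ").replace("\n", " ").split()
        hyp_len += len(h)
        ref_len += len(r)
        for n in range(1, 5):
            hgrams = [tuple(h[i:i + n]) for i in range(len(h) - n + 1)]
            rgrams = Counter(tuple(r[i:i + n]) for i in range(len(r) - n + 1))
            den[n - 1] += len(hgrams)
            clipped = Counter()
            for g in hgrams:
                if clipped[g] < rgrams[g]:
                    clipped[g] += 1
            num[n - 1] += sum(clipped.values())
    if hyp_len == 0:
        return 0.0
    precisions = []
    smooth = 1.0
    for n in range(4):
        if den[n] == 0:
            return 0.0
        if num[n] == 0:
            smooth *= 2.0
            precisions.append(100.0 / (smooth * den[n]))
        else:
            precisions.append(100.0 * num[n] / den[n])
    bp = 1.0 if hyp_len >= ref_len else math.exp(1.0 - ref_len / hyp_len)
    return bp * math.exp(sum(math.log(p) for p in precisions) / 4.0)


def _random_annotation_corpora(n_corpora=100, seed=123):
    rng = np.random.default_rng(seed)
    vocab = [f"w{i}" for i in range(30)] + ["tw o", "thr ee"]
    for _ in range(n_corpora):
        n = int(rng.integers(3, 20))
        hyps, refs = [], []
        for _ in range(n):
            def ann():
                n_series = int(rng.integers(1, 3))
                lines = []
                for _ in range(n_series):
                    k = int(rng.integers(1, 8))
                    lines.append("*".join(vocab[int(i)] for i in rng.integers(0, len(vocab), k)))
                return "\n".join(lines)
            hyps.append(ann())
            refs.append(ann())
        yield hyps, refs


class TestCorpusBleu:
    def test_identical_is_100(self, small_corpus):
        refs = [a.serialize() for a in list(small_corpus.clean_annotations.values())[:40]]
        assert pc.corpus_bleu(refs, refs) == pytest.approx(100.0)

    def test_disjoint_is_near_zero(self):
        hyps = ["a b c d e"] * 10
        refs = ["v w x y z"] * 10
        assert pc.corpus_bleu(hyps, refs) < 1.0

    def test_hand_computed_brevity_penalty_case(self):
        # 4-token hypothesis inside a 5-token reference: all precisions 1,
        # BLEU = 100 * exp(1 - 5/4)
        assert pc.corpus_bleu(["a b c d"], ["a b c d e"]) == \
            pytest.approx(100.0 * math.exp(1 - 5 / 4))

    def test_matches_naive_oracle_on_random_corpora(self):
        for hyps, refs in _random_annotation_corpora(100):
            assert pc.corpus_bleu(hyps, refs) == pytest.approx(
                naive_corpus_bleu(hyps, refs), abs=1e-4)

    def test_separators_are_token_boundaries(self):
        assert pc.corpus_bleu(["a*b\nc d"], ["a b c d"]) == \
            pc.corpus_bleu(["a b c d"], ["a b c d"])

    def test_input_validation(self):
        with pytest.raises(LengthMismatchError):
            pc.corpus_bleu(["a"], ["a", "b"])
        with pytest.raises(EmptyCorpusError):
            pc.corpus_bleu([], [])


class TestPairedBootstrap:
    def test_self_comparison_not_significant(self):
        hyps = [f"a{i} b c d" for i in range(30)]
        refs = [f"a{i} b c x" for i in range(30)]
        cmp_ = pc.paired_bootstrap(hyps, hyps, refs, n_resamples=200, seed=1)
        assert cmp_.direction == "n.s."
        assert cmp_.p_value >= 0.05

    def test_perfect_vs_disjoint_highly_significant(self):
        rng = np.random.default_rng(2)
        refs = [" ".join(f"w{int(i)}" for i in rng.integers(0, 40, 6))
                for _ in range(100)]
        perfect = list(refs)
        disjoint = ["q r s t u v"] * 100
        cmp_ = pc.paired_bootstrap(disjoint, perfect, refs, n_resamples=1000, seed=3)
        assert cmp_.direction == "+"
        assert cmp_.p_value < 0.001
        assert cmp_.system.bleu == pytest.approx(100.0)

    def test_seeded_determinism(self):
        hyps_a = ["a b c d"] * 20
        hyps_b = ["a b x d"] * 20
        refs = ["a b c d"] * 20
        r1 = pc.paired_bootstrap(hyps_a, hyps_b, refs, n_resamples=200, seed=7)
        r2 = pc.paired_bootstrap(hyps_a, hyps_b, refs, n_resamples=200, seed=7)
        assert r1 == r2

    def test_minimum_resamples_enforced(self):
        with pytest.raises(ValueError):
            pc.paired_bootstrap(["a"], ["a"], ["a"], n_resamples=10)


def _ann(*series: str) -> pc.Annotation:
    return pc.parse_annotation("\n".join(series))


class TestPerCodeScores:
    def test_perfect_predictions(self):
        refs = [_ann("a*b*c"), _ann("a*d")]
        scores = pc.per_code_scores(refs, refs)
        assert all(s.f1 == 1.0 for s in scores)

    def test_never_predicted_code_has_zero_recall(self):
        scores = pc.per_code_scores([_ann("a")], [_ann("a*b")])
        by_code = {s.code: s for s in scores}
        assert by_code["b"].recall == 0.0
        assert by_code["b"].f1 == 0.0

    def test_hand_counted_example(self):
        refs = [_ann("a*b"), _ann("a")]
        preds = [_ann("a"), _ann("a*c")]
        by_code = {s.code: s for s in pc.per_code_scores(preds, refs)}
        assert (by_code["a"].tp, by_code["a"].fp, by_code["a"].fn) == (2, 0, 0)
        assert by_code["a"].f1 == 1.0
        assert by_code["b"].fn == 1 and by_code["b"].f1 == 0.0
        assert by_code["c"].fp == 1 and by_code["c"].f1 == 0.0

    def test_conservation_of_reference_counts(self, small_corpus):
        refs = list(small_corpus.clean_annotations.values())[:100]
        preds = list(small_corpus.noised_annotations.values())[:100]
        scores = pc.per_code_scores(preds, refs)
        total_ref = sum(len(a.all_terms()) for a in refs)
        assert sum(s.tp for s in scores) + sum(s.fn for s in scores) == total_ref
        for s in scores:
            assert s.tp + s.fn == s.support

    def test_multiset_semantics_within_report(self):
        # duplicated code: one match, one miss
        by_code = {s.code: s for s in pc.per_code_scores([_ann("a")], [_ann("a*a")])}
        assert (by_code["a"].tp, by_code["a"].fn) == (1, 1)


class TestFrequencyBinning:
    def _scores(self, supports):
        return [pc.CodeScore(code=f"c{i}", support=s, tp=s, fp=0, fn=0)
                for i, s in enumerate(supports)]

    def test_equal_supports_split_evenly(self):
        bins = frequency_binned_f1(self._scores([10] * 6), n_bins=2)
        assert [b.n_codes for b in bins] == [3, 3]

    def test_single_bin_equals_global_mean(self):
        scores = pc.per_code_scores([_ann("a*b")], [_ann("a*c")])
        bins = frequency_binned_f1(scores, n_bins=1)
        assert len(bins) == 1
        assert bins[0].mean_f1 == pytest.approx(
            sum(s.f1 for s in scores) / len(scores))

    def test_zipf_supports_give_decreasing_mean_support(self, small_corpus):
        refs = list(small_corpus.clean_annotations.values())
        preds = list(small_corpus.noised_annotations.values())
        bins = frequency_binned_f1(pc.per_code_scores(preds, refs), n_bins=10)
        mean_supports = [b.mean_support for b in bins]
        assert all(a > b for a, b in zip(mean_supports, mean_supports[1:]))

    def test_support_conservation(self, small_corpus):
        refs = list(small_corpus.clean_annotations.values())
        preds = list(small_corpus.noised_annotations.values())
        scores = pc.per_code_scores(preds, refs)
        bins = frequency_binned_f1(scores, n_bins=20)
        assert sum(b.total_support for b in bins) == sum(s.support for s in scores)


class TestSubgroups:
    def test_bin_boundaries_inclusive(self):
        assert length_bin(0) == "0-80"
        assert length_bin(80) == "0-80"
        assert length_bin(81) == "81-200"
        assert length_bin(200) == "81-200"
        assert length_bin(201) == "201-400"
        assert length_bin(400) == "201-400"
        assert length_bin(401) == "401+"

    def test_twelve_rows_and_identical_systems_ns(self, small_corpus):
        records = small_corpus.reports[:120]
        refs = [small_corpus.clean_annotations[r.report_id].serialize()
                for r in records]
        preds = {"ref_sys": refs, "same": list(refs)}
        rows = subgroup_analysis(records, preds, "ref_sys",
                                 n_resamples=100, seed=0)
        assert len(rows) == 12
        for row in rows:
            for cmp_ in row.comparisons.values():
                assert cmp_.direction == "n.s."

    def test_single_type_corpus_populates_four_rows(self, small_corpus):
        records = [r for r in small_corpus.reports if r.report_type == "S"][:60]
        refs = [small_corpus.clean_annotations[r.report_id].serialize()
                for r in records]
        rows = subgroup_analysis(records, {"a": refs, "b": refs}, "a",
                                 n_resamples=100, seed=0)
        populated = [r for r in rows if r.count > 0]
        assert all(r.report_type == "S" for r in populated)
        assert sum(r.count for r in rows) == len(records)


class TestErrorRates:
    def test_identical_strings(self):
        m = pc.error_rate_metrics(["a*b*c"], ["a*b*c"])
        assert m["wer"] == 0.0 and m["cer"] == 0.0 and m["mer"] == 0.0
        assert m["wip"] == 1.0 and m["wil"] == 0.0

    def test_single_substitution_wer(self):
        m = pc.error_rate_metrics(["a b"], ["a c"])
        assert m["wer"] == pytest.approx(0.5)

    def test_insertion_and_deletion(self):
        assert pc.error_rate_metrics(["a b c"], ["a b"])["wer"] == pytest.approx(0.5)
        assert pc.error_rate_metrics(["a"], ["a b"])["wer"] == pytest.approx(0.5)

    def test_wil_wip_complementarity(self, small_corpus):
        refs = [a.serialize() for a in list(small_corpus.clean_annotations.values())[:30]]
        hyps = [a.serialize() for a in list(small_corpus.noised_annotations.values())[:30]]
        m = pc.error_rate_metrics(hyps, refs)
        assert m["wil"] + m["wip"] == pytest.approx(1.0)
        assert 0.0 <= m["wer"] and 0.0 <= m["cer"] <= 1.0


def test_tokenize_merges_separators():
    assert tokenize("a*b c\nd") == ["a", "b", "c", "d"]
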