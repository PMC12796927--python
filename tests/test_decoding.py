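"""Decoder behavior: mask compliance, determinism, diversity, and
equivalence with brute-force enumeration scoring."""

from __future__ import annotations

import math

import numpy as np
import pytest

import pathocode as pc
from pathocode.dag import EOS
from pathocode.decoding import BigramScorer, UniformScorer

from conftest import WORKED_SAMPLES


def _normalized_path_score(scorer, source: str, path: tuple[str, ...]) -> float:
    """Independent oracle: score a complete root-to-EOS path directly."""
    total = 0.0
    for i, term in enumerate(path):
        total += scorer.score_next(source, path[:i])[term]
    total += scorer.score_next(source, path)[EOS]
    return total / (len(path) + 1)


@pytest.fixture(scope="module")
def worked_scorers(worked_thesaurus):
    anns = [pc.parse_annotation(s, worked_thesaurus) for s in WORKED_SAMPLES]
    bigram = BigramScorer(anns, vocab=worked_thesaurus.terms())
    uniform = UniformScorer(bigram.vocabulary())
    return {"uniform": uniform, "bigram": bigram}


class TestConstrainedDecoding:
    def test_greedy_output_is_an_enumerable_path(self, worked_dag, worked_scorers):
        res = pc.decode("", worked_scorers["uniform"],
                        pc.DecodeParams(mode="greedy"), worked_dag)
        assert res[0].sequence in set(worked_dag.enumerate_paths())

    def test_mask_overrides_out_of_dag_preference(self, worked_dag, worked_scorers):
        # scorer that puts all its mass on a unit the DAG never allows first
        class Hostile:
            def vocabulary(self):
                return ["biopt", EOS] + worked_scorers["uniform"].vocabulary()

            def score_next(self, source, prefix):
                scores = {u: -10.0 for u in self.vocabulary()}
                scores["biopt"] = 0.0  # invalid as an opener: it is a procedure
                return scores

        res = pc.decode("", Hostile(), pc.DecodeParams(), worked_dag)
        for r in res:
            assert worked_dag.is_generatable(r.raw_sequence)

    def test_deterministic_given_same_inputs(self, worked_dag, worked_scorers):
        params = pc.DecodeParams()
        a = pc.decode("src", worked_scorers["bigram"], params, worked_dag)
        b = pc.decode("src", worked_scorers["bigram"], params, worked_dag)
        assert [(r.sequence, r.score) for r in a] == [(r.sequence, r.score) for r in b]

    def test_zero_penalty_equals_plain_beam_search(self, worked_dag, worked_scorers):
        grouped = pc.decode("", worked_scorers["bigram"],
                            pc.DecodeParams(num_beams=6, num_groups=2,
                                            diversity_penalty=0.0), worked_dag)
        plain = pc.decode("", worked_scorers["bigram"],
                          pc.DecodeParams(num_beams=6, num_groups=1,
                                          diversity_penalty=0.0), worked_dag)
        assert {r.sequence for r in grouped} == {r.sequence for r in plain}

    def test_diversity_penalty_spreads_same_step_units(self):
        """With two branches both preferring the same morphology, plain beam
        search picks it twice; the grouped penalty forces the second group
        onto the runner-up at that step."""
        th = pc.Thesaurus(pc.ThesaurusEntry(*e) for e in [
            ("T00001", "a", "T"), ("T00002", "b", "T"),
            ("P00001", "p", "P"), ("P00002", "q", "P"),
            ("M00001", "m1", "M"), ("M00002", "m2", "M"),
        ])
        dag = pc.build_dag(["a*p*m1", "a*p*m2", "b*q*m1", "b*q*m2"], th)

        class FixedUnitScorer:
            prefs = {"m1": -0.1, "m2": -1.0}

            def vocabulary(self):
                return ["a", "b", "p", "q", "m1", "m2", EOS]

            def score_next(self, source, prefix):
                return {u: self.prefs.get(u, -0.5) for u in self.vocabulary()}

        plain = pc.decode("", FixedUnitScorer(),
                          pc.DecodeParams(num_beams=2, num_groups=1,
                                          diversity_penalty=0.0), dag)
        diverse = pc.decode("", FixedUnitScorer(),
                            pc.DecodeParams(num_beams=2, num_groups=2,
                                            diversity_penalty=10.0), dag)
        assert {r.sequence[-1] for r in plain if r.finished} == {"m1"}
        assert {r.sequence[-1] for r in diverse if r.finished} == {"m1", "m2"}

    def test_beam_matches_enumeration_argmax(self, worked_dag, worked_scorers):
        # beam width >= path count must find the best-scoring complete path
        paths = worked_dag.enumerate_paths()
        for name, scorer in worked_scorers.items():
            best_score = max(_normalized_path_score(scorer, "", p) for p in paths)
            ties = [p for p in paths
                    if math.isclose(_normalized_path_score(scorer, "", p), best_score)]
            best = min(ties)  # decoder breaks score ties lexicographically
            res = pc.decode("", scorer,
                            pc.DecodeParams(num_beams=8, num_groups=1,
                                            diversity_penalty=0.0), worked_dag)
            assert res[0].sequence == best, name
            assert math.isclose(res[0].normalized_score,
                                _normalized_path_score(scorer, "", best))

    def test_oracle_equivalence_on_random_dags(self, small_corpus):
        """On randomly grown DAGs with few paths, constrained beam search with
        enough width returns the enumeration argmax of the normalized score."""
        rng = np.random.default_rng(11)
        anns = list(small_corpus.clean_annotations.values())
        profile = pc.RuleProfile(require_procedure=False)
        checked = 0
        for trial in range(50):
            take = rng.choice(len(anns), size=6, replace=False)
            dag = pc.build_dag([anns[i] for i in take], profile=profile)
            paths = dag.enumerate_paths(max_count=201)
            if not paths or len(paths) > 200:
                continue
            scorer = pc.AdversarialScorer(
                [t for p in paths for t in p], seed=int(rng.integers(2**31)))
            best_score = max(_normalized_path_score(scorer, "", p) for p in paths)
            res = pc.decode("", scorer,
                            pc.DecodeParams(num_beams=max(4, len(paths)),
                                            num_groups=1, diversity_penalty=0.0),
                            dag)
            top_finished = [r for r in res if r.finished][0]
            assert math.isclose(top_finished.normalized_score, best_score,
                                rel_tol=1e-12)
            checked += 1
        assert checked >= 30  # most trials must actually exercise the oracle


class TestUnconstrainedDecoding:
    def test_adversarial_scorer_produces_invalid_output(self, worked_dag):
        adv = pc.AdversarialScorer(
            ["huid", "links", "biopt", "excisie"], seed=5)
        res = pc.decode("", adv, pc.DecodeParams(constrained=False, mode="greedy"))
        assert not worked_dag.is_generatable(res[0].raw_sequence)

    def test_requires_dag_when_constrained(self):
        with pytest.raises(ValueError):
            pc.decode("", pc.UniformScorer(["a"]), pc.DecodeParams(constrained=True))


class TestParams:
    def test_beam_group_divisibility(self):
        with pytest.raises(ValueError):
            pc.DecodeParams(num_beams=5, num_groups=2)

    @pytest.mark.parametrize("kwargs", [
        dict(max_length=0), dict(diversity_penalty=-0.1), dict(mode="sample")])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            pc.DecodeParams(**kwargs)


class TestToyScorers:
    def test_uniform_scores_log_inverse_vocab(self):
        s = pc.UniformScorer(["a", "b", "c"])
        scores = s.score_next("", [])
        assert len(scores) == 4  # three units plus EOS
        assert all(math.isclose(v, -math.log(4)) for v in scores.values())

    def test_bigram_prefers_observed_succession(self, worked_thesaurus):
        anns = [pc.parse_annotation(s, worked_thesaurus) for s in WORKED_SAMPLES]
        bigram = BigramScorer(anns)
        after_links = bigram.score_next("", ["huid", "links"])
        # links -> biopt observed twice; links -> excisie never
        assert after_links["biopt"] > after_links["excisie"]

    def test_lexical_bonus_for_terms_in_source(self, worked_thesaurus):
        anns = [pc.parse_annotation(s, worked_thesaurus) for s in WORKED_SAMPLES]
        bigram = BigramScorer(anns)
        lexical = pc.LexicalScorer(bigram, bonus=2.0)
        src = "verslag over de huid van de patient"
        assert lexical.score_next(src, [])["huid"] == \
            pytest.approx(bigram.score_next(src, [])["huid"] + 2.0)
        assert lexical.score_next(src, [])["pleura"] == \
            pytest.approx(bigram.score_next(src, [])["pleura"])

    def test_toy_scorer_bundle(self, small_corpus):
        scorers = pc.toy_scorers(small_corpus.reports, small_corpus.thesaurus)
        assert set(scorers) == {"uniform", "bigram", "lexical"}
        vocab = scorers["bigram"].vocabulary()
        assert EOS in vocab
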