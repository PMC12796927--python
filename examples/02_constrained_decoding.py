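"""Decode annotations for synthetic reports, with and without the DAG mask.

A toy lexical scorer (bigram statistics plus a bonus for terms present in
the conclusion text) stands in for a fine-tuned seq2seq model.  With the
constraint DAG attached, every output is a known-valid series; without it,
an adversarial scorer happily emits rule-violating sequences.
"""

import pathocode as pc
from pathocode.synthdata import GeneratorConfig

corpus = pc.generate(GeneratorConfig(n_reports={"T": 300, "C": 100, "S": 100}), seed=7)
dag = pc.build_dag(list(corpus.clean_annotations.values()),
                   profile=pc.RuleProfile(require_procedure=False))
scorers = pc.toy_scorers(corpus.reports, corpus.thesaurus)

params = pc.DecodeParams()  # 6 beams, 2 groups, diversity penalty 0.3
print("constrained decodes (top beam vs reference):")
for record in corpus.reports[:5]:
    result = pc.decode(record.conclusion, scorers["lexical"], params, dag)[0]
    ref = corpus.clean_annotations[record.report_id].serialize()
    print(f"  ref: {ref!r}")
    print(f"  hyp: {result.annotation_string()!r}"
          f"  (mean log-score {result.normalized_score:.2f}, "
          f"valid: {dag.is_generatable(result.raw_sequence)})")

adversary = pc.AdversarialScorer(corpus.thesaurus.terms(), seed=1)
free = pc.decode("", adversary, pc.DecodeParams(constrained=False, mode="greedy"))[0]
masked = pc.decode("", adversary, pc.DecodeParams(mode="greedy"), dag)[0]
print("\nadversarial scorer, no mask :", free.sequence,
      "-> generatable:", dag.is_generatable(free.raw_sequence))
print("adversarial scorer, masked  :", masked.sequence,
      "-> generatable:", dag.is_generatable(masked.raw_sequence))
# The mask turns an arbitrary preference over units into a valid series:
# the decoder can only follow successions seen in the rule-filtered history.
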