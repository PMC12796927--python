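# Methods

This note documents the models and procedures implemented in `pathocode`,
the parameters that matter, the numerical choices, and the limits of what
the synthetic corpus can show.

## Code series and validity rules

A code series is an ordered sequence of thesaurus units.  Each raw code is
one or more atomic parts, each a category letter in {T, P, M, D, E, F}
followed by uppercase letters/digits; combination codes concatenate several
atomic parts (e.g. a site+procedure pair) and count for every category they
contain.  Parsing splits combinations greedily left-to-right at boundaries
that begin a thesaurus-known atomic code; without a thesaurus, at every
category letter that starts a maximal `[TPMDEF][A-Z0-9]+` run with the
constraint that a part has at least two characters.

`validate_series` checks the minimal requirements: ≥1 topography, ≥1
procedure (waived for report type C, cytology), ≥1 diagnosis-category unit
(M, D, E or F), and the order constraint applied to *first occurrences
only* (first T < first P < first diagnosis, at part granularity).  Units
after the first diagnosis are unrestricted — `T*P*M*T` is valid.  When the
procedure requirement is waived but a procedure still appears before the
first diagnosis, it must follow a topography; a procedure after the first
diagnosis is free, like any other trailing unit.  Term lookup is
case-insensitive with whitespace normalized, tolerating dictation
artifacts.

## The constraint DAG

**Node identity.** Nodes are keyed `(phase, term, dedup_index)` where
*phase* ∈ {TOPOGRAPHY, PROCEDURE, DIAGNOSIS, POST} is the state of the rule
machine when the unit is inserted (POST = anything after the first
diagnosis).  Phase-keying reproduces the intended sharing — a laterality
following two different topographies is a single multi-parent node — while
preventing a term observed in different rule states from merging across
them, which could otherwise let invalid category structures recombine.

**Acyclicity.** Edges never decrease the phase, so cycles could only form
within a phase.  If linking to an existing node would close such a cycle
(checked by same-phase reachability), the successor is duplicated with an
incremented `dedup_index` instead.  Topological sortability is
property-tested under shuffled insertion orders.

**EOS policy.** EOS is recorded on every node whose unit is a morphology
(category M); a configuration widens this to all diagnosis categories
(MDEF).  Because EOS is the only way to terminate, a series whose final
unit cannot carry EOS would leave a leaf the decoder can never finish
from.  The build profile therefore also requires the *final* unit of an
inserted series to be EOS-eligible (`require_terminal_diagnosis`, on by
default); series failing it are counted in `rejected_count` like any other
rule violation.  With this filter, every inserted series is a root-to-EOS
path and constrained decoding can always terminate — dead ends signal a
corrupted DAG, not a reachable state.

**Rule profile.** The profile used at build time defines validity for the
whole structure.  For mixed-type corpora the procedure requirement should
be relaxed (`require_procedure=False`), matching the fact that a single
archive-wide DAG must admit cytology series without procedures; the
termination guarantee ("at least one topography and one morphology") is
unaffected.  Multi-series decoding via an optional series separator token
(valid exactly where EOS is valid, resetting traversal to the root) is
implemented but off by default, since single-sequence serialization of
multi-series annotations is a deployment choice, not part of the core
method.

**Granularity.** The DAG operates on whole annotation units (terms), not
subwords.  A production system with a subword tokenizer would expand each
term into a token path; the desk-scale scorers here treat units as atomic.

## Decoding

`decode` implements greedy search and group-wise diverse beam search over
an abstract scorer contract.  Numerical choices:

- **Masking** is hard: units outside `valid_continuations(prefix)` get −∞
  before top-k selection.  No renormalization is needed because ranking is
  score-based.
- **Diversity.** At each step the expansions of all alive beams form one
  shared candidate pool; beams are selected in `num_groups` sequential
  blocks, and a candidate is penalized by `diversity_penalty` for each
  time its unit was already chosen at the same step by an earlier block
  (Hamming-style penalty).  The penalty steers selection only; accumulated
  beam scores stay raw.  With penalty 0 the block selection without
  replacement is exactly plain beam search — a property the test suite
  relies on.  This shared-pool formulation was chosen over the variant in
  which each group expands only its own beams, precisely to keep the
  zero-penalty case equivalent to plain beam search.
- **Ranking.** Results are ordered by length-normalized total score (mean
  log-score per decision, normalization exponent 1.0; the EOS step counts
  as a decision).  Ties break lexicographically on the term sequence,
  making decoding fully deterministic.
- **Defaults** follow the study conditions: 6 beams, 2 groups, penalty
  0.3, maximum output length 128 units.
- With beam width at least the number of complete paths and zero penalty,
  beam search provably returns the enumeration argmax of the normalized
  score; this is asserted against a brute-force oracle on small DAGs.

**Toy scorers.** `uniform` scores the whole vocabulary equally; `bigram`
uses add-one-smoothed unit bigrams estimated from reference annotations
(per series, with begin and EOS transitions); `lexical` adds a bonus of 6
log-units for units whose term occurs case-insensitively in the conclusion
text *and* has not yet been generated.  The bonus exceeds the spread of
the Zipf prior so that source evidence dominates marginal frequency, and
the coverage condition stops one source mention from rewarding endless
repetition.  An `AdversarialScorer` with a seeded random fixed preference
exists purely to demonstrate that unmasked decoding violates the rules.
These scorers are deliberately crude stand-ins for a fine-tuned
encoder–decoder; they share only its interface.

## Quantitative evaluation

**BLEU.** Annotation strings are mapped to tokens by replacing `*` and
newlines with spaces and splitting on whitespace (tokens are terms and the
words of multi-word terms).  Corpus BLEU-4 sums per-segment clipped n-gram
counts, applies exponential smoothing to zero numerators (halving the
smoothed precision per successive zero order), multiplies by the brevity
penalty `exp(1 − ref_len/hyp_len)` when the hypothesis is shorter, and
reports 0–100.  The implementation is validated against an independently
written naive accumulator on random corpora to 4 decimals plus a
closed-form single-pair case.

**Paired bootstrap.** Item indices are resampled with replacement (default
1000 times); per resample both systems' BLEU is recomputed from cached
per-item sufficient statistics, which makes a resample a row-sum rather
than a re-tokenization.  The CI half-width is half the 2.5–97.5 percentile
range; the p-value is the fraction of resamples whose BLEU difference
contradicts (opposes or ties) the full-data sign, doubled and capped at 1;
directions `+`/`−` are assigned at α = 0.05.  Under simulated null pairs
(two independent corruptions of the same references) the empirical
rejection rate at α = 0.05 is ≈3–5% over 200 corpora of 200 items.  This
recipe is a documented choice; other CI/p-value constructions are equally
defensible.

**Per-code scores.** Within a report, prediction and reference are reduced
to unit multisets pooled over all series (scored on terms by default, raw
codes via a flag); per code, tp is the clipped overlap, fp/fn the
one-sided surpluses, and P/R/F1 come from the micro counts.  This avoids
arbitrary alignment of series between prediction and reference.  The
conservation identity Σtp + Σfn = total reference codes is asserted.

**Frequency binning.** Codes sorted by descending support are cut at equal
increments of cumulative support (boundary codes to the earlier bin);
per-bin unweighted mean F1 and mean support are reported.  Both 10 and 20
bins are supported; 20 is the default.

**Subgroups.** Reports stratify into report type × conclusion length with
inclusive character bins [0, 80], [81, 200], [201, 400], [401, ∞) — 12
cells — each compared against a named reference system with the paired
bootstrap; empty cells carry a count of zero and no statistics.

**Error rates.** WER, MER, WIL and WIP are computed from pooled
hit/substitution/deletion/insertion counts of a Levenshtein alignment on
the same tokens as BLEU; CER on raw characters.  WIP = 1 − WIL by
construction.

## Case-based retrieval

A query is a disjunction of conjunctive clauses; a clause matches a series
iff the series contains every member (term or raw code, order-free), and a
report matches iff any series matches any clause.  Clause scope is
within-series by default — a series is the unit of one coherent diagnosis —
with an `across_series` flag to relax it.  A patient is retrieved iff at
least one of their reports matches.  `compare_retrieval` reports the O/M
set algebra at patient and report level; the partition identities
|O\M| + |O∩M| = |O| and |M\O| + |O∩M| = |M| are asserted on randomized
fixtures.

`classify_miss` is an explicitly heuristic proxy for a manual audit:
NO_CODES for empty output; ABSENCE_OF_RELEVANT_INFORMATION when no query
surface form (member or its thesaurus display term) occurs in the
conclusion; ESSENTIAL_CODE_NOT_RECOGNIZED when at least half of the
model's units match the reference yet a query-required code is missing;
WRONG_CODES otherwise.  It orders audit plumbing, not pathologist
judgment.

## Synthetic corpus generator

The generator emulates the *statistical* shape of a pathology archive, not
its language.  Per seeded run it produces a thesaurus (defaults: 80 T, 40
P, 120 M, 20 D, 10 E, 10 F codes plus ~4% combination codes, with
pronounceable synthetic terms), reports of three types, patients, planted
queries with ground truth, and optionally noised annotations.

- **Code usage** is category-conditional Zipf.  The exponent (default
  1.0) was calibrated once so that at the default vocabulary and a
  10,000-report corpus the top-5 codes carry ≈26% and the top-20 ≈49% of
  all code occurrences, matching the documented skew of archive code
  usage; it is a stored default, not a per-run fit.
- **Series structure** is T⁺P?M⁺ plus unrestricted trailing units, with
  the procedure omitted for cytology with probability 0.3 and every series
  closing on a morphology unit (see the DAG termination rationale).
  Codes-per-annotation medians/IQRs default to 4 (3–5) for histology and
  cytology and 4 (3–8) for autopsy, drawn from a log-normal matched to
  median and IQR.
- **Conclusions** are filler tokens with the annotation's terms embedded
  (80% of terms), shuffled; lengths in tokens follow log-normals matched
  to medians/IQRs of 15 (9–26) histology, 11 (7–17) cytology, 124 (65–207)
  autopsy, with `chars_per_token` (default 7) bridging token lengths to
  the character bins used in subgroup analysis.  The report-type mix
  defaults to 58.7/18.8/22.5% (T/C/S).
- **Patients** partition reports with sizes 1 + Poisson(mean − 1),
  default mean 2 reports per patient.
- **Noise** applies, per annotation with probability `noise_rate`, one
  validity-preserving edit — drop a non-mandatory unit, substitute a
  diagnosis unit by a same-category sibling, or drop an extra series —
  and logs it.  Noised annotations remain 100% rule-valid.

All output is a pure function of (config, seed) and byte-reproducible.

**What the generator does not emulate.** No natural-language grammar, no
real co-occurrence structure between sites and morphologies beyond the
planted series, no temporal drift, no inter-annotator style variation.
Passing tests on this corpus demonstrate the correctness of the machinery
(rule filtering, masking, metrics, set algebra), not clinical performance
on real reports.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
corpora of ~400–1,000 reports for decoding and retrieval checks, 10,000
reports for the frequency-calibration check, 1,000 randomized decodes for
the mask-compliance stress test, 50 small DAGs (≤200 paths) for the
enumeration oracle, and 200 null corpora × 1,000 resamples for bootstrap
calibration.

## Known limitations

- **Held-out regeneration coverage is scale-bound.**  A series is
  generatable iff each of its successions was observed, so held-out
  coverage equals observed-bigram coverage.  Under the calibrated Zipf
  skew this rises from ≈45% at 10k training reports to ≈60% at 30k and
  approaches 1 only at archive scale (~10⁶ records, where the production
  DAG lives).  The suite asserts what desk scale can show: training series
  are always regenerable and coverage grows strictly with history size.
- The toy scorers have no encoder; their BLEU (≈20–25 on synthetic data)
  characterizes the harness, not any learned model.
- Constraint granularity is the whole term; subword-level constraints for
  real tokenizers would need the adapter layer sketched above.
- The bootstrap CI/p-value recipe is one defensible construction among
  several; comparisons across implementations should re-state it.
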