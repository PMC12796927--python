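"""Inspect what the synthetic corpus generator produces.

The generator emulates the statistical shape of a pathology archive: three
report types with distinct length and codes-per-annotation distributions,
a Zipf-skewed code usage, patients owning several reports, and optional
annotation noise — everything seeded and byte-reproducible.
"""

import statistics
from collections import Counter

import pathocode as pc
from pathocode.synthdata import GeneratorConfig

config = GeneratorConfig(n_reports={"T": 1174, "C": 376, "S": 450})
corpus = pc.generate(config, seed=2)

print(f"{len(corpus.reports)} reports, {len(corpus.patients)} patients, "
      f"thesaurus of {len(corpus.thesaurus)} codes")

for rtype, label in [("T", "histology"), ("C", "cytology"), ("S", "autopsy")]:
    lengths = [len(r.conclusion.split()) for r in corpus.reports
               if r.report_type == rtype]
    n_codes = [len(corpus.clean_annotations[r.report_id].all_terms())
               for r in corpus.reports if r.report_type == rtype]
    print(f"  {label:>9}: n={len(lengths):>4}, "
          f"median conclusion length {statistics.median(lengths):>5.0f} tokens "
          f"(target {config.lengths[rtype][0]}), "
          f"median codes {statistics.median(n_codes):.0f}")

counts = Counter(u.code.raw for a in corpus.clean_annotations.values()
                 for s in a.series for u in s.units)
total = sum(counts.values())
top = counts.most_common(20)
print(f"\ncode usage skew: top-5 = {100 * sum(c for _, c in top[:5]) / total:.1f}% "
      f"of all {total} code occurrences, "
      f"top-20 = {100 * sum(c for _, c in top) / total:.1f}%")

valid = sum(pc.validate_series(s, r.report_type).valid
            for r in corpus.reports
            for s in corpus.clean_annotations[r.report_id].series)
n_series = sum(len(a.series) for a in corpus.clean_annotations.values())
print(f"rule-valid series: {valid}/{n_series}")
print(f"noise edits applied: {len(corpus.noise_log)} "
      f"(rate {config.noise_rate}); noised annotations stay rule-valid")
multi = sum(len(a.series) > 1 for a in corpus.clean_annotations.values())
print(f"multi-series annotations: {multi} "
      f"({100 * multi / len(corpus.reports):.0f}% of reports)")
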