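"""Build a constraint DAG from three historical annotations and query it.

The DAG stores every observed, rule-valid code series as a root-to-EOS
path.  During generation it answers "which units may follow this prefix",
which is what turns a free seq2seq decoder into one that cannot hallucinate
codes or break the topography -> procedure -> diagnosis rules.
"""

import pathocode as pc

entries = [
    ("T01000", "huid", "T"), ("T02000", "pleura", "T"), ("TYY980", "links", "T"),
    ("P11200", "excisie", "P"), ("P11400", "biopt", "P"),
    ("M01000", "dermale naevus", "M"), ("M02000", "verruca seborrhoica", "M"),
    ("M03000", "ontsteking", "M"), ("M04000", "geen afwijking", "M"),
]
thesaurus = pc.Thesaurus(pc.ThesaurusEntry(*e) for e in entries)

history = [
    "huid*excisie*dermale naevus",
    "huid*links*biopt*verruca seborrhoica*ontsteking",
    "pleura*links*biopt*geen afwijking",
]
dag = pc.build_dag(history, thesaurus)

print("inserted series:", dag.source_count, "| nodes:", dag.node_count())
print("openers:", sorted(dag.valid_continuations([])))
print("after [huid]:", sorted(dag.valid_continuations(["huid"])))
print("after [huid, links, biopt]:",
      sorted(dag.valid_continuations(["huid", "links", "biopt"])))
print("may stop after 'verruca seborrhoica':",
      pc.EOS in dag.valid_continuations(
          ["huid", "links", "biopt", "verruca seborrhoica"]))

paths = dag.enumerate_paths()
print(f"\nall {len(paths)} generatable series:")
for p in paths:
    print("  " + "*".join(p))

# The two opener terms are the two observed topographies; 'links' is shared
# between them (one node, two parents), and recombination of the shared
# biopsy branch is why 3 inserted series yield 7 generatable ones.
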