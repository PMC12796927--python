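"""Shared fixtures: the three-sample worked-example DAG and a small
deterministic synthetic corpus."""

from __future__ import annotations

import pytest

import pathocode as pc
from pathocode.synthdata import GeneratorConfig

#: the three-sample annotation set whose staged DAG construction the tool's
#: documentation walks through (skin/pleura biopsies)
WORKED_SAMPLES = [
    "huid*excisie*dermale naevus",
    "huid*links*biopt*verruca seborrhoica*ontsteking",
    "pleura*links*biopt*geen afwijking",
]

WORKED_ENTRIES = [
    ("T01000", "huid", "T"),
    ("T02000", "pleura", "T"),
    ("TYY980", "links", "T"),
    ("P11200", "excisie", "P"),
    ("P11400", "biopt", "P"),
    ("M01000", "dermale naevus", "M"),
    ("M02000", "verruca seborrhoica", "M"),
    ("M03000", "ontsteking", "M"),
    ("M04000", "geen afwijking", "M"),
]


@pytest.fixture(scope="session")
def worked_thesaurus() -> pc.Thesaurus:
    return pc.Thesaurus(pc.ThesaurusEntry(*e) for e in WORKED_ENTRIES)


@pytest.fixture(scope="session")
def worked_dag(worked_thesaurus) -> pc.AnnotationDAG:
    return pc.build_dag(WORKED_SAMPLES, worked_thesaurus)


@pytest.fixture(scope="session")
def small_corpus() -> "pc.synthdata.SyntheticCorpus":
    """~400 reports, enough structure for decoding/evaluation tests."""
    config = GeneratorConfig(n_reports={"T": 235, "C": 75, "S": 90})
    return pc.generate(config, seed=20250929 % 2**31)


@pytest.fixture(scope="session")
def small_dag(small_corpus) -> pc.AnnotationDAG:
    profile = pc.RuleProfile(require_procedure=False)
    return pc.build_dag(list(small_corpus.clean_annotations.values()), profile=profile)
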