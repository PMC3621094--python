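"""Shared fixtures.

The planted-genome recovery dataset (20 decayed proviruses on their own
scaffolds plus 50 provirus-free decoys) is expensive to search, so it is
built once per session and shared by the pipeline-recovery and acceptance
tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import pytest

from proviscan import references
from proviscan.pipeline import delineate_and_annotate
from proviscan.search import intersect_gene_hits, search_genome
from proviscan.simulate import simulate_genome

MEGABAT_R = 4.0e-10

# ages chosen so LTR-pair divergence 2·R·T spans ~0.004–0.056 (all <= 0.06)
RECALL_AGES_MYR = [5, 8, 11, 14, 17, 20, 23, 26, 29, 32, 35, 38, 41, 44, 47,
                   50, 55, 60, 65, 70]


@dataclass
class RecallRun:
    scaffolds: list
    truths: list
    hits: object
    loci: list
    records: list


@pytest.fixture(scope="session")
def recall_run() -> RecallRun:
    groups = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
    plants = [{"group": groups[i % 8], "rate_R": MEGABAT_R,
               "age_years": RECALL_AGES_MYR[i] * 1e6}
              for i in range(20)]
    scaffolds, truths = simulate_genome(plants, n_decoys=50, decoy_length=6000,
                                        seed=20)
    hits = search_genome(references.search_queries(), scaffolds)
    by = {g: hits[hits.gene == g] for g in ("gag", "pol", "env")}
    loci = intersect_gene_hits(by["gag"], by["pol"], by["env"],
                               scaffold_lengths={s.id: len(s) for s in scaffolds})
    by_id = {s.id: s for s in scaffolds}
    records = [delineate_and_annotate(by_id[locus.scaffold_id], locus,
                                      f"rec_{k}", run_repeat_search=False)
               for k, locus in enumerate(loci)]
    return RecallRun(scaffolds, truths, hits, loci, records)
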