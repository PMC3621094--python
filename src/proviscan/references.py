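"""Access to the packaged reference fixtures.

The package ships deterministic synthetic stand-ins for the betaretroviral
reference set (Gag/Pro/Pol/Env polyproteins with the conserved motif blocks,
Pol lineage variants acting as phylogenetic-placement anchors, a distinct
gammaretroviral Env lineage, and lysine-tRNA 3'-end 18-mers); see
``scripts/build_reference_fixtures.py`` for how they are generated.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

GENES = ("gag", "pro", "pol", "env")


def _data(name: str) -> str:
    return resources.files("proviscan").joinpath("data").joinpath(name).read_text()


def read_fasta_str(text: str) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    return records


@lru_cache(maxsize=None)
def ref_proteins() -> dict[str, str]:
    return read_fasta_str(_data("ref_proteins.synthetic.faa"))


@lru_cache(maxsize=None)
def ref_cds() -> dict[str, str]:
    return read_fasta_str(_data("ref_cds.synthetic.fna"))


@lru_cache(maxsize=None)
def trna_library() -> dict[str, str]:
    """Lysine-tRNA 3'-end 18-mers, keyed Lys1_2 / Lys3 / LysAlt."""
    return read_fasta_str(_data("trna_lys.synthetic.fa"))


@dataclass(frozen=True)
class MotifDef:
    motif_id: str
    gene: str
    ref_start: int
    pattern: str
    key_positions: tuple[int, ...]


@lru_cache(maxsize=None)
def motif_table() -> tuple[MotifDef, ...]:
    rows = []
    for line in _data("motifs.tsv").splitlines()[1:]:
        if not line.strip():
            continue
        mid, gene, start, pattern, keys = line.split("\t")
        rows.append(MotifDef(mid, gene, int(start), pattern,
                             tuple(int(k) for k in keys.split(","))))
    return tuple(rows)


@lru_cache(maxsize=None)
def clade_rates() -> dict[str, float]:
    """Per-clade neutral substitution rates (substitutions/site/year)."""
    return {k: float(v) for k, v in yaml.safe_load(_data("rates.yaml")).items()}


def search_queries() -> dict[str, list[tuple[str, str]]]:
    """Default per-gene protein query sets for the translated search.

    env carries both the betaretroviral and the gammaretroviral reference so
    gamma-env recombinant proviruses are found too.
    """
    prots = ref_proteins()
    return {
        "gag": [("GAG", prots["GAG"])],
        "pol": [("POL", prots["POL"])],
        "env": [("ENVB", prots["ENVB"]), ("ENVG", prots["ENVG"])],
    }


def pol_lineage_refs() -> dict[str, str]:
    return {k.removeprefix("POL_"): v
            for k, v in ref_proteins().items() if k.startswith("POL_")}


def env_lineage_refs() -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    prots = ref_proteins()
    beta = [(k, v) for k, v in prots.items() if k.startswith("ENVB")]
    gamma = [(k, v) for k, v in prots.items() if k.startswith("ENVG")]
    return beta, gamma


def gene_reference_cds(gene: str) -> str:
    """The ancestral coding sequence for a core gene (env: betaretroviral)."""
    key = {"gag": "GAG", "pro": "PRO", "pol": "POL", "env": "ENVB"}[gene]
    return ref_cds()[key]
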