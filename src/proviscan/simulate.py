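"""Synthetic genome scaffolds with planted, neutrally decayed proviruses.

A provirus is assembled as 5'LTR – PBS/leader – gag – pro – pol – env
(– extra ORFs) – PPT – 3'LTR with the two LTR copies exactly identical, then
planted into a background scaffold behind a 4-nt target-site duplication
(TSD) and aged by a neutral substitution/indel process.  Because both LTR
copies are present in the planted sequence and every site mutates
independently at rate_R × age_T substitutions per site, the expected
5'-vs-3' LTR divergence is 2·R·T — the generative direction of the
molecular-clock estimator T = (D/R)/2.

Everything is driven by explicit seeds and returns a ground-truth record
(:class:`PlantTruth`) so downstream recovery can be scored exactly.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from proviscan import references
from proviscan.seqtools import BASES, purine_fraction, random_dna, revcomp

PLACEMENTS = ("pre-gag", "in-frame-overlap", "post-env", "in-3ltr")
_STOPS = {"TAA", "TAG", "TGA"}

#: all-purine 19-mer; the scale of naturally annotated betaretroviral PPTs
DEFAULT_PPT = "AGGAAGGGGAAAGAAAGGG"

# offset of the engineered +1-frame ATG inside the betaretroviral env CDS
# (see scripts/build_reference_fixtures.py)
_ENV_OVERLAP_ATG = 1624


@dataclass
class SyntheticScaffold:
    id: str
    sequence: str
    n_runs: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProvirusTemplate:
    """Blueprint for one provirus; `gene_block` maps gene -> coding DNA."""

    name: str
    ltr_seq: str
    pbs_trna: str
    gene_block: dict[str, str]
    ppt_seq: str = DEFAULT_PPT
    extra_orfs: list[tuple[str, int]] = field(default_factory=list)
    env_lineage: str = "beta"
    group_label: str = "unclassified"

    def __post_init__(self) -> None:
        n_in_ltr = sum(3 * n + 3 for p, n in self.extra_orfs if p == "in-3ltr")
        final_ltr = len(self.ltr_seq) + n_in_ltr
        if not 300 <= final_ltr <= 1400:
            raise ValueError(f"LTR length {final_ltr} outside [300, 1400]")
        if self.pbs_trna not in references.trna_library():
            raise ValueError(f"unknown PBS tRNA {self.pbs_trna!r}")
        if list(self.gene_block) != ["gag", "pro", "pol", "env"]:
            raise ValueError("gene_block must contain gag, pro, pol, env in order")
        if len(self.ppt_seq) < 15 or purine_fraction(self.ppt_seq) < 0.85:
            raise ValueError("ppt_seq must be >=15 nt and purine-rich")
        for placement, _ in self.extra_orfs:
            if placement not in PLACEMENTS:
                raise ValueError(f"unknown ORF placement {placement!r}")


@dataclass
class DecayParams:
    """Neutral post-integration decay: R substitutions/site/year for T years."""

    rate_R: float
    age_T: float
    indel_rate: float = 0.05  # indel events per substitution event
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_R <= 0:
            raise ValueError("rate_R must be > 0")
        if self.age_T < 0:
            raise ValueError("age_T must be >= 0")
        if not 0 <= self.indel_rate <= 0.2:
            raise ValueError("indel_rate must be in [0, 0.2]")


@dataclass
class PlantTruth:
    """Ground truth for one planted provirus (scaffold coordinates, 0-based half-open)."""

    scaffold_id: str
    insert_pos: int
    tsd: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    element_spans: dict[str, tuple[int, int]]
    events: dict[str, list[tuple[str, int, int]]]
    ltr_divergence: float
    template_name: str
    group_label: str = "unclassified"


def _template_rng(name: str, salt: str = "") -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(f"{name}/{salt}".encode()) % 2**31)


def make_background(length: int, gc: float, n_run_spec: list[tuple[int, int]],
                    seed: int | np.random.Generator = 0,
                    scaffold_id: str = "scaffold") -> SyntheticScaffold:
    """I.i.d. background scaffold with optional N-runs (non-sequenced regions)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = list(random_dna(length, gc, rng))
    for s, e in n_run_spec:
        if not (0 <= s < e <= length):
            raise ValueError(f"N-run span ({s}, {e}) outside sequence")
        seq[s:e] = "N" * (e - s)
    return SyntheticScaffold(scaffold_id, "".join(seq), sorted(n_run_spec))


def _nonstop_codons(n: int, rng: np.random.Generator) -> str:
    out = []
    while len(out) < n:
        codon = "".join(BASES[i] for i in rng.integers(0, 4, 3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _orf_dna(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + (n_codons - 1) non-stop codons + TAA."""
    return "ATG" + _nonstop_codons(n_codons - 1, rng) + "TAA"


def _overlap_orf_tail(env_cds: str, n_codons: int, rng: np.random.Generator) -> str:
    """DNA appended after env so an ORF starting at the engineered +1-frame
    ATG inside env runs for n_codons codons, ending with a stop."""
    orf_start = _ENV_OVERLAP_ATG
    overlap = len(env_cds) - orf_start
    tail = []
    # complete the codon that straddles the env/tail boundary without making a stop
    partial = overlap % 3
    if partial:
        prefix = env_cds[orf_start + overlap - partial:]
        while True:
            fill = "".join(BASES[i] for i in rng.integers(0, 4, 3 - partial))
            if prefix + fill not in _STOPS:
                tail.append(fill)
                break
    codons_so_far = (len(env_cds) - orf_start + len("".join(tail))) // 3
    if codons_so_far >= n_codons:
        raise ValueError("overlap ORF shorter than the env overlap itself")
    tail.append(_nonstop_codons(n_codons - codons_so_far, rng))
    tail.append("TAA")
    return "".join(tail)


def build_provirus(template: ProvirusTemplate) -> tuple[str, dict[str, tuple[int, int]]]:
    """Assemble the proviral DNA and an element->span annotation map.

    The 5' and 3' LTR copies are exactly identical (age 0); all filler
    sequence is derived deterministically from the template name.
    """
    rng = _template_rng(template.name, "assembly")
    trna = references.trna_library()[template.pbs_trna]
    pbs = revcomp(trna)

    ltr = template.ltr_seq
    orf_in_ltr_span = None
    for placement, n in template.extra_orfs:
        if placement == "in-3ltr":
            orf = _orf_dna(n, rng)
            off = len(ltr) // 3
            ltr = ltr[:off] + orf + ltr[off:]
            orf_in_ltr_span = (off, off + len(orf))  # relative to LTR start

    parts: list[str] = []
    spans: dict[str, tuple[int, int]] = {}

    def add(name: str | None, seq: str) -> tuple[int, int]:
        start = sum(len(p) for p in parts)
        parts.append(seq)
        if name is not None:
            spans[name] = (start, start + len(seq))
        return (start, start + len(seq))

    add("ltr5", ltr)
    add("pbs", pbs)
    pregag = [n for p, n in template.extra_orfs if p == "pre-gag"]
    if pregag:
        add(None, random_dna(20, 0.5, rng))
        add("orf:pre-gag", _orf_dna(pregag[0], rng))
        add(None, random_dna(26, 0.5, rng))  # ORF ends 26 nt upstream of gag
    else:
        add(None, random_dna(62, 0.5, rng))

    for gene in ("gag", "pro", "pol"):
        add(gene, template.gene_block[gene])
        add(None, random_dna(30, 0.5, rng))
    env_span = add("env", template.gene_block["env"])

    overlap = [n for p, n in template.extra_orfs if p == "in-frame-overlap"]
    if overlap:
        tail = _overlap_orf_tail(template.gene_block["env"], overlap[0], rng)
        tail_span = add(None, tail)
        spans["orf:in-frame-overlap"] = (env_span[0] + _ENV_OVERLAP_ATG, tail_span[1])

    postenv = [n for p, n in template.extra_orfs if p == "post-env"]
    if postenv:
        add(None, random_dna(40, 0.5, rng))
        add("orf:post-env", _orf_dna(postenv[0], rng))

    # pyrimidine cap so the polypurine tract has a crisp upstream boundary
    add(None, random_dna(26, 0.5, rng) + "CTCT")
    add("ppt", template.ppt_seq)
    ltr3_span = add("ltr3", ltr)
    if orf_in_ltr_span is not None:
        spans["orf:in-3ltr"] = (ltr3_span[0] + orf_in_ltr_span[0],
                                ltr3_span[0] + orf_in_ltr_span[1])

    dna = "".join(parts)
    assert dna[spans["ltr5"][0]:spans["ltr5"][1]] == dna[spans["ltr3"][0]:spans["ltr3"][1]]
    return dna, spans


_HOMOPOLYMERS = {b * 4 for b in BASES}


def _draw_tsd(rng: np.random.Generator) -> str:
    while True:
        tsd = "".join(BASES[i] for i in rng.integers(0, 4, 4))
        if tsd not in _HOMOPOLYMERS:
            return tsd


def plant(scaffold: SyntheticScaffold, provirus: str,
          annotation: dict[str, tuple[int, int]], decay: DecayParams,
          insert_pos: int | None = None) -> tuple[SyntheticScaffold, PlantTruth]:
    """Insert a provirus behind a duplicated 4-nt target site and age it.

    Each site receives Poisson(R·T) substitution events and a Bernoulli
    indel (length 1–3) at indel_rate × R·T; both LTR copies are part of the
    planted sequence, so they decay independently and their expected pairwise
    divergence is 2·R·T.
    """
    rng = np.random.default_rng(decay.seed)
    L = len(provirus)
    p_site = decay.rate_R * decay.age_T

    cells: list[str] = list(provirus)
    events_at: list[tuple[str, int, int]] = []

    n_subs = rng.poisson(p_site, size=L)
    for i in np.nonzero(n_subs)[0]:
        base = cells[i]
        for _ in range(int(n_subs[i])):
            new = BASES[int(rng.integers(0, 4))]
            while new == base:
                new = BASES[int(rng.integers(0, 4))]
            base = new
        if base != provirus[i]:
            cells[i] = base
            events_at.append(("substitution", int(i), 1))

    if decay.indel_rate > 0 and p_site > 0:
        hit = np.nonzero(rng.random(L) < decay.indel_rate * p_site)[0]
        for i in hit:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                ins = "".join(BASES[j] for j in rng.integers(0, 4, size))
                cells[i] = cells[i] + ins
                events_at.append(("insertion", int(i), size))
            else:
                for j in range(i, min(i + size, L)):
                    cells[j] = ""
                events_at.append(("deletion", int(i), min(i + size, L) - i))

    lengths = np.fromiter((len(c) for c in cells), dtype=np.int64, count=L)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    mutated = "".join(cells)

    # realized LTR-pair divergence over substitution-only columns
    (s5, e5), (s3, e3) = annotation["ltr5"], annotation["ltr3"]
    sites = diffs = 0
    for a, b in zip(range(s5, e5), range(s3, e3)):
        if len(cells[a]) == 1 and len(cells[b]) == 1:
            sites += 1
            diffs += cells[a] != cells[b]
    divergence = diffs / sites if sites else 0.0

    if insert_pos is None:
        margin = 500 if len(scaffold) > 1000 else 1
        candidates = [p for p in range(margin, len(scaffold) - margin)
                      if not any(s - 4 <= p < e + 4 for s, e in scaffold.n_runs)]
        insert_pos = int(rng.choice(candidates))
    if any(s <= insert_pos < e for s, e in scaffold.n_runs):
        raise ValueError("insertion site inside an N-run")

    tsd = _draw_tsd(rng)
    new_seq = (scaffold.sequence[:insert_pos] + tsd + mutated + tsd
               + scaffold.sequence[insert_pos:])
    offset = insert_pos + len(tsd)
    inserted_len = 2 * len(tsd) + len(mutated)
    new_runs = [(s, e) if e <= insert_pos else (s + inserted_len, e + inserted_len)
                for s, e in scaffold.n_runs]

    element_spans = {name: (offset + int(cum[s]), offset + int(cum[e]))
                     for name, (s, e) in annotation.items()}
    events: dict[str, list[tuple[str, int, int]]] = {n: [] for n in annotation}
    for kind, pos, size in events_at:
        for name, (s, e) in annotation.items():
            if s <= pos < e:
                events[name].append((kind, pos - s, size))

    truth = PlantTruth(
        scaffold_id=scaffold.id,
        insert_pos=insert_pos,
        tsd=tsd,
        ltr5=element_spans["ltr5"],
        ltr3=element_spans["ltr3"],
        element_spans=element_spans,
        events=events,
        ltr_divergence=divergence,
        template_name="",
    )
    return SyntheticScaffold(scaffold.id, new_seq, new_runs), truth


def make_transcripts(provirus: str, fragment_lengths: list[int], overlap: int,
                     id_prefix: str = "transcript"
                     ) -> list[tuple[str, str, tuple[int, int]]]:
    """Tile the provirus into overlapping transcript fragments.

    Consecutive fragments share exactly `overlap` identical nucleotides; the
    tiling must cover the provirus end to end.
    """
    if any(f > len(provirus) for f in fragment_lengths):
        raise ValueError("fragment longer than the provirus")
    if len(fragment_lengths) > 1:
        if overlap <= 0:
            raise ValueError("overlap must be positive when merging is intended")
        if overlap >= min(fragment_lengths):
            raise ValueError("overlap must be smaller than every fragment")
    out = []
    start = 0
    for k, flen in enumerate(fragment_lengths):
        end = start + flen
        if end > len(provirus):
            raise ValueError("fragments extend past the provirus")
        out.append((f"{id_prefix}_{k + 1}", provirus[start:end], (start, end)))
        start = end - overlap
    if out and out[-1][2][1] != len(provirus):
        raise ValueError("fragments do not tile the provirus end to end")
    return out


# ---------------------------------------------------------------------------
# canonical templates: one per betaretroviral sub-group (I–VIII)
# ---------------------------------------------------------------------------

_GROUP_SPECS = {
    # group: (ltr_len, pbs, pol ref, env ref, extra orfs)
    "I":    (968,  "Lys1_2", "POL_HERVK",      "ENVB", []),
    "II":   (422,  "Lys1_2", "POL_EARLYBAT",   "ENVB", []),
    "III":  (479,  "Lys3",   "POL_MICROBAT",   "ENVB", []),
    "IV":   (440,  "LysAlt", "POL_TYPEB",      "ENVB", [("pre-gag", 110)]),
    "V":    (1265, "Lys3",   "POL_TYPEB",      "ENVB", [("in-3ltr", 123)]),
    "VI":   (398,  "Lys1_2", "POL_TYPED_JSRV", "ENVB", [("in-frame-overlap", 110)]),
    "VII":  (370,  "Lys3",   "POL_TYPED_JSRV", "ENVB", [("pre-gag", 101)]),
    "VIII": (427,  "Lys1_2", "POL_TYPED_MPMV", "ENVG", [("post-env", 90)]),
}


def make_group_template(group: str, name: str | None = None) -> ProvirusTemplate:
    """A provirus template with the defining architecture of one sub-group."""
    ltr_len, pbs, pol_key, env_key, orfs = _GROUP_SPECS[group]
    name = name or f"group{group}"
    cds = references.ref_cds()
    in_ltr = sum(3 * n + 3 for p, n in orfs if p == "in-3ltr")
    # canonical retroviral att sites: LTRs begin TG and end CA
    ltr = "TG" + random_dna(ltr_len - in_ltr - 4, 0.45, _template_rng(name, "ltr")) + "CA"
    return ProvirusTemplate(
        name=name,
        ltr_seq=ltr,
        pbs_trna=pbs,
        gene_block={"gag": cds["GAG"], "pro": cds["PRO"],
                    "pol": cds[pol_key], "env": cds[env_key]},
        extra_orfs=list(orfs),
        env_lineage="gamma" if env_key == "ENVG" else "beta",
        group_label=group,
    )


def canonical_templates() -> dict[str, ProvirusTemplate]:
    return {g: make_group_template(g) for g in _GROUP_SPECS}


def simulate_genome(plants: list[dict], n_decoys: int = 0, decoy_length: int = 6000,
                    background_length: int = 6000, gc: float = 0.42,
                    seed: int = 0) -> tuple[list[SyntheticScaffold], list[PlantTruth]]:
    """Build a small genome: one scaffold per plant plus provirus-free decoys.

    Each plant dict has keys ``group``, ``rate_R``, ``age_years`` and
    optionally ``indel_rate``, ``n_runs``.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(2 * len(plants) + n_decoys + 1) % 2**31
    scaffolds: list[SyntheticScaffold] = []
    truths: list[PlantTruth] = []
    for k, spec in enumerate(plants):
        template = make_group_template(spec["group"], name=f"plant{k}_{spec['group']}")
        dna, ann = build_provirus(template)
        bg = make_background(background_length, gc, spec.get("n_runs", []),
                             seed=int(child[2 * k]), scaffold_id=f"scaffold_{k:03d}")
        decay = DecayParams(rate_R=spec["rate_R"], age_T=spec["age_years"],
                            indel_rate=spec.get("indel_rate", 0.05),
                            seed=int(child[2 * k + 1]))
        scaffold, truth = plant(bg, dna, ann, decay)
        truth.template_name = template.name
        truth.group_label = template.group_label
        scaffolds.append(scaffold)
        truths.append(truth)
    for d in range(n_decoys):
        scaffolds.append(make_background(
            decoy_length, gc, [], seed=int(child[2 * len(plants) + d]),
            scaffold_id=f"decoy_{d:03d}"))
    return scaffolds, truths
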