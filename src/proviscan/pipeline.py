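"""End-to-end orchestration: simulate/load → search → delineate → annotate →
date → classify, with seeded determinism and tabular reporting.

All per-provirus coordinates in a :class:`ProvirusRecord` are in the
*oriented locus frame*: positions within the candidate locus sequence,
read 5'→3' along the provirus (for minus-strand loci the locus is reverse
complemented first).  `locus_span`/`strand` anchor that frame on the
scaffold; for plus-strand records scaffold coordinates are obtained by
adding ``locus_span[0]``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from proviscan import io as pio
from proviscan import references
from proviscan.align import align_local, nucleotide_aligner
from proviscan.annotate import (
    GeneState,
    OrfRecord,
    PbsCall,
    assign_pbs,
    call_gene_state,
    classify_placement,
    dutpase_present,
    find_orfs,
    find_repeats,
    pick_reference_cds,
    reconstruct_protein,
    scan_motifs,
)
from proviscan.classify import (
    FeatureVector,
    GroupLabel,
    classify_group,
    env_lineage,
    ltr_length_class,
    pol_proxy,
)
from proviscan.dating import clade_rate, estimate_age, ltr_divergence
from proviscan.delineate import (
    LTRPair,
    PptCall,
    SelfAlignParams,
    TsdCall,
    find_ltr_pair,
    find_ppt,
    find_tsd,
    snap_edges_to_tsd,
)
from proviscan.search import (
    AlignmentParams,
    CandidateLocus,
    intersect_gene_hits,
    search_genome,
)
from proviscan.seqtools import revcomp
from proviscan.simulate import SyntheticScaffold, simulate_genome

GENES = ("gag", "pro", "pol", "env")


@dataclass
class RunConfig:
    """Everything a run needs; every field has a usable default."""

    input_fasta: str | None = None
    simulate: dict | None = None  # kwargs for simulate.simulate_genome
    clade: str = "megabat"
    seed: int = 0
    out_dir: str | None = None
    evalue_cutoff: float = 1e-10
    max_locus_span: int = 15000
    locus_flank: int = 2000
    min_orf_codons: int = 100
    run_repeat_search: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


@dataclass
class ProvirusRecord:
    """Machine-readable provirus description (one summary-table row)."""

    id: str
    scaffold: str
    strand: str
    locus_span: tuple[int, int]
    ltr_pair: LTRPair | None = None
    tsd: TsdCall | None = None
    ppt: PptCall | None = None
    pbs: PbsCall | None = None
    gene_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    gene_states: dict[str, GeneState] = field(default_factory=dict)
    orfs: list[OrfRecord] = field(default_factory=list)
    motif_ids: list[str] = field(default_factory=list)
    dutpase: bool = False
    divergence: float | None = None
    age_myr: float | None = None
    group: str = "unclassified"
    group_trace: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def genome_size(self) -> int | None:
        if self.ltr_pair is None:
            return None
        return self.ltr_pair.ltr3[1] - self.ltr_pair.ltr5[0]

    @property
    def extra_orf_count(self) -> int:
        return sum(o.placement not in ("core", "gene-fragment", "other")
                   for o in self.orfs)


@dataclass
class RunReport:
    seed: int
    n_scaffolds: int = 0
    n_hits: int = 0
    n_loci: int = 0
    n_proviruses: int = 0
    n_dated: int = 0
    n_classified: int = 0
    records: list[ProvirusRecord] = field(default_factory=list)


def _oriented_locus(scaffold_seq: str, locus: CandidateLocus
                    ) -> tuple[str, dict[str, tuple[int, int]]]:
    s0, s1 = locus.span
    seq = scaffold_seq[s0:s1]
    spans = {g: (a - s0, b - s0) for g, (a, b) in locus.gene_spans.items()}
    if locus.strand == "-":
        L = len(seq)
        seq = revcomp(seq)
        spans = {g: (L - b, L - a) for g, (a, b) in spans.items()}
    return seq, spans


def _locate_pro(olocus: str, gag_span, pol_span) -> tuple[int, int] | None:
    """pro is not a search gene; find it between gag and pol by reference alignment."""
    lo = max(0, gag_span[1] - 45)
    hi = min(len(olocus), pol_span[0] + 45)
    if hi - lo < 150:
        return None
    region = olocus[lo:hi]
    hit = align_local(references.ref_cds()["PRO"], region, nucleotide_aligner(mode="local"))
    if hit is None or hit.aligned_columns < 300:
        return None
    return (lo + hit.target_span[0], lo + hit.target_span[1])


def delineate_and_annotate(scaffold: SyntheticScaffold, locus: CandidateLocus,
                           rec_id: str, clade: str = "megabat",
                           min_orf_codons: int = 100,
                           run_repeat_search: bool = True,
                           self_params: SelfAlignParams | None = None
                           ) -> ProvirusRecord:
    """Full per-locus analysis; coordinates in the oriented locus frame."""
    rec = ProvirusRecord(id=rec_id, scaffold=scaffold.id, strand=locus.strand,
                         locus_span=locus.span)
    olocus, gene_spans = _oriented_locus(scaffold.sequence, locus)

    pair = find_ltr_pair(olocus, gene_spans, self_params)
    if pair is None:
        rec.notes.append("no qualifying LTR pair: betaretrovirus-like retroelement")
        return rec
    pair = snap_edges_to_tsd(olocus, pair)
    rec.ltr_pair = pair
    rec.tsd = find_tsd(olocus, pair)

    ppt_window = 60
    up = olocus[max(0, pair.ltr3[0] - ppt_window):pair.ltr3[0]]
    ppt = find_ppt(up)
    if ppt is not None:
        off = pair.ltr3[0] - len(up)
        ppt = PptCall(span=(off + ppt.span[0], off + ppt.span[1]),
                      length=ppt.length, purine_frac=ppt.purine_frac)
    rec.ppt = ppt

    # Re-anchor gene spans at the DNA level: protein hits truncate at
    # frameshifts, so each gene's chosen reference CDS is locally aligned
    # across the whole LTR interior to recover the full (indel-tolerant) span.
    interior = (pair.ltr5[1], pair.ltr3[0])
    interior_seq = olocus[interior[0]:interior[1]]
    nt_local = nucleotide_aligner(mode="local")
    regions: dict[str, tuple[int, int]] = {}
    chosen_refs: dict[str, tuple[str, str]] = {}
    for g in ("gag", "pol", "env"):
        a, b = gene_spans[g]
        hit_region = olocus[max(interior[0], a):min(interior[1], b)]
        ref_name, ref_cds = pick_reference_cds(hit_region, g)
        chosen_refs[g] = (ref_name, ref_cds)
        hit = align_local(ref_cds, interior_seq, nt_local)
        if hit is not None and hit.aligned_columns >= 300:
            regions[g] = (interior[0] + hit.target_span[0],
                          interior[0] + hit.target_span[1])
        else:
            regions[g] = (max(interior[0], a), min(interior[1], b))
    pro_span = _locate_pro(olocus, regions["gag"], regions["pol"])
    if pro_span is not None:
        regions["pro"] = pro_span
        chosen_refs["pro"] = ("PRO", references.ref_cds()["PRO"])
    rec.gene_spans = {g: regions[g] for g in GENES if g in regions}

    # small left pad: the inner LTR edge can be fuzzy by a few nt and must
    # not clip the primer binding site
    leader = olocus[max(0, pair.ltr5[1] - 10):regions["gag"][0]]
    rec.pbs = assign_pbs(leader)

    proteins: dict[str, str] = {}
    for g in GENES:
        if g not in regions:
            rec.gene_states[g] = GeneState(gene=g, state="unknown")
            continue
        dna = olocus[regions[g][0]:regions[g][1]]
        ref_name, ref_cds = chosen_refs[g]
        state = call_gene_state(dna, ref_cds, gene=g)
        state.reference = ref_name
        rec.gene_states[g] = state
        proteins[g] = reconstruct_protein(dna, ref_cds)

    motif_hits = scan_motifs(proteins)
    rec.motif_ids = sorted({h.motif_id for h in motif_hits if h.assessable})
    rec.dutpase = dutpase_present(motif_hits)

    provirus_span = (pair.ltr5[0], pair.ltr3[1])
    elements = {"ltr5": pair.ltr5, "ltr3": pair.ltr3, **rec.gene_spans}
    orfs = find_orfs(olocus[provirus_span[0]:provirus_span[1]],
                     min_codons=min_orf_codons)
    for o in orfs:
        o.span = (o.span[0] + provirus_span[0], o.span[1] + provirus_span[0])
        o.placement = classify_placement(o.span, elements)
    rec.orfs = orfs

    if run_repeat_search and "env" in regions:
        env_s, env_e = regions["env"]
        window = olocus[env_s:pair.ltr3[1]]
        rec.notes.extend(
            f"repeat:{h.kind}:{h.arm1[0] + env_s}-{h.arm1[1] + env_s}/"
            f"{h.arm2[0] + env_s}-{h.arm2[1] + env_s}"
            + (":TBE-candidate" if h.tbe_candidate else "")
            for h in find_repeats(window, env_stop=env_e - env_s))

    ltr5_seq = olocus[pair.ltr5[0]:pair.ltr5[1]]
    ltr3_seq = olocus[pair.ltr3[0]:pair.ltr3[1]]
    div = ltr_divergence(ltr5_seq, ltr3_seq)
    rec.divergence = div.D
    age = estimate_age(div.D, clade_rate(clade))
    rec.age_myr = None if age is None else age.T_myr

    fv = FeatureVector(
        pbs_type=rec.pbs.trna_id if rec.pbs else "unknown",
        ltr_class=ltr_length_class(min(pair.lengths)),
        env_lineage=env_lineage(proteins["env"]) if "env" in proteins else "unknown",
        extra_orf_placements=frozenset(
            o.placement for o in orfs
            if o.placement not in ("core", "gene-fragment", "other")),
        dutpase_present=rec.dutpase,
        phylo_proxy=pol_proxy(proteins["pol"]) if "pol" in proteins else "unknown",
    )
    label: GroupLabel = classify_group(fv)
    rec.group, rec.group_trace = label.group, label.trace
    return rec


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage; deterministic under a fixed config (incl. seed)."""
    if config.simulate is not None:
        scaffolds, truths = simulate_genome(seed=config.seed, **config.simulate)
    elif config.input_fasta is not None:
        scaffolds = [SyntheticScaffold(name, seq)
                     for name, seq in pio.read_fasta(config.input_fasta)]
        truths = []
    else:
        raise ValueError("config needs either input_fasta or simulate")

    params = AlignmentParams(evalue_cutoff=config.evalue_cutoff)
    hits = search_genome(references.search_queries(), scaffolds, params)
    by_gene = {g: hits[hits.gene == g] for g in ("gag", "pol", "env")}
    loci = intersect_gene_hits(by_gene["gag"], by_gene["pol"], by_gene["env"],
                               max_span=config.max_locus_span,
                               flank=config.locus_flank,
                               scaffold_lengths={s.id: len(s) for s in scaffolds})

    by_id = {s.id: s for s in scaffolds}
    records = []
    for k, locus in enumerate(loci):
        rec = delineate_and_annotate(
            by_id[locus.scaffold_id], locus, rec_id=f"ERV_{k + 1:03d}",
            clade=config.clade, min_orf_codons=config.min_orf_codons,
            run_repeat_search=config.run_repeat_search)
        records.append(rec)

    report = RunReport(
        seed=config.seed,
        n_scaffolds=len(scaffolds),
        n_hits=len(hits),
        n_loci=len(loci),
        n_proviruses=sum(r.ltr_pair is not None for r in records),
        n_dated=sum(r.age_myr is not None for r in records),
        n_classified=sum(r.group != "unclassified" for r in records),
        records=records,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_fasta(out / "scaffolds.fa", [(s.id, s.sequence) for s in scaffolds])
        hits.to_csv(out / "hits.tsv", sep="\t", index=False)
        if config.simulate is not None:
            pio.write_json(out / "truth.json", truths)
        pio.write_json(out / "report.json", report)
        t2, t3 = summarize(records)
        t2.to_csv(out / "summary_proviruses.tsv", sep="\t", index=False)
        t3.to_csv(out / "summary_ages.tsv", sep="\t", index=False)
        pio.write_gff3(out / "annotations.gff3", _gff_lines(records))
    return report


def _gff_lines(records: list[ProvirusRecord]) -> list[str]:
    lines = []
    for rec in records:
        if rec.ltr_pair is None:
            continue
        off = rec.locus_span[0] if rec.strand == "+" else None

        def conv(span: tuple[int, int]) -> tuple[int, int]:
            if off is not None:
                return (span[0] + off, span[1] + off)
            L = rec.locus_span[1] - rec.locus_span[0]
            return (rec.locus_span[0] + L - span[1], rec.locus_span[0] + L - span[0])

        feats: list[tuple[str, tuple[int, int]]] = [
            ("LTR5", rec.ltr_pair.ltr5), ("LTR3", rec.ltr_pair.ltr3)]
        if rec.tsd and rec.tsd.status == "present":
            feats += [("TSD", (rec.tsd.pos5, rec.tsd.pos5 + 4)),
                      ("TSD", (rec.tsd.pos3, rec.tsd.pos3 + 4))]
        if rec.ppt:
            feats.append(("PPT", rec.ppt.span))
        if rec.pbs and rec.pbs.span:
            pbs_off = rec.ltr_pair.ltr5[1]
            feats.append(("PBS", (rec.pbs.span[0] + pbs_off, rec.pbs.span[1] + pbs_off)))
        feats += [(g, sp) for g, sp in rec.gene_spans.items()]
        feats += [("ORF", o.span) for o in rec.orfs if o.placement not in ("core",)]
        for ftype, span in feats:
            lines.append(pio.to_gff3_line(rec.scaffold, ftype, conv(span),
                                          rec.strand, attrs={"Parent": rec.id}))
    return lines


def summarize_report_json(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rebuild the two summary tables from a serialized report.json."""
    import json

    with open(path) as fh:
        data = json.load(fh)
    records = []
    for d in data.get("records", []):
        rec = ProvirusRecord(id=d["id"], scaffold=d["scaffold"], strand=d["strand"],
                             locus_span=tuple(d["locus_span"]))
        if d.get("ltr_pair"):
            rec.ltr_pair = LTRPair(ltr5=tuple(d["ltr_pair"]["ltr5"]),
                                   ltr3=tuple(d["ltr_pair"]["ltr3"]),
                                   identity=d["ltr_pair"]["identity"])
        if d.get("tsd"):
            rec.tsd = TsdCall(**d["tsd"])
        if d.get("pbs"):
            pbs = dict(d["pbs"])
            if pbs.get("span"):
                pbs["span"] = tuple(pbs["span"])
            rec.pbs = PbsCall(**pbs)
        for g, s in (d.get("gene_states") or {}).items():
            rec.gene_states[g] = GeneState(gene=g, state=s["state"],
                                           coverage=s.get("coverage", 0.0))
        for o in d.get("orfs") or []:
            rec.orfs.append(OrfRecord(span=tuple(o["span"]), strand=o["strand"],
                                      frame=o["frame"],
                                      length_codons=o["length_codons"],
                                      placement=o.get("placement", "other")))
        rec.divergence = d.get("divergence")
        rec.age_myr = d.get("age_myr")
        rec.group = d.get("group", "unclassified")
        rec.notes = d.get("notes", [])
        records.append(rec)
    return summarize(records)


def summarize(records: list[ProvirusRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two report tables: provirus census and integration-age estimates.

    Undefined divergence propagates as the string "ND" in the age table.
    """
    rows2, rows3 = [], []
    for rec in records:
        states = {g: rec.gene_states.get(g, GeneState(g, "unknown")).state
                  for g in GENES}
        rows2.append({
            "name": rec.id, "scaffold": rec.scaffold, "strand": rec.strand,
            "genome_size": rec.genome_size,
            **{g: states[g] for g in GENES},
            "extra_orfs": rec.extra_orf_count,
            "ltr_length": None if rec.ltr_pair is None else min(rec.ltr_pair.lengths),
            "pbs": rec.pbs.trna_id if rec.pbs else "unknown",
            "tsd": (rec.tsd.sequence or rec.tsd.status) if rec.tsd else "absent",
            "group": rec.group,
            "notes": ";".join(n for n in rec.notes if not n.startswith("repeat:")),
        })
        rows3.append({
            "name": rec.id,
            "divergence": "ND" if rec.divergence is None else round(rec.divergence, 3),
            "age_myr": "ND" if rec.age_myr is None else rec.age_myr,
        })
    cols2 = ["name", "scaffold", "strand", "genome_size", *GENES, "extra_orfs",
             "ltr_length", "pbs", "tsd", "group", "notes"]
    cols3 = ["name", "divergence", "age_myr"]
    return (pd.DataFrame(rows2, columns=cols2), pd.DataFrame(rows3, columns=cols3))
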