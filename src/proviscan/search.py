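"""Translated protein-vs-genome homology search and three-gene locus intersection.

Reference Gag/Pol/Env polyproteins are aligned against all six reading
frames of each scaffold with full affine-gap Smith–Waterman (BLOSUM62,
gap existence 11 / extension 1) and scored with Karlin–Altschul statistics
E = K·m·n·e^(−λS).  Scaffolds hit by all three genes in colinear
same-strand order nominate candidate proviral loci.

The search is exact dynamic programming; no word seeding is applied, so the
results do not depend on heuristic seed survival.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from proviscan.align import align_local, protein_local_aligner, sanitize_protein
from proviscan.seqtools import mask_low_complexity, revcomp

GENES = ("gag", "pol", "env")


@dataclass
class AlignmentParams:
    """Scoring and significance parameters for the translated search.

    K and lam default to the published gapped-BLOSUM62 (11/1) Karlin–Altschul
    constants; they can be overridden, e.g. with values calibrated from
    shuffle nulls.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    K: float = 0.041
    lam: float = 0.267
    evalue_cutoff: float = 1e-10
    low_complexity_filter: bool = True

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("K and lam must be positive")


@dataclass
class TranslatedSegment:
    """One reading frame of a scaffold with its DNA coordinate map."""

    scaffold_id: str
    frame: int  # +1, +2, +3, -1, -2, -3
    protein: str
    dna_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    def dna_span(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Forward-strand DNA span (0-based half-open) of residues [aa_start, aa_end)."""
        off = abs(self.frame) - 1
        if self.frame > 0:
            return (off + 3 * aa_start, off + 3 * aa_end)
        return (self.dna_length - off - 3 * aa_end, self.dna_length - off - 3 * aa_start)


def _translate_frame(dna: str) -> str:
    usable = len(dna) - len(dna) % 3
    if usable == 0:
        return ""
    return str(Seq(dna[:usable]).translate())


def six_frame_translate(dna: str, scaffold_id: str = "") -> list[TranslatedSegment]:
    """All six reading frames; codons containing N translate to 'X'."""
    dna = dna.upper()
    rc = revcomp(dna)
    out = []
    for off in range(3):
        out.append(TranslatedSegment(scaffold_id, off + 1, _translate_frame(dna[off:]), len(dna)))
    for off in range(3):
        out.append(TranslatedSegment(scaffold_id, -(off + 1), _translate_frame(rc[off:]), len(dna)))
    return out


def local_align_protein(query: str, target: str, params: AlignmentParams | None = None):
    """Best affine-gap Smith–Waterman local alignment (see align.LocalHit).

    Residues outside the matrix alphabet are treated as X (score 0 against
    everything).  An all-negative problem yields None (empty alignment,
    score 0 by convention).
    """
    params = params or AlignmentParams()
    aligner = protein_local_aligner(params.gap_open, params.gap_extend)
    return align_local(sanitize_protein(query), sanitize_protein(target), aligner)


def evalue(score_S: float, m: int, n: int, params: AlignmentParams | None = None) -> float:
    """Karlin–Altschul expectation E = K·m·n·e^(−λS) for search space m·n."""
    params = params or AlignmentParams()
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    return params.K * m * n * math.exp(-params.lam * score_S)


_HIT_COLUMNS = ["qid", "gene", "sid", "frame", "strand", "pident", "length",
                "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def search_genome(queries: dict[str, list[tuple[str, str]]], scaffolds,
                  params: AlignmentParams | None = None) -> pd.DataFrame:
    """Search every scaffold's six frames with every per-gene query protein.

    Returns a BLAST-tabular-like DataFrame of hits with E < cutoff, sorted by
    E ascending.  `scaffolds` is an iterable of objects with .id/.sequence or
    (id, sequence) tuples.
    """
    params = params or AlignmentParams()
    aligner = protein_local_aligner(params.gap_open, params.gap_extend)
    rows = []
    for scaffold in scaffolds:
        sid, seq = (scaffold.id, scaffold.sequence) if hasattr(scaffold, "sequence") \
            else scaffold
        segments = six_frame_translate(seq, sid)
        for seg in segments:
            target = sanitize_protein(seg.protein)
            if params.low_complexity_filter:
                target = mask_low_complexity(target)
            if not target:
                continue
            for gene, qlist in queries.items():
                for qid, qseq in qlist:
                    q = sanitize_protein(qseq)
                    score = aligner.score(q, target)
                    e = evalue(score, len(q), len(seq), params)
                    if e >= params.evalue_cutoff:
                        continue
                    hit = align_local(q, target, aligner)
                    if hit is None:
                        continue
                    sstart, send = seg.dna_span(*hit.target_span)
                    rows.append({
                        "qid": qid, "gene": gene, "sid": sid, "frame": seg.frame,
                        "strand": seg.strand,
                        "pident": round(100.0 * hit.identity, 2),
                        "length": hit.aligned_columns,
                        "qstart": hit.query_span[0], "qend": hit.query_span[1],
                        "sstart": sstart, "send": send,
                        "evalue": e, "bitscore": hit.score,
                    })
    df = pd.DataFrame(rows, columns=_HIT_COLUMNS)
    return df.sort_values("evalue", kind="mergesort").reset_index(drop=True)


def summarize_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Per (query, gene): lowest e-value and number of hits (report shape)."""
    if hits.empty:
        return pd.DataFrame(columns=["qid", "gene", "lowest_evalue", "n_hits"])
    grouped = hits.groupby(["qid", "gene"], sort=True)
    out = grouped.agg(lowest_evalue=("evalue", "min"), n_hits=("evalue", "size"))
    return out.reset_index()


@dataclass
class CandidateLocus:
    """A scaffold region hit by gag, pol and env in colinear same-strand order."""

    scaffold_id: str
    strand: str
    gene_spans: dict[str, tuple[int, int]]
    span: tuple[int, int]
    evalues: dict[str, float] = field(default_factory=dict)


def _colinear(g, p, e, strand: str) -> bool:
    if strand == "+":
        return g["sstart"] < p["sstart"] < e["sstart"]
    return e["sstart"] < p["sstart"] < g["sstart"]


def intersect_gene_hits(gag_hits: pd.DataFrame, pol_hits: pd.DataFrame,
                        env_hits: pd.DataFrame, max_span: int = 15000,
                        flank: int = 2000,
                        scaffold_lengths: dict[str, int] | None = None
                        ) -> list[CandidateLocus]:
    """Scaffolds hit by all three genes become candidate loci.

    One locus per colinear same-strand gag<pol<env triple whose overall span
    is at most max_span; overlapping triples are merged.  The locus span is
    padded by `flank` on both sides (clipped to the scaffold).
    """
    loci: list[CandidateLocus] = []
    if gag_hits.empty or pol_hits.empty or env_hits.empty:
        return loci
    sids = set(gag_hits.sid) & set(pol_hits.sid) & set(env_hits.sid)
    for sid in sorted(sids):
        for strand in "+-":
            gs = gag_hits[(gag_hits.sid == sid) & (gag_hits.strand == strand)]
            ps = pol_hits[(pol_hits.sid == sid) & (pol_hits.strand == strand)]
            es = env_hits[(env_hits.sid == sid) & (env_hits.strand == strand)]
            triples = []
            for _, g in gs.iterrows():
                for _, p in ps.iterrows():
                    for _, e in es.iterrows():
                        span = (min(g.sstart, p.sstart, e.sstart),
                                max(g.send, p.send, e.send))
                        if span[1] - span[0] <= max_span and _colinear(g, p, e, strand):
                            triples.append((span, g, p, e))
            triples.sort(key=lambda t: t[0])
            merged: list[list] = []
            for span, g, p, e in triples:
                if merged and span[0] < merged[-1][0][1]:
                    prev = merged[-1]
                    prev[0] = (prev[0][0], max(prev[0][1], span[1]))
                    for slot, hit in ((1, g), (2, p), (3, e)):
                        if hit.evalue < prev[slot].evalue:
                            prev[slot] = hit
                else:
                    merged.append([span, g, p, e])
            for span, g, p, e in merged:
                length = None if scaffold_lengths is None else scaffold_lengths.get(sid)
                lo = max(0, span[0] - flank)
                hi = span[1] + flank if length is None else min(length, span[1] + flank)
                loci.append(CandidateLocus(
                    scaffold_id=sid, strand=strand,
                    gene_spans={"gag": (int(g.sstart), int(g.send)),
                                "pol": (int(p.sstart), int(p.send)),
                                "env": (int(e.sstart), int(e.send))},
                    span=(int(lo), int(hi)),
                    evalues={"gag": float(g.evalue), "pol": float(p.evalue),
                             "env": float(e.evalue)},
                ))
    return loci
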