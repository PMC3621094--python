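"""Provirus annotation: ORFs, PBS–tRNA assignment, motifs, gene states, repeats.

Gene-level calls are anchored on the packaged reference coding sequences: a
gene region is globally aligned to its reference CDS, indels (frameshifts)
and premature stops are read off the alignment, and a reference-coordinate
protein is reconstructed so that motif blocks can be checked at the position
where the reference carries them (free-floating regex over a translation is
deliberately not used — it is far too permissive).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from proviscan import references
from proviscan.align import align_local, nucleotide_aligner
from proviscan.references import MotifDef
from proviscan.seqtools import revcomp

_STOPS = {"TAA", "TAG", "TGA"}
_CODON = {}


def _codon_table() -> dict[str, str]:
    if not _CODON:
        from Bio.Data.CodonTable import unambiguous_dna_by_id
        _CODON.update(unambiguous_dna_by_id[1].forward_table)
        for s in _STOPS:
            _CODON[s] = "*"
    return _CODON


# ---------------------------------------------------------------------------
# open reading frames
# ---------------------------------------------------------------------------

@dataclass
class OrfRecord:
    span: tuple[int, int]  # includes the stop codon
    strand: str
    frame: int  # 0, 1, 2 (offset within the strand)
    length_codons: int  # coding codons, excluding the stop
    placement: str = "other"


def _scan_strand(dna: str, min_codons: int) -> list[OrfRecord]:
    table = _codon_table()
    out = []
    for frame in range(3):
        start_candidate: int | None = None
        for pos in range(frame, len(dna) - 2, 3):
            codon = dna[pos:pos + 3]
            if codon == "ATG" and start_candidate is None:
                start_candidate = pos
            elif table.get(codon, "X") == "*":
                if start_candidate is not None:
                    n = (pos - start_candidate) // 3
                    if n >= min_codons:
                        out.append(OrfRecord((start_candidate, pos + 3), "+", frame, n))
                start_candidate = None
    return out


def classify_placement(span: tuple[int, int],
                       element_spans: dict[str, tuple[int, int]]) -> str:
    s, e = span
    genes = {g: element_spans[g] for g in ("gag", "pro", "pol", "env")
             if g in element_spans}
    for ltr in ("ltr5", "ltr3"):
        if ltr in element_spans:
            ls, le = element_spans[ltr]
            if ls <= s and e <= le:
                return "in-LTR"
    for gs, ge in genes.values():
        inter = min(e, ge) - max(s, gs)
        if inter > 0 and inter >= 0.8 * (e - s):
            # mostly inside one gene: either the gene's own reading frame
            # (the gene ORF or an in-frame sub-ORF) or a shifted-frame
            # fragment of a defective gene — not a novel extra ORF either way
            return "core" if (s - gs) % 3 == 0 else "gene-fragment"
    if genes:
        if e <= min(gs for gs, _ in genes.values()):
            return "pre-gag"
        if s >= max(ge for _, ge in genes.values()):
            return "post-env"
        if any(min(e, ge) > max(s, gs) for gs, ge in genes.values()):
            return "within-core-alt-frame"
    return "other"


def find_orfs(dna: str, min_codons: int = 100, both_strands: bool = False,
              element_spans: dict[str, tuple[int, int]] | None = None
              ) -> list[OrfRecord]:
    """All ATG→stop open reading frames of at least min_codons codons.

    One ORF per stop codon (the longest, i.e. earliest ATG after the previous
    in-frame stop).  The 100-codon default deliberately suppresses incidental
    non-coding ORFs.
    """
    orfs = _scan_strand(dna.upper(), min_codons)
    if both_strands:
        rc = revcomp(dna.upper())
        for o in _scan_strand(rc, min_codons):
            s, e = o.span
            orfs.append(OrfRecord((len(dna) - e, len(dna) - s), "-", o.frame,
                                  o.length_codons))
    if element_spans:
        for o in orfs:
            o.placement = classify_placement(o.span, element_spans)
    return sorted(orfs, key=lambda o: o.span)


# ---------------------------------------------------------------------------
# primer binding site
# ---------------------------------------------------------------------------

@dataclass
class PbsCall:
    trna_id: str  # Lys1_2 | Lys3 | LysAlt | unknown
    matched_length: int = 0
    matches: int = 0
    span: tuple[int, int] | None = None


def assign_pbs(leader: str, trna_lib: dict[str, str] | None = None,
               min_matches: int = 14, window: int = 18) -> PbsCall:
    """Assign the tRNA whose 3' end the primer binding site is complementary to.

    The reverse complement of each tRNA 3'-end `window`-mer is slid (ungapped)
    along the leader (5'LTR→gag region); the best tRNA is called only when it
    reaches min_matches and beats the runner-up by at least 2 matches,
    otherwise the call is unknown.  N positions never match.
    """
    trna_lib = trna_lib or references.trna_library()
    leader = leader.upper()
    if len(leader) < window:
        return PbsCall("unknown")
    scores: list[tuple[int, int, str]] = []
    for trna_id, trna in sorted(trna_lib.items()):
        probe = revcomp(trna[-window:])
        best, best_off = -1, 0
        for off in range(len(leader) - window + 1):
            m = sum(a == b and a != "N"
                    for a, b in zip(probe, leader[off:off + window]))
            if m > best:
                best, best_off = m, off
        scores.append((best, best_off, trna_id))
    scores.sort(key=lambda t: (-t[0], t[2]))
    top, runner = scores[0], scores[1]
    if top[0] < min_matches or top[0] - runner[0] < 2:
        return PbsCall("unknown", matched_length=window, matches=max(top[0], 0))
    return PbsCall(top[2], matched_length=window, matches=top[0],
                   span=(top[1], top[1] + window))


# ---------------------------------------------------------------------------
# reference-anchored gene analysis
# ---------------------------------------------------------------------------

@dataclass
class GeneEvent:
    kind: str  # frameshift | premature_stop
    pos: int  # 0-based nucleotide offset within the gene region
    indel_len: int = 0


@dataclass
class GeneState:
    gene: str
    state: str  # intact | defective | unknown
    events: list[GeneEvent] = field(default_factory=list)
    coverage: float = 0.0
    reference: str = ""


@dataclass
class _RefAlignment:
    """Gene DNA mapped onto reference-CDS coordinates."""

    qchar: list[str]  # query nucleotide per reference position ('-' if deleted)
    qpos: list[int]  # query coordinate per reference position (-1 if deleted)
    indels: list[tuple[str, int, int]]  # (insertion|deletion, query pos, length)
    coverage: float


def _align_to_reference(gene_dna: str, ref_cds: str) -> _RefAlignment:
    aligner = nucleotide_aligner(mode="global", end_gaps_free=True)
    aln = next(iter(aligner.align(ref_cds, gene_dna)))
    rblocks, qblocks = aln.aligned
    n = len(ref_cds)
    qchar = ["-"] * n
    qpos = [-1] * n
    indels: list[tuple[str, int, int]] = []
    prev_r = prev_q = None
    for (rs, re_), (qs, qe) in ((tuple(map(int, rb)), tuple(map(int, qb)))
                                for rb, qb in zip(rblocks, qblocks)):
        if prev_r is not None:
            dr, dq = rs - prev_r, qs - prev_q
            if dr and not dq:
                indels.append(("deletion", int(prev_q), int(dr)))
            elif dq and not dr:
                indels.append(("insertion", int(prev_q), int(dq)))
            else:  # simultaneous gap on both sides: treat as paired indels
                indels.append(("deletion", int(prev_q), int(dr)))
                indels.append(("insertion", int(prev_q), int(dq)))
        for k in range(re_ - rs):
            qchar[rs + k] = gene_dna[qs + k]
            qpos[rs + k] = qs + k
        prev_r, prev_q = re_, qe
    covered = sum(c != "-" for c in qchar)
    return _RefAlignment(qchar, qpos, indels, covered / n if n else 0.0)


def reconstruct_protein(gene_dna: str, ref_cds: str) -> str:
    """Translate the gene region codon-by-codon in reference coordinates.

    Frameshifts are absorbed by the alignment, so each reference codon is
    rebuilt from the nucleotides aligned to it; missing or N-containing
    codons become 'X'.  The returned protein has exactly len(ref_cds)//3
    residues (including the terminal stop as '*', if present).
    """
    table = _codon_table()
    ra = _align_to_reference(gene_dna.upper(), ref_cds.upper())
    prot = []
    for c in range(len(ref_cds) // 3):
        codon = "".join(ra.qchar[3 * c:3 * c + 3])
        prot.append(table.get(codon, "X") if "-" not in codon and "N" not in codon
                    else "X")
    return "".join(prot)


def candidate_reference_cds(gene: str) -> dict[str, str]:
    cds = references.ref_cds()
    prefix = {"gag": "GAG", "pro": "PRO", "pol": "POL", "env": "ENV"}[gene]
    return {k: v for k, v in cds.items() if k.startswith(prefix)}


def pick_reference_cds(gene_dna: str, gene: str) -> tuple[str, str]:
    """Best-scoring packaged reference CDS for a gene region (name, sequence)."""
    aligner = nucleotide_aligner(mode="local")
    best = None
    for name, cds in sorted(candidate_reference_cds(gene).items()):
        score = aligner.score(cds, gene_dna.upper())
        if best is None or score > best[0]:
            best = (score, name, cds)
    return best[1], best[2]


def call_gene_state(gene_dna: str, ref_cds: str, gene: str = "",
                    min_coverage: float = 0.9, nsr_min_run: int = 20) -> GeneState:
    """Intact / defective / unknown call for one gene region.

    Defective means at least one frameshift (indel of length not divisible
    by 3) or premature stop relative to the reference CDS; in-frame indels
    alone do not disqualify a gene.  A gene overlapped by a non-sequenced
    region (N-run) that shows no events is unknown rather than intact.
    """
    gene_dna = gene_dna.upper()
    table = _codon_table()
    ra = _align_to_reference(gene_dna, ref_cds.upper())
    events: list[GeneEvent] = []
    for kind, qp, length in ra.indels:
        if length % 3 != 0:
            events.append(GeneEvent("frameshift", qp, length))
    last_codon = len(ref_cds) // 3 - 1  # the reference's own stop codon
    for c in range(last_codon):
        codon = "".join(ra.qchar[3 * c:3 * c + 3])
        if "-" in codon or "N" in codon:
            continue
        if table.get(codon, "X") == "*":
            events.append(GeneEvent("premature_stop", ra.qpos[3 * c]))
    events.sort(key=lambda e: e.pos)

    has_nsr = _longest_n_run(gene_dna) >= nsr_min_run
    if events:
        state = "defective"
    elif has_nsr:
        state = "unknown"
    elif ra.coverage >= min_coverage:
        state = "intact"
    else:
        state = "defective"
    return GeneState(gene=gene, state=state, events=events, coverage=ra.coverage)


def _longest_n_run(seq: str) -> int:
    best = cur = 0
    for c in seq:
        cur = cur + 1 if c == "N" else 0
        best = max(best, cur)
    return best


# ---------------------------------------------------------------------------
# motif scan
# ---------------------------------------------------------------------------

@dataclass
class MotifHit:
    motif_id: str
    gene: str
    position: int  # aa position in the reference coordinate system
    matched: str
    assessable: bool = True


def scan_motifs(gene_proteins: dict[str, str],
                motifs: tuple[MotifDef, ...] | None = None,
                min_block_identity: float = 0.6) -> list[MotifHit]:
    """Check each conserved motif block at its reference-anchored position.

    `gene_proteins` maps gene -> protein reconstructed in reference
    coordinates (see reconstruct_protein).  A motif is a hit when every key
    residue matches and the block overall reaches min_block_identity; blocks
    whose key positions are unresolved ('X') are reported as not assessable.
    """
    motifs = motifs or references.motif_table()
    hits: list[MotifHit] = []
    for m in motifs:
        prot = gene_proteins.get(m.gene)
        if prot is None:
            continue
        window = prot[m.ref_start:m.ref_start + len(m.pattern)]
        if len(window) < len(m.pattern):
            continue
        if any(window[k] == "X" for k in m.key_positions):
            hits.append(MotifHit(m.motif_id, m.gene, m.ref_start, window,
                                 assessable=False))
            continue
        keys_ok = all(window[k] == m.pattern[k] for k in m.key_positions)
        ident = sum(a == b for a, b in zip(window, m.pattern)) / len(m.pattern)
        if keys_ok and ident >= min_block_identity:
            hits.append(MotifHit(m.motif_id, m.gene, m.ref_start, window))
    return hits


def dutpase_present(hits: list[MotifHit], min_blocks: int = 3) -> bool:
    """The betaretroviral dUTPase domain is called present when at least
    min_blocks of its five conserved blocks are found in pro."""
    found = {h.motif_id for h in hits if h.assessable
             and h.motif_id.startswith("dUTPase")}
    return len(found) >= min_blocks


# ---------------------------------------------------------------------------
# direct / inverted repeat search (CTE-style export-element architecture)
# ---------------------------------------------------------------------------

@dataclass
class RepeatHit:
    kind: str  # direct | inverted
    arm1: tuple[int, int]
    arm2: tuple[int, int]
    identity: float
    score: int
    tbe_candidate: bool = False


def _extend_ungapped(s1: str, s2: str, i: int, j: int, word: int,
                     match: int, mismatch: int, xdrop: int,
                     max_total: int | None = None) -> tuple[int, int, int]:
    """Maximal-scoring ungapped extension of an exact word seed.

    Returns (left_ext, right_ext, score).  Extension proceeds one column at a
    time; the cumulative score argmax defines the arm (first maximum on ties,
    i.e. the shortest extension), and extension stops after the running score
    drops xdrop below the best.
    """
    score = word * match
    left = 0
    best, cur = 0, 0
    k = 1
    while i - k >= 0 and j - k >= 0:
        cur += match if s1[i - k] == s2[j - k] and s1[i - k] != "N" else mismatch
        if cur > best:
            best, left = cur, k
        if cur < best - xdrop:
            break
        k += 1
    score += best
    right = 0
    best, cur = 0, 0
    k = 0
    while i + word + k < len(s1) and j + word + k < len(s2):
        if max_total is not None and left + word + k + 1 > max_total:
            break
        a, b = s1[i + word + k], s2[j + word + k]
        cur += match if a == b and a != "N" else mismatch
        if cur > best:
            best, right = cur, k + 1
        if cur < best - xdrop:
            break
        k += 1
    score += best
    return left, right, score


def find_repeats(dna: str, word: int = 11, match: int = 1, mismatch: int = -3,
                 min_score: int = 11, xdrop: int = 12,
                 env_stop: int | None = None) -> list[RepeatHit]:
    """Direct and inverted nucleotide repeats within a region.

    Seeded with exact `word`-mers (self vs self off-diagonal for direct
    repeats; self vs reverse complement for inverted), extended ungapped to
    the maximal-scoring arms.  Low-complexity sequence is deliberately NOT
    filtered.  Direct-repeat pairs lying entirely downstream of `env_stop`
    are flagged as Tap-binding-element (CTE-architecture) candidates.
    """
    dna = dna.upper()
    n = len(dna)
    hits: dict[tuple, RepeatHit] = {}

    def record(kind: str, a1: tuple[int, int], a2: tuple[int, int], score: int) -> None:
        if a1 > a2:
            a1, a2 = a2, a1
        if a1[1] > a2[0]:  # overlapping arms
            return
        length = a1[1] - a1[0]
        s1 = dna[a1[0]:a1[1]]
        s2 = dna[a2[0]:a2[1]] if kind == "direct" else revcomp(dna[a2[0]:a2[1]])
        ident = sum(a == b for a, b in zip(s1, s2)) / length if length else 0.0
        key = (kind, a1, a2)
        if key not in hits or hits[key].score < score:
            tbe = (kind == "direct" and env_stop is not None
                   and a1[0] >= env_stop and a2[0] >= env_stop)
            hits[key] = RepeatHit(kind, a1, a2, round(ident, 4), score, tbe)

    index: dict[str, list[int]] = {}
    for i in range(n - word + 1):
        w = dna[i:i + word]
        if "N" not in w:
            index.setdefault(w, []).append(i)

    for w, positions in index.items():
        for ai, i in enumerate(positions):
            for j in positions[ai + 1:]:
                if j - i < word:
                    continue
                left, right, score = _extend_ungapped(
                    dna, dna, i, j, word, match, mismatch, xdrop, max_total=j - i)
                if score >= min_score:
                    record("direct", (i - left, i + word + right),
                           (j - left, j + word + right), score)

    rc = revcomp(dna)
    rc_index: dict[str, list[int]] = {}
    for j in range(n - word + 1):
        w = rc[j:j + word]
        if "N" not in w:
            rc_index.setdefault(w, []).append(j)
    for w, positions in index.items():
        for i in positions:
            for j in rc_index.get(w, ()):
                left, right, score = _extend_ungapped(dna, rc, i, j, word,
                                                      match, mismatch, xdrop)
                a1 = (i - left, i + word + right)
                a2_rc = (j - left, j + word + right)
                a2 = (n - a2_rc[1], n - a2_rc[0])
                if score >= min_score and a1 < a2:
                    record("inverted", a1, a2, score)

    out = sorted(hits.values(), key=lambda h: (h.arm1, h.arm2))
    return _prune_contained(out)


def _prune_contained(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Drop hits whose arms are both contained in another hit of the same kind."""
    keep: list[RepeatHit] = []
    for h in hits:
        contained = any(
            g is not h and g.kind == h.kind
            and g.arm1[0] <= h.arm1[0] and h.arm1[1] <= g.arm1[1]
            and g.arm2[0] <= h.arm2[0] and h.arm2[1] <= g.arm2[1]
            and (g.arm1[1] - g.arm1[0]) >= (h.arm1[1] - h.arm1[0])
            for g in hits)
        if not contained:
            keep.append(h)
    return keep
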