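"""Provirus delineation: LTR pair by self-alignment, TSD, PPT, flanks, merging.

The flanking long terminal repeats are found the way an annotator would with
a self-BLASTn: exact word seeds (word size 11) between the two ends of the
candidate locus are clustered by diagonal, the implied repeat windows are
locally aligned (match +1, mismatch −3, gap existence 5 / extension 2), and
the alignment ends give the repeat boundaries.  The termini are then
refined against the two independent signals a genuine integration leaves:
an exact 4-nt target-site duplication flanking the pair and the canonical
retroviral att dinucleotides (LTRs begin TG and end CA).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from proviscan.align import LocalHit, align_local, nucleotide_aligner
from proviscan.seqtools import purine_fraction


@dataclass
class SelfAlignParams:
    """Self-alignment parameters for repeat (LTR) discovery."""

    word: int = 11
    match: int = 1
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    min_len: int = 250
    max_len: int = 1500
    min_identity: float = 0.80
    window_pad: int = 60
    diag_tolerance: int = 30


@dataclass
class LTRPair:
    """Direct repeat pair flanking the gene block (0-based half-open spans)."""

    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    identity: float

    @property
    def lengths(self) -> tuple[int, int]:
        return (self.ltr5[1] - self.ltr5[0], self.ltr3[1] - self.ltr3[0])


@dataclass
class TsdCall:
    status: str  # present | absent | masked
    sequence: str | None = None
    pos5: int | None = None
    pos3: int | None = None


@dataclass
class PptCall:
    span: tuple[int, int]
    length: int
    purine_frac: float


def _seed_matches(left: str, right: str, word: int) -> list[tuple[int, int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(left) - word + 1):
        w = left[i:i + word]
        if "N" not in w:
            index.setdefault(w, []).append(i)
    out = []
    for j in range(len(right) - word + 1):
        w = right[j:j + word]
        for i in index.get(w, ()):
            out.append((i, j))
    return out


def _best_diagonal_cluster(matches: list[tuple[int, int]], tol: int
                           ) -> list[tuple[int, int]]:
    if not matches:
        return []
    matches = sorted(matches, key=lambda m: (m[1] - m[0], m[0]))
    best: list[tuple[int, int]] = []
    cur: list[tuple[int, int]] = []
    for m in matches:
        if cur and (m[1] - m[0]) - (cur[-1][1] - cur[-1][0]) > tol:
            if len({i for i, _ in cur}) > len({i for i, _ in best}):
                best = cur
            cur = []
        cur.append(m)
    if len({i for i, _ in cur}) > len({i for i, _ in best}):
        best = cur
    return best


def find_ltr_pair(locus_dna: str, gene_spans: dict[str, tuple[int, int]],
                  params: SelfAlignParams | None = None) -> LTRPair | None:
    """Highest-identity direct repeat pair bracketing the gene hits, or None.

    Loci without a qualifying repeat pair are reported upstream as
    betaretrovirus-like retroelements rather than full proviruses.
    """
    params = params or SelfAlignParams()
    left_end = min(s for s, _ in gene_spans.values())
    right_start = max(e for _, e in gene_spans.values())
    left = locus_dna[:left_end]
    right = locus_dna[right_start:]
    if len(left) < params.word or len(right) < params.word:
        return None
    cluster = _best_diagonal_cluster(_seed_matches(left, right, params.word),
                                     params.diag_tolerance)
    if not cluster:
        return None
    i_lo = min(i for i, _ in cluster) - params.window_pad
    i_hi = max(i for i, _ in cluster) + params.word + params.window_pad
    j_lo = min(j for _, j in cluster) - params.window_pad
    j_hi = max(j for _, j in cluster) + params.word + params.window_pad
    w5 = (max(0, i_lo), min(len(left), i_hi))
    w3 = (max(0, j_lo), min(len(right), j_hi))
    aligner = nucleotide_aligner(params.match, params.mismatch, params.gap_open,
                                 params.gap_extend, mode="local")
    hit: LocalHit | None = align_local(left[w5[0]:w5[1]], right[w3[0]:w3[1]], aligner)
    if hit is None:
        return None
    ltr5 = (w5[0] + hit.query_span[0], w5[0] + hit.query_span[1])
    ltr3 = (right_start + w3[0] + hit.target_span[0],
            right_start + w3[0] + hit.target_span[1])
    len5, len3 = ltr5[1] - ltr5[0], ltr3[1] - ltr3[0]
    if not (params.min_len <= len5 <= params.max_len
            and params.min_len <= len3 <= params.max_len):
        return None
    if hit.identity < params.min_identity:
        return None
    if not (ltr5[1] <= left_end and ltr3[0] >= right_start):
        return None
    return LTRPair(ltr5=ltr5, ltr3=ltr3, identity=hit.identity)


def snap_edges_to_tsd(scaffold_seq: str, pair: LTRPair, max_shift: int = 18) -> LTRPair:
    """Refine the LTR termini using integration-site evidence.

    Raw self-alignment can over- or under-run the true termini by several
    bases when flanking sequence resembles the other copy's context (the
    purine-rich PPT next to the 3' LTR, the PBS next to the 5' LTR, or the
    TSD itself).  Candidate shifts of the alignment start (moves the 5' LTR
    start) and end (moves the 3' LTR end) are scored on two independent
    signals of a genuine provirus terminus: an exact 4-nt target-site
    duplication flanking the shifted pair, and the canonical retroviral
    att dinucleotides (LTRs begin TG and end CA).  Shifts beyond 4 nt are
    accepted only when both att sites support them.  The winning shift is
    also applied to the corresponding inner edges, which track the alignment
    start/end.  With no qualifying candidate the alignment edges stand.
    """
    (s5, e5), (s3, e3) = pair.ltr5, pair.ltr3
    best = None  # (score, -(|ds|+|de|), ds, de)
    for ds in range(-max_shift, max_shift + 1):
        a = s5 + ds
        left = scaffold_seq[max(0, a - 4):a]
        if len(left) < 4 or "N" in left:
            continue
        tg = scaffold_seq[a:a + 2] == "TG"
        for de in range(-max_shift, max_shift + 1):
            b = e3 + de
            right = scaffold_seq[b:b + 4]
            if len(right) < 4 or "N" in right:
                continue
            if left != right:
                continue
            ca = scaffold_seq[b - 2:b] == "CA"
            cost = abs(ds) + abs(de)
            # larger shifts need att-site support: one anchor up to 10 nt,
            # both anchors beyond
            if cost > 4 and not (tg or ca):
                continue
            if cost > 10 and not (tg and ca):
                continue
            score = 4 + 2 * tg + 2 * ca - 0.1 * (abs(ds) + abs(de))
            cand = (score, -cost, -abs(ds), ds, de)
            if best is None or cand > best:
                best = cand
    if best is None:
        return pair
    ds, de = best[3], best[4]
    ltr5 = (s5 + ds, max(s5 + ds + 1, e5 + de))
    ltr3 = (min(s3 + ds, e3 + de - 1), e3 + de)
    return LTRPair(ltr5=ltr5, ltr3=ltr3, identity=pair.identity)


def find_tsd(scaffold_seq: str, pair: LTRPair, max_mismatch: int = 0) -> TsdCall:
    """The 4-nt target-site duplication immediately flanking the LTR pair.

    Exact 4/4 match required by default; N in either flank yields status
    "masked" (non-sequenced region).
    """
    s5, e3 = pair.ltr5[0], pair.ltr3[1]
    left = scaffold_seq[s5 - 4:s5]
    right = scaffold_seq[e3:e3 + 4]
    if len(left) < 4 or len(right) < 4:
        return TsdCall(status="absent")
    if "N" in left or "N" in right:
        return TsdCall(status="masked")
    mismatches = sum(a != b for a, b in zip(left, right))
    if mismatches <= max_mismatch:
        return TsdCall(status="present", sequence=left, pos5=s5 - 4, pos3=e3)
    return TsdCall(status="absent")


def find_ppt(upstream: str, min_len: int = 12, min_purine: float = 0.85,
             max_gap: int = 5) -> PptCall | None:
    """Polypurine tract in the DNA immediately 5' of the 3' LTR.

    `upstream` must end exactly where the 3' LTR begins.  Returns the longest
    window with purine fraction >= min_purine whose end lies within max_gap
    of the LTR; the window must start and end on a purine (a tract bounded by
    pyrimidines is trimmed).  Ties: longest, then closest to the LTR.
    """
    if len(upstream) < min_len:
        return None
    n = len(upstream)
    best: PptCall | None = None
    for end in range(n, max(min_len - 1, n - max_gap - 1), -1):
        for start in range(0, end - min_len + 1):
            window = upstream[start:end]
            if window[0] not in "AG" or window[-1] not in "AG":
                continue
            frac = purine_fraction(window)
            if frac < min_purine:
                continue
            cand = PptCall(span=(start, end), length=end - start, purine_frac=frac)
            if (best is None or cand.length > best.length
                    or (cand.length == best.length and cand.span[1] > best.span[1])):
                best = cand
    return best


def compare_flanks(up_a: str, down_a: str, up_b: str, down_b: str,
                   flank_len: int = 1000, min_identity: float = 0.8) -> str:
    """Are two proviruses duplicates of one integration event?

    'homologous' iff local alignments of both the upstream and downstream
    flank pairs reach min_identity over at least half of flank_len;
    'indeterminate' when a flank is short or mostly N.
    """
    for f in (up_a, down_a, up_b, down_b):
        if len(f) < flank_len or f.count("N") > len(f) // 2:
            return "indeterminate"
    aligner = nucleotide_aligner(mode="local")
    for a, b in ((up_a[-flank_len:], up_b[-flank_len:]),
                 (down_a[:flank_len], down_b[:flank_len])):
        hit = align_local(a, b, aligner)
        if hit is None or hit.aligned_columns < flank_len // 2 \
                or hit.identity < min_identity:
            return "not"
    return "homologous"


class AmbiguousOverlapError(ValueError):
    """More than one distinct perfect overlap between two transcripts."""


def merge_overlapping_transcripts(t1: str, t2: str, min_overlap: int = 100,
                                  trim5: int = 0, trim3: int = 0) -> str | None:
    """Merge two transcripts sharing a perfect suffix/prefix overlap.

    Requires 100% identity over an overlap of at least min_overlap nt (after
    optionally trimming trim5 nt from the 5' end of t2 and trim3 nt from the
    3' end of t1, mirroring manual cleanup of ragged contig ends).  Returns
    t1 + t2 minus the overlap, or None when no qualifying overlap exists.
    Multiple distinct qualifying overlaps raise AmbiguousOverlapError (the
    merge would be recombination-ambiguous).
    """
    if not t1 or not t2:
        raise ValueError("transcripts must be non-empty")
    t1 = t1[:len(t1) - trim3] if trim3 else t1
    t2 = t2[trim5:] if trim5 else t2
    hits = [L for L in range(min_overlap, min(len(t1), len(t2)) + 1)
            if t1[-L:] == t2[:L]]
    if not hits:
        return None
    if len(hits) > 1:
        raise AmbiguousOverlapError(f"{len(hits)} distinct overlaps: {hits}")
    L = hits[0]
    return t1 + t2[L:]
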