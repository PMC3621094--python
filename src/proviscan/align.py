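"""Pairwise-alignment helpers shared by the search, delineation and dating stages.

All dynamic programming is delegated to :class:`Bio.Align.PairwiseAligner`
(full Smith–Waterman / Needleman–Wunsch, affine gaps); this module only
configures scoring and converts Biopython alignments into plain spans.

Scoring conventions follow BLAST's cost parameterisation: a "gap existence
cost g, extension cost e" means a gap of length k costs g + k·e, i.e. the
aligner's open score is -(g + e) and its extension score is -e.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=None)
def blosum62_neutral_x():
    """BLOSUM62 with the 'X' row/column zeroed.

    Unknown residues (from N-containing codons / non-sequenced regions) score
    0 against everything so they neither reward nor punish an alignment.
    """
    m = substitution_matrices.load("BLOSUM62")
    alphabet = m.alphabet
    xi = alphabet.index("X")
    for j in range(len(alphabet)):
        m[xi, j] = 0.0
        m[j, xi] = 0.0
    return m


def sanitize_protein(seq: str) -> str:
    """Map residues outside the scoring alphabet to 'X'."""
    alphabet = set(blosum62_neutral_x().alphabet)
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def protein_local_aligner(gap_open: int = 11, gap_extend: int = 1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = blosum62_neutral_x()
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def nucleotide_aligner(match: int = 1, mismatch: int = -3, gap_open: int = 5,
                       gap_extend: int = 2, mode: str = "local",
                       end_gaps_free: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.wildcard = "N"
    if end_gaps_free and mode == "global":
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


@dataclass(frozen=True)
class LocalHit:
    """A single best local alignment, in 0-based half-open coordinates."""

    score: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    identities: int
    mismatches: int
    gap_columns: int

    @property
    def aligned_columns(self) -> int:
        return self.identities + self.mismatches + self.gap_columns

    @property
    def identity(self) -> float:
        n = self.aligned_columns
        return self.identities / n if n else 0.0


def align_local(query: str, target: str, aligner: Align.PairwiseAligner) -> LocalHit | None:
    """Best local alignment of query vs target, or None for an empty alignment.

    Biopython enumerates co-optimal alignments in a deterministic order; the
    first one is used, which resolves ties reproducibly.
    """
    if not query or not target:
        return None
    score = aligner.score(query, target)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(query, target)))
    qblocks, tblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    counts = aln.counts()
    return LocalHit(
        score=float(score),
        query_span=(int(qblocks[0][0]), int(qblocks[-1][1])),
        target_span=(int(tblocks[0][0]), int(tblocks[-1][1])),
        identities=int(counts.identities),
        mismatches=int(counts.mismatches),
        gap_columns=int(counts.gaps),
    )
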