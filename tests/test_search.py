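"""Translated search: six-frame semantics, Smith–Waterman vs oracle, E-values."""
import math
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

from proviscan import references
from proviscan.search import (
    AlignmentParams,
    evalue,
    intersect_gene_hits,
    local_align_protein,
    search_genome,
    six_frame_translate,
)
from proviscan.seqtools import revcomp
from proviscan.simulate import make_background

AA = "ACDEFGHIKLMNPQRSTVWY"


# --- independent oracles -----------------------------------------------------

def oracle_translate(dna: str) -> str:
    """Codon walk straight off the codon table (independent of Bio.Seq)."""
    table = dict(unambiguous_dna_by_id[1].forward_table)
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i:i + 3]
        if codon in ("TAA", "TAG", "TGA"):
            out.append("*")
        else:
            out.append(table.get(codon, "X"))
    return "".join(out)


def oracle_sw_affine(q: str, t: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Brute-force Gotoh local alignment (gap of length k costs open + k*ext)."""
    m62 = substitution_matrices.load("BLOSUM62")

    def score(a, b):
        if a == "X" or b == "X":
            return 0.0
        return m62[a, b]

    n, m = len(q), len(t)
    NEG = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (t consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target
    best = 0.0
    go = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + score(q[i - 1], t[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# --- six-frame translation ---------------------------------------------------

class TestSixFrame:
    def test_forward_codon_table(self):
        segs = six_frame_translate("ATGGCC")
        assert segs[0].protein == "MA"

    def test_reverse_strand_symmetry(self):
        segs = six_frame_translate("CAT")
        assert segs[3].protein == "M"  # revcomp is ATG

    def test_n_codons_become_x(self):
        assert six_frame_translate("ANNGCC")[0].protein == "XA"

    def test_all_frames_match_codon_walk_oracle(self):
        rng = random.Random(17)
        for _ in range(20):
            dna = "".join(rng.choice("ACGT") for _ in range(60))
            segs = six_frame_translate(dna)
            rc = revcomp(dna)
            for off in range(3):
                assert segs[off].protein == oracle_translate(dna[off:])
                assert segs[3 + off].protein == oracle_translate(rc[off:])

    def test_coordinate_map_roundtrip(self):
        dna = make_background(90, 0.5, [], seed=2).sequence
        for seg in six_frame_translate(dna, "s"):
            for i in range(len(seg.protein)):
                s, e = seg.dna_span(i, i + 1)
                codon = dna[s:e] if seg.frame > 0 else revcomp(dna[s:e])
                assert oracle_translate(codon) == seg.protein[i]

    def test_empty_input(self):
        assert all(s.protein == "" for s in six_frame_translate(""))


# --- local alignment ---------------------------------------------------------

class TestLocalAlign:
    def test_self_alignment_equals_diagonal_sum(self):
        m62 = substitution_matrices.load("BLOSUM62")
        q = "HEAGAWGHEE"
        hit = local_align_protein(q, q)
        assert hit.score == sum(m62[c, c] for c in q)
        assert hit.identity == 1.0

    def test_textbook_pair_matches_oracle(self):
        hit = local_align_protein("HEAGAWGHEE", "PAWHEAE")
        assert hit.score == oracle_sw_affine("HEAGAWGHEE", "PAWHEAE")

    def test_all_negative_problem_gives_empty_alignment(self):
        assert local_align_protein("WWWW", "PPPP") is None

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_dp_on_random_pairs(self, seed):
        rng = random.Random(100 + seed)
        for _ in range(25):
            q = "".join(rng.choice(AA) for _ in range(rng.randint(3, 10)))
            t = "".join(rng.choice(AA) for _ in range(rng.randint(3, 10)))
            got = local_align_protein(q, t)
            want = oracle_sw_affine(q, t)
            assert (0.0 if got is None else got.score) == want, (q, t)


# --- Karlin–Altschul statistics ---------------------------------------------

class TestEvalue:
    def test_closed_form_hand_calculation(self):
        e = evalue(50, 100, 1000, AlignmentParams(K=0.041, lam=0.267))
        assert e == pytest.approx(0.041 * 100 * 1000 * math.exp(-0.267 * 50))
        assert e == pytest.approx(6.6e-3, rel=0.02)

    def test_strictly_decreasing_in_score(self):
        es = [evalue(s, 100, 1000) for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))
        assert es[-1] < 1e-15

    def test_linear_in_search_space(self):
        assert evalue(40, 100, 2000) == pytest.approx(2 * evalue(40, 100, 1000))
        assert evalue(40, 200, 1000) == pytest.approx(2 * evalue(40, 100, 1000))


# --- genome search -----------------------------------------------------------

class TestSearchGenome:
    def test_exact_planted_coding_sequence_is_found(self):
        gag_cds = references.ref_cds()["GAG"]
        bg = make_background(3000, 0.42, [], seed=5).sequence
        scaffold = ("s1", bg[:1500] + gag_cds + bg[1500:])
        hits = search_genome({"gag": references.search_queries()["gag"]}, [scaffold])
        assert len(hits) >= 1
        top = hits.iloc[0]
        assert top.pident > 99.0 and top.evalue < 1e-100
        assert top.sstart >= 1500 and top.send <= 1500 + len(gag_cds)

    def test_random_scaffold_yields_no_hits_at_cutoff(self):
        scaffold = make_background(100_000, 0.42, [], seed=23, scaffold_id="r")
        hits = search_genome(references.search_queries(), [scaffold])
        assert hits.empty

    def test_true_target_beats_shuffled_nulls(self):
        # composition-preserving shuffles of the target should essentially
        # never reach the score of the genuine homolog
        from proviscan.align import protein_local_aligner, sanitize_protein

        query = sanitize_protein(references.ref_proteins()["GAG"])
        target = list(query)  # the true target: the homolog itself
        aligner = protein_local_aligner()
        true_score = aligner.score(query, "".join(target))
        rng = np.random.default_rng(7)
        wins = 0
        for _ in range(100):
            perm = rng.permutation(len(target))
            shuffled = "".join(target[i] for i in perm)
            if aligner.score(query, shuffled) < true_score:
                wins += 1
        assert wins >= 95


class TestIntersection:
    def _hit(self, sid, gene, start, end, strand="+", ev=1e-30):
        import pandas as pd
        return pd.DataFrame([{"qid": gene.upper(), "gene": gene, "sid": sid,
                              "frame": 1 if strand == "+" else -1,
                              "strand": strand, "pident": 90.0,
                              "length": end - start, "qstart": 0, "qend": 10,
                              "sstart": start, "send": end, "evalue": ev,
                              "bitscore": 500.0}])

    def test_missing_gene_gives_no_locus(self):
        import pandas as pd
        gag = self._hit("s", "gag", 100, 400)
        pol = self._hit("s", "pol", 500, 900)
        env = pd.DataFrame(columns=gag.columns)
        assert intersect_gene_hits(gag, pol, env) == []

    def test_colinear_triple_gives_one_locus(self):
        gag = self._hit("s", "gag", 1000, 2300)
        pol = self._hit("s", "pol", 2400, 4900)
        env = self._hit("s", "env", 5000, 6600)
        loci = intersect_gene_hits(gag, pol, env, scaffold_lengths={"s": 10000})
        assert len(loci) == 1
        assert loci[0].span == (0, 8600)  # padded by 2 kb, clipped at 0
        assert loci[0].strand == "+"

    def test_wrong_order_rejected(self):
        gag = self._hit("s", "gag", 5000, 6300)
        pol = self._hit("s", "pol", 2400, 4900)
        env = self._hit("s", "env", 1000, 2300)
        assert intersect_gene_hits(gag, pol, env) == []
        # ...but the same layout is a valid minus-strand locus
        gag_m = self._hit("s", "gag", 5000, 6300, strand="-")
        pol_m = self._hit("s", "pol", 2400, 4900, strand="-")
        env_m = self._hit("s", "env", 1000, 2300, strand="-")
        loci = intersect_gene_hits(gag_m, pol_m, env_m,
                                   scaffold_lengths={"s": 10000})
        assert len(loci) == 1 and loci[0].strand == "-"

    def test_two_distant_proviruses_give_two_loci(self):
        import pandas as pd
        gag = pd.concat([self._hit("s", "gag", 1000, 2300),
                         self._hit("s", "gag", 31000, 32300)])
        pol = pd.concat([self._hit("s", "pol", 2400, 4900),
                         self._hit("s", "pol", 32400, 34900)])
        env = pd.concat([self._hit("s", "env", 5000, 6600),
                         self._hit("s", "env", 35000, 36600)])
        loci = intersect_gene_hits(gag, pol, env, scaffold_lengths={"s": 50000})
        assert len(loci) == 2
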