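"""ORF finding, PBS assignment, motif scan, gene-state calling, repeat search."""
import numpy as np
import pytest

from proviscan import references
from proviscan.annotate import (
    assign_pbs,
    call_gene_state,
    dutpase_present,
    find_orfs,
    find_repeats,
    reconstruct_protein,
    scan_motifs,
)
from proviscan.seqtools import random_dna, revcomp
from proviscan.simulate import build_provirus, make_group_template

STOPS = ("TAA", "TAG", "TGA")


# --- ORFs --------------------------------------------------------------------

def oracle_orfs(dna, min_codons):
    """Independent per-frame scan: earliest ATG after each in-frame stop."""
    found = []
    for frame in range(3):
        codons = [(i, dna[i:i + 3]) for i in range(frame, len(dna) - 2, 3)]
        start = None
        for i, c in codons:
            if c in STOPS:
                if start is not None and (i - start) // 3 >= min_codons:
                    found.append((start, i + 3))
                start = None
            elif c == "ATG" and start is None:
                start = i
    return sorted(found)


class TestFindOrfs:
    def test_no_atg_no_orfs(self):
        assert find_orfs("GGCCGGTTCCGG" * 100) == []

    def test_matches_bruteforce_frame_scan(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            dna = random_dna(3000, 0.45, rng)
            got = sorted(o.span for o in find_orfs(dna, min_codons=20))
            assert got == oracle_orfs(dna, 20)

    def test_ltr_orf_of_123_codons_reported_in_ltr(self):
        dna, spans = build_provirus(make_group_template("V"))
        elements = {k: spans[k] for k in ("ltr5", "ltr3", "gag", "pro", "pol", "env")}
        orfs = find_orfs(dna, min_codons=100, element_spans=elements)
        in_ltr = [o for o in orfs if o.placement == "in-LTR"]
        assert len(in_ltr) == 2  # the ORF exists in both identical LTR copies
        # the scanner reports the longest ORF per stop, so an in-frame ATG a
        # few codons upstream of the planted one may extend it slightly
        assert all(o.span[1] == spans[ltr][0] + spans["orf:in-3ltr"][1]
                   - spans["ltr3"][0] for o, ltr in zip(in_ltr, ("ltr5", "ltr3")))
        assert all(123 <= o.length_codons <= 133 for o in in_ltr)

    def test_gene_orfs_classified_core(self):
        dna, spans = build_provirus(make_group_template("II"))
        elements = {k: spans[k] for k in ("ltr5", "ltr3", "gag", "pro", "pol", "env")}
        orfs = find_orfs(dna, min_codons=100, element_spans=elements)
        core = [o for o in orfs if o.placement == "core"]
        for g in ("gag", "pro", "pol", "env"):
            gs, ge = spans[g]
            # one core ORF ends exactly at the gene's stop codon; its start may
            # sit a few in-frame codons upstream in the spacer
            assert any(o.span[1] == ge and abs(o.span[0] - gs) <= 30
                       and (o.span[0] - gs) % 3 == 0 for o in core), g

    def test_overlap_orf_classified_alt_frame(self):
        dna, spans = build_provirus(make_group_template("VI"))
        elements = {k: spans[k] for k in ("ltr5", "ltr3", "gag", "pro", "pol", "env")}
        orfs = find_orfs(dna, min_codons=100, element_spans=elements)
        alt = [o for o in orfs if o.placement == "within-core-alt-frame"]
        assert spans["orf:in-frame-overlap"] in [o.span for o in alt]

    def test_minus_strand_scan(self):
        orf = "ATG" + "GCT" * 30 + "TAA"
        rng = np.random.default_rng(50)
        dna = random_dna(200, 0.5, rng) + revcomp(orf) + random_dna(200, 0.5, rng)
        hits = [o for o in find_orfs(dna, min_codons=30, both_strands=True)
                if o.strand == "-"]
        assert (200, 200 + len(orf)) in [o.span for o in hits]


# --- PBS ---------------------------------------------------------------------

class TestAssignPbs:
    def setup_method(self):
        self.lib = references.trna_library()
        self.rng = np.random.default_rng(33)

    def _leader(self, trna_id, n_mut=0):
        pbs = list(revcomp(self.lib[trna_id]))
        if n_mut:
            for p in self.rng.choice(len(pbs), size=n_mut, replace=False):
                pbs[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[pbs[p]]
        return "".join(pbs) + random_dna(60, 0.5, self.rng)

    def test_exact_pbs_18_of_18(self):
        call = assign_pbs(self._leader("Lys3"))
        assert call.trna_id == "Lys3" and call.matches == 18
        assert call.span == (0, 18)

    def test_never_miscalls_between_lys12_and_lys3_unmutated(self):
        for trna_id in ("Lys1_2", "Lys3", "LysAlt"):
            for _ in range(10):
                assert assign_pbs(self._leader(trna_id)).trna_id == trna_id

    def test_recovery_with_two_mutations(self):
        correct = 0
        for trna_id in ("Lys1_2", "Lys3"):
            for _ in range(50):
                correct += assign_pbs(self._leader(trna_id, n_mut=2)).trna_id == trna_id
        assert correct >= 95

    def test_fully_masked_leader_unknown(self):
        assert assign_pbs("N" * 80).trna_id == "unknown"

    def test_short_leader_unknown(self):
        assert assign_pbs("ACGT").trna_id == "unknown"


# --- motifs ------------------------------------------------------------------

def _translate(cds):
    from Bio.Seq import Seq
    return str(Seq(cds).translate())


class TestScanMotifs:
    def test_all_motif_classes_found_in_unmutated_template(self):
        cds = references.ref_cds()
        proteins = {"gag": _translate(cds["GAG"]), "pro": _translate(cds["PRO"]),
                    "pol": _translate(cds["POL"]), "env": _translate(cds["ENVB"])}
        hits = scan_motifs(proteins)
        ids = {h.motif_id for h in hits if h.assessable}
        assert {"MHR", "zinc_knuckle_1", "zinc_knuckle_2", "protease_DxG",
                "RT_DDD", "IN_DDE"} <= ids
        assert dutpase_present(hits)

    def test_protease_active_site_ablation(self):
        cds = references.ref_cds()
        motif = next(m for m in references.motif_table()
                     if m.motif_id == "protease_DxG")
        pro = list(_translate(cds["PRO"]))
        d_pos = motif.ref_start + motif.key_positions[0]
        assert pro[d_pos] == "D"
        pro[d_pos] = "A"  # D -> A kills the catalytic site
        hits = scan_motifs({"pro": "".join(pro)})
        assert "protease_DxG" not in {h.motif_id for h in hits if h.assessable}
        assert dutpase_present(hits)  # the dUTPase blocks are untouched

    def test_unresolved_key_position_not_assessable(self):
        cds = references.ref_cds()
        motif = next(m for m in references.motif_table() if m.motif_id == "RT_DDD")
        pol = list(_translate(cds["POL"]))
        pol[motif.ref_start + motif.key_positions[0]] = "X"
        hits = scan_motifs({"pol": "".join(pol)})
        rt = [h for h in hits if h.motif_id == "RT_DDD"]
        assert rt and not rt[0].assessable

    def test_dutpase_found_in_every_canonical_template(self):
        for group in ("I", "II", "III", "IV", "V", "VI", "VII", "VIII"):
            dna, spans = build_provirus(make_group_template(group))
            pro = dna[spans["pro"][0]:spans["pro"][1]]
            hits = scan_motifs({"pro": _translate(pro)})
            assert dutpase_present(hits), group


# --- gene states -------------------------------------------------------------

class TestGeneState:
    def setup_method(self):
        self.gag = references.ref_cds()["GAG"]

    def test_unmutated_gene_intact(self):
        st = call_gene_state(self.gag, self.gag, gene="gag")
        assert st.state == "intact" and st.events == []
        assert st.coverage == 1.0

    def test_single_insertion_is_one_frameshift_at_known_position(self):
        # insert 1 nt in a non-repetitive context so the alignment is unambiguous
        pos = 601
        assert self.gag[pos - 1] != "T" != self.gag[pos]
        mutated = self.gag[:pos] + "T" + self.gag[pos:]
        st = call_gene_state(mutated, self.gag, gene="gag")
        assert st.state == "defective"
        fs = [e for e in st.events if e.kind == "frameshift"]
        assert len(fs) == 1 and fs[0].indel_len == 1
        assert abs(fs[0].pos - pos) <= 1

    def test_two_nt_deletion_frameshift(self):
        pos = 450
        mutated = self.gag[:pos] + self.gag[pos + 2:]
        st = call_gene_state(mutated, self.gag, gene="gag")
        fs = [e for e in st.events if e.kind == "frameshift"]
        assert st.state == "defective" and len(fs) == 1
        assert fs[0].indel_len == 2 and abs(fs[0].pos - pos) <= 2

    def test_in_frame_deletion_not_defective(self):
        mutated = self.gag[:300] + self.gag[330:]  # clean 30-nt in-frame deletion
        st = call_gene_state(mutated, self.gag, gene="gag")
        assert st.state == "intact"

    def test_premature_stop_position(self):
        # find a codon turnable into TAA by one substitution
        for c in range(10, len(self.gag) // 3 - 10):
            codon = self.gag[3 * c:3 * c + 3]
            if codon[0] == "T" and codon[1:] != "AA" and codon not in STOPS:
                if "T" + "AA" not in STOPS:
                    continue
                mutated = self.gag[:3 * c] + "TAA" + self.gag[3 * c + 3:]
                st = call_gene_state(mutated, self.gag, gene="gag")
                stops = [e for e in st.events if e.kind == "premature_stop"]
                assert st.state == "defective"
                assert [e.pos for e in stops] == [3 * c]
                break
        else:
            pytest.fail("no suitable codon found")

    def test_nsr_overlap_gives_unknown(self):
        mutated = self.gag[:500] + "N" * 102 + self.gag[602:]
        st = call_gene_state(mutated, self.gag, gene="gag")
        assert st.state == "unknown"

    def test_single_stop_in_pro_semantics(self):
        # "one stop short of intact": a provirus whose only defect is one
        # premature stop in pro
        pro = references.ref_cds()["PRO"]
        c = 150
        mutated = pro[:3 * c] + "TGA" + pro[3 * c + 3:]
        st = call_gene_state(mutated, pro, gene="pro")
        assert st.state == "defective"
        assert [(e.kind, e.pos) for e in st.events] == [("premature_stop", 3 * c)]

    def test_reconstructed_protein_reads_through_frameshift(self):
        pos = 900
        mutated = self.gag[:pos] + "A" + self.gag[pos:]
        prot = reconstruct_protein(mutated, self.gag)
        ref = _translate(self.gag)
        agree = sum(a == b for a, b in zip(prot, ref)) / len(ref)
        assert agree > 0.95  # downstream of the indel still aligned in frame


# --- repeats -----------------------------------------------------------------

def oracle_repeats(dna, word=11, match=1, mismatch=-3, min_score=11, xdrop=12):
    """Quadratic scan over all position pairs, with its own extension logic."""

    def ext(s1, s2, i, j, cap=None):
        # leftwards: walk k = 1, 2, ... taking the first cumulative maximum
        best_l, cum, best = 0, 0, 0
        k = 1
        while i - k >= 0 and j - k >= 0:
            cum += match if (s1[i - k] == s2[j - k] != "N") else mismatch
            if cum > best:
                best, best_l = cum, k
            if cum < best - xdrop:
                break
            k += 1
        score = word * match + best
        best_r, cum, best = 0, 0, 0
        k = 0
        while i + word + k < len(s1) and j + word + k < len(s2):
            if cap is not None and best_l + word + k + 1 > cap:
                break
            cum += match if (s1[i + word + k] == s2[j + word + k] != "N") else mismatch
            if cum > best:
                best, best_r = cum, k + 1
            if cum < best - xdrop:
                break
            k += 1
        return best_l, best_r, score + best

    hits = set()
    n = len(dna)
    rc = revcomp(dna)
    for i in range(n - word + 1):
        for j in range(i + word, n - word + 1):
            if dna[i:i + word] == dna[j:j + word] and "N" not in dna[i:i + word]:
                l, r, sc = ext(dna, dna, i, j, cap=j - i)
                a1, a2 = (i - l, i + word + r), (j - l, j + word + r)
                if sc >= min_score and a1[1] <= a2[0]:
                    hits.add(("direct", a1, a2))
        for j in range(n - word + 1):
            if dna[i:i + word] == rc[j:j + word] and "N" not in dna[i:i + word]:
                l, r, sc = ext(dna, rc, i, j)
                a1 = (i - l, i + word + r)
                a2 = (n - (j + word + r), n - (j - l))
                if sc >= min_score and a1 < a2 and a1[1] <= a2[0]:
                    hits.add(("inverted", a1, a2))
    # drop hits contained (both arms) in a larger hit of the same kind
    def contained(h, g):
        return (h is not g and h[0] == g[0]
                and g[1][0] <= h[1][0] and h[1][1] <= g[1][1]
                and g[2][0] <= h[2][0] and h[2][1] <= g[2][1]
                and (g[1][1] - g[1][0]) >= (h[1][1] - h[1][0]))

    return sorted(h for h in hits if not any(contained(h, g) for g in hits))


class TestFindRepeats:
    def test_planted_direct_repeat(self):
        rng = np.random.default_rng(61)
        arm = "ACGTACGTTTGG"
        dna = (random_dna(300, 0.5, rng) + arm + random_dna(400, 0.5, rng)
               + arm + random_dna(300, 0.5, rng))
        hits = [h for h in find_repeats(dna) if h.kind == "direct"]
        assert any(dna[h.arm1[0]:h.arm1[1]].find(arm) >= 0
                   or arm.find(dna[h.arm1[0]:h.arm1[1]]) >= 0 for h in hits)
        top = max(hits, key=lambda h: h.score)
        assert top.identity == 1.0

    def test_planted_inverted_repeat(self):
        rng = np.random.default_rng(62)
        arm = "GGATCCGTTACA"
        dna = (random_dna(250, 0.5, rng) + arm + random_dna(200, 0.5, rng)
               + revcomp(arm) + random_dna(250, 0.5, rng))
        inv = [h for h in find_repeats(dna) if h.kind == "inverted"]
        assert any(h.arm1[0] <= 250 + len(arm) and h.arm2[1] >= 462 for h in inv)

    def test_random_sequence_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(63)
        for _ in range(5):
            dna = random_dna(1500, 0.5, rng)
            got = sorted((h.kind, h.arm1, h.arm2) for h in find_repeats(dna))
            assert got == oracle_repeats(dna)

    def test_tbe_candidate_flagging(self):
        rng = np.random.default_rng(64)
        arm = "TTACGGATACCA"
        dna = (random_dna(500, 0.5, rng) + arm + random_dna(60, 0.5, rng)
               + arm + random_dna(100, 0.5, rng))
        hits = find_repeats(dna, env_stop=450)
        assert any(h.tbe_candidate for h in hits if h.kind == "direct")
        hits_late = find_repeats(dna, env_stop=600)
        assert not any(h.tbe_candidate for h in hits_late)
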