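"""Regenerate the synthetic reference fixtures packaged under src/proviscan/data/.

The real query set used for betaretrovirus mining (MMTV / MPMV / JSRV / SRV /
SMR Gag, Pol and Env polyproteins, and mammalian lysine-tRNA 3' ends) consists
of public GenBank records.  This repository instead ships deterministic
*synthetic* stand-ins with the same architecture: polyprotein-sized random
proteins carrying the conserved betaretroviral motif blocks (Gag MHR and two
CCHC zinc knuckles; Pro DxG protease active site and the five short blocks of
a trimeric dUTPase; Pol RT catalytic DDD and integrase DDE), lineage variants
forming the phylogenetic clusters the classifier uses as proxies, and a
distinct gammaretroviral-type Env lineage.  Everything is generated from a
fixed seed so the fixtures are bit-reproducible; the planted-provirus
simulator builds its proviruses from the same coding sequences, which keeps
the whole recovery-test truth channel self-consistent.

Run from the repository root:  python scripts/build_reference_fixtures.py
"""
from __future__ import annotations

import pathlib

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "proviscan" / "data"

AA = "ACDEFGHIKLMNPQRSTVWY"
STOPS = {"TAA", "TAG", "TGA"}

# motif_id, gene, ref aa start, consensus block, indices that must match exactly
MOTIFS = [
    ("MHR",            "gag", 260, "KEPFQSYVDRFL",   (0, 4, 8, 9)),
    ("zinc_knuckle_1", "gag", 380, "CAYCKEKGHWAKDC", (0, 3, 8, 13)),
    ("zinc_knuckle_2", "gag", 401, "CAYCKEKGHWAKDC", (0, 3, 8, 13)),
    ("dUTPase_1",      "pro",  20, "AGLDL",          (0, 1, 3)),
    ("dUTPase_2",      "pro",  50, "SGLAAK",         (0, 1)),
    ("dUTPase_3",      "pro",  80, "GVIDSDYRGEIK",   (0, 3, 5)),
    ("dUTPase_4",      "pro", 110, "VAQLIV",         (0, 1)),
    ("dUTPase_5",      "pro", 140, "RGSGGFGSTG",     (0, 5, 9)),
    ("protease_DxG",   "pro", 180, "LLDTGADDTV",     (2, 4)),
    ("RT_DDD",         "pol", 200, "KVDDDLLI",       (2, 3, 4)),
    ("IN_DDE",         "pol", 650, "SADGSDPQSREL",   (2, 5, 10)),
]

GENE_LENGTHS = {"gag": 450, "pro": 300, "pol": 850, "env": 560}

# Pol lineage variants: the classifier's stand-in for phylogenetic placement.
POL_LINEAGES = ["HERVK", "EARLYBAT", "MICROBAT", "TYPEB", "TYPED_JSRV", "TYPED_MPMV"]


def random_protein(n: int, rng: np.random.Generator) -> list[str]:
    prot = ["M"] + [AA[i] for i in rng.integers(0, len(AA), n - 1)]
    return prot


def embed_motifs(prot: list[str], gene: str) -> tuple[list[str], list[tuple[int, int]]]:
    spans = []
    for _, g, start, block, _ in MOTIFS:
        if g != gene:
            continue
        prot[start:start + len(block)] = list(block)
        spans.append((start, start + len(block)))
    return prot, spans


def mutate(prot: list[str], rate: float, protected: list[tuple[int, int]],
           rng: np.random.Generator) -> list[str]:
    shielded = set()
    for s, e in protected:
        shielded.update(range(s, e))
    shielded.add(0)  # keep the start Met
    out = list(prot)
    for i in range(len(out)):
        if i in shielded or rng.random() >= rate:
            continue
        out[i] = AA[int(rng.integers(0, len(AA)))]
        while out[i] == prot[i]:
            out[i] = AA[int(rng.integers(0, len(AA)))]
    return out


def back_translate(prot: list[str], rng: np.random.Generator,
                   forced: dict[int, str] | None = None) -> str:
    table = unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for v in by_aa.values():
        v.sort()
    codons = []
    for i, aa in enumerate(prot):
        if forced and i in forced:
            codons.append(forced[i])
        else:
            opts = by_aa[aa]
            codons.append(opts[int(rng.integers(0, len(opts)))])
    codons.append("TAA")
    return "".join(codons)


def fix_plus1_stops(cds: str, start: int, rng: np.random.Generator,
                    protein: list[str]) -> str:
    """Recode codons synonymously so no stop occurs in the +1 frame from
    `start` to the end of the CDS (makes room for an overlapping alt-frame ORF)."""
    table = unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    cds = list(cds)
    for _ in range(200):
        bad = None
        for p in range(start, len(cds) - 2, 3):
            if "".join(cds[p:p + 3]) in STOPS:
                bad = p
                break
        if bad is None:
            return "".join(cds)
        # the +1-frame triplet at `bad` overlaps codons bad//3 and bad//3 + 1
        for ci in (bad // 3, bad // 3 + 1):
            if ci >= len(protein):
                continue
            opts = by_aa[protein[ci]]
            cur = "".join(cds[3 * ci:3 * ci + 3])
            alts = [c for c in opts if c != cur]
            if alts:
                cds[3 * ci:3 * ci + 3] = list(alts[int(rng.integers(0, len(alts)))])
                break
    raise RuntimeError("could not clear +1-frame stops")


def write_fasta(path: pathlib.Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(712013)

    prot_records: list[tuple[str, str]] = []
    cds_records: list[tuple[str, str]] = []
    protected: dict[str, list[tuple[int, int]]] = {}
    base: dict[str, list[str]] = {}

    for gene in ("gag", "pro", "pol"):
        p = random_protein(GENE_LENGTHS[gene], rng)
        p, spans = embed_motifs(p, gene)
        base[gene] = p
        protected[gene] = spans
        prot_records.append((gene.upper(), "".join(p)))
        cds_records.append((gene.upper(), back_translate(p, rng)))

    # Betaretroviral Env: engineer the tail so a +1-frame ATG sits 59 nt before
    # the env stop with a clear run to the CDS end (overlapping-ORF templates).
    envb = random_protein(GENE_LENGTHS["env"], rng)
    envb[541] = "D"
    envb[542] = "V"
    cds_envb = back_translate(envb, rng, forced={541: "GAT", 542: "GTG"})
    cds_envb = fix_plus1_stops(cds_envb, 1624, rng, envb)
    assert cds_envb[1624:1627] == "ATG"
    for p in range(1624, len(cds_envb) - 2, 3):
        assert cds_envb[p:p + 3] not in STOPS
    base["env"] = envb
    protected["env"] = [(541, 543)]
    prot_records.append(("ENVB", "".join(envb)))
    cds_records.append(("ENVB", cds_envb))

    # Gammaretroviral-type Env: an independent lineage (unrelated sequence).
    envg = random_protein(GENE_LENGTHS["env"], rng)
    prot_records.append(("ENVG", "".join(envg)))
    cds_records.append(("ENVG", back_translate(envg, rng)))

    # Pol lineage variants (phylogenetic-placement proxies) at ~18% aa divergence.
    for name in POL_LINEAGES:
        v = mutate(base["pol"], 0.18, protected["pol"], rng)
        prot_records.append((f"POL_{name}", "".join(v)))
        cds_records.append((f"POL_{name}", back_translate(v, rng)))

    # Env lineage variants used as additional classification references.
    for name, parent, prot in [("ENVB_TYPEB", "env", envb), ("ENVB_TYPED", "env", envb),
                               ("ENVG_MPMV", None, envg)]:
        v = mutate(prot, 0.15, protected["env"] if parent else [], rng)
        prot_records.append((name, "".join(v)))

    write_fasta(OUT / "ref_proteins.synthetic.faa", prot_records)
    write_fasta(OUT / "ref_cds.synthetic.fna", cds_records)

    # Lysine-tRNA 3'-end 18-mers.  Lys3 is the canonical mammalian tRNA-Lys3
    # 3' end; the other two are synthetic variants at Hamming distance 6 from
    # it (disjoint mutated position sets, so they are 12 apart from each other).
    lys3 = "TGGCGCCCGAACAGGGAC"
    nxt = {"A": "C", "C": "G", "G": "T", "T": "A"}

    def variant(seq: str, positions: list[int]) -> str:
        s = list(seq)
        for p in positions:
            s[p] = nxt[s[p]]
        return "".join(s)

    lys12 = variant(lys3, [8, 10, 11, 12, 13, 15])
    lysalt = variant(lys3, [3, 4, 5, 6, 7, 9])
    for a, b in [(lys3, lys12), (lys3, lysalt), (lys12, lysalt)]:
        assert sum(x != y for x, y in zip(a, b)) >= 6
    write_fasta(OUT / "trna_lys.synthetic.fa",
                [("Lys1_2", lys12), ("Lys3", lys3), ("LysAlt", lysalt)])

    with open(OUT / "motifs.tsv", "w") as fh:
        fh.write("motif_id\tgene\tref_start\tpattern\tkey_positions\n")
        for mid, gene, start, block, keys in MOTIFS:
            fh.write(f"{mid}\t{gene}\t{start}\t{block}\t{','.join(map(str, keys))}\n")

    with open(OUT / "rates.yaml", "w") as fh:
        fh.write(
            "# Neutral genomic substitution rates (substitutions/site/year) per host\n"
            "# clade, used by the LTR molecular clock T = (D/R)/2.  Back-calculated\n"
            "# from published provirus divergence/age pairs; override per analysis.\n"
            "megabat: 4.0e-10\n"
            "microbat: 9.5238e-10\n"
        )
    print(f"wrote fixtures to {OUT}")


if __name__ == "__main__":
    main()
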