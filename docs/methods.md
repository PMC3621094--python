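# Methods

This note documents the models, parameters and numerical choices behind
`proviscan`, and what the synthetic validation does and does not establish.

## The provirus model and the generative clock

A provirus is assembled as `5'LTR – PBS/leader – gag – pro – pol – env
(– extra ORFs) – PPT – 3'LTR` with the two LTR copies exactly identical,
then inserted behind a duplicated 4-nt target site (TSD) — the state of a
genuine integration at age zero.  Post-integration decay is neutral: every
site receives Poisson(R·T) substitution events (uniform replacement,
Jukes–Cantor style; the p-distance estimator downstream matches this
model), plus an indel (length 1–3, insertion/deletion equiprobable) with
probability `indel_rate × R·T` per site.  Because the planted sequence
contains both LTR copies and all sites mutate independently, the expected
5'-vs-3' LTR pairwise divergence is `2·R·T` — exactly the assumption the
molecular clock `T = (D/R)/2` inverts.

Parameters and defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| `rate_R` | per plant (megabat 4.0×10⁻¹⁰, microbat 9.52×10⁻¹⁰) | subs/site/year | back-calculated from published divergence/age pairs; shipped in `data/rates.yaml`, overridable — rates are configuration, not estimated here |
| `age_T` | per plant | years | study variable |
| `indel_rate` | 0.05 | indel events per substitution event | no indel model is established for this decay process; 5% with lengths 1–3 generates realistic frameshift/defective gene states without destroying delineation; flagged as a stand-in |
| LTR length | 300–1,400 nt (group templates 370–1,265) | nt | Type D ~300–500, Type B ~1,200 |
| TSD | uniform 4-mers, homopolymers excluded | — | avoids degenerate flank matches |
| background GC | 0.42 | fraction | mammalian-like |

LTRs in the group templates begin `TG` and end `CA`, the canonical
retroviral att dinucleotides left by integrase — both a fidelity feature
and the anchor the delineator's edge refinement uses (below).

## Synthetic reference set

The packaged reference proteins, coding sequences and lysine-tRNA 3' ends
are deterministic synthetic stand-ins (generated by
`scripts/build_reference_fixtures.py`, fixed seed), not database records:
polyprotein-sized random sequences carrying the conserved motif blocks at
fixed positions (Gag MHR + two CCHC knuckles; Pro DxG + five dUTPase
blocks; Pol RT-DDD + IN-DDE), six Pol lineage variants at ~18% amino-acid
divergence forming the clusters the classifier anchors to, and an
independent gammaretroviral-type Env lineage.  The tRNA 18-mers are the
canonical mammalian tRNA-Lys3 3' end plus two variants at Hamming
distance 6 (so a ≤2-mutation PBS can never flip between classes under the
≥2-match margin rule).  The simulator builds provirus gene blocks from the
same coding sequences, which makes recovery exact by construction.

Consequence for interpretation: passing the recovery tests shows the
pipeline's machinery is correct under its own model — real assemblies add
nested/solo LTR elements, host gene paralogs, repeat families, assembly
errors and non-uniform base composition that the simulator does not
emulate, so real-data performance is not certified by these tests.

## Search statistics and alignment scoring

All pairwise alignment is full dynamic programming (Biopython's
PairwiseAligner): no heuristic word seeding is used in the search path, so
sensitivity does not depend on seed survival.  Scoring follows BLAST cost
conventions (a gap of length k costs existence + k·extension): protein
BLOSUM62 with 11/1, nucleotide +1/−3 with 5/2.  Unknown residues (X, from
N-containing codons) score 0 against everything — non-sequenced regions
neither support nor penalise an alignment.  E-values use the
Karlin–Altschul form `E = K·m·n·e^(−λS)` with the published gapped
BLOSUM62 constants K = 0.041, λ = 0.267 (overridable; the search space is
query length × scaffold nucleotide length).  With the 10⁻¹⁰ cutoff a
random 100-kb scaffold produces no hits, while planted genes at ≤6% LTR
divergence score thousands of bits above threshold.  Low-complexity
filtering is a windowed Shannon-entropy mask (12-residue window, 2.2-bit
threshold), on for the search, off for the repeat finder.

Gene spans for annotation are re-anchored at the DNA level: protein-level
local hits truncate at frameshifts, so the chosen reference CDS is locally
aligned across the whole LTR interior (nucleotide alignment steps over
indels), recovering full gene extents; `pro` — not a search gene — is
located the same way between gag and pol.

## LTR delineation and edge refinement

The locus is self-aligned via exact 11-mer seeds between its two ends,
clustered by diagonal (tolerance 30 nt, accommodating indels); the best
cluster's windows (±60 nt pad) are locally aligned and the alignment ends
give the repeat boundaries.  Accepted pairs need identity ≥0.80 and
lengths in [250, 1500] nt, bracketing all three gene hits.

Raw alignment termini can err by up to ~15 nt: the purine-rich PPT abuts
the 3' LTR and the PBS abuts the 5' LTR, so flanking sequence can
spuriously extend (or terminal mutations truncate) the repeat alignment.
Edge refinement searches alignment-start/end shifts (±18 nt) for positions
where the flanking 4-mers match exactly (the TSD), scored with bonuses for
the `TG…CA` att dinucleotides; shifts beyond 4 nt require at least one att
anchor, beyond 10 nt both.  The winning shift is applied to both edges
that track the same alignment endpoint.  A chance 4-mer pair can still
mis-snap an edge by a few nt in rare cases (order 10⁻²–10⁻³ per provirus);
elements with truncated LTRs can acquire a spurious "TSD" from the
small-shift window with probability of a few percent — a known limitation.

Other delineation rules: the TSD requires an exact 4/4 match (no mismatch
tolerance); N in a flank makes the call "masked".  The PPT is the longest
window with purine fraction ≥0.85 ending within 5 nt of the 3' LTR,
required to begin and end on a purine (otherwise any 19-nt tract would
report as 20+ by absorbing one adjacent pyrimidine); ties prefer longest,
then closest.  Transcript merging demands 100% identity over ≥100 nt of
suffix/prefix overlap, with explicit end-trim parameters for ragged contig
ends; multiple distinct qualifying overlaps are an error rather than a
guess.  Flank comparison calls two proviruses duplication products when
both upstream and downstream 1-kb flanks locally align at ≥80% identity
over ≥half the flank.

## Annotation

ORFs are ATG→stop spans of ≥100 codons (one per stop codon, longest ATG),
a cutoff chosen to suppress incidental ORFs; note that frameshifted genes
legitimately produce long shifted-frame ORFs from internal ATGs, so ORFs
≥80% contained in a core gene are classified `core` (same frame) or
`gene-fragment` (shifted frame) and not counted as novel extra ORFs.
Incidental alt-frame ORFs crossing element boundaries can still
occasionally pass the cutoff — the count of extra ORFs carries that noise,
as any fixed cutoff does.

The PBS is assigned by sliding the reverse complement of each tRNA 3'
18-mer ungapped along the 5'LTR→gag leader: call the best tRNA iff it
reaches ≥14/18 matches and beats the runner-up by ≥2; an indel inside the
PBS defeats the ungapped probe by design (the call degrades to unknown
rather than guessing).  The leader is taken with a 10-nt pad into the 5'
LTR so a fuzzy inner edge cannot clip the PBS.

Motifs are checked only at the positions where the reference carries them,
on a protein reconstructed codon-by-codon in reference coordinates from
the DNA alignment (this reads through frameshifts); a motif block is a hit
when all key residues match and ≥60% of the block is identical, and "not
assessable" when a key position is unresolved.  The dUTPase domain is
called present when ≥3 of its 5 blocks are found.  Gene states: defective
iff at least one frameshift (indel length ≢ 0 mod 3) or premature stop;
in-frame indels alone do not disqualify; an N-run ≥20 nt with no events
gives unknown.  Premature-stop positions are the first nucleotide of the
stop codon; indel positions are the alignment's (leftmost) placement, which
in repetitive context can differ by a base or two from the generative
event.

The repeat finder (direct: self vs self off-diagonal; inverted: self vs
reverse complement) uses exact 11-mer seeds with maximal-scoring ungapped
extension (+1/−3, X-drop 12, minimum score 11), arms non-overlapping,
contained hits pruned, and low complexity deliberately unfiltered.
Direct-repeat pairs entirely downstream of the env stop are flagged as
CTE/Tap-binding-element architecture candidates — an architectural flag
only; no RNA secondary structure is assessed.

## Dating

`D` is an uncorrected p-distance over the globally aligned LTR pair with
gap and N columns excluded from numerator and denominator (the clock's
calibration is itself p-distance-based; no multiple-hit correction).
`T = (D/R)/2` is reported in Myr to one decimal, rounding halves up (the
convention of the age tables this format mirrors) with a 10⁻⁶ guard so
values that are exact halves in rational arithmetic do not flip down
through float representation.  Undefined D (masked or unalignable LTRs)
propagates as "ND".  Gene conversion between LTRs would bias D downward;
it is a caveat of the method, not corrected.

Calibration: over 200 replicate plants per age point (1,400-nt LTRs,
substitution-only decay — the regime in which the binomial error bound is
the only noise source), the mean estimated age is within 5% of truth for
T ∈ {5, 15, 30} Myr at the megabat rate.  At T = 5 Myr the 5% band is
≈1.7 binomial standard errors of the 200-plant mean, so that point is
intrinsically near the statistical floor of the design.  Single-provirus
estimates with 400-nt LTRs scatter much more widely (a handful of
divergence sites), as the worked example in the README shows.

## Classification

Phylogenetic placement is proxied by the best Pol local-alignment score
against the packaged lineage references — group membership is ultimately
anchored to named representatives, which is what the score recovers; full
ML trees are out of scope.  Env lineage requires the winning reference set
to beat the other by >5% of the top score (recombination chimeras and
weak alignments return unknown).  The rules fire in order: gamma env →
VIII (dominates all contradictions, with a warning in the rule trace);
HERV-K proxy + Lys 1,2 → I; early-bat proxy → II; microbat proxy + Lys 3 →
III (microbat proxy without Lys 3 is reported "II-or-III ambiguous"
rather than guessed); LysAlt + Type B → IV; long LTR + Lys 3 + Type B → V;
short LTR + Lys 1,2 + beta env → VI; short LTR + Lys 3 + beta env → VII.
Every call carries its fired-rule trace.

## Problem sizes and determinism

Validation runs use one scaffold per plant (~6-kb background plus the
provirus) with 20 plants spanning LTR divergences 0.004–0.056, 50
provirus-free 6-kb decoy scaffolds, and 3×200 plants for the age grid —
sizes at which exact dynamic programming completes in about a minute while
every statistical bound retains its power.  All randomness flows from
explicit integer seeds (child seeds via NumPy SeedSequence); a pipeline
rerun with the same config and seed is byte-identical, including the JSON
report.

## Known limitations

- The indel decay model is a stand-in; no empirical indel spectrum is fit.
- Edge refinement can mis-snap a boundary by ≤4 nt on rare chance 4-mer
  matches, and truncated-LTR elements can gain a spurious TSD call.
- Nested and solo-LTR elements, tandem arrays and host repeat families are
  not modelled or resolved.
- The Pol score proxy may not separate closely related lineage clusters on
  inputs far from every packaged reference (reported as ambiguous).
- Minus-strand loci are processed by reverse-complementing the locus; all
  simulator plants are forward-strand, so that path is exercised only by
  synthetic hit-table tests.
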