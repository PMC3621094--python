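"""Rule-based assignment of proviruses to the eight betaretroviral sub-groups.

The genus splits into eight sub-groups (I–VIII) distinguished by a few
discrete characters: which lysine tRNA the primer binding site is
complementary to (Lys 1,2 vs Lys 3 vs an alternative lysine tRNA), LTR
length class (Type B ~1,200 nt vs Type D ~300–500 nt), whether the env
lineage is betaretroviral or was acquired from gammaretroviruses, extra
ORFs and their placement, and phylogenetic placement of the highly
conserved Pol.  Full maximum-likelihood trees are out of scope here;
phylogenetic placement is proxied by the best Pol local-alignment score
against the packaged lineage references, which anchors each cluster to its
named representative exactly as the grouping scheme does.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from proviscan import references
from proviscan.align import align_local, protein_local_aligner, sanitize_protein

GROUPS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


@dataclass
class FeatureVector:
    """Discrete classification characters for one provirus."""

    pbs_type: str  # Lys1_2 | Lys3 | LysAlt | unknown
    ltr_class: str  # short (<=600 nt) | long (>=1000 nt) | unknown
    env_lineage: str  # beta | gamma | unknown
    extra_orf_placements: frozenset[str] = frozenset()
    dutpase_present: bool = True
    phylo_proxy: str = "unknown"  # HERVK|EARLYBAT|MICROBAT|TYPEB|TYPED_JSRV|TYPED_MPMV


@dataclass
class GroupLabel:
    group: str  # I..VIII | unclassified
    trace: list[str] = field(default_factory=list)


def ltr_length_class(length: int | None) -> str:
    if length is None:
        return "unknown"
    if length <= 600:
        return "short"
    if length >= 1000:
        return "long"
    return "unknown"


def env_lineage(env_protein: str,
                beta_refs: list[tuple[str, str]] | None = None,
                gamma_refs: list[tuple[str, str]] | None = None,
                margin: float = 0.05, score_floor: float = 50.0) -> str:
    """beta or gamma, by which reference Env set aligns better.

    The winning set must beat the other by more than `margin` of the top
    score; anything closer — e.g. a recombination chimera — is unknown.
    """
    if beta_refs is None or gamma_refs is None:
        b, g = references.env_lineage_refs()
        beta_refs = beta_refs or b
        gamma_refs = gamma_refs or g
    aligner = protein_local_aligner()
    query = sanitize_protein(env_protein)

    def best(refs: list[tuple[str, str]]) -> float:
        return max(aligner.score(query, sanitize_protein(seq)) for _, seq in refs)

    sb, sg = best(beta_refs), best(gamma_refs)
    top = max(sb, sg)
    if top < score_floor:
        return "unknown"
    if abs(sb - sg) < margin * top:
        return "unknown"
    return "beta" if sb > sg else "gamma"


def pol_proxy(pol_protein: str, refs: dict[str, str] | None = None) -> str:
    """Nearest Pol lineage reference by local-alignment score (phylogeny proxy)."""
    refs = refs or references.pol_lineage_refs()
    aligner = protein_local_aligner()
    query = sanitize_protein(pol_protein)
    best_name, best_score = "unknown", float("-inf")
    for name in sorted(refs):
        score = aligner.score(query, sanitize_protein(refs[name]))
        if score > best_score:
            best_name, best_score = name, score
    return best_name if best_score > 0 else "unknown"


def classify_group(fv: FeatureVector) -> GroupLabel:
    """Ordered decision rules mapping a feature vector to sub-group I–VIII.

    A gammaretroviral env dominates every other character (it defines group
    VIII); contradictory features are noted in the rule trace rather than
    silently discarded.
    """
    trace: list[str] = []

    if fv.env_lineage == "gamma":
        trace.append("env lineage gamma -> VIII (MPMV-like Type D)")
        if fv.ltr_class == "long":
            trace.append("warning: long LTR contradicts Type D; env rule dominates")
        return GroupLabel("VIII", trace)

    if fv.phylo_proxy == "HERVK" and fv.pbs_type == "Lys1_2":
        trace.append("Pol near HERV-K anchor + Lys1,2 PBS -> I")
        return GroupLabel("I", trace)
    if fv.phylo_proxy == "EARLYBAT":
        trace.append("Pol in early-branching bat cluster -> II")
        return GroupLabel("II", trace)
    if fv.phylo_proxy == "MICROBAT":
        if fv.pbs_type == "Lys3":
            trace.append("divergent microbat Pol cluster + Lys3 PBS -> III")
            return GroupLabel("III", trace)
        trace.append("divergent microbat Pol without Lys3 PBS: II-or-III ambiguous")
        return GroupLabel("unclassified", trace)

    if fv.pbs_type == "LysAlt" and fv.phylo_proxy == "TYPEB":
        trace.append("alternative lysine tRNA PBS + Type B Pol -> IV")
        return GroupLabel("IV", trace)
    if fv.ltr_class == "long" and fv.pbs_type == "Lys3" and fv.phylo_proxy == "TYPEB":
        trace.append("long (~1200 nt) LTR + Lys3 PBS + Type B Pol -> V (MMTV-like)")
        return GroupLabel("V", trace)
    if fv.ltr_class == "short" and fv.pbs_type == "Lys1_2" and fv.env_lineage == "beta":
        trace.append("short LTR + Lys1,2 PBS + beta env -> VI (JSRV-like Type D)")
        return GroupLabel("VI", trace)
    if fv.ltr_class == "short" and fv.pbs_type == "Lys3" and fv.env_lineage == "beta":
        trace.append("short LTR + Lys3 PBS + beta env -> VII")
        if "pre-gag" in fv.extra_orf_placements:
            trace.append("pre-gag ORF, typical of VII")
        return GroupLabel("VII", trace)

    trace.append("no rule fired")
    return GroupLabel("unclassified", trace)


def canonical_feature_vectors() -> dict[str, FeatureVector]:
    """One feature vector per sub-group representative (the Figure-4 panels)."""
    return {
        "I": FeatureVector("Lys1_2", ltr_length_class(968), "beta",
                           frozenset(), True, "HERVK"),
        "II": FeatureVector("Lys1_2", ltr_length_class(422), "beta",
                            frozenset(), True, "EARLYBAT"),
        "III": FeatureVector("Lys3", ltr_length_class(479), "beta",
                             frozenset(), True, "MICROBAT"),
        "IV": FeatureVector("LysAlt", ltr_length_class(440), "beta",
                            frozenset({"pre-gag"}), True, "TYPEB"),
        "V": FeatureVector("Lys3", ltr_length_class(1265), "beta",
                           frozenset({"in-LTR"}), True, "TYPEB"),
        "VI": FeatureVector("Lys1_2", ltr_length_class(398), "beta",
                            frozenset({"within-core-alt-frame"}), True, "TYPED_JSRV"),
        "VII": FeatureVector("Lys3", ltr_length_class(370), "beta",
                             frozenset({"pre-gag"}), True, "TYPED_JSRV"),
        "VIII": FeatureVector("Lys1_2", ltr_length_class(427), "gamma",
                              frozenset({"post-env"}), True, "TYPED_MPMV"),
    }
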