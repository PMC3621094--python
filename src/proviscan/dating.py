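"""Molecular-clock dating of proviral integrations from LTR-pair divergence.

The two LTR copies of a provirus are identical at integration and decay
independently afterwards, so their pairwise divergence D (an uncorrected
p-distance: differences per aligned site, gap and N columns excluded) clocks
the insertion age as

    T = (D / R) / 2

where R is the host clade's neutral substitution rate in substitutions per
site per year, and the division by 2 accounts for mutations accumulating on
both copies.  No multiple-hit correction is applied: for the percent-scale
divergences of interest a p-distance is what the clock is calibrated
against.  D may be compromised by gene conversion between the LTRs; that
caveat is inherent to the method and is not corrected for.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from proviscan import references
from proviscan.align import nucleotide_aligner


@dataclass(frozen=True)
class DivergenceResult:
    """Uncorrected p-distance between a provirus's two LTRs."""

    D: float | None
    aligned_sites: int
    differences: int
    gap_columns: int


@dataclass(frozen=True)
class AgeEstimate:
    """Integration age T = (D/R)/2, reported in million years (Myr)."""

    T_myr: float  # rounded to one decimal for reporting
    T_myr_raw: float
    D: float
    R: float


def ltr_divergence(ltr5: str, ltr3: str) -> DivergenceResult:
    """Global alignment of the two LTRs; D = mismatched / retained columns.

    Columns containing a gap or an N on either side are excluded from both
    numerator and denominator.  D is None (age not computable) when no
    column survives.
    """
    if not ltr5 or not ltr3:
        raise ValueError("both LTR sequences must be non-empty")
    ltr5, ltr3 = ltr5.upper(), ltr3.upper()
    aligner = nucleotide_aligner(mode="global")
    aln = next(iter(aligner.align(ltr5, ltr3)))
    blocks5, blocks3 = aln.aligned
    retained = diffs = 0
    gap_cols = 0
    prev5 = prev3 = 0
    for (s5, e5), (s3, e3) in zip(blocks5, blocks3):
        gap_cols += (s5 - prev5) + (s3 - prev3)
        for a, b in zip(ltr5[s5:e5], ltr3[s3:e3]):
            if a == "N" or b == "N":
                continue
            retained += 1
            diffs += a != b
        prev5, prev3 = e5, e3
    gap_cols += (len(ltr5) - prev5) + (len(ltr3) - prev3)
    D = diffs / retained if retained else None
    return DivergenceResult(D=D, aligned_sites=retained, differences=diffs,
                            gap_columns=gap_cols)


def estimate_age(D: float | None, R: float) -> AgeEstimate | None:
    """Invasion time in Myr from divergence D and clade rate R (per site per year).

    Returns None when D is undefined (masked or unalignable LTRs) — the
    report then shows "ND".
    """
    if R <= 0:
        raise ValueError("substitution rate R must be > 0")
    if D is None:
        return None
    t_years = (D / R) / 2.0
    t_myr = t_years / 1e6
    # report to one decimal, rounding halves up (the convention of the age
    # tables this mirrors); the 1e-6 guard keeps values that are exactly
    # x.x5 in exact arithmetic from flipping down through float error
    t_rounded = math.floor(t_myr * 10 + 0.5 + 1e-6) / 10
    return AgeEstimate(T_myr=t_rounded, T_myr_raw=t_myr, D=D, R=R)


def clade_rate(clade: str) -> float:
    """Configured substitution rate for a host clade (e.g. megabat, microbat)."""
    rates = references.clade_rates()
    try:
        return rates[clade]
    except KeyError:
        raise KeyError(f"no rate configured for clade {clade!r}; "
                       f"known: {sorted(rates)}") from None
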