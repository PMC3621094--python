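"""Small shared sequence utilities (DNA alphabet {A,C,G,T,N})."""
from __future__ import annotations

import math

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_content(seq: str) -> float:
    acgt = [c for c in seq if c in BASES]
    if not acgt:
        return 0.0
    return sum(c in "GC" for c in acgt) / len(acgt)


def purine_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(c in PURINES for c in seq) / len(seq)


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. DNA with P(G)+P(C) = gc (split evenly within GC and AT)."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def shannon_entropy(seq: str) -> float:
    if not seq:
        return 0.0
    counts: dict[str, int] = {}
    for c in seq:
        counts[c] = counts.get(c, 0) + 1
    n = len(seq)
    return -sum((k / n) * math.log2(k / n) for k in counts.values())


def mask_low_complexity(protein: str, window: int = 12, min_entropy: float = 2.2) -> str:
    """Replace residues inside low-entropy windows with 'X'.

    A lightweight stand-in for SEG-style low-complexity filtering: any window
    of `window` residues whose Shannon entropy falls below `min_entropy` bits
    is masked entirely.
    """
    if len(protein) < window:
        return protein
    masked = list(protein)
    for i in range(len(protein) - window + 1):
        if shannon_entropy(protein[i:i + window]) < min_entropy:
            for j in range(i, i + window):
                masked[j] = "X"
    return "".join(masked)
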