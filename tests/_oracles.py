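"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: translation goes
through Bio.Seq, site counting enumerates all nine substitutions per codon,
and the hypergeometric tail enumerates subsets directly.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

from Bio.Seq import Seq


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_force_sites(cds: str) -> tuple[float, float]:
    """(n_sites, s_sites) by enumerating all 9 substitutions of every codon."""
    n = s = 0.0
    for start in range(0, len(cds), 3):
        codon = cds[start:start + 3]
        ref_aa = translate_codon(codon)
        for offset in range(3):
            for base in "ACGT":
                if base == codon[offset]:
                    continue
                alt_aa = translate_codon(codon[:offset] + base + codon[offset + 1:])
                if alt_aa == ref_aa:
                    s += 1 / 3
                else:
                    n += 1 / 3
    return n, s


def brute_force_consequence(codon: str, offset: int, alt: str) -> str:
    """Translate-and-compare consequence for a mid-CDS sense codon."""
    ref_aa = translate_codon(codon)
    alt_aa = translate_codon(codon[:offset] + alt + codon[offset + 1:])
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop_gain"
    return "missense"


def hypergeom_tail_by_enumeration(k: int, K: int, n: int, M: int) -> float:
    """P[X >= k] by enumerating every size-n subset of an M-element universe."""
    universe = list(range(M))
    marked = set(range(K))
    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        if sum(1 for x in draw if x in marked) >= k:
            hits += 1
    return hits / total


def bh_stepup_reference(p_values) -> list[float]:
    """Textbook BH step-up: sort, scale by m/rank, enforce monotonicity."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running_min = min(running_min, p_values[i] * m / rank)
        adjusted[i] = running_min
    return adjusted
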