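"""Brute-force enumeration oracles, independent of the analytic engine.

A hexaploid parent is represented as an explicit tuple of six homolog
allele counts (0/1 per homolog).  Gametes are enumerated as all C(6,3)=20
homolog subsets; offspring as all 400 ordered gamete pairs.  No formulas —
pure counting.
"""

from __future__ import annotations

import itertools
from fractions import Fraction


def parent_homologs(dosage: int) -> tuple[int, ...]:
    return tuple([1] * dosage + [0] * (6 - dosage))


def enumerate_gamete_pmf(homologs: tuple[int, ...]) -> dict[int, Fraction]:
    """PMF of allele copies in a gamete by enumerating all 3-of-6 subsets."""
    pmf: dict[int, Fraction] = {k: Fraction(0) for k in range(4)}
    subsets = list(itertools.combinations(range(6), 3))
    for subset in subsets:
        k = sum(homologs[i] for i in subset)
        pmf[k] += Fraction(1, len(subsets))
    return pmf


def enumerate_offspring_pmf(d1: int, d2: int) -> dict[int, Fraction]:
    """PMF of offspring dosage by enumerating all 400 gamete pairs."""
    h1, h2 = parent_homologs(d1), parent_homologs(d2)
    pmf: dict[int, Fraction] = {k: Fraction(0) for k in range(7)}
    s1 = list(itertools.combinations(range(6), 3))
    for a in s1:
        for b in s1:
            k = sum(h1[i] for i in a) + sum(h2[i] for i in b)
            pmf[k] += Fraction(1, len(s1) ** 2)
    return pmf


def enumerate_two_locus_classes(same_homolog: bool) -> tuple[Fraction, ...]:
    """(both, first-only, second-only, neither) for a duplex parent x nulliplex.

    Two simplex alleles sit either both on homolog 0, or on homologs 0 and
    1; the gamete is an enumerated 3-of-6 subset, the nulliplex mate adds
    nothing.  Exact rf=0 case (no exchange between homologs).
    """
    loc1_hom, loc2_hom = (0, 0) if same_homolog else (0, 1)
    counts = [Fraction(0)] * 4
    subsets = list(itertools.combinations(range(6), 3))
    for subset in subsets:
        a = loc1_hom in subset
        b = loc2_hom in subset
        idx = 0 if (a and b) else 1 if a else 2 if b else 3
        counts[idx] += Fraction(1, len(subsets))
    return tuple(counts)
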