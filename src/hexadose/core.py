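"""Closed-form hexasomic inheritance engine.

An autohexaploid carries six homologous copies of each chromosome. Under
random bivalent pairing at meiosis, each gamete receives a uniformly random
3-of-6 subset of the homologs, so the number of copies of an allele present
on ``d`` of the six homologs that a gamete inherits is hypergeometric:

    P(k copies | d) = C(d, k) * C(6 - d, 3 - k) / C(6, 3)

Everything downstream — offspring dosage distributions, expected pooled
alternative-allele frequencies, dominant presence/absence segregation
ratios, and the two-locus class probabilities for a duplex parent — follows
from this single transmission model.  This module is pure computation and is
the analytic reference the rest of the package is validated against.
"""

from __future__ import annotations

import enum
from math import comb

import numpy as np

PLOIDY = 6
GAMETE_PLOIDY = PLOIDY // 2

__all__ = [
    "PLOIDY",
    "GAMETE_PLOIDY",
    "Phase",
    "gamete_dosage_pmf",
    "offspring_dosage_pmf",
    "expected_aaf",
    "expected_presence_segregation",
    "two_locus_class_probs",
]


class Phase(enum.Enum):
    """Placement of two simplex alleles within one parent.

    ``COUPLING``: both alleles on the same homolog (co-transmitted).
    ``REPULSION``: alleles on two different homologs (anti-transmitted).
    """

    COUPLING = "coupling"
    REPULSION = "repulsion"


def _check_dosage(d: int, ploidy: int = PLOIDY) -> int:
    d = int(d)
    if not 0 <= d <= ploidy:
        raise ValueError(f"dosage must be in [0, {ploidy}], got {d}")
    return d


def gamete_dosage_pmf(parent_dosage: int) -> np.ndarray:
    """PMF of allele copies (0..3) in a gamete from a parent of given dosage.

    Parameters
    ----------
    parent_dosage : int
        Number of homologs (0..6) of the parent that carry the allele.

    Returns
    -------
    numpy.ndarray
        Length-4 array ``p`` with ``p[k] = P(gamete carries k copies)``.
    """
    d = _check_dosage(parent_dosage)
    total = comb(PLOIDY, GAMETE_PLOIDY)  # 20 equally likely homolog subsets
    pmf = np.array(
        [comb(d, k) * comb(PLOIDY - d, GAMETE_PLOIDY - k) for k in range(GAMETE_PLOIDY + 1)],
        dtype=float,
    )
    return pmf / total


def offspring_dosage_pmf(dosage_p1: int, dosage_p2: int) -> np.ndarray:
    """PMF of offspring dosage (0..6) for a biparental cross.

    The offspring dosage is the sum of two independent gamete dosages, so
    the PMF is the convolution of the two gamete PMFs.
    """
    g1 = gamete_dosage_pmf(dosage_p1)
    g2 = gamete_dosage_pmf(dosage_p2)
    return np.convolve(g1, g2)


def expected_aaf(dosage_p1: int, dosage_p2: int) -> float:
    """Expected pooled alternative-allele read fraction in the F1.

    With the ALT allele on ``d1`` of parent 1's homologs and ``d2`` of
    parent 2's, the mean offspring dosage is ``(d1 + d2)/2`` of 6 copies,
    so the expected read fraction pooled across progeny is ``(d1 + d2)/12``.
    """
    d1 = _check_dosage(dosage_p1)
    d2 = _check_dosage(dosage_p2)
    return (d1 + d2) / (2 * PLOIDY)


def expected_presence_segregation(dosage_p1: int, dosage_p2: int) -> tuple[float, float]:
    """Probabilities (carrier, non-carrier) of offspring for a dominant allele.

    A carrier has at least one allele copy.  Duplex x nulliplex gives 4:1,
    simplex x nulliplex 1:1, simplex x simplex 3:1.
    """
    pmf = offspring_dosage_pmf(dosage_p1, dosage_p2)
    p_non = float(pmf[0])
    return 1.0 - p_non, p_non


def two_locus_class_probs(phase: Phase, recombination_fraction: float = 0.0) -> np.ndarray:
    """Joint transmission classes for two simplex alleles of a duplex parent.

    One parent carries one simplex allele at each of two loci, either on
    the same homolog (coupling) or on two different homologs (repulsion);
    the mate is nulliplex for both.  Returns the probabilities of offspring
    classes ``(both, first-only, second-only, neither)``.

    At ``rf = 0``, repulsion placement gives 2:3:3:2 (a gamete draws 3 of 6
    homologs: P(both marked homologs) = C(4,1)/20, P(exactly one) =
    C(4,2)/20 each, P(neither) = C(4,3)/20) and coupling gives 1:0:0:1.
    For ``rf > 0`` the classes are interpolated linearly (weight ``2*rf``)
    toward independence (1/4 each); this extension is a modelling
    convenience, exact only at the endpoints.
    """
    rf = float(recombination_fraction)
    if not 0.0 <= rf <= 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5], got {rf}")
    if phase is Phase.REPULSION:
        base = np.array([4, 6, 6, 4], dtype=float) / 20.0
    elif phase is Phase.COUPLING:
        base = np.array([0.5, 0.0, 0.0, 0.5])
    else:  # pragma: no cover - exhaustive over the enum
        raise TypeError(f"phase must be a Phase, got {phase!r}")
    independent = np.full(4, 0.25)
    w = 2.0 * rf
    return (1.0 - w) * base + w * independent
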