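"""Hexasomic segregation ratios and chi-squared goodness-of-fit tests.

Reproduces the classic dominant-locus arithmetic for an autohexaploid
F1 cross: a duplex x nulliplex locus segregates 4:1 for allele presence,
a double-simplex locus 3:1 under the dominant encoding, and two duplex
alleles in repulsion yield 2:3:3:2 combined two-locus classes.  Observed
class counts from a real-sized population (n = 102) are then tested
against those ratios.
"""

import numpy as np

from hexadose.core import (
    Phase,
    expected_presence_segregation,
    gamete_dosage_pmf,
    offspring_dosage_pmf,
    two_locus_class_probs,
)
from hexadose.segtest import gof_chi2

print("== analytic inheritance ==")
print("gamete allele-count PMF of a duplex parent:", gamete_dosage_pmf(2))
carrier, non = expected_presence_segregation(2, 0)
print(f"duplex x nulliplex carriers : non-carriers = {carrier / non:.0f} : 1")
carrier, non = expected_presence_segregation(1, 1)
print(f"double-simplex non-hom : hom = {carrier / non:.0f} : 1")
print(
    "repulsion duplex two-locus classes (both/first/second/neither):",
    two_locus_class_probs(Phase.REPULSION, 0.0),
)
print("offspring dosage PMF, simplex x simplex:", np.round(offspring_dosage_pmf(1, 1), 4))

print("\n== goodness of fit of observed counts ==")
r = gof_chi2([81, 21], [4, 1])
print(f"81 cleaved : 21 non-cleaved vs 4:1  -> chi2 = {r.chi2:.3f}, P = {r.p_value:.2f}")
r = gof_chi2([24, 30, 27, 21], [2, 3, 3, 2])
print(f"24:30:27:21 two-gene classes vs 2:3:3:2 -> chi2 = {r.chi2:.2f}, P = {r.p_value:.2f}")
r = gof_chi2([54, 48], [1, 1])
print(f"54 : 48 simplex marker vs 1:1        -> chi2 = {r.chi2:.3f}, P = {r.p_value:.2f}")
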