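"""Goodness-of-fit and cosegregation machinery.

Chi-squared tests of observed class counts against integer segregation
ratios (4:1, 1:1, 3:1, 2:3:3:2 ...), combined two-marker genotype tables,
recombinant counting between a marker and a reference status, and the
two-class split of a bimodal phenotype.  No continuity correction is
applied anywhere; the tests are plain Pearson chi-squared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegTestResult",
    "CosegregationTable",
    "gof_chi2",
    "combined_genotype_counts",
    "cosegregation_check",
    "classify_phenotype_bimodal",
    "read_gene_table",
]


@dataclass(frozen=True)
class SegTestResult:
    """Result of a chi-squared goodness-of-fit test against a ratio."""

    observed: tuple[int, ...]
    expected_ratio: tuple[int, ...]
    chi2: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "observed": list(self.observed),
            "expected_ratio": list(self.expected_ratio),
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class CosegregationTable:
    """Agreement between a two-class marker and a two-class reference status."""

    n: int
    counts: tuple[int, int, int, int]  # (both, marker-only, status-only, neither)
    recombinants: int
    orientation: str  # "coupling" or "repulsion"


def gof_chi2(observed: Sequence[int], ratio: Sequence[int]) -> SegTestResult:
    """Pearson chi-squared test of ``observed`` counts against an integer ratio.

    ``chi2 = sum((obs - exp)^2 / exp)`` with ``exp = n * ratio_i / sum(ratio)``
    and ``df = classes - 1``.  No continuity correction.

    >>> r = gof_chi2([81, 21], [4, 1])
    >>> round(r.chi2, 3), round(r.p_value, 2)
    (0.022, 0.88)
    """
    obs = np.asarray(observed, dtype=float)
    rat = np.asarray(ratio, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("need at least two observed classes")
    if rat.shape != obs.shape:
        raise ValueError("ratio length must match the number of classes")
    if np.any(rat <= 0):
        raise ValueError("expected ratio classes must be positive")
    n = obs.sum()
    if n <= 0:
        raise ValueError("observed counts sum to zero")
    exp = n * rat / rat.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegTestResult(
        observed=tuple(int(x) for x in obs),
        expected_ratio=tuple(int(x) for x in rat),
        chi2=chi2,
        df=df,
        p_value=p,
    )


def _as_bool_pair(a, b):
    x = np.asarray(a)
    y = np.asarray(b)
    if x.shape != y.shape:
        raise ValueError("the two vectors must cover the same samples")
    return x.astype(bool), y.astype(bool)


def combined_genotype_counts(marker_a, marker_b) -> tuple[int, int, int, int]:
    """2x2 class counts (both, A-only, B-only, neither) for two presence vectors.

    Inputs are boolean/0-1 carrier vectors over the same samples; entries
    where either is negative (missing) are dropped.
    """
    a = np.asarray(marker_a)
    b = np.asarray(marker_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("marker vectors must be non-empty and share samples")
    keep = (a >= 0) & (b >= 0)
    if not keep.any():
        raise ValueError("no shared non-missing samples")
    x, y = a[keep].astype(bool), b[keep].astype(bool)
    both = int(np.sum(x & y))
    a_only = int(np.sum(x & ~y))
    b_only = int(np.sum(~x & y))
    neither = int(np.sum(~x & ~y))
    return both, a_only, b_only, neither


def cosegregation_check(marker, reference_status) -> CosegregationTable:
    """Count recombinants between a two-class marker and a reference status.

    The coupling orientation identifies marker-presence with status-presence;
    the orientation with the fewer disagreements is reported, so perfectly
    complementary vectors count zero recombinants in repulsion orientation.
    Symmetric in its two arguments.
    """
    both, a_only, b_only, neither = combined_genotype_counts(marker, reference_status)
    n = both + a_only + b_only + neither
    coupling_rec = a_only + b_only
    repulsion_rec = both + neither
    if coupling_rec <= repulsion_rec:
        orientation, rec = "coupling", coupling_rec
    else:
        orientation, rec = "repulsion", repulsion_rec
    return CosegregationTable(
        n=n, counts=(both, a_only, b_only, neither), recombinants=rec, orientation=orientation
    )


def classify_phenotype_bimodal(
    phenotype: pd.Series, low_cut: float, high_cut: float
) -> pd.DataFrame:
    """Split a bimodal trait into two classes by strict cutoffs.

    Values strictly below ``low_cut`` are the "low" class (e.g. carotenoid
    cleavage present), values strictly above ``high_cut`` the "high" class;
    anything in between (including the cutoffs themselves) is flagged
    unclassified rather than guessed.

    Returns a DataFrame indexed like ``phenotype`` with columns
    ``value``, ``klass`` ("low"/"high"/"unclassified").
    """
    if not low_cut < high_cut:
        raise ValueError("low_cut must be below high_cut")
    values = pd.Series(phenotype, dtype=float)
    klass = np.where(
        values < low_cut, "low", np.where(values > high_cut, "high", "unclassified")
    )
    return pd.DataFrame({"value": values, "klass": klass}, index=values.index)


def read_gene_table(path) -> pd.DataFrame:
    """Read a gene presence/absence CSV with columns sample, gene, status (+/-).

    Returns a sample x gene DataFrame of booleans (True = present).
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"sample", "gene", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    df["present"] = df["status"].astype(str).str.strip().map({"+": True, "-": False})
    if df["present"].isna().any():
        raise ValueError("gene status entries must be '+' or '-'")
    return df.pivot(index="sample", columns="gene", values="present")
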