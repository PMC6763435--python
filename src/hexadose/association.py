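"""Single-marker GLM association scan with Bonferroni control.

Each encoded marker is a two-class (homozygous vs non-homozygous) factor;
the scan fits ordinary least squares of the trait on a 0/1 indicator and
reports the F statistic on (1, n-2) degrees of freedom, which equals the
squared pooled-variance two-sample t statistic.  Missing genotypes or
phenotypes are dropped pairwise per marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mining import HOM, MISSING, NON_HOM, EncodedMarker

__all__ = [
    "AssocResult",
    "glm_scan",
    "bonferroni_threshold",
    "significant_markers",
    "results_to_frame",
]


@dataclass
class AssocResult:
    """Per-marker association result."""

    marker: str
    contig: str
    pos: int
    cross_type: str
    n_used: int
    mean_hom: float
    mean_non_hom: float
    f_stat: float
    p_value: float
    flag: str = ""  # "", "monomorphic-in-sample", "small-class"
    significant: bool = False


def _ols_indicator_f(y: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """F statistic and p-value for OLS of y on [1, g] with a 0/1 indicator.

    Closed-form via the between/within sum-of-squares decomposition of the
    two-group one-way layout; identical to the regression F test.
    """
    n = y.size
    n1 = int(g.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0 or n < 3:
        return 0.0, 1.0
    mean = y.mean()
    m0 = y[g == 0].mean()
    m1 = y[g == 1].mean()
    ssb = n0 * (m0 - mean) ** 2 + n1 * (m1 - mean) ** 2
    ssw = float(np.sum((y[g == 0] - m0) ** 2) + np.sum((y[g == 1] - m1) ** 2))
    if ssw <= 0.0:
        # zero residual variance: perfect separation unless the groups share
        # a constant value, in which case there is no signal at all
        return (np.inf, 0.0) if ssb > 0 else (0.0, 1.0)
    f = ssb / (ssw / (n - 2))
    return float(f), float(stats.f.sf(f, 1, n - 2))


def glm_scan(
    markers: list[EncodedMarker], phenotype: pd.Series, progeny: list[str]
) -> list[AssocResult]:
    """Association of every marker with the trait by single-marker OLS F test.

    ``phenotype`` is indexed by sample id; ``progeny`` gives the sample
    order of the marker code vectors.  Individuals missing either the
    genotype or the phenotype are excluded marker by marker.
    """
    phen = phenotype.reindex(progeny).to_numpy(dtype=float)
    results = []
    for m in markers:
        ok = (m.codes != MISSING) & np.isfinite(phen)
        y = phen[ok]
        g = (m.codes[ok] == NON_HOM).astype(int)
        n = y.size
        n_non_hom = int(g.sum())
        n_hom = n - n_non_hom
        flag = ""
        if n_hom == 0 or n_non_hom == 0:
            flag = "monomorphic-in-sample"
            f, p = 0.0, 1.0
        else:
            if min(n_hom, n_non_hom) < 2:
                flag = "small-class"
            f, p = _ols_indicator_f(y, g)
        results.append(
            AssocResult(
                marker=m.marker_id,
                contig=m.contig,
                pos=m.pos,
                cross_type=m.cross_type,
                n_used=n,
                mean_hom=float(y[g == 0].mean()) if n_hom else np.nan,
                mean_non_hom=float(y[g == 1].mean()) if n_non_hom else np.nan,
                f_stat=f,
                p_value=p,
                flag=flag,
            )
        )
    return results


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise significance threshold alpha/m for m tested markers."""
    if m < 1:
        raise ValueError("need at least one marker for a Bonferroni threshold")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def significant_markers(
    results: list[AssocResult], threshold: float
) -> tuple[list[AssocResult], dict[str, int]]:
    """Results with p below the threshold, sorted by p (ties by coordinate).

    Also returns the count of significant markers per cross type.
    """
    hits = [r for r in results if r.p_value < threshold]
    for r in hits:
        r.significant = True
    hits.sort(key=lambda r: (r.p_value, r.contig, r.pos))
    by_type: dict[str, int] = {}
    for r in hits:
        by_type[r.cross_type] = by_type.get(r.cross_type, 0) + 1
    return hits, by_type


def results_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    if not df.empty:
        df["neg_log10_p"] = -np.log10(np.clip(df["p_value"], 1e-300, None))
    return df
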