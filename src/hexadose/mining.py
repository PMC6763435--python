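"""Single-dose SNP selection from allele-depth data.

The selection pipeline for a biparental autohexaploid F1 population:

1. depth/missingness filters (per-point depth >= 10, per-locus missing
   fraction < 0.25);
2. pooled alternative-allele frequency (AAF) over the progeny;
3. classification into simplex / double-simplex cross types by the pooled
   AAF falling into one of four half-open windows around the expected
   values 1/12, 2/12, 10/12 and 11/12;
4. dominant two-class encoding of each individual (homozygous vs
   non-homozygous for the majority allele) — intermediate heterozygous
   dosage classes cannot be resolved at practical read depths, so a
   simplex marker segregates 1:1 and a double-simplex marker 3:1;
5. a chi-squared goodness-of-fit filter retaining markers whose observed
   two-class counts are consistent with the expected ratio (P >= 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LocusReadCounts
from .segtest import gof_chi2

logger = logging.getLogger(__name__)

__all__ = [
    "CrossType",
    "EncodedMarker",
    "AAF_WINDOWS",
    "MISSING",
    "HOM",
    "NON_HOM",
    "locus_filters",
    "pooled_aaf",
    "per_individual_aaf",
    "classify_cross_type",
    "encode_individuals",
    "segregation_filter",
    "mine_single_dose",
    "markers_to_frame",
]

# integer codes for the dominant two-class encoding
MISSING = -1
HOM = 0  # homozygous for the majority allele (no minority-allele read)
NON_HOM = 1  # at least one minority-allele read

# Half-open pooled-AAF windows [low, high) per cross type, centred on the
# expected fractions 1/12, 2/12, 10/12 and 11/12.  The boundary constants
# are the conventional 4-decimal midpoints between adjacent dosage classes.
AAF_WINDOWS = {
    "simplex_alt_rare": (0.0417, 0.1250),
    "double_simplex_alt_rare": (0.1250, 0.2083),
    "double_simplex_alt_common": (0.7917, 0.8750),
    "simplex_alt_common": (0.8750, 0.9583),
}


class CrossType:
    SIMPLEX_ALT_RARE = "simplex_alt_rare"
    DOUBLE_SIMPLEX_ALT_RARE = "double_simplex_alt_rare"
    DOUBLE_SIMPLEX_ALT_COMMON = "double_simplex_alt_common"
    SIMPLEX_ALT_COMMON = "simplex_alt_common"
    UNCLASSIFIED = "unclassified"

    SIMPLEX = frozenset({SIMPLEX_ALT_RARE, SIMPLEX_ALT_COMMON})
    DOUBLE_SIMPLEX = frozenset({DOUBLE_SIMPLEX_ALT_RARE, DOUBLE_SIMPLEX_ALT_COMMON})


@dataclass
class EncodedMarker:
    """A single-dose marker after classification and dominant encoding."""

    contig: str
    pos: int
    cross_type: str
    pooled_aaf: float
    codes: np.ndarray  # per progeny sample: HOM / NON_HOM / MISSING
    expected_ratio: tuple[int, int]  # (non_hom, hom): (1,1) simplex, (3,1) double-simplex
    seg_chi2: float = np.nan
    seg_p: float = np.nan
    # log-likelihood margin of a 3:1 vs a 4:1 carrier ratio; positive favours
    # 3:1 (true double-simplex) over a duplex-in-one-parent locus, which has
    # the same pooled AAF of 2/12 but segregates 4:1
    loglik_31_vs_41: float = np.nan

    @property
    def marker_id(self) -> str:
        return f"{self.contig}_{self.pos}"

    @property
    def is_simplex(self) -> bool:
        return self.cross_type in CrossType.SIMPLEX

    def class_counts(self) -> tuple[int, int]:
        """(non-homozygous, homozygous) counts over non-missing individuals."""
        return int(np.sum(self.codes == NON_HOM)), int(np.sum(self.codes == HOM))


def locus_filters(
    counts: LocusReadCounts,
    min_depth: int = 10,
    max_missing: float = 0.25,
    progeny: list[str] | None = None,
) -> tuple[LocusReadCounts, np.ndarray]:
    """Apply the depth and missingness filters.

    A data point with depth below ``min_depth`` is set missing; loci whose
    missing fraction over the progeny reaches ``max_missing`` are dropped.
    Returns the surviving loci and the per-point missing mask (aligned to
    the progeny columns of the returned counts).
    """
    if counts.n_samples == 0:
        raise ValueError("no samples in the read-count table")
    progeny = list(progeny) if progeny is not None else list(counts.samples)
    idx = counts.sample_indices(progeny)
    depth = counts.depth[:, idx]
    missing = depth < min_depth
    frac = missing.mean(axis=1)
    keep = frac < max_missing
    kept = counts.subset_loci(keep)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("locus_filters: dropped %d/%d loci for missingness", n_drop, counts.n_loci)
    return kept, missing[keep]


def pooled_aaf(
    counts: LocusReadCounts,
    missing: np.ndarray,
    progeny: list[str] | None = None,
) -> np.ndarray:
    """Pooled ALT read fraction per locus over non-missing progeny points.

    Parents are excluded: pooling progeny read counts estimates the
    combined parental dosage (expected AAF = (d1 + d2)/12).  Loci with no
    usable depth get NaN.
    """
    progeny = list(progeny) if progeny is not None else list(counts.samples)
    idx = counts.sample_indices(progeny)
    alt = np.where(missing, 0, counts.alt_counts[:, idx])
    tot = np.where(missing, 0, counts.depth[:, idx])
    total = tot.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        aaf = np.where(total > 0, alt.sum(axis=1) / np.where(total > 0, total, 1), np.nan)
    return aaf


def per_individual_aaf(
    counts: LocusReadCounts, missing: np.ndarray, progeny: list[str] | None = None
) -> np.ndarray:
    """Per individual x locus ALT fraction; NaN where missing."""
    progeny = list(progeny) if progeny is not None else list(counts.samples)
    idx = counts.sample_indices(progeny)
    alt = counts.alt_counts[:, idx].astype(float)
    depth = counts.depth[:, idx].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        aaf = alt / depth
    aaf[missing | (depth == 0)] = np.nan
    return aaf


def classify_cross_type(aaf: float) -> str:
    """Cross-type call from a pooled AAF by window membership.

    Windows are half-open [low, high); anything outside the four windows
    (including duplex/triplex intermediates near 0.5) is unclassified.
    """
    if np.isnan(aaf):
        return CrossType.UNCLASSIFIED
    if not 0.0 <= aaf <= 1.0:
        raise ValueError(f"AAF must be in [0, 1], got {aaf}")
    for name, (lo, hi) in AAF_WINDOWS.items():
        if lo <= aaf < hi:
            return name
    return CrossType.UNCLASSIFIED


def encode_individuals(
    counts: LocusReadCounts,
    locus_index: int,
    cross_type: str,
    missing_row: np.ndarray,
    pooled: float,
    progeny: list[str] | None = None,
) -> EncodedMarker:
    """Dominant two-class encoding of one classified locus.

    For alt-rare cross types an individual with zero ALT reads is
    homozygous REF and any ALT read makes it non-homozygous; for alt-common
    types the roles of REF and ALT swap.  Missing points stay missing.
    """
    if cross_type == CrossType.UNCLASSIFIED:
        raise ValueError("cannot encode an unclassified locus")
    progeny = list(progeny) if progeny is not None else list(counts.samples)
    idx = counts.sample_indices(progeny)
    alt = counts.alt_counts[locus_index, idx]
    ref = counts.ref_counts[locus_index, idx]
    minority = alt if cross_type.endswith("alt_rare") else ref
    codes = np.where(minority > 0, NON_HOM, HOM).astype(np.int8)
    codes[missing_row] = MISSING
    ratio = (1, 1) if cross_type in CrossType.SIMPLEX else (3, 1)
    row = counts.loci.iloc[locus_index]
    marker = EncodedMarker(
        contig=str(row["contig"]),
        pos=int(row["pos"]),
        cross_type=cross_type,
        pooled_aaf=float(pooled),
        codes=codes,
        expected_ratio=ratio,
    )
    if cross_type in CrossType.DOUBLE_SIMPLEX:
        non_hom, hom = marker.class_counts()
        n = non_hom + hom
        if n:
            marker.loglik_31_vs_41 = float(
                stats.binom.logpmf(non_hom, n, 0.75) - stats.binom.logpmf(non_hom, n, 0.8)
            )
    return marker


def segregation_filter(
    markers: list[EncodedMarker], alpha: float = 0.01
) -> list[EncodedMarker]:
    """Keep markers whose two-class counts fit the expected ratio (P >= alpha).

    The test is a Pearson chi-squared goodness of fit on the observed
    (non-homozygous, homozygous) counts, missing individuals excluded.
    Markers with an empty class count still get a test (chi-squared against
    the expected ratio is defined); markers with no scored individuals are
    dropped.
    """
    kept = []
    for m in markers:
        non_hom, hom = m.class_counts()
        if non_hom + hom == 0:
            logger.info("segregation_filter: %s all-missing, dropped", m.marker_id)
            continue
        res = gof_chi2([non_hom, hom], list(m.expected_ratio))
        m.seg_chi2 = res.chi2
        m.seg_p = res.p_value
        if res.p_value >= alpha:
            kept.append(m)
    return kept


def mine_single_dose(
    counts: LocusReadCounts,
    min_depth: int = 10,
    max_missing: float = 0.25,
    seg_alpha: float = 0.01,
    parent_samples: tuple[str, str] | None = None,
) -> tuple[list[EncodedMarker], pd.DataFrame]:
    """Full selection stage: filters -> pooled AAF -> classify -> encode -> filter.

    ``parent_samples`` names the two parents present in ``counts``; they are
    excluded from pooled AAF, encoding and the segregation test.  Returns
    the retained markers plus a per-locus audit table (pooled AAF and
    cross-type call for every locus that survived the depth filters).
    """
    if parent_samples:
        progeny = [s for s in counts.samples if s not in set(parent_samples)]
    else:
        progeny = list(counts.samples)
    filtered, missing = locus_filters(counts, min_depth, max_missing, progeny)
    aaf = pooled_aaf(filtered, missing, progeny)
    calls = [classify_cross_type(a) for a in aaf]
    audit = filtered.loci.copy()
    audit["pooled_aaf"] = aaf
    audit["cross_type"] = calls
    markers = [
        encode_individuals(filtered, i, call, missing[i], aaf[i], progeny)
        for i, call in enumerate(calls)
        if call != CrossType.UNCLASSIFIED
    ]
    retained = segregation_filter(markers, seg_alpha)
    audit["retained"] = audit["contig"].str.cat(audit["pos"].astype(str), sep="_").isin(
        {m.marker_id for m in retained}
    )
    return retained, audit


def markers_to_frame(markers: list[EncodedMarker], progeny: list[str]) -> pd.DataFrame:
    """Marker table with per-sample VCF-style codes (0/0, 0/1, 1/1, ./.)."""
    rows = []
    for m in markers:
        hom_code = "0/0" if m.cross_type.endswith("alt_rare") else "1/1"
        text = {HOM: hom_code, NON_HOM: "0/1", MISSING: "./."}
        non_hom, hom = m.class_counts()
        row = {
            "marker": m.marker_id,
            "contig": m.contig,
            "pos": m.pos,
            "cross_type": m.cross_type,
            "pooled_aaf": m.pooled_aaf,
            "non_hom": non_hom,
            "hom": hom,
            "expected_ratio": f"{m.expected_ratio[0]}:{m.expected_ratio[1]}",
            "seg_chi2": m.seg_chi2,
            "seg_p": m.seg_p,
        }
        row.update({s: text[int(c)] for s, c in zip(progeny, m.codes)})
        rows.append(row)
    return pd.DataFrame(rows)
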