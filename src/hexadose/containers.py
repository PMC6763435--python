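"""Shared in-memory containers for per-locus, per-sample read counts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LocusReadCounts"]

LOCUS_COLUMNS = ("contig", "pos", "ref", "alt")


@dataclass
class LocusReadCounts:
    """REF/ALT read counts for a set of biallelic loci across samples.

    Attributes
    ----------
    loci : pandas.DataFrame
        One row per locus with columns ``contig``, ``pos`` (1-based),
        ``ref``, ``alt`` (allele strings).
    samples : list of str
        Sample identifiers, one per column of the count matrices.
    ref_counts, alt_counts : numpy.ndarray
        Integer arrays of shape ``(n_loci, n_samples)``.
    """

    loci: pd.DataFrame
    samples: list[str]
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        missing_cols = set(LOCUS_COLUMNS) - set(self.loci.columns)
        if missing_cols:
            raise ValueError(f"loci table lacks columns {sorted(missing_cols)}")
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        shape = (len(self.loci), len(self.samples))
        if self.ref_counts.shape != shape or self.alt_counts.shape != shape:
            raise ValueError(
                f"count matrices must have shape {shape}, got "
                f"{self.ref_counts.shape} and {self.alt_counts.shape}"
            )
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def depth(self) -> np.ndarray:
        """Total read depth per locus x sample (REF + ALT)."""
        return self.ref_counts + self.alt_counts

    def locus_ids(self) -> pd.Series:
        """Marker identifiers formatted ``contig_position``."""
        return self.loci["contig"].astype(str) + "_" + self.loci["pos"].astype(str)

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample {exc}") from None

    def subset_samples(self, names) -> "LocusReadCounts":
        idx = self.sample_indices(names)
        return LocusReadCounts(
            loci=self.loci.copy(),
            samples=list(names),
            ref_counts=self.ref_counts[:, idx],
            alt_counts=self.alt_counts[:, idx],
        )

    def subset_loci(self, mask_or_index) -> "LocusReadCounts":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return LocusReadCounts(
            loci=self.loci.iloc[idx],
            samples=list(self.samples),
            ref_counts=self.ref_counts[idx],
            alt_counts=self.alt_counts[idx],
        )
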