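"""End-to-end pipeline driver: mine -> GWAS -> segregation tests -> linkage.

The driver consumes a VCF with allele depths for two parents plus their F1
progeny and a phenotype CSV, and emits the marker table, association table,
significant-marker linkage groups, segregation reports and a run manifest.
Everything is deterministic given the inputs and configuration.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    bonferroni_threshold,
    glm_scan,
    results_to_frame,
    significant_markers,
)
from .containers import LocusReadCounts
from .linkage import all_pairs, group_markers, groups_to_frame, order_markers
from .mining import CrossType, EncodedMarker, markers_to_frame, mine_single_dose
from .segtest import classify_phenotype_bimodal, gof_chi2
from .vcfio import read_phenotype_csv, read_vcf_ad

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "assign_parent_of_origin", "PipelineResult"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    vcf: str = ""
    phenotype: str = ""
    out_dir: str = "hexadose_out"
    parent_samples: tuple[str, str] = ("P1", "P2")
    min_depth: int = 10
    max_missing: float = 0.25
    seg_alpha: float = 0.01
    gwas_alpha: float = 0.05
    lod_min: float = 3.0
    rf_max: float = 0.35
    min_shared: int = 20
    phenotype_low_cut: float = 2.2
    phenotype_high_cut: float = 29.6
    phenotype_ratio: tuple[int, int] = (4, 1)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.parent_samples, list):
            cfg.parent_samples = tuple(cfg.parent_samples)
        if isinstance(cfg.phenotype_ratio, list):
            cfg.phenotype_ratio = tuple(cfg.phenotype_ratio)
        return cfg


@dataclass
class PipelineResult:
    markers: list[EncodedMarker]
    marker_table: pd.DataFrame
    association: pd.DataFrame
    significant: pd.DataFrame
    counts_by_type: dict
    linkage_groups: pd.DataFrame
    segregation: dict
    threshold: float
    parent_of_origin: dict[str, str]


def assign_parent_of_origin(
    counts: LocusReadCounts, marker: EncodedMarker, parent_samples: tuple[str, str]
) -> str:
    """Which parent carries the minority allele of a simplex marker.

    Decided from the parents' own reads: a simplex carrier parent shows a
    minority-allele read fraction near 1/6, the other parent near the
    sequencing error rate.  Returns "P1"/"P2" style labels (the sample
    names given) or "unknown" when depths are uninformative.
    """
    locus = counts.loci.index[
        (counts.loci["contig"] == marker.contig) & (counts.loci["pos"] == marker.pos)
    ]
    if len(locus) != 1:
        return "unknown"
    i = int(locus[0])
    idx = counts.sample_indices(list(parent_samples))
    alt = counts.alt_counts[i, idx].astype(float)
    ref = counts.ref_counts[i, idx].astype(float)
    depth = alt + ref
    if (depth == 0).any():
        return "unknown"
    frac = alt / depth if marker.cross_type.endswith("alt_rare") else ref / depth
    carrier = frac >= 0.08
    if carrier[0] and not carrier[1]:
        return parent_samples[0]
    if carrier[1] and not carrier[0]:
        return parent_samples[1]
    return "unknown"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full chain and write all report files under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        counts = read_vcf_ad(config.vcf)
    except Exception as exc:
        raise RuntimeError(f"stage read_vcf: {exc}") from exc
    progeny = [s for s in counts.samples if s not in set(config.parent_samples)]
    if not progeny:
        raise RuntimeError("stage read_vcf: no progeny samples besides the parents")

    try:
        markers, audit = mine_single_dose(
            counts,
            min_depth=config.min_depth,
            max_missing=config.max_missing,
            seg_alpha=config.seg_alpha,
            parent_samples=config.parent_samples,
        )
    except Exception as exc:
        raise RuntimeError(f"stage mine: {exc}") from exc
    marker_table = markers_to_frame(markers, progeny)

    try:
        phen = read_phenotype_csv(config.phenotype)
        results = glm_scan(markers, phen, progeny)
    except Exception as exc:
        raise RuntimeError(f"stage gwas: {exc}") from exc
    threshold = bonferroni_threshold(config.gwas_alpha, max(len(results), 1))
    hits, by_type = significant_markers(results, threshold)
    assoc_df = results_to_frame(results)
    hits_df = results_to_frame(hits)

    parent_of_origin = {
        m.marker_id: assign_parent_of_origin(counts, m, config.parent_samples)
        for m in markers
        if m.is_simplex
    }

    # linkage among significant simplex markers, per parent of origin
    hit_ids = {r.marker for r in hits}
    group_frames = []
    for parent in config.parent_samples:
        simplex_hits = [
            m
            for m in markers
            if m.is_simplex
            and m.marker_id in hit_ids
            and parent_of_origin.get(m.marker_id) == parent
        ]
        if not simplex_hits:
            continue
        pairs = all_pairs(simplex_hits, min_shared=config.min_shared)
        groups = group_markers(
            [m.marker_id for m in simplex_hits], pairs, config.lod_min, config.rf_max
        )
        ordered = [order_markers(g, pairs) for g in groups]
        gf = groups_to_frame(ordered)
        gf.insert(0, "parent", parent)
        group_frames.append(gf)
    linkage_df = (
        pd.concat(group_frames, ignore_index=True)
        if group_frames
        else pd.DataFrame(columns=["parent", "group", "marker", "cm"])
    )

    # phenotype segregation against the configured dominant-locus ratio
    classes = classify_phenotype_bimodal(
        phen, config.phenotype_low_cut, config.phenotype_high_cut
    )
    n_low = int((classes["klass"] == "low").sum())
    n_high = int((classes["klass"] == "high").sum())
    n_un = int((classes["klass"] == "unclassified").sum())
    segregation = {
        "low": n_low,
        "high": n_high,
        "unclassified": n_un,
        "ratio_tested": list(config.phenotype_ratio),
    }
    if n_low + n_high > 0:
        seg = gof_chi2([n_low, n_high], list(config.phenotype_ratio))
        segregation.update(chi2=seg.chi2, df=seg.df, p_value=seg.p_value)

    _write_tsv(audit, out / "loci_audit.tsv")
    _write_tsv(marker_table, out / "markers.tsv")
    _write_tsv(assoc_df, out / "association.tsv")
    _write_tsv(hits_df, out / "significant.tsv")
    _write_tsv(linkage_df, out / "linkage_groups.tsv")
    if not assoc_df.empty:
        _write_tsv(
            assoc_df[["contig", "pos", "neg_log10_p"]], out / "manhattan.tsv"
        )
    with open(out / "segregation.json", "w") as fh:
        json.dump(segregation, fh, indent=2)
    manifest = {
        "hexadose_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(config),
        "n_loci_input": int(counts.n_loci),
        "n_markers_retained": len(markers),
        "n_significant": len(hits),
        "significant_by_type": by_type,
        "bonferroni_threshold": threshold,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(
        markers=markers,
        marker_table=marker_table,
        association=assoc_df,
        significant=hits_df,
        counts_by_type=by_type,
        linkage_groups=linkage_df,
        segregation=segregation,
        threshold=threshold,
        parent_of_origin=parent_of_origin,
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
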