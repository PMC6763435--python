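"""VCF reading/writing of per-sample allele depths (FORMAT AD/DP).

Only biallelic SNP records are consumed; multiallelic sites and indels are
skipped with a logged count.  DP is taken from the DP tag when present and
falls back to the AD sum.  Writing emits minimal VCF 4.2 with GT left
unknown (``./.``) — all downstream work is from allele depths.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import LocusReadCounts

logger = logging.getLogger(__name__)

__all__ = ["read_vcf_ad", "write_vcf", "read_phenotype_csv", "write_phenotype_csv"]


def read_vcf_ad(path: str) -> LocusReadCounts:
    """Parse a VCF with FORMAT AD into a :class:`LocusReadCounts`.

    Raises ``ValueError`` if the file declares no AD FORMAT field.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")
    rows, refs, alts = [], [], []
    n_skipped_multi = n_skipped_indel = 0
    saw_ad = False
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped_multi += 1
            continue
        if len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            n_skipped_indel += 1
            continue
        try:
            ad = variant.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            continue
        saw_ad = True
        ad = np.asarray(ad)
        if ad.ndim != 2 or ad.shape[1] < 2:
            continue
        ref_c = ad[:, 0].astype(np.int64)
        alt_c = ad[:, 1].astype(np.int64)
        # cyvcf2 encodes missing AD entries as negative sentinels
        ref_c[ref_c < 0] = 0
        alt_c[alt_c < 0] = 0
        rows.append(
            {
                "contig": variant.CHROM,
                "pos": variant.POS,
                "ref": variant.REF,
                "alt": variant.ALT[0],
            }
        )
        refs.append(ref_c)
        alts.append(alt_c)
    if not saw_ad:
        raise ValueError(f"{path}: no biallelic records with an AD FORMAT field")
    if n_skipped_multi or n_skipped_indel:
        logger.info(
            "read_vcf_ad: skipped %d multiallelic and %d indel records",
            n_skipped_multi,
            n_skipped_indel,
        )
    return LocusReadCounts(
        loci=pd.DataFrame(rows),
        samples=samples,
        ref_counts=np.vstack(refs),
        alt_counts=np.vstack(alts),
    )


def write_vcf(counts: LocusReadCounts, path: str, source: str = "hexadose") -> None:
    """Write counts as a minimal VCF 4.2 with GT:AD:DP per sample."""
    contigs = list(dict.fromkeys(counts.loci["contig"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(counts.samples)
            + "\n"
        )
        depth = counts.depth
        for i, row in counts.loci.iterrows():
            cells = [
                f"./.:{r},{a}:{d}"
                for r, a, d in zip(counts.ref_counts[i], counts.alt_counts[i], depth[i])
            ]
            fh.write(
                f"{row['contig']}\t{row['pos']}\t{row['contig']}_{row['pos']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT:AD:DP\t" + "\t".join(cells) + "\n"
            )


def read_phenotype_csv(path: str) -> pd.Series:
    """Read a phenotype CSV (sample_id, value); extra replicate columns averaged."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("phenotype CSV needs a sample column and at least one value column")
    ids = df.iloc[:, 0].astype(str)
    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").mean(axis=1)
    series = pd.Series(values.to_numpy(), index=ids, name="phenotype")
    if series.index.duplicated().any():
        raise ValueError("duplicate sample ids in phenotype table")
    return series


def write_phenotype_csv(phen: pd.Series, path: str) -> None:
    pd.DataFrame({"sample_id": phen.index, "value": phen.to_numpy()}).to_csv(
        path, index=False
    )
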