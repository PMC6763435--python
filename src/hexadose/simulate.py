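"""Synthetic biparental autohexaploid F1 populations with read-count genotyping.

Generates the study design end to end: two hexaploid parents with alleles
placed on explicit homologs, hexasomic meiosis under random bivalent pairing
with Haldane (no-interference) crossovers, an F1 of arbitrary size, RAD-seq
style REF/ALT read counts with an overdispersed depth model, and a bimodal
quantitative phenotype controlled by a dominant duplex causal locus.

The default scenario mirrors a cross between a duplex carrier of a dominant
"cleavage" allele (the two copies on different homologs, each tagged in
coupling by nearby simplex SNPs) and a nulliplex mate, in a population of
102 offspring — so the downstream single-dose SNP selection, GWAS and
linkage stages can be exercised and validated without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import LocusReadCounts
from .core import GAMETE_PLOIDY, PLOIDY

__all__ = [
    "DepthModel",
    "PhenotypeModel",
    "ChromosomeMap",
    "ParentGenome",
    "Scenario",
    "ScenarioConfig",
    "build_scenario",
    "simulate_meiosis",
    "simulate_f1",
    "simulate_reads",
    "simulate_phenotype",
    "simulate_dataset",
    "F1Population",
]

# locus categories recorded in the truth table
CAT_SIMPLEX_P1 = "simplex_p1"
CAT_SIMPLEX_P2 = "simplex_p2"
CAT_DOUBLE_SIMPLEX = "double_simplex"
CAT_MULTIPLEX = "multiplex"
CAT_CAUSAL = "causal"
CAT_TAG = "tag_snp"

SINGLE_DOSE_SUMS = frozenset({1, 2, 10, 11})


@dataclass(frozen=True)
class DepthModel:
    """Read-depth model: negative binomial with a point mass at zero.

    ``mean_depth`` and ``dispersion`` parameterize the negative binomial
    (variance = mean + mean^2/dispersion); ``error_rate`` is the per-read
    miscall probability and ``missing_rate`` the chance a sample x locus
    has no coverage at all.
    """

    mean_depth: float = 40.0
    dispersion: float = 5.0
    error_rate: float = 0.005
    missing_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class PhenotypeModel:
    """Bimodal trait model (concentrations in ug/g fresh weight).

    Carriers of the dominant allele sit in a low log-normal mode truncated
    below ``carrier_max``; non-carriers are uniform on the log scale between
    ``noncarrier_low`` and ``noncarrier_high``.
    """

    carrier_median: float = 1.0
    carrier_log_sd: float = 0.3
    carrier_max: float = 2.2
    noncarrier_low: float = 29.6
    noncarrier_high: float = 130.4

    def __post_init__(self) -> None:
        if not self.carrier_max <= self.noncarrier_low:
            raise ValueError("carrier values must lie below the non-carrier range")
        if not self.noncarrier_low < self.noncarrier_high:
            raise ValueError("noncarrier_low must be below noncarrier_high")
        if self.carrier_median >= self.carrier_max:
            raise ValueError("carrier_median must be below carrier_max")


@dataclass
class ChromosomeMap:
    """Shared locus map for one chromosome (all six homologs)."""

    name: str
    pos_bp: np.ndarray
    pos_cm: np.ndarray
    length_cm: float

    def __post_init__(self) -> None:
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        if self.pos_bp.shape != self.pos_cm.shape:
            raise ValueError("pos_bp and pos_cm must align")
        if np.any(np.diff(self.pos_bp) <= 0) or np.any(np.diff(self.pos_cm) < 0):
            raise ValueError("locus positions must be increasing")

    @property
    def n_loci(self) -> int:
        return self.pos_bp.size


@dataclass
class ParentGenome:
    """Six explicit homologs per chromosome, ALT indicators per locus."""

    chromosomes: list[ChromosomeMap]
    homologs: list[np.ndarray]  # per chromosome: (6, n_loci) uint8 ALT indicator

    def __post_init__(self) -> None:
        if len(self.chromosomes) != len(self.homologs):
            raise ValueError("one homolog matrix per chromosome required")
        for cm_map, hom in zip(self.chromosomes, self.homologs):
            if hom.shape != (PLOIDY, cm_map.n_loci):
                raise ValueError(
                    f"homolog matrix for {cm_map.name} must be (6, {cm_map.n_loci})"
                )

    @property
    def n_loci(self) -> int:
        return sum(c.n_loci for c in self.chromosomes)

    def dosages(self) -> np.ndarray:
        """Per-locus ALT dosage (0..6), concatenated over chromosomes."""
        return np.concatenate([h.sum(axis=0) for h in self.homologs])


@dataclass
class F1Population:
    """Simulated offspring: true dosages plus the transmitted gamete dosages."""

    dosages: np.ndarray  # (n_individuals, n_loci) 0..6
    gamete_p1: np.ndarray  # (n_individuals, n_loci) 0..3 ALT copies from parent 1
    gamete_p2: np.ndarray

    @property
    def n(self) -> int:
        return self.dosages.shape[0]


@dataclass
class Scenario:
    """Two parent genomes plus the per-locus truth table."""

    parent1: ParentGenome
    parent2: ParentGenome
    truth: pd.DataFrame  # contig,pos,cm,dosage_p1,dosage_p2,category,linked_to_causal
    causal_index: int | None

    @property
    def n_loci(self) -> int:
        return len(self.truth)


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration for :func:`build_scenario`.

    Defaults approximate the study design: ~2,000 loci over three
    chromosomes, a duplex causal locus in parent 1 (alleles on homologs 1
    and 2 of the first chromosome, i.e. in repulsion with each other), a
    nulliplex parent 2, ten coupling-phase simplex tag SNPs within ~8 cM of
    each causal allele (matching the density of coupling simplex SNPs the
    study resolved into its two homolog linkage groups), and background
    loci in roughly the proportions of single-dose classes observed among
    real RAD-seq SNP candidates (~7% simplex, ~10.5% double-simplex, the
    rest multiplex).
    """

    n_chromosomes: int = 3
    chrom_length_cm: float = 100.0
    loci_per_chromosome: int = 660
    frac_simplex: float = 0.07
    frac_double_simplex: float = 0.105
    with_causal: bool = True
    causal_cm: float = 50.0
    tag_offsets_cm: tuple[float, ...] = (
        -8.0,
        -6.5,
        -5.0,
        -3.5,
        -2.0,
        1.0,
        2.5,
        4.0,
        5.5,
        7.0,
    )
    n_f1: int = 102

    def __post_init__(self) -> None:
        if self.frac_simplex + self.frac_double_simplex > 1:
            raise ValueError("category fractions exceed 1")
        if self.n_chromosomes < 1 or self.loci_per_chromosome < 0:
            raise ValueError("invalid scenario dimensions")
        if self.with_causal and not 0 < self.causal_cm < self.chrom_length_cm:
            raise ValueError("causal_cm must lie inside the first chromosome")


def _draw_positions(n: int, length_cm: float, rng: np.random.Generator) -> np.ndarray:
    return np.sort(rng.uniform(0.0, length_cm, size=n))


def _choose_homologs(dosage: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(PLOIDY, size=dosage, replace=False)


def _multiplex_pair(rng: np.random.Generator) -> tuple[int, int]:
    # any segregating dosage pair that is not single-dose (sum outside
    # {1,2,10,11}) and not monomorphic (sum 0 or 12)
    while True:
        d1 = int(rng.integers(0, PLOIDY + 1))
        d2 = int(rng.integers(0, PLOIDY + 1))
        s = d1 + d2
        if 0 < s < 12 and s not in SINGLE_DOSE_SUMS:
            return d1, d2


def build_scenario(
    config: ScenarioConfig = ScenarioConfig(), rng: np.random.Generator | int | None = 0
) -> Scenario:
    """Build the two parent genomes and the locus truth table.

    Deterministic given the seed/generator.  The causal locus is placed
    duplex in parent 1 with the two copies on homologs 0 and 1 (repulsion),
    nulliplex in parent 2, and each copy is tagged by coupling-phase simplex
    SNPs at ``tag_offsets_cm`` around it.
    """
    rng = np.random.default_rng(rng)
    p_simplex = config.frac_simplex
    p_ds = config.frac_double_simplex

    chrom_maps: list[ChromosomeMap] = []
    homs1: list[np.ndarray] = []
    homs2: list[np.ndarray] = []
    truth_rows: list[dict] = []
    causal_index: int | None = None
    global_index = 0

    for ci in range(config.n_chromosomes):
        name = f"chr{ci + 1:02d}"
        cm = _draw_positions(config.loci_per_chromosome, config.chrom_length_cm, rng)
        extra: list[tuple[float, str, int]] = []  # (cm, category, p1 homolog)
        if config.with_causal and ci == 0:
            extra.append((config.causal_cm, CAT_CAUSAL, -1))
            for hom in (0, 1):
                for off in config.tag_offsets_cm:
                    extra.append((config.causal_cm + off, CAT_TAG, hom))
        all_cm = np.concatenate([cm, np.array([e[0] for e in extra])])
        order = np.argsort(all_cm, kind="stable")
        all_cm = all_cm[order]
        categories = np.array(
            ["" for _ in cm] + [e[1] for e in extra], dtype=object
        )[order]
        tag_homolog = np.array([-1] * len(cm) + [e[2] for e in extra])[order]
        n_loci = all_cm.size
        # nominal physical coordinates: 10 kb per locus index plus cM jitter
        pos_bp = (np.arange(n_loci) * 10_000 + (all_cm * 1e3).astype(np.int64) + 1).astype(
            np.int64
        )
        chrom_maps.append(ChromosomeMap(name, pos_bp, all_cm, config.chrom_length_cm))

        h1 = np.zeros((PLOIDY, n_loci), dtype=np.uint8)
        h2 = np.zeros((PLOIDY, n_loci), dtype=np.uint8)
        for li in range(n_loci):
            cat = categories[li]
            if cat == CAT_CAUSAL:
                d1, d2 = 2, 0
                h1[[0, 1], li] = 1
                causal_index = global_index
            elif cat == CAT_TAG:
                d1, d2 = 1, 0
                h1[tag_homolog[li], li] = 1
            else:
                u = rng.random()
                alt_common = rng.random() < 0.5
                if u < p_simplex:
                    in_p1 = rng.random() < 0.5
                    cat = CAT_SIMPLEX_P1 if in_p1 else CAT_SIMPLEX_P2
                    d1, d2 = (1, 0) if in_p1 else (0, 1)
                    if alt_common:
                        d1, d2 = PLOIDY - d1, PLOIDY - d2
                elif u < p_simplex + p_ds:
                    cat = CAT_DOUBLE_SIMPLEX
                    d1 = d2 = 5 if alt_common else 1
                else:
                    cat = CAT_MULTIPLEX
                    d1, d2 = _multiplex_pair(rng)
                if d1:
                    h1[_choose_homologs(d1, rng), li] = 1
                if d2:
                    h2[_choose_homologs(d2, rng), li] = 1
                categories[li] = cat
            # coupling with a causal allele: rare allele of parent 1 shares a
            # homolog (0 or 1) with a causal copy on the causal chromosome
            rare_is_alt = (d1 + d2) <= PLOIDY
            p1_rare = h1[:, li].astype(bool) if rare_is_alt else ~h1[:, li].astype(bool)
            linked = (
                config.with_causal
                and ci == 0
                and d1 not in (0, PLOIDY)
                and bool(p1_rare[0] or p1_rare[1])
            )
            truth_rows.append(
                {
                    "contig": name,
                    "pos": int(pos_bp[li]),
                    "cm": float(all_cm[li]),
                    "dosage_p1": d1,
                    "dosage_p2": d2,
                    "category": categories[li],
                    "linked_to_causal": linked,
                }
            )
            global_index += 1
        homs1.append(h1)
        homs2.append(h2)

    truth = pd.DataFrame(truth_rows)
    truth["marker"] = truth["contig"] + "_" + truth["pos"].astype(str)
    parent1 = ParentGenome(chrom_maps, homs1)
    parent2 = ParentGenome(
        [replace(c) for c in chrom_maps], homs2
    )
    return Scenario(parent1, parent2, truth, causal_index)


def simulate_meiosis(parent: ParentGenome, rng: np.random.Generator) -> list[np.ndarray]:
    """One gamete: 3 recombinant homologs per chromosome.

    The six homologs pair uniformly at random into three bivalents.  Within
    a bivalent, crossovers occur as a Poisson process with mean equal to the
    map length in Morgans (so two-locus recombinant fractions follow the
    Haldane map function), and one of the two recombinant products is
    transmitted.  Returns one ``(3, n_loci)`` ALT-indicator array per
    chromosome.
    """
    gamete = []
    for cm_map, hom in zip(parent.chromosomes, parent.homologs):
        order = rng.permutation(PLOIDY)
        products = np.empty((GAMETE_PLOIDY, cm_map.n_loci), dtype=np.uint8)
        length_morgans = cm_map.length_cm / 100.0
        for b in range(GAMETE_PLOIDY):
            a, c = order[2 * b], order[2 * b + 1]
            strands = hom[[a, c]]
            n_xo = rng.poisson(length_morgans)
            if n_xo:
                xo = np.sort(rng.uniform(0.0, cm_map.length_cm, size=n_xo))
                parity = np.searchsorted(xo, cm_map.pos_cm, side="right") % 2
            else:
                parity = np.zeros(cm_map.n_loci, dtype=np.intp)
            start = int(rng.integers(2))
            products[b] = strands[(start + parity) % 2, np.arange(cm_map.n_loci)]
        gamete.append(products)
    return gamete


def simulate_f1(
    p1: ParentGenome, p2: ParentGenome, n: int, rng: np.random.Generator | int | None = None
) -> F1Population:
    """Simulate ``n`` F1 individuals, one gamete from each parent."""
    rng = np.random.default_rng(rng)
    if [c.n_loci for c in p1.chromosomes] != [c.n_loci for c in p2.chromosomes]:
        raise ValueError("parents must share the same locus map")
    n_loci = p1.n_loci
    g1 = np.zeros((n, n_loci), dtype=np.int8)
    g2 = np.zeros((n, n_loci), dtype=np.int8)
    for i in range(n):
        g1[i] = np.concatenate([p.sum(axis=0) for p in simulate_meiosis(p1, rng)])
        g2[i] = np.concatenate([p.sum(axis=0) for p in simulate_meiosis(p2, rng)])
    return F1Population(dosages=(g1 + g2).astype(np.int8), gamete_p1=g1, gamete_p2=g2)


def simulate_reads(
    dosages: np.ndarray,
    depth_model: DepthModel = DepthModel(),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """REF/ALT read counts for a (n_individuals, n_loci) dosage matrix.

    Depth is negative binomial (zero with ``missing_rate``); ALT reads are
    binomial with success probability ``(d/6)(1-e) + (1-d/6)e``.
    Returns ``(ref_counts, alt_counts)`` with shape ``(n_loci, n_samples)``
    (transposed to locus-major, matching :class:`LocusReadCounts`).
    """
    rng = np.random.default_rng(rng)
    d = np.asarray(dosages)
    m = depth_model
    nb_n = m.dispersion
    nb_p = m.dispersion / (m.dispersion + m.mean_depth)
    depth = rng.negative_binomial(nb_n, nb_p, size=d.shape)
    if m.missing_rate > 0:
        depth[rng.random(d.shape) < m.missing_rate] = 0
    frac = d / PLOIDY
    p_alt = frac * (1.0 - m.error_rate) + (1.0 - frac) * m.error_rate
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt
    return ref.T.astype(np.int64), alt.T.astype(np.int64)


def simulate_phenotype(
    causal_dosages: np.ndarray,
    model: PhenotypeModel = PhenotypeModel(),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Bimodal trait values from carrier status at the causal locus.

    Carriers (dosage >= 1) are log-normal around ``carrier_median``,
    truncated below ``carrier_max``; non-carriers are uniform on the log
    scale over the non-carrier range.
    """
    rng = np.random.default_rng(rng)
    d = np.asarray(causal_dosages)
    n = d.size
    carrier = d >= 1
    out = np.empty(n, dtype=float)
    # truncated log-normal for carriers via rejection (truncation is mild)
    n_car = int(carrier.sum())
    vals = np.empty(0)
    while vals.size < n_car:
        draw = model.carrier_median * np.exp(
            rng.normal(0.0, model.carrier_log_sd, size=max(2 * n_car, 8))
        )
        vals = np.concatenate([vals, draw[draw < model.carrier_max]])
    out[carrier] = vals[:n_car]
    lo, hi = np.log(model.noncarrier_low), np.log(model.noncarrier_high)
    out[~carrier] = np.exp(rng.uniform(lo, hi, size=n - n_car))
    return out


def simulate_dataset(
    config: ScenarioConfig = ScenarioConfig(),
    depth_model: DepthModel = DepthModel(),
    phenotype_model: PhenotypeModel = PhenotypeModel(),
    seed: int | None = 0,
):
    """Full dataset: read counts (parents + F1), phenotype table, truth.

    Returns ``(counts, phenotype, scenario, f1)`` where ``counts`` is a
    :class:`LocusReadCounts` whose first two samples are the parents P1 and
    P2, and ``phenotype`` is a Series over the F1 sample ids (ug/g FW).
    """
    rng = np.random.default_rng(seed)
    scenario = build_scenario(config, rng)
    f1 = simulate_f1(scenario.parent1, scenario.parent2, config.n_f1, rng)
    parent_dosages = np.vstack(
        [scenario.parent1.dosages(), scenario.parent2.dosages()]
    )
    all_dosages = np.vstack([parent_dosages, f1.dosages])
    ref, alt = simulate_reads(all_dosages, depth_model, rng)
    samples = ["P1", "P2"] + [f"F1_{i + 1:03d}" for i in range(config.n_f1)]
    loci = scenario.truth[["contig", "pos"]].copy()
    loci["ref"] = "A"
    loci["alt"] = "T"
    counts = LocusReadCounts(loci=loci, samples=samples, ref_counts=ref, alt_counts=alt)
    if scenario.causal_index is not None:
        causal_dosage = f1.dosages[:, scenario.causal_index]
    else:
        causal_dosage = np.zeros(config.n_f1, dtype=int)
    phen = pd.Series(
        simulate_phenotype(causal_dosage, phenotype_model, rng),
        index=samples[2:],
        name="carotenoid_ug_per_g_fw",
    )
    return counts, phen, scenario, f1
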