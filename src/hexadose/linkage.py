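"""Two-point linkage grouping and ordering of simplex markers.

Simplex markers segregating from one parent behave like testcross loci:
each offspring either received the marked homolog or did not, so the
recombination fraction between two coupling-phase markers is simply the
discordance rate of their two-class codes.  Grouping is single-linkage on
(LOD >= lod_min, rf <= rf_max) edges using coupling-phase pairs only —
repulsion-phase pairs in a hexaploid carry little linkage information and
groups are meant to correspond to single homologs.  Ordering is a greedy
nearest-neighbour seriation with Haldane map distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mining import MISSING, NON_HOM, EncodedMarker

logger = logging.getLogger(__name__)

__all__ = [
    "LinkagePair",
    "LinkageGroup",
    "pairwise_rf",
    "all_pairs",
    "group_markers",
    "order_markers",
    "haldane_cm",
]


@dataclass(frozen=True)
class LinkagePair:
    marker_a: str
    marker_b: str
    rf: float
    lod: float
    phase: str  # "coupling" or "repulsion"
    n: int


@dataclass
class LinkageGroup:
    markers: list[str]
    positions_cm: list[float]


def haldane_cm(rf: float) -> float:
    """Haldane map distance in cM for a recombination fraction."""
    rf = min(max(float(rf), 0.0), 0.5 - 1e-12)
    return -50.0 * np.log(1.0 - 2.0 * rf)


def _lod(r: int, n: int, rf: float) -> float:
    # log10 likelihood ratio of binomial(n, rf) vs binomial(n, 1/2)
    with np.errstate(divide="ignore"):
        ll = 0.0
        if r:
            ll += r * np.log10(rf)
        if n - r:
            ll += (n - r) * np.log10(1.0 - rf)
    return float(ll - n * np.log10(0.5))


def pairwise_rf(
    a: EncodedMarker, b: EncodedMarker, min_shared: int = 20
) -> LinkagePair | None:
    """Two-point recombination fraction between two simplex markers.

    Coupling orientation counts discordant codes as recombinants; if the
    discordance exceeds 1/2 the pair is re-expressed in repulsion
    orientation.  Pairs with fewer than ``min_shared`` jointly scored
    individuals are skipped (returns None).
    """
    if not (a.is_simplex and b.is_simplex):
        raise ValueError("pairwise_rf is defined for simplex markers only")
    ok = (a.codes != MISSING) & (b.codes != MISSING)
    n = int(ok.sum())
    if n < min_shared:
        logger.info("pair %s-%s skipped: only %d shared individuals", a.marker_id, b.marker_id, n)
        return None
    x = (a.codes[ok] == NON_HOM)
    y = (b.codes[ok] == NON_HOM)
    disc = int(np.sum(x != y))
    if disc <= n - disc:
        phase, r = "coupling", disc
    else:
        phase, r = "repulsion", n - disc
    rf = r / n
    lod = _lod(r, n, max(rf, 1e-9)) if rf < 0.5 else 0.0
    ma, mb = sorted([a.marker_id, b.marker_id])
    return LinkagePair(ma, mb, rf=rf, lod=max(lod, 0.0), phase=phase, n=n)


def all_pairs(markers: list[EncodedMarker], min_shared: int = 20) -> list[LinkagePair]:
    """Pairwise table over all simplex marker pairs (skipped pairs omitted)."""
    pairs = []
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            p = pairwise_rf(markers[i], markers[j], min_shared)
            if p is not None:
                pairs.append(p)
    return pairs


def group_markers(
    marker_ids: list[str],
    pairs: list[LinkagePair],
    lod_min: float = 3.0,
    rf_max: float = 0.35,
) -> list[list[str]]:
    """Single-linkage clustering on coupling-phase edges.

    Markers are joined when some coupling pair has LOD >= lod_min and
    rf <= rf_max.  Deterministic: groups sorted by their smallest marker
    id, markers sorted within each group.
    """
    ids = sorted(set(marker_ids))
    parent = {m: m for m in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in sorted(pairs, key=lambda q: (q.marker_a, q.marker_b)):
        if p.phase != "coupling" or p.lod < lod_min or p.rf > rf_max:
            continue
        if p.marker_a in parent and p.marker_b in parent:
            ra, rb = find(p.marker_a), find(p.marker_b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[str, list[str]] = {}
    for m in ids:
        clusters.setdefault(find(m), []).append(m)
    groups = [sorted(v) for v in clusters.values()]
    groups.sort(key=lambda g: g[0])
    return groups


def order_markers(group: list[str], pairs: list[LinkagePair]) -> LinkageGroup:
    """Greedy seriation of one group with cumulative Haldane positions.

    Starts from an endpoint of the most distant (max rf) within-group pair
    and repeatedly appends the nearest unplaced marker; positions are
    cumulative Haldane-transformed adjacent recombination fractions.
    """
    members = sorted(set(group))
    if len(members) == 1:
        return LinkageGroup(markers=members, positions_cm=[0.0])
    rf_map: dict[tuple[str, str], float] = {}
    for p in pairs:
        if p.marker_a in members and p.marker_b in members:
            rf_map[(p.marker_a, p.marker_b)] = p.rf
            rf_map[(p.marker_b, p.marker_a)] = p.rf

    def rf_of(a: str, b: str) -> float:
        return rf_map.get((a, b), 0.5)

    # endpoint of the most separated pair (tie-break by marker id)
    best = max(
        ((rf_of(a, b), min(a, b), a, b) for a in members for b in members if a != b),
        key=lambda t: (t[0], t[1]),
    )
    current = min(best[2], best[3])
    order = [current]
    placed = {current}
    positions = [0.0]
    while len(order) < len(members):
        candidates = sorted(m for m in members if m not in placed)
        nxt = min(candidates, key=lambda m: (rf_of(current, m), m))
        positions.append(positions[-1] + haldane_cm(rf_of(current, nxt)))
        order.append(nxt)
        placed.add(nxt)
        current = nxt
    return LinkageGroup(markers=order, positions_cm=positions)


def groups_to_frame(groups: list[LinkageGroup]) -> pd.DataFrame:
    rows = []
    for gi, g in enumerate(groups, start=1):
        for m, pos in zip(g.markers, g.positions_cm):
            rows.append({"group": gi, "marker": m, "cm": pos})
    return pd.DataFrame(rows, columns=["group", "marker", "cm"])
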