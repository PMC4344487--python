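"""Genomic localization of catalogue regions.

Regions are assigned to exactly one of six genomic categories by the position
of their midpoint base, with a regulatory-first precedence:
promoter > 5'UTR > 3'UTR > exon (CDS) > intron > intergenic.  The promoter is
the 3 kb window upstream of the TSS (strand-aware).  The module also profiles
region density around TSSs by combinatorial complexity, computes the recovery
of external element sets (>= 1 bp overlap), and aggregates a per-base
conservation-style score track around site summits.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .catalogue import CatalogueRegion, NonRedundantSite
from .core import (
    AnnotationModel,
    CrmcatError,
    GenomicInterval,
    ScoreTrack,
)

__all__ = [
    "CATEGORIES",
    "TssProfile",
    "ConservationProfile",
    "assign_category",
    "category_table",
    "tss_profile",
    "resource_recovery",
    "conservation_profile",
]

CATEGORIES = ("promoter", "utr5", "utr3", "exon", "intron", "intergenic")

DEFAULT_COMPLEXITY_GROUPS: Tuple[Tuple[str, int, int], ...] = (
    ("1", 1, 1),
    ("2-4", 2, 4),
    ("5-9", 5, 9),
    ("10+", 10, 10**9),
)


class _CategoryIndex:
    """Per-category sorted interval arrays for midpoint membership tests."""

    def __init__(self, annotation: AnnotationModel, promoter_upstream: int) -> None:
        ivs: Dict[str, List[Tuple[str, int, int]]] = {c: [] for c in CATEGORIES[:-1]}
        for g in annotation.genes:
            if g.strand == "+":
                ivs["promoter"].append((g.chrom, g.tss - promoter_upstream, g.tss))
            else:
                ivs["promoter"].append((g.chrom, g.tss + 1, g.tss + 1 + promoter_upstream))
            coding = g.cds_start < g.cds_end
            for es, ee in zip(g.exon_starts, g.exon_ends):
                if coding:
                    left = (g.chrom, es, min(ee, g.cds_start))
                    right = (g.chrom, max(es, g.cds_end), ee)
                    five, three = (left, right) if g.strand == "+" else (right, left)
                    if five[1] < five[2]:
                        ivs["utr5"].append(five)
                    if three[1] < three[2]:
                        ivs["utr3"].append(three)
                    a, b = max(es, g.cds_start), min(ee, g.cds_end)
                    if a < b:
                        ivs["exon"].append((g.chrom, a, b))
                else:
                    ivs["exon"].append((g.chrom, es, ee))
            ivs["intron"].append((g.chrom, g.tx_start, g.tx_end))
        self._index: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]] = {}
        for cat, triples in ivs.items():
            per_chrom: Dict[str, List[Tuple[int, int]]] = {}
            for chrom, a, b in triples:
                if max(a, 0) < b:
                    per_chrom.setdefault(chrom, []).append((max(a, 0), b))
            self._index[cat] = {}
            for chrom, pairs in per_chrom.items():
                pairs.sort()
                starts = np.array([p[0] for p in pairs])
                # intervals of one category may overlap (e.g. promoters of two
                # genes); the running max of ends makes containment O(log n)
                ends = np.maximum.accumulate(np.array([p[1] for p in pairs]))
                self._index[cat][chrom] = (starts, ends)

    def contains(self, cat: str, chrom: str, pos: int) -> bool:
        per_chrom = self._index.get(cat, {})
        if chrom not in per_chrom:
            return False
        starts, cummax_ends = per_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < cummax_ends[i]


def assign_category(
    region: GenomicInterval,
    annotation: AnnotationModel,
    promoter_upstream: int = 3_000,
    _index: Optional[_CategoryIndex] = None,
) -> str:
    """Category of the region's midpoint base, by fixed precedence.

    The intron test uses the transcript span (midpoints inside a gene that are
    not exonic/UTR fall in introns because the exon tests take precedence).
    """
    index = _index or _CategoryIndex(annotation, promoter_upstream)
    mid = region.midpoint
    for cat in CATEGORIES[:-1]:
        if index.contains(cat, region.chrom, mid):
            return cat
    return "intergenic"


def category_table(
    regions: Sequence[CatalogueRegion],
    annotation: AnnotationModel,
    promoter_upstream: int = 3_000,
) -> Dict[str, int]:
    """Counts of regions per genomic category (exclusive midpoint calls)."""
    index = _CategoryIndex(annotation, promoter_upstream)
    counts = Counter(
        assign_category(r.interval, annotation, promoter_upstream, _index=index)
        for r in regions
    )
    return {cat: counts.get(cat, 0) for cat in CATEGORIES}


@dataclass
class TssProfile:
    """Density of region midpoints by signed distance to the nearest TSS."""

    bin_edges: np.ndarray  # signed distances, upstream negative
    densities: Dict[str, np.ndarray]  # complexity group -> density per bin
    counts: Dict[str, np.ndarray]


def tss_profile(
    regions: Sequence[CatalogueRegion],
    annotation: AnnotationModel,
    window: int = 2_500,
    bin_width: int = 50,
    complexity_groups: Sequence[Tuple[str, int, int]] = DEFAULT_COMPLEXITY_GROUPS,
) -> TssProfile:
    """Histogram of region midpoints around TSSs, per complexity group.

    Distances are strand-oriented (upstream of the TSS is negative); regions
    whose midpoint lies further than ``window`` from every TSS are excluded.
    Each group's histogram is normalised to a density over the included bins.
    """
    if window <= 0 or (2 * window) % bin_width:
        raise CrmcatError("bin_width must divide 2*window")
    tss = annotation.tss_list()
    if not tss:
        raise CrmcatError("annotation contains no TSS")
    by_chrom: Dict[str, Tuple[np.ndarray, List[str]]] = {}
    for chrom in {c for c, _, _ in tss}:
        entries = sorted((p, s) for c, p, s in tss if c == chrom)
        by_chrom[chrom] = (
            np.array([p for p, _ in entries]),
            [s for _, s in entries],
        )
    edges = np.arange(-window, window + 1, bin_width)
    counts = {
        label: np.zeros(edges.size - 1, dtype=np.int64)
        for label, _, _ in complexity_groups
    }

    def group_of(n: int) -> Optional[str]:
        for label, lo, hi in complexity_groups:
            if lo <= n <= hi:
                return label
        return None

    for r in regions:
        label = group_of(len(r.tf_set))
        if label is None or r.interval.chrom not in by_chrom:
            continue
        positions, strands = by_chrom[r.interval.chrom]
        mid = r.interval.midpoint
        i = int(np.searchsorted(positions, mid))
        best, best_dist = None, None
        for j in (i - 1, i):
            if 0 <= j < positions.size:
                d = abs(mid - int(positions[j]))
                if best_dist is None or d < best_dist:
                    best, best_dist = j, d
        if best is None:
            continue
        signed = mid - int(positions[best])
        if strands[best] == "-":
            signed = -signed
        if -window <= signed < window:
            counts[label][(signed + window) // bin_width] += 1

    densities = {}
    for label, arr in counts.items():
        total = arr.sum()
        densities[label] = arr / total if total else arr.astype(float)
    return TssProfile(bin_edges=edges, densities=densities, counts=counts)


def resource_recovery(
    catalogue: Sequence[CatalogueRegion],
    elements: Sequence[GenomicInterval],
    crm_only: bool = False,
) -> float:
    """Percentage of elements overlapped (>= 1 bp) by any catalogue region."""
    if not elements:
        raise CrmcatError("resource_recovery: empty element list")
    regions = [r for r in catalogue if not crm_only or r.kind == "crm"]
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.interval.chrom, []).append(
            (r.interval.start, r.interval.end)
        )
    arrays = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        arrays[chrom] = (
            np.array([p[0] for p in pairs]),
            np.maximum.accumulate(np.array([p[1] for p in pairs])),
        )
    hit = 0
    for el in elements:
        if el.chrom not in arrays:
            continue
        starts, cummax_ends = arrays[el.chrom]
        i = int(np.searchsorted(starts, el.end, side="left")) - 1
        if i >= 0 and cummax_ends[i] > el.start:
            hit += 1
    return 100.0 * hit / len(elements)


@dataclass
class ConservationProfile:
    """Mean score per offset from the summit, per TF, with coverage counts."""

    offsets: np.ndarray
    means: Dict[str, np.ndarray]
    coverage: Dict[str, np.ndarray]


def conservation_profile(
    sites_by_tf: Dict[str, Sequence[NonRedundantSite]],
    track: ScoreTrack,
    half_window: int = 1_000,
) -> ConservationProfile:
    """Summit-centred aggregation of a per-base score track.

    For each offset in [-half_window, +half_window], the mean of the track
    over all sites where the base has a value; absent bases are excluded from
    both numerator and denominator.
    """
    offsets = np.arange(-half_window, half_window + 1)
    means: Dict[str, np.ndarray] = {}
    coverage: Dict[str, np.ndarray] = {}
    for tf, sites in sites_by_tf.items():
        if not sites:
            raise CrmcatError(f"no sites for TF {tf}")
        total = np.zeros(offsets.size)
        count = np.zeros(offsets.size, dtype=np.int64)
        for s in sites:
            window = track.window(
                s.interval.chrom, s.summit - half_window, s.summit + half_window + 1
            )
            ok = ~np.isnan(window)
            total[ok] += window[ok]
            count[ok] += 1
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, total / np.where(count > 0, count, 1), np.nan)
        means[tf] = mean
        coverage[tf] = count
    return ConservationProfile(offsets=offsets, means=means, coverage=coverage)
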