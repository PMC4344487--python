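"""Non-redundant per-TF binding sites and the cross-TF CRM catalogue.

ChIP-seq experiments for the same TF, performed in different studies and
conditions, call heavily overlapping peaks at genuinely bound loci.  Merging
overlapping peaks (>= 1 bp shared, half-open semantics) of one TF yields its
*non-redundant sites*, with the merged summit defined as the average of member
summits.  Merging sites across all TFs yields catalogue regions: regions bound
by two or more distinct TFs are *cis-regulatory modules* (CRMs), regions bound
by a single TF are *singletons*.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple

from .core import CrmcatError, DatasetLabel, GenomicInterval, Peak

__all__ = [
    "NonRedundantSite",
    "CatalogueRegion",
    "ComplexityDistribution",
    "merge_tf_peaks",
    "build_crms",
    "complexity_distribution",
    "summit_displacement_stats",
]


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class NonRedundantSite:
    """Merged peak of one TF across datasets; summit = mean of member summits."""

    interval: GenomicInterval
    tf: str
    summit: int
    member_summits: Tuple[int, ...]
    source_datasets: Tuple[DatasetLabel, ...] = ()

    @property
    def n_members(self) -> int:
        return len(self.member_summits)


@dataclass(frozen=True)
class CatalogueRegion:
    """Merged cross-TF region: a CRM if bound by >= 2 TFs, else a singleton."""

    interval: GenomicInterval
    tf_set: FrozenSet[str]
    n_sites: int

    @property
    def kind(self) -> str:
        return "crm" if len(self.tf_set) >= 2 else "singleton"


@dataclass
class ComplexityDistribution:
    """Histogram of catalogue regions by number of distinct bound TFs."""

    counts: Dict[str, int]
    labels: List[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def proportions(self) -> Dict[str, float]:
        total = self.total
        if total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / total for k, v in self.counts.items()}


def merge_tf_peaks(peaks: Sequence[Peak]) -> List[NonRedundantSite]:
    """Merge overlapping peaks of a single TF into non-redundant sites.

    Components of the >=1 bp overlap relation are merged; book-ended peaks
    (end == next start) stay separate under half-open semantics.  The merged
    summit is the arithmetic mean of member summits, rounded half-up and
    clamped inside the merged interval (the clamp cannot trigger for contained
    members; it guards rounding at the right edge).
    """
    if not peaks:
        return []
    tfs = {p.dataset.tf_name for p in peaks}
    if len(tfs) > 1:
        raise CrmcatError(f"merge_tf_peaks got peaks from several TFs: {sorted(tfs)}")
    tf = tfs.pop()

    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    sites: List[NonRedundantSite] = []
    members: List[Peak] = []

    def flush() -> None:
        if not members:
            return
        chrom = members[0].interval.chrom
        start = min(p.interval.start for p in members)
        end = max(p.interval.end for p in members)
        summits = tuple(p.summit for p in members)
        summit = _round_half_up(sum(summits) / len(summits))
        summit = min(max(summit, start), end - 1)
        sites.append(
            NonRedundantSite(
                interval=GenomicInterval(chrom, start, end),
                tf=tf,
                summit=summit,
                member_summits=summits,
                source_datasets=tuple(p.dataset for p in members),
            )
        )

    cur_end = -1
    for p in ordered:
        if members and p.interval.chrom == members[0].interval.chrom and p.interval.start < cur_end:
            members.append(p)
            cur_end = max(cur_end, p.interval.end)
        else:
            flush()
            members = [p]
            cur_end = p.interval.end
    flush()
    return sites


def build_crms(sites: Sequence[NonRedundantSite]) -> List[CatalogueRegion]:
    """Merge all TFs' non-redundant sites into CRMs and singletons."""
    ordered = sorted(sites, key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))
    regions: List[CatalogueRegion] = []
    members: List[NonRedundantSite] = []
    cur_end = -1

    def flush() -> None:
        if not members:
            return
        chrom = members[0].interval.chrom
        start = min(s.interval.start for s in members)
        end = max(s.interval.end for s in members)
        regions.append(
            CatalogueRegion(
                interval=GenomicInterval(chrom, start, end),
                tf_set=frozenset(s.tf for s in members),
                n_sites=len(members),
            )
        )

    for s in ordered:
        if members and s.interval.chrom == members[0].interval.chrom and s.interval.start < cur_end:
            members.append(s)
            cur_end = max(cur_end, s.interval.end)
        else:
            flush()
            members = [s]
            cur_end = s.interval.end
    flush()
    return regions


def complexity_distribution(
    regions: Sequence[CatalogueRegion],
    singles_up_to: int = 14,
    open_thresholds: Sequence[int] = (15, 50),
) -> ComplexityDistribution:
    """Bin catalogue regions by TF-set size.

    Default bins: 1 (singletons), 2, ..., ``singles_up_to`` individually, then
    half-open groups between consecutive ``open_thresholds`` and a final
    unbounded ``T+`` bin — the groupings used for combinatorial-complexity
    barplots (e.g. 1..14, 15+, 50+).
    """
    thresholds = sorted(open_thresholds)
    if thresholds and thresholds[0] <= singles_up_to:
        raise CrmcatError("open_thresholds must exceed singles_up_to")
    labels = [str(i) for i in range(1, singles_up_to + 1)]
    labels += [f"{t}+" for t in thresholds]

    def label_for(n_tfs: int) -> str:
        if n_tfs <= singles_up_to:
            return str(n_tfs)
        chosen = None
        for t in thresholds:
            if n_tfs >= t:
                chosen = f"{t}+"
        if chosen is None:
            raise CrmcatError(
                f"complexity {n_tfs} not covered by bins "
                f"(singles to {singles_up_to}, thresholds {thresholds})"
            )
        return chosen

    raw = Counter(label_for(len(r.tf_set)) for r in regions)
    counts = {lab: raw.get(lab, 0) for lab in labels}
    return ComplexityDistribution(counts=counts, labels=labels)


def summit_displacement_stats(
    sites: Sequence[NonRedundantSite],
) -> Tuple[float, float]:
    """Mean and median of |merged summit - member summit| over all members.

    Quantifies how far individual dataset summits sit from the averaged summit
    of the non-redundant site they belong to; single-member sites contribute 0.
    """
    if not sites:
        raise CrmcatError("summit_displacement_stats: empty site list")
    import numpy as np

    disps: List[int] = []
    for s in sites:
        disps.extend(abs(s.summit - m) for m in s.member_summits)
    arr = np.asarray(disps, dtype=float)
    return float(arr.mean()), float(np.median(arr))
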