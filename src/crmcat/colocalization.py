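"""Pairwise TF co-localization significance and the specificity network.

For a query binding site, the placement null asks: if an interval of the same
length were dropped uniformly at any valid position inside the analysis
domain, how often would it land at least as close to the reference TF's sites
as the query does?  That fraction is an exact p-value for the observed
proximity.  The percentage of a query TF's sites significantly overlapping a
reference TF's sites (p <= alpha) fills an asymmetric matrix; per query row,
partners whose percentage exceeds Q3 + 1.5*IQR (moderate) or Q3 + 3*IQR
(strong) are *specific* co-localization partners, and the resulting call graph
is partitioned into communities with the weighted Louvain algorithm.

Distances are gaps in bp: 0 for intervals sharing >= 1 base, 1 for book-ended
intervals, and so on.  Placements are restricted to lie wholly within a
single domain segment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .catalogue import NonRedundantSite
from .core import CrmcatError, GenomicInterval, NoPlacementError, merge_intervals

__all__ = [
    "PlacementNull",
    "OverlapMatrix",
    "SpecificityCall",
    "CoNetwork",
    "interval_overlap_pvalue",
    "significant_overlap_fraction",
    "pairwise_matrix",
    "specificity_outliers",
    "build_and_partition_network",
    "default_domain",
]


def _as_arrays(intervals: Sequence[GenomicInterval]) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    merged = merge_intervals(intervals)
    out: Dict[str, List[Tuple[int, int]]] = {}
    for iv in merged:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        chrom: (
            np.array([p[0] for p in pairs], dtype=np.int64),
            np.array([p[1] for p in pairs], dtype=np.int64),
        )
        for chrom, pairs in out.items()
    }


def _intersection_length(
    a_starts: np.ndarray, a_ends: np.ndarray, b_starts: np.ndarray, b_ends: np.ndarray
) -> int:
    """Total overlap between two disjoint, sorted interval sets."""
    if not a_starts.size or not b_starts.size:
        return 0
    pre = np.concatenate(([0], np.cumsum(b_ends - b_starts)))
    j0 = np.searchsorted(b_ends, a_starts, side="right")
    j1 = np.searchsorted(b_starts, a_ends, side="left")
    full = pre[j1] - pre[j0]
    has = j0 < j1
    left = np.zeros_like(full)
    right = np.zeros_like(full)
    left[has] = np.maximum(0, a_starts[has] - b_starts[j0[has]])
    right[has] = np.maximum(0, b_ends[j1[has] - 1] - a_ends[has])
    return int(np.sum(full - left - right))


def _merge_runs(starts: np.ndarray, ends: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Union of runs given sorted starts (runs may overlap)."""
    if starts.size <= 1:
        return starts, ends
    cummax = np.maximum.accumulate(ends)
    new = np.concatenate(([True], starts[1:] > cummax[:-1]))
    idx = np.where(new)[0]
    return starts[idx], np.concatenate((cummax[idx[1:] - 1], [cummax[-1]]))


class PlacementNull:
    """Exact placement null for one reference set within one domain.

    Precomputes merged per-chromosome reference and domain-segment arrays so
    that each query costs O(|reference| + |segments|) vectorised work.
    """

    def __init__(
        self,
        reference: Sequence[GenomicInterval],
        domain: Sequence[GenomicInterval],
    ) -> None:
        if not reference:
            raise CrmcatError("empty reference set")
        if not domain:
            raise CrmcatError("empty domain")
        self.refs = _as_arrays(reference)
        self.segments = _as_arrays(domain)

    def distance(self, query: GenomicInterval) -> float:
        """Gap distance from the query to the nearest reference interval."""
        if query.chrom not in self.refs:
            return math.inf
        starts, ends = self.refs[query.chrom]
        i = int(np.searchsorted(starts, query.end, side="left")) - 1
        best = math.inf
        if i >= 0:
            if ends[i] > query.start:
                return 0.0
            best = query.start - int(ends[i]) + 1
        if i + 1 < starts.size:
            best = min(best, int(starts[i + 1]) - query.end + 1)
        return float(best)

    def total_placements(self, qlen: int) -> int:
        total = 0
        for starts, ends in self.segments.values():
            total += int(np.sum(np.maximum(0, (ends - starts) - qlen + 1)))
        return total

    def close_placements(self, qlen: int, dist: float) -> int:
        """Placements of a qlen interval at gap distance <= dist of a ref."""
        if math.isinf(dist):
            return self.total_placements(qlen)
        d = int(dist)
        count = 0
        for chrom, (ref_s, ref_e) in self.refs.items():
            if chrom not in self.segments:
                continue
            seg_s, seg_e = self.segments[chrom]
            ok = (seg_e - seg_s) >= qlen
            if not np.any(ok):
                continue
            valid_s = seg_s[ok]
            valid_e = seg_e[ok] - qlen + 1  # exclusive end of valid starts
            near_s, near_e = _merge_runs(ref_s - d - qlen + 1, ref_e + d)
            count += _intersection_length(near_s, near_e, valid_s, valid_e)
        return count

    def pvalue(self, query: GenomicInterval) -> float:
        total = self.total_placements(query.length)
        if total == 0:
            raise NoPlacementError(
                f"query of length {query.length} fits in no domain segment"
            )
        d = self.distance(query)
        count = self.close_placements(query.length, d)
        p = count / total
        return min(1.0, p if p > 0 else 1.0 / total)


def interval_overlap_pvalue(
    query: GenomicInterval,
    reference: Sequence[GenomicInterval],
    domain: Sequence[GenomicInterval],
) -> float:
    """P-value of the query's proximity to the reference set.

    p = (#placements of a same-length interval inside the domain whose gap
    distance to the nearest reference interval is <= the observed distance) /
    (#valid placements).  Exact by construction; p in (0, 1].
    """
    return PlacementNull(reference, domain).pvalue(query)


def significant_overlap_fraction(
    query_sites: Sequence[GenomicInterval],
    reference_sites: Sequence[GenomicInterval],
    domain: Sequence[GenomicInterval],
    alpha: float = 0.05,
) -> float:
    """Percentage of query sites with placement-null p-value <= alpha."""
    if not query_sites or not reference_sites:
        raise CrmcatError("both site lists must be non-empty")
    null = PlacementNull(reference_sites, domain)
    n_sig = 0
    n_eval = 0
    for q in query_sites:
        try:
            p = null.pvalue(q)
        except NoPlacementError:
            warnings.warn(f"skipping unplaceable query {q}", stacklevel=2)
            continue
        n_eval += 1
        if p <= alpha:
            n_sig += 1
    if n_eval == 0:
        raise CrmcatError("no query site could be evaluated")
    return 100.0 * n_sig / n_eval


@dataclass
class OverlapMatrix:
    """Asymmetric matrix of significant-overlap percentages (query x ref)."""

    tfs: List[str]
    values: np.ndarray  # NaN on the diagonal
    alpha: float

    def percentage(self, query_tf: str, reference_tf: str) -> float:
        return float(
            self.values[self.tfs.index(query_tf), self.tfs.index(reference_tf)]
        )


def default_domain(
    sites: Sequence[GenomicInterval], pad: int = 10_000
) -> List[GenomicInterval]:
    """Union of the catalogue padded by ``pad`` bp: the analysis domain.

    A whole-genome null would make every overlap look significant; padding the
    occupied space keeps the null local while still allowing non-trivial
    placements.
    """
    padded = [
        GenomicInterval(iv.chrom, max(0, iv.start - pad), iv.end + pad)
        for iv in sites
    ]
    return merge_intervals(padded)


def pairwise_matrix(
    sites_by_tf: Dict[str, Sequence[NonRedundantSite]],
    domain: Optional[Sequence[GenomicInterval]] = None,
    alpha: float = 0.05,
    domain_pad: int = 10_000,
) -> OverlapMatrix:
    """Directed significant-overlap percentages for every ordered TF pair."""
    usable = {tf: sites for tf, sites in sites_by_tf.items() if sites}
    for tf in set(sites_by_tf) - set(usable):
        warnings.warn(f"TF {tf} has no sites and is excluded", stacklevel=2)
    tfs = sorted(usable)
    if len(tfs) < 2:
        raise CrmcatError("need at least two TFs with sites")
    intervals = {tf: [s.interval for s in usable[tf]] for tf in tfs}
    if domain is None:
        domain = default_domain(
            [iv for ivs in intervals.values() for iv in ivs], pad=domain_pad
        )
    values = np.full((len(tfs), len(tfs)), np.nan)
    for j, ref_tf in enumerate(tfs):
        null = PlacementNull(intervals[ref_tf], domain)
        for i, query_tf in enumerate(tfs):
            if i == j:
                continue
            n_sig = 0
            n_eval = 0
            for q in intervals[query_tf]:
                try:
                    p = null.pvalue(q)
                except NoPlacementError:
                    continue
                n_eval += 1
                if p <= alpha:
                    n_sig += 1
            values[i, j] = 100.0 * n_sig / n_eval if n_eval else np.nan
    return OverlapMatrix(tfs=tfs, values=values, alpha=alpha)


@dataclass(frozen=True)
class SpecificityCall:
    """A specifically co-localized partner of a query TF."""

    query: str
    partner: str
    level: str  # "moderate" or "strong"
    percentage: float


def specificity_outliers(matrix: OverlapMatrix) -> List[SpecificityCall]:
    """IQR-fence outliers per query row of the overlap matrix.

    A partner is moderately specific when its percentage strictly exceeds
    Q3 + 1.5*IQR of the query's row, strongly specific beyond Q3 + 3*IQR
    (strong subsumes moderate).  Quartiles use linear interpolation.  Rows
    with fewer than 4 finite entries yield no calls.
    """
    calls: List[SpecificityCall] = []
    for i, query_tf in enumerate(matrix.tfs):
        row = np.delete(matrix.values[i], i)
        partners = [tf for k, tf in enumerate(matrix.tfs) if k != i]
        finite = np.isfinite(row)
        if finite.sum() < 4:
            warnings.warn(
                f"row for {query_tf} has fewer than 4 entries; no calls",
                stacklevel=2,
            )
            continue
        vals = row[finite]
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        iqr = q3 - q1
        moderate_fence = q3 + 1.5 * iqr
        strong_fence = q3 + 3.0 * iqr
        for partner, value in zip(
            [p for p, f in zip(partners, finite) if f], vals
        ):
            if value > moderate_fence:
                level = "strong" if value > strong_fence else "moderate"
                calls.append(
                    SpecificityCall(
                        query=query_tf,
                        partner=partner,
                        level=level,
                        percentage=float(value),
                    )
                )
    return calls


@dataclass
class CoNetwork:
    """Undirected specificity network with its Louvain partition."""

    graph: nx.Graph
    communities: Dict[str, int]
    resolution: float
    seed: int


def build_and_partition_network(
    calls: Sequence[SpecificityCall],
    matrix: OverlapMatrix,
    resolution: float = 0.51,
    seed: int = 0,
) -> CoNetwork:
    """Collapse directed calls into a weighted graph and partition it.

    Edges carry weight 2 (strong) or 1 (moderate); when both directions call,
    the stronger level wins.  The edge colour value is the larger of the two
    directed percentages.  Communities come from weighted Louvain modularity
    maximisation at the given resolution with a fixed seed.
    """
    if not calls:
        raise CrmcatError("no specificity calls; network undefined")
    graph = nx.Graph()
    for call in calls:
        a, b = call.query, call.partner
        weight = 2 if call.level == "strong" else 1
        colour = max(
            matrix.percentage(a, b),
            matrix.percentage(b, a),
        )
        if graph.has_edge(a, b):
            prev = graph[a][b]
            prev["weight"] = max(prev["weight"], weight)
            prev["level"] = "strong" if prev["weight"] == 2 else "moderate"
            prev["colour"] = max(prev["colour"], colour)
        else:
            graph.add_edge(
                a,
                b,
                weight=weight,
                level=call.level,
                colour=colour,
            )
    partition = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=int(seed)
    )
    communities = {
        node: cid for cid, nodes in enumerate(partition) for node in nodes
    }
    nx.set_node_attributes(graph, communities, "community")
    nx.set_node_attributes(graph, dict(graph.degree()), "n_partners")
    return CoNetwork(
        graph=graph, communities=communities, resolution=resolution, seed=int(seed)
    )
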