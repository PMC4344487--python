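"""TF enrichment of user regions against the catalogue (annotation tool).

Given a set of query regions (e.g. gained or lost variant enhancer loci), each
catalogue region is classified as *hit* when it overlaps at least one query
region — either by >= 1 bp (default) or by placement-null significance.  For
each TF the over-representation of its regions among the hits is scored with
an upper-tail hypergeometric test:

    N = catalogue regions, K = regions containing the TF,
    n = hit regions,       k = hit regions containing the TF,
    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

with Benjamini-Hochberg q-values across the TF panel and fold enrichment
(k/n) / (K/N).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .catalogue import CatalogueRegion
from .colocalization import PlacementNull, default_domain
from .core import CrmcatError, GenomicInterval, NoPlacementError

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "tf_enrichment",
    "gained_lost_report",
    "coverage_percentage",
]


@dataclass(frozen=True)
class EnrichmentResult:
    tf: str
    N: int
    K: int
    n: int
    k: int
    fold: float
    p_value: float
    q_value: float


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); log-space stable."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise CrmcatError(
            f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    if p > 1e-280:
        return p
    # extreme tail: sum the pmf in log space; terms decay monotonically
    # beyond the mode so the full range is cheap and exact to fp precision
    ks = np.arange(k, min(K, n) + 1)
    logp = logsumexp(stats.hypergeom.logpmf(ks, N, K, n))
    return max(float(np.exp(logp)), 5e-324)


def _hit_flags(
    catalogue: Sequence[CatalogueRegion],
    query_regions: Sequence[GenomicInterval],
    mode: str,
    alpha: float,
    domain: Optional[Sequence[GenomicInterval]] = None,
) -> np.ndarray:
    if mode == "bp1":
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for q in query_regions:
            by_chrom.setdefault(q.chrom, []).append((q.start, q.end))
        arrays = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            arrays[chrom] = (
                np.array([p[0] for p in pairs]),
                np.maximum.accumulate(np.array([p[1] for p in pairs])),
            )
        flags = np.zeros(len(catalogue), dtype=bool)
        for i, r in enumerate(catalogue):
            if r.interval.chrom not in arrays:
                continue
            starts, cummax_ends = arrays[r.interval.chrom]
            j = int(np.searchsorted(starts, r.interval.end, side="left")) - 1
            flags[i] = j >= 0 and cummax_ends[j] > r.interval.start
        return flags
    if mode == "placement_null":
        if domain is None:
            domain = default_domain([r.interval for r in catalogue])
        null = PlacementNull(list(query_regions), domain)
        flags = np.zeros(len(catalogue), dtype=bool)
        for i, r in enumerate(catalogue):
            try:
                flags[i] = null.pvalue(r.interval) <= alpha
            except NoPlacementError:
                flags[i] = False
        return flags
    raise CrmcatError(f"unknown overlap mode {mode!r}")


def tf_enrichment(
    catalogue: Sequence[CatalogueRegion],
    query_regions: Sequence[GenomicInterval],
    mode: str = "bp1",
    alpha: float = 0.05,
    correction: str = "bh",
    domain: Optional[Sequence[GenomicInterval]] = None,
) -> List[EnrichmentResult]:
    """Per-TF hypergeometric enrichment among catalogue regions hit by queries.

    Results are sorted by p-value, ties broken by descending fold then TF
    name.  ``correction`` is one of bh | bonferroni | none.
    """
    if not catalogue or not query_regions:
        raise CrmcatError("catalogue and query regions must be non-empty")
    flags = _hit_flags(catalogue, query_regions, mode, alpha, domain)
    N = len(catalogue)
    n = int(flags.sum())
    if n == 0:
        warnings.warn("no catalogue region is hit by the query set", stacklevel=2)
    tfs = sorted({tf for r in catalogue for tf in r.tf_set})
    rows = []
    for tf in tfs:
        member = np.array([tf in r.tf_set for r in catalogue])
        K = int(member.sum())
        k = int((member & flags).sum())
        p = hypergeom_upper_tail(k, K, n, N)
        fold = (k / n) / (K / N) if n and K else math.nan
        rows.append((tf, N, K, n, k, fold, p))
    pvals = np.array([r[6] for r in rows])
    if correction == "bh":
        qvals = multipletests(pvals, method="fdr_bh")[1]
    elif correction == "bonferroni":
        qvals = np.minimum(pvals * len(pvals), 1.0)
    elif correction == "none":
        qvals = pvals.copy()
    else:
        raise CrmcatError(f"unknown correction {correction!r}")
    results = [
        EnrichmentResult(tf, N, K, n, k, fold, p, float(q))
        for (tf, N, K, n, k, fold, p), q in zip(rows, qvals)
    ]
    results.sort(
        key=lambda r: (r.p_value, -(r.fold if math.isfinite(r.fold) else -1.0), r.tf)
    )
    return results


def coverage_percentage(
    catalogue: Sequence[CatalogueRegion], query_regions: Sequence[GenomicInterval]
) -> float:
    """Percentage of query regions overlapping >= 1 catalogue region."""
    from .localization import resource_recovery

    return resource_recovery(catalogue, list(query_regions), crm_only=False)


def gained_lost_report(
    catalogue: Sequence[CatalogueRegion],
    gained: Sequence[GenomicInterval],
    lost: Sequence[GenomicInterval],
    mode: str = "bp1",
    alpha: float = 0.05,
    correction: str = "bh",
) -> Tuple[List[EnrichmentResult], List[EnrichmentResult], Dict[str, float]]:
    """Independent enrichment tables for gained and lost region sets.

    Also reports, per set, the percentage of query regions containing at
    least one catalogue region (coverage).
    """
    if not gained or not lost:
        raise CrmcatError("both gained and lost sets must be non-empty")
    gained_results = tf_enrichment(catalogue, gained, mode, alpha, correction)
    lost_results = tf_enrichment(catalogue, lost, mode, alpha, correction)
    coverage = {
        "gained": coverage_percentage(catalogue, gained),
        "lost": coverage_percentage(catalogue, lost),
    }
    return gained_results, lost_results, coverage
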