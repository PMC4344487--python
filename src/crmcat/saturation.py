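"""CRM saturation analysis by random TF subsampling.

Does CRM discovery level off as TFs are added?  For increasing panel sizes,
random TF subsets are drawn (uniformly, without replacement), the CRM count
(multi-TF regions only) is recomputed from each subset's non-redundant sites,
and the per-size medians are smoothed with a lowess line.  A curve that keeps
rising indicates the regulatory space is not saturated by the assayed TFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set

import numpy as np
import statsmodels.api as sm

from .catalogue import NonRedundantSite, build_crms
from .core import CrmcatError

__all__ = ["SaturationPoint", "SaturationCurve", "crm_count_for_subset", "saturation_curve"]


@dataclass
class SaturationPoint:
    n_tfs: int
    replicate_counts: List[int]
    median: float
    q1: float
    q3: float
    smoothed_median: float = float("nan")


@dataclass
class SaturationCurve:
    points: List[SaturationPoint]
    replicates: int
    seed: int
    lowess_fraction: float

    def medians(self) -> np.ndarray:
        return np.array([p.median for p in self.points])


def crm_count_for_subset(
    sites_by_tf: Dict[str, Sequence[NonRedundantSite]],
    tf_subset: Set[str],
    include_singletons: bool = False,
) -> int:
    """Number of CRMs obtained from the given TFs' sites only."""
    if not tf_subset:
        raise CrmcatError("tf_subset must be non-empty")
    unknown = set(tf_subset) - set(sites_by_tf)
    if unknown:
        raise CrmcatError(f"unknown TFs: {sorted(unknown)}")
    sites = [s for tf in sorted(tf_subset) for s in sites_by_tf[tf]]
    regions = build_crms(sites)
    if include_singletons:
        return len(regions)
    return sum(1 for r in regions if r.kind == "crm")


def saturation_curve(
    sites_by_tf: Dict[str, Sequence[NonRedundantSite]],
    sizes: Sequence[int],
    replicates: int = 100,
    seed: int = 0,
    lowess_fraction: float = 0.3,
    include_singletons: bool = False,
) -> SaturationCurve:
    """CRM counts across random TF panels of increasing size.

    One random substream per (size, replicate), derived from the master seed,
    so adding sizes or replicates never reshuffles existing draws.  The
    smoothed medians come from lowess (tricube weights, 2 robustness
    iterations) over the (size, median) pairs; with fewer than 3 sizes the
    medians are returned unsmoothed.
    """
    tfs = sorted(sites_by_tf)
    if replicates < 1:
        raise CrmcatError("replicates must be >= 1")
    for size in sizes:
        if not (1 <= size <= len(tfs)):
            raise CrmcatError(f"size {size} outside [1, {len(tfs)}]")
    points: List[SaturationPoint] = []
    for size in sorted(sizes):
        counts = []
        for rep in range(replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(size, rep))
            )
            subset = set(rng.choice(tfs, size=size, replace=False).tolist())
            counts.append(
                crm_count_for_subset(sites_by_tf, subset, include_singletons)
            )
        arr = np.asarray(counts, dtype=float)
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
        points.append(
            SaturationPoint(
                n_tfs=size,
                replicate_counts=counts,
                median=float(med),
                q1=float(q1),
                q3=float(q3),
            )
        )
    xs = np.array([p.n_tfs for p in points], dtype=float)
    ys = np.array([p.median for p in points])
    if xs.size >= 3:
        smoothed = sm.nonparametric.lowess(
            ys, xs, frac=lowess_fraction, it=2, return_sorted=False
        )
    else:
        smoothed = ys
    for p, s in zip(points, smoothed):
        p.smoothed_median = float(s)
    return SaturationCurve(
        points=points,
        replicates=replicates,
        seed=seed,
        lowess_fraction=lowess_fraction,
    )
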