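"""Dataset quality metrics: strand cross-correlation, NSC/RSC, FRiP, score.

The strand cross-correlation profile measures, for each shift d, the Pearson
correlation between per-base 5' read counts on the forward strand and on the
reverse strand shifted left by d.  Well-enriched libraries show a maximum at
the fragment length; all real libraries additionally show a "phantom" maximum
at the read length.  Two ratios summarise the profile:

* NSC (normalised strand coefficient) = cc(fragment) / min(cc)
* RSC (relative strand coefficient)
      = (cc(fragment) - min(cc)) / (cc(read length) - min(cc))

A dataset receives one basal point per attained threshold (NSC >= 1.05 and
1.10; RSC >= 0.8 and 1.0) plus one point if FRiP (fraction of reads in peaks)
is >= 1%, giving a 0-5 score; datasets scoring <= 1, or with fewer than 100
peaks, are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    DatasetLabel,
    InsufficientReadsError,
    Peak,
    ReadPositions,
    UndefinedMetricError,
    merge_intervals,
)

__all__ = [
    "CCProfile",
    "QCReport",
    "cross_correlation_profile",
    "cc_metrics",
    "frip",
    "quality_score",
    "retention_decision",
    "evaluate_dataset",
    "NSC_THRESHOLDS",
    "RSC_THRESHOLDS",
    "FRIP_THRESHOLD",
]

NSC_THRESHOLDS = (1.05, 1.10)
RSC_THRESHOLDS = (0.8, 1.0)
FRIP_THRESHOLD = 0.01
MIN_PEAKS = 100
PHANTOM_EXCLUSION_HALF_WIDTH = 10


@dataclass
class CCProfile:
    """Strand cross-correlation as a function of shift."""

    shifts: np.ndarray
    values: np.ndarray
    read_length: int
    fragment_peak_shift: int
    cc_fragment: float
    cc_read_length: float
    cc_min: float


@dataclass
class QCReport:
    dataset: DatasetLabel
    nsc: float
    rsc: float
    frip: float
    n_peaks: int
    score: int
    retained: bool


def _strand_moments(positions: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Prefix count and sum of squared per-base multiplicities.

    Evaluated lazily at any position bound via searchsorted on the unique
    positions.
    """
    uniq, counts = np.unique(positions, return_counts=True)
    csum = np.concatenate(([0], np.cumsum(counts)))
    csq = np.concatenate(([0], np.cumsum(counts.astype(np.int64) ** 2)))
    return uniq, np.vstack([csum, csq])


def _chrom_profile(
    plus: np.ndarray, minus: np.ndarray, length: int, shifts: np.ndarray
) -> np.ndarray:
    """Pearson correlation of stranded 5' count vectors for each shift.

    At shift d the forward counts over [0, length-d) are correlated with the
    reverse counts over [d, length).  Counts (not indicators) are used, so
    duplicated positions contribute their multiplicity.
    """
    max_shift = int(shifts[-1])
    # coincidence counts m(d) = sum_p c_plus(p) * c_minus(p + d)
    m = np.zeros(max_shift + 1, dtype=np.int64)
    lo = np.searchsorted(minus, plus)  # first minus >= p
    hi = np.searchsorted(minus, plus + max_shift, side="right")
    for p, a, b in zip(plus, lo, hi):
        if a < b:
            d = minus[a:b] - p
            np.add.at(m, d, 1)

    uniq_p, mom_p = _strand_moments(plus)
    uniq_m, mom_m = _strand_moments(minus)

    values = np.full(shifts.size, np.nan)
    for i, d in enumerate(shifts):
        n = length - d
        if n < 2:
            continue
        # forward strand restricted to [0, n)
        jp = int(np.searchsorted(uniq_p, n, side="left"))
        sx, sxx = mom_p[0, jp], mom_p[1, jp]
        # reverse strand restricted to [d, length)
        jm = int(np.searchsorted(uniq_m, d, side="left"))
        sy = mom_m[0, -1] - mom_m[0, jm]
        syy = mom_m[1, -1] - mom_m[1, jm]
        sxy = m[d]
        var_x = n * sxx - sx * sx
        var_y = n * syy - sy * sy
        if var_x <= 0 or var_y <= 0:
            continue
        values[i] = (n * sxy - sx * sy) / math.sqrt(float(var_x) * float(var_y))
    return values


def cross_correlation_profile(
    reads: ReadPositions,
    max_shift: int,
    exclusion_half_width: int = PHANTOM_EXCLUSION_HALF_WIDTH,
) -> CCProfile:
    """Strand cross-correlation profile over shifts 0..max_shift.

    Per-chromosome profiles are combined by chromosome-length weighting.  The
    fragment peak is the argmax outside the phantom-peak exclusion zone
    (read_length +/- ``exclusion_half_width``).
    """
    rlen = reads.read_length
    if max_shift < rlen + 50:
        raise ValueError("max_shift must be at least read_length + 50")
    shifts = np.arange(max_shift + 1)
    chroms = [
        c
        for c in reads.chroms
        if reads.plus.get(c) is not None
        and reads.minus.get(c) is not None
        and reads.plus[c].size
        and reads.minus[c].size
    ]
    if not chroms:
        raise InsufficientReadsError("need reads on both strands of a chromosome")

    acc = np.zeros(shifts.size)
    wsum = np.zeros(shifts.size)
    for chrom in chroms:
        length = reads.effective_length(chrom)
        vals = _chrom_profile(reads.plus[chrom], reads.minus[chrom], length, shifts)
        ok = ~np.isnan(vals)
        acc[ok] += length * vals[ok]
        wsum[ok] += length
    values = np.where(wsum > 0, acc / np.where(wsum > 0, wsum, 1.0), np.nan)
    if np.all(np.isnan(values)):
        raise InsufficientReadsError("cross-correlation undefined at every shift")

    exclude = np.abs(shifts - rlen) <= exclusion_half_width
    candidates = np.where(~exclude & ~np.isnan(values))[0]
    if candidates.size == 0:
        raise InsufficientReadsError("no shift outside the phantom exclusion zone")
    frag_idx = int(candidates[np.argmax(values[candidates])])
    cc_read_length = float(values[rlen]) if not np.isnan(values[rlen]) else float("nan")
    return CCProfile(
        shifts=shifts,
        values=values,
        read_length=rlen,
        fragment_peak_shift=int(shifts[frag_idx]),
        cc_fragment=float(values[frag_idx]),
        cc_read_length=cc_read_length,
        cc_min=float(np.nanmin(values)),
    )


def cc_metrics(profile: CCProfile) -> Tuple[float, float]:
    """(NSC, RSC) from a cross-correlation profile.

    NSC = cc_fragment / cc_min; RSC = (cc_fragment - cc_min) /
    (cc_read_length - cc_min).  Raises when the RSC denominator vanishes
    (flat profile at the read length); callers report that as failed QC.
    """
    if profile.cc_read_length == profile.cc_min or math.isnan(profile.cc_read_length):
        raise UndefinedMetricError("RSC undefined: cc(read_length) equals cc_min")
    nsc = profile.cc_fragment / profile.cc_min if profile.cc_min != 0 else float("inf")
    rsc = (profile.cc_fragment - profile.cc_min) / (
        profile.cc_read_length - profile.cc_min
    )
    return nsc, rsc


def frip(reads: ReadPositions, peaks: Sequence[Peak]) -> float:
    """Fraction of 5' read positions (both strands) inside the peak union."""
    total = reads.n_reads()
    if total == 0:
        raise UndefinedMetricError("FRiP undefined for zero reads")
    if not peaks:
        return 0.0
    union = merge_intervals([p.interval for p in peaks])
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in union:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    inside = 0
    for chrom, ivs in by_chrom.items():
        starts = np.array([a for a, _ in ivs])
        ends = np.array([b for _, b in ivs])
        for side in (reads.plus, reads.minus):
            pos = side.get(chrom)
            if pos is None or not pos.size:
                continue
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = idx >= 0
            inside += int(np.count_nonzero(pos[ok] < ends[idx[ok]]))
    return inside / total


def quality_score(nsc: float, rsc: float, frip_value: float) -> int:
    """0-5 score: attained NSC/RSC thresholds plus the FRiP bonus point."""
    score = sum(1 for t in NSC_THRESHOLDS if nsc >= t)
    score += sum(1 for t in RSC_THRESHOLDS if rsc >= t)
    if frip_value >= FRIP_THRESHOLD:
        score += 1
    return score


def retention_decision(score: int, n_peaks: int) -> bool:
    """Keep a dataset iff score >= 2 and it has at least 100 peaks."""
    return score >= 2 and n_peaks >= MIN_PEAKS


def evaluate_dataset(
    dataset: DatasetLabel,
    reads: ReadPositions,
    peaks: Sequence[Peak],
    max_shift: Optional[int] = None,
) -> QCReport:
    """Full QC gate for one dataset; RSC failures score 0 RSC points."""
    if max_shift is None:
        max_shift = max(500, reads.read_length + 50)
    profile = cross_correlation_profile(reads, max_shift)
    try:
        nsc, rsc = cc_metrics(profile)
    except UndefinedMetricError:
        nsc = profile.cc_fragment / profile.cc_min if profile.cc_min else float("inf")
        rsc = float("nan")
    frip_value = frip(reads, peaks)
    rsc_for_score = -math.inf if math.isnan(rsc) else rsc
    score = quality_score(nsc, rsc_for_score, frip_value)
    return QCReport(
        dataset=dataset,
        nsc=nsc,
        rsc=rsc,
        frip=frip_value,
        n_peaks=len(peaks),
        score=score,
        retained=retention_decision(score, len(peaks)),
    )
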