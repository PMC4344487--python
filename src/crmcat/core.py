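"""Core domain types for the regulatory-catalogue pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)`` throughout the
package (BED convention).  A *dataset* is one ChIP-seq experiment for one
transcription factor (TF) in one biological condition, labelled with the dotted
string ``SERIES.TF.CONDITION``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CrmcatError",
    "MalformedLabelError",
    "InvalidRecordError",
    "InvalidTrackError",
    "SimulationError",
    "PlacementError",
    "InsufficientReadsError",
    "UndefinedMetricError",
    "NoPlacementError",
    "DatasetLabel",
    "GenomicInterval",
    "Peak",
    "ReadPositions",
    "ScoreTrack",
    "Gene",
    "AnnotationModel",
]


class CrmcatError(Exception):
    """Base class for all package errors."""


class MalformedLabelError(CrmcatError):
    """Dataset label does not have the SERIES.TF.CONDITION form."""


class InvalidRecordError(CrmcatError):
    """A file record violates an invariant (coordinates, summit, ...)."""


class InvalidTrackError(CrmcatError):
    """A score track has overlapping or unsorted runs."""


class SimulationError(CrmcatError):
    """Invalid simulation configuration or impossible request."""


class PlacementError(SimulationError):
    """Could not place the requested non-overlapping sites."""


class InsufficientReadsError(CrmcatError):
    """A strand is empty genome-wide; cross-correlation is undefined."""


class UndefinedMetricError(CrmcatError):
    """A QC metric is undefined for the given inputs (e.g. zero reads)."""


class NoPlacementError(CrmcatError):
    """The query interval fits in no domain segment."""


@dataclass(frozen=True)
class DatasetLabel:
    """Identifier of one ChIP-seq dataset: series, TF and biological condition.

    The string form is the dot-concatenation of the three parts, e.g.
    ``GSE41561.ESR1.MCF-7``.  The condition may itself contain dots; parsing
    splits on the first two dots only.
    """

    series_id: str
    tf_name: str
    condition: str

    def __post_init__(self) -> None:
        for part in (self.series_id, self.tf_name, self.condition):
            if not part:
                raise MalformedLabelError(
                    f"empty component in dataset label {self!r}"
                )

    def __str__(self) -> str:
        return f"{self.series_id}.{self.tf_name}.{self.condition}"

    @classmethod
    def parse(cls, text: str) -> "DatasetLabel":
        parts = text.split(".", 2)
        if len(parts) != 3 or not all(parts):
            raise MalformedLabelError(
                f"dataset label {text!r} is not of the form SERIES.TF.CONDITION"
            )
        return cls(series_id=parts[0], tf_name=parts[1], condition=parts[2])


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidRecordError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called ChIP-seq peak with its summit (base of maximal signal)."""

    interval: GenomicInterval
    summit: int
    dataset: DatasetLabel
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise InvalidRecordError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:[{self.interval.start},{self.interval.end})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class ReadPositions:
    """Stranded 5' read positions per chromosome.

    Parameters
    ----------
    plus, minus
        Mapping chromosome -> sorted array of 5' positions of reads on the
        forward / reverse strand.
    read_length
        Sequenced read length in bp.
    chrom_lengths
        Optional chromosome sizes.  When absent, the effective length of a
        chromosome defaults to ``max(position) + read_length``.
    """

    def __init__(
        self,
        plus: Dict[str, Sequence[int]],
        minus: Dict[str, Sequence[int]],
        read_length: int,
        chrom_lengths: Optional[Dict[str, int]] = None,
    ) -> None:
        if read_length < 1:
            raise InvalidRecordError("read_length must be >= 1")
        self.read_length = int(read_length)
        self.plus = {c: self._check(c, p) for c, p in plus.items()}
        self.minus = {c: self._check(c, p) for c, p in minus.items()}
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None

    @staticmethod
    def _check(chrom: str, positions: Sequence[int]) -> np.ndarray:
        arr = np.asarray(positions, dtype=np.int64)
        if arr.size and arr.min() < 0:
            raise InvalidRecordError(f"negative read position on {chrom}")
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            arr = np.sort(arr)
        return arr

    @property
    def chroms(self) -> List[str]:
        return sorted(set(self.plus) | set(self.minus))

    def n_reads(self) -> int:
        return int(
            sum(a.size for a in self.plus.values())
            + sum(a.size for a in self.minus.values())
        )

    def effective_length(self, chrom: str) -> int:
        if self.chrom_lengths and chrom in self.chrom_lengths:
            return self.chrom_lengths[chrom]
        hi = 0
        for side in (self.plus, self.minus):
            if chrom in side and side[chrom].size:
                hi = max(hi, int(side[chrom][-1]))
        return hi + self.read_length


class ScoreTrack:
    """Piecewise-constant per-base score track (bedGraph semantics).

    Runs are half-open, non-overlapping and sorted per chromosome; bases not
    covered by any run are *absent* (NaN in window queries).
    """

    def __init__(self, runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise InvalidTrackError(f"empty or inverted run on {chrom}")
            if starts.size > 1 and np.any(starts[1:] < ends[:-1]):
                raise InvalidTrackError(f"overlapping runs on {chrom}")
            self._runs[chrom] = (starts, ends, values)

    @classmethod
    def from_records(
        cls, records: Sequence[Tuple[str, int, int, float]]
    ) -> "ScoreTrack":
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        runs = {}
        for chrom, recs in by_chrom.items():
            starts = np.array([r[0] for r in recs])
            ends = np.array([r[1] for r in recs])
            values = np.array([r[2] for r in recs])
            runs[chrom] = (starts, ends, values)
        return cls(runs)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._runs)

    def records(self) -> List[Tuple[str, int, int, float]]:
        out = []
        for chrom in self.chroms:
            starts, ends, values = self._runs[chrom]
            out.extend(
                (chrom, int(s), int(e), float(v))
                for s, e, v in zip(starts, ends, values)
            )
        return out

    def value_at(self, chrom: str, pos: int) -> float:
        """Score at one base, or NaN when the base is absent from the track."""
        if chrom not in self._runs:
            return float("nan")
        starts, ends, values = self._runs[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return float("nan")

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over ``[start, end)``; absent bases are NaN."""
        out = np.full(end - start, np.nan)
        if chrom not in self._runs or end <= start:
            return out
        starts, ends, values = self._runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(int(starts[i]), start)
            b = min(int(ends[i]), end)
            if a < b:
                out[a - start : b - start] = values[i]
        return out


@dataclass(frozen=True)
class Gene:
    """Gene model with transcript, CDS and exon-block structure (BED12-like)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: Tuple[int, ...]
    exon_ends: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidRecordError(f"bad strand {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise InvalidRecordError(f"bad transcript bounds for {self.gene_id}")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise InvalidRecordError(f"bad exon blocks for {self.gene_id}")
        prev_end = self.tx_start - 1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise InvalidRecordError(f"exon outside transcript in {self.gene_id}")
            if s < prev_end:
                raise InvalidRecordError(f"overlapping exons in {self.gene_id}")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site: tx_start on +, tx_end-1 on - strand."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass
class AnnotationModel:
    """A set of gene models used for genomic-category assignment."""

    genes: List[Gene] = field(default_factory=list)

    def tss_list(self) -> List[Tuple[str, int, str]]:
        return [(g.chrom, g.tss, g.strand) for g in self.genes]


def merge_intervals(
    intervals: Sequence[GenomicInterval],
) -> List[GenomicInterval]:
    """Union of intervals: connected components of the >=1 bp overlap relation.

    Book-ended intervals (end == next start) are NOT merged, consistent with
    half-open semantics where they share no base.
    """
    out: List[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out
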