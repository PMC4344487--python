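"""Readers and writers for the on-disk formats.

Dialects (all whitespace-delimited, no headers unless noted, track/comment
lines starting with ``track`` or ``#`` ignored, 0-based half-open):

* peaks      — BED4+: chrom, start, end, summit offset from start[, score]
* catalogue  — BED5+: chrom, start, end, comma-joined TF list, TF count
               [, n_sites]
* score track — bedGraph: chrom, start, end, value
* read positions — one file per strand: ``#read_length=N`` header
               (optionally ``#chrom_lengths=chr:len,...``), then chrom, 5' pos
* annotation — BED12
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .core import (
    AnnotationModel,
    DatasetLabel,
    Gene,
    GenomicInterval,
    InvalidRecordError,
    InvalidTrackError,
    Peak,
    ReadPositions,
    ScoreTrack,
)

Pathish = Union[str, "os.PathLike[str]"]


def parse_dataset_label(text: str) -> DatasetLabel:
    """Parse a dotted ``SERIES.TF.CONDITION`` label.

    The condition keeps any further dots (``S1.TF1.cond.a`` -> condition
    ``cond.a``).
    """
    return DatasetLabel.parse(text)


def _data_lines(path: Pathish) -> Iterable[Tuple[int, List[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line.split()


def _to_int(token: str, path: Pathish, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise InvalidRecordError(
            f"{path}:{lineno}: non-integer coordinate {token!r}"
        ) from None


def read_peaks(path: Pathish, dataset: DatasetLabel) -> List[Peak]:
    """Read a BED4+ peak file; column 4 is the summit offset from start."""
    peaks: List[Peak] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 4:
            raise InvalidRecordError(f"{path}:{lineno}: expected >= 4 columns")
        chrom = cols[0]
        start = _to_int(cols[1], path, lineno)
        end = _to_int(cols[2], path, lineno)
        offset = _to_int(cols[3], path, lineno)
        summit = start + offset
        if not (start <= summit < end):
            raise InvalidRecordError(
                f"{path}:{lineno}: summit {summit} outside [{start},{end})"
            )
        score = float(cols[4]) if len(cols) > 4 else None
        peaks.append(
            Peak(GenomicInterval(chrom, start, end), summit, dataset, score)
        )
    return peaks


def write_peaks(peaks: Sequence[Peak], path: Pathish) -> None:
    """Write peaks as BED4+ sorted by (chrom, start)."""
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    with open(path, "w") as fh:
        for p in rows:
            cols = [
                p.interval.chrom,
                str(p.interval.start),
                str(p.interval.end),
                str(p.summit - p.interval.start),
            ]
            if p.score is not None:
                cols.append(repr(float(p.score)))
            fh.write("\t".join(cols) + "\n")


def write_regions(regions: Sequence, path: Pathish) -> None:
    """Write catalogue regions (or peaks) as a BED file sorted by position.

    ``CatalogueRegion`` rows carry the comma-joined sorted TF list in the name
    column, the TF count in the score column and the member-site count in an
    extra sixth column.  Plain ``Peak`` inputs are delegated to
    :func:`write_peaks`.
    """
    if regions and isinstance(regions[0], Peak):
        write_peaks(regions, path)
        return
    rows = sorted(regions, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    with open(path, "w") as fh:
        for r in rows:
            tfs = ",".join(sorted(r.tf_set))
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{tfs}\t{len(r.tf_set)}\t{r.n_sites}\n"
            )


def read_regions(path: Pathish) -> List["CatalogueRegion"]:
    """Read a BED5+ catalogue file back into CatalogueRegion records."""
    from .catalogue import CatalogueRegion  # local import to avoid a cycle

    regions = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 5:
            raise InvalidRecordError(f"{path}:{lineno}: expected >= 5 columns")
        chrom = cols[0]
        start = _to_int(cols[1], path, lineno)
        end = _to_int(cols[2], path, lineno)
        tf_set = frozenset(cols[3].split(","))
        n_tfs = _to_int(cols[4], path, lineno)
        if n_tfs != len(tf_set):
            raise InvalidRecordError(
                f"{path}:{lineno}: TF count {n_tfs} != {len(tf_set)} listed TFs"
            )
        n_sites = _to_int(cols[5], path, lineno) if len(cols) > 5 else len(tf_set)
        regions.append(
            CatalogueRegion(
                interval=GenomicInterval(chrom, start, end),
                tf_set=tf_set,
                n_sites=n_sites,
            )
        )
    return regions


def read_score_track(path: Pathish) -> ScoreTrack:
    """Read a bedGraph file; overlapping runs are rejected."""
    records = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 4:
            raise InvalidRecordError(f"{path}:{lineno}: expected 4 columns")
        chrom = cols[0]
        start = _to_int(cols[1], path, lineno)
        end = _to_int(cols[2], path, lineno)
        try:
            value = float(cols[3])
        except ValueError:
            raise InvalidTrackError(f"{path}:{lineno}: bad value {cols[3]!r}") from None
        records.append((chrom, start, end, value))
    return ScoreTrack.from_records(records)


def write_score_track(track: ScoreTrack, path: Pathish) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


def write_read_positions(
    reads: ReadPositions, plus_path: Pathish, minus_path: Pathish
) -> None:
    for side, path in ((reads.plus, plus_path), (reads.minus, minus_path)):
        with open(path, "w") as fh:
            fh.write(f"#read_length={reads.read_length}\n")
            if reads.chrom_lengths:
                pairs = ",".join(
                    f"{c}:{l}" for c, l in sorted(reads.chrom_lengths.items())
                )
                fh.write(f"#chrom_lengths={pairs}\n")
            for chrom in sorted(side):
                for pos in side[chrom]:
                    fh.write(f"{chrom}\t{int(pos)}\n")


def read_read_positions(plus_path: Pathish, minus_path: Pathish) -> ReadPositions:
    def load(path: Pathish):
        read_length = None
        chrom_lengths: Optional[Dict[str, int]] = None
        positions: Dict[str, List[int]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line:
                    continue
                if line.startswith("#read_length="):
                    read_length = int(line.split("=", 1)[1])
                    continue
                if line.startswith("#chrom_lengths="):
                    chrom_lengths = {}
                    for pair in line.split("=", 1)[1].split(","):
                        chrom, length = pair.rsplit(":", 1)
                        chrom_lengths[chrom] = int(length)
                    continue
                if line.startswith("#"):
                    continue
                cols = line.split()
                if len(cols) < 2:
                    raise InvalidRecordError(f"{path}:{lineno}: expected 2 columns")
                positions.setdefault(cols[0], []).append(
                    _to_int(cols[1], path, lineno)
                )
        if read_length is None:
            raise InvalidRecordError(f"{path}: missing #read_length header")
        return read_length, chrom_lengths, positions

    rl_p, cl_p, plus = load(plus_path)
    rl_m, cl_m, minus = load(minus_path)
    if rl_p != rl_m:
        raise InvalidRecordError("read_length differs between strand files")
    return ReadPositions(plus, minus, rl_p, cl_p or cl_m)


def read_annotation_bed12(path: Pathish) -> AnnotationModel:
    """Read gene models from a BED12 file."""
    genes = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 12:
            raise InvalidRecordError(f"{path}:{lineno}: expected 12 columns")
        chrom = cols[0]
        tx_start = _to_int(cols[1], path, lineno)
        tx_end = _to_int(cols[2], path, lineno)
        name = cols[3]
        strand = cols[5]
        cds_start = _to_int(cols[6], path, lineno)
        cds_end = _to_int(cols[7], path, lineno)
        n_blocks = _to_int(cols[9], path, lineno)
        sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
        offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise InvalidRecordError(f"{path}:{lineno}: block count mismatch")
        exon_starts = tuple(tx_start + o for o in offsets)
        exon_ends = tuple(s + sz for s, sz in zip(exon_starts, sizes))
        genes.append(
            Gene(
                gene_id=name,
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=cds_start,
                cds_end=cds_end,
                exon_starts=exon_starts,
                exon_ends=exon_ends,
            )
        )
    return AnnotationModel(genes)


def write_annotation_bed12(annotation: AnnotationModel, path: Pathish) -> None:
    rows = sorted(annotation.genes, key=lambda g: (g.chrom, g.tx_start, g.tx_end))
    with open(path, "w") as fh:
        for g in rows:
            sizes = ",".join(
                str(e - s) for s, e in zip(g.exon_starts, g.exon_ends)
            )
            offsets = ",".join(str(s - g.tx_start) for s in g.exon_starts)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.tx_start),
                        str(g.tx_end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.cds_start),
                        str(g.cds_end),
                        "0",
                        str(len(g.exon_starts)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def read_intervals_bed(path: Pathish) -> List[GenomicInterval]:
    """Read plain BED3+ intervals (extra columns ignored)."""
    out = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 3:
            raise InvalidRecordError(f"{path}:{lineno}: expected >= 3 columns")
        out.append(
            GenomicInterval(
                cols[0], _to_int(cols[1], path, lineno), _to_int(cols[2], path, lineno)
            )
        )
    return out


def write_intervals_bed(intervals: Sequence[GenomicInterval], path: Pathish) -> None:
    rows = sorted(intervals)
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
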