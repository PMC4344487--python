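"""Synthetic ground-truth generator for the catalogue pipeline.

Emulates the statistical structure of a multi-study ChIP-seq compendium on a
small toy genome with *known truth*, so every downstream stage has a
parameter-recovery test:

* a gene annotation (for genomic-category and TSS analyses),
* planted regulatory sites: multi-TF modules whose TF membership follows a
  block (community) structure, plus singleton sites,
* per-dataset peak calls with summit jitter, width variation, missed sites
  and uniform false-positive peaks,
* stranded 5' read positions with a fixed fragment length, uniform background
  and a read-length "phantom" duplication artefact (present in real data and
  required for the RSC quality metric to behave as it does on real data),
* query region sets spiked with chosen TFs' sites (enrichment inputs).

Randomness is hierarchical: one global seed feeds fixed per-component
substreams (genome / sites / datasets / reads / queries), so e.g. changing the
number of datasets never perturbs gene or site placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .core import (
    AnnotationModel,
    DatasetLabel,
    Gene,
    GenomicInterval,
    Peak,
    PlacementError,
    ReadPositions,
    SimulationError,
)

__all__ = [
    "SimConfig",
    "TruthSite",
    "default_blocks",
    "simulate_genome_annotation",
    "plant_regulatory_sites",
    "simulate_peak_datasets",
    "simulate_reads",
    "simulate_query_regions",
]

# substream keys for the hierarchical seeding scheme
_KEY_GENOME, _KEY_SITES, _KEY_DATASETS, _KEY_READS, _KEY_QUERIES = range(5)


def default_blocks(n_tfs: int, block_size: int = 5) -> Dict[str, Tuple[str, ...]]:
    """Partition TF01..TFnn into consecutive blocks (B1, B2, ...)."""
    tfs = [f"TF{i:02d}" for i in range(1, n_tfs + 1)]
    blocks: Dict[str, Tuple[str, ...]] = {}
    for b, lo in enumerate(range(0, n_tfs, block_size), start=1):
        blocks[f"B{b}"] = tuple(tfs[lo : lo + block_size])
    return blocks


@dataclass
class SimConfig:
    """Study conditions for the synthetic compendium.

    Defaults describe a small but realistic desk-scale study: a 3 Mb genome,
    20 TFs organised in co-binding blocks of 5, 200 planted modules, peaks of
    ~300 bp (the scale of short ChIP-seq peaks containing summits), 3 datasets
    per TF with 85% per-dataset sensitivity, 15 bp summit jitter and 10 false
    peaks per dataset, and single-end 36 bp reads from 200 bp fragments with
    20% uniform background.
    """

    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_000_000}
    )
    n_tfs: int = 20
    community_blocks: Optional[Dict[str, Tuple[str, ...]]] = None
    n_modules: int = 200
    singleton_rate: float = 0.2
    mean_site_width: int = 300
    datasets_per_tf: int = 3
    summit_jitter_sd: float = 15.0
    peak_width_sd: float = 30.0
    sensitivity: float = 0.85
    noise_peaks_per_dataset: int = 10
    fragment_length: int = 200
    read_length: int = 36
    reads_per_site: int = 30
    background_read_fraction: float = 0.2
    # block co-binding structure
    within_block_prob: float = 0.8
    between_block_prob: float = 0.02
    # placement
    promoter_bias: float = 0.3
    promoter_bias_per_extra_tf: float = 0.0
    promoter_offset_sd: float = 500.0
    min_site_gap: int = 400
    # reads
    read_scatter_sd: float = 20.0
    phantom_read_fraction: float = 0.05
    # annotation
    n_genes: int = 40
    min_gene_length: int = 2_000
    max_gene_length: int = 20_000
    max_exons: int = 6

    def __post_init__(self) -> None:
        if self.community_blocks is None:
            self.community_blocks = default_blocks(self.n_tfs)
        self.validate()

    def validate(self) -> None:
        counts = (
            self.n_tfs,
            self.n_modules,
            self.mean_site_width,
            self.datasets_per_tf,
            self.noise_peaks_per_dataset,
            self.reads_per_site,
            self.n_genes,
        )
        if any(c < 0 for c in counts):
            raise SimulationError("counts must be >= 0")
        fracs = (
            self.singleton_rate,
            self.sensitivity,
            self.background_read_fraction,
            self.within_block_prob,
            self.between_block_prob,
            self.promoter_bias,
            self.phantom_read_fraction,
        )
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise SimulationError("fractions must lie in [0, 1]")
        if self.fragment_length <= self.read_length:
            raise SimulationError("fragment_length must exceed read_length")
        if not self.chrom_lengths:
            raise SimulationError("chrom_lengths must be non-empty")
        panel = [tf for tfs in self.community_blocks.values() for tf in tfs]
        if len(panel) != len(set(panel)):
            raise SimulationError("community_blocks must partition the TF panel")

    @property
    def tf_panel(self) -> List[str]:
        return sorted(tf for tfs in self.community_blocks.values() for tf in tfs)

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["community_blocks"] = {k: list(v) for k, v in self.community_blocks.items()}
        return d


@dataclass(frozen=True)
class TruthSite:
    """A planted regulatory site with its true TF membership."""

    interval: GenomicInterval
    summit: int
    tf_set: FrozenSet[str]
    module_id: int
    block_id: str

    @property
    def is_singleton(self) -> bool:
        return len(self.tf_set) == 1


def _weighted_chrom(rng: np.random.Generator, chrom_lengths: Dict[str, int]) -> str:
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    return chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]


def simulate_genome_annotation(config: SimConfig) -> AnnotationModel:
    """Place non-overlapping gene models on the toy genome (seeded key 0)."""
    rng = config.rng(_KEY_GENOME)
    if config.n_genes == 0:
        return AnnotationModel([])
    if max(config.chrom_lengths.values()) < config.min_gene_length:
        raise SimulationError("every chromosome is too short to host a gene")

    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in config.chrom_lengths}
    genes: List[Gene] = []
    for g in range(config.n_genes):
        placed = False
        for _ in range(200):
            chrom = _weighted_chrom(rng, config.chrom_lengths)
            chrom_len = config.chrom_lengths[chrom]
            max_len = min(config.max_gene_length, chrom_len)
            if max_len < config.min_gene_length:
                continue
            length = int(rng.integers(config.min_gene_length, max_len + 1))
            start = int(rng.integers(0, chrom_len - length + 1))
            end = start + length
            if any(start < e and s < end for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_make_gene(rng, f"G{g + 1:03d}", chrom, strand, start, end, config))
            placed = True
            break
        if not placed:
            raise SimulationError(f"could not place gene {g + 1} without overlap")
    genes.sort(key=lambda x: (x.chrom, x.tx_start))
    return AnnotationModel(genes)


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    tx_start: int,
    tx_end: int,
    config: SimConfig,
) -> Gene:
    length = tx_end - tx_start
    n_ex = int(rng.integers(1, config.max_exons + 1))
    # alternating exon/intron segmentation anchored at the transcript ends
    n_cuts = 2 * (n_ex - 1)
    while True:
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_cuts, replace=False)) if n_cuts else np.array([], dtype=int)
        bounds = np.concatenate(([0], cuts, [length]))
        if np.all(np.diff(bounds) >= 1):
            break
    exon_starts = tuple(int(tx_start + bounds[i]) for i in range(0, 2 * n_ex, 2))
    exon_ends = tuple(int(tx_start + bounds[i + 1]) for i in range(0, 2 * n_ex, 2))
    if n_ex == 1:
        # CDS strictly inside the single exon so both UTRs exist
        a, b = exon_starts[0], exon_ends[0]
        if b - a >= 4:
            cds_start = a + max(1, (b - a) // 4)
            cds_end = b - max(1, (b - a) // 4)
        else:
            cds_start, cds_end = a, b
    else:
        first_a, first_b = exon_starts[0], exon_ends[0]
        last_a, last_b = exon_starts[-1], exon_ends[-1]
        cds_start = first_a + (first_b - first_a) // 2
        cds_end = last_a + max(1, (last_b - last_a) // 2)
    return Gene(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds_start,
        cds_end=cds_end,
        exon_starts=exon_starts,
        exon_ends=exon_ends,
    )


def _draw_tf_set(
    rng: np.random.Generator,
    blocks: Dict[str, Tuple[str, ...]],
    block_id: str,
    within: float,
    between: float,
    max_tries: int = 500,
) -> FrozenSet[str]:
    members = blocks[block_id]
    others = [tf for b, tfs in sorted(blocks.items()) if b != block_id for tf in tfs]
    for _ in range(max_tries):
        chosen = [tf for tf in members if rng.random() < within]
        chosen += [tf for tf in others if rng.random() < between]
        if len(chosen) >= 2:
            return frozenset(chosen)
    raise SimulationError("could not draw a module TF set with >= 2 members")


def plant_regulatory_sites(
    config: SimConfig, annotation: AnnotationModel
) -> List[TruthSite]:
    """Plant non-overlapping module and singleton sites (seeded key 1).

    Each module draws a block, then includes block members with probability
    ``within_block_prob`` and outside TFs with ``between_block_prob`` (redrawn
    until >= 2 members).  Site centres are TSS-proximal with probability
    ``promoter_bias`` (+ ``promoter_bias_per_extra_tf`` per TF beyond 2,
    capped at 1), otherwise uniform.  Intervals on one chromosome never
    overlap and keep at least ``min_site_gap`` bp between each other.
    """
    rng = config.rng(_KEY_SITES)
    blocks = config.community_blocks
    block_ids = sorted(blocks)
    width = config.mean_site_width
    tss = annotation.tss_list()
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in config.chrom_lengths}

    def place(size: int) -> Tuple[str, int]:
        bias = min(1.0, config.promoter_bias + config.promoter_bias_per_extra_tf * max(0, size - 2))
        for _ in range(500):
            if tss and rng.random() < bias:
                chrom, pos, _strand = tss[int(rng.integers(len(tss)))]
                center = pos + int(round(rng.normal(0.0, config.promoter_offset_sd)))
            else:
                chrom = _weighted_chrom(rng, config.chrom_lengths)
                center = int(rng.integers(width // 2, config.chrom_lengths[chrom] - width // 2))
            start = center - width // 2
            end = start + width
            if start < 0 or end > config.chrom_lengths[chrom]:
                continue
            pad = config.min_site_gap
            if any(start - pad < e and s < end + pad for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            return chrom, start
        raise PlacementError("genome too small for the requested non-overlapping sites")

    sites: List[TruthSite] = []
    module_id = 0
    for _ in range(config.n_modules):
        block_id = block_ids[int(rng.integers(len(block_ids)))]
        tf_set = _draw_tf_set(
            rng, blocks, block_id, config.within_block_prob, config.between_block_prob
        )
        chrom, start = place(len(tf_set))
        sites.append(
            TruthSite(
                interval=GenomicInterval(chrom, start, start + width),
                summit=start + width // 2,
                tf_set=tf_set,
                module_id=module_id,
                block_id=block_id,
            )
        )
        module_id += 1
    panel = config.tf_panel
    tf_to_block = {tf: b for b, tfs in blocks.items() for tf in tfs}
    for _ in range(int(round(config.singleton_rate * config.n_modules))):
        tf = panel[int(rng.integers(len(panel)))]
        chrom, start = place(1)
        sites.append(
            TruthSite(
                interval=GenomicInterval(chrom, start, start + width),
                summit=start + width // 2,
                tf_set=frozenset([tf]),
                module_id=module_id,
                block_id=tf_to_block[tf],
            )
        )
        module_id += 1
    return sites


def simulate_peak_datasets(
    config: SimConfig, truth: Sequence[TruthSite]
) -> Tuple[Dict[DatasetLabel, List[Peak]], Dict[DatasetLabel, List[int]]]:
    """Generate per-dataset peak calls from the planted truth (seeded key 2).

    Dataset ``k`` of TF ``t`` (label ``SIMk.t.synthetic``) recovers each truth
    site containing ``t`` with probability ``sensitivity``; recovered peaks
    get a jittered summit (clamped inside the peak) and a jittered width
    (>= 50 bp), and ``noise_peaks_per_dataset`` false peaks are placed
    uniformly.  Returns the peak map and a parallel provenance map giving each
    peak's truth module_id (-1 for noise peaks, even when they overlap truth
    by chance).
    """
    if config.datasets_per_tf < 1:
        raise SimulationError("datasets_per_tf must be >= 1")
    datasets: Dict[DatasetLabel, List[Peak]] = {}
    provenance: Dict[DatasetLabel, List[int]] = {}
    for tf_idx, tf in enumerate(config.tf_panel):
        bound = [s for s in truth if tf in s.tf_set]
        for k in range(1, config.datasets_per_tf + 1):
            rng = config.rng(_KEY_DATASETS, tf_idx, k)
            label = DatasetLabel(f"SIM{k}", tf, "synthetic")
            peaks: List[Peak] = []
            origins: List[int] = []
            for site in bound:
                if rng.random() >= config.sensitivity:
                    continue
                chrom_len = config.chrom_lengths[site.interval.chrom]
                w = max(50, int(round(config.mean_site_width + rng.normal(0.0, config.peak_width_sd))))
                w = min(w, chrom_len)
                summit = site.summit + int(round(rng.normal(0.0, config.summit_jitter_sd)))
                start = summit - w // 2
                start = min(max(start, 0), chrom_len - w)
                end = start + w
                summit = min(max(summit, start), end - 1)
                peaks.append(Peak(GenomicInterval(site.interval.chrom, start, end), summit, label))
                origins.append(site.module_id)
            for _ in range(config.noise_peaks_per_dataset):
                chrom = _weighted_chrom(rng, config.chrom_lengths)
                chrom_len = config.chrom_lengths[chrom]
                w = max(50, int(round(config.mean_site_width + rng.normal(0.0, config.peak_width_sd))))
                w = min(w, chrom_len)
                start = int(rng.integers(0, chrom_len - w + 1))
                peaks.append(
                    Peak(GenomicInterval(chrom, start, start + w), start + w // 2, label)
                )
                origins.append(-1)
            datasets[label] = peaks
            provenance[label] = origins
    return datasets, provenance


# anything with .interval/.summit (TruthSite, Peak, NonRedundantSite)
SiteLike = Union[TruthSite, Peak, Tuple[str, int]]


def _site_chrom_summit(site) -> Tuple[str, int]:
    if hasattr(site, "interval"):
        return site.interval.chrom, int(site.summit)
    chrom, summit = site
    return chrom, int(summit)


def simulate_reads(config: SimConfig, sites: Sequence[SiteLike]) -> ReadPositions:
    """Generate stranded 5' read positions for a dataset (seeded key 3).

    The read budget is ``len(sites) * reads_per_site``; a
    ``background_read_fraction`` of it is placed uniformly over the genome on
    random strands and the rest is split evenly over the sites.  A signal read
    comes from a ``fragment_length`` fragment whose centre scatters normally
    (sd ``read_scatter_sd``) around the site summit; the fragment is sequenced
    from a uniformly chosen end (plus-strand 5' at the left end, minus-strand
    5' at the right end).  With probability ``phantom_read_fraction`` a read is
    emitted as a duplicated strand pair at the same locus offset by
    ``read_length - 1`` — the "phantom" artefact of real libraries.
    """
    rng = config.rng(_KEY_READS)
    flen = config.fragment_length
    rlen = config.read_length
    plus: Dict[str, List[int]] = {c: [] for c in config.chrom_lengths}
    minus: Dict[str, List[int]] = {c: [] for c in config.chrom_lengths}

    def emit(chrom: str, pos: int, strand_plus: bool) -> None:
        chrom_len = config.chrom_lengths[chrom]
        p = min(max(pos, 0), chrom_len - 1)
        (plus if strand_plus else minus)[chrom].append(p)
        if rng.random() < config.phantom_read_fraction:
            # duplicated-position artefact: the same locus read on both
            # strands, with the strand-pair offset at the read length so the
            # cross-correlation phantom peak sits at shift = read_length
            if strand_plus:
                minus[chrom].append(min(p + rlen, chrom_len - 1))
            else:
                plus[chrom].append(max(p - rlen, 0))

    total = len(sites) * config.reads_per_site
    n_bg = int(round(config.background_read_fraction * total))
    n_signal = total - n_bg

    if sites and n_signal:
        base, extra = divmod(n_signal, len(sites))
        for i, site in enumerate(sites):
            chrom, summit = _site_chrom_summit(site)
            chrom_len = config.chrom_lengths[chrom]
            n_here = base + (1 if i < extra else 0)
            for _ in range(n_here):
                center = summit + int(round(rng.normal(0.0, config.read_scatter_sd)))
                x = center - flen // 2
                x = min(max(x, 0), max(0, chrom_len - flen))
                if rng.random() < 0.5:
                    emit(chrom, x, True)
                else:
                    emit(chrom, x + flen - 1, False)

    for _ in range(n_bg):
        chrom = _weighted_chrom(rng, config.chrom_lengths)
        chrom_len = config.chrom_lengths[chrom]
        pos = int(rng.integers(0, max(1, chrom_len - rlen + 1)))
        if rng.random() < 0.5:
            emit(chrom, pos, True)
        else:
            emit(chrom, pos + rlen - 1, False)

    plus_arr = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in plus.items() if v}
    minus_arr = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in minus.items() if v}
    return ReadPositions(plus_arr, minus_arr, rlen, dict(config.chrom_lengths))


def simulate_query_regions(
    config: SimConfig,
    truth: Sequence[TruthSite],
    enriched_tfs: Set[str],
    n_regions: int,
    spike_fraction: float,
    region_width: int = 2_000,
) -> Tuple[List[GenomicInterval], List[str]]:
    """Generate query regions spiked with chosen TFs' sites (seeded key 4).

    ``spike_fraction`` of the regions are windows centred on randomly chosen
    truth sites containing at least one enriched TF; the rest are uniform
    windows.  Returns the regions and a parallel provenance list
    ("spiked"/"background").
    """
    if not set(enriched_tfs) <= set(config.tf_panel):
        raise SimulationError("enriched_tfs must be a subset of the TF panel")
    eligible = [s for s in truth if s.tf_set & set(enriched_tfs)]
    if not eligible:
        raise SimulationError("no truth site contains any enriched TF")
    rng = config.rng(_KEY_QUERIES)
    n_spiked = int(round(spike_fraction * n_regions))
    regions: List[GenomicInterval] = []
    provenance: List[str] = []
    for _ in range(n_spiked):
        site = eligible[int(rng.integers(len(eligible)))]
        chrom_len = config.chrom_lengths[site.interval.chrom]
        w = min(region_width, chrom_len)
        start = site.summit - w // 2
        start = min(max(start, 0), chrom_len - w)
        regions.append(GenomicInterval(site.interval.chrom, start, start + w))
        provenance.append("spiked")
    for _ in range(n_regions - n_spiked):
        chrom = _weighted_chrom(rng, config.chrom_lengths)
        chrom_len = config.chrom_lengths[chrom]
        w = min(region_width, chrom_len)
        start = int(rng.integers(0, chrom_len - w + 1))
        regions.append(GenomicInterval(chrom, start, start + w))
        provenance.append("background")
    return regions, provenance
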