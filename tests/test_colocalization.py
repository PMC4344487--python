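"""Placement-null overlap p-values, the specificity matrix and the network."""

import warnings

import numpy as np
import pytest

from crmcat.core import CrmcatError, GenomicInterval
from crmcat.colocalization import (
    OverlapMatrix,
    PlacementNull,
    build_and_partition_network,
    default_domain,
    interval_overlap_pvalue,
    pairwise_matrix,
    significant_overlap_fraction,
    specificity_outliers,
)

from conftest import make_site


def enumeration_oracle(query, reference, domain):
    """Exhaustive placement enumeration (every valid start in every segment)."""

    def distance(chrom, start, end):
        best = None
        for r in reference:
            if r.chrom != chrom:
                continue
            if start < r.end and r.start < end:
                return 0
            gap = (r.start - end + 1) if r.start >= end else (start - r.end + 1)
            best = gap if best is None else min(best, gap)
        return best

    qlen = query.length
    d_obs = distance(query.chrom, query.start, query.end)
    count = total = 0
    for seg in domain:
        for x in range(seg.start, seg.end - qlen + 1):
            total += 1
            d = distance(seg.chrom, x, x + qlen)
            if d_obs is None or (d is not None and d <= d_obs):
                count += 1
    return count / total


class TestIntervalOverlapPvalue:
    def test_reference_covering_domain_gives_one(self):
        domain = [GenomicInterval("c", 0, 1_000)]
        reference = [GenomicInterval("c", 0, 1_000)]
        assert interval_overlap_pvalue(GenomicInterval("c", 10, 20), reference, domain) == 1.0

    def test_worked_enumeration_example(self):
        # domain [0,1000), reference [500,510), query [500,508):
        # overlapping placements of an 8 bp interval: starts 493..509 -> 17
        # of 993 valid placements
        domain = [GenomicInterval("c", 0, 1_000)]
        reference = [GenomicInterval("c", 500, 510)]
        p = interval_overlap_pvalue(GenomicInterval("c", 500, 508), reference, domain)
        assert p == pytest.approx(17 / 993)

    def test_pvalue_increases_with_distance(self):
        domain = [GenomicInterval("c", 0, 100_000)]
        reference = [GenomicInterval("c", 50_000, 50_300)]
        ps = [
            interval_overlap_pvalue(
                GenomicInterval("c", 50_400 + d, 50_600 + d), reference, domain
            )
            for d in (0, 500, 2_000, 10_000)
        ]
        assert ps == sorted(ps)
        assert ps[0] < ps[-1]

    def test_matches_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            # fragmented domain over two chromosomes, <= ~20 kb total
            domain = []
            for chrom in ("c1", "c2"):
                pos = 0
                for _ in range(int(rng.integers(1, 4))):
                    pos += int(rng.integers(100, 2_000))
                    width = int(rng.integers(200, 5_000))
                    domain.append(GenomicInterval(chrom, pos, pos + width))
                    pos += width
            reference = []
            for _ in range(int(rng.integers(1, 6))):
                seg = domain[int(rng.integers(len(domain)))]
                a = int(rng.integers(seg.start, seg.end - 10))
                reference.append(GenomicInterval(seg.chrom, a, a + int(rng.integers(5, 200))))
            seg = domain[int(rng.integers(len(domain)))]
            qlen = int(rng.integers(5, min(300, seg.length)))
            qstart = int(rng.integers(seg.start, seg.end - qlen + 1))
            query = GenomicInterval(seg.chrom, qstart, qstart + qlen)
            p = interval_overlap_pvalue(query, reference, domain)
            assert p == pytest.approx(enumeration_oracle(query, reference, domain))

    def test_uniform_queries_are_calibrated(self):
        # references sparse enough that the overlap atom F(0) << alpha, so
        # the 0.05 quantile of the placement distance CDF is attainable
        rng = np.random.default_rng(3)
        domain = [GenomicInterval("c", 0, 500_000)]
        reference = [
            GenomicInterval("c", int(s), int(s) + 60)
            for s in np.sort(rng.choice(490_000, 15, replace=False))
        ]
        null = PlacementNull(reference, domain)
        qlen = 50
        hits = 0
        n = 600
        for _ in range(n):
            x = int(rng.integers(0, 500_000 - qlen + 1))
            if null.pvalue(GenomicInterval("c", x, x + qlen)) <= 0.05:
                hits += 1
        assert hits / n == pytest.approx(0.05, abs=0.03)


class TestSignificantOverlapFraction:
    def test_identical_sparse_sets_nearly_all_significant(self):
        sites = [GenomicInterval("c", i * 10_000, i * 10_000 + 300) for i in range(1, 30)]
        domain = [GenomicInterval("c", 0, 400_000)]
        assert significant_overlap_fraction(sites, sites, domain) > 95.0

    def test_saturating_reference_gives_zero(self):
        domain = [GenomicInterval("c", 0, 10_000)]
        reference = [GenomicInterval("c", 0, 10_000)]
        queries = [GenomicInterval("c", 100, 300), GenomicInterval("c", 5_000, 5_100)]
        assert significant_overlap_fraction(queries, reference, domain) == 0.0

    def test_empty_inputs_rejected(self):
        domain = [GenomicInterval("c", 0, 1_000)]
        with pytest.raises(CrmcatError):
            significant_overlap_fraction([], [GenomicInterval("c", 0, 10)], domain)


class TestPairwiseMatrix:
    def make_sites(self, tf, starts, width=300):
        return [make_site("c", s, s + width, tf) for s in starts]

    def test_identical_tfs_symmetric_and_high(self):
        starts = [i * 20_000 for i in range(1, 25)]
        sites = {"A": self.make_sites("A", starts), "B": self.make_sites("B", starts)}
        matrix = pairwise_matrix(sites)
        ab = matrix.percentage("A", "B")
        ba = matrix.percentage("B", "A")
        assert ab == ba > 95.0

    def test_subset_asymmetry(self):
        starts_b = [i * 20_000 for i in range(1, 40)]
        starts_a = starts_b[:6]
        sites = {
            "A": self.make_sites("A", starts_a),
            "B": self.make_sites("B", starts_b),
        }
        matrix = pairwise_matrix(sites)
        assert matrix.percentage("A", "B") > matrix.percentage("B", "A")

    def test_matches_per_pair_recomputation(self):
        rng = np.random.default_rng(15)
        sites = {}
        for tf in "ABCD":
            starts = np.sort(rng.choice(300_000, 12, replace=False))
            sites[tf] = self.make_sites(tf, starts.tolist(), width=250)
        domain = default_domain(
            [s.interval for tf_sites in sites.values() for s in tf_sites]
        )
        matrix = pairwise_matrix(sites, domain=domain)
        for q in "ABCD":
            for r in "ABCD":
                if q == r:
                    continue
                expected = significant_overlap_fraction(
                    [s.interval for s in sites[q]],
                    [s.interval for s in sites[r]],
                    domain,
                )
                assert matrix.percentage(q, r) == pytest.approx(expected)


class TestSpecificityOutliers:
    def row_matrix(self, row):
        # query TF "Q" against partners P1..Pn
        tfs = ["Q"] + [f"P{i}" for i in range(1, len(row) + 1)]
        values = np.full((len(tfs), len(tfs)), np.nan)
        values[0, 1:] = row
        values[1:, 0] = 0.0
        for i in range(1, len(tfs)):
            for j in range(1, len(tfs)):
                if i != j:
                    values[i, j] = 0.0
        return OverlapMatrix(tfs=tfs, values=values, alpha=0.05)

    def test_zero_iqr_edge_calls_strong(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calls = specificity_outliers(self.row_matrix([5, 5, 5, 5, 5, 80]))
        q_calls = [c for c in calls if c.query == "Q"]
        assert len(q_calls) == 1
        assert q_calls[0].partner == "P6"
        assert q_calls[0].level == "strong"

    def test_all_equal_row_no_outliers(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calls = specificity_outliers(self.row_matrix([5, 5, 5, 5, 5]))
        assert [c for c in calls if c.query == "Q"] == []

    def test_quartile_arithmetic_example(self):
        # row {10,12,14,16,40}: Q3=16, IQR=6 -> 40 exceeds both fences
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calls = specificity_outliers(self.row_matrix([10, 12, 14, 16, 40]))
        q_calls = [c for c in calls if c.query == "Q"]
        assert len(q_calls) == 1
        assert q_calls[0].level == "strong"
        assert q_calls[0].percentage == 40.0

    def test_short_rows_yield_no_calls(self):
        with pytest.warns(UserWarning):
            calls = specificity_outliers(self.row_matrix([1, 2, 3]))
        assert calls == []

    def test_row_shift_invariance(self):
        base = [10, 12, 14, 16, 40]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calls1 = specificity_outliers(self.row_matrix(base))
            calls2 = specificity_outliers(self.row_matrix([v + 25 for v in base]))
        assert [(c.partner, c.level) for c in calls1 if c.query == "Q"] == [
            (c.partner, c.level) for c in calls2 if c.query == "Q"
        ]


class TestNetwork:
    def clique_calls(self, tfs):
        from crmcat.colocalization import SpecificityCall

        calls = []
        for a in tfs:
            for b in tfs:
                if a < b:
                    calls.append(SpecificityCall(a, b, "strong", 80.0))
        return calls

    def full_matrix(self, tfs):
        values = np.full((len(tfs), len(tfs)), 5.0)
        np.fill_diagonal(values, np.nan)
        return OverlapMatrix(tfs=list(tfs), values=values, alpha=0.05)

    def test_disjoint_cliques_give_two_communities(self):
        tfs = ["A", "B", "C", "D", "E", "F"]
        calls = self.clique_calls(tfs[:3]) + self.clique_calls(tfs[3:])
        net = build_and_partition_network(calls, self.full_matrix(tfs), seed=1)
        assert len(set(net.communities.values())) == 2
        assert {frozenset(k for k, v in net.communities.items() if v == c)
                for c in set(net.communities.values())} == {
            frozenset("ABC"), frozenset("DEF")
        }

    def test_single_edge_deterministic(self):
        from crmcat.colocalization import SpecificityCall

        calls = [SpecificityCall("A", "B", "strong", 70.0)]
        matrix = self.full_matrix(["A", "B"])
        nets = [
            build_and_partition_network(calls, matrix, resolution=0.51, seed=4)
            for _ in range(2)
        ]
        assert nets[0].communities == nets[1].communities
        assert set(nets[0].graph.nodes) == {"A", "B"}
        assert nets[0].graph["A"]["B"]["weight"] == 2

    def test_empty_calls_rejected(self):
        with pytest.raises(CrmcatError):
            build_and_partition_network([], self.full_matrix(["A", "B"]))

    def test_modularity_no_worse_than_trivial_partition(self):
        import networkx as nx

        tfs = list("ABCDEFGH")
        calls = self.clique_calls(tfs[:4]) + self.clique_calls(tfs[4:])
        net = build_and_partition_network(calls, self.full_matrix(tfs), seed=0)
        parts = {}
        for node, cid in net.communities.items():
            parts.setdefault(cid, set()).add(node)
        q_found = nx.community.modularity(net.graph, parts.values(), weight="weight")
        q_trivial = nx.community.modularity(
            net.graph, [set(net.graph.nodes)], weight="weight"
        )
        assert q_found >= q_trivial

    def test_planted_blocks_recovered_when_minority_of_row(self):
        # 6 blocks of 5 TFs: each row has 4/29 high same-block entries, the
        # IQR fence applies, and Louvain recovers the planted partition
        from sklearn.metrics import adjusted_rand_score

        from crmcat.catalogue import merge_tf_peaks
        from crmcat.simulate import (
            SimConfig,
            default_blocks,
            plant_regulatory_sites,
            simulate_genome_annotation,
            simulate_peak_datasets,
        )

        cfg = SimConfig(
            seed=1,
            chrom_lengths={"chr1": 10_000_000},
            n_tfs=30,
            community_blocks=default_blocks(30, 5),
            n_modules=300,
            singleton_rate=0.2,
            datasets_per_tf=2,
            sensitivity=0.9,
            noise_peaks_per_dataset=10,
            within_block_prob=0.8,
            between_block_prob=0.02,
        )
        truth = plant_regulatory_sites(cfg, simulate_genome_annotation(cfg))
        datasets, _ = simulate_peak_datasets(cfg, truth)
        by_tf = {}
        for label, peaks in datasets.items():
            by_tf.setdefault(label.tf_name, []).extend(peaks)
        sites = {tf: merge_tf_peaks(p) for tf, p in by_tf.items()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            matrix = pairwise_matrix(sites, alpha=0.05)
        calls = specificity_outliers(matrix)
        assert calls
        net = build_and_partition_network(calls, matrix, resolution=0.51, seed=1)
        block_of = {tf: b for b, tfs in cfg.community_blocks.items() for tf in tfs}
        nodes = sorted(net.communities)
        ari = adjusted_rand_score(
            [block_of[n] for n in nodes], [net.communities[n] for n in nodes]
        )
        assert ari >= 0.8
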