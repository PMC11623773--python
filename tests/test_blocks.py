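"""Segmentation, block tables and sample clustering."""

import numpy as np
import pandas as pd
import pytest

from cfdecon import (
    BlockSet,
    CpGMap,
    MethylationFragment,
    block_methylation_table,
    cluster_samples,
    per_cpg_methylation,
    segment_genome,
    top_variance_blocks,
)
from cfdecon.fragments import FragmentCollection


def _map(positions, chroms=("chr1",), offsets=None):
    positions = np.asarray(positions, dtype=np.int64)
    if offsets is None:
        offsets = np.array([0, positions.size])
    return CpGMap(chroms, np.asarray(offsets), positions)


class TestSegmentation:
    def test_homogeneous_run_is_one_block(self):
        cmap = _map(1000 + 25 * np.arange(8))  # 8 CpGs in <200 bp
        beta = np.full((8, 3), 0.9)
        blocks = segment_genome(beta, cmap, min_cpg=4, max_bp=5000)
        assert len(blocks) == 1
        b = next(iter(blocks))
        assert (b.start_cpg, b.end_cpg, b.n_cpgs) == (0, 8, 8)

    def test_sparse_cpgs_force_empty_blockset(self):
        cmap = _map(6000 * np.arange(10))
        beta = np.full((10, 2), 0.5)
        blocks = segment_genome(beta, cmap, min_cpg=4, max_bp=5000)
        assert len(blocks) == 0

    def test_methylation_jump_splits_at_boundary(self):
        cmap = _map(1000 + 30 * np.arange(8))
        beta = np.concatenate([np.zeros((4, 2)), np.ones((4, 2))])
        blocks = segment_genome(beta, cmap, min_cpg=4, max_bp=5000,
                                homogeneity_tol=0.25)
        assert [(b.start_cpg, b.end_cpg) for b in blocks] == [(0, 4), (4, 8)]

    def test_single_sample_jump_splits_with_max_statistic(self):
        # only 1 of 20 samples is hypomethylated on the right half: the
        # cross-sample mean moves by just 0.045, but max aggregation splits
        cmap = _map(1000 + 30 * np.arange(8))
        beta = np.full((8, 20), 0.9)
        beta[4:, 0] = 0.0
        blocks = segment_genome(beta, cmap, min_cpg=4, homogeneity_stat="max")
        assert [(b.start_cpg, b.end_cpg) for b in blocks] == [(0, 4), (4, 8)]
        blocks_mean = segment_genome(beta, cmap, min_cpg=4,
                                     homogeneity_stat="mean")
        assert [(b.start_cpg, b.end_cpg) for b in blocks_mean] == [(0, 8)]

    def test_chromosome_processing_is_independent(self):
        pos = np.concatenate([1000 + 30 * np.arange(6), 1000 + 30 * np.arange(6)])
        cmap2 = _map(pos, chroms=("chr1", "chr2"), offsets=[0, 6, 12])
        beta = np.full((12, 2), 0.5)
        blocks = segment_genome(beta, cmap2, min_cpg=4)
        spans = [(b.chrom, b.start_cpg, b.end_cpg) for b in blocks]
        assert spans == [("chr1", 0, 6), ("chr2", 6, 12)]

    def test_blocks_disjoint_sorted_invariant(self, tiny_world):
        cfg, cmap, methylomes, _ = tiny_world
        beta = np.column_stack([m.propensity for m in methylomes.values()])
        blocks = segment_genome(beta, cmap, min_cpg=4)
        starts = blocks.start_cpgs
        ends = blocks.end_cpgs
        assert np.all(starts[1:] >= ends[:-1])
        assert np.all(np.diff(starts) > 0)

    def test_bad_parameters_rejected(self):
        cmap = _map([10, 20])
        with pytest.raises(ValueError):
            segment_genome(np.zeros((2, 1)), cmap, min_cpg=0)
        with pytest.raises(ValueError):
            segment_genome(np.zeros((2, 1)), cmap, homogeneity_stat="median")


class TestBlockTable:
    @pytest.fixture
    def simple(self, make_collection):
        cmap = _map(1000 + 10 * np.arange(10))
        blocks = BlockSet(
            pd.DataFrame(
                {
                    "chrom": ["chr1"],
                    "start_bp": [1000],
                    "end_bp": [1052],
                    "start_cpg": [0],
                    "end_cpg": [5],
                }
            )
        )
        return cmap, blocks

    def test_mean_methylation_arithmetic(self, simple, make_collection):
        cmap, blocks = simple
        # 10 calls in block [0, 5): 3 methylated
        coll = make_collection(
            [
                ("chr1", 0, (1, 1, 0, 0, 0), 1),
                ("chr1", 0, (1, 0, 0, 0, 0), 1),
            ]
        )
        t = block_methylation_table(blocks, {"s": coll}, cmap, min_depth=5)
        assert t.values.iloc[0, 0] == pytest.approx(0.3)
        assert t.coverage.iloc[0, 0] == 10

    def test_below_min_depth_is_missing(self, simple, make_collection):
        cmap, blocks = simple
        coll = make_collection([("chr1", 0, (1, 0, 1, 0), 1)])  # 4 calls
        t = block_methylation_table(blocks, {"s": coll}, cmap, min_depth=5)
        assert np.isnan(t.values.iloc[0, 0])

    def test_zero_calls_missing_regardless(self, simple, make_collection):
        cmap, blocks = simple
        coll = make_collection([("chr1", 7, (1, 1), 1)])  # outside block
        t = block_methylation_table(blocks, {"s": coll}, cmap, min_depth=0)
        assert np.isnan(t.values.iloc[0, 0])

    def test_multiplicity_counts_weighted(self, simple, make_collection):
        cmap, blocks = simple
        coll = make_collection([("chr1", 0, (1, 0, 0, 0, 0), 3)])  # 15 calls
        t = block_methylation_table(blocks, {"s": coll}, cmap, min_depth=5)
        assert t.coverage.iloc[0, 0] == 15
        assert t.values.iloc[0, 0] == pytest.approx(0.2)

    def test_matches_brute_force_tally_oracle(self, tiny_world):
        from cfdecon import sample_fragments, segment_genome

        cfg, cmap, methylomes, _ = tiny_world
        coll = sample_fragments(methylomes["cell01"], cmap, 6.0, cfg, seed=9)
        beta = methylomes["cell01"].propensity[:, None]
        blocks = segment_genome(beta, cmap, min_cpg=4)
        t = block_methylation_table(blocks, {"s": coll}, cmap, min_depth=1)

        # brute force: per-CpG tallies via plain python iteration
        meth = np.zeros(cmap.n_cpgs)
        depth = np.zeros(cmap.n_cpgs)
        for frag in coll:
            for off, call in enumerate(frag.pattern):
                if call != 2:
                    depth[frag.start_cpg + off] += frag.count
                    meth[frag.start_cpg + off] += frag.count * (call == 1)
        for i, b in enumerate(blocks):
            d = depth[b.start_cpg:b.end_cpg].sum()
            m = meth[b.start_cpg:b.end_cpg].sum()
            if d >= 1:
                assert t.values.iloc[i, 0] == pytest.approx(m / d)
            assert t.coverage.iloc[i, 0] == d


class TestTopVariance:
    def _table(self, values):
        values = np.asarray(values, dtype=float)
        n = values.shape[0]
        blocks = BlockSet(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start_bp": 100 * np.arange(n),
                    "end_bp": 100 * np.arange(n) + 50,
                    "start_cpg": 10 * np.arange(n),
                    "end_cpg": 10 * np.arange(n) + 5,
                }
            )
        )
        from cfdecon.blocks import BlockTable

        vals = pd.DataFrame(values, columns=[f"s{j}" for j in
                                             range(values.shape[1])])
        cov = pd.DataFrame(np.full_like(values, 50), columns=vals.columns)
        return BlockTable(blocks, vals, cov, 10)

    def test_one_percent_of_200_complete_blocks_is_2(self):
        rng = np.random.default_rng(0)
        t = self._table(rng.random((200, 4)))
        top = top_variance_blocks(t, 0.01)
        assert len(top.blocks) == 2

    def test_block_with_any_missing_never_selected(self):
        vals = np.random.default_rng(1).random((50, 3))
        vals[7, 1] = np.nan  # most variable row forced incomplete
        vals[7, 0], vals[7, 2] = 0.0, 1.0
        t = self._table(vals)
        top = top_variance_blocks(t, 0.1)
        assert 70 not in top.blocks.frame["start_cpg"].to_list()
        assert not top.values.isna().any().any()

    def test_constant_table_tie_break_by_genomic_order(self):
        t = self._table(np.full((10, 3), 0.5))
        top = top_variance_blocks(t, 0.3)
        assert len(top.blocks) == 3  # ceil(0.3 * 10)
        assert list(top.blocks.frame["start_cpg"]) == [0, 10, 20]

    def test_no_complete_blocks_raises(self):
        vals = np.full((5, 2), np.nan)
        t = self._table(vals)
        with pytest.raises(ValueError):
            top_variance_blocks(t, 0.5)

    def test_selection_ranked_by_variance(self):
        vals = np.array(
            [[0.5, 0.5], [0.0, 1.0], [0.4, 0.6], [0.2, 0.8]]
        )
        t = self._table(vals)
        top = top_variance_blocks(t, 0.5)  # keep 2 of 4
        assert list(top.blocks.frame["start_cpg"]) == [10, 30]


class TestClustering:
    def _table_from_samples(self, x, labels):
        from cfdecon.blocks import BlockTable

        x = np.asarray(x, dtype=float)
        n_blocks = x.shape[1]
        blocks = BlockSet(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start_bp": 100 * np.arange(n_blocks),
                    "end_bp": 100 * np.arange(n_blocks) + 50,
                    "start_cpg": 10 * np.arange(n_blocks),
                    "end_cpg": 10 * np.arange(n_blocks) + 5,
                }
            )
        )
        vals = pd.DataFrame(x.T, columns=labels)
        cov = pd.DataFrame(np.full_like(x.T, 50), columns=labels)
        return BlockTable(blocks, vals, cov, 10)

    def test_duplicate_sample_merges_first_at_height_zero(self):
        t = self._table_from_samples(
            [[0.1, 0.2, 0.3], [0.1, 0.2, 0.3], [0.9, 0.9, 0.9]], ["a", "b", "c"]
        )
        d = cluster_samples(t)
        assert d.heights[0] == pytest.approx(0.0)

    def test_three_sample_average_linkage_hand_computed(self):
        # city-block distances: d(A,B)=1, d(A,C)=10, d(B,C)=10
        t = self._table_from_samples(
            [[0.0, 0.0], [0.0, 1.0], [9.5, 0.5]], ["A", "B", "C"]
        )
        d = cluster_samples(t)
        assert d.heights[0] == pytest.approx(1.0)
        assert d.heights[1] == pytest.approx(10.0)  # (10 + 10) / 2

    def test_permutation_invariance_of_heights(self):
        rng = np.random.default_rng(4)
        x = rng.random((6, 8))
        labels = [f"s{i}" for i in range(6)]
        t1 = self._table_from_samples(x, labels)
        perm = rng.permutation(6)
        t2 = self._table_from_samples(x[perm], [labels[i] for i in perm])
        h1 = cluster_samples(t1).heights
        h2 = cluster_samples(t2).heights
        assert np.allclose(np.sort(h1), np.sort(h2))

    def test_matches_brute_force_average_linkage_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.random((7, 5))
        t = self._table_from_samples(x, [f"s{i}" for i in range(7)])
        got = np.sort(cluster_samples(t).heights)
        expected = np.sort(_average_linkage_oracle(x))
        assert np.allclose(got, expected)

    def test_missing_cells_rejected(self):
        t = self._table_from_samples([[0.1, np.nan], [0.2, 0.3]], ["a", "b"])
        with pytest.raises(ValueError):
            cluster_samples(t)

    def test_fewer_than_two_samples_rejected(self):
        t = self._table_from_samples([[0.1, 0.2]], ["a"])
        with pytest.raises(ValueError):
            cluster_samples(t)


def _average_linkage_oracle(x: np.ndarray) -> list[float]:
    """O(n^3) agglomeration with exact average linkage on L1 distances."""
    clusters = [[i] for i in range(x.shape[0])]
    heights = []

    def dist(c1, c2):
        return float(
            np.mean(
                [np.abs(x[i] - x[j]).sum() for i in c1 for j in c2]
            )
        )

    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = dist(clusters[a], clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return heights


class TestPerCpgMethylation:
    def test_tallies(self, make_collection):
        cmap = _map(1000 + 10 * np.arange(5))
        coll = make_collection(
            [("chr1", 0, (1, 0), 2), ("chr1", 1, (1, 2, 0), 1)]
        )
        beta, depth, names = per_cpg_methylation({"s": coll}, cmap)
        assert names == ["s"]
        assert depth[:, 0].tolist() == [2, 3, 0, 1, 0]  # missing call skipped
        assert beta[0, 0] == pytest.approx(1.0)
        assert beta[1, 0] == pytest.approx(1 / 3)
        assert np.isnan(beta[2, 0])


class TestBlockSetIO:
    def test_tsv_round_trip(self, tmp_path, tiny_world):
        cfg, cmap, methylomes, _ = tiny_world
        beta = np.column_stack([m.propensity for m in methylomes.values()])
        blocks = segment_genome(beta, cmap, min_cpg=4)
        p = tmp_path / "blocks.tsv"
        blocks.to_tsv(p)
        again = BlockSet.from_tsv(p)
        pd.testing.assert_frame_equal(blocks.frame, again.frame)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError):
            BlockSet(
                pd.DataFrame(
                    {
                        "chrom": ["chr1", "chr1"],
                        "start_bp": [0, 10],
                        "end_bp": [100, 200],
                        "start_cpg": [0, 3],
                        "end_cpg": [5, 8],
                    }
                )
            )
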