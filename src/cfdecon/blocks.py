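"""Co-methylated block segmentation, block methylation tables, clustering.

Adjacent CpGs are highly correlated in methylation, so analysis proceeds on
blocks of co-methylated CpGs rather than single sites. The segmentation here
is a greedy left-to-right scan: a growing block absorbs the next CpG while
(a) the genomic span stays within ``max_bp``, (b) the chromosome is unchanged
and (c) the candidate CpG's cross-sample methylation vector stays within
``homogeneity_tol`` mean absolute difference of the running block mean.
Runs shorter than ``min_cpg`` are discarded.

Per-block mean methylation across samples is assembled into a
:class:`BlockTable` with the missingness rule "coverage < min_depth -> NA",
and samples are clustered by average-linkage / city-block distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .cpgmap import CpGMap
from .fragments import METH, MISSING, FragmentCollection

__all__ = [
    "Block",
    "BlockSet",
    "BlockTable",
    "Dendrogram",
    "per_cpg_methylation",
    "segment_genome",
    "block_methylation_table",
    "top_variance_blocks",
    "cluster_samples",
]

BLOCK_COLUMNS = ["chrom", "start_bp", "end_bp", "start_cpg", "end_cpg", "n_cpgs"]


class Block(NamedTuple):
    chrom: str
    start_bp: int
    end_bp: int
    start_cpg: int  # 0-based, half-open CpG-index interval
    end_cpg: int
    n_cpgs: int

    @property
    def block_id(self) -> str:
        return f"{self.chrom}:{self.start_bp}-{self.end_bp}"


class BlockSet:
    """Sorted, disjoint CpG-index intervals (wgbstools-style 5-column blocks)."""

    def __init__(self, frame: pd.DataFrame) -> None:
        frame = frame.reset_index(drop=True).copy()
        if "n_cpgs" not in frame.columns:
            frame["n_cpgs"] = frame["end_cpg"] - frame["start_cpg"]
        self.frame = frame[BLOCK_COLUMNS]
        starts = self.frame["start_cpg"].to_numpy()
        ends = self.frame["end_cpg"].to_numpy()
        if np.any(ends - starts < 1):
            raise ValueError("blocks must contain at least one CpG")
        if np.any(np.diff(starts) < 0) or np.any(starts[1:] < ends[:-1]):
            raise ValueError("blocks must be sorted and non-overlapping")

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[Block]:
        for row in self.frame.itertuples(index=False):
            yield Block(*row)

    @property
    def start_cpgs(self) -> np.ndarray:
        return self.frame["start_cpg"].to_numpy()

    @property
    def end_cpgs(self) -> np.ndarray:
        return self.frame["end_cpg"].to_numpy()

    @property
    def block_ids(self) -> pd.Index:
        f = self.frame
        return pd.Index(
            f["chrom"].astype(str)
            + ":"
            + f["start_bp"].astype(str)
            + "-"
            + f["end_bp"].astype(str),
            name="block",
        )

    def subset(self, mask_or_idx) -> "BlockSet":
        return BlockSet(self.frame.loc[mask_or_idx].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BlockSet":
        return cls(pd.read_csv(path, sep="\t"))


def per_cpg_methylation(
    samples: Mapping[str, FragmentCollection], cmap: CpGMap
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-CpG mean methylation and call depth for each sample.

    Returns ``beta`` (n_cpgs x n_samples, NaN where depth 0), ``depth``
    (same shape, multiplicity-weighted call counts) and the sample order.
    """
    names = list(samples)
    n = cmap.n_cpgs
    beta = np.full((n, len(names)), np.nan)
    depth = np.zeros((n, len(names)), dtype=np.int64)
    for j, name in enumerate(names):
        meth_j, depth_j = _per_cpg_tallies(samples[name], n)
        depth[:, j] = depth_j
        covered = depth_j > 0
        beta[covered, j] = meth_j[covered] / depth_j[covered]
    return beta, depth, names


def _per_cpg_tallies(
    coll: FragmentCollection, n_cpgs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicity-weighted methylated / total call counts per CpG."""
    if coll.n_fragments == 0:
        z = np.zeros(n_cpgs, dtype=np.int64)
        return z, z.copy()
    idx = coll.call_cpg_indices()
    w = np.repeat(coll.counts, coll.lengths)
    informative = coll.calls != MISSING
    idx, w, calls = idx[informative], w[informative], coll.calls[informative]
    depth = np.bincount(idx, weights=w, minlength=n_cpgs).astype(np.int64)
    is_meth = calls == METH
    meth = np.bincount(
        idx[is_meth], weights=w[is_meth], minlength=n_cpgs
    ).astype(np.int64)
    return meth, depth


def segment_genome(
    beta: np.ndarray,
    cmap: CpGMap,
    min_cpg: int = 4,
    max_bp: int = 5000,
    homogeneity_tol: float = 0.25,
    homogeneity_stat: str = "max",
) -> BlockSet:
    """Greedy segmentation of the CpG universe into co-methylated blocks.

    ``beta`` is the (n_cpgs x n_samples) per-CpG methylation matrix (NaN
    allowed). The candidate CpG is compared with the running block mean over
    samples where both are defined; with no overlap the block is closed.
    ``homogeneity_stat`` chooses how per-sample deviations aggregate: "max"
    (default) closes the block as soon as any single sample's methylation
    jumps by more than ``homogeneity_tol`` — necessary for boundaries that
    are specific to one cell type among many, whose effect on the
    cross-sample mean shrinks as 1/n_samples — while "mean" uses the average
    absolute deviation. Output blocks cover a subset of CpGs, disjoint and
    sorted; each chromosome is processed independently, so processing order
    cannot change the result.
    """
    if min_cpg < 1 or max_bp < 1:
        raise ValueError("min_cpg and max_bp must be >= 1")
    if homogeneity_stat not in ("max", "mean"):
        raise ValueError("homogeneity_stat must be 'max' or 'mean'")
    agg = np.max if homogeneity_stat == "max" else np.mean
    beta = np.asarray(beta, dtype=np.float64)
    if beta.ndim == 1:
        beta = beta[:, None]
    if beta.shape[0] != cmap.n_cpgs:
        raise ValueError("beta row count does not match the CpG map")
    pos = cmap.positions
    rows = []

    def _emit(chrom: str, s: int, e: int) -> None:
        if e - s >= min_cpg:
            rows.append(
                {
                    "chrom": chrom,
                    "start_bp": int(pos[s]),
                    "end_bp": int(pos[e - 1]) + 2,
                    "start_cpg": s,
                    "end_cpg": e,
                    "n_cpgs": e - s,
                }
            )

    for ci, chrom in enumerate(cmap.chroms):
        lo, hi = int(cmap.chrom_offsets[ci]), int(cmap.chrom_offsets[ci + 1])
        if hi <= lo:
            continue
        s = lo
        run_sum = np.nan_to_num(beta[lo], nan=0.0).copy()
        run_cnt = (~np.isnan(beta[lo])).astype(np.float64)
        for i in range(lo + 1, hi):
            ok = int(pos[i]) + 2 - int(pos[s]) <= max_bp
            if ok:
                both = (run_cnt > 0) & ~np.isnan(beta[i])
                if not both.any():
                    ok = False
                else:
                    mean_vec = run_sum[both] / run_cnt[both]
                    ok = float(agg(np.abs(beta[i][both] - mean_vec))) <= (
                        homogeneity_tol
                    )
            if ok:
                run_sum += np.nan_to_num(beta[i], nan=0.0)
                run_cnt += ~np.isnan(beta[i])
            else:
                _emit(chrom, s, i)
                s = i
                run_sum = np.nan_to_num(beta[i], nan=0.0).copy()
                run_cnt = (~np.isnan(beta[i])).astype(np.float64)
        _emit(chrom, s, hi)

    frame = pd.DataFrame(rows, columns=BLOCK_COLUMNS)
    return BlockSet(frame)


@dataclass
class BlockTable:
    """Blocks x samples mean-methylation matrix with missingness.

    ``values[b, s]`` is methylated calls / total calls over block ``b`` in
    sample ``s``, or NaN when the call depth is below ``min_depth``;
    ``coverage`` holds the depths.
    """

    blocks: BlockSet
    values: pd.DataFrame
    coverage: pd.DataFrame
    min_depth: int

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def complete_mask(self) -> np.ndarray:
        return ~self.values.isna().any(axis=1).to_numpy()

    def subset(self, mask_or_idx) -> "BlockTable":
        return BlockTable(
            self.blocks.subset(mask_or_idx),
            self.values.loc[mask_or_idx].reset_index(drop=True),
            self.coverage.loc[mask_or_idx].reset_index(drop=True),
            self.min_depth,
        )


def block_methylation_table(
    blocks: BlockSet,
    samples: Mapping[str, FragmentCollection],
    cmap: CpGMap,
    min_depth: int = 10,
) -> BlockTable:
    """Mean methylation per block per sample; NA where depth < ``min_depth``."""
    names = list(samples)
    s_idx = blocks.start_cpgs
    e_idx = blocks.end_cpgs
    if len(blocks) and e_idx.max() > cmap.n_cpgs:
        raise ValueError("blocks exceed the CpG map bounds")
    vals = np.full((len(blocks), len(names)), np.nan)
    cov = np.zeros((len(blocks), len(names)), dtype=np.int64)
    for j, name in enumerate(names):
        meth_per_cpg, depth_per_cpg = _per_cpg_tallies(samples[name], cmap.n_cpgs)
        cm = np.concatenate(([0], np.cumsum(meth_per_cpg)))
        cd = np.concatenate(([0], np.cumsum(depth_per_cpg)))
        meth_b = cm[e_idx] - cm[s_idx]
        depth_b = cd[e_idx] - cd[s_idx]
        cov[:, j] = depth_b
        ok = depth_b >= max(min_depth, 1)
        vals[ok, j] = meth_b[ok] / depth_b[ok]
    ids = blocks.block_ids
    return BlockTable(
        blocks,
        pd.DataFrame(vals, index=ids, columns=names).reset_index(drop=True),
        pd.DataFrame(cov, index=ids, columns=names).reset_index(drop=True),
        min_depth,
    )


def top_variance_blocks(table: BlockTable, fraction: float = 0.01) -> BlockTable:
    """Keep the top ``fraction`` of fully observed blocks by variance.

    Blocks with any missing cell are excluded first; the remaining blocks are
    ranked by across-sample variance and the top ``ceil(fraction * n)`` kept,
    ties broken by genomic order. The returned table preserves genomic order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    complete = table.complete_mask()
    n_complete = int(complete.sum())
    if n_complete == 0:
        raise ValueError("no blocks are complete across all samples")
    idx = np.flatnonzero(complete)
    var = table.values.iloc[idx].var(axis=1, ddof=1).to_numpy()
    k = int(np.ceil(fraction * n_complete))
    order = np.argsort(-var, kind="stable")  # stable: ties stay in genomic order
    keep = np.sort(idx[order[:k]])
    return table.subset(keep)


@dataclass
class Dendrogram:
    """Average-linkage merge history over samples."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 format

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [
            (int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix
        ]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def cluster_samples(table: BlockTable) -> Dendrogram:
    """Hierarchical clustering of samples (average linkage, L1 metric)."""
    x = table.values.to_numpy().T  # samples x blocks
    if x.shape[0] < 2:
        raise ValueError("clustering needs at least two samples")
    if np.isnan(x).any():
        raise ValueError("block table contains missing cells; filter first")
    z = linkage(x, method="average", metric="cityblock", optimal_ordering=True)
    return Dendrogram(table.samples, z)
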