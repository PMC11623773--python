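"""Cell-type-specific hypomethylated marker selection.

A block is a candidate marker for a target cell type when (i) at most
``max_na_frac`` of each group's samples are missing, (ii) the
background-minus-target mean methylation difference is at least ``min_diff``
(0.3 by default) and (iii) a two-sided Welch two-sample t-test gives
p <= ``alpha`` (0.05). Candidates are then ranked by the separation margin —
the background group's 2.5th percentile minus the target group's 75th
percentile — and the top ``k`` kept per cell type.

No multiple-testing correction is applied: the raw p <= alpha rule is the
procedure this stage reproduces (see docs/methods.md for the caveat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import BlockTable

__all__ = [
    "MarkerSelectionConfig",
    "MarkerSet",
    "find_markers",
    "rank_and_select",
    "select_markers",
]

#: marker-count grid used by the spike-in study
STANDARD_MARKER_COUNTS = (25, 50, 100, 250, 300, 400, 500)

CANDIDATE_COLUMNS = [
    "chrom",
    "start_bp",
    "end_bp",
    "start_cpg",
    "end_cpg",
    "n_cpgs",
    "target_mean",
    "background_mean",
    "diff",
    "p_value",
    "margin",
]


@dataclass
class MarkerSelectionConfig:
    """Thresholds for marker candidacy and ranking.

    ``direction="hypermethylated"`` selects markers methylated specifically
    in the target by running the same rule on ``1 - methylation``; reported
    means stay on the original scale while ``diff`` and ``margin`` are the
    separation in the chosen direction.
    """

    min_diff: float = 0.3
    alpha: float = 0.05
    max_na_frac: float = 1.0 / 3.0
    min_depth: int = 5
    direction: str = "hypomethylated"
    k: int = 500

    def __post_init__(self) -> None:
        if not 0 < self.min_diff <= 1:
            raise ValueError("min_diff must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.direction not in ("hypomethylated", "hypermethylated"):
            raise ValueError("direction must be hypo- or hypermethylated")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class MarkerSet:
    """Ranked markers of one cell type (best separation margin first)."""

    cell_type: str
    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=CANDIDATE_COLUMNS)
    )

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(5, "cell_type", self.cell_type)
        out.rename(columns={"p_value": "p"}).to_csv(path, sep="\t", index=False)


def _welch_rows(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sided Welch t-test p-values (NaN-aware, vectorized).

    Equivalent to ``scipy.stats.ttest_ind(..., equal_var=False,
    nan_policy='omit')`` per row (asserted against it in the test suite) but
    avoids the masked-array path, which dominates runtime on large tables.
    """
    na = np.count_nonzero(~np.isnan(a), axis=1).astype(np.float64)
    nb = np.count_nonzero(~np.isnan(b), axis=1).astype(np.float64)
    ma = np.nanmean(a, axis=1)
    mb = np.nanmean(b, axis=1)
    va = np.nanvar(a, axis=1, ddof=1)
    vb = np.nanvar(b, axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return p, ma, mb


def _row_percentile(x: np.ndarray, q: float) -> np.ndarray:
    """Row-wise percentile (linear interpolation), fast when rows lack NaN."""
    has_nan = np.isnan(x).any(axis=1)
    out = np.empty(x.shape[0])
    if (~has_nan).any():
        out[~has_nan] = np.percentile(x[~has_nan], q, axis=1)
    if has_nan.any():
        out[has_nan] = np.nanpercentile(x[has_nan], q, axis=1)
    return out


def find_markers(
    table: BlockTable,
    target_group: Sequence[str],
    background_group: Sequence[str],
    config: MarkerSelectionConfig | None = None,
) -> pd.DataFrame:
    """Candidate cell-type-specific markers from a block table.

    Blocks are dropped when the missing fraction exceeds ``max_na_frac`` in
    either group, or when fewer than two non-missing values remain in a group
    (Welch's test is undefined). Retained candidates satisfy the
    ``min_diff`` / ``alpha`` rule; each carries its separation ``margin``.
    """
    config = config or MarkerSelectionConfig()
    target_group = list(target_group)
    background_group = list(background_group)
    if not target_group or not background_group:
        raise ValueError("target and background groups must be non-empty")
    if set(target_group) & set(background_group):
        raise ValueError("target and background groups must be disjoint")

    vals = table.values
    tgt = vals[target_group].to_numpy(dtype=np.float64)
    bg = vals[background_group].to_numpy(dtype=np.float64)
    if config.direction == "hypermethylated":
        tgt, bg = 1.0 - tgt, 1.0 - bg

    na_t = np.isnan(tgt)
    na_b = np.isnan(bg)
    eligible = (
        (na_t.mean(axis=1) <= config.max_na_frac)
        & (na_b.mean(axis=1) <= config.max_na_frac)
        & ((~na_t).sum(axis=1) >= 2)
        & ((~na_b).sum(axis=1) >= 2)
    )
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)

    t_sub, b_sub = tgt[idx], bg[idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant groups yield NaN p; filtered below
        p, t_mean, b_mean = _welch_rows(t_sub, b_sub)
        margin = _row_percentile(b_sub, 2.5) - _row_percentile(t_sub, 75)
    diff = b_mean - t_mean
    keep = (diff >= config.min_diff) & (p <= config.alpha) & np.isfinite(p)

    sel = idx[keep]
    out = table.blocks.frame.iloc[sel].reset_index(drop=True).copy()
    if config.direction == "hypermethylated":
        out["target_mean"] = 1.0 - t_mean[keep]
        out["background_mean"] = 1.0 - b_mean[keep]
    else:
        out["target_mean"] = t_mean[keep]
        out["background_mean"] = b_mean[keep]
    out["diff"] = diff[keep]
    out["p_value"] = p[keep]
    out["margin"] = margin[keep]
    return out[CANDIDATE_COLUMNS]


def rank_and_select(
    candidates: pd.DataFrame, k: int, cell_type: str = ""
) -> MarkerSet:
    """Top-``k`` candidates by margin (desc), ties by p-value then position."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(candidates) == 0:
        warnings.warn(
            f"no marker candidates for {cell_type or 'cell type'}; "
            "returning an empty marker set",
            stacklevel=2,
        )
        return MarkerSet(cell_type, candidates.copy())
    ordered = candidates.sort_values(
        ["margin", "p_value", "chrom", "start_cpg"],
        ascending=[False, True, True, True],
        kind="stable",
        ignore_index=True,
    )
    return MarkerSet(cell_type, ordered.head(k).reset_index(drop=True))


def select_markers(
    table: BlockTable,
    groups: dict[str, Sequence[str]],
    config: MarkerSelectionConfig | None = None,
) -> dict[str, MarkerSet]:
    """Markers for every cell type: each vs the union of all others."""
    config = config or MarkerSelectionConfig()
    out: dict[str, MarkerSet] = {}
    for ct, members in groups.items():
        background = [
            s for other, mem in groups.items() if other != ct for s in mem
        ]
        cands = find_markers(table, list(members), background, config)
        out[ct] = rank_and_select(cands, config.k, ct)
    return out
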