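"""Fragment-level (U/X/M) methylation deconvolution.

Each fragment overlapping a marker is classified by its methylated-call
fraction over the marker's CpGs: U (mostly unmethylated) when the fraction is
at most ``u_threshold``, M (mostly methylated) at or above ``m_threshold``,
X in between; fragments with fewer than ``min_fragment_cpgs`` informative
calls inside the marker are excluded. The reference atlas stores, per marker
and cell type, the U-fraction of that cell type's fragments. Mixture
proportions are then the non-negative least-squares solution of
``A x ~ b`` (b = per-marker mixture U-fractions), normalized to sum to one.

The model/results split follows the statsmodels convention:
``MethylationDeconvolution(atlas).fit(mixture)`` returns a
:class:`DeconvolutionResults` with estimates, residual and ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .blocks import Block
from .fragments import METH, MISSING, FragmentCollection

__all__ = [
    "DeconvolutionConfig",
    "Atlas",
    "MethylationDeconvolution",
    "DeconvolutionResults",
    "classify_fragment",
    "uxm_counts",
    "build_atlas",
    "deconvolve",
]

logger = logging.getLogger(__name__)

U, X, M = 0, 1, 2  # class indices in count arrays


@dataclass
class DeconvolutionConfig:
    """U/X/M thresholds and marker support requirements."""

    u_threshold: float = 0.25
    m_threshold: float = 0.75
    min_fragment_cpgs: int = 3
    min_fragments_per_marker: int = 1
    detection_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.u_threshold < self.m_threshold <= 1:
            raise ValueError("need 0 <= u_threshold < m_threshold <= 1")
        if self.min_fragment_cpgs < 1:
            raise ValueError("min_fragment_cpgs must be >= 1")
        if self.min_fragments_per_marker < 1:
            raise ValueError("min_fragments_per_marker must be >= 1")


def classify_fragment(
    fragment, marker: Block, config: DeconvolutionConfig | None = None
) -> str:
    """Classify one fragment over one marker: 'U', 'X', 'M' or 'excluded'.

    Only the fragment's non-missing calls at CpGs inside the marker's
    CpG-index interval are considered.
    """
    config = config or DeconvolutionConfig()
    lo = max(fragment.start_cpg, marker.start_cpg)
    hi = min(fragment.start_cpg + len(fragment.pattern), marker.end_cpg)
    calls = [
        c
        for i, c in enumerate(fragment.pattern, start=fragment.start_cpg)
        if lo <= i < hi and c != MISSING
    ]
    if len(calls) < config.min_fragment_cpgs:
        return "excluded"
    frac = sum(1 for c in calls if c == METH) / len(calls)
    if frac <= config.u_threshold:
        return "U"
    if frac >= config.m_threshold:
        return "M"
    return "X"


def uxm_counts(
    collection: FragmentCollection,
    marker_start_cpgs: np.ndarray,
    marker_end_cpgs: np.ndarray,
    config: DeconvolutionConfig | None = None,
) -> np.ndarray:
    """Multiplicity-weighted (n_markers x 3) U/X/M counts for a collection.

    Markers must be sorted, disjoint CpG-index intervals. Fully vectorized:
    every call is binned to a marker, per-(fragment, marker) methylated /
    total tallies are reduced with ``np.unique``, and each pair is classified
    once and weighted by the fragment's count.
    """
    config = config or DeconvolutionConfig()
    starts = np.asarray(marker_start_cpgs, dtype=np.int64)
    ends = np.asarray(marker_end_cpgs, dtype=np.int64)
    n_markers = starts.size
    out = np.zeros((n_markers, 3), dtype=np.int64)
    if collection.n_fragments == 0 or n_markers == 0:
        return out

    cpg_idx = collection.call_cpg_indices()
    frag_id = np.repeat(
        np.arange(collection.n_fragments, dtype=np.int64), collection.lengths
    )
    m_id = np.searchsorted(starts, cpg_idx, side="right") - 1
    inside = (m_id >= 0) & (cpg_idx < ends[np.clip(m_id, 0, n_markers - 1)])
    informative = collection.calls != MISSING
    sel = inside & informative
    if not sel.any():
        return out

    key = frag_id[sel] * n_markers + m_id[sel]
    meth = (collection.calls[sel] == METH).astype(np.float64)
    uniq, inv, tot = np.unique(key, return_inverse=True, return_counts=True)
    meth_per_pair = np.bincount(inv, weights=meth, minlength=uniq.size)

    ok = tot >= config.min_fragment_cpgs
    if not ok.any():
        return out
    frac = meth_per_pair[ok] / tot[ok]
    cls = np.full(frac.size, X, dtype=np.int8)
    cls[frac <= config.u_threshold] = U
    cls[frac >= config.m_threshold] = M
    pair_marker = (uniq[ok] % n_markers).astype(np.int64)
    pair_frag = (uniq[ok] // n_markers).astype(np.int64)
    w = collection.counts[pair_frag]
    np.add.at(out, (pair_marker, cls), w)
    return out


@dataclass
class Atlas:
    """Markers x cell-types U-fraction reference matrix.

    ``frame`` rows are markers (index = "chrom:start-end"), columns cell
    types; ``markers`` carries the aligned marker metadata including the
    owning cell type. Rows lacking the minimum fragment support in any cell
    type are dropped at construction and listed in ``dropped_rows``.
    """

    frame: pd.DataFrame
    markers: pd.DataFrame
    config: DeconvolutionConfig = field(default_factory=DeconvolutionConfig)
    dropped_rows: list[str] = field(default_factory=list)

    @property
    def cell_types(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    def marker_intervals(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.markers["start_cpg"].to_numpy(dtype=np.int64),
            self.markers["end_cpg"].to_numpy(dtype=np.int64),
        )

    def to_tsv(self, path) -> None:
        out = self.markers[
            ["chrom", "start_bp", "end_bp", "start_cpg", "end_cpg", "cell_type"]
        ].copy()
        out.insert(0, "marker", self.frame.index)
        for ct in self.frame.columns:
            out[ct] = self.frame[ct].to_numpy()
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, config: "DeconvolutionConfig | None" = None) -> "Atlas":
        df = pd.read_csv(path, sep="\t")
        meta_cols = [
            "marker", "chrom", "start_bp", "end_bp", "start_cpg", "end_cpg",
            "cell_type",
        ]
        cts = [c for c in df.columns if c not in meta_cols]
        frame = df[cts].copy()
        frame.index = pd.Index(df["marker"], name="marker")
        return cls(frame, df[meta_cols[1:]].copy(), config or DeconvolutionConfig())


def _merge(collections) -> FragmentCollection:
    if isinstance(collections, FragmentCollection):
        return collections
    return FragmentCollection.concatenate(list(collections))


def build_atlas(
    reference_fragments: Mapping[str, FragmentCollection | Sequence[FragmentCollection]],
    markers: pd.DataFrame,
    config: DeconvolutionConfig | None = None,
) -> Atlas:
    """U-fraction atlas over the union of all cell types' markers.

    ``markers`` is a BED-like frame (chrom, start_bp, end_bp, start_cpg,
    end_cpg, cell_type) — the concatenated per-cell-type marker sets. Rows
    are the union of markers across cell types; any row where some cell type
    has fewer than ``min_fragments_per_marker`` classifiable fragments is
    dropped (and logged). A cell type with zero classifiable fragments
    anywhere raises.
    """
    config = config or DeconvolutionConfig()
    mk = (
        markers.drop_duplicates(subset=["start_cpg", "end_cpg"])
        .sort_values(["start_cpg"], kind="stable")
        .reset_index(drop=True)
    )
    starts = mk["start_cpg"].to_numpy(dtype=np.int64)
    ends = mk["end_cpg"].to_numpy(dtype=np.int64)
    ids = (
        mk["chrom"].astype(str)
        + ":"
        + mk["start_bp"].astype(str)
        + "-"
        + mk["end_bp"].astype(str)
    )

    cols = {}
    support = {}
    for ct, colls in reference_fragments.items():
        counts = uxm_counts(_merge(colls), starts, ends, config)
        total = counts.sum(axis=1)
        if total.sum() == 0:
            raise ValueError(
                f"cell type {ct!r} has zero classifiable fragments over the markers"
            )
        with np.errstate(invalid="ignore"):
            cols[ct] = np.where(total > 0, counts[:, U] / np.maximum(total, 1), np.nan)
        support[ct] = total
    frame = pd.DataFrame(cols, index=pd.Index(ids, name="marker"))
    supp = pd.DataFrame(support, index=frame.index)

    ok = (supp >= config.min_fragments_per_marker).all(axis=1).to_numpy()
    dropped = list(frame.index[~ok])
    if dropped:
        logger.info(
            "dropping %d/%d atlas rows with insufficient reference support",
            len(dropped),
            len(frame),
        )
    return Atlas(
        frame.loc[ok],
        mk.loc[ok].reset_index(drop=True),
        config,
        dropped,
    )


@dataclass
class DeconvolutionResults:
    """Estimated mixture composition from one NNLS fit."""

    proportions: pd.Series
    residual: float
    n_markers_used: int
    n_fragments_used: int
    raw_coefficients: pd.Series

    def detected(self, epsilon: float = 0.0) -> list[str]:
        """Cell types with estimated proportion strictly above ``epsilon``."""
        return list(self.proportions.index[self.proportions > epsilon])

    def summary(self) -> str:
        lines = [
            "Fragment-level methylation deconvolution (NNLS on U-fractions)",
            f"markers used: {self.n_markers_used}    "
            f"fragments used: {self.n_fragments_used}    "
            f"residual ||Ax-b||: {self.residual:.4g}",
            "-" * 58,
            f"{'cell type':<24}{'proportion':>12}",
        ]
        for ct, v in self.proportions.sort_values(ascending=False).items():
            lines.append(f"{ct:<24}{v:>12.4f}")
        return "\n".join(lines)


class MethylationDeconvolution:
    """NNLS deconvolution model of a cfDNA mixture against an atlas."""

    def __init__(self, atlas: Atlas, config: DeconvolutionConfig | None = None):
        if atlas.n_markers == 0:
            raise ValueError("atlas has no markers")
        self.atlas = atlas
        self.config = config or atlas.config

    def fit(self, mixture: FragmentCollection) -> DeconvolutionResults:
        starts, ends = self.atlas.marker_intervals()
        counts = uxm_counts(mixture, starts, ends, self.config)
        total = counts.sum(axis=1)
        covered = total >= self.config.min_fragments_per_marker
        if not covered.any():
            raise ValueError("no informative markers covered by the mixture")
        a = self.atlas.frame.to_numpy(dtype=np.float64)[covered]
        b = counts[covered, U] / total[covered]
        x, rnorm = nnls(a, b)
        s = x.sum()
        if s <= 0:
            logger.warning("NNLS returned the zero vector; proportions undefined")
            props = np.zeros_like(x)
        else:
            props = x / s
        cts = self.atlas.cell_types
        return DeconvolutionResults(
            proportions=pd.Series(props, index=cts, name="proportion"),
            residual=float(rnorm),
            n_markers_used=int(covered.sum()),
            n_fragments_used=int(total[covered].sum()),
            raw_coefficients=pd.Series(x, index=cts, name="nnls_x"),
        )


def deconvolve(
    mixture: FragmentCollection,
    atlas: Atlas,
    config: DeconvolutionConfig | None = None,
) -> DeconvolutionResults:
    """Functional wrapper around :class:`MethylationDeconvolution`."""
    return MethylationDeconvolution(atlas, config).fit(mixture)
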