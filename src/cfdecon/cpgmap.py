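"""Ordered universe of CpG sites.

All fragment and block coordinates in this package are expressed as indices
into a :class:`CpGMap`: the genome-wide, 0-based ordering of CpG sites.
Genomic base-pair positions are carried alongside so that block spans can be
bounded in bp and results written as BED-like intervals. The 0-based/1-based
shift for on-disk PAT records happens only in :mod:`cfdecon.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CpGMap"]


@dataclass(frozen=True)
class CpGMap:
    """Immutable map between CpG index and genomic coordinate.

    Parameters
    ----------
    chroms
        Chromosome labels, in genome order.
    chrom_offsets
        Array of length ``len(chroms) + 1``; CpG indices of chromosome
        ``i`` are ``range(chrom_offsets[i], chrom_offsets[i + 1])``.
    positions
        Base-pair position (0-based) of every CpG, strictly increasing
        within each chromosome.
    """

    chroms: tuple[str, ...]
    chrom_offsets: np.ndarray
    positions: np.ndarray
    _label_to_idx: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        offsets = np.asarray(self.chrom_offsets, dtype=np.int64)
        positions = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "chrom_offsets", offsets)
        object.__setattr__(self, "positions", positions)
        if len(self.chroms) == 0 or offsets[0] != 0 or offsets[-1] != positions.size:
            raise ValueError("chrom_offsets must start at 0 and end at n_cpgs")
        if np.any(np.diff(offsets) < 0):
            raise ValueError("chrom_offsets must be non-decreasing")
        for i in range(len(self.chroms)):
            lo, hi = offsets[i], offsets[i + 1]
            if hi - lo > 1 and np.any(np.diff(positions[lo:hi]) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on {self.chroms[i]}"
                )
        object.__setattr__(
            self, "_label_to_idx", {c: i for i, c in enumerate(self.chroms)}
        )

    @property
    def n_cpgs(self) -> int:
        return int(self.positions.size)

    def chrom_index_of(self, cpg_index: np.ndarray | int) -> np.ndarray | int:
        """Chromosome number(s) for CpG index/indices."""
        return np.searchsorted(self.chrom_offsets, cpg_index, side="right") - 1

    def chrom_of(self, cpg_index: int) -> str:
        return self.chroms[int(self.chrom_index_of(cpg_index))]

    def chrom_bounds(self, chrom: str) -> tuple[int, int]:
        """Half-open CpG index interval of a chromosome."""
        i = self._label_to_idx[chrom]
        return int(self.chrom_offsets[i]), int(self.chrom_offsets[i + 1])

    def coord(self, cpg_index: int) -> tuple[str, int]:
        return self.chrom_of(cpg_index), int(self.positions[cpg_index])

    def __len__(self) -> int:
        return self.n_cpgs
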