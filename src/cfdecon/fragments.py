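"""Fragment-level methylation observations (PAT records in memory).

A :class:`MethylationFragment` is one sequencing-read-level observation: the
consecutive CpG methylation calls of a cfDNA/WGBS fragment plus a
multiplicity count. A :class:`FragmentCollection` stores many of them
columnarly (numpy arrays) so that millions of calls can be tallied without a
Python loop, while still iterating as plain fragment records.

Call encoding: 0 = unmethylated, 1 = methylated, 2 = missing ('.').
"""

from __future__ import annotations

from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "UNMETH",
    "METH",
    "MISSING",
    "MethylationFragment",
    "FragmentCollection",
]

UNMETH: int = 0
METH: int = 1
MISSING: int = 2


class MethylationFragment(NamedTuple):
    """One fragment: consecutive CpG calls starting at ``start_cpg``."""

    chrom: str
    start_cpg: int
    pattern: tuple[int, ...]
    count: int = 1

    @property
    def n_meth(self) -> int:
        return sum(1 for c in self.pattern if c == METH)

    @property
    def n_informative(self) -> int:
        return sum(1 for c in self.pattern if c != MISSING)


class FragmentCollection:
    """Columnar multiset of methylation fragments.

    Parameters
    ----------
    chroms
        Chromosome label per fragment (category codes + categories).
    starts, lengths, counts
        Per-fragment arrays: first covered CpG index (0-based, global),
        number of CpGs covered, multiplicity (>= 1).
    calls
        Flattened call codes; fragment ``i`` owns
        ``calls[offsets[i]:offsets[i + 1]]``.
    provenance
        Free-text label of the generating sample / mixture.
    seed
        RNG seed used to generate the collection, if any.
    origin
        Optional per-fragment int8 tag (used by mixing to track which pool
        a fragment came from; internal validation only).
    """

    def __init__(
        self,
        chrom_codes: np.ndarray,
        chrom_categories: Sequence[str],
        starts: np.ndarray,
        lengths: np.ndarray,
        calls: np.ndarray,
        counts: np.ndarray | None = None,
        provenance: str = "",
        seed: int | None = None,
        origin: np.ndarray | None = None,
    ) -> None:
        self.chrom_codes = np.asarray(chrom_codes, dtype=np.int32)
        self.chrom_categories = tuple(chrom_categories)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self.calls = np.asarray(calls, dtype=np.uint8)
        n = self.starts.size
        if counts is None:
            counts = np.ones(n, dtype=np.int64)
        self.counts = np.asarray(counts, dtype=np.int64)
        self.provenance = provenance
        self.seed = seed
        self.origin = None if origin is None else np.asarray(origin, dtype=np.int8)
        if not (self.chrom_codes.size == self.lengths.size == self.counts.size == n):
            raise ValueError("per-fragment arrays must share one length")
        if n and (self.lengths.min() < 1):
            raise ValueError("fragment pattern length must be >= 1")
        if n and (self.counts.min() < 1):
            raise ValueError("fragment count must be >= 1")
        if int(self.lengths.sum()) != self.calls.size:
            raise ValueError("calls array does not match summed lengths")
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths)))

    # -- construction ------------------------------------------------------

    @classmethod
    def from_fragments(
        cls,
        fragments: Iterable[MethylationFragment],
        provenance: str = "",
        seed: int | None = None,
    ) -> "FragmentCollection":
        frags = list(fragments)
        cats: list[str] = []
        cat_idx: dict[str, int] = {}
        codes = np.empty(len(frags), dtype=np.int32)
        for i, f in enumerate(frags):
            if f.chrom not in cat_idx:
                cat_idx[f.chrom] = len(cats)
                cats.append(f.chrom)
            codes[i] = cat_idx[f.chrom]
        starts = np.array([f.start_cpg for f in frags], dtype=np.int64)
        lengths = np.array([len(f.pattern) for f in frags], dtype=np.int64)
        counts = np.array([f.count for f in frags], dtype=np.int64)
        calls = (
            np.concatenate([np.array(f.pattern, dtype=np.uint8) for f in frags])
            if frags
            else np.empty(0, dtype=np.uint8)
        )
        return cls(codes, cats, starts, lengths, calls, counts, provenance, seed)

    @classmethod
    def empty(cls, provenance: str = "") -> "FragmentCollection":
        z = np.empty(0, dtype=np.int64)
        return cls(z, (), z, z, np.empty(0, dtype=np.uint8), z, provenance)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_fragments(self) -> int:
        return int(self.starts.size)

    @property
    def n_records(self) -> int:
        """Total fragments counting multiplicity."""
        return int(self.counts.sum()) if self.n_fragments else 0

    def total_calls(self, include_missing: bool = False) -> int:
        """Number of CpG calls, weighted by fragment multiplicity."""
        if self.n_fragments == 0:
            return 0
        if include_missing:
            return int((self.lengths * self.counts).sum())
        per_call_count = np.repeat(self.counts, self.lengths)
        return int(per_call_count[self.calls != MISSING].sum())

    def call_cpg_indices(self) -> np.ndarray:
        """Global CpG index of every stored call (unweighted by count)."""
        if self.n_fragments == 0:
            return np.empty(0, dtype=np.int64)
        total = self.calls.size
        base = np.repeat(self.starts, self.lengths)
        within = np.arange(total, dtype=np.int64) - np.repeat(
            self.offsets[:-1], self.lengths
        )
        return base + within

    def fragment(self, i: int) -> MethylationFragment:
        lo, hi = self.offsets[i], self.offsets[i + 1]
        return MethylationFragment(
            self.chrom_categories[self.chrom_codes[i]],
            int(self.starts[i]),
            tuple(int(c) for c in self.calls[lo:hi]),
            int(self.counts[i]),
        )

    def __iter__(self) -> Iterator[MethylationFragment]:
        for i in range(self.n_fragments):
            yield self.fragment(i)

    def __len__(self) -> int:
        return self.n_fragments

    # -- manipulation ------------------------------------------------------

    def take(self, indices: np.ndarray, provenance: str | None = None,
             counts: np.ndarray | None = None) -> "FragmentCollection":
        """New collection from (possibly repeated) fragment indices."""
        idx = np.asarray(indices, dtype=np.int64)
        lens = self.lengths[idx]
        # gather flattened calls of each selected fragment
        if idx.size:
            flat = np.repeat(self.offsets[idx], lens) + (
                np.arange(int(lens.sum()), dtype=np.int64)
                - np.repeat(np.concatenate(([0], np.cumsum(lens)))[:-1], lens)
            )
            calls = self.calls[flat]
        else:
            calls = np.empty(0, dtype=np.uint8)
        return FragmentCollection(
            self.chrom_codes[idx],
            self.chrom_categories,
            self.starts[idx],
            lens,
            calls,
            self.counts[idx] if counts is None else counts,
            provenance if provenance is not None else self.provenance,
            self.seed,
            None if self.origin is None else self.origin[idx],
        )

    @staticmethod
    def concatenate(
        collections: Sequence["FragmentCollection"], provenance: str = ""
    ) -> "FragmentCollection":
        collections = [c for c in collections if c.n_fragments > 0]
        if not collections:
            return FragmentCollection.empty(provenance)
        cats: list[str] = []
        cat_idx: dict[str, int] = {}
        code_arrays = []
        for c in collections:
            remap = np.empty(max(len(c.chrom_categories), 1), dtype=np.int32)
            for j, label in enumerate(c.chrom_categories):
                if label not in cat_idx:
                    cat_idx[label] = len(cats)
                    cats.append(label)
                remap[j] = cat_idx[label]
            code_arrays.append(remap[c.chrom_codes])
        origin = None
        if all(c.origin is not None for c in collections):
            origin = np.concatenate([c.origin for c in collections])
        return FragmentCollection(
            np.concatenate(code_arrays),
            cats,
            np.concatenate([c.starts for c in collections]),
            np.concatenate([c.lengths for c in collections]),
            np.concatenate([c.calls for c in collections]),
            np.concatenate([c.counts for c in collections]),
            provenance,
            None,
            origin,
        )

    def sorted(self) -> "FragmentCollection":
        """Deterministic sort by (chromosome label, start, pattern)."""
        if self.n_fragments == 0:
            return self
        labels = np.array(
            [self.chrom_categories[c] for c in self.chrom_codes], dtype=object
        )
        pats = np.array(
            [
                bytes(self.calls[self.offsets[i]: self.offsets[i + 1]])
                for i in range(self.n_fragments)
            ],
            dtype=object,
        )
        order = np.lexsort((pats, self.starts, labels))
        return self.take(order)
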