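"""On-disk formats: PAT fragment files, block/marker BED-like TSV, atlas TSV.

The PAT dialect is a 4-column tab-separated file: chromosome, 1-based start
CpG index, pattern over {C = methylated, T = unmethylated, . = missing},
multiplicity count. All coordinate shifts between the 1-based disk convention
and the package's 0-based internal CpG indices happen here and nowhere else.
Writers emit deterministically sorted output so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .cpgmap import CpGMap
from .fragments import METH, MISSING, UNMETH, FragmentCollection

__all__ = [
    "read_pat",
    "write_pat",
    "read_cpg_map",
    "write_cpg_map",
    "write_ledger_bed",
]

_CHAR_TO_CALL = {"C": METH, "T": UNMETH, ".": MISSING}
_CALL_TO_CHAR = {METH: "C", UNMETH: "T", MISSING: "."}


class PatFormatError(ValueError):
    """Malformed PAT input, reported with its line number."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_pat(path, provenance: str | None = None) -> FragmentCollection:
    """Read a PAT file into a :class:`FragmentCollection`.

    Disk start indices are 1-based and are shifted to the 0-based internal
    convention. Empty files give an empty collection; malformed lines raise
    :class:`PatFormatError` naming the line.
    """
    chroms: list[str] = []
    starts: list[int] = []
    patterns: list[bytes] = []
    counts: list[int] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise PatFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, start_s, pattern, count_s = fields
            try:
                start = int(start_s)
                count = int(count_s)
            except ValueError as exc:
                raise PatFormatError(
                    f"{path}:{lineno}: non-integer start or count"
                ) from exc
            if start < 1:
                raise PatFormatError(f"{path}:{lineno}: start must be >= 1")
            if count < 1:
                raise PatFormatError(f"{path}:{lineno}: count must be >= 1")
            if not pattern or any(c not in _CHAR_TO_CALL for c in pattern):
                raise PatFormatError(
                    f"{path}:{lineno}: pattern must be non-empty over C/T/."
                )
            chroms.append(chrom)
            starts.append(start - 1)  # 1-based disk -> 0-based internal
            patterns.append(
                bytes(_CHAR_TO_CALL[c] for c in pattern)
            )
            counts.append(count)

    if not starts:
        return FragmentCollection.empty(provenance or str(path))
    cats: list[str] = []
    cat_idx: dict[str, int] = {}
    codes = np.empty(len(chroms), dtype=np.int32)
    for i, c in enumerate(chroms):
        if c not in cat_idx:
            cat_idx[c] = len(cats)
            cats.append(c)
        codes[i] = cat_idx[c]
    lengths = np.array([len(p) for p in patterns], dtype=np.int64)
    calls = np.frombuffer(b"".join(patterns), dtype=np.uint8).copy()
    return FragmentCollection(
        codes,
        cats,
        np.array(starts, dtype=np.int64),
        lengths,
        calls,
        np.array(counts, dtype=np.int64),
        provenance or str(path),
    )


def write_pat(
    collection: FragmentCollection, path, merge_duplicates: bool = False
) -> None:
    """Write a PAT file: sorted, 0->1-based shift, deterministic bytes.

    With ``merge_duplicates`` records identical in (chromosome, start,
    pattern) are merged by summing counts (multiset semantics).
    """
    srt = collection.sorted()
    with _open_text(path, "wt") as fh:
        prev = None  # (chrom, start, pattern) of pending record
        pending_count = 0

        def _flush():
            if prev is not None:
                chrom, start, pattern = prev
                fh.write(f"{chrom}\t{start + 1}\t{pattern}\t{pending_count}\n")

        for frag in srt:
            pattern = "".join(_CALL_TO_CHAR[c] for c in frag.pattern)
            key = (frag.chrom, frag.start_cpg, pattern)
            if merge_duplicates and key == prev:
                pending_count += frag.count
            else:
                _flush()
                prev = key
                pending_count = frag.count
        _flush()


def write_cpg_map(cmap: CpGMap, path) -> None:
    """Persist a CpG map as TSV (chrom, position, cpg_index 1-based)."""
    chrom_per_cpg = np.repeat(
        np.array(cmap.chroms, dtype=object), np.diff(cmap.chrom_offsets)
    )
    pd.DataFrame(
        {
            "chrom": chrom_per_cpg,
            "position": cmap.positions,
            "cpg_index": np.arange(1, cmap.n_cpgs + 1),
        }
    ).to_csv(path, sep="\t", index=False)


def read_cpg_map(path) -> CpGMap:
    df = pd.read_csv(path, sep="\t")
    chroms = list(dict.fromkeys(df["chrom"]))  # unique, order preserved
    sizes = [int((df["chrom"] == c).sum()) for c in chroms]
    offsets = np.array([0] + list(np.cumsum(sizes)), dtype=np.int64)
    return CpGMap(
        tuple(chroms), offsets, df["position"].to_numpy(dtype=np.int64)
    )


def write_ledger_bed(ledger: pd.DataFrame, path) -> None:
    """Ground-truth planted blocks as BED with a cell-type name column."""
    cols = ["chrom", "start_bp", "end_bp", "cell_type", "start_cpg", "end_cpg"]
    ledger[cols].to_csv(path, sep="\t", index=False, header=True)
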