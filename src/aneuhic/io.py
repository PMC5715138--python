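"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: two-column ``chrom.sizes``, BED3/BED6, bedGraph,
upper-triangle COO contact text (``chromA startA chromB startB count``,
tab-separated) and dense TSV matrices. All coordinates are 0-based
half-open. Text writers use 6 significant digits.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    AneuhicError,
    BinMap,
    ContactMatrix,
    GenomeDef,
    Interval,
    ScalarTrack,
)

_FMT = "%.6g"


def _fmt(x: float) -> str:
    return _FMT % x


# -- genome / chrom.sizes ----------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeDef:
    names: list[str] = []
    lengths: list[int] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise AneuhicError(f"{path}:{ln}: expected 'chrom<TAB>length'")
        names.append(parts[0])
        lengths.append(int(parts[1]))
    return GenomeDef(tuple(names), tuple(lengths))


def write_chrom_sizes(genome: GenomeDef, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


# -- COO contact text --------------------------------------------------------

def read_contacts_coo(path: str | Path, binmap: BinMap) -> ContactMatrix:
    """Read ``chromA startA chromB startB count`` rows into a symmetric
    matrix. Starts must align to bin starts; violations report the line
    number."""
    n = binmap.n_bins
    values = np.zeros((n, n))
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise AneuhicError(f"{path}:{ln}: expected 5 tab-separated fields")
        ca, sa, cb, sb, count = parts
        try:
            i = binmap.bin_index(ca, int(sa))
            j = binmap.bin_index(cb, int(sb))
        except AneuhicError as exc:
            raise AneuhicError(f"{path}:{ln}: {exc}") from None
        v = float(count)
        if v < 0:
            raise AneuhicError(f"{path}:{ln}: negative count")
        values[i, j] += v
        if i != j:
            values[j, i] += v
    return ContactMatrix(binmap, values, "raw")


def write_contacts_coo(matrix: ContactMatrix, path: str | Path) -> None:
    """Write the nonzero upper triangle (including the diagonal)."""
    bm = matrix.binmap
    iu, ju = np.nonzero(np.triu(matrix.values))
    with open(path, "w") as fh:
        for i, j in zip(iu, ju):
            fh.write(
                f"{bm.chrom_name(i)}\t{int(bm.starts[i])}\t"
                f"{bm.chrom_name(j)}\t{int(bm.starts[j])}\t"
                f"{_fmt(matrix.values[i, j])}\n"
            )


# -- dense TSV matrix --------------------------------------------------------

def write_matrix_tsv(matrix: ContactMatrix, path: str | Path) -> None:
    bm = matrix.binmap
    labels = [f"{bm.chrom_name(i)}:{int(bm.starts[i])}" for i in range(bm.n_bins)]
    df = pd.DataFrame(matrix.values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format=_FMT)


def read_matrix_tsv(path: str | Path, binmap: BinMap, kind: str = "raw") -> ContactMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape != (binmap.n_bins, binmap.n_bins):
        raise AneuhicError(f"{path}: matrix shape {df.shape} does not match binmap")
    return ContactMatrix(binmap, df.to_numpy(dtype=float), kind)


# -- bedGraph ----------------------------------------------------------------

def read_track_bedgraph(path: str | Path, binmap: BinMap, name: str = "track") -> ScalarTrack:
    """Read a bedGraph into a per-bin track.

    Each interval must cover whole bins; two intervals mapping a value
    onto the same bin is an error.
    """
    vals = np.full(binmap.n_bins, np.nan)
    seen = np.zeros(binmap.n_bins, dtype=bool)
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise AneuhicError(f"{path}:{ln}: expected 4 bedGraph fields")
        chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if end <= start:
            raise AneuhicError(f"{path}:{ln}: interval end <= start")
        try:
            lo = binmap.bin_index(chrom, start)
        except AneuhicError as exc:
            raise AneuhicError(f"{path}:{ln}: {exc}") from None
        pos = start
        i = lo
        while pos < end:
            if i >= binmap.n_bins or binmap.chrom_name(i) != chrom:
                raise AneuhicError(f"{path}:{ln}: interval extends past chromosome")
            if seen[i]:
                raise AneuhicError(
                    f"{path}:{ln}: overlapping intervals map to bin "
                    f"{chrom}:{int(binmap.starts[i])}"
                )
            vals[i] = value
            seen[i] = True
            pos = int(binmap.ends[i])
            i += 1
    return ScalarTrack(binmap, vals, name)


def write_track_bedgraph(track: ScalarTrack, path: str | Path) -> None:
    bm = track.binmap
    with open(path, "w") as fh:
        for i in range(bm.n_bins):
            v = track.values[i]
            if np.isfinite(v):
                fh.write(
                    f"{bm.chrom_name(i)}\t{int(bm.starts[i])}\t"
                    f"{int(bm.ends[i])}\t{_fmt(v)}\n"
                )


# -- BED ---------------------------------------------------------------------

def read_intervals_bed(
    path: str | Path, genome: GenomeDef | None = None
) -> list[tuple]:
    """Read BED3/BED6 intervals, returned sorted by (chrom order, start).

    Chromosome order follows ``genome`` when given, else lexicographic.
    Rows keep a ``name`` field when present.
    """
    out: list[tuple] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise AneuhicError(f"{path}:{ln}: expected >=3 BED fields")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if end <= start:
            raise AneuhicError(f"{path}:{ln}: interval end <= start")
        if genome is not None and chrom not in genome.chrom_names:
            raise AneuhicError(f"{path}:{ln}: unknown chromosome {chrom!r}")
        if len(parts) >= 4:
            out.append((chrom, start, end, parts[3]))
        else:
            out.append((chrom, start, end))

    def key(iv: tuple):
        order = genome.chrom_order(iv[0]) if genome is not None else iv[0]
        return (order, iv[1], iv[2])

    return sorted(out, key=key)


def write_intervals_bed(intervals: Iterable[Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")
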