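"""Genomic coordinate bookkeeping and in-memory containers.

Everything downstream (normalization, CNV calling, TAD and compartment
analysis) is indexed against a :class:`BinMap`: an ordered tiling of a
genome into fixed-resolution bins with 0-based half-open coordinates.
Bins that overlap declared assembly gaps (telomere/centromere stand-ins)
or that have zero marginal coverage in a raw contact matrix are *masked*
and excluded from normalization, insulation, PCA and regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

Interval = tuple[str, int, int]

VALID_MATRIX_KINDS = ("raw", "expected", "ice", "covnorm")


class AneuhicError(Exception):
    """Base class for user-facing errors raised by this package."""


@dataclass(frozen=True)
class GenomeDef:
    """A genome as an ordered set of named chromosomes with gap intervals.

    Parameters
    ----------
    chrom_names
        Ordered chromosome identifiers; must be unique.
    chrom_lengths
        Length in base pairs of each chromosome (same order); all > 0.
    gap_intervals
        ``(chrom, start, end)`` regions (0-based half-open) treated as
        unassayable gaps; bins overlapping them by >= 1 bp are masked.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    gap_intervals: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise AneuhicError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise AneuhicError("chromosome names must be unique")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise AneuhicError(f"chromosome {name} has non-positive length")
        lengths = dict(zip(self.chrom_names, self.chrom_lengths))
        for chrom, start, end in self.gap_intervals:
            if chrom not in lengths:
                raise AneuhicError(f"gap on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise AneuhicError(
                    f"gap {chrom}:{start}-{end} outside chromosome bounds"
                )

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    def chrom_length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise AneuhicError(f"unknown chromosome {chrom!r}") from None

    def chrom_order(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise AneuhicError(f"unknown chromosome {chrom!r}") from None


@dataclass
class BinMap:
    """Fixed-resolution tiling of a genome into ordered bins.

    Bins tile each chromosome without overlap; the last bin of a
    chromosome may be shorter than ``resolution``. The global bin index
    is determined by chromosome order and start coordinate and is stable
    across reconstructions from the same :class:`GenomeDef`.
    """

    genome: GenomeDef
    resolution: int
    chrom_ids: np.ndarray  # int index into genome.chrom_names, per bin
    starts: np.ndarray
    ends: np.ndarray
    masked: np.ndarray  # bool per bin

    def __post_init__(self) -> None:
        n = len(self.starts)
        if not (len(self.ends) == len(self.chrom_ids) == len(self.masked) == n):
            raise AneuhicError("BinMap arrays have inconsistent lengths")
        self._offsets: dict[str, tuple[int, int]] = {}
        for ci, name in enumerate(self.genome.chrom_names):
            idx = np.flatnonzero(self.chrom_ids == ci)
            if idx.size:
                self._offsets[name] = (int(idx[0]), int(idx[-1]) + 1)
        self._index: dict[tuple[str, int], int] = {
            (self.genome.chrom_names[ci], int(s)): i
            for i, (ci, s) in enumerate(zip(self.chrom_ids, self.starts))
        }

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Half-open global-index range of the bins of ``chrom``."""
        if chrom not in self._offsets:
            raise AneuhicError(f"unknown chromosome {chrom!r}")
        return self._offsets[chrom]

    def bin_index(self, chrom: str, start: int) -> int:
        """Global index of the bin starting exactly at ``start``."""
        key = (chrom, int(start))
        if key not in self._index:
            raise AneuhicError(
                f"{chrom}:{start} is not a bin start at resolution {self.resolution}"
            )
        return self._index[key]

    def bin_at(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing position ``pos``."""
        lo, hi = self.chrom_range(chrom)
        length = self.genome.chrom_length(chrom)
        if not (0 <= pos < length):
            raise AneuhicError(f"position {chrom}:{pos} outside chromosome")
        return lo + min(int(pos) // self.resolution, hi - lo - 1)

    def chrom_name(self, i: int) -> str:
        return self.genome.chrom_names[int(self.chrom_ids[i])]

    def bin_interval(self, i: int) -> Interval:
        return (self.chrom_name(i), int(self.starts[i]), int(self.ends[i]))

    def copy(self) -> "BinMap":
        return BinMap(
            self.genome,
            self.resolution,
            self.chrom_ids.copy(),
            self.starts.copy(),
            self.ends.copy(),
            self.masked.copy(),
        )


def make_binmap(genome: GenomeDef, resolution: int) -> BinMap:
    """Tile ``genome`` into bins of ``resolution`` base pairs.

    The last bin of each chromosome may be short. Bins overlapping any
    gap interval by at least one base pair are masked.
    """
    if resolution < 1:
        raise AneuhicError("resolution must be >= 1")
    if resolution > max(genome.chrom_lengths):
        raise AneuhicError("resolution larger than the longest chromosome")
    chrom_ids: list[int] = []
    starts: list[int] = []
    ends: list[int] = []
    for ci, (name, length) in enumerate(zip(genome.chrom_names, genome.chrom_lengths)):
        for s in range(0, length, resolution):
            chrom_ids.append(ci)
            starts.append(s)
            ends.append(min(s + resolution, length))
    chrom_arr = np.asarray(chrom_ids, dtype=np.int32)
    start_arr = np.asarray(starts, dtype=np.int64)
    end_arr = np.asarray(ends, dtype=np.int64)
    masked = np.zeros(len(starts), dtype=bool)
    for chrom, gs, ge in genome.gap_intervals:
        ci = genome.chrom_order(chrom)
        overlap = (chrom_arr == ci) & (start_arr < ge) & (end_arr > gs)
        masked |= overlap
    return BinMap(genome, resolution, chrom_arr, start_arr, end_arr, masked)


@dataclass
class ContactMatrix:
    """Symmetric nonnegative contact matrix over a :class:`BinMap`.

    ``kind`` records provenance: ``raw`` counts, ``expected`` (noise-free
    model mean), ``ice`` or ``covnorm`` normalized values.
    """

    binmap: BinMap
    values: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.binmap.n_bins, self.binmap.n_bins):
            raise AneuhicError("matrix shape does not match binmap")
        if self.kind not in VALID_MATRIX_KINDS:
            raise AneuhicError(f"unknown matrix kind {self.kind!r}")
        if np.nanmin(v) < -1e-9:
            raise AneuhicError("contact matrix has negative entries")
        if not np.allclose(v, v.T, rtol=1e-8, atol=1e-8, equal_nan=True):
            raise AneuhicError("contact matrix is not symmetric")
        self.values = v

    def chrom_view(self, chrom: str) -> np.ndarray:
        """Read-only view of the cis block of ``chrom``."""
        lo, hi = self.binmap.chrom_range(chrom)
        view = self.values[lo:hi, lo:hi]
        view.flags.writeable = False
        return view

    def pair_view(self, chrom_a: str, chrom_b: str) -> np.ndarray:
        lo_a, hi_a = self.binmap.chrom_range(chrom_a)
        lo_b, hi_b = self.binmap.chrom_range(chrom_b)
        view = self.values[lo_a:hi_a, lo_b:hi_b]
        view.flags.writeable = False
        return view

    def marginals(self) -> np.ndarray:
        return self.values.sum(axis=1)


@dataclass
class ScalarTrack:
    """One value per bin (NaN marks missing), with a descriptive name."""

    binmap: BinMap
    values: np.ndarray
    name: str = "track"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.binmap.n_bins,):
            raise AneuhicError("track length does not match binmap")
        self.values = v

    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def mask_zero_coverage(matrix: ContactMatrix) -> ContactMatrix:
    """Return a matrix whose binmap additionally masks zero-coverage bins.

    Masked rows/columns are zeroed so downstream code can rely on the
    invariant that masked bins carry no signal.
    """
    bm = matrix.binmap.copy()
    cov = matrix.values.sum(axis=1)
    bm.masked |= cov <= 0
    vals = matrix.values.copy()
    vals[bm.masked, :] = 0.0
    vals[:, bm.masked] = 0.0
    return ContactMatrix(bm, vals, matrix.kind)


def coarsen_matrix(matrix: ContactMatrix, coarse_resolution: int) -> ContactMatrix:
    """Sum fine-bin counts into bins of ``coarse_resolution``.

    A fine bin is assigned to the coarse bin containing its start (so
    coarse resolutions need not be exact multiples of the fine one).
    A coarse bin is masked if it overlaps a declared gap or if all its
    constituent fine bins are masked.
    """
    fine = matrix.binmap
    if coarse_resolution < fine.resolution:
        raise AneuhicError("coarse resolution must be >= the fine resolution")
    coarse = make_binmap(fine.genome, coarse_resolution)
    # map each fine bin to its coarse bin
    fmap = np.empty(fine.n_bins, dtype=np.int64)
    for i in range(fine.n_bins):
        chrom = fine.chrom_name(i)
        fmap[i] = coarse.bin_at(chrom, int(fine.starts[i]))
    n = coarse.n_bins
    # accumulate with two passes of np.add.at on the row-compressed matrix
    tmp = np.zeros((n, fine.n_bins))
    np.add.at(tmp, fmap, matrix.values)
    out = np.zeros((n, n))
    np.add.at(out.T, fmap, tmp.T)
    all_fine_masked = np.ones(n, dtype=bool)
    np.logical_and.at(all_fine_masked, fmap, fine.masked)
    coarse.masked |= all_fine_masked
    out[coarse.masked, :] = 0.0
    out[:, coarse.masked] = 0.0
    return ContactMatrix(coarse, out, matrix.kind)


def paint_track(
    binmap: BinMap, intervals: Iterable[tuple[str, int, int, float]], name: str
) -> ScalarTrack:
    """Paint interval values onto bins (a bin takes the value of the
    interval containing its start; NaN where no interval applies)."""
    vals = np.full(binmap.n_bins, np.nan)
    for chrom, start, end, value in intervals:
        lo, hi = binmap.chrom_range(chrom)
        sel = (binmap.starts[lo:hi] >= start) & (binmap.starts[lo:hi] < end)
        vals[lo:hi][sel] = value
    return ScalarTrack(binmap, vals, name)
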