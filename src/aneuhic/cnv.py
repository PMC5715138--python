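"""Integer copy-number estimation from binned depth or Hi-C coverage.

The caller is deliberately transparent: median-normalize depth to the
given baseline ploidy, smooth with a centered running median, round to
the nearest integer (ties to even), then absorb runs shorter than
``min_block_bins`` into the flanking block with the closer raw copy
number. The same caller serves WGS-style depth tracks and Hi-C marginal
coverage, so the two estimates are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AneuhicError, BinMap, ContactMatrix, ScalarTrack

CNVBlock = tuple[str, int, int, int]  # chrom, start, end, copy number
Breakpoint = tuple[str, int]  # boundary between adjacent blocks of differing CN


@dataclass
class CopyNumberProfile:
    """Per-bin integer copy numbers (defined at unmasked bins)."""

    binmap: BinMap
    copy_number: np.ndarray  # int per bin; content at masked bins is undefined
    source: str = "wgs"  # "wgs" | "hic"
    ploidy: int = 2

    def __post_init__(self) -> None:
        cn = np.asarray(self.copy_number)
        if cn.shape != (self.binmap.n_bins,):
            raise AneuhicError("copy number length does not match binmap")
        if cn[~self.binmap.masked].min(initial=0) < 0:
            raise AneuhicError("copy numbers must be >= 0")
        self.copy_number = cn.astype(np.int64)


def hic_coverage_track(matrix: ContactMatrix) -> ScalarTrack:
    """Per-bin marginal sum of a raw matrix — the Hi-C depth stand-in."""
    cov = matrix.values.sum(axis=1)
    cov[matrix.binmap.masked] = np.nan
    return ScalarTrack(matrix.binmap, cov, "coverage")


def call_cnv_from_depth(
    depth: ScalarTrack,
    ploidy: int,
    min_block_bins: int = 5,
    smooth_window: int = 5,
    source: str = "wgs",
) -> CopyNumberProfile:
    """Estimate per-bin integer copy numbers from a depth track.

    raw CN = ploidy * depth / median(depth over defined bins), smoothed
    per chromosome with a centered running median of ``smooth_window``
    bins, rounded half-to-even, with short runs absorbed. The result is
    invariant to rescaling the depth by any positive constant.
    """
    binmap = depth.binmap
    vals = depth.values
    usable = depth.defined() & ~binmap.masked
    if not usable.any() or np.nansum(vals[usable]) == 0:
        raise AneuhicError("all-zero depth track: cannot call copy number")
    med = float(np.median(vals[usable]))
    if med <= 0:
        raise AneuhicError("genome-wide median depth is zero")
    raw = ploidy * vals / med

    cn = np.zeros(binmap.n_bins, dtype=np.int64)
    for chrom in binmap.genome.chrom_names:
        lo, hi = binmap.chrom_range(chrom)
        use = usable[lo:hi]
        if not use.any():
            continue
        sub = raw[lo:hi][use]
        smooth = (
            pd.Series(sub)
            .rolling(smooth_window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        rounded = np.rint(smooth).astype(np.int64)  # half-to-even
        rounded = np.clip(rounded, 0, None)
        rounded = _absorb_short_runs(rounded, sub, min_block_bins)
        cn_chr = np.zeros(hi - lo, dtype=np.int64)
        cn_chr[use] = rounded
        cn[lo:hi] = cn_chr
    return CopyNumberProfile(binmap, cn, source=source, ploidy=ploidy)


def _absorb_short_runs(cn: np.ndarray, raw: np.ndarray, min_bins: int) -> np.ndarray:
    """Merge runs shorter than ``min_bins`` into the flanking run whose
    copy number is closer to the run's mean raw value."""
    cn = cn.copy()
    while True:
        runs = _runs(cn)
        if len(runs) <= 1:
            return cn
        short = [
            (e - s, k) for k, (s, e, _v) in enumerate(runs) if e - s < min_bins
        ]
        if not short:
            return cn
        _, k = min(short)
        s, e, _v = runs[k]
        mean_raw = float(raw[s:e].mean())
        candidates = []
        if k > 0:
            candidates.append((abs(runs[k - 1][2] - mean_raw), runs[k - 1][2]))
        if k + 1 < len(runs):
            candidates.append((abs(runs[k + 1][2] - mean_raw), runs[k + 1][2]))
        cn[s:e] = min(candidates)[1]


def _runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal values as (start, end, value)."""
    out = []
    s = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[s]:
            out.append((s, i, int(values[s])))
            s = i
    return out


def blocks_and_breakpoints(
    profile: CopyNumberProfile,
) -> tuple[list[CNVBlock], list[Breakpoint]]:
    """Maximal same-CN runs over unmasked bins and their shared edges.

    Blocks span the unmasked extent of each chromosome; masked interior
    bins do not split a block when the copy number matches on both
    sides. Chromosome ends are not breakpoints; a breakpoint sits at
    the start coordinate of the downstream block.
    """
    binmap = profile.binmap
    blocks: list[CNVBlock] = []
    breakpoints: list[Breakpoint] = []
    for chrom in binmap.genome.chrom_names:
        lo, hi = binmap.chrom_range(chrom)
        idx = np.arange(lo, hi)[~binmap.masked[lo:hi]]
        if idx.size == 0:
            continue
        cn = profile.copy_number[idx]
        s = 0
        for i in range(1, len(cn) + 1):
            if i == len(cn) or cn[i] != cn[s]:
                blocks.append(
                    (
                        chrom,
                        int(binmap.starts[idx[s]]),
                        int(binmap.ends[idx[i - 1]]),
                        int(cn[s]),
                    )
                )
                if i < len(cn):
                    breakpoints.append((chrom, int(binmap.starts[idx[i]])))
                s = i
    return blocks, breakpoints


def paint_profile(
    binmap: BinMap, blocks: list[CNVBlock], source: str = "wgs", ploidy: int = 2
) -> CopyNumberProfile:
    """Inverse of :func:`blocks_and_breakpoints`: paint blocks onto bins."""
    cn = np.zeros(binmap.n_bins, dtype=np.int64)
    for chrom, start, end, c in blocks:
        lo, hi = binmap.chrom_range(chrom)
        sel = (binmap.starts[lo:hi] >= start) & (binmap.starts[lo:hi] < end)
        cn[lo:hi][sel] = c
    return CopyNumberProfile(binmap, cn, source=source, ploidy=ploidy)


def correlate_cnv(a: CopyNumberProfile, b: CopyNumberProfile) -> float:
    """Pearson correlation of two profiles over co-defined bins."""
    use = ~a.binmap.masked & ~b.binmap.masked
    x = a.copy_number[use].astype(float)
    y = b.copy_number[use].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise AneuhicError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
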