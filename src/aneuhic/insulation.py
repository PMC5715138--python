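"""Insulation scores, TAD calling, and breakpoint-boundary association.

The insulation score of bin *i* is the mean contact signal in the
square window spanning bins (i-w..i-1) x (i+1..i+w), log2-ratioed to
its chromosome mean. Valleys of the score (zero-crossings of a
left/right delta vector from negative to positive) mark TAD
boundaries; domains are assembled between consecutive boundaries and
filtered by a minimum size and by overlap with assembly gaps.

The association analyses measure whether copy-number breakpoints sit
near TAD boundaries: nearest-boundary distances with a
location-randomized null (one-sided rank-sum test) and an averaged
insulation profile around site sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .core import AneuhicError, BinMap, ContactMatrix, ScalarTrack

Boundary = tuple[str, int]


@dataclass
class InsulationTrack(ScalarTrack):
    window_bp: int = 0
    delta_window_bp: int = 0


@dataclass
class TADSet:
    intervals: list[tuple[str, int, int]]
    boundaries: list[Boundary]
    source: str = ""

    def sizes(self) -> np.ndarray:
        return np.array([e - s for _c, s, e in self.intervals], dtype=float)


@dataclass
class SiteProfile:
    label: str
    offsets: np.ndarray  # bins, -F..+F
    means: np.ndarray
    n_sites: np.ndarray  # sites contributing per offset


def insulation_score(matrix: ContactMatrix, window_bp: int = 480_000) -> InsulationTrack:
    """Sliding square-window insulation score, log2-ratioed per chromosome.

    The score is missing where the window exceeds the chromosome, at
    masked bins, and where more than 50% of the window entries involve
    masked bins.
    """
    bm = matrix.binmap
    res = bm.resolution
    w = window_bp // res
    if w < 2:
        raise AneuhicError("insulation window must span at least 2 bins")
    un = (~bm.masked).astype(float)
    vals = np.full(bm.n_bins, np.nan)
    for chrom in bm.genome.chrom_names:
        lo, hi = bm.chrom_range(chrom)
        m = hi - lo
        M = matrix.values[lo:hi, lo:hi] * np.outer(un[lo:hi], un[lo:hi])
        C = np.outer(un[lo:hi], un[lo:hi])
        # integral images for O(1) rectangle sums
        S = np.zeros((m + 1, m + 1))
        S[1:, 1:] = np.cumsum(np.cumsum(M, axis=0), axis=1)
        N = np.zeros((m + 1, m + 1))
        N[1:, 1:] = np.cumsum(np.cumsum(C, axis=0), axis=1)

        def rect(T: np.ndarray, r0: int, r1: int, c0: int, c1: int) -> float:
            return T[r1, c1] - T[r0, c1] - T[r1, c0] + T[r0, c0]

        raw = np.full(m, np.nan)
        for i in range(m):
            if bm.masked[lo + i]:
                continue
            r0, r1 = i - w, i
            c0, c1 = i + 1, i + w + 1
            if r0 < 0 or c1 > m:
                continue
            n_def = rect(N, r0, r1, c0, c1)
            if n_def < 0.5 * w * w:
                continue
            raw[i] = rect(S, r0, r1, c0, c1) / n_def
        defined = np.isfinite(raw) & (raw > 0)
        if defined.any():
            mean_raw = raw[defined].mean()
            vals[lo:hi][defined] = np.log2(raw[defined] / mean_raw)
    track = InsulationTrack(bm, vals, "insulation")
    track.window_bp = window_bp
    return track


def _delta_vector(t: np.ndarray, d: int) -> np.ndarray:
    """mean(track over right delta-window) - mean(over left delta-window)."""
    m = len(t)
    delta = np.full(m, np.nan)
    for i in range(m):
        left = t[max(0, i - d) : i]
        right = t[i + 1 : min(m, i + d + 1)]
        left = left[np.isfinite(left)]
        right = right[np.isfinite(right)]
        if left.size == 0 or right.size == 0 or not np.isfinite(t[i]):
            continue
        delta[i] = right.mean() - left.mean()
    return delta


def call_boundaries(
    track: InsulationTrack,
    delta_window_bp: int = 120_000,
    strength_min: float = 0.1,
) -> list[Boundary]:
    """Boundaries at insulation valleys.

    A valley is a zero-crossing of the delta vector from negative to
    positive; its strength is the delta amplitude across the crossing
    (local max after minus local min before, within the delta window).
    The boundary is placed at the bin with minimal insulation within
    one bin of the crossing.
    """
    bm = track.binmap
    res = bm.resolution
    d = max(1, delta_window_bp // res)
    if not np.isfinite(track.values).any():
        warnings.warn("fully-missing insulation track", RuntimeWarning)
        return []
    out: list[Boundary] = []
    for chrom in bm.genome.chrom_names:
        lo, hi = bm.chrom_range(chrom)
        t = track.values[lo:hi]
        delta = _delta_vector(t, d)
        m = len(t)
        for i in range(m - 1):
            if not (np.isfinite(delta[i]) and np.isfinite(delta[i + 1])):
                continue
            if not (delta[i] < 0 <= delta[i + 1]):
                continue
            before = delta[max(0, i - d + 1) : i + 1]
            after = delta[i + 1 : min(m, i + 1 + d)]
            before = before[np.isfinite(before)]
            after = after[np.isfinite(after)]
            strength = after.max() - before.min()
            if strength < strength_min:
                continue
            cand = [
                j
                for j in range(max(0, i - 1), min(m, i + 3))
                if np.isfinite(t[j])
            ]
            if not cand:
                continue
            b = min(cand, key=lambda j: t[j])
            pos = int(bm.starts[lo + b])
            if not out or out[-1] != (chrom, pos):
                out.append((chrom, pos))
    return sorted(set(out))


def assemble_tads(
    boundaries: list[Boundary],
    binmap: BinMap,
    min_size: int = 200_000,
    source: str = "",
) -> TADSet:
    """Domains between consecutive boundaries, dropping intervals
    smaller than ``min_size`` or overlapping declared gap intervals."""
    genome = binmap.genome
    intervals: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in boundaries:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, poss in by_chrom.items():
        poss = sorted(set(poss))
        gaps = [g[1:] for g in genome.gap_intervals if g[0] == chrom]
        for s, e in zip(poss, poss[1:]):
            if e - s < min_size:
                continue
            if any(s < ge and e > gs for gs, ge in gaps):
                continue
            intervals.append((chrom, s, e))
    order = {c: k for k, c in enumerate(genome.chrom_names)}
    intervals.sort(key=lambda iv: (order.get(iv[0], len(order)), iv[1]))
    return TADSet(intervals, sorted(set(boundaries)), source)


def tad_stats(tads: TADSet) -> tuple[int, float | None, float | None]:
    """(count, median size, mean size); sizes are None for empty sets."""
    sizes = tads.sizes()
    if sizes.size == 0:
        return 0, None, None
    return len(sizes), float(np.median(sizes)), float(sizes.mean())


def conserved_tads(
    a: TADSet, b: TADSet, frac: float = 0.70
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Reciprocal-overlap TAD matching between two samples.

    TADs x in ``a`` and y in ``b`` are conserved iff their overlap is
    at least ``frac`` of both lengths; each TAD matches at most one
    partner (greatest overlap wins, ties to the leftmost partner).
    Returns (conserved index pairs, changed indices in a, changed in b).
    """
    candidates = []
    for i, (ca, sa, ea) in enumerate(a.intervals):
        for j, (cb, sb, eb) in enumerate(b.intervals):
            if ca != cb:
                continue
            ov = min(ea, eb) - max(sa, sb)
            if ov <= 0:
                continue
            if ov >= frac * (ea - sa) and ov >= frac * (eb - sb):
                candidates.append((ov, sb, i, j))
    # greatest overlap first; ties resolved by leftmost partner
    candidates.sort(key=lambda c: (-c[0], c[1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _ov, _sb, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    changed_a = [i for i in range(len(a.intervals)) if i not in used_a]
    changed_b = [j for j in range(len(b.intervals)) if j not in used_b]
    return pairs, changed_a, changed_b


# ---------------------------------------------------------------------------
# breakpoint <-> boundary association
# ---------------------------------------------------------------------------

def breakpoint_boundary_distances(
    breakpoints: list[tuple[str, int]],
    boundaries: list[Boundary],
    near_bp: int = 120_000,
) -> tuple[list[float], dict[str, float]]:
    """Nearest same-chromosome boundary distance per breakpoint.

    Breakpoints on a chromosome with no boundary get NaN and are
    excluded from the summary fractions: fraction at distance 0 and
    fraction within ``near_bp`` (inclusive).
    """
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in boundaries:
        by_chrom.setdefault(chrom, [])
    for chrom, pos in boundaries:
        by_chrom[chrom].append(pos)  # type: ignore[union-attr]
    by_chrom = {c: np.asarray(sorted(p)) for c, p in by_chrom.items()}
    dists: list[float] = []
    for chrom, pos in breakpoints:
        if chrom not in by_chrom or by_chrom[chrom].size == 0:
            dists.append(np.nan)
            continue
        dists.append(float(np.abs(by_chrom[chrom] - pos).min()))
    arr = np.asarray(dists)
    defined = np.isfinite(arr)
    n = int(defined.sum())
    summary = {
        "n": n,
        "frac_exact": float((arr[defined] == 0).mean()) if n else np.nan,
        "frac_near": float((arr[defined] <= near_bp).mean()) if n else np.nan,
    }
    return dists, summary


def random_site_null(
    sites: list[tuple[str, int]],
    binmap: BinMap,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Location-randomized sites, count-matched per chromosome, drawn
    uniformly over unmasked bin starts."""
    out: list[tuple[str, int]] = []
    counts: dict[str, int] = {}
    for chrom, _pos in sites:
        counts[chrom] = counts.get(chrom, 0) + 1
    for chrom, k in counts.items():
        lo, hi = binmap.chrom_range(chrom)
        starts = binmap.starts[lo:hi][~binmap.masked[lo:hi]]
        if starts.size == 0:
            continue
        picks = rng.choice(starts, size=k, replace=True)
        out.extend((chrom, int(p)) for p in picks)
    return out


def distance_null_test(
    observed: list[float], null: list[float]
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test (observed < null).

    Returns (statistic, p_value); NaN distances are dropped.
    """
    obs = np.asarray(observed, dtype=float)
    nul = np.asarray(null, dtype=float)
    obs = obs[np.isfinite(obs)]
    nul = nul[np.isfinite(nul)]
    if obs.size == 0 or nul.size == 0:
        raise AneuhicError("empty distance sample for the rank-sum test")
    stat, p = scipy.stats.ranksums(obs, nul, alternative="less")
    return float(stat), float(p)


def site_insulation_profile(
    sites: list[tuple[str, int]],
    track: ScalarTrack,
    flank: int = 1_000_000,
    label: str = "sites",
) -> SiteProfile:
    """Mean insulation at offsets -F..+F bins around a site set.

    Sites nearer than the flank to a chromosome end contribute only
    their defined offsets.
    """
    if not sites:
        raise AneuhicError("empty site list")
    bm = track.binmap
    F = flank // bm.resolution
    offsets = np.arange(-F, F + 1)
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets), dtype=int)
    for chrom, pos in sites:
        i = bm.bin_at(chrom, pos)
        lo, hi = bm.chrom_range(chrom)
        for k, off in enumerate(offsets):
            j = i + off
            if j < lo or j >= hi:
                continue
            v = track.values[j]
            if np.isfinite(v):
                sums[k] += v
                counts[k] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SiteProfile(label, offsets, means, counts)
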