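"""Synthetic aneuploid genomes with planted ground truth.

The generator plants the structures the analysis pipeline is meant to
measure: integer copy-number blocks on a multi-chromosome genome,
distance-decay Hi-C contacts whose expected counts scale with the
product of bin copy numbers, block-diagonal TAD enrichment, plaid A/B
compartment structure, decaying inter-chromosomal contact stripes at
translocation junctions, Poisson count noise, read-depth tracks
proportional to copy number, junction-candidate tables with support
read counts, and compartment-dependent expression.

Expected intra-chromosomal count for bins i, j (copy numbers c_i, c_j,
baseline ploidy p, bin distance d = |i - j|):

    E[i,j] = s * (c_i * c_j / p^2) * (1 + d)^(-alpha)
             * tau   if i and j lie in the same TAD
             * pi    if i and j share a compartment label

Inter-chromosomal pairs get a background beta * c_i * c_j / p^2 plus,
near each translocation junction, a stripe sigma * (1 + d_J)^(-alpha)
where d_J is the L1 bin distance from the junction bin pair. Observed
counts are independent Poisson draws of E on the upper triangle,
symmetrized by construction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    AneuhicError,
    BinMap,
    ContactMatrix,
    GenomeDef,
    ScalarTrack,
    make_binmap,
)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named stage, stable under pipeline growth.

    The child seed is a CRC32 hash of ``stage:seed`` so adding a stage
    never perturbs the randomness of existing ones.
    """
    child = zlib.crc32(f"{stage}:{seed}".encode()) % (2**31)
    return np.random.default_rng(child)


@dataclass
class SimConfig:
    """Knobs of the synthetic benchmark.

    The defaults define the standard desk-scale benchmark: 4 chromosomes
    of 20 Mb with 40-kb fine bins (500 per chromosome), 500-kb
    compartment bins and 2-Mb structural-variant bins, baseline ploidy
    2, with one 400-kb centromere-like gap per chromosome.
    """

    n_chroms: int = 4
    chrom_length: int = 20_000_000
    fine_resolution: int = 40_000
    coarse_resolution: int = 500_000
    sv_resolution: int = 2_000_000
    ploidy: int = 2
    gap_length: int = 400_000

    # contact model
    alpha: float = 1.0          # distance-decay exponent
    intra_scale: float = 60.0   # s: cis counts at distance 0 per copy-pair
    inter_scale: float = 0.3    # beta: trans background per copy-pair
    tad_factor: float = 1.8     # tau > 1: same-TAD enrichment
    compartment_factor: float = 1.5  # pi > 1: same-label enrichment
    stripe_scale: float = 150.0      # sigma: junction stripe amplitude
    stripe_width_bins: int = 25      # L1 cap on the stripe extent

    # planted structure
    blocks_per_chrom: tuple[int, int] = (4, 6)
    cnv_levels: tuple[int, ...] = (1, 2, 3, 4)
    min_block_bins: int = 25
    tad_size_bins: tuple[int, int] = (10, 25)
    compartment_run_bins: tuple[int, int] = (2, 6)  # in coarse bins
    n_translocations: int = 3
    boundary_alignment_fraction: float = 0.5

    # read depth
    depth_per_copy: float = 500.0  # lambda: mean depth at baseline ploidy

    # junction candidates
    n_decoys: int = 6

    # expression / compartments across conditions
    expr_base: float = 5.0
    expr_delta: float = 1.0
    expr_sd: float = 0.3
    gene_density_a: float = 12.0
    gene_density_b: float = 4.0
    normal_flip_fraction: float = 0.15
    second_tumor_flip_fraction: float = 0.05

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intra_scale", "inter_scale", "stripe_scale"):
            if getattr(self, name) < 0:
                raise AneuhicError(f"{name} must be >= 0")
        if self.tad_factor <= 1 or self.compartment_factor <= 1:
            raise AneuhicError("tad_factor and compartment_factor must be > 1")
        if not 0 <= self.boundary_alignment_fraction <= 1:
            raise AneuhicError("boundary_alignment_fraction must be in [0, 1]")

    def make_genome(self) -> GenomeDef:
        names = tuple(f"chr{i + 1}" for i in range(self.n_chroms))
        lengths = tuple(self.chrom_length for _ in range(self.n_chroms))
        gaps = []
        if self.gap_length > 0:
            res = self.fine_resolution
            for name in names:
                # gap starts at the (bin-aligned) midpoint so it stays
                # inside a single coarse bin at every analysis scale
                mid = (self.chrom_length // 2 // res) * res
                glen = (self.gap_length // res) * res
                gaps.append((name, mid, mid + glen))
        return GenomeDef(names, lengths, tuple(gaps))


@dataclass
class GenomeModel:
    """A planted aneuploid genome: the ground truth of one benchmark run."""

    genome: GenomeDef
    ploidy: int
    cnv_blocks: list[tuple[str, int, int, int]]
    tad_intervals: list[tuple[str, int, int]]
    compartment_labels: np.ndarray  # 'A'/'B' per coarse bin
    coarse_binmap: BinMap
    translocations: list[tuple[str, int, str, int]]

    def __post_init__(self) -> None:
        covered: dict[str, int] = {c: 0 for c in self.genome.chrom_names}
        for chrom, start, end, cn in self.cnv_blocks:
            if cn < 0:
                raise AneuhicError("copy number must be >= 0")
            if start != covered[chrom]:
                raise AneuhicError(f"CNV blocks do not tile {chrom}")
            covered[chrom] = end
        for chrom, length in zip(self.genome.chrom_names, self.genome.chrom_lengths):
            if covered[chrom] != length:
                raise AneuhicError(f"CNV blocks do not tile {chrom}")
        for ca, pa, cb, pb in self.translocations:
            if not (0 <= pa < self.genome.chrom_length(ca)):
                raise AneuhicError("translocation position outside chromosome")
            if not (0 <= pb < self.genome.chrom_length(cb)):
                raise AneuhicError("translocation position outside chromosome")

    def planted_breakpoints(self) -> list[tuple[str, int]]:
        """CNV block boundaries interior to a chromosome."""
        out = []
        for chrom, start, end, _cn in self.cnv_blocks:
            if start > 0:
                out.append((chrom, start))
        return sorted(set(out))

    def planted_boundaries(self) -> list[tuple[str, int]]:
        """TAD junction coordinates interior to a chromosome arm."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.tad_intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        out = []
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if e1 == s2:  # contiguous junction, not an arm edge
                    out.append((chrom, s2))
        return sorted(out)

    def copy_number_per_bin(self, binmap: BinMap) -> np.ndarray:
        cn = np.zeros(binmap.n_bins, dtype=float)
        for chrom, start, end, c in self.cnv_blocks:
            lo, hi = binmap.chrom_range(chrom)
            sel = (binmap.starts[lo:hi] >= start) & (binmap.starts[lo:hi] < end)
            cn[lo:hi][sel] = c
        return cn

    def tad_id_per_bin(self, binmap: BinMap) -> np.ndarray:
        """Index of the TAD containing each bin (-1 outside any TAD)."""
        tid = np.full(binmap.n_bins, -1, dtype=np.int64)
        for k, (chrom, start, end) in enumerate(self.tad_intervals):
            lo, hi = binmap.chrom_range(chrom)
            sel = (binmap.starts[lo:hi] >= start) & (binmap.starts[lo:hi] < end)
            tid[lo:hi][sel] = k
        return tid

    def compartment_label_per_bin(self, binmap: BinMap) -> np.ndarray:
        """Coarse A/B labels mapped down to the bins of ``binmap``."""
        labels = np.empty(binmap.n_bins, dtype="<U1")
        for i in range(binmap.n_bins):
            j = self.coarse_binmap.bin_at(binmap.chrom_name(i), int(binmap.starts[i]))
            labels[i] = self.compartment_labels[j]
        return labels


def _tile_tads(
    arm_start: int, arm_end: int, res: int, size_bins: tuple[int, int],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    lo_bins, hi_bins = size_bins
    out = []
    pos = arm_start
    while pos < arm_end:
        size = int(rng.integers(lo_bins, hi_bins + 1)) * res
        end = min(pos + size, arm_end)
        out.append((pos, end))
        pos = end
    # absorb a short terminal remainder into the previous TAD
    if len(out) >= 2 and (out[-1][1] - out[-1][0]) < lo_bins * res:
        s, _ = out[-2]
        _, e = out[-1]
        out[-2:] = [(s, e)]
    return out


def simulate_genome_model(config: SimConfig, rng: np.random.Generator | None = None) -> GenomeModel:
    """Draw a planted genome: TADs, compartments, CNV blocks, junctions.

    The requested ``boundary_alignment_fraction`` of CNV breakpoints is
    placed exactly on TAD boundary coordinates; the rest are placed
    uniformly inside TADs (never on a boundary). Deterministic for a
    fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genome = config.make_genome()
    res = config.fine_resolution
    fine = make_binmap(genome, res)
    coarse = make_binmap(genome, config.coarse_resolution)

    # --- TADs: tile each chromosome arm (gaps force arm edges) ---
    tads: list[tuple[str, int, int]] = []
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        gaps = sorted(g[1:] for g in genome.gap_intervals if g[0] == chrom)
        arms = []
        pos = 0
        for gs, ge in gaps:
            if gs > pos:
                arms.append((pos, gs))
            pos = ge
        if pos < length:
            arms.append((pos, length))
        for a0, a1 in arms:
            for s, e in _tile_tads(a0, a1, res, config.tad_size_bins, rng):
                tads.append((chrom, s, e))

    # --- compartments: alternating A/B runs over coarse bins ---
    labels = np.empty(coarse.n_bins, dtype="<U1")
    for chrom in genome.chrom_names:
        lo, hi = coarse.chrom_range(chrom)
        lab = "A" if rng.random() < 0.5 else "B"
        i = lo
        while i < hi:
            run = int(rng.integers(config.compartment_run_bins[0], config.compartment_run_bins[1] + 1))
            labels[i : min(i + run, hi)] = lab
            lab = "B" if lab == "A" else "A"
            i += run

    # --- CNV blocks: breakpoints aligned (or not) to TAD boundaries ---
    min_gap = config.min_block_bins * res
    cnv_blocks: list[tuple[str, int, int, int]] = []
    all_breaks: dict[str, list[int]] = {}
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        n_blocks = int(rng.integers(config.blocks_per_chrom[0], config.blocks_per_chrom[1] + 1))
        if n_blocks > length // res:
            raise AneuhicError("more CNV blocks requested than bins available")
        boundary_pool = [p for c, p in _internal_boundaries(tads, chrom)]
        breaks: list[int] = []
        # breakpoints jitter around an even grid so block lengths stay
        # comparable; each is snapped onto the nearest TAD boundary with
        # probability boundary_alignment_fraction, else kept strictly
        # inside a TAD
        for kk in range(1, n_blocks):
            ideal = kk * length / n_blocks
            jitter = rng.uniform(-0.2, 0.2) * length / n_blocks
            cand = int(round((ideal + jitter) / res)) * res
            cand = min(max(cand, min_gap), length - min_gap)
            if boundary_pool and rng.random() < config.boundary_alignment_fraction:
                cand = int(min(boundary_pool, key=lambda b: abs(b - cand)))
            else:
                for _ in range(100):
                    if cand not in boundary_pool:
                        break
                    cand += res
            if all(abs(cand - b) >= min_gap for b in breaks) and min_gap <= cand <= length - min_gap:
                breaks.append(cand)
        breaks.sort()
        all_breaks[chrom] = breaks
        edges = [0] + breaks + [length]
        for s, e in zip(edges, edges[1:]):
            cnv_blocks.append((chrom, s, e, -1))  # CN filled below

    # assign copy numbers: CNV blocks alternate with baseline-ploidy
    # runs (most of a tumor genome stays at the baseline, which is also
    # what median normalization in the CNV caller assumes); the altered
    # blocks cycle a shuffled list of the non-baseline levels so every
    # requested level appears genome-wide
    alt_levels = [lv for lv in config.cnv_levels if lv != config.ploidy] or [
        config.ploidy + 1
    ]
    pool = alt_levels * (len(cnv_blocks) // len(alt_levels) + 1)
    rng.shuffle(pool)
    filled: list[tuple[str, int, int, int]] = []
    k = 0
    chrom_pos = 0
    prev_chrom = None
    for chrom, s, e, _ in cnv_blocks:
        if chrom != prev_chrom:
            chrom_pos = 0  # chromosomes start at the baseline ploidy
            prev_chrom = chrom
        if chrom_pos % 2 == 0:
            cn = config.ploidy
        else:
            cn = int(pool[k % len(pool)])
            k += 1
        filled.append((chrom, s, e, cn))
        chrom_pos += 1

    # --- translocations: distinct chromosome pairs, positions off gaps ---
    translocations: list[tuple[str, int, str, int]] = []
    chrom_pairs = [
        (a, b)
        for ia, a in enumerate(genome.chrom_names)
        for b in genome.chrom_names[ia + 1 :]
    ]
    rng.shuffle(chrom_pairs)
    for ca, cb in chrom_pairs[: config.n_translocations]:
        pa = _draw_position(genome, ca, res, rng, config.sv_resolution)
        pb = _draw_position(genome, cb, res, rng, config.sv_resolution)
        translocations.append((ca, pa, cb, pb))

    return GenomeModel(
        genome=genome,
        ploidy=config.ploidy,
        cnv_blocks=filled,
        tad_intervals=tads,
        compartment_labels=labels,
        coarse_binmap=coarse,
        translocations=translocations,
    )


def _internal_boundaries(
    tads: Sequence[tuple[str, int, int]], chrom: str
) -> list[tuple[str, int]]:
    ivs = sorted((s, e) for c, s, e in tads if c == chrom)
    out = []
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if e1 == s2:
            out.append((chrom, s2))
    return out


def _draw_position(
    genome: GenomeDef, chrom: str, res: int, rng: np.random.Generator,
    avoid_resolution: int | None = None,
) -> int:
    """Random bin-aligned position away from gaps; with
    ``avoid_resolution`` the whole coarse bin overlapping a gap is
    avoided (junctions inside centromeric bins are unassayable)."""
    length = genome.chrom_length(chrom)
    gaps = [g[1:] for g in genome.gap_intervals if g[0] == chrom]
    pad = avoid_resolution or res
    for _ in range(1000):
        pos = int(rng.integers(2, length // res - 2)) * res
        cell = (pos // pad) * pad
        if all(not (cell < ge and cell + pad > gs) for gs, ge in gaps):
            return pos
    raise AneuhicError(f"could not place a junction on {chrom}")


# ---------------------------------------------------------------------------
# Hi-C simulation
# ---------------------------------------------------------------------------

def expected_hic(model: GenomeModel, config: SimConfig) -> ContactMatrix:
    """Noise-free expected contact matrix on the fine binmap.

    Implements the generative mean described in the module docstring;
    masked (gap) bins carry zero signal.
    """
    binmap = make_binmap(model.genome, config.fine_resolution)
    n = binmap.n_bins
    p = model.ploidy
    c = model.copy_number_per_bin(binmap)
    tid = model.tad_id_per_bin(binmap)
    lab = model.compartment_label_per_bin(binmap)
    E = np.zeros((n, n))
    cn_pair = np.outer(c, c) / p**2

    for chrom in model.genome.chrom_names:
        lo, hi = binmap.chrom_range(chrom)
        m = hi - lo
        idx = np.arange(m)
        decay = (1.0 + np.abs(idx[:, None] - idx[None, :])) ** (-config.alpha)
        block = config.intra_scale * cn_pair[lo:hi, lo:hi] * decay
        t = tid[lo:hi]
        same_tad = (t[:, None] == t[None, :]) & (t[:, None] >= 0)
        block = np.where(same_tad, block * config.tad_factor, block)
        same_comp = lab[lo:hi, None] == lab[None, lo:hi]
        block = np.where(same_comp, block * config.compartment_factor, block)
        E[lo:hi, lo:hi] = block

    # trans background
    chrom_of = binmap.chrom_ids
    trans = chrom_of[:, None] != chrom_of[None, :]
    E[trans] = (config.inter_scale * cn_pair)[trans]

    # translocation stripes
    w = config.stripe_width_bins
    for ca, pa, cb, pb in model.translocations:
        ia = binmap.bin_at(ca, pa)
        ib = binmap.bin_at(cb, pb)
        lo_a = max(binmap.chrom_range(ca)[0], ia - w)
        hi_a = min(binmap.chrom_range(ca)[1], ia + w + 1)
        lo_b = max(binmap.chrom_range(cb)[0], ib - w)
        hi_b = min(binmap.chrom_range(cb)[1], ib + w + 1)
        da = np.abs(np.arange(lo_a, hi_a) - ia)
        db = np.abs(np.arange(lo_b, hi_b) - ib)
        d = da[:, None] + db[None, :]
        stripe = np.where(d <= w, config.stripe_scale * (1.0 + d) ** (-config.alpha), 0.0)
        E[lo_a:hi_a, lo_b:hi_b] += stripe
        E[lo_b:hi_b, lo_a:hi_a] += stripe.T

    E[binmap.masked, :] = 0.0
    E[:, binmap.masked] = 0.0
    return ContactMatrix(binmap, E, "expected")


def simulate_hic(
    model: GenomeModel,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> ContactMatrix:
    """Poisson-sampled raw contact matrix (upper triangle drawn once,
    symmetrized). With ``noise=False`` the expected matrix is returned."""
    exp = expected_hic(model, config)
    if not noise:
        return exp
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = exp.binmap.n_bins
    iu, ju = np.triu_indices(n)
    draws = rng.poisson(exp.values[iu, ju]).astype(float)
    vals = np.zeros((n, n))
    vals[iu, ju] = draws
    vals[ju, iu] = draws
    return ContactMatrix(exp.binmap, vals, "raw")


def simulate_wgs_depth(
    model: GenomeModel, config: SimConfig, rng: np.random.Generator | None = None
) -> ScalarTrack:
    """Per-bin read depth ~ Poisson(lambda * c / p); gap bins missing."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    binmap = make_binmap(model.genome, config.fine_resolution)
    c = model.copy_number_per_bin(binmap)
    mean = config.depth_per_copy * c / model.ploidy
    depth = rng.poisson(mean).astype(float)
    depth[binmap.masked] = np.nan
    return ScalarTrack(binmap, depth, "depth")


def simulate_junction_candidates(
    model: GenomeModel, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Junction-candidate table with planted truth.

    One record per true translocation whose support counts pass the
    support-fraction (>10% both sides) and support-sum (>40) filters,
    plus ``n_decoys`` decoy records that violate one of them. The
    ``is_true`` column is the hidden truth flag for scoring.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for ca, pa, cb, pb in model.translocations:
        ta = int(rng.integers(90, 180))
        tb = int(rng.integers(90, 180))
        sa = int(round(rng.uniform(0.25, 0.45) * ta))
        sb = int(round(rng.uniform(0.25, 0.45) * tb))
        rows.append((ca, pa, cb, pb, sa, ta, sb, tb, True))
    genome = model.genome
    res = config.fine_resolution
    names = genome.chrom_names
    for k in range(config.n_decoys):
        ia, ib = rng.choice(len(names), size=2, replace=False)
        ca, cb = names[ia], names[ib]
        pa = _draw_position(genome, ca, res, rng, config.sv_resolution)
        pb = _draw_position(genome, cb, res, rng, config.sv_resolution)
        if k % 2 == 0:
            # violates the support-fraction rule on side A
            ta = int(rng.integers(150, 300))
            sa = int(round(rng.uniform(0.02, 0.08) * ta))
            tb = int(rng.integers(90, 180))
            sb = int(round(rng.uniform(0.25, 0.45) * tb))
        else:
            # passes the fraction rule but the support sum is <= 40
            ta = int(rng.integers(40, 70))
            tb = int(rng.integers(40, 70))
            sa = int(round(rng.uniform(0.2, 0.3) * ta))
            sb = min(int(round(rng.uniform(0.2, 0.3) * tb)), 40 - sa)
            sb = max(sb, int(np.ceil(0.11 * tb)))
            if sa + sb > 40:
                sa = 40 - sb
        rows.append((ca, pa, cb, pb, sa, ta, sb, tb, False))
    return pd.DataFrame(
        rows,
        columns=[
            "chromA", "posA", "chromB", "posB",
            "supportA", "totalA", "supportB", "totalB", "is_true",
        ],
    )


def simulate_gene_density(
    model: GenomeModel,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    labels: np.ndarray | None = None,
) -> ScalarTrack:
    """Genes per coarse bin, denser in A than in B compartments."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if labels is None:
        labels = model.compartment_labels
    mean = np.where(labels == "A", config.gene_density_a, config.gene_density_b)
    vals = rng.poisson(mean).astype(float)
    vals[model.coarse_binmap.masked] = np.nan
    return ScalarTrack(model.coarse_binmap, vals, "gene_density")


def simulate_covariates(
    binmap: BinMap, rng: np.random.Generator | None = None
) -> dict[str, ScalarTrack]:
    """Synthetic per-bin covariates for regression normalization.

    Effective restriction-fragment length, GC content and mappability,
    drawn independently of the planted copy numbers (so regression
    normalization on them cannot absorb copy-number bias).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = binmap.n_bins
    tracks = {
        "eff_length": rng.uniform(0.5, 1.5, n),
        "gc": rng.uniform(0.35, 0.55, n),
        "mappability": rng.uniform(0.7, 1.0, n),
    }
    out = {}
    for name, vals in tracks.items():
        v = vals.astype(float)
        v[binmap.masked] = np.nan
        out[name] = ScalarTrack(binmap, v, name)
    return out


def perturb_labels(
    labels: np.ndarray, flip_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip a random fraction of A/B labels (condition-to-condition change)."""
    out = labels.copy()
    n = len(out)
    n_flip = int(round(flip_fraction * n))
    idx = rng.choice(n, size=n_flip, replace=False)
    for i in idx:
        out[i] = "B" if out[i] == "A" else "A"
    return out


def simulate_expression(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    binmap: BinMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ScalarTrack, ScalarTrack]:
    """Per-bin log2 expression for two conditions.

    log-expression = base + delta * 1[label == A] + Normal(0, sd),
    each condition using its own label vector.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = []
    for labels, name in ((labels_a, "expr_a"), (labels_b, "expr_b")):
        vals = (
            config.expr_base
            + config.expr_delta * (labels == "A")
            + rng.normal(0.0, config.expr_sd, size=binmap.n_bins)
        )
        vals[binmap.masked] = np.nan
        out.append(ScalarTrack(binmap, vals, name))
    return out[0], out[1]
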