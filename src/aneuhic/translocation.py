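"""Translocation evidence: junction filtering and Hi-C enrichment.

Junction candidates (support/total read counts at the two sides of a
putative inter-chromosomal junction) are filtered with strict rules:
both support fractions must exceed 10% and the summed support must
exceed 40 reads. Filtered junctions are then tested for enrichment
among the top-ranked inter-chromosomal contact-bin pairs of a
coarse-resolution matrix with a one-sided Fisher (hypergeometric)
test over the universe of unmasked inter-chromosomal bin pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import AneuhicError, BinMap, ContactMatrix

JUNCTION_COLUMNS = [
    "chromA", "posA", "chromB", "posB",
    "supportA", "totalA", "supportB", "totalB",
]


@dataclass
class EnrichmentResult:
    n_universe: int   # unmasked inter-chromosomal bin pairs
    n_marked: int     # pairs containing >= 1 filtered junction
    k_top: int        # top pairs taken
    overlap: int
    expected: float   # n_marked * k_top / n_universe
    obs_exp_ratio: float
    p_value: float    # one-sided hypergeometric tail (Fisher)


def filter_junctions(
    records: pd.DataFrame,
    min_fraction: float = 0.10,
    min_support_sum: int = 40,
) -> pd.DataFrame:
    """Apply the support filters; returns a copy with ``passed_filters``
    and ``reject_reason`` columns.

    A record passes iff supportA/totalA > min_fraction AND
    supportB/totalB > min_fraction AND supportA + supportB >
    min_support_sum (all strict). Records with a zero total are
    rejected with reason "zero coverage".
    """
    df = records.copy()
    passed = []
    reasons = []
    for _, r in df.iterrows():
        if r["totalA"] <= 0 or r["totalB"] <= 0:
            passed.append(False)
            reasons.append("zero coverage")
            continue
        frac_a = r["supportA"] / r["totalA"]
        frac_b = r["supportB"] / r["totalB"]
        if not (frac_a > min_fraction and frac_b > min_fraction):
            passed.append(False)
            reasons.append("support fraction <= threshold")
        elif not (r["supportA"] + r["supportB"] > min_support_sum):
            passed.append(False)
            reasons.append("support sum <= threshold")
        else:
            passed.append(True)
            reasons.append("")
    df["passed_filters"] = passed
    df["reject_reason"] = reasons
    return df


def top_interchrom_pairs(matrix: ContactMatrix, k: int = 100) -> pd.DataFrame:
    """The ``k`` largest unmasked inter-chromosomal upper-triangle
    entries, ties broken by (chromA, startA, chromB, startB).

    Returns fewer than ``k`` rows only if fewer nonzero pairs exist.
    """
    if k < 1:
        raise AneuhicError("k must be >= 1")
    bm = matrix.binmap
    un = ~bm.masked
    iu, ju = np.triu_indices(bm.n_bins, k=1)
    inter = bm.chrom_ids[iu] != bm.chrom_ids[ju]
    usable = inter & un[iu] & un[ju]
    iu, ju = iu[usable], ju[usable]
    vals = matrix.values[iu, ju]
    nz = vals > 0
    if not nz.any():
        warnings.warn("no inter-chromosomal signal", RuntimeWarning)
        return pd.DataFrame(
            columns=["chromA", "startA", "chromB", "startB", "binA", "binB", "value"]
        )
    iu, ju, vals = iu[nz], ju[nz], vals[nz]
    # sort by descending value, then lexicographic bin order (global bin
    # index encodes (chrom order, start))
    order = np.lexsort((ju, iu, -vals))
    order = order[: min(k, len(order))]
    return pd.DataFrame(
        {
            "chromA": [bm.chrom_name(i) for i in iu[order]],
            "startA": bm.starts[iu[order]],
            "chromB": [bm.chrom_name(j) for j in ju[order]],
            "startB": bm.starts[ju[order]],
            "binA": iu[order],
            "binB": ju[order],
            "value": vals[order],
        }
    )


def _junction_bin_pairs(
    junctions: pd.DataFrame, binmap: BinMap
) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    for _, r in junctions.iterrows():
        try:
            i = binmap.bin_at(r["chromA"], int(r["posA"]))
            j = binmap.bin_at(r["chromB"], int(r["posB"]))
        except AneuhicError:
            continue
        if binmap.masked[i] or binmap.masked[j]:
            continue
        if binmap.chrom_ids[i] == binmap.chrom_ids[j]:
            continue
        pairs.add((min(i, j), max(i, j)))
    return pairs


def junction_enrichment(
    junctions: pd.DataFrame,
    top_pairs: pd.DataFrame,
    binmap_coarse: BinMap,
) -> EnrichmentResult:
    """Fisher enrichment of filtered junctions among the top contact
    pairs.

    A coarse bin pair is "marked" if some filtered junction falls into
    it in either orientation. The 2x2 table is over the universe of
    unmasked inter-chromosomal coarse bin pairs; the p-value is the
    one-sided (greater) hypergeometric tail.
    """
    if "passed_filters" in junctions.columns:
        junctions = junctions[junctions["passed_filters"]]
    if len(junctions) == 0:
        raise AneuhicError("no filtered junctions to test")
    un = np.flatnonzero(~binmap_coarse.masked)
    chrom_of = binmap_coarse.chrom_ids[un]
    n_universe = 0
    for a in range(len(un)):
        n_universe += int(np.sum(chrom_of[a + 1 :] != chrom_of[a]))
    k_top = len(top_pairs)
    if n_universe < k_top:
        raise AneuhicError("universe smaller than the number of top pairs")
    marked = _junction_bin_pairs(junctions, binmap_coarse)
    top_set = {
        (min(int(a), int(b)), max(int(a), int(b)))
        for a, b in zip(top_pairs["binA"], top_pairs["binB"])
    }
    overlap = len(marked & top_set)
    n_marked = len(marked)
    expected = n_marked * k_top / n_universe
    ratio = overlap / expected if expected > 0 else np.nan
    p = float(scipy.stats.hypergeom.sf(overlap - 1, n_universe, n_marked, k_top))
    return EnrichmentResult(n_universe, n_marked, k_top, overlap, expected, ratio, p)


def genes_near_junctions(
    junctions: pd.DataFrame,
    genes: list[tuple],
    window: int = 1_000_000,
) -> list[str]:
    """Names of genes whose interval comes within ``window`` bp of
    either junction coordinate (same chromosome); deduplicated, sorted."""
    if "passed_filters" in junctions.columns:
        junctions = junctions[junctions["passed_filters"]]
    hits: set[str] = set()
    for _, r in junctions.iterrows():
        for chrom, pos in ((r["chromA"], r["posA"]), (r["chromB"], r["posB"])):
            for g in genes:
                gc, gs, ge = g[0], g[1], g[2]
                name = g[3] if len(g) > 3 else f"{gc}:{gs}-{ge}"
                if gc != chrom:
                    continue
                dist = max(0, gs - pos, pos - (ge - 1))
                if dist <= window:
                    hits.add(str(name))
    return sorted(hits)
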