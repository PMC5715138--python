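"""A/B compartment calling and switch-expression association.

Per chromosome, the coarse-resolution normalized matrix is converted to
observed/expected by dividing each diagonal by its mean, the Pearson
correlation matrix of the unmasked bins is formed, and the leading
eigenvector of that correlation matrix splits bins into two
compartments by sign. The sign is oriented so that the positive side
has the higher mean gene density; positive bins are labelled A
(gene-dense, active) and negative bins B.

Switch classes across a (normal, tumor1, tumor2) triple of label
tracks are associated with per-bin expression changes via Welch
two-sample t-tests of each switch category against the pooled stable
categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import AneuhicError, BinMap, ContactMatrix, ScalarTrack

logger = logging.getLogger(__name__)

SWITCH_CATEGORIES = (
    "stable A",
    "stable B",
    "A to B in one",
    "A to B in both",
    "B to A in one",
    "B to A in both",
    "undefined",
)


@dataclass
class CompartmentTrack:
    binmap: BinMap
    eigenvector: np.ndarray  # NaN where undefined
    labels: np.ndarray  # 'A' | 'B' | '' per bin


@dataclass
class SwitchClass:
    binmap: BinMap
    categories: np.ndarray  # one of SWITCH_CATEGORIES per bin


def observed_over_expected(values: np.ndarray, defined: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its mean over defined entries.

    Diagonals with fewer than 3 defined entries fall back to the mean
    over all defined entries.
    """
    m = values.shape[0]
    oe = np.zeros_like(values, dtype=float)
    pair_def = np.outer(defined, defined)
    global_mean = values[pair_def].mean() if pair_def.any() else 0.0
    for k in range(m):
        diag = np.diagonal(values, offset=k)
        dmask = np.diagonal(pair_def, offset=k)
        if dmask.sum() >= 3:
            mean = diag[dmask].mean()
        else:
            mean = global_mean
        if mean <= 0:
            mean = global_mean if global_mean > 0 else 1.0
        idx = np.arange(m - k)
        oe[idx, idx + k] = diag / mean
        oe[idx + k, idx] = diag / mean
    return oe


def compartment_eigenvector(
    matrix: ContactMatrix,
    gene_density: ScalarTrack,
    min_bins: int = 10,
) -> CompartmentTrack:
    """Leading eigenvector of the per-chromosome O/E correlation matrix,
    oriented so A (positive) bins are the gene-dense ones."""
    bm = matrix.binmap
    ev = np.full(bm.n_bins, np.nan)
    labels = np.full(bm.n_bins, "", dtype="<U1")
    for chrom in bm.genome.chrom_names:
        lo, hi = bm.chrom_range(chrom)
        un = np.flatnonzero(~bm.masked[lo:hi]) + lo
        if un.size < min_bins:
            logger.warning("chromosome %s has <%d usable bins; labels undefined", chrom, min_bins)
            continue
        sub = matrix.values[np.ix_(un, un)]
        oe = observed_over_expected(sub, np.ones(un.size, dtype=bool))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(oe)
        if not np.isfinite(corr).all():
            logger.warning("correlation undefined on %s (constant rows); labels undefined", chrom)
            continue
        w, v = np.linalg.eigh(corr)
        vec = v[:, -1]  # eigenvector of the largest eigenvalue
        gd = gene_density.values[un]
        pos = vec > 0
        neg = vec < 0
        mean_pos = np.nanmean(gd[pos]) if pos.any() else -np.inf
        mean_neg = np.nanmean(gd[neg]) if neg.any() else -np.inf
        if mean_neg > mean_pos:
            vec = -vec
        ev[un] = vec
        labels[un] = np.where(vec >= 0, "A", "B")
    return CompartmentTrack(bm, ev, labels)


def classify_switches(
    normal: CompartmentTrack, t1: CompartmentTrack, t2: CompartmentTrack
) -> SwitchClass:
    """Per-bin switch category across (normal, tumor1, tumor2)."""
    bm = normal.binmap
    cats = np.full(bm.n_bins, "undefined", dtype="<U16")
    for i in range(bm.n_bins):
        n, a, b = normal.labels[i], t1.labels[i], t2.labels[i]
        if "" in (n, a, b):
            continue
        if n == a == b:
            cats[i] = f"stable {n}"
        elif n == "A":
            cats[i] = "A to B in both" if (a == b == "B") else "A to B in one"
        else:
            cats[i] = "B to A in both" if (a == b == "A") else "B to A in one"
    return SwitchClass(bm, cats)


def switch_proportions(switch: SwitchClass) -> dict[str, float]:
    """Fraction of defined bins per switch category."""
    cats = switch.categories
    defined = cats != "undefined"
    n = int(defined.sum())
    out = {}
    for c in SWITCH_CATEGORIES[:-1]:
        out[c] = float((cats == c).sum() / n) if n else np.nan
    return out


def switch_expression_association(
    switch: SwitchClass,
    expr_normal: ScalarTrack,
    expr_tumor: ScalarTrack,
    min_bins: int = 3,
) -> pd.DataFrame:
    """Association of switch class with expression change.

    Per bin, delta = tumor - normal log2 expression. Each switch
    category is compared against the pooled stable categories with a
    Welch two-sample t-test. Categories with fewer than ``min_bins``
    defined bins get a missing p-value.
    """
    delta = expr_tumor.values - expr_normal.values
    cats = switch.categories
    defined = np.isfinite(delta) & (cats != "undefined")
    stable = defined & np.isin(cats, ("stable A", "stable B"))
    if stable.sum() < min_bins:
        raise AneuhicError("too few stable bins for a reference group")
    rows = []
    for c in SWITCH_CATEGORIES[:-1]:
        sel = defined & (cats == c)
        n = int(sel.sum())
        mean_d = float(delta[sel].mean()) if n else np.nan
        if c.startswith("stable") or n < min_bins:
            p = np.nan
        else:
            _t, p = scipy.stats.ttest_ind(delta[sel], delta[stable], equal_var=False)
            p = float(p)
        rows.append({"category": c, "n_bins": n, "mean_delta": mean_d, "p_value": p})
    return pd.DataFrame(rows)
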