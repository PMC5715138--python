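"""Matrix normalization and the copy-number bias diagnostic.

Two normalizers are provided. Iterative correction (ICE) balances the
matrix so every unmasked bin has the same marginal sum, absorbing all
multiplicative per-bin biases — including copy number. The covariate
normalizer fits a Poisson log-link regression of counts on the log
product of per-bin covariates (effective length, GC, mappability) per
chromosome and divides counts by the fitted mean; since copy number is
not among the covariates, this style of normalization does not remove
copy-number bias.

The diagnostic regresses the median near-diagonal interaction value of
each copy-number block on the block's copy number; a significantly
positive slope (F-test) indicates residual copy-number bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats
import statsmodels.api as sm

from .core import AneuhicError, BinMap, ContactMatrix, ScalarTrack
from .cnv import CNVBlock, CopyNumberProfile, blocks_and_breakpoints


@dataclass
class BiasVector:
    """Multiplicative per-bin bias with geometric mean 1 over defined bins."""

    binmap: BinMap
    values: np.ndarray  # NaN at masked bins
    kind: str = "ice"
    converged: bool = True
    n_iter: int = 0
    final_cv: float = 0.0


@dataclass
class BiasRegressionResult:
    """OLS of block median diagonal value on block copy number."""

    points: list[tuple[int, float]]  # (copy_number, median_diagonal_value)
    slope: float
    intercept: float
    f_statistic: float
    p_value: float
    n_blocks: int


def ice_normalize(
    matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-5
) -> tuple[ContactMatrix, BiasVector]:
    """Iteratively balance a raw matrix so unmasked marginals are equal.

    Iterates dividing by marginal sums until the coefficient of
    variation of unmasked row sums drops below ``tol`` or ``max_iter``
    is reached (then a warning is issued and the bias vector flagged).
    The output is rescaled so its mean unmasked entry equals the mean
    unmasked entry of the input; the bias vector has geometric mean 1.
    """
    bm = matrix.binmap
    un = ~bm.masked
    if un.sum() < 2:
        raise AneuhicError("need at least 2 unmasked bins for ICE")
    W = matrix.values.astype(float).copy()
    W[~un, :] = 0.0
    W[:, ~un] = 0.0
    if W.sum() == 0:
        raise AneuhicError("all-zero matrix: cannot normalize")
    sub = np.ix_(un, un)
    input_mean = float(W[sub].mean())
    bias = np.ones(bm.n_bins)
    converged = False
    cv = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        s = W.sum(axis=1)
        s_un = s[un]
        mean_s = s_un.mean()
        if mean_s == 0:
            raise AneuhicError("all-zero marginals during ICE")
        cv = float(s_un.std() / mean_s)
        if cv < tol:
            converged = True
            break
        scale = np.ones(bm.n_bins)
        nz = un & (s > 0)
        scale[nz] = s[nz] / mean_s
        W /= np.outer(scale, scale)
        bias *= scale
    if not converged:
        warnings.warn(
            f"ICE did not converge after {max_iter} iterations (CV={cv:.3g})",
            RuntimeWarning,
        )
    out_mean = float(W[sub].mean())
    if out_mean > 0:
        W *= input_mean / out_mean
    logb = np.log(bias[un][bias[un] > 0])
    gmean = float(np.exp(logb.mean())) if logb.size else 1.0
    bias /= gmean
    bias_vals = np.where(un, bias, np.nan)
    return (
        ContactMatrix(bm, W, "ice"),
        BiasVector(bm, bias_vals, "ice", converged, it, cv),
    )


def covnorm_normalize(
    matrix: ContactMatrix, covariates: dict[str, ScalarTrack]
) -> ContactMatrix:
    """Poisson-regression normalization on per-bin covariates.

    Per chromosome, counts of unmasked cis bin pairs are regressed
    (log link) on the log product of each covariate at the two bins;
    normalized value = count / fitted mean. Trans pairs are normalized
    by one genome-wide fit of the same design. The output is rescaled
    to the input's mean unmasked entry. Copy number is not a covariate,
    so copy-number bias survives this normalization.
    """
    bm = matrix.binmap
    un = ~bm.masked
    cov_arrays = {}
    for name, track in covariates.items():
        v = track.values
        if np.any(v[un] <= 0) or np.any(~np.isfinite(v[un])):
            raise AneuhicError(f"covariate {name!r} must be strictly positive at unmasked bins")
        cov_arrays[name] = v
    out = matrix.values.astype(float).copy()

    def _fit_and_divide(ii: np.ndarray, jj: np.ndarray) -> None:
        y = matrix.values[ii, jj]
        cols, names = [], []
        for name, v in cov_arrays.items():
            col = np.log(v[ii] * v[jj])
            if np.ptp(col) > 1e-12:
                cols.append(col)
                names.append(name)
        X = np.column_stack([np.ones_like(y)] + cols) if cols else np.ones((len(y), 1))
        if cols:
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise AneuhicError(
                    "singular covariate design; collinear covariates: " + ", ".join(names)
                )
        # deterministic stride subsample keeps the IRLS fit cheap on
        # large pair sets; prediction uses all pairs
        step = max(1, len(y) // 200_000)
        fit = sm.GLM(y[::step], X[::step], family=sm.families.Poisson()).fit()
        mu = np.exp(X @ fit.params)
        out[ii, jj] = y / mu
        out[jj, ii] = out[ii, jj]

    un_idx = np.flatnonzero(un)
    # cis, per chromosome
    for chrom in bm.genome.chrom_names:
        lo, hi = bm.chrom_range(chrom)
        idx = un_idx[(un_idx >= lo) & (un_idx < hi)]
        if idx.size < 2:
            continue
        ii, jj = np.meshgrid(idx, idx, indexing="ij")
        keep = ii <= jj
        _fit_and_divide(ii[keep], jj[keep])
    # trans, one genome-wide fit
    ii, jj = np.meshgrid(un_idx, un_idx, indexing="ij")
    keep = (ii < jj) & (bm.chrom_ids[ii] != bm.chrom_ids[jj])
    if keep.any():
        _fit_and_divide(ii[keep], jj[keep])

    sub = np.ix_(un, un)
    out_mean = float(out[sub].mean())
    if out_mean > 0:
        out *= float(matrix.values[sub].mean()) / out_mean
    out[~un, :] = 0.0
    out[:, ~un] = 0.0
    return ContactMatrix(bm, out, "covnorm")


def median_block_diagonal(
    matrix: ContactMatrix, block: CNVBlock, band_width: int = 0
) -> float | None:
    """Median near-diagonal value inside a copy-number block.

    Considers unmasked bin pairs (i, j) with |i - j| <= band_width whose
    bins lie fully inside the block. Returns None for fully masked
    blocks (excluded from the bias regression). Even-count medians use
    the mean-of-middle convention.
    """
    bm = matrix.binmap
    chrom, start, end, _cn = block
    lo, hi = bm.chrom_range(chrom)
    inside = np.flatnonzero(
        (bm.starts[lo:hi] >= start)
        & (bm.ends[lo:hi] <= end)
        & ~bm.masked[lo:hi]
    ) + lo
    if inside.size == 0:
        return None
    vals = []
    pos = {int(i): k for k, i in enumerate(inside)}
    for i in inside:
        for off in range(0, band_width + 1):
            j = i + off
            if int(j) in pos:
                vals.append(matrix.values[i, j])
    if not vals:
        return None
    return float(np.median(vals))


def cnv_bias_regression(
    matrix: ContactMatrix,
    profile: CopyNumberProfile,
    band_width: int = 0,
) -> BiasRegressionResult:
    """Regress block median diagonal values on block copy numbers.

    Blocks with copy number 0 or no usable bins are excluded. Slope,
    intercept and the F-test of zero slope come from the closed-form
    regression ANOVA. Raises if fewer than two distinct copy-number
    levels remain.
    """
    blocks, _ = blocks_and_breakpoints(profile)
    points: list[tuple[int, float]] = []
    for block in blocks:
        if block[3] == 0:
            continue
        med = median_block_diagonal(matrix, block, band_width)
        if med is not None:
            points.append((block[3], med))
    cns = {cn for cn, _ in points}
    if len(cns) < 2:
        raise AneuhicError("regression inapplicable: <2 distinct copy-number levels")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    n = len(x)
    sxx = float(((x - x.mean()) ** 2).sum())
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    sse = float(((y - fitted) ** 2).sum())
    ssr = float(((fitted - y.mean()) ** 2).sum())
    if n > 2 and sse > 0:
        f_stat = ssr / (sse / (n - 2))
        p = float(scipy.stats.f.sf(f_stat, 1, n - 2))
    elif n > 2:
        f_stat = np.inf
        p = 0.0
    else:
        f_stat = np.nan
        p = np.nan
    return BiasRegressionResult(points, slope, intercept, f_stat, p, n)
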