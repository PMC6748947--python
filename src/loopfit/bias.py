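"""Per-bin bias factors: stratified coverage ratios or ICE matrix balancing."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from loopfit.io_contacts import BinAnnotation, BinnedContactMap


@dataclass
class BiasVector:
    """Per-bin multiplicative bias; 0 marks undefined (zero-coverage) bins."""

    method: str  # "coverage" | "ice" | "none"
    values: Dict[str, np.ndarray] = field(default_factory=dict)
    converged: bool = True

    def get(self, chrom: str, i: int) -> float:
        v = self.values.get(chrom)
        if v is None or i >= len(v):
            return 0.0
        return float(v[i])


def coverage_bias_array(coverage: np.ndarray, peak_flags: np.ndarray) -> np.ndarray:
    """Stratified coverage-ratio bias for a single array of bins.

    Bias of a non-zero bin = coverage / mean coverage of the non-zero
    bins with the same peak status; zero-coverage bins get 0.
    """
    coverage = np.asarray(coverage, dtype=float)
    peak_flags = np.asarray(peak_flags, dtype=bool)
    if (coverage < 0).any():
        raise ValueError("coverage must be non-negative")
    bias = np.zeros_like(coverage, dtype=float)
    for status in (True, False):
        sel = (peak_flags == status) & (coverage > 0)
        if not sel.any():
            if (peak_flags == status).any():
                warnings.warn(
                    f"no non-zero coverage bins in {'peak' if status else 'non-peak'} stratum"
                )
            continue
        bias[sel] = coverage[sel] / coverage[sel].mean()
    return bias


def coverage_bias(ann: BinAnnotation) -> BiasVector:
    """Bias = coverage / mean coverage of non-zero bins with the same peak status.

    Zero-coverage bins get bias 0 and are excluded downstream.  Within
    each stratum the non-zero biases have mean 1 by construction.
    """
    bv = BiasVector(method="coverage")
    any_nonzero = {True: False, False: False}
    for chrom in ann.chroms():
        cov = np.asarray(ann.coverage[chrom], dtype=float)
        if (cov < 0).any():
            raise ValueError("coverage must be non-negative")
        flags = ann.peak_flags[chrom]
        for status in (True, False):
            if ((flags == status) & (cov > 0)).any():
                any_nonzero[status] = True
    # strata pooled genome-wide so per-chromosome depth does not skew biases
    pooled_cov = {}
    pooled_flags = {}
    for chrom in ann.chroms():
        pooled_cov[chrom] = np.asarray(ann.coverage[chrom], dtype=float)
        pooled_flags[chrom] = np.asarray(ann.peak_flags[chrom], dtype=bool)
    means = {}
    for status in (True, False):
        vals = np.concatenate(
            [pooled_cov[c][(pooled_flags[c] == status) & (pooled_cov[c] > 0)] for c in ann.chroms()]
        ) if ann.chroms() else np.array([])
        if vals.size == 0:
            if not any_nonzero[status]:
                warnings.warn(f"no non-zero coverage bins in {'peak' if status else 'non-peak'} stratum")
            means[status] = np.nan
        else:
            means[status] = vals.mean()
    for chrom in ann.chroms():
        cov = pooled_cov[chrom]
        flags = pooled_flags[chrom]
        bias = np.zeros_like(cov)
        for status in (True, False):
            sel = (flags == status) & (cov > 0)
            if sel.any() and np.isfinite(means[status]):
                bias[sel] = cov[sel] / means[status]
        bv.values[chrom] = bias
        ann.bias[chrom] = bias
    return bv


def _ice_dense(mat: np.ndarray, max_iter: int, tol: float) -> tuple[np.ndarray, bool]:
    """Iterative correction on a dense symmetric matrix.

    Returns biases rescaled to mean 1 over bins with non-zero marginal;
    zero-marginal bins get 0.
    """
    n = mat.shape[0]
    work = mat.astype(float).copy()
    marg0 = work.sum(axis=1)
    alive = marg0 > 0
    bias = np.ones(n)
    converged = False
    for _ in range(max_iter):
        marg = work.sum(axis=1)
        nz = marg[alive]
        if nz.size == 0:
            break
        delta = np.ones(n)
        delta[alive] = marg[alive] / nz.mean()
        delta[delta == 0] = 1.0
        work /= np.outer(delta, delta)
        bias *= delta
        if np.abs(delta - 1).max() < tol:
            converged = True
            break
    bias[~alive] = 0.0
    if alive.any():
        bias[alive] /= bias[alive].mean()
    return bias, converged


def ice_bias(
    cmap: BinnedContactMap,
    ann: BinAnnotation,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> BiasVector:
    """ICE balancing biases from the symmetric view of the sparse map.

    All bins are treated identically regardless of peak status.  Biases
    are rescaled to mean 1 over bins with non-zero marginals; empty bins
    get bias 0.
    """
    bv = BiasVector(method="ice")
    all_converged = True
    for chrom in ann.chroms():
        n = ann.n_bins[chrom]
        mat = np.zeros((n, n))
        for (i, j), k in cmap.counts.get(chrom, {}).items():
            if i < n and j < n:
                mat[i, j] += k
                if i != j:
                    mat[j, i] += k
        bias, converged = _ice_dense(mat, max_iter=max_iter, tol=tol)
        if not converged:
            all_converged = False
        bv.values[chrom] = bias
        ann.bias[chrom] = bias
    if not all_converged:
        warnings.warn("ICE did not converge within max_iter on at least one chromosome")
        bv.converged = False
    return bv


def unit_bias(ann: BinAnnotation) -> BiasVector:
    """All-ones bias (no correction); used by the no-bias significance mode."""
    bv = BiasVector(method="none")
    for chrom in ann.chroms():
        b = np.ones(ann.n_bins[chrom])
        bv.values[chrom] = b
        ann.bias[chrom] = b
    return bv
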