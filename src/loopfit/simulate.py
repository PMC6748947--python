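"""Simulation utilities.

Two generators live here: (1) iterative proportional scaling of a
symmetric source matrix toward a target coverage (marginal) vector,
mimicking a pulldown of a Hi-C-like map by a 1D signal, and (2) fully
synthetic single-chromosome fixtures with distance decay, peak-bin
coverage enrichment, and implanted high-fold loops with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from loopfit.io_contacts import BinAnnotation, BinnedContactMap


@dataclass
class ScalingResult:
    """Outcome of the alternating row/column proportional scaling."""

    matrix: np.ndarray
    iterations: int
    converged: bool
    correlation: float
    diffs: List[float] = field(default_factory=list)


def ipf_scale(
    M0: np.ndarray,
    V: np.ndarray,
    eps: Optional[float] = None,
    max_iter: int = 500,
) -> ScalingResult:
    """Alternating row- then column-wise scaling of M0 toward marginals V.

    Each sweep rescales every row i by ``V[i] / rowsum_i``, then every
    column j by ``V[j] / colsum_j``, then symmetrizes ``(A + A.T) / 2``.
    Stops when the sum of absolute differences between consecutive
    iterates drops below ``eps`` (default ``1e-6 * sum(M0)``) or after
    ``max_iter`` sweeps.  Rows/columns with V == 0 are zeroed and
    excluded from the reported Pearson correlation between the final
    row sums and V.
    """
    M = np.array(M0, dtype=float)
    V = np.asarray(V, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M0 must be a square matrix")
    if len(V) != M.shape[0]:
        raise ValueError("V length must match matrix dimension")
    if (M < 0).any() or (V < 0).any():
        raise ValueError("matrix and target vector must be non-negative")
    if M.sum() == 0 or V.sum() == 0:
        raise ValueError("matrix and target vector must not be all zero")
    alive = V > 0
    if not alive.all():
        import warnings

        warnings.warn(f"{int((~alive).sum())} bins with zero target coverage; zeroing them")
        M[~alive, :] = 0.0
        M[:, ~alive] = 0.0
    eps = float(eps) if eps is not None else 1e-6 * M.sum()
    diffs: List[float] = []
    converged = False
    t = 0
    for t in range(1, max_iter + 1):
        prev = M.copy()
        rs = M.sum(axis=1)
        scale = np.ones_like(rs)
        nz = rs > 0
        scale[nz] = V[nz] / rs[nz]
        M = M * scale[:, None]
        cs = M.sum(axis=0)
        scale = np.ones_like(cs)
        nz = cs > 0
        scale[nz] = V[nz] / cs[nz]
        M = M * scale[None, :]
        M = (M + M.T) / 2.0
        diff = float(np.abs(M - prev).sum())
        diffs.append(diff)
        if diff < eps:
            converged = True
            break
    rows = M.sum(axis=1)
    if alive.sum() >= 2 and np.std(rows[alive]) > 0 and np.std(V[alive]) > 0:
        corr = float(np.corrcoef(rows[alive], V[alive])[0, 1])
    else:
        corr = np.nan
    return ScalingResult(matrix=M, iterations=t, converged=converged, correlation=corr, diffs=diffs)


def rescale_total(M: np.ndarray, target_total: float) -> np.ndarray:
    """Scale the matrix so its entries sum to ``target_total``."""
    M = np.asarray(M, dtype=float)
    s = M.sum()
    if s <= 0:
        raise ValueError("matrix sum must be positive")
    if target_total <= 0:
        raise ValueError("target total must be positive")
    return M * (target_total / s)


def shuffle_coverage(V: Sequence[float], seed: int) -> np.ndarray:
    """Uniform random permutation of the coverage vector (seed-reproducible)."""
    rng = np.random.default_rng(seed)
    V = np.asarray(V, dtype=float)
    return rng.permutation(V)


@dataclass
class FixtureSpec:
    """Parameters of a synthetic single-chromosome fixture."""

    n_bins: int = 400
    binsize: int = 5000
    chrom: str = "chrSim"
    alpha: float = 1.0  # decay exponent: E[count] ~ scale * d^-alpha
    scale: float = 4e6  # bp-scaled so counts at 20 kb are O(scale/20000)
    peak_fraction: float = 0.2
    peak_multiplier: float = 1.0  # extra coverage multiplier m for peak bins
    cov_sigma: float = 0.4  # lognormal sd of per-bin efficiency factors
    n_loops: int = 20
    loop_fold: float = 8.0
    loops: Optional[List[Tuple[int, int, float]]] = None  # explicit (i, j, fold)
    distance_low: int = 20_000
    distance_high: int = 2_000_000
    seed: int = 0


@dataclass
class Fixture:
    """Generated fixture: contact map, annotation, and implanted-loop truth."""

    cmap: BinnedContactMap
    ann: BinAnnotation
    peaks: pd.DataFrame
    truth: pd.DataFrame  # chrom, i, j, fold
    spec: FixtureSpec


def _pick_peak_bins(n_bins: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    n_peaks = max(2, int(round(n_bins * fraction)))
    return np.sort(rng.choice(n_bins, size=min(n_peaks, n_bins), replace=False))


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a Poisson fixture with decay, per-bin efficiency, implants.

    Expected count of pair (i, j) at distance d is
    ``scale * d**-alpha * m_i * m_j`` where ``m_i`` is a lognormal
    per-bin efficiency factor (sd ``cov_sigma``) times
    ``peak_multiplier`` for peak bins; implanted pairs get their
    expectation multiplied by their fold before the Poisson draw.

    With ``peak_multiplier == 1`` the expectation is fully explained by
    per-bin factors, which the stratified coverage-bias regression can
    absorb, so only the implants are enriched over the fitted null.  A
    multiplier > 1 adds a peak-status effect that the (stratum-
    normalized) biases deliberately cannot explain.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bins
    binsize = spec.binsize
    peak_bins = _pick_peak_bins(n, spec.peak_fraction, rng)
    flags = np.zeros(n, dtype=bool)
    flags[peak_bins] = True

    implants: dict[Tuple[int, int], float] = {}
    if spec.loops is not None:
        for i, j, fold in spec.loops:
            implants[(min(i, j), max(i, j))] = float(fold)
    elif spec.n_loops > 0 and spec.loop_fold != 1.0:
        # implant among well-separated PP pairs inside the distance range
        candidates = []
        for a in range(len(peak_bins)):
            for b in range(a + 1, len(peak_bins)):
                i, j = int(peak_bins[a]), int(peak_bins[b])
                d = (j - i) * binsize
                if spec.distance_low <= d <= spec.distance_high:
                    candidates.append((i, j))
        rng.shuffle(candidates)
        for i, j in candidates:
            if len(implants) >= spec.n_loops:
                break
            if all(max(abs(i - x), abs(j - y)) > 3 for x, y in implants):
                implants[(i, j)] = spec.loop_fold
        if len(implants) < spec.n_loops:
            raise ValueError(
                f"could only place {len(implants)}/{spec.n_loops} implanted loops; "
                "increase n_bins or peak_fraction"
            )

    o_min = max(1, -(-spec.distance_low // binsize))
    o_max = min(spec.distance_high // binsize, n - 1)
    cmap = BinnedContactMap(binsize=binsize)
    eff = rng.lognormal(mean=0.0, sigma=spec.cov_sigma, size=n) if spec.cov_sigma > 0 else np.ones(n)
    mult = eff * np.where(flags, spec.peak_multiplier, 1.0)
    total_expected = 0.0
    for o in range(o_min, o_max + 1):
        d = o * binsize
        base = spec.scale * d ** (-spec.alpha)
        i = np.arange(0, n - o)
        j = i + o
        lam = base * mult[i] * mult[j]
        for (a, b), fold in implants.items():
            if b - a == o:
                lam[a] *= fold
        total_expected += lam.sum()
        counts = rng.poisson(lam)
        nz = counts > 0
        for a, b, k in zip(i[nz], j[nz], counts[nz]):
            cmap.add(spec.chrom, int(a), int(b), int(k))
    if total_expected <= 0:
        raise ValueError("fixture spec produces zero expected counts")

    ann = BinAnnotation(binsize=binsize, n_bins={spec.chrom: n})
    ann.peak_flags[spec.chrom] = flags
    # coverage plays the role of a matching ChIP-seq track: proportional to
    # the per-bin factors that actually scaled the simulated counts (map
    # marginals would systematically under-cover bins near the chromosome
    # ends and are available via marginal_coverage instead)
    ann.coverage[spec.chrom] = mult * 100.0

    peaks = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "start": peak_bins * binsize,
            "end": (peak_bins + 1) * binsize,
        }
    )
    truth = pd.DataFrame(
        [(spec.chrom, i, j, fold) for (i, j), fold in sorted(implants.items())],
        columns=["chrom", "i", "j", "fold"],
    )
    return Fixture(cmap=cmap, ann=ann, peaks=peaks, truth=truth, spec=spec)


def decay_matrix(
    n: int, binsize: int, alpha: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric Poisson Hi-C-like matrix with E[count] = scale * d^-alpha."""
    M = np.zeros((n, n))
    for o in range(1, n):
        d = o * binsize
        lam = scale * d ** (-alpha)
        vals = rng.poisson(lam, size=n - o).astype(float)
        idx = np.arange(n - o)
        M[idx, idx + o] = vals
        M[idx + o, idx] = vals
    return M


def matrix_to_contact_map(
    M: np.ndarray, binsize: int, chrom: str = "chrSim", integerize: bool = True
) -> BinnedContactMap:
    """Upper-triangular (i < j) sparse map from a dense symmetric matrix."""
    cmap = BinnedContactMap(binsize=binsize)
    n = M.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = M[iu, ju]
    if integerize:
        vals = np.rint(vals).astype(int)
    for a, b, k in zip(iu, ju, vals):
        if k > 0:
            cmap.add(chrom, int(a), int(b), int(k) if integerize else k)
    return cmap
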