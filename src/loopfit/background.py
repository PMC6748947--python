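"""Empirical null model for contact significance.

The background is built genome-wide from a chosen set of locus pairs
(zero counts included): pairs are sorted by genomic distance and split
into ~equal-occupancy strata by total contact count; each stratum
yields a prior contact probability and, when bias correction is on, a
log-log regression of counts on the two anchor biases.  Priors (or the
per-stratum regression coefficients) are smoothed along distance with
splines and looked up at test time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator, make_smoothing_spline
from sklearn.isotonic import IsotonicRegression

from loopfit.bias import BiasVector
from loopfit.io_contacts import BinAnnotation, BinnedContactMap

BACKGROUND_STRINGENT = "S"  # peak-to-peak pairs
BACKGROUND_LOOSE = "L"  # peak-to-all pairs
BACKGROUND_ALL = "ALL"  # every pair (all-to-all foreground)

DEFAULT_M = 200


def enumerate_pairs(
    cmap: BinnedContactMap,
    ann: BinAnnotation,
    background_class: str,
    distance_low: int,
    distance_high: int,
) -> pd.DataFrame:
    """All possible locus pairs of the given class in the distance range.

    Zero-count pairs are included.  Returns a frame with columns
    ``chrom, i, j, distance, count, klass`` sorted by distance.
    """
    binsize = cmap.binsize
    o_min = max(1, -(-distance_low // binsize))  # ceil
    o_max = distance_high // binsize
    frames = []
    for chrom in ann.chroms():
        n = ann.n_bins[chrom]
        flags = np.asarray(ann.peak_flags[chrom], dtype=bool)
        bucket = cmap.counts.get(chrom, {})
        for o in range(o_min, min(o_max, n - 1) + 1):
            i = np.arange(0, n - o)
            j = i + o
            fi, fj = flags[i], flags[j]
            if background_class == BACKGROUND_STRINGENT:
                sel = fi & fj
            elif background_class == BACKGROUND_LOOSE:
                sel = fi | fj
            elif background_class == BACKGROUND_ALL:
                sel = np.ones(len(i), dtype=bool)
            else:
                raise ValueError(f"unknown background class {background_class!r}")
            if not sel.any():
                continue
            i, j = i[sel], j[sel]
            k = np.fromiter((bucket.get((a, b), 0) for a, b in zip(i, j)), dtype=int, count=len(i))
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "i": i,
                        "j": j,
                        "distance": o * binsize,
                        "count": k,
                    }
                )
            )
    if not frames:
        raise ValueError(
            f"no locus pairs for background class {background_class!r} "
            f"in distance range [{distance_low}, {distance_high}]"
        )
    out = pd.concat(frames, ignore_index=True)
    out.sort_values(["distance", "chrom", "i", "j"], inplace=True, kind="mergesort")
    out.reset_index(drop=True, inplace=True)
    return out


@dataclass
class OccupancyBin:
    """One distance stratum from equal-occupancy binning."""

    index: int
    n_pairs: int  # n_j, zero-count pairs included
    total_count: int  # S_j
    mean_distance: float  # D_j over all n_j pairs
    prior_probability: float  # p_j = (S_j / n_j) / C
    beta0: float = np.nan
    beta1: float = np.nan
    beta2: float = np.nan


def equal_occupancy_binning(pairs: pd.DataFrame, M: int = DEFAULT_M) -> List[OccupancyBin]:
    """Split distance-sorted pairs into <=M strata of ~equal total count.

    All pairs at an identical distance stay in one stratum (tie rule),
    so fewer than M strata can result.  Requires total count C > 0; if
    C < M, M is reduced to C with a warning.
    """
    C = int(pairs["count"].sum())
    if C <= 0:
        raise ValueError("total contact count must be positive for occupancy binning")
    if C < M:
        warnings.warn(f"total count C={C} < M={M}; reducing M to C")
        M = C
    target = C / M
    grouped = pairs.groupby("distance", sort=True)
    dist_vals = []
    dist_n = []
    dist_s = []
    for d, g in grouped:
        dist_vals.append(float(d))
        dist_n.append(len(g))
        dist_s.append(int(g["count"].sum()))
    bins: List[OccupancyBin] = []
    run_n = run_s = 0
    run_d = 0.0
    for d, n, s in zip(dist_vals, dist_n, dist_s):
        run_n += n
        run_s += s
        run_d += d * n
        if run_s >= target:
            bins.append(_make_bin(len(bins) + 1, run_n, run_s, run_d, C))
            run_n = run_s = 0
            run_d = 0.0
    if run_n:
        bins.append(_make_bin(len(bins) + 1, run_n, run_s, run_d, C))
    return bins


def _make_bin(idx: int, n: int, s: int, dsum: float, C: int) -> OccupancyBin:
    return OccupancyBin(
        index=idx,
        n_pairs=n,
        total_count=s,
        mean_distance=dsum / n,
        prior_probability=(s / n) / C,
    )


class ClampedSpline:
    """A 1-D function clamped to its endpoint values outside the fit domain."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], lo: float, hi: float):
        self._fn = fn
        self.lo = float(lo)
        self.hi = float(hi)

    def __call__(self, d):
        x = np.clip(np.asarray(d, dtype=float), self.lo, self.hi)
        out = np.asarray(self._fn(x), dtype=float)
        if np.isscalar(d) or np.ndim(d) == 0:
            return float(out)
        return out


def fit_distance_spline(distances: Sequence[float], probs: Sequence[float]) -> ClampedSpline:
    """Monotone non-increasing fit of prior probability vs distance.

    Isotonic (decreasing) regression followed by a monotone cubic
    (PCHIP) interpolant through the projected points; values clamped to
    the endpoints outside the fitted domain and floored at 0.
    """
    d = np.asarray(distances, dtype=float)
    p = np.asarray(probs, dtype=float)
    if len(d) != len(p) or len(d) == 0:
        raise ValueError("distances and probabilities must be equal-length and non-empty")
    order = np.argsort(d)
    d, p = d[order], p[order]
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    p_iso = iso.fit_transform(d, p)
    # collapse duplicate abscissae (PCHIP needs strictly increasing x)
    ud, inv = np.unique(d, return_inverse=True)
    up = np.array([p_iso[inv == t].mean() for t in range(len(ud))])
    if len(ud) < 4:
        warnings.warn("fewer than 4 distinct points; falling back to monotone linear interpolation")
        if len(ud) == 1:
            const = float(up[0])
            return ClampedSpline(lambda x: np.full_like(np.asarray(x, float), const), ud[0], ud[0])
        fn = lambda x: np.interp(x, ud, up)  # noqa: E731
        return ClampedSpline(lambda x: np.maximum(fn(x), 0.0), ud[0], ud[-1])
    pchip = PchipInterpolator(ud, up, extrapolate=False)
    return ClampedSpline(lambda x: np.maximum(np.nan_to_num(pchip(x)), 0.0), ud[0], ud[-1])


def fit_bias_regression(
    counts: np.ndarray, bias1: np.ndarray, bias2: np.ndarray
) -> tuple[float, float, float, bool]:
    """OLS of log(count) on (log b1, log b2) with intercept.

    Inputs must already be filtered to count >= 1 and positive biases.
    Returns (beta0, beta1, beta2, degenerate); a constant bias column
    gets coefficient 0 and sets the degenerate flag.
    """
    k = np.asarray(counts, dtype=float)
    b1 = np.asarray(bias1, dtype=float)
    b2 = np.asarray(bias2, dtype=float)
    if (k < 1).any() or (b1 <= 0).any() or (b2 <= 0).any():
        raise ValueError("regression requires counts >= 1 and strictly positive biases")
    if len(k) < 3:
        raise ValueError("need at least 3 pairs for the bias regression")
    y = np.log(k)
    x1, x2 = np.log(b1), np.log(b2)
    use1 = np.ptp(x1) > 1e-12
    use2 = np.ptp(x2) > 1e-12
    cols = [np.ones_like(y)]
    if use1:
        cols.append(x1)
    if use2:
        cols.append(x2)
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    beta0 = float(coef[0])
    pos = 1
    beta1 = beta2 = 0.0
    if use1:
        beta1 = float(coef[pos])
        pos += 1
    if use2:
        beta2 = float(coef[pos])
    return beta0, beta1, beta2, not (use1 and use2)


def fit_coefficient_splines(
    distances: Sequence[float],
    beta0: Sequence[float],
    beta1: Sequence[float],
    beta2: Sequence[float],
    lam: Optional[float] = None,
) -> tuple[ClampedSpline, ClampedSpline, ClampedSpline]:
    """Cubic smoothing splines of the regression coefficients vs distance.

    Not constrained to be monotone.  The smoothing parameter defaults to
    generalized cross-validation.  Coefficients may contain NaN (strata
    where the regression was skipped); those points are dropped, but at
    most 50% may be missing.
    """
    d = np.asarray(distances, dtype=float)
    betas = [np.asarray(b, dtype=float) for b in (beta0, beta1, beta2)]
    ok = np.isfinite(d)
    for b in betas:
        ok &= np.isfinite(b)
    if ok.sum() < max(4, len(d) * 0.5):
        raise ValueError(
            f"coefficients available for only {int(ok.sum())}/{len(d)} strata; "
            "need >=50% and >=4"
        )
    d = d[ok]
    order = np.argsort(d)
    d = d[order]
    ud, inv = np.unique(d, return_inverse=True)
    out = []
    for b in betas:
        v = b[ok][order]
        uv = np.array([v[inv == t].mean() for t in range(len(ud))])
        spl = make_smoothing_spline(ud, uv, lam=lam)
        out.append(ClampedSpline(spl, ud[0], ud[-1]))
    return tuple(out)


@dataclass
class BackgroundModel:
    """Fitted empirical null: totals plus distance (or coefficient) splines."""

    background_class: str
    M: int
    total_observed: int  # C over the background pair set
    occupancy_bins: List[OccupancyBin]
    distance_spline: Optional[ClampedSpline] = None
    beta_splines: Optional[tuple[ClampedSpline, ClampedSpline, ClampedSpline]] = None
    total_expected: float = np.nan  # C' over the same pair set (bias mode)
    bias_mode: bool = False
    regression_pairs: int = 0

    def prior_probability(self, d) -> float:
        if self.distance_spline is None:
            raise ValueError("model has no distance spline (bias mode)")
        return self.distance_spline(d)

    def expected_count(self, d, b1, b2):
        """log c' = f_b0(d) + f_b1(d)*log b1 + f_b2(d)*log b2."""
        if self.beta_splines is None:
            raise ValueError("model has no coefficient splines (no-bias mode)")
        b1 = np.asarray(b1, dtype=float)
        b2 = np.asarray(b2, dtype=float)
        if (b1 <= 0).any() or (b2 <= 0).any():
            raise ValueError("expected_count requires strictly positive biases")
        f0, f1, f2 = self.beta_splines
        logc = f0(d) + f1(d) * np.log(b1) + f2(d) * np.log(b2)
        return np.exp(logc)

    def occupancy_frame(self) -> pd.DataFrame:
        rows = [
            (
                b.index,
                b.n_pairs,
                b.total_count,
                b.mean_distance,
                b.prior_probability,
                b.beta0,
                b.beta1,
                b.beta2,
            )
            for b in self.occupancy_bins
        ]
        return pd.DataFrame(
            rows, columns=["j", "n_j", "S_j", "D_j", "p_j", "beta0", "beta1", "beta2"]
        )


def fit_background(
    cmap: BinnedContactMap,
    ann: BinAnnotation,
    bias: BiasVector,
    background_class: str = BACKGROUND_LOOSE,
    M: int = DEFAULT_M,
    distance_low: int = 20_000,
    distance_high: int = 2_000_000,
    use_bias_regression: bool = True,
    min_regression_pairs: int = 3,
) -> BackgroundModel:
    """Fit the full background model genome-wide (all chromosomes pooled)."""
    pairs = enumerate_pairs(cmap, ann, background_class, distance_low, distance_high)
    bins = equal_occupancy_binning(pairs, M=M)
    C = int(pairs["count"].sum())
    model = BackgroundModel(
        background_class=background_class,
        M=M,
        total_observed=C,
        occupancy_bins=bins,
        bias_mode=use_bias_regression,
    )
    if not use_bias_regression:
        model.distance_spline = fit_distance_spline(
            [b.mean_distance for b in bins], [b.prior_probability for b in bins]
        )
        return model

    # attach biases and run the per-stratum regression
    b1 = np.fromiter(
        (bias.get(c, i) for c, i in zip(pairs["chrom"], pairs["i"])), dtype=float, count=len(pairs)
    )
    b2 = np.fromiter(
        (bias.get(c, j) for c, j in zip(pairs["chrom"], pairs["j"])), dtype=float, count=len(pairs)
    )
    pairs = pairs.assign(b1=b1, b2=b2)
    # assign each pair to its occupancy stratum by cumulative position
    edges = np.cumsum([b.n_pairs for b in bins])
    stratum = np.searchsorted(edges, np.arange(len(pairs)), side="right")
    pairs = pairs.assign(stratum=stratum)
    n_used = 0
    for b in bins:
        g = pairs[pairs["stratum"] == b.index - 1]
        sel = (g["count"] >= 1) & (g["b1"] > 0) & (g["b2"] > 0)
        g = g[sel]
        if len(g) < min_regression_pairs:
            continue
        b.beta0, b.beta1, b.beta2, _ = fit_bias_regression(
            g["count"].to_numpy(), g["b1"].to_numpy(), g["b2"].to_numpy()
        )
        n_used += len(g)
    model.regression_pairs = n_used
    model.beta_splines = fit_coefficient_splines(
        [b.mean_distance for b in bins],
        [b.beta0 for b in bins],
        [b.beta1 for b in bins],
        [b.beta2 for b in bins],
    )
    # C' over the background set restricted to testable (positive-bias) pairs
    testable = (pairs["b1"] > 0) & (pairs["b2"] > 0)
    sub = pairs[testable]
    cprime = model.expected_count(
        sub["distance"].to_numpy(), sub["b1"].to_numpy(), sub["b2"].to_numpy()
    )
    model.total_expected = float(np.sum(cprime))
    return model
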