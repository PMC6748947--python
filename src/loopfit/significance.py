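"""Binomial significance of contact counts and genome-wide loop calling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from loopfit.background import (
    BACKGROUND_ALL,
    BACKGROUND_LOOSE,
    BACKGROUND_STRINGENT,
    BackgroundModel,
    enumerate_pairs,
    fit_background,
)
from loopfit.bias import BiasVector, coverage_bias, ice_bias, unit_bias
from loopfit.io_contacts import BinAnnotation, BinnedContactMap, marginal_coverage

FOREGROUND_PEAK2PEAK = "peak2peak"
FOREGROUND_PEAK2ALL = "peak2all"
FOREGROUND_ALL2ALL = "all2all"

_FG_TO_CLASS = {
    FOREGROUND_PEAK2PEAK: BACKGROUND_STRINGENT,
    FOREGROUND_PEAK2ALL: BACKGROUND_LOOSE,
    FOREGROUND_ALL2ALL: BACKGROUND_ALL,
}


@dataclass
class CallConfig:
    """Options controlling a loop-calling run."""

    binsize: int = 5000
    foreground: str = FOREGROUND_PEAK2ALL
    background: str = BACKGROUND_LOOSE
    bias_mode: str = "coverage"  # coverage | ice | none
    fdr: float = 0.01
    distance_low: int = 20_000
    distance_high: int = 2_000_000
    M: int = 200
    merge: bool = False
    merge_window: int = 2

    def __post_init__(self):
        if not (0 < self.fdr < 1):
            raise ValueError("FDR threshold must be in (0, 1)")
        if self.foreground not in _FG_TO_CLASS:
            raise ValueError(f"unknown foreground {self.foreground!r}")
        if self.background not in (BACKGROUND_STRINGENT, BACKGROUND_LOOSE, BACKGROUND_ALL):
            raise ValueError(f"unknown background {self.background!r}")
        if self.bias_mode not in ("coverage", "ice", "none"):
            raise ValueError(f"unknown bias mode {self.bias_mode!r}")


def binomial_pvalue(k, C: int, p) -> float | np.ndarray:
    """P(X >= k) for X ~ Binomial(C, p); P(X >= 0) = 1."""
    k_arr = np.asarray(k)
    if (k_arr < 0).any() or (k_arr > C).any():
        raise ValueError("require 0 <= k <= C")
    out = stats.binom.sf(k_arr - 1, C, p)
    if np.ndim(k) == 0 and np.ndim(p) == 0:
        return float(out)
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def expected_probability(cprime, total_expected: float):
    """p' = c' / C' where C' sums expected counts over the pairs considered."""
    if total_expected <= 0:
        raise ValueError("C' must be positive")
    return np.asarray(cprime, dtype=float) / total_expected


@dataclass
class LoopSet:
    """Tested pairs with significance estimates, plus run metadata."""

    loops: pd.DataFrame
    config: CallConfig
    model: BackgroundModel
    n_tested: int = 0
    all_tests: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.loops)

    def write_bedpe(self, path) -> None:
        bs = self.config.binsize
        with open(path, "w") as fh:
            fh.write("#chr1\ts1\te1\tchr2\ts2\te2\tcount\texp_count\texp_prob\tpvalue\tqvalue\n")
            for row in self.loops.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.i * bs}\t{(row.i + 1) * bs}\t"
                    f"{row.chrom}\t{row.j * bs}\t{(row.j + 1) * bs}\t"
                    f"{row.count}\t{row.exp_count:.6g}\t{row.exp_prob:.6g}\t"
                    f"{row.pvalue:.6g}\t{row.qvalue:.6g}\n"
                )


def _sort_loops(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(
        by=["qvalue", "pvalue", "count", "chrom", "i", "j"],
        ascending=[True, True, False, True, True, True],
        kind="mergesort",
    )
    return df.reset_index(drop=True)


def call_loops(
    cmap: BinnedContactMap,
    ann: BinAnnotation,
    config: CallConfig,
    bias: Optional[BiasVector] = None,
) -> LoopSet:
    """Full significance pipeline for one contact map.

    Builds the background model per ``config``, tests every foreground
    pair with observed count >= 1 and strictly positive anchor biases,
    applies a single genome-wide BH correction, and returns pairs with
    q <= FDR (optionally merge-filtered).
    """
    if cmap.binsize != config.binsize:
        raise ValueError("contact map binsize does not match config")
    if bias is None:
        if config.bias_mode == "coverage":
            if all(not np.any(ann.coverage[c]) for c in ann.chroms()):
                marginal_coverage(cmap, ann)
            bias = coverage_bias(ann)
        elif config.bias_mode == "ice":
            bias = ice_bias(cmap, ann)
        else:
            bias = unit_bias(ann)

    use_regression = config.bias_mode != "none"
    model = fit_background(
        cmap,
        ann,
        bias,
        background_class=config.background,
        M=config.M,
        distance_low=config.distance_low,
        distance_high=config.distance_high,
        use_bias_regression=use_regression,
    )

    fg = enumerate_pairs(
        cmap, ann, _FG_TO_CLASS[config.foreground], config.distance_low, config.distance_high
    )
    b1 = np.fromiter(
        (bias.get(c, i) for c, i in zip(fg["chrom"], fg["i"])), dtype=float, count=len(fg)
    )
    b2 = np.fromiter(
        (bias.get(c, j) for c, j in zip(fg["chrom"], fg["j"])), dtype=float, count=len(fg)
    )
    fg = fg.assign(b1=b1, b2=b2)
    tested = fg[(fg["count"] >= 1) & (fg["b1"] > 0) & (fg["b2"] > 0)].copy()
    if tested.empty:
        raise ValueError(
            "no testable pairs (count >= 1 with positive biases) for "
            f"foreground {config.foreground!r}"
        )

    C = model.total_observed
    if use_regression:
        cprime = model.expected_count(
            tested["distance"].to_numpy(), tested["b1"].to_numpy(), tested["b2"].to_numpy()
        )
        pprime = expected_probability(cprime, model.total_expected)
    else:
        pprime = np.asarray(model.prior_probability(tested["distance"].to_numpy()))
        cprime = pprime * C
    pprime = np.clip(pprime, 0.0, 1.0)
    pvals = stats.binom.sf(tested["count"].to_numpy() - 1, C, pprime)
    qvals = bh_fdr(pvals)
    tested = tested.assign(exp_count=cprime, exp_prob=pprime, pvalue=pvals, qvalue=qvals)
    tested = _sort_loops(tested)

    sig = tested[tested["qvalue"] <= config.fdr].copy().reset_index(drop=True)
    result = LoopSet(
        loops=sig, config=config, model=model, n_tested=len(tested), all_tests=tested
    )
    if config.merge and not sig.empty:
        from loopfit.merge_filter import MergeConfig, apply_merge_filter

        result.loops = apply_merge_filter(sig, MergeConfig(window=config.merge_window))
    if sig.empty:
        warnings.warn("no significant loops at the requested FDR")
    return result
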