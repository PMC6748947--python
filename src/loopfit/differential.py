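"""Differential contact analysis between two conditions with replicates.

Each locus pair in the union of non-zero pairs is tested with an exact
conditional count test after library-size normalization: negative
binomial with a method-of-moments common dispersion, degrading to the
Poisson (binomial-split) exact test when the dispersion estimate is
non-positive.  Calls pass an FDR gate and a fold-change gate, are
categorized by the 1D signal change of their two anchors, and can be
filtered down to calls supported by a significant loop in at least one
replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from loopfit.significance import bh_fdr

CLASS_HIGH_DIFF = "HD"
CLASS_NO_DIFF = "ND"
CLASS_LOW_DIFF = "LD"

PAIR_CATEGORIES = ("ND-ND", "LD-ND", "LD-LD", "HD-LD/ND", "HD-HD")


def _common_dispersion(norm_counts: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled over pairs (replicate axis=1)."""
    if norm_counts.shape[1] < 2:
        return 0.0
    m = norm_counts.mean(axis=1)
    v = norm_counts.var(axis=1, ddof=1)
    sel = m > 0
    if not sel.any():
        return 0.0
    phi = (v[sel] - m[sel]) / m[sel] ** 2
    return float(max(np.median(phi), 0.0))


def exact_count_test(total_a: float, total_b: float, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact test of condition totals conditional on their sum.

    ``total_a``/``total_b`` are summed library-normalized counts over
    the ``n_a``/``n_b`` replicates.  With dispersion ``phi <= 0`` the
    split of the total follows a binomial with p = n_a / (n_a + n_b);
    otherwise the two totals are NB(size n/phi) and the p-value sums the
    probabilities of all splits at most as likely as the observed one.
    """
    ka = int(round(total_a))
    kb = int(round(total_b))
    t = ka + kb
    if t == 0:
        return 1.0
    x = np.arange(t + 1)
    if phi <= 0:
        probs = stats.binom.pmf(x, t, n_a / (n_a + n_b))
    else:
        mu = t / (n_a + n_b)
        ra, rb = n_a / phi, n_b / phi
        pa = ra / (ra + n_a * mu)
        pb = rb / (rb + n_b * mu)
        probs = stats.nbinom.pmf(x, ra, pa) * stats.nbinom.pmf(t - x, rb, pb)
        s = probs.sum()
        if s <= 0:
            return 1.0
        probs = probs / s
    obs = probs[ka]
    return float(min(probs[probs <= obs * (1 + 1e-12)].sum(), 1.0))


@dataclass
class DifferentialResult:
    calls: pd.DataFrame  # significant differential contacts
    table: pd.DataFrame  # every tested pair with statistics
    dispersion: float


def differential_contacts(
    counts: pd.DataFrame,
    cond_a_cols: Sequence[str],
    cond_b_cols: Sequence[str],
    fdr: float = 0.05,
    min_abs_fc: float = 2.0,
) -> DifferentialResult:
    """Test the union set of pairs for differential contact counts.

    ``counts`` has columns chrom, i, j plus one count column per
    replicate.  Pairs with zero counts in every replicate are dropped.
    Significant calls satisfy q <= fdr and |fold change| > min_abs_fc.
    """
    a_cols, b_cols = list(cond_a_cols), list(cond_b_cols)
    rep_cols = a_cols + b_cols
    mat = counts[rep_cols].to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib[: len(a_cols)].sum() == 0) or (lib[len(a_cols) :].sum() == 0):
        raise ValueError("a condition has zero total counts")
    keep = mat.sum(axis=1) > 0
    df = counts.loc[keep, ["chrom", "i", "j"]].copy().reset_index(drop=True)
    mat = mat[keep]
    # normalize each replicate to the mean library size
    norm = mat * (lib.mean() / lib)[None, :]
    phi = _common_dispersion(norm)
    na, nb = len(a_cols), len(b_cols)
    tot_a = norm[:, :na].sum(axis=1)
    tot_b = norm[:, na:].sum(axis=1)
    pvals = np.array([exact_count_test(ta, tb, na, nb, phi) for ta, tb in zip(tot_a, tot_b)])
    qvals = bh_fdr(pvals)
    # prior-damped fold change of per-replicate means
    prior = 0.5
    log2fc = np.log2((tot_b / nb + prior) / (tot_a / na + prior))
    df = df.assign(
        mean_a=tot_a / na, mean_b=tot_b / nb, log2fc=log2fc, pvalue=pvals, qvalue=qvals
    )
    sig = df[(df["qvalue"] <= fdr) & (np.abs(df["log2fc"]) > np.log2(min_abs_fc))]
    return DifferentialResult(calls=sig.reset_index(drop=True), table=df, dispersion=phi)


def classify_bins_1d(
    cov_a: np.ndarray,
    cov_b: np.ndarray,
    fdr: float = 0.05,
    nd_threshold: float = 0.25,
) -> np.ndarray:
    """Per-bin 1D change class: HD / ND / LD.

    Coverages are scaled to equal totals first.  HD = significant exact
    count test at the given FDR; otherwise ND if the relative difference
    ``|a - b| / max(a, b)`` is below ``nd_threshold`` (0/0 counts as
    ND); the rest are LD.
    """
    a = np.asarray(cov_a, dtype=float)
    b = np.asarray(cov_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coverage vectors must have equal length")
    grand = (a.sum() + b.sum()) / 2.0
    sa = a * (grand / a.sum()) if a.sum() > 0 else a
    sb = b * (grand / b.sum()) if b.sum() > 0 else b
    pvals = np.array(
        [exact_count_test(x, y, 1, 1, 0.0) if x + y > 0 else 1.0 for x, y in zip(sa, sb)]
    )
    qvals = bh_fdr(pvals)
    mx = np.maximum(sa, sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        reldiff = np.where(mx > 0, np.abs(sa - sb) / mx, 0.0)
    classes = np.full(a.shape, CLASS_LOW_DIFF, dtype=object)
    classes[reldiff < nd_threshold] = CLASS_NO_DIFF
    classes[qvals <= fdr] = CLASS_HIGH_DIFF
    return classes


def pair_category(class_i: str, class_j: str) -> str:
    """Unordered anchor-class pair to one of the five categories."""
    pair = frozenset((class_i, class_j))
    if pair == {CLASS_HIGH_DIFF}:
        return "HD-HD"
    if CLASS_HIGH_DIFF in pair:
        return "HD-LD/ND"
    if pair == {CLASS_NO_DIFF}:
        return "ND-ND"
    if pair == {CLASS_LOW_DIFF}:
        return "LD-LD"
    return "LD-ND"


def attach_categories(
    calls: pd.DataFrame, classes: Dict[str, np.ndarray]
) -> pd.DataFrame:
    """Annotate differential calls with anchor classes and pair category."""
    ci, cj, cat = [], [], []
    for row in calls.itertuples(index=False):
        cls = classes[row.chrom]
        a, b = cls[int(row.i)], cls[int(row.j)]
        ci.append(a)
        cj.append(b)
        cat.append(pair_category(a, b))
    return calls.assign(class_i=ci, class_j=cj, category=cat)


def filter_by_loops(
    calls: pd.DataFrame,
    loops_a: List[pd.DataFrame],
    loops_b: List[pd.DataFrame],
) -> pd.DataFrame:
    """Keep calls that exactly match a loop in >= 1 replicate; label exclusivity.

    ``loops_a``/``loops_b`` are per-replicate significant-loop tables
    (chrom, i, j) from the two conditions.  Exclusivity is ``cond1`` /
    ``cond2`` / ``both`` depending on which condition's replicates carry
    the loop.
    """

    def key_set(frames: List[pd.DataFrame]) -> set:
        keys = set()
        for f in frames:
            keys.update(zip(f["chrom"], f["i"].astype(int), f["j"].astype(int)))
        return keys

    in_a = key_set(loops_a)
    in_b = key_set(loops_b)
    kept_rows = []
    labels = []
    for idx, row in enumerate(calls.itertuples(index=False)):
        key = (row.chrom, int(row.i), int(row.j))
        a, b = key in in_a, key in in_b
        if not (a or b):
            continue
        kept_rows.append(idx)
        labels.append("both" if a and b else ("cond1" if a else "cond2"))
    out = calls.iloc[kept_rows].copy()
    out["exclusivity"] = labels
    return out.reset_index(drop=True)
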