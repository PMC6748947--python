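"""Loop-set comparison: slack overlap, recovery curves, aggregate analysis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

DEFAULT_SLACK = 5000


def _anchors(loop) -> Tuple[str, int, int, int, int]:
    """Normalize a loop record to (chrom, s1, e1, s2, e2) with left anchor first."""
    chrom, s1, e1, s2, e2 = loop
    if s2 < s1:
        s1, e1, s2, e2 = s2, e2, s1, e1
    return chrom, int(s1), int(e1), int(s2), int(e2)


def loops_overlap(a, b, slack: int = DEFAULT_SLACK) -> bool:
    """True iff both slack-extended anchors of ``a`` intersect those of ``b``.

    Loops are (chrom, start1, end1, start2, end2) tuples; anchors are
    ordered left < right before matching; inter-chromosomal pairs never
    overlap.
    """
    ca, a1s, a1e, a2s, a2e = _anchors(a)
    cb, b1s, b1e, b2s, b2e = _anchors(b)
    if ca != cb:
        return False

    def hit(s1, e1, s2, e2):
        return (s1 - slack) < (e2 + slack) and (s2 - slack) < (e1 + slack)

    return hit(a1s, a1e, b1s, b1e) and hit(a2s, a2e, b2s, b2e)


def bin_loop_frame(df: pd.DataFrame, binsize: int) -> pd.DataFrame:
    """Map variable-width anchors to bins via their midpoints; de-duplicate.

    Input needs columns chrom, s1, e1, s2, e2; output has chrom, i, j
    (bin indices, i <= j) with duplicates removed.
    """
    mid1 = (df["s1"] + df["e1"]) // 2
    mid2 = (df["s2"] + df["e2"]) // 2
    i = (mid1 // binsize).astype(int)
    j = (mid2 // binsize).astype(int)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    out = pd.DataFrame({"chrom": df["chrom"], "i": lo, "j": hi})
    return out.drop_duplicates().reset_index(drop=True)


def _loop_tuples(df: pd.DataFrame, binsize: Optional[int]) -> list:
    if {"s1", "e1", "s2", "e2"}.issubset(df.columns):
        return [
            (r.chrom, int(r.s1), int(r.e1), int(r.s2), int(r.e2)) for r in df.itertuples(index=False)
        ]
    if binsize is None:
        raise ValueError("binsize required for bin-indexed loop frames")
    return [
        (r.chrom, r.i * binsize, (r.i + 1) * binsize, r.j * binsize, (r.j + 1) * binsize)
        for r in df.itertuples(index=False)
    ]


def recovery_curve(
    calls: pd.DataFrame,
    reference: pd.DataFrame,
    slack: int = DEFAULT_SLACK,
    binsize: Optional[int] = None,
) -> pd.DataFrame:
    """Fraction of reference loops hit by the top-m calls, for every m.

    ``calls`` must already carry its ranking order (row order).  Output
    columns: ``n_calls``, ``fraction``; the fraction is non-decreasing.
    """
    if reference.empty:
        raise ValueError("reference loop set is empty")
    call_t = _loop_tuples(calls, binsize)
    ref_t = _loop_tuples(reference, binsize)
    hit = np.zeros(len(ref_t), dtype=bool)
    fractions = []
    for m, c in enumerate(call_t, start=1):
        for r_idx, r in enumerate(ref_t):
            if not hit[r_idx] and loops_overlap(c, r, slack):
                hit[r_idx] = True
        fractions.append(hit.mean())
    return pd.DataFrame({"n_calls": np.arange(1, len(call_t) + 1), "fraction": fractions})


def top_k(
    loops: pd.DataFrame, k: int, dist_range: Optional[Tuple[int, int]] = None
) -> pd.DataFrame:
    """Best k loops (row order = ranking) after optional distance filtering."""
    df = loops
    if dist_range is not None and "distance" in df.columns:
        lo, hi = dist_range
        df = df[(df["distance"] >= lo) & (df["distance"] <= hi)]
    if k > len(df):
        import warnings

        warnings.warn(f"requested top {k} of {len(df)} loops; returning all")
    return df.head(k).reset_index(drop=True)


@dataclass
class APAResult:
    """Aggregate matrix around loop centers with enrichment scores."""

    matrix: np.ndarray
    score: float  # center vs 15-30 kb lower-left block
    center_ratio: float  # R: center vs all remaining pixels
    corner_scores: Dict[str, float]  # ul, ur, ll, lr
    n_loops: int
    n_skipped: int


def apa(
    loops: pd.DataFrame,
    matrices: Dict[str, np.ndarray],
    binsize: int,
    window: int = 50_000,
    dist_range: Tuple[int, int] = (150_000, 1_000_000),
    block_offsets: Tuple[int, int] = (3, 6),
    corner_size: int = 3,
) -> APAResult:
    """Aggregate analysis of (normalized) contact submatrices around loops.

    For each loop (bin pair i < j) inside ``dist_range`` the
    ``(2w+1) x (2w+1)`` submatrix centered on (i, j) is extracted
    (w = window // binsize); loops whose window leaves the matrix or
    crosses the diagonal are skipped.  Scores on the element-wise mean:

    * ``score``: center / mean of the block spanning row offsets
      ``+lo..+hi`` and column offsets ``-hi..-lo`` (default 15-30 kb at
      5 kb resolution, toward the diagonal).
    * ``center_ratio`` (R): center / mean of all other pixels.
    * corner scores: center / mean of each ``corner_size``-square corner
      block (within 10 kb of the corner at default settings).
    """
    w = window // binsize
    lo_d, hi_d = dist_range
    agg = np.zeros((2 * w + 1, 2 * w + 1))
    n_used = n_skip = 0
    for row in loops.itertuples(index=False):
        chrom, i, j = row.chrom, int(row.i), int(row.j)
        if i > j:
            i, j = j, i
        d = (j - i) * binsize
        if d < lo_d or d > hi_d:
            n_skip += 1
            continue
        mat = matrices.get(chrom)
        if mat is None:
            n_skip += 1
            continue
        n = mat.shape[0]
        if i - w < 0 or j + w >= n or (i + w) >= (j - w):
            n_skip += 1
            continue
        agg += mat[i - w : i + w + 1, j - w : j + w + 1]
        n_used += 1
    if n_used == 0:
        raise ValueError("no loops contributed to the aggregate matrix")
    agg /= n_used
    c = w
    center = agg[c, c]
    lo, hi = block_offsets
    block = agg[c + lo : c + hi + 1, c - hi : c - lo + 1]
    score = _ratio(center, block.mean())
    rest = agg.sum() - center
    center_ratio = _ratio(center, rest / (agg.size - 1))
    s = corner_size
    corners = {
        "ul": agg[:s, :s].mean(),
        "ur": agg[:s, -s:].mean(),
        "ll": agg[-s:, :s].mean(),
        "lr": agg[-s:, -s:].mean(),
    }
    corner_scores = {k: _ratio(center, v) for k, v in corners.items()}
    return APAResult(
        matrix=agg,
        score=score,
        center_ratio=center_ratio,
        corner_scores=corner_scores,
        n_loops=n_used,
        n_skipped=n_skip,
    )


def _ratio(num: float, den: float) -> float:
    return float(num / den) if den > 0 else float("nan")


def write_apa_matrix(result: APAResult, path) -> None:
    np.savetxt(path, result.matrix, delimiter="\t", fmt="%.6g")


def write_apa_heatmap(result: APAResult, path) -> None:
    """Basic PNG heatmap of the aggregate matrix (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(result.matrix, cmap="Reds")
    ax.set_title(f"APA {result.score:.2f} (R {result.center_ratio:.2f}, n={result.n_loops})")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
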