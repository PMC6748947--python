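"""Bystander-loop reduction: connected components + iterative window selection.

Significant loops on one chromosome form a binary matrix over bin pairs.
Adjacent calls (Chebyshev distance <= 1, the 8-connectivity rule) are
grouped into connected components; within each component either a single
minimum-p loop is kept (MIN) or a greedy iterative pass admits every
loop that is not within the B-bin window of an already-admitted one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import networkx as nx
import pandas as pd

RANK_SIGNIFICANCE = "q"
RANK_COUNT = "count"


@dataclass
class MergeConfig:
    window: int = 2  # half-width B in bins; admitted iff Chebyshev distance > B
    rank: str = RANK_SIGNIFICANCE

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window half-width must be >= 1")
        if self.rank not in (RANK_SIGNIFICANCE, RANK_COUNT):
            raise ValueError(f"unknown ranking {self.rank!r}")


def _rank_sorted(df: pd.DataFrame, rank: str) -> pd.DataFrame:
    if rank == RANK_COUNT:
        by, asc = ["count", "i", "j"], [False, True, True]
        if "qvalue" in df.columns:
            by, asc = ["count", "qvalue", "i", "j"], [False, True, True, True]
    else:
        by = [c for c in ("qvalue", "pvalue") if c in df.columns]
        asc = [True] * len(by)
        if "count" in df.columns:
            by, asc = by + ["count"], asc + [False]
        by, asc = by + ["i", "j"], asc + [True, True]
    return df.sort_values(by=by, ascending=asc, kind="mergesort")


def connected_components(loops: pd.DataFrame) -> List[pd.DataFrame]:
    """Partition one chromosome's loops into 8-connectivity components."""
    if loops.empty:
        return []
    if loops["chrom"].nunique() > 1:
        raise ValueError("connected_components expects loops from a single chromosome")
    g = nx.Graph()
    index_of = {}
    for row in loops.itertuples():
        key = (int(row.i), int(row.j))
        index_of[key] = row.Index
        g.add_node(key)
    for (i, j) in list(index_of):
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                nb = (i + di, j + dj)
                if nb in index_of:
                    g.add_edge((i, j), nb)
    comps = []
    for nodes in nx.connected_components(g):
        idx = [index_of[n] for n in nodes]
        comps.append(loops.loc[sorted(idx)])
    comps.sort(key=lambda c: (int(c["i"].min()), int(c["j"].min())))
    return comps


def iterative_merge(component: pd.DataFrame, config: MergeConfig) -> pd.DataFrame:
    """Greedy representative selection within one component.

    Repeatedly take the best-ranked remaining loop; admit it iff its
    Chebyshev distance (on bin indices) to every admitted loop is > B.
    """
    ranked = _rank_sorted(component, config.rank)
    admitted: list[tuple[int, int]] = []
    keep = []
    B = config.window
    for row in ranked.itertuples():
        i, j = int(row.i), int(row.j)
        if all(max(abs(i - ai), abs(j - aj)) > B for ai, aj in admitted):
            admitted.append((i, j))
            keep.append(row.Index)
    return component.loc[sorted(keep)]


def min_filter(component: pd.DataFrame) -> pd.DataFrame:
    """Keep the single minimum-p loop of the component (deterministic ties)."""
    by = [c for c in ("pvalue", "qvalue") if c in component.columns]
    asc = [True] * len(by)
    if "count" in component.columns:
        by, asc = by + ["count"], asc + [False]
    by, asc = by + ["i", "j"], asc + [True, True]
    return component.sort_values(by=by, ascending=asc, kind="mergesort").iloc[:1]


def apply_merge_filter(
    loops: pd.DataFrame, config: MergeConfig | None = None, mode: str = "iterative"
) -> pd.DataFrame:
    """Apply the merging filter per chromosome to a loop table."""
    config = config or MergeConfig()
    if loops.empty:
        return loops.copy()
    kept = []
    for _, sub in loops.groupby("chrom", sort=True):
        for comp in connected_components(sub):
            if mode == "iterative":
                kept.append(iterative_merge(comp, config))
            elif mode == "min":
                kept.append(min_filter(comp))
            else:
                raise ValueError(f"unknown merge mode {mode!r}")
    out = pd.concat(kept)
    return out.loc[sorted(out.index)].reset_index(drop=True)
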