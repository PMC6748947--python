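"""Parsing of valid-pairs / sparse contact / BED inputs and bin-level annotation.

Coordinates are 0-based half-open throughout.  A genomic bin with index
``i`` at bin size ``s`` spans ``[i*s, (i+1)*s)``.  Pair distance is the
bin-start difference ``(j - i) * s``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default intra-chromosomal distance window, in bp (closed bounds)
DEFAULT_DISTANCE_LOW = 20_000
DEFAULT_DISTANCE_HIGH = 2_000_000


def bin_position(pos: int, binsize: int) -> int:
    """Map a 0-based genomic position to its bin index (floor division)."""
    if pos < 0:
        raise ValueError(f"position must be non-negative, got {pos}")
    if binsize <= 0:
        raise ValueError(f"binsize must be positive, got {binsize}")
    return int(pos) // int(binsize)


def classify_pair(flag_i: bool, flag_j: bool) -> str:
    """Classify a bin pair by peak status: ``PP``, ``PN`` or ``NN``."""
    if flag_i and flag_j:
        return "PP"
    if flag_i or flag_j:
        return "PN"
    return "NN"


@dataclass
class BinnedContactMap:
    """Sparse upper-triangular (i <= j) contact counts per chromosome."""

    binsize: int
    counts: Dict[str, Dict[Tuple[int, int], int]] = field(default_factory=dict)
    trans_pairs: int = 0
    distance_filtered: int = 0

    def add(self, chrom: str, i: int, j: int, k: int = 1) -> None:
        if i > j:
            i, j = j, i
        if k < 0:
            raise ValueError("contact count must be non-negative")
        bucket = self.counts.setdefault(chrom, {})
        bucket[(i, j)] = bucket.get((i, j), 0) + k

    def get(self, chrom: str, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        return self.counts.get(chrom, {}).get((i, j), 0)

    def chroms(self) -> list[str]:
        return sorted(self.counts)

    def pairs(self) -> Iterator[Tuple[str, int, int, int]]:
        for chrom in self.chroms():
            for (i, j), k in sorted(self.counts[chrom].items()):
                yield chrom, i, j, k

    def total(self, distance_low: int | None = None, distance_high: int | None = None) -> int:
        """Total contact count, optionally restricted to a distance range (bp, closed)."""
        tot = 0
        for chrom, i, j, k in self.pairs():
            d = (j - i) * self.binsize
            if distance_low is not None and d < distance_low:
                continue
            if distance_high is not None and d > distance_high:
                continue
            tot += k
        return tot

    def n_pairs(self) -> int:
        return sum(len(v) for v in self.counts.values())

    def max_bin(self, chrom: str) -> int:
        bucket = self.counts.get(chrom, {})
        if not bucket:
            return -1
        return max(j for (_, j) in bucket)

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.pairs())
        return pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "count"])

    # --- sparse text round-trip: `chrom  bin1_start  bin2_start  count` ---

    def write_text(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, i, j, k in self.pairs():
                fh.write(f"{chrom}\t{i * self.binsize}\t{j * self.binsize}\t{k}\n")

    @classmethod
    def read_text(cls, path, binsize: int) -> "BinnedContactMap":
        cmap = cls(binsize=binsize)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
                chrom, s1, s2, k = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
                cmap.add(chrom, s1 // binsize, s2 // binsize, k)
        return cmap


def load_validpairs(
    path,
    binsize: int,
    distance_low: int = DEFAULT_DISTANCE_LOW,
    distance_high: int = DEFAULT_DISTANCE_HIGH,
) -> BinnedContactMap:
    """Bin a HiC-Pro style valid-pairs text file into a sparse contact map.

    Expected whitespace-delimited columns (extra columns ignored)::

        read_id  chr1  pos1  strand1  chr2  pos2  strand2  ...

    Intra-chromosomal pairs are aggregated per (bin_i, bin_j) with
    ``i <= j``; pairs outside the closed distance window are dropped;
    trans pairs are dropped and tallied on the returned map.
    """
    cmap = BinnedContactMap(binsize=binsize)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"{path}:{lineno}: expected >=7 columns, got {len(parts)}")
            try:
                chr1, pos1 = parts[1], int(parts[2])
                chr2, pos2 = parts[4], int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed positions") from exc
            if chr1 != chr2:
                cmap.trans_pairs += 1
                continue
            i = bin_position(pos1, binsize)
            j = bin_position(pos2, binsize)
            if i > j:
                i, j = j, i
            d = (j - i) * binsize
            if d < distance_low or d > distance_high:
                cmap.distance_filtered += 1
                continue
            cmap.add(chr1, i, j, 1)
    if cmap.trans_pairs:
        logger.info("dropped %d trans pairs", cmap.trans_pairs)
    if cmap.n_pairs() == 0:
        warnings.warn("no intra-chromosomal pairs retained from %s" % path)
    return cmap


@dataclass
class BinAnnotation:
    """Per-bin peak status, 1D coverage, and (optional) bias values."""

    binsize: int
    n_bins: Dict[str, int]
    peak_flags: Dict[str, np.ndarray] = field(default_factory=dict)
    coverage: Dict[str, np.ndarray] = field(default_factory=dict)
    bias: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, n in self.n_bins.items():
            self.peak_flags.setdefault(chrom, np.zeros(n, dtype=bool))
            self.coverage.setdefault(chrom, np.zeros(n, dtype=float))

    @classmethod
    def from_chromsizes(cls, chromsizes: Dict[str, int], binsize: int) -> "BinAnnotation":
        n_bins = {c: -(-int(length) // binsize) for c, length in chromsizes.items()}
        return cls(binsize=binsize, n_bins=n_bins)

    def chroms(self) -> list[str]:
        return sorted(self.n_bins)

    def to_frame(self) -> pd.DataFrame:
        """Bias table: chrom, start, end, coverage, is_peak, bias."""
        rows = []
        for chrom in self.chroms():
            n = self.n_bins[chrom]
            b = self.bias.get(chrom, np.zeros(n))
            for i in range(n):
                rows.append(
                    (
                        chrom,
                        i * self.binsize,
                        (i + 1) * self.binsize,
                        float(self.coverage[chrom][i]),
                        bool(self.peak_flags[chrom][i]),
                        float(b[i]),
                    )
                )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "coverage", "is_peak", "bias"])


def read_chromsizes(path) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split()[:2]
            sizes[chrom] = int(length)
    return sizes


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    return df


def annotate_peaks(
    peaks: pd.DataFrame | list,
    binsize: int,
    chromsizes: Dict[str, int],
) -> BinAnnotation:
    """Flag every bin that overlaps a peak interval by at least 1 bp.

    ``peaks`` is a BED3-like frame or list of (chrom, start, end), 0-based
    half-open.  Peaks extending beyond the chromosome end are clipped with
    a warning.
    """
    ann = BinAnnotation.from_chromsizes(chromsizes, binsize)
    if isinstance(peaks, pd.DataFrame):
        records = peaks[["chrom", "start", "end"]].itertuples(index=False)
    else:
        records = iter(peaks)
    for chrom, start, end in records:
        if chrom not in ann.n_bins:
            continue
        start, end = int(start), int(end)
        length = ann.n_bins[chrom] * binsize
        if end > chromsizes[chrom]:
            warnings.warn(f"peak {chrom}:{start}-{end} beyond chromosome end; clipping")
            end = min(end, length)
        if end <= start:
            continue
        first = start // binsize
        last = (end - 1) // binsize  # half-open: last covered base is end-1
        ann.peak_flags[chrom][first : last + 1] = True
    return ann


def marginal_coverage(cmap: BinnedContactMap, ann: BinAnnotation) -> None:
    """Fill ``ann.coverage`` with the contact-map marginals.

    Each aligned end contributes its pair's count once to its own bin.
    """
    for chrom in ann.chroms():
        ann.coverage[chrom] = np.zeros(ann.n_bins[chrom], dtype=float)
    for chrom, i, j, k in cmap.pairs():
        if chrom not in ann.coverage:
            continue
        cov = ann.coverage[chrom]
        if i < len(cov):
            cov[i] += k
        if j < len(cov):
            cov[j] += k


def read_bedgraph_coverage(path, ann: BinAnnotation) -> None:
    """Load per-bin coverage from a bedGraph-like file into ``ann.coverage``.

    Values are distributed to bins proportionally to bp overlap.
    """
    for chrom in ann.chroms():
        ann.coverage[chrom] = np.zeros(ann.n_bins[chrom], dtype=float)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split()[:4]
            if chrom not in ann.coverage:
                continue
            start, end, value = int(start), int(end), float(value)
            cov = ann.coverage[chrom]
            first = start // ann.binsize
            last = (end - 1) // ann.binsize
            for b in range(first, min(last, len(cov) - 1) + 1):
                lo = max(start, b * ann.binsize)
                hi = min(end, (b + 1) * ann.binsize)
                cov[b] += value * (hi - lo)
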