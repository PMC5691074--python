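"""Window-based co-occurrence of footprints and protein-binding sites.

The genome is tiled into fixed-width windows (50 nt by default, final window
truncated, no wrap across the circular origin).  A window counts as hit by an
interval set when at least 1 nt of at least one interval falls inside it, and
enrichment of joint hits is tested with the upper-tail hypergeometric
probability P(X >= k) for population N windows, K hit by set A, n drawn by
set B, k hit by both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .coverage_io import Interval, GenomeSpec

__all__ = ["WindowGrid", "OverlapTable", "make_windows", "windows_hit", "hypergeometric_overlap_test"]


@dataclass
class WindowGrid:
    """Consecutive non-overlapping windows tiling [0, genome.length)."""

    genome: GenomeSpec
    width: int
    windows: list[Interval]

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class OverlapTable:
    """2x2 window-overlap counts and the enrichment p-value."""

    N: int  # total windows
    K: int  # windows hit by set A
    n: int  # windows hit by set B
    k: int  # windows hit by both
    p_value: float


def make_windows(genome: GenomeSpec, width: int = 50) -> WindowGrid:
    """Tile the genome into ``width``-nt windows; the last may be shorter."""
    if width < 1:
        raise ValueError(f"window width must be >= 1, got {width}")
    edges = list(range(0, genome.length, width)) + [genome.length]
    windows = [
        Interval(genome, s, e, label=f"win{i:04d}")
        for i, (s, e) in enumerate(zip(edges[:-1], edges[1:]))
    ]
    return WindowGrid(genome, width, windows)


def windows_hit(
    intervals: Sequence[Interval], grid: WindowGrid, strand: str | None = None
) -> np.ndarray:
    """Boolean vector: window flagged iff >= 1 nt overlap with >= 1 interval.

    Strand-agnostic unless ``strand`` is given, in which case only intervals
    on that strand (or unstranded ones) count.
    """
    hits = np.zeros(len(grid.windows), dtype=bool)
    w = grid.width
    L = grid.genome.length
    for iv in intervals:
        if iv.genome.length != L:
            raise ValueError("interval genome does not match grid genome")
        if strand is not None and iv.strand not in (strand, "."):
            continue
        first = iv.start // w
        last = (iv.end - 1) // w
        hits[first : last + 1] = True
    return hits


def window_hit_counts(intervals: Sequence[Interval], grid: WindowGrid) -> np.ndarray:
    """Per-window interval counts (reported alongside the binary hits)."""
    counts = np.zeros(len(grid.windows), dtype=int)
    w = grid.width
    for iv in intervals:
        counts[iv.start // w : (iv.end - 1) // w + 1] += 1
    return counts


def hypergeometric_overlap_test(N: int, K: int, n: int, k: int) -> OverlapTable:
    """Upper-tail hypergeometric test of joint window hits.

    p = P(X >= k) with X ~ Hypergeometric(N, K, n); symmetric in K and n.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return OverlapTable(N=N, K=K, n=n, k=k, p_value=min(p, 1.0))


def overlap_test(
    set_a: Sequence[Interval], set_b: Sequence[Interval], grid: WindowGrid
) -> OverlapTable:
    """Convenience wrapper: bin both interval sets and run the test."""
    a = windows_hit(set_a, grid)
    b = windows_hit(set_b, grid)
    return hypergeometric_overlap_test(
        N=len(grid.windows), K=int(a.sum()), n=int(b.sum()), k=int((a & b).sum())
    )
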