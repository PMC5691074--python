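"""Footprint detection on a C-score track.

A footprint is a central span of 8–40 nt whose mean C score is strictly below
the mean of each of its two 3-nt flanks, quantified by the F score

    F = 10^(C - L) + 10^(C - R)

where C, L, R are the mean C scores of the central, left-flank and right-flank
regions.  F equals 2 when the centre matches its flanks and drops below 2 as
the centre becomes protected; candidates additionally require F < 2.

Overlapping candidates are resolved by greedy non-maximum suppression in
ascending F-score order (best-protected first), ties broken by leftmost start
then shortest span, so the scan is deterministic.  On circular genomes both
the central region and the flanks may wrap the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage_io import GenomeSpec
from .scoring import CScoreTrack

__all__ = ["ScanParams", "Footprint", "f_score", "candidate_spans", "scan_footprints", "region_means"]

#: absolute margin for the central-below-flank comparisons; far below any
#: meaningful C-score difference but above cumulative-sum roundoff
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class ScanParams:
    """Width/flank bounds and the F-score threshold for the footprint scan."""

    min_len: int = 8
    max_len: int = 40
    flank_len: int = 3
    f_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")
        if self.flank_len < 1:
            raise ValueError("flank_len must be >= 1")
        if self.f_threshold <= 0:
            raise ValueError("f_threshold must be positive")


@dataclass
class Footprint:
    """A protected central span with its flank statistics.

    ``start`` is always in ``[0, genome.length)``; ``end = start + width`` and
    may exceed ``genome.length`` when the central region wraps the circular
    origin (position indices are taken modulo the genome length).
    """

    genome: GenomeSpec
    strand: str
    start: int
    end: int
    c_central: float
    c_left: float
    c_right: float
    f_score: float
    name: str = ""

    @property
    def width(self) -> int:
        return self.end - self.start

    def positions(self) -> np.ndarray:
        """Genome positions covered by the central region (modular)."""
        return np.arange(self.start, self.end) % self.genome.length


def f_score(c_central: float, c_left: float, c_right: float):
    """F score of a candidate span: 10^(C-L) + 10^(C-R).

    Symmetric in the two flanks; equals 2.0 when C = L = R.
    """
    c_central = np.asarray(c_central, dtype=float)
    return 10.0 ** (c_central - c_left) + 10.0 ** (c_central - c_right)


def region_means(
    values: np.ndarray, start: int, width: int, flank: int, circular: bool
) -> tuple[float, float, float]:
    """Mean score over a central span and its two flanks.

    Returns ``(central, left, right)``.  On circular genomes indices wrap; on
    linear genomes the caller must ensure the flanks are in bounds.
    """
    L = len(values)
    if circular:
        central_idx = np.arange(start, start + width) % L
        left_idx = np.arange(start - flank, start) % L
        right_idx = np.arange(start + width, start + width + flank) % L
    else:
        if start - flank < 0 or start + width + flank > L:
            raise ValueError("span flanks out of bounds on a linear genome")
        central_idx = np.arange(start, start + width)
        left_idx = np.arange(start - flank, start)
        right_idx = np.arange(start + width, start + width + flank)
    return (
        float(values[central_idx].mean()),
        float(values[left_idx].mean()),
        float(values[right_idx].mean()),
    )


def _candidate_arrays(
    values: np.ndarray,
    params: ScanParams,
    circular: bool,
    valid_mask: np.ndarray | None = None,
):
    """All spans passing the both-flank and F-threshold conditions, as arrays.

    Returns (starts, widths, central, left, right, fscores).  Vectorized per
    width using a cumulative sum over the doubled track (circular case).
    """
    L = len(values)
    if L <= params.max_len + 2 * params.flank_len:
        raise ValueError(
            f"genome of {L} nt is too short for max_len={params.max_len} "
            f"with {params.flank_len} nt flanks"
        )
    fl = params.flank_len
    if circular:
        cs = np.concatenate([[0.0], np.cumsum(np.concatenate([values, values]))])
    else:
        cs = np.concatenate([[0.0], np.cumsum(values)])
    # optional low-coverage mask: spans touching an invalid position (central
    # or flank) are excluded; counted via a cumulative sum of invalid flags
    bad_cum = None
    if valid_mask is not None:
        bad = (~np.asarray(valid_mask, dtype=bool)).astype(float)
        if circular:
            bad_cum = np.concatenate([[0.0], np.cumsum(np.concatenate([bad, bad]))])
        else:
            bad_cum = np.concatenate([[0.0], np.cumsum(bad)])
    out = {k: [] for k in ("s", "w", "c", "l", "r", "f")}
    for w in range(params.min_len, params.max_len + 1):
        if circular:
            starts = np.arange(L)
            central = (cs[starts + w] - cs[starts]) / w
            ls = (starts - fl) % L
            left = (cs[ls + fl] - cs[ls]) / fl
            rs = starts + w
            right = (cs[rs + fl] - cs[rs]) / fl
        else:
            if fl + w + fl > L:
                continue
            starts = np.arange(fl, L - w - fl + 1)
            central = (cs[starts + w] - cs[starts]) / w
            left = (cs[starts] - cs[starts - fl]) / fl
            right = (cs[starts + w + fl] - cs[starts + w]) / fl
        fsc = 10.0 ** (central - left) + 10.0 ** (central - right)
        # strict below-both-flanks condition, with a small absolute margin so
        # prefix-sum roundoff cannot promote exactly-tied spans (C is O(1))
        keep = (
            (central < left - _TIE_TOL)
            & (central < right - _TIE_TOL)
            & (fsc < params.f_threshold)
        )
        if bad_cum is not None:
            span = w + 2 * fl
            lo = (starts - fl) % len(values) if circular else starts - fl
            keep &= (bad_cum[lo + span] - bad_cum[lo]) == 0
        out["s"].append(starts[keep])
        out["w"].append(np.full(keep.sum(), w))
        out["c"].append(central[keep])
        out["l"].append(left[keep])
        out["r"].append(right[keep])
        out["f"].append(fsc[keep])
    return tuple(np.concatenate(out[k]) if out[k] else np.array([]) for k in "swclrf")


def _to_footprints(track: CScoreTrack, arrays, order=None) -> list[Footprint]:
    s, w, c, l, r, f = arrays
    idx = range(len(s)) if order is None else order
    return [
        Footprint(
            genome=track.genome,
            strand=track.strand,
            start=int(s[i]),
            end=int(s[i] + w[i]),
            c_central=float(c[i]),
            c_left=float(l[i]),
            c_right=float(r[i]),
            f_score=float(f[i]),
        )
        for i in idx
    ]


def candidate_spans(
    cscores: CScoreTrack,
    params: ScanParams = ScanParams(),
    valid_mask: np.ndarray | None = None,
) -> list[Footprint]:
    """Every span satisfying the footprint conditions, overlaps included.

    ``valid_mask`` (optional, per-position booleans) excludes spans whose
    central region or flanks touch a masked position — used to drop loci
    with untreated coverage below a floor.  Off by default.
    """
    arrays = _candidate_arrays(cscores.values, params, cscores.genome.circular, valid_mask)
    return _to_footprints(cscores, arrays)


def scan_footprints(
    cscores: CScoreTrack,
    params: ScanParams = ScanParams(),
    valid_mask: np.ndarray | None = None,
) -> list[Footprint]:
    """Non-overlapping footprints, greedily selected by ascending F score.

    Returned footprints are sorted by start coordinate; their central regions
    are pairwise disjoint.  ``valid_mask`` as in :func:`candidate_spans`.
    """
    values = cscores.values
    L = len(values)
    s, w, c, l, r, f = _candidate_arrays(values, params, cscores.genome.circular, valid_mask)
    if len(s) == 0:
        return []
    # ascending f, then leftmost start, then shortest span
    order = np.lexsort((w, s, f))
    occupied = np.zeros(L, dtype=bool)
    accepted: list[int] = []
    for i in order:
        pos = np.arange(s[i], s[i] + w[i]) % L
        if occupied[pos].any():
            continue
        occupied[pos] = True
        accepted.append(int(i))
    accepted.sort(key=lambda i: (s[i], w[i]))
    fps = _to_footprints(cscores, (s, w, c, l, r, f), accepted)
    for k, fp in enumerate(fps):
        fp.name = f"fp{k + 1:04d}"
    return fps
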