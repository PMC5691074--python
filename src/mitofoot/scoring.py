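"""Per-nucleotide cleavage-accessibility (C) and structure-propensity (R) scores.

Both scores read the normalized 5' coverage of the nucleotide immediately
downstream of the inspected position (an endonuclease that cuts 5' of base
``i+1`` exposes base ``i``):

* ``C_i = log10((max(A, T1, If)_{i+1} + 1) / (Untreated_{i+1} + 1))`` —
  high C means the base is accessible to at least one RNase, low C means it is
  protected (bound by protein or otherwise shielded).
* ``R_i = log2((A_{i+1} + 1) / (T1_{i+1} + 1))`` — the ratio of
  double-strand-specific to single-strand-specific cleavage; higher R means
  greater secondary-structure propensity.

On a circular genome the ``i+1`` index wraps to 0; on a linear genome the last
position has no downstream neighbour and is set to 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coverage_io import CleavageProfile, CoverageTrack, GenomeSpec

__all__ = ["CScoreTrack", "RScoreTrack", "compute_c_score", "compute_r_score", "r_score_log2fc"]


@dataclass
class _ScoreTrack:
    genome: GenomeSpec
    strand: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.genome.length,):
            raise ValueError("score track length does not match genome length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score values must be finite")


class CScoreTrack(_ScoreTrack):
    """Per-position RNase-accessibility score (log10 scale)."""


class RScoreTrack(_ScoreTrack):
    """Per-position double/single-strand cleavage ratio (log2 scale)."""


def _downstream(track: CoverageTrack) -> np.ndarray:
    """Coverage of position i+1 aligned to position i (circular wrap)."""
    return np.roll(track.values, -1)


def _fix_linear_end(values: np.ndarray, genome: GenomeSpec, what: str) -> None:
    if not genome.circular:
        values[-1] = 0.0
        warnings.warn(
            f"linear genome: {what} at the final position has no downstream "
            "neighbour and is set to 0",
            stacklevel=3,
        )


def compute_c_score(profile: CleavageProfile) -> CScoreTrack:
    """Compute the C-score track for a cleavage profile.

    Pseudocounts of +1 are applied to the normalized (RPM) coverage values,
    and the maximum over the three RNase conditions is taken per position.
    """
    a = _downstream(profile.a)
    t1 = _downstream(profile.t1)
    if_ = _downstream(profile.if_)
    u = _downstream(profile.untreated)
    best = np.maximum(np.maximum(a, t1), if_)
    c = np.log10((best + 1.0) / (u + 1.0))
    _fix_linear_end(c, profile.genome, "C score")
    return CScoreTrack(profile.genome, profile.strand, c)


def compute_r_score(profile: CleavageProfile) -> RScoreTrack:
    """Compute the R-score (structure-propensity) track for a cleavage profile."""
    a = _downstream(profile.a)
    t1 = _downstream(profile.t1)
    r = np.log2((a + 1.0) / (t1 + 1.0))
    _fix_linear_end(r, profile.genome, "R score")
    return RScoreTrack(profile.genome, profile.strand, r)


def r_score_log2fc(ko: RScoreTrack, wt: RScoreTrack) -> np.ndarray:
    """Per-position log2 fold change of R scores, knockout over control.

    log2(2^R_KO / 2^R_WT) simplifies exactly to R_KO - R_WT; the difference is
    what is computed.
    """
    if ko.genome != wt.genome or ko.strand != wt.strand:
        raise ValueError("R-score tracks must share genome and strand")
    return ko.values - wt.values
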