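"""Differential footprint analysis between genotypes.

Footprints are discovered on one genotype's C-score track (the reference), the
F score of the same coordinates is computed on both genotypes, and the log2
fold change of F scores (knockout/control) is tested against an empirical null
built by permuting per-position C scores of both samples genome-wide 1000
times and recomputing the fold change at the same loci.  The fold-change
threshold is calibrated so that the estimated false discovery rate —

    FDR(t) = (mean over shuffles of #null fold changes beyond t)
             / (#observed fold changes beyond t)

— does not exceed the target level (5% by default).  Candidate loci must also
satisfy a direction requirement: the central region's mean C score in the
non-reference genotype must exceed that in the reference genotype (protection
present in the reference, absent in the other).

For control-defined footprints (protection lost in the knockout) significant
fold changes are positive; for knockout-defined footprints (protection gained
in the knockout) the knockout/control orientation makes them negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

from .coverage_io import CleavageProfile, Interval
from .footprint_detection import Footprint, ScanParams, f_score, region_means, scan_footprints
from .scoring import CScoreTrack, RScoreTrack, compute_c_score, r_score_log2fc

__all__ = [
    "DifferentialFootprint",
    "DifferentialCallSet",
    "ShuffleNull",
    "RChangeSummary",
    "evaluate_locus",
    "build_shuffle_null",
    "estimate_fdr",
    "calibrate_fdr_threshold",
    "detect_differential_footprints",
    "summarize_r_change",
]

Direction = Literal["up", "down"]
ScanDirection = Literal["control_defined", "knockout_defined"]


@dataclass
class DifferentialFootprint:
    """Paired F scores for one locus and its significance call."""

    footprint: Footprint
    f_control: float
    f_experiment: float
    log2fc: float
    c_central_control: float
    c_central_experiment: float
    significant: bool = False

    @property
    def name(self) -> str:
        return self.footprint.name


@dataclass
class ShuffleNull:
    """Null F-score fold changes from genome-wide C-score permutations.

    ``null_log2fc`` has one row per locus and one column per shuffle; a single
    permutation (column) evaluates every locus, and each shuffle draws its own
    substream from the seed so shuffle k is reproducible in isolation.
    """

    n_shuffles: int
    seed: int
    null_log2fc: np.ndarray  # shape (n_loci, n_shuffles)

    def __post_init__(self) -> None:
        self.null_log2fc = np.atleast_2d(np.asarray(self.null_log2fc, dtype=float))
        if self.null_log2fc.size and self.null_log2fc.shape[1] != self.n_shuffles:
            raise ValueError("null_log2fc must have n_shuffles columns")


def evaluate_locus(
    footprint: Footprint,
    cs_a: CScoreTrack,
    cs_b: CScoreTrack,
    flank: int | None = None,
) -> DifferentialFootprint:
    """Recompute central/flank means and F scores for one locus on two tracks.

    ``cs_a`` is the control track, ``cs_b`` the experiment; the fold change is
    ``log2(F_b / F_a)``.  ``flank`` defaults to the 3 nt used by the scan.
    """
    if cs_a.genome != cs_b.genome or cs_a.strand != cs_b.strand:
        raise ValueError("C-score tracks must share genome and strand")
    L = cs_a.genome.length
    if not (0 <= footprint.start < L and footprint.width >= 1 and footprint.width <= L):
        raise ValueError("footprint coordinates out of range")
    fl = 3 if flank is None else flank
    circ = cs_a.genome.circular
    ca, la, ra = region_means(cs_a.values, footprint.start, footprint.width, fl, circ)
    cb, lb, rb = region_means(cs_b.values, footprint.start, footprint.width, fl, circ)
    fa = float(f_score(ca, la, ra))
    fb = float(f_score(cb, lb, rb))
    return DifferentialFootprint(
        footprint=footprint,
        f_control=fa,
        f_experiment=fb,
        log2fc=math.log2(fb / fa),
        c_central_control=ca,
        c_central_experiment=cb,
    )


def _locus_fold_changes(
    a_values: np.ndarray,
    b_values: np.ndarray,
    starts: np.ndarray,
    widths: np.ndarray,
    flank: int,
) -> np.ndarray:
    """Vectorized log2(F_b/F_a) over loci, via doubled cumulative sums."""
    L = len(a_values)

    def f_per_locus(values: np.ndarray) -> np.ndarray:
        cs = np.concatenate([[0.0], np.cumsum(np.concatenate([values, values]))])
        central = (cs[starts + widths] - cs[starts]) / widths
        ls = (starts - flank) % L
        left = (cs[ls + flank] - cs[ls]) / flank
        rs = starts + widths
        right = (cs[rs + flank] - cs[rs]) / flank
        return 10.0 ** (central - left) + 10.0 ** (central - right)

    return np.log2(f_per_locus(b_values) / f_per_locus(a_values))


def build_shuffle_null(
    cs_a: CScoreTrack,
    cs_b: CScoreTrack,
    loci: Sequence[Footprint],
    n_shuffles: int = 1000,
    seed: int = 0,
    flank: int = 3,
) -> ShuffleNull:
    """Empirical null of F-score fold changes at fixed loci.

    For each shuffle both tracks' per-position C scores are independently
    permuted genome-wide (within the strand), and the fold change is
    recomputed at the same coordinates for every locus.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if not loci:
        return ShuffleNull(n_shuffles, seed, np.empty((0, n_shuffles)))
    starts = np.array([fp.start for fp in loci])
    widths = np.array([fp.width for fp in loci])
    null = np.empty((len(loci), n_shuffles))
    streams = np.random.SeedSequence(seed).spawn(n_shuffles)
    for k in range(n_shuffles):
        rng = np.random.default_rng(streams[k])
        pa = rng.permutation(cs_a.values)
        pb = rng.permutation(cs_b.values)
        null[:, k] = _locus_fold_changes(pa, pb, starts, widths, flank)
    return ShuffleNull(n_shuffles, seed, null)


def _fdr_curve(observed: np.ndarray, null: ShuffleNull, direction: Direction):
    """Candidate thresholds with their estimated FDR, on the 'up' scale."""
    sign = 1.0 if direction == "up" else -1.0
    obs = np.sort(sign * observed)
    nul = np.sort(sign * null.null_log2fc.ravel())
    pooled = np.concatenate([obs, nul])
    lo = pooled.min() - 1.0 if pooled.size else -1.0
    cands = np.concatenate([[lo], np.unique(pooled)])
    n_obs_beyond = obs.size - np.searchsorted(obs, cands, side="right")
    n_null_beyond = nul.size - np.searchsorted(nul, cands, side="right")
    mean_null_beyond = n_null_beyond / max(null.n_shuffles, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_obs_beyond > 0, mean_null_beyond / n_obs_beyond, np.inf)
    return sign, cands, fdr, n_obs_beyond


def estimate_fdr(
    observed: Sequence[float], null: ShuffleNull, threshold: float, direction: Direction
) -> float:
    """Estimated FDR of calling observed fold changes beyond ``threshold``."""
    sign = 1.0 if direction == "up" else -1.0
    obs = sign * np.asarray(observed, dtype=float)
    nul = sign * null.null_log2fc.ravel()
    t = sign * threshold
    n_called = int((obs > t).sum())
    if n_called == 0:
        return 0.0
    return float((nul > t).sum() / max(null.n_shuffles, 1) / n_called)


def calibrate_fdr_threshold(
    observed_log2fc: Sequence[float],
    null: ShuffleNull,
    target_fdr: float = 0.05,
    direction: Direction = "up",
) -> float:
    """Smallest-magnitude fold-change threshold achieving the target FDR.

    A locus is called when its fold change is strictly beyond the threshold
    (> t for ``up``, < t for ``down``).  Returns ``+inf`` (``-inf`` for
    ``down``) when no threshold attains the target: no discoveries.
    """
    observed = np.asarray(observed_log2fc, dtype=float)
    if observed.size == 0:
        raise ValueError("observed fold-change list is empty")
    if not (0.0 < target_fdr < 1.0):
        raise ValueError("target_fdr must be in (0, 1)")
    sign, cands, fdr, n_obs_beyond = _fdr_curve(observed, null, direction)
    ok = (fdr <= target_fdr) & (n_obs_beyond > 0)
    if not ok.any():
        return sign * math.inf
    return float(sign * cands[ok].min())


class DifferentialCallSet(Sequence):
    """Sequence of :class:`DifferentialFootprint` plus calibration metadata."""

    def __init__(
        self,
        results: list[DifferentialFootprint],
        direction: ScanDirection,
        threshold: float,
        estimated_fdr: float,
        n_candidates: int,
        n_shuffles: int,
        seed: int,
    ) -> None:
        self.results = results
        self.direction = direction
        self.threshold = threshold
        self.estimated_fdr = estimated_fdr
        self.n_candidates = n_candidates
        self.n_shuffles = n_shuffles
        self.seed = seed

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, i):
        return self.results[i]

    def __iter__(self) -> Iterator[DifferentialFootprint]:
        return iter(self.results)

    @property
    def significant(self) -> list[DifferentialFootprint]:
        return [r for r in self.results if r.significant]


def detect_differential_footprints(
    ctrl: CleavageProfile,
    ko: CleavageProfile,
    direction: ScanDirection = "control_defined",
    params: ScanParams = ScanParams(),
    target_fdr: float = 0.05,
    n_shuffles: int = 1000,
    seed: int = 0,
    min_untreated: float | None = None,
) -> DifferentialCallSet:
    """Scan, evaluate and significance-filter footprints between genotypes.

    ``control_defined`` scans the control C track and tests for protection
    lost in the knockout (positive fold changes); ``knockout_defined`` scans
    the knockout track and tests for protection gained (negative fold
    changes, by the knockout/control orientation).  ``min_untreated``
    optionally masks positions whose untreated coverage (read downstream,
    like the scores) falls below the floor; off by default.
    """
    if ctrl.genome != ko.genome or ctrl.strand != ko.strand:
        raise ValueError("profiles must share genome and strand")
    cs_ctrl = compute_c_score(ctrl)
    cs_ko = compute_c_score(ko)
    reference = cs_ctrl if direction == "control_defined" else cs_ko
    valid_mask = None
    if min_untreated is not None:
        ref_profile = ctrl if direction == "control_defined" else ko
        valid_mask = np.roll(ref_profile.untreated.values, -1) >= min_untreated
    loci = scan_footprints(reference, params, valid_mask=valid_mask)
    results = [
        evaluate_locus(fp, cs_ctrl, cs_ko, flank=params.flank_len) for fp in loci
    ]
    if direction == "control_defined":
        passes = [r.c_central_experiment > r.c_central_control for r in results]
        tail: Direction = "up"
    else:
        passes = [r.c_central_control > r.c_central_experiment for r in results]
        tail = "down"
    candidates = [r for r, p in zip(results, passes) if p]
    if not candidates:
        threshold = math.inf if tail == "up" else -math.inf
        return DifferentialCallSet(results, direction, threshold, 0.0, 0, n_shuffles, seed)
    null = build_shuffle_null(
        cs_ctrl, cs_ko, [r.footprint for r in candidates], n_shuffles, seed,
        flank=params.flank_len,
    )
    observed = [r.log2fc for r in candidates]
    threshold = calibrate_fdr_threshold(observed, null, target_fdr, tail)
    est = estimate_fdr(observed, null, threshold, tail) if math.isfinite(threshold) else 0.0
    for r, p in zip(results, passes):
        if not p:
            continue
        r.significant = r.log2fc > threshold if tail == "up" else r.log2fc < threshold
    return DifferentialCallSet(
        results, direction, threshold, est, len(candidates), n_shuffles, seed
    )


# ---------------------------------------------------------------------------
# Structure-propensity change in footprints vs their flanks
# ---------------------------------------------------------------------------


@dataclass
class RChangeSummary:
    """Per-footprint mean R-score log2 fold change, central vs 10-nt flanks."""

    names: list[str]
    central: np.ndarray
    left_flank: np.ndarray
    right_flank: np.ndarray
    flank: int = 10

    def __len__(self) -> int:
        return len(self.names)

    def medians(self) -> dict[str, float]:
        if len(self.names) == 0:
            return {"central": math.nan, "left_flank": math.nan, "right_flank": math.nan}
        return {
            "central": float(np.median(self.central)),
            "left_flank": float(np.median(self.left_flank)),
            "right_flank": float(np.median(self.right_flank)),
        }

    def quantiles(self, q=(0.05, 0.25, 0.5, 0.75, 0.95)) -> dict[str, list[float]]:
        """Distribution quantiles for violin-style export."""
        out = {"q": list(q)}
        for key, arr in (
            ("central", self.central),
            ("left_flank", self.left_flank),
            ("right_flank", self.right_flank),
        ):
            out[key] = [float(v) for v in np.quantile(arr, q)] if len(arr) else []
        return out


def _footprint_overlaps_site(fp: Footprint, site: Interval) -> bool:
    L = fp.genome.length
    segments = (
        [(fp.start, fp.end)] if fp.end <= L else [(fp.start, L), (0, fp.end - L)]
    )
    return any(s < site.end and site.start < e for s, e in segments)


def summarize_r_change(
    footprints: Sequence[Footprint],
    r_ko: RScoreTrack,
    r_wt: RScoreTrack,
    sites: Sequence[Interval],
    flank: int = 10,
) -> RChangeSummary:
    """Mean R-score change in footprints overlapping binding sites, vs flanks.

    Restricts to footprints overlapping at least one site by >= 1 nt, then
    averages the per-position R log2 fold change (knockout - control) over the
    central region and over each ``flank``-nt flanking region.
    """
    delta = r_score_log2fc(r_ko, r_wt)
    L = r_ko.genome.length
    names, cen, lef, rig = [], [], [], []
    for fp in footprints:
        if not any(_footprint_overlaps_site(fp, s) for s in sites):
            continue
        central_idx = fp.positions()
        left_idx = np.arange(fp.start - flank, fp.start) % L
        right_idx = np.arange(fp.end, fp.end + flank) % L
        names.append(fp.name)
        cen.append(delta[central_idx].mean())
        lef.append(delta[left_idx].mean())
        rig.append(delta[right_idx].mean())
    return RChangeSummary(
        names=names,
        central=np.array(cen),
        left_flank=np.array(lef),
        right_flank=np.array(rig),
        flank=flank,
    )
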