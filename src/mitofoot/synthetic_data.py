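"""Synthetic cleavage-coverage experiments with planted ground truth.

Emulates the statistical structure of an RNase-footprinting experiment on a
circular mitochondrial-sized genome: per-position 5'-cleavage counts for four
digestion conditions (RNase A, T1, If, untreated) in two genotypes, with

* multiplicative *protection* at planted intervals — all three RNase rates
  divided by ``protection_factor`` in the control genotype only (the bound
  protein is absent in the knockout, so protection disappears there);
* *structure* effects at planted intervals in the knockout only — the
  double-strand-specific RNase A rate multiplied, and the single-strand
  T1 rate divided, by ``structure_factor`` (structure gained when the
  protein is lost);
* independent count noise (Poisson by default, negative binomial for
  overdispersed libraries) and per-track library-size normalization to RPM.

The untreated track measures background 5' ends and is unaffected by
protection or structure.  One strand is simulated per run.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .coverage_io import (
    CleavageProfile,
    CoverageTrack,
    GenomeSpec,
    Interval,
    normalize_rpm,
    write_track_bedgraph,
)

__all__ = ["SimulationSpec", "SyntheticTruth", "simulate_experiment", "write_fixture"]

#: relative cleavage efficiency of the three enzymes at an average position;
#: RNase A is the most efficient, If the least, so A usually drives the
#: max() in the C score while T1 still contributes to the R score.
ENZYME_PREFERENCE = {"a": 1.0, "t1": 0.7, "if_": 0.4}

CONDITIONS = ("a", "t1", "if_", "untreated")
GENOTYPES = ("control", "knockout")


@dataclass
class SimulationSpec:
    """Parameters of one synthetic footprinting experiment (one strand).

    Rates are mean 5'-cleavage (or background) counts per position before
    enzyme preference and planted effects.  Planted intervals are pairwise
    disjoint with >= 10 nt gaps.
    """

    genome_length: int = 16300
    n_protected: int = 30
    protected_width_range: tuple[int, int] = (8, 40)
    protection_factor: float = 8.0
    n_structured: int = 0
    structured_width_range: tuple[int, int] = (8, 40)
    structure_factor: float = 4.0
    base_rate: float = 100.0
    untreated_rate: float = 100.0
    library_size: int = 2_000_000
    noise: str = "poisson"  # or "negative_binomial"
    dispersion: float = 10.0  # NB size parameter; larger = closer to Poisson
    strand: str = "+"
    seed: int = 0
    min_gap: int = 10

    def __post_init__(self) -> None:
        if self.genome_length < 100:
            raise ValueError("genome_length must be >= 100")
        if self.protection_factor <= 1 or self.structure_factor <= 1:
            raise ValueError("planted effect factors must be > 1")
        if min(self.base_rate, self.untreated_rate) <= 0:
            raise ValueError("rates must be positive")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def genome(self) -> GenomeSpec:
        return GenomeSpec("chrM", self.genome_length, circular=True)


@dataclass
class SyntheticTruth:
    """Planted intervals with their effect sizes, for recovery scoring."""

    protected: list[Interval]
    structured: list[Interval]


def _place_intervals(
    rng: np.random.Generator,
    genome: GenomeSpec,
    n: int,
    width_range: tuple[int, int],
    occupied: list[tuple[int, int]],
    min_gap: int,
    label_prefix: str,
    score: float,
) -> list[Interval]:
    """Place n disjoint intervals, >= min_gap nt from each other and from
    previously placed ones.  No wrap across the origin, to keep truth BEDs
    plain.
    """
    placed: list[Interval] = []
    lo, hi = width_range
    for i in range(n):
        for _attempt in range(10_000):
            w = int(rng.integers(lo, hi + 1))
            s = int(rng.integers(0, genome.length - w))
            clash = any(
                s - min_gap < e and o < s + w + min_gap for o, e in occupied
            )
            if not clash:
                occupied.append((s, s + w))
                placed.append(
                    Interval(
                        genome, s, s + w, strand=".",
                        label=f"{label_prefix}{i + 1:03d}", score=score,
                    )
                )
                break
        else:
            raise RuntimeError(
                f"could not place {n} intervals of width {width_range} on a "
                f"{genome.length} nt genome with {min_gap} nt gaps"
            )
    return placed


def _draw_counts(rng: np.random.Generator, rate: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    if spec.noise == "poisson":
        return rng.poisson(rate).astype(float)
    r = spec.dispersion
    p = r / (r + rate)
    return rng.negative_binomial(r, p).astype(float)


def simulate_experiment(
    spec: SimulationSpec,
) -> tuple[CleavageProfile, CleavageProfile, SyntheticTruth]:
    """Simulate control and knockout cleavage profiles with known truth.

    Identical spec (including seed) gives identical output.  Protection acts
    on the control genotype's RNase tracks; structure modulation acts on the
    knockout's A and T1 tracks; the untreated track never carries planted
    effects.
    """
    genome = spec.genome
    rng = np.random.default_rng(spec.seed)
    occupied: list[tuple[int, int]] = []
    protected = _place_intervals(
        rng, genome, spec.n_protected, spec.protected_width_range, occupied,
        spec.min_gap, "prot", spec.protection_factor,
    )
    structured = _place_intervals(
        rng, genome, spec.n_structured, spec.structured_width_range, occupied,
        spec.min_gap, "struct", spec.structure_factor,
    )
    truth = SyntheticTruth(protected=protected, structured=structured)

    prot_mask = np.zeros(genome.length, dtype=bool)
    for iv in protected:
        prot_mask[iv.start : iv.end] = True
    struct_mask = np.zeros(genome.length, dtype=bool)
    for iv in structured:
        struct_mask[iv.start : iv.end] = True

    profiles = {}
    for genotype in GENOTYPES:
        tracks = {}
        for cond in CONDITIONS:
            if cond == "untreated":
                rate = np.full(genome.length, spec.untreated_rate)
            else:
                rate = np.full(genome.length, spec.base_rate * ENZYME_PREFERENCE[cond])
                if genotype == "control":
                    rate[prot_mask] /= spec.protection_factor
                else:
                    if cond == "a":
                        rate[struct_mask] *= spec.structure_factor
                    elif cond == "t1":
                        rate[struct_mask] /= spec.structure_factor
            counts = _draw_counts(rng, rate, spec)
            raw = CoverageTrack(genome, spec.strand, counts)
            tracks[cond] = normalize_rpm(raw, spec.library_size)
        profiles[genotype] = CleavageProfile(
            a=tracks["a"],
            t1=tracks["t1"],
            if_=tracks["if_"],
            untreated=tracks["untreated"],
            sample_label=f"sim_{genotype}",
            genotype=genotype,
        )
    return profiles["control"], profiles["knockout"], truth


def _write_truth_bed(intervals: list[Interval], path: Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.genome.name}\t{iv.start}\t{iv.end}\t{iv.label}\t"
                f"{iv.score if iv.score is not None else 0}\t{iv.strand}\n"
            )


def write_fixture(
    control: CleavageProfile,
    knockout: CleavageProfile,
    truth: SyntheticTruth,
    out_dir: str | os.PathLike,
    library_size: int | None = None,
) -> dict:
    """Write a simulated experiment as on-disk bedGraph/BED files.

    Emits 8 bedGraph files (4 conditions x 2 genotypes) of normalized RPM
    coverage, truth BEDs, and a ``config.yaml`` stub consumable by the
    pipeline.  Returns the config dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = control.genome
    cov_paths = {}
    for genotype, profile in (("control", control), ("knockout", knockout)):
        for cond in CONDITIONS:
            track: CoverageTrack = getattr(profile, cond)
            name = f"{genotype}_{cond.rstrip('_')}.bedGraph"
            write_track_bedgraph(track, out / name)
            cov_paths.setdefault(genotype, {})[cond.rstrip("_")] = name
    _write_truth_bed(truth.protected, out / "truth_protected.bed")
    _write_truth_bed(truth.structured, out / "truth_structured.bed")
    lib = library_size or control.a.library_size or 1_000_000
    config = {
        "genome": {"name": genome.name, "length": genome.length, "circular": genome.circular},
        "strand": control.strand,
        "coverage": cov_paths,
        "coverage_normalized": True,
        "library_size": lib,
        "scan": {"min_len": 8, "max_len": 40, "flank_len": 3, "f_threshold": 2.0},
        "target_fdr": 0.05,
        "n_shuffles": 1000,
        "seed": 0,
        "window_width": 50,
        "r_flank": 10,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config
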