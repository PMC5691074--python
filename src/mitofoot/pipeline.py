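"""End-to-end pipeline: config, stage orchestration, provenance.

A run loads the eight coverage tracks (four digestion conditions x two
genotypes, one strand), normalizes them if needed, computes C and R score
tracks, performs the control-defined and knockout-defined differential
footprint scans with the shuffle-null FDR filter, summarizes R-score changes
in significant footprints vs their flanks, runs the window-overlap test when
a binding-site BED is supplied, and writes all tables plus a JSON report.
Runs are idempotent for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coverage_io import (
    CleavageProfile,
    GenomeSpec,
    Interval,
    normalize_rpm,
    read_coverage_bedgraph,
    read_intervals_bed,
    write_footprints,
    write_score_tsv,
)
from .differential_analysis import (
    DifferentialCallSet,
    detect_differential_footprints,
    summarize_r_change,
)
from .footprint_detection import Footprint, ScanParams
from .overlap_analysis import make_windows, overlap_test, window_hit_counts, windows_hit
from .scoring import compute_c_score, compute_r_score

__all__ = ["RunConfig", "load_config", "load_profiles", "run_pipeline"]

log = logging.getLogger("mitofoot")

CONDITIONS = ("a", "t1", "if", "untreated")


@dataclass
class RunConfig:
    """Resolved parameters and file paths for one pipeline run."""

    genome: GenomeSpec
    strand: str
    coverage: dict  # genotype -> condition -> path
    library_size: int
    coverage_normalized: bool = True
    scan: ScanParams = field(default_factory=ScanParams)
    target_fdr: float = 0.05
    n_shuffles: int = 1000
    seed: int = 0
    window_width: int = 50
    r_flank: int = 10
    sites_bed: str | None = None
    min_untreated: float | None = None

    def validate_paths(self) -> None:
        missing = []
        for genotype in ("control", "knockout"):
            for cond in CONDITIONS:
                p = Path(self.coverage[genotype][cond])
                if not p.exists():
                    missing.append(str(p))
        if self.sites_bed and not Path(self.sites_bed).exists():
            missing.append(self.sites_bed)
        if missing:
            raise FileNotFoundError(
                "missing coverage/site files: " + ", ".join(missing)
            )


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML run config; relative paths resolve against the config dir."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    base = path.parent
    genome = GenomeSpec(
        name=raw["genome"]["name"],
        length=int(raw["genome"]["length"]),
        circular=bool(raw["genome"].get("circular", True)),
    )
    coverage = {
        genotype: {cond: str(base / p) for cond, p in conds.items()}
        for genotype, conds in raw["coverage"].items()
    }
    scan_raw = raw.get("scan", {})
    sites = raw.get("sites_bed")
    return RunConfig(
        genome=genome,
        strand=raw.get("strand", "+"),
        coverage=coverage,
        library_size=int(raw["library_size"]),
        coverage_normalized=bool(raw.get("coverage_normalized", True)),
        scan=ScanParams(
            min_len=int(scan_raw.get("min_len", 8)),
            max_len=int(scan_raw.get("max_len", 40)),
            flank_len=int(scan_raw.get("flank_len", 3)),
            f_threshold=float(scan_raw.get("f_threshold", 2.0)),
        ),
        target_fdr=float(raw.get("target_fdr", 0.05)),
        n_shuffles=int(raw.get("n_shuffles", 1000)),
        seed=int(raw.get("seed", 0)),
        window_width=int(raw.get("window_width", 50)),
        r_flank=int(raw.get("r_flank", 10)),
        sites_bed=str(base / sites) if sites else None,
        min_untreated=(
            float(raw["min_untreated"]) if raw.get("min_untreated") is not None else None
        ),
    )


def load_profiles(config: RunConfig) -> dict[str, CleavageProfile]:
    """Read the eight coverage tracks into per-genotype cleavage profiles."""
    profiles = {}
    for genotype in ("control", "knockout"):
        tracks = {}
        for cond in CONDITIONS:
            track = read_coverage_bedgraph(
                config.coverage[genotype][cond], config.genome, config.strand
            )
            if not config.coverage_normalized:
                track = normalize_rpm(track, config.library_size)
            else:
                track.library_size = config.library_size
            tracks[cond] = track
        profiles[genotype] = CleavageProfile(
            a=tracks["a"],
            t1=tracks["t1"],
            if_=tracks["if"],
            untreated=tracks["untreated"],
            sample_label=genotype,
            genotype=genotype,
        )
    return profiles


def _footprints_to_intervals(calls) -> list[Interval]:
    """Significant footprints as plain intervals (wrapped ones split)."""
    out = []
    for rec in calls:
        if not rec.significant:
            continue
        fp = rec.footprint
        L = fp.genome.length
        if fp.end <= L:
            out.append(Interval(fp.genome, fp.start, fp.end, fp.strand, fp.name))
        else:
            out.append(Interval(fp.genome, fp.start, L, fp.strand, fp.name + "/a"))
            out.append(Interval(fp.genome, 0, fp.end - L, fp.strand, fp.name + "/b"))
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write tables plus a JSON run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.validate_paths()

    log.info("loading coverage tracks")
    profiles = load_profiles(config)

    log.info("computing C and R score tracks")
    positions = range(config.genome.length)
    for genotype, profile in profiles.items():
        c = compute_c_score(profile)
        r = compute_r_score(profile)
        write_score_tsv(positions, config.strand, c.values, out / f"c_score_{genotype}.tsv")
        write_score_tsv(positions, config.strand, r.values, out / f"r_score_{genotype}.tsv")

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "params": {
            "scan": asdict(config.scan),
            "target_fdr": config.target_fdr,
            "n_shuffles": config.n_shuffles,
            "window_width": config.window_width,
            "r_flank": config.r_flank,
            "library_size": config.library_size,
        },
        "genome": {"name": config.genome.name, "length": config.genome.length},
        "directions": {},
    }

    calls_by_direction: dict[str, DifferentialCallSet] = {}
    for direction in ("control_defined", "knockout_defined"):
        log.info("differential scan: %s", direction)
        calls = detect_differential_footprints(
            profiles["control"],
            profiles["knockout"],
            direction=direction,
            params=config.scan,
            target_fdr=config.target_fdr,
            n_shuffles=config.n_shuffles,
            seed=config.seed,
            min_untreated=config.min_untreated,
        )
        calls_by_direction[direction] = calls
        write_footprints(calls, out / f"footprints_{direction}.tsv")
        report["directions"][direction] = {
            "n_footprints": len(calls),
            "n_candidates": calls.n_candidates,
            "n_significant": len(calls.significant),
            "threshold": calls.threshold,
            "estimated_fdr": calls.estimated_fdr,
        }
        log.info(
            "%s: %d footprints, %d candidates, %d significant (threshold %.4g)",
            direction, len(calls), calls.n_candidates, len(calls.significant),
            calls.threshold,
        )

    sites = read_intervals_bed(config.sites_bed, config.genome) if config.sites_bed else None

    if sites is not None:
        log.info("R-change summary and window-overlap test")
        r_wt = compute_r_score(profiles["control"])
        r_ko = compute_r_score(profiles["knockout"])
        sig_fps = [r.footprint for r in calls_by_direction["control_defined"].significant]
        summary = summarize_r_change(sig_fps, r_ko, r_wt, sites, flank=config.r_flank)
        with open(out / "r_change_summary.tsv", "w") as fh:
            fh.write("#name\tcentral\tleft_flank\tright_flank\n")
            for nm, c_, l_, r_ in zip(
                summary.names, summary.central, summary.left_flank, summary.right_flank
            ):
                fh.write(f"{nm}\t{c_!r}\t{l_!r}\t{r_!r}\n")
        report["r_change"] = {"n_footprints": len(summary), "medians": summary.medians()}

        grid = make_windows(config.genome, config.window_width)
        fp_iv = _footprints_to_intervals(calls_by_direction["control_defined"])
        table = overlap_test(fp_iv, sites, grid)
        fp_hits = windows_hit(fp_iv, grid)
        site_hits = windows_hit(sites, grid)
        fp_counts = window_hit_counts(fp_iv, grid)
        site_counts = window_hit_counts(sites, grid)
        with open(out / "window_overlap.tsv", "w") as fh:
            fh.write("#window_start\twindow_end\tfootprint_hit\tsite_hit\tn_footprints\tn_sites\n")
            for win, fh_, sh_, fc_, sc_ in zip(
                grid.windows, fp_hits, site_hits, fp_counts, site_counts
            ):
                fh.write(f"{win.start}\t{win.end}\t{int(fh_)}\t{int(sh_)}\t{fc_}\t{sc_}\n")
        report["overlap"] = {
            "N": table.N, "K": table.K, "n": table.n, "k": table.k,
            "p_value": table.p_value,
        }
        log.info(
            "overlap: N=%d K=%d n=%d k=%d p=%.3g",
            table.N, table.K, table.n, table.k, table.p_value,
        )

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "genome": {
                    "name": config.genome.name,
                    "length": config.genome.length,
                    "circular": config.genome.circular,
                },
                "strand": config.strand,
                "coverage": config.coverage,
                "coverage_normalized": config.coverage_normalized,
                "library_size": config.library_size,
                "scan": asdict(config.scan),
                "target_fdr": config.target_fdr,
                "n_shuffles": config.n_shuffles,
                "seed": config.seed,
                "window_width": config.window_width,
                "r_flank": config.r_flank,
                "sites_bed": config.sites_bed,
            },
            fh,
            sort_keys=False,
        )
    return report
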