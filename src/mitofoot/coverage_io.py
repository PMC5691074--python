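"""Genome-track and interval I/O.

Dense per-base coverage tracks (bedGraph in, bedGraph/TSV out), BED interval
lists, and the tabular footprint format used by the differential stage.  All
coordinates are 0-based half-open, matching BED/bedGraph conventions.

The genome here is typically a mitochondrial genome: a single circular
~16 kb contig analysed one strand at a time.  Coverage values are 5'-read-start
counts normalized to reads per million (RPM) of the sequenced library.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "CoverageTrack",
    "CleavageProfile",
    "Interval",
    "read_coverage_bedgraph",
    "normalize_rpm",
    "read_intervals_bed",
    "write_footprints",
    "read_footprints",
    "write_track_bedgraph",
    "write_score_tsv",
]

STRANDS = ("+", "-")
#: strand value for intervals with no strand information (BED3)
NO_STRAND = "."


class CoverageIOError(ValueError):
    """Raised for malformed or out-of-bounds track/interval records."""


@dataclass(frozen=True)
class GenomeSpec:
    """A named reference sequence with a length and a topology flag."""

    name: str
    length: int
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"genome length must be >= 1, got {self.length}")


@dataclass
class CoverageTrack:
    """Dense per-base coverage for one strand of one sample.

    ``values[i]`` is the (normalized) number of 5' read starts at position
    ``i``.  ``library_size`` records the total sequenced reads used for RPM
    normalization; it is ``None`` for raw (un-normalized) tracks.
    """

    genome: GenomeSpec
    strand: str
    values: np.ndarray
    library_size: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.genome.length,):
            raise ValueError(
                f"track has {self.values.shape[0]} values for a "
                f"{self.genome.length} nt genome"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coverage values must be finite")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")
        if self.library_size is not None and self.library_size <= 0:
            raise ValueError("library_size must be positive")


@dataclass
class CleavageProfile:
    """The four digestion-condition tracks for one strand of one sample.

    RNase A and RNase T1 preferentially cut single-stranded RNA, RNase If cuts
    double-stranded RNA; the untreated track measures background 5' ends.
    """

    a: CoverageTrack
    t1: CoverageTrack
    if_: CoverageTrack
    untreated: CoverageTrack
    sample_label: str = ""
    genotype: str = "control"

    def __post_init__(self) -> None:
        tracks = [self.a, self.t1, self.if_, self.untreated]
        genomes = {t.genome for t in tracks}
        strands = {t.strand for t in tracks}
        if len(genomes) != 1 or len(strands) != 1:
            raise ValueError("all four tracks must share genome and strand")
        if self.genotype not in ("control", "knockout"):
            raise ValueError(f"genotype must be control/knockout, got {self.genotype!r}")

    @property
    def genome(self) -> GenomeSpec:
        return self.a.genome

    @property
    def strand(self) -> str:
        return self.a.strand


@dataclass
class Interval:
    """A half-open genomic interval, optionally stranded and scored."""

    genome: GenomeSpec
    start: int
    end: int
    strand: str = NO_STRAND
    label: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end <= self.genome.length):
            raise ValueError(
                f"interval [{self.start}, {self.end}) out of bounds for "
                f"{self.genome.length} nt genome"
            )
        if self.strand not in STRANDS + (NO_STRAND,):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_BEDGRAPH_COLS = ["chrom", "start", "end", "value"]


def _read_table(path: str | os.PathLike, n_cols_min: int) -> pd.DataFrame:
    """Read a whitespace-separated BED-family file, skipping track/comment lines."""
    try:
        frame = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            skip_blank_lines=True,
            dtype=str,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    # drop UCSC 'track'/'browser' header lines if present
    mask = frame[0].isin(["track", "browser"])
    frame = frame[~mask].reset_index(drop=True)
    if len(frame) and frame.shape[1] < n_cols_min:
        raise CoverageIOError(
            f"{path}: expected >= {n_cols_min} columns, found {frame.shape[1]}"
        )
    return frame


def read_coverage_bedgraph(
    path: str | os.PathLike, genome: GenomeSpec, strand: str
) -> CoverageTrack:
    """Read a 4-column bedGraph into a dense per-base track.

    Positions absent from the file get coverage 0.  Records whose chrom does
    not match ``genome.name`` or that extend past ``genome.length`` are errors.
    """
    frame = _read_table(path, 4)
    values = np.zeros(genome.length, dtype=float)
    if len(frame) == 0:
        return CoverageTrack(genome, strand, values)
    frame = frame.iloc[:, :4]
    frame.columns = _BEDGRAPH_COLS
    try:
        starts = frame["start"].astype(int).to_numpy()
        ends = frame["end"].astype(int).to_numpy()
        vals = frame["value"].astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        # locate the first offending line for the error message
        for lineno, row in enumerate(frame.itertuples(index=False), start=1):
            try:
                int(row.start), int(row.end), float(row.value)
            except (ValueError, TypeError):
                raise CoverageIOError(
                    f"{path}: malformed bedGraph record at data line {lineno}: "
                    f"{' '.join(map(str, row))}"
                ) from exc
        raise
    bad_chrom = frame["chrom"] != genome.name
    if bad_chrom.any():
        lineno = int(np.argmax(bad_chrom.to_numpy())) + 1
        raise CoverageIOError(
            f"{path}: data line {lineno} references chrom "
            f"{frame['chrom'][bad_chrom].iloc[0]!r}, expected {genome.name!r}"
        )
    if np.any(vals < 0):
        lineno = int(np.argmax(vals < 0)) + 1
        raise CoverageIOError(f"{path}: negative coverage at data line {lineno}")
    if np.any((starts < 0) | (starts >= ends) | (ends > genome.length)):
        bad = (starts < 0) | (starts >= ends) | (ends > genome.length)
        lineno = int(np.argmax(bad)) + 1
        raise CoverageIOError(
            f"{path}: record at data line {lineno} outside "
            f"[0, {genome.length}) or with start >= end"
        )
    for s, e, v in zip(starts, ends, vals):
        values[s:e] += v
    return CoverageTrack(genome, strand, values)


def normalize_rpm(raw: CoverageTrack, library_size: int) -> CoverageTrack:
    """Scale a raw-count track to reads per million of ``library_size``."""
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    return CoverageTrack(
        genome=raw.genome,
        strand=raw.strand,
        values=raw.values * (1e6 / library_size),
        library_size=library_size,
    )


def read_intervals_bed(path: str | os.PathLike, genome: GenomeSpec) -> list[Interval]:
    """Read BED3/BED6 intervals, validating against the genome bounds."""
    frame = _read_table(path, 3)
    out: list[Interval] = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=1):
        fields = list(row)
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except (ValueError, TypeError) as exc:
            raise CoverageIOError(
                f"{path}: malformed BED record at data line {lineno}"
            ) from exc
        if chrom != genome.name:
            raise CoverageIOError(
                f"{path}: data line {lineno} references chrom {chrom!r}, "
                f"expected {genome.name!r}"
            )
        label = str(fields[3]) if len(fields) > 3 and fields[3] is not None else ""
        score: float | None = None
        if len(fields) > 4 and fields[4] not in (None, ".", ""):
            score = float(fields[4])
        strand = str(fields[5]) if len(fields) > 5 and fields[5] is not None else NO_STRAND
        try:
            out.append(
                Interval(genome, start, end, strand=strand, label=label, score=score)
            )
        except ValueError as exc:
            raise CoverageIOError(f"{path}: data line {lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_FOOTPRINT_HEADER = (
    "#chrom\tstart\tend\tname\tlog2fc\tstrand\tf_control\tf_experiment\tsignificant"
)


def write_footprints(footprints: Sequence, path: str | os.PathLike) -> None:
    """Write differential footprint calls as a BED6+3 table.

    Columns: chrom, start, end, name, log2 fold change (knockout/control),
    strand, F score in control, F score in experiment, significance flag.
    Footprints whose central region wraps the circular origin are split into
    two rows sharing the name with ``/a`` and ``/b`` suffixes.
    """
    lines = [_FOOTPRINT_HEADER]
    for i, rec in enumerate(footprints):
        fp = rec.footprint
        name = fp_name = rec.name if getattr(rec, "name", "") else f"fp{i + 1:04d}"
        L = fp.genome.length
        segs: list[tuple[int, int, str]]
        if fp.end <= L:
            segs = [(fp.start, fp.end, name)]
        else:  # wraps the origin
            segs = [(fp.start, L, fp_name + "/a"), (0, fp.end - L, fp_name + "/b")]
        for s, e, nm in segs:
            lines.append(
                "\t".join(
                    [
                        fp.genome.name,
                        str(s),
                        str(e),
                        nm,
                        repr(float(rec.log2fc)),
                        fp.strand,
                        repr(float(rec.f_control)),
                        repr(float(rec.f_experiment)),
                        "1" if rec.significant else "0",
                    ]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass
class FootprintRecord:
    """One row (or re-joined wrapped pair) of a footprint table."""

    genome: GenomeSpec
    strand: str
    start: int
    end: int  # may exceed genome.length when the region wraps the origin
    name: str
    log2fc: float
    f_control: float
    f_experiment: float
    significant: bool


def read_footprints(path: str | os.PathLike, genome: GenomeSpec) -> list[FootprintRecord]:
    """Read a table written by :func:`write_footprints`, re-joining wrapped rows."""
    frame = _read_table(path, 9)
    rows = []
    for row in frame.itertuples(index=False):
        rows.append(
            FootprintRecord(
                genome=genome,
                strand=str(row[5]),
                start=int(row[1]),
                end=int(row[2]),
                name=str(row[3]),
                log2fc=float(row[4]),
                f_control=float(row[6]),
                f_experiment=float(row[7]),
                significant=bool(int(row[8])),
            )
        )
    out: list[FootprintRecord] = []
    pending: dict[str, FootprintRecord] = {}
    for rec in rows:
        if rec.name.endswith("/a"):
            pending[rec.name[:-2]] = rec
        elif rec.name.endswith("/b"):
            first = pending.pop(rec.name[:-2])
            first.name = rec.name[:-2]
            first.end = genome.length + rec.end
            out.append(first)
        else:
            out.append(rec)
    return out


def write_track_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write a dense track as run-length-encoded bedGraph (zero runs included)."""
    v = track.values
    change = np.flatnonzero(np.diff(v) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(v)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{track.genome.name}\t{s}\t{e}\t{float(v[s])!r}\n")


def write_score_tsv(
    positions: Iterable[int], strand: str, scores: Iterable[float], path: str | os.PathLike
) -> None:
    """Write a per-position score track: position (0-based), strand, score."""
    with open(path, "w") as fh:
        fh.write("#position\tstrand\tscore\n")
        for p, s in zip(positions, scores):
            fh.write(f"{p}\t{strand}\t{float(s)!r}\n")
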