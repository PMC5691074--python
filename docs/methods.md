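# Methods

## Model and procedure

The analysis treats one strand of a circular genome as a dense array of
per-base 5′-cleavage coverage in four digestion conditions (RNase A, RNase
T1, RNase If, untreated) for each of two genotypes.  Tracks are normalized
to reads per million of the sequenced library before any scoring; the
library size is supplied explicitly in the run config, because coverage on a
mitochondrial genome is a subset of the whole sequenced library and cannot
be inferred from the track itself.

**C score.** `C_i = log10((max(A,T1,If)_{i+1} + 1)/(Untreated_{i+1} + 1))`.
The +1 pseudocounts are applied to the normalized values, and the max over
the three enzymes is taken after normalization (each track normalized by its
own library size).  The `i+1` offset reflects that a cut 5′ of base `i+1`
exposes base `i`; it wraps across the circular origin.  For linear
references (e.g. a cytoplasmic rRNA control) the final position has no
downstream neighbour: it is set to 0 and a warning is emitted.  No smoothing
or minimum-coverage masking is applied at the scoring stage; an optional
untreated-coverage floor (`min_untreated`) masks positions at the detection
stage and is off by default.

**Footprint scan.** Every span of width 8–40 nt whose central mean C is
strictly below the mean of *each* 3-nt flank, with
`F = 10^(C−L) + 10^(C−R) < 2`, is a candidate.  The both-flank reading (not
a pooled 6-nt flank) matches the F score's two separate flank terms, and
F < 2 is the value the identity case C = L = R attains.  Candidate
enumeration is vectorized per width over a doubled cumulative sum, so spans
and flanks may wrap the origin.  The strict "below both flanks" comparisons
carry an absolute margin of 1e-9 so cumulative-sum roundoff cannot promote
exactly tied spans (meaningful C-score differences are many orders of
magnitude larger).  Overlapping candidates are resolved by greedy
non-maximum suppression in ascending F-score order (best-protected first),
ties broken by leftmost start then shortest span; the result is
deterministic and its central regions are pairwise disjoint.  A footprint
whose central region wraps is one in-memory record (`end > genome.length`)
and is split into two BED rows sharing a `/a`–`/b` name suffix on output.

**Differential calling.** Footprints are discovered on the reference
genotype's C track (control for `control_defined`, knockout for
`knockout_defined`), then the central/flank means and F scores are
recomputed on both genotypes at identical coordinates and
`log2fc = log2(F_knockout/F_control)`.  The null model permutes both
genotypes' per-position C scores uniformly at random genome-wide (within the
strand), independently for the two samples, 1000 times; one permutation
evaluates every locus, and each shuffle draws an independent substream from
the seed so shuffle *k* is reproducible in isolation.  The fold-change
threshold *t* is the smallest magnitude for which

    FDR(t) = (mean over shuffles of null fold changes beyond t)
             / (observed fold changes beyond t)  ≤  target (0.05),

with "beyond" one-sided per direction (`> t` for control-defined, `< t` for
knockout-defined; knockout-defined calls are negative by the
knockout/control orientation).  Candidate thresholds are the pooled unique
observed and null values plus one value below all of them, so perfect
separation yields the most permissive threshold; when no threshold attains
the target the result is ±∞ (no discoveries).  Calls must additionally pass
the direction requirement — central mean C greater in the non-reference
genotype — which is applied before calibration; when no locus passes, the
shuffle stage is skipped entirely (this makes the identical-profiles null
case exact and fast).  A ratio-of-expected-counts estimator is used rather
than per-locus p-values with Benjamini–Hochberg, matching the
genome-wide-shuffle framing of the calibration.

**R score and its fold change.** `R_i = log2((A_{i+1}+1)/(T1_{i+1}+1))`;
the footprint-level summary restricts to footprints overlapping at least
one binding site by ≥1 nt and averages the per-position difference
`R_KO − R_WT` (algebraically identical to the printed
`log2(2^R_KO/2^R_WT)` form) over the central region and over each 10-nt
flank.

**Window overlap.** The genome is tiled into 50-nt windows (final window
truncated; no wrap across the origin, matching standard windowing tools).  A
window is hit when ≥1 nt of ≥1 interval falls in it; binarized hits feed an
upper-tail hypergeometric test `P(X ≥ k)` with population N windows, K hit
by one set, n by the other, k by both.  The test is symmetric in which set
plays "draws", so the assignment is immaterial; per-window interval counts
are reported alongside for transparency.

## Synthetic data

The simulator emulates the statistical structure of the experiment, not its
sequence content: homogeneous per-position cleavage rates (`base_rate` 100
counts/position) scaled by relative enzyme efficiencies (A 1.0, T1 0.7, If
0.4 — chosen so RNase A usually drives the C-score max while T1 still
informs the R score), an untreated background of 100 counts/position,
Poisson counts by default (negative binomial with configurable dispersion
for overdispersed libraries), and RPM normalization with a 2×10⁶ default
library size — a regime giving baseline C ≈ 0 and clearly negative C inside
protections, comparable to a well-covered mitochondrial library.  Planted
protections divide all three RNase rates by `protection_factor` in the
control genotype only; planted structure effects multiply the A rate and
divide the T1 rate by `structure_factor` in the knockout only; the untreated
track never carries planted effects.  Planted intervals are pairwise
disjoint with ≥10-nt gaps and do not wrap the origin.  Enzyme
sequence preferences, fragment-length effects, read-level artifacts and
alignment noise are *not* modeled, so passing recovery tests demonstrates
the correctness and calibration of the scoring/FDR machinery under count
noise — not robustness to mappability or sequence-bias structure in real
libraries.

Default panel conditions used by the tests and the acceptance script: 16.3-kb
circular genome, 30 planted 20-nt protections of factor 8, control-defined
scan, 1000 shuffles, nominal 5% FDR, 20 seeds.  These sizes run the full
panel in well under a minute per stage on one CPU while keeping Monte-Carlo
error on the realized FDR small.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere, including outputs.
- Detected footprints sit one base 5′ of the planted truth because the score
  reads the downstream nucleotide; recovery is therefore assessed with a
  boundary tolerance (≤5 nt).
- `calibrate_fdr_threshold` uses strict inequalities ("beyond" = `> t`), so
  a threshold equal to an observed value excludes it; the extra candidate
  below the pooled minimum allows calling every observed value under
  perfect separation.
- Strands never mix: tracks, scans and nulls are per-strand; two-strand
  analyses are two runs.
- The pipeline writes `repr`-precision floats and sorted JSON keys so a
  rerun with the same config and seed is byte-identical.

## Limitations

- The shuffle null destroys all spatial autocorrelation of C scores;
  real coverage is locally correlated, which can make the null slightly
  anti-conservative at loci in smooth high-coverage regions.  The simulator
  shares this i.i.d. structure, so the calibration test validates the
  estimator, not the exchangeability assumption itself.
- The hypergeometric overlap test conditions on the observed number of hit
  windows and ignores interval length and clustering beyond the 50-nt
  binning.
- No per-locus p-values are produced; significance is a genome-wide
  threshold call at the target FDR.
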