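# Methods

## Coordinate and data conventions

Core promoter sequences cover positions −50..+50 around the TSS with the
TSS at +1 and no position 0 (standard promoter numbering; the INR window
"central A between −4 and +5" only makes sense under this convention).  A
100-base string maps index *i* to position *i*−50 upstream and *i*−49
downstream.  Probesets carry 15 probes at offsets −700..+700 bp in 100-bp
steps, strand-oriented (negative = upstream of the TSS in transcription
direction).  All sequences are stored in transcribed orientation; minus
strands only matter for BED/FASTA export and orientation of external input.

## Synthetic cohort generator

The generator stands in for a promoter tiling-array experiment.  Its
blueprint fixes, per cohort: background GC, a motif planting table
(promoter index, class, anchor), a bivariate occupancy model, an expression
link, a PIC footprint, replicate noise, TSS-shape labels and a seed.  All
randomness flows from a single `numpy` `SeedSequence` spawned into
independent streams (sequences, occupancy, probe noise, expression, tags,
shapes), so cohorts are byte-reproducible.

**Plant-then-scrub (fixture mode).**  Background bases are drawn i.i.d.
from the GC composition; planted motifs are instantiated from their IUPAC
patterns (degenerate symbols resolved uniformly, `N` from the background;
"like-only" BREu plantings are given exactly one mismatch) and frozen.  The
scrubber then repeatedly rescans every *unplanted* class at its legal scan
positions and resamples the non-frozen bases of any matching window, up to
200 rounds; non-convergence or an unrepairable hit on a fully frozen window
is a hard error — never a silent partial fixture.  Only windows at legal
scan positions are scrubbed; sequence outside any scan window is
unconstrained.  Implications are honored rather than scrubbed: a planted
TATA (`TATAW` at −31) is itself a W-run inside −40..−20, so TATA-like is
automatically present, and a planted BREu satisfies BREu-like.  Under this
contract scanner counts equal planted counts exactly, which is what lets
preset cohorts encode published compositions as integer counts.

**Presets.**  Eight shipped blueprints encode the compositions of the
promoter groups analysed in the study (top-100 TFIIB-bound, high- and
low-TFIIB percentiles, TFIIB-/NC2-dominated ratio sets, two co-occurrence
reference sets, and a footprint-only profile cohort).  `low_tfiib` uses
n = 500 so its 1.4% TATA frequency is an exact count.  The printed size
distribution of motif combinations in the dominated sets is arithmetically
inconsistent by one carrier with the printed per-class frequencies (the
collapsed-class slots sum to 129 versus the 130 the size histogram
requires); the presets keep the combination histogram and the
TATA/DPE/INR marginals exact and absorb the one-carrier discrepancy in the
BREu-like count, which is the least-constrained class.

**Occupancy, signals, expression, tags.**  Log2 occupancy of the two
factors is bivariate normal (default location 1.0, spread 1.0, correlation
0.8).  A probe's log2 ChIP/input ratio is baseline + occupancy × footprint
density at the probe offset + Gaussian noise, with the footprint a
max-normalized Gaussian centered at −50 (default spread 150 bp); the same
noise scale (`replicate_noise`, default 0.3) is drawn independently per
replicate, so smaller values mean higher replicate concordance.  Note the
median-of-15 probeset score has an intrinsic resolution limit: with a
150-bp footprint the median-rank probe sits ~350 bp from the peak where the
density is ≈ 0.07, so replicate correlations saturate well below 1 even at
low noise.  Expression is coeff × log2-occupancy(TFIIB) + Gaussian noise
(defaults 1.0 and 0.5) with a 90% 'present'-call rate; only present genes
enter correlations.  CAGE-like vectors put ≥ 80% of tags on one dominant
site (+1) for focused promoters, and three modes ≥ 25 bp apart at 35/35/30%
for dispersed ones; totals are 1 + Poisson(mean − 1).

The `profile_minus50` preset narrows the footprint to 15 bp.  At the
default 150-bp spread the density ratio between adjacent 10-bp bins is
≈ 0.998, far below sampling noise at any realistic probe count, so a
binned profile cannot resolve a mode; a spread comparable to the bin width
makes the −50 mode recoverable with ~5σ margin at 5,000 probes.  This is a
resolution argument about the 10-bp binning, fixed before use, not a fitted
value.

**What the generator does not emulate.**  Probe sequence thermodynamics,
dye effects, spatial array artifacts, genomic background outside the 1.5-kb
windows, correlated motif syntax beyond the planted tables, CpG-island
structure, and promoter-to-expression-probeset matching ambiguity (inputs
are id-joined).  Passing tests therefore certify the pipeline's arithmetic
and its contracts on this data shape, not performance on real arrays.

## Signal processing

Scaling subtracts the one-step Tukey biweight location (M = median,
S = MAD, u = (x−M)/(c·S+ε), weights (1−u²)² for |u| < 1, fallback M when
all weights vanish) with c = 5 and ε = 1e−4, the usual array-analysis
constants.  The peak caller thresholds at mean + k·sd with the population
(n-denominator) standard deviation of the scored series and requires
≥ `min_run` (default 2) consecutive strictly-above-threshold positions;
apex ties break leftmost.  Stringencies are nested by construction: every
peak at larger k lies inside a peak at smaller k.  Binding profiles assign
each probe offset to its nearest multiple of 10 (ties toward 0), divide
high-score by available probes per bin, omit empty bins, and optionally
rescale the maximum to 1.  Top-percentile selections use value ≥ the
(100−pct)th percentile with boundary ties included, for determinism.

## Statistics

The bootstrap KS test uses the exact sup-ECDF statistic (computed by pooled
sorting, tie-aware) and the estimator p = (1 + #{D\* ≥ D})/(n_boot + 1),
resampling the pooled sample with replacement into the original group
sizes; the +1 correction avoids p = 0 and the procedure is valid under
ties.  With equal small group sizes D lives on a lattice of multiples of
1/n and the ≥ convention's point mass makes p conservative; calibration
checks therefore use unequal sizes.  The rank-sum test on probe positions
is the two-sided Mann–Whitney U with tie-corrected normal approximation and
continuity correction (scipy).  Ratio curves convert log2 enrichments to
the linear scale before averaging — a ratio of mean log-ratios can be
negative or undefined, while per-gene linear ratios are strictly positive —
and are invariant under common log2 shifts.  Dominated-set selection
requires genes at or above the 60th percentile (default) in both factors
and expression, ranks by linear ratio and breaks rank ties by gene id.
TSS-shape thresholds (4-bp single span, > 0.5 dominant fraction, ≥ 2 modes
≥ 25 bp apart each ≥ 20% for multimodal) are operational choices exposed as
parameters; "dominant" requires a strict majority so that two exactly equal
peaks fall through to the multimodal rule.

The sliding-window expression curve uses non-overlapping occupancy windows
of width = step (default 0.1 on the log2 scale), merging windows below 10
genes into the next; its Pearson r is computed over the window means.
Under independence this r is not tightly bound: with W windows its null sd
is ≈ 1/√W (≈ 0.14 at the default settings), which the tests account for;
the coupled generator yields r > 0.9.

## Problem sizes and runtime

Preset fixtures run at their native n (100 or 500) in well under a second.
Stochastic recoveries use 1,000 promoters (GC) and 5,000 footprint probes
over a deterministic uniform background (profile mode).  Calibration suites
use 1,000 KS replications at n_boot = 199 and 200 uniformity replications
at n_boot = 500.  The whole test suite completes in well under a minute on
one CPU.

## Known limitations

* The threshold-run peak caller deliberately replaces the original
  double-regression peak model of the Mpeak program; only the stringency
  semantics (mean + k·sd tiers) are reproduced, with a documented per-series
  standard deviation.
* Exact preset compositions are guaranteed only at the preset's native
  cohort size; rescaling planting counts to another n is proportional and
  only supported for presets with contiguous planting blocks.
* The 15-probe, 100-bp tiling cannot localize the footprint mode below
  probe spacing; cohort-level profile modes land on probe-grid bins (0 or
  −100), and fine mode recovery is exercised through the footprint sampling
  model instead.
* No multiple-testing correction is applied anywhere, matching the scope of
  the statistics implemented.
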