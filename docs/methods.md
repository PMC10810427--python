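# Methods

## The problem

Vertebrate mitochondrial genomes often carry tandem repeats in the
non-coding control region (NCR).  In the barn owl (*Tyto alba*) the NCR
holds two such arrays: a *long* repeat with a 256 bp unit and a *short*
repeat with an 80 bp unit.  The number of copies varies strongly between
individuals, but short-read assemblies collapse the arrays, so the copy
number cannot be read off a per-sample assembly.  This package implements
the read-depth route instead: if the reference keeps exactly one copy of
each repeat unit, reads originating from all *k* true copies of that unit
have nowhere else to align, so the unit's depth is inflated by a factor of
*k* relative to the rest of the molecule.

## Pipeline

1. **Repeat detection** (`find_tandem_repeats`).  Candidate periods come
   from the offsets of exact k-mer self-matches (default k = 12).  For each
   candidate (period, locus), array bounds are grown one unit at a time
   against a running majority-rule consensus, accepting a unit when its
   identity to the consensus reaches the threshold (default 0.90, matching
   the dot-plot similarity convention used to display these repeats).
   Growth tolerates one isolated diverged copy (skip-one rescue).  Each call
   is canonicalized to the smallest divisor of its period that still
   explains the array — the divisor check is consensus-based because a
   copy-vs-copy comparison carries twice the per-copy divergence.
   Overlapping calls are ranked by matched evidence (span minus one period),
   then identity, then smaller period; this prevents a harmonic call (period
   2p or 3p) from shadowing the true period.  Circular inputs are handled on
   the doubled sequence with coordinates mapped back modulo the length, so
   detection is rotation-invariant.

2. **Reference trimming** (`trim_reference`).  For each array all whole
   copies except the 5'-most are excised; a fractional tail copy stays
   attached.  Keeping the 5'-most copy leaves every upstream coordinate —
   in particular the whole coding region — unchanged.  The liftover between
   original and trimmed coordinates is exact and invertible outside the
   excised segments.

3. **Estimation windows.**  The default window is the retained unit shrunk
   by a 25 bp margin on each side.  The margin dodges the depth shoulder at
   the unit edges: a read crossing a copy junction aligns as split segments,
   and pieces shorter than the mapper's minimum split length (20 bp) are
   lost, which depresses depth within ~20 bp of the unit boundaries but not
   in the interior.  For units too short to take the full margin, the margin
   degrades so at least a third of the unit remains.  Externally calibrated
   window coordinates can be injected per repeat and override the default.

4. **Copy number** (`estimate_copies`).  copies = round(mean depth in
   window / median depth of the whole trimmed molecule), with halves rounded
   away from zero (banker's rounding would bias ratio data at .5).  The
   median is taken over all positions including the inflated windows; those
   windows are under 2% of the molecule, so the median is unaffected.  The
   coding-region median (positions 1–15,542) is computed and carried as a
   model covariate, never used for normalization.  A zero median marks the
   sample unusable; batch runs keep failed samples with explicit status
   codes.  `detect_plateau` offers an automatic alternative to fixed
   windows: the longest run of positions within 15% of the run's own median,
   falling back to the margin window when no run of ≥ 10 positions exists.

## Synthetic data

`SimulationConfig` defaults describe the study system: a 15,542 bp coding
segment, the 256/80 bp units, 150 bp paired-end reads, modal copy numbers 5
(long) and 34 (short), 1% divergence between copies, 0.5% sequencing error,
50× coverage.  Spacers place the retained long unit at positions
16,725–16,980 of the trimmed molecule, mirroring the real coordinate frame.
Copy-number draws across cohorts span the observed ranges (4–38 long,
6–135 short).

Two generators produce depth:

* **Mechanistic** — fragments drawn uniformly on the circle (so coverage is
  uniform across the origin), paired 150 bp reads with substitution errors,
  and a deliberately naive internal mapper: exact k-mer seeding (k = 31),
  ungapped best-segment extension (+1 match / −2 mismatch), ties to the
  leftmost position.  Portions of a read left unaligned by the primary
  segment are re-seeded at k = 13 and emitted as supplementary records with
  soft clips; a read whose every 31-mer straddles a mismatch is rescued the
  same way.  Split placement is essential: junction-crossing reads have no
  full-length gap-free image in the trimmed reference, and only their
  pieces, mapped separately, deposit all bases on the retained unit.  The
  pile-up consequently counts supplementary records in this loop — the
  segments are disjoint parts of one read, so nothing is double-counted —
  while `depth_from_sam` ignores them by default for externally produced
  alignments.
* **Idealized** (`simulate_depth`) — expected depth λ everywhere, k·λ
  across each retained unit with a ≤ 24 bp linear shoulder just inside the
  unit edges, and per-position noise (Poisson by default; a negative
  binomial option with dispersion 0.1 models the overdispersion of real
  libraries).  The flanks stay at baseline: on a trimmed reference the
  collapsed-array pile-up cannot spill outside the unit, and the two NCR
  windows sit only ~20 bp apart, so any outward ramp would contaminate the
  neighbouring window.

The cohort generator (`make_cohort`) reproduces the sampled population
structure (16 western palearctic populations with their sizes and island
flags), draws sex, age class (juvenile/adult, missing for about half the
birds), tissue and haplogroup per sample, and generates copy numbers as
base + factor effects + Gaussian noise, with the short count following the
long count linearly (slope 2.2, residual sd 8.5 — chosen so the long/short
correlation matches the observed strength, r ≈ 0.6).  A confounded mode
copies the real sampling imbalance: island birds mostly adults sampled from
muscle or internal organs, mainland birds mostly juveniles sampled from
blood or feathers.  Under that allocation a single-factor age contrast is
significant in the full cohort even when the generative age effect is zero,
and vanishes in the muscle/organ subset where both ages occur — the
diagnostic the contingency tables exist for.

What the generator does *not* emulate: indels (in errors or between
copies), GC-dependent coverage, nuclear mitochondrial insertions, soft-clip
behaviour of production aligners at array junctions, or heteroplasmy
(intra-individual mixtures of copy numbers).  Passing tests therefore show
that the estimator recovers copy numbers when its collapse-and-pile-up
assumption holds exactly; they do not validate mapping behaviour on real
libraries.

## Statistical stage

Models are ordinary least squares on treatment-coded factors (alphabetical
baseline), fitted with statsmodels.  Backward elimination removes, at each
step, the single term whose removal most lowers AICc, respecting
marginality (a main effect inside a retained interaction is not droppable);
elimination happens on a fixed row set so criteria stay comparable.  AICc =
−2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting every estimated parameter
including the residual variance; Akaike weights are exp(−Δ/2) normalized.
ANOVA tables are Type-I (sequential) in term order, the default of the
modelling environment this analysis mirrors.  The population-within-island
question is answered by a dedicated projection-based nested ANOVA
(`nested_anova`): every population is wholly island or mainland, so the
inner factor aliases the outer one and degrees of freedom must come from
projection ranks (island 1 df, population-within-island n_pops − 2 df)
rather than from column counts; `run_factor_analysis` includes this table
when asked to nest.  Tukey post hocs use the
studentized-range distribution with the Tukey–Kramer standard error for
unequal group sizes, on raw level means with the model's residual mean
square.  Models fitted to different row subsets (the missing-age trap)
cannot be AICc-compared unless explicitly overridden.  Rank-deficient
designs (confounded factors, single-level factors after subsetting) drop
the aliased terms and report them.

## Numerical and design choices

* Coordinates are 1-based inclusive throughout; 0-based half-open appears
  only at the BED boundary.
* Rounding of copy ratios: half away from zero.
* Detection defaults: k = 12 seeds, identity 0.90, ≥ 2 copies, period
  10–2000 bp.  The dot plot caps its seed length so that any qualifying
  window is guaranteed (pigeonhole) to contain an exact seed, making the
  seeded scan identical to the all-pairs scan.
* Mapper defaults: seed k = 31, split seed k = 13, minimum split segment
  20 bp, minimum segment score 15.  These are test-harness settings, not
  aligner recommendations.
* Overlap tie-breaks, consensus ties (argmax on counts, A<C<G<T order) and
  read-placement ties (leftmost) are all deterministic; every output is a
  pure function of (config, seed).

## Recovery limits at 50× coverage

The estimator is unbiased through both simulation paths (verified by
comparing mapped depth with the bases actually sampled into reads), but
exact integer recovery is limited by counting statistics.  Reads sample the
array in 150 bp lumps, so the window mean has a relative standard deviation
of roughly (#array-overlapping fragments)^−1/2; through the mechanistic
path this makes the short-repeat estimate's standard deviation ≈ 0.25·√k
copies at 50× (≈ 1.2 copies at k = 23, ≈ 3 at k = 135).  Exact recovery of
large copy numbers at this depth is therefore a coin flip regardless of
implementation quality; recovery rates reported by the acceptance run
should be read against this floor.  The idealized per-position path has a
much smaller standard deviation (√(k/30λ)·λ scale) and recovers essentially
all of the long range and most of the short range exactly.  At the
coverage of real resequencing data (hundreds to thousands fold for mtDNA)
the floor drops accordingly.

## Problem sizes in the shipped runs

The test suite runs scaled-down replicate counts (25 mechanistic and 60
idealized recovery simulations, 60 planted-repeat detections, 400 null
cohorts); `scripts/acceptance.py` runs the fuller versions (60/100
simulations, 200 detections, 500 cohorts, 5,000 alignments).  These sizes
were chosen to keep a complete run on one CPU within a coffee break while
leaving the Monte Carlo standard errors well below the thresholds being
checked.

## Known limitations

* The naive mapper treats the trimmed reference as linear; reads spanning
  the trim origin are placed as split segments rather than wrapped
  alignments, leaving a small dip at the origin that does not touch the
  windows or the median.
* Repeat detection is substitution-only (no indel alignment inside units);
  indel-diverged arrays would fragment into multiple calls.
* The plateau detector is quadratic in the unit length and intended for
  unit-scale windows, not whole-genome scans.
* `aicc_compare` treats Gaussian OLS likelihoods only; GLMs are out of
  scope.
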