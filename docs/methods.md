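# Methods

## Velocity profile model

Material velocity along the root axis, viewed from the tip, is modelled
with the flexible logistic family

    v(x) = vf · [1 + e^(−k(x−x0))]^(−1/n),

`x` in mm from the quiescent center increasing shootward, `v` in mm/h.
The family is monotone nondecreasing with limits 0 and `vf`; `n` skews
the REGR profile (n = 1 gives the symmetric logistic, REGR peak `vf·k/4`
at `x0`). REGR is computed analytically, never by numerical
differentiation of data:

    REGR(x) = vf·(k/n)·u·(1+u)^(−(1+1/n)),   u = e^(−k(x−x0)),

evaluated in log space (`log u − (1+1/n)·log1p(u)`) so far-tipward
positions do not overflow. Closed forms used for traits: peak position
`x0 − ln(n)/k`; peak height `vf·k·(1+n)^(−(1+1/n))` (×100 → % h⁻¹).

**Zone length** has no unique operational definition; here it is the
width of the region where REGR ≥ `zone_fraction`·REGR_max, default
`zone_fraction = 0.2`. With typical Arabidopsis parameters this yields
widths in the 0.25–0.8 mm range observed in real populations. The edges
are located by Brent root-finding on each flank (tolerance 1e-9 mm)
inside brackets placed far enough out that the exponential tails are
guaranteed below the target.

## Fitting

`scipy.optimize.least_squares` with bounds confining parameters to
biologically plausible ranges (vf ≤ 2 mm/h, x0 ∈ [−2, 3] mm,
k ∈ [0.1, 100] /mm, n ∈ [0.02, 50]). Initialisation is data-driven:
vf₀ = 95th-percentile velocity, x0₀ = first crossing of vf₀/2, k₀ from
the local slope at x0₀ scaled by 4/vf₀, n₀ = 1. Plain least squares is
the default; `reject_outliers` adds one pass of 3·MAD residual rejection
and a refit.

The (k, n) pair is weakly identified at realistic noise: a ridge of
near-equivalent curve shapes runs toward large k and n (a Gompertz-type
limit), and a minority of noisy-cloud fits terminate on a bound with an
adequate curve but meaningless individual parameters. Because each RIL is
summarised by the arithmetic mean of its replicate parameters (the
RIL-average curve is the curve of the averaged parameters, not the
pointwise mean), a single ridge fit can corrupt the average. Fits are
therefore flagged `at_bound` and excluded from averaging, alongside
non-converged fits; a RIL with no interior converged replicate raises an
error rather than returning a silently corrupted average.

## Genome scan

- **Pseudomarker grid**: each inter-marker gap of d cM is split into
  ⌈d/step⌉ equal subintervals (default step 1 cM), so the grid contains
  every true marker and no gap exceeds the step.
- **Genotype probabilities**: scaled forward–backward over the two
  homozygous states. Transitions between positions d cM apart use the
  RIL-by-selfing recombination fraction R = 2r/(1+2r) with Haldane
  r = (1−e^(−2d/100))/2 (no interference; residual heterozygosity
  ignored, appropriate for advanced selfed RILs). Emissions: correct
  call with probability 1−ε, cross-class ε (default ε = 0.001); missing
  observations are uninformative. Verified against exhaustive hidden-path
  enumeration to 1e-10.
- **Haley–Knott regression**: phenotype on [1, P(BB)]; with one
  regressor, LOD = −(N/2)·log10(1−r²), algebraically equal to
  (N/2)·log10(RSS0/RSS1). P(AA) is omitted because it is collinear with
  the intercept in a two-class cross. Missing phenotypes are dropped
  trait-wise; scans with fewer than 10 lines warn (below 4, error).
- **Permutations**: the whole phenotype vector is shuffled against the
  RIL rows (preserving linkage disequilibrium among positions); the
  threshold is the empirical 0.95 quantile of genome-wide maximum LOD.
  The permutation scan is a single matrix product over all permutations,
  so large n_perm (25,000 for a definitive run; 1,000 in tests and the
  default config) is cheap.
- **Peaks**: one peak per chromosome per trait (leftmost grid position on
  ties); significance is LOD ≥ threshold; the support interval is the
  contiguous region around the peak with LOD ≥ peak − 1.5. Additive
  effect = half the fitted difference between genotype-class means at the
  peak. Variance explained per trait is the R² of one joint multiple
  regression on P(BB) at all of that trait's significant peaks (not the
  sum of single-locus R², which double-counts under linkage).

## Gravitropism summaries

- **PCA** of the RIL × 241 tip-angle matrix: column-centered, unscaled
  (all columns share degree units). Component signs are fixed so each
  loading vector sums positive; the PC basis is refit to the analysed
  population rather than imported.
- **Maximum swing rate**: the maximum over the curve of the slope of a
  sliding least-squares line, default window 5 frames (10 min at 2-min
  sampling), reported in °/h. The window is exposed because no canonical
  smoothing exists for this statistic.
- **Pearson matrix**: pairwise-complete observations, minimum 3 complete
  pairs, zero-variance columns flagged as undefined.
- **CCA**: both blocks z-scored (sample SD), first canonical pair from
  the SVD of Sxx^(−1/2)·Sxy·Syy^(−1/2); weights scaled to unit-variance
  variates; sign anchored so the weight on the first x column (maximum
  REGR by convention) is nonnegative. Rank-deficient blocks raise an
  error naming the collinear columns. The permutation threshold shuffles
  the row order of the gravitropism block only — equivalent under
  exchangeability to permuting either block, and cheaper. Listwise
  deletion for CCA; pairwise for Pearson.

## Synthetic study conditions

The generator reproduces the design the analysis expects, not any real
dataset:

- **Map**: 5 chromosomes of (120, 72, 92, 80, 120) cM — an
  Arabidopsis-like ~484 cM genome — with 234 markers spread
  proportionally; optional jitter.
- **Genotypes**: 160 RILs by default, first-marker alleles Bernoulli(½),
  then a Markov chain with the same R = 2r/(1+2r) Haldane transitions the
  HMM assumes; calls masked at 3% to exercise the missing-data path. No
  segregation distortion, no epistasis, fully inbred lines.
- **Phenotypes**: parameter = baseline + Σ QTL effects + noise. Baselines
  (vf 0.20 mm/h, x0 0.40 mm, k 9 /mm, n 1.0) and SD scales (0.040, 0.050,
  1.2, 0.15) put the derived traits in realistic ranges (elongation rate
  0.08–0.32 mm/h, max REGR ~30–60 % h⁻¹, peak position 0.25–0.57 mm, zone
  length 0.25–0.8 mm). A QTL of effect a (trait-SD units) contributes
  a·SD·c with allele code c = ±1 at the marker nearest its position;
  noise is scaled so the planted QTL jointly explain the configured
  heritability share (h² → 1 means no noise). An optional background_sd
  adds variation to parameters without planted QTL so demo populations
  have no constant traits. Positivity is enforced by resampling offending
  rows, not clipping, to avoid point masses at bounds.
- **Clouds**: default 120 points uniform over 0–1.5 mm with i.i.d.
  Gaussian velocity noise (sd 0.02 mm/h); 7–10 replicates per RIL.
  Negative noisy velocities are kept.
- **Tip-angle curves**: θ(t) = A·(1 − e^(−rate·max(t−lag,0))), per-RIL
  (lag, rate, asymptote) built from polygenic scores over the genotypes
  (so repeated experiments share genetics, heritability 0.7) plus
  experiment-specific deviations and AR(1) measurement noise (sd 1°,
  φ = 0.8). Rate variation dominates (sd 0.16 h⁻¹ on a 0.55 h⁻¹ base),
  which makes PC1 carry >90% of curve variance — the regime the PC1
  summary assumes. Real gravitropism curves can overshoot and oscillate;
  this family cannot, so passing tests demonstrate correctness of the
  summaries, not realism of every curve shape.

Planted demo QTL sit at chr1@21.5 (vf), chr3@39.7 (k), chr5@76.7 (x0)
with additive effects of 0.5 trait-SD and heritability 0.5 per parameter.
Effect sizes and heritabilities are placeholders for power studies, not
estimates of any real locus.

All stages draw from named substreams of one seed
(`default_rng([seed, crc32(name)])`); a fixed config is byte-identical on
rerun.

## Problem sizes

Statistical checks run at the sizes that make their tolerances
meaningful: 1000 parameter draws against 10⁶-point grids for the
closed-form identities; 200 noisy clouds for fit recovery; 500 fresh null
scans of a 160-RIL cross against a 2000-permutation threshold (binomial
3-SE band around 5%); 200 seeded crosses for planted-QTL detection and
interval coverage; n = 5000 for canonical-correlation recovery and 500
null datasets for CCA calibration. The acceptance script uses the same
designs with 100 QTL-recovery runs.

## Known limitations

- Single-QTL scans only: no multi-QTL search, no 2-D interaction scans,
  no composite interval mapping, no X-chromosome handling.
- The x-origin convention (quiescent center vs visible apex) is an input
  convention; the pipeline does not re-register profiles.
- 1.5-LOD support intervals are approximate confidence intervals; their
  empirical coverage (reported by the acceptance script, typically
  ~90%) is not a calibrated 95%.
- The HK LOD is an approximation to full interval-mapping likelihood;
  with 3% missing genotypes and a dense grid the difference is
  negligible, but it grows with missingness.
- CCA weights on only ~160 lines are high-variance; the permutation
  threshold guards the correlation, not the stability of individual
  weights.
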