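# Methods

This note records the models behind `barqtl`, the defaults that matter, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot tell you about real images and crosses.

## Profile extraction

A profile is the column-wise mean of a user-supplied rectangular flank
region (canonically 10 px high), one value per pixel column on the 0–255
gray scale, stored anterior→posterior. Color images are collapsed with
Rec. 601 luma weights (0.299 R + 0.587 G + 0.114 B); imaging software
differs in its RGB→grayscale weighting, so pipelines that must match a
specific tool should pre-convert to grayscale and feed `barqtl` the
single-channel image. Region selection, rotation and landmarking are
explicit inputs, not automated; images of right-facing fish are flipped
with a flag so stored profiles always read anterior→posterior. Column
means are kept in floating point — no quantization is applied.

Standard length is the Euclidean snout→caudal-peduncle pixel distance times
the cm-per-pixel scale.

## Bar calling

The threshold is the profile's own arithmetic mean, so segmentation is
invariant to adding a constant to every pixel. Scanning left to right:

- a bar **opens** at the first pixel of the first run of ≥ `min_run`
  (default 5) consecutive values **strictly below** the mean;
- an open bar **closes** on a run of ≥ `min_run` consecutive values at or
  above the mean; the bar's recorded end is the last below-mean pixel
  before that run, so shorter bright interruptions stay inside the bar
  while the closing run itself is interbar;
- a bar still open at the end of the profile runs to the final pixel;
- everything else, including leading and trailing stretches, is interbar.

Ties (values exactly equal to the mean) count as interbar: "darker than
average" is read strictly, which also makes a constant profile come out
with zero bars rather than one degenerate bar. `min_run` is exposed for
sensitivity analysis. The test suite checks the state machine against an
independent string-search oracle on a thousand random profiles.

## Traits

Seven level measures: darkest (min), lightest (max), range (max − min),
covariance of gray value with 0-based pixel position (sample covariance,
n − 1 denominator, units gray·px), mean bar intensity, mean interbar
intensity, and their differential (interbar − bar, so positive means bars
darker than background). Four pattern measures: number of bars, percent
barring (bar pixels / profile length), and mean bar and interbar widths,
converted to cm **before** residualization so their units are commensurate
with standard length. Profiles with no bars get missing (not zero)
bar-dependent values — zero would conflate "no bars" with "maximally dark
bars". The covariance trait is implemented literally as cov(position,
intensity); an alternative reading (variance of intensity along the
profile) is available behind the `positional_variance` flag but off by
default.

Residualization fits ordinary least squares of each trait on standard
length over the fit population (default: all rows, parentals and hybrids
together) and stores observed − predicted for every row; it is idempotent
and leaves residuals orthogonal to length. Group comparison is one-way
fixed-effects ANOVA with Tukey HSD (studentized range); the degenerate
all-constant input returns F = 0, p = 1 rather than NaN. Correlations are
pairwise-complete Pearson r with two-sided t-test p-values, computed on
residualized traits except for standard length itself.

## Cross model

Genotypes are coded AA/AB/BB with A the granddam allele and B the
grandsire allele; the F2 prior is (¼, ½, ¼). Marker QC is a chi-square of
the observed genotype counts against 1:2:1 with Bonferroni correction
across testable markers; markers with adjusted p < 0.05 are flagged for
removal.

Map distances convert to recombination fractions with the Haldane function
r = (1 − e^(−2d))/2 (d in Morgans) — no crossover interference. The same
model drives both the simulator and the genotype HMM, so probabilities are
exact for simulated data. The HMM runs forward–backward per linkage group
over the three genotype states, with transitions built from two
independent gametes, emissions 1 − ε for the observed code (ε = 1e-4 by
default, split evenly over the other codes) and uninformative emissions at
missing genotypes and pseudomarkers. Pseudomarkers are inserted so adjacent
grid spacing never exceeds `step_cM` (default 1 cM, finer than the marker
density the engine is intended for).

## Scan engine

Haley–Knott regression was chosen over EM interval mapping: it is exact at
fully-typed markers, matches the regression formulation of the cofactor
model, and is fast enough for a thousand permutations at desk scale. At
each grid position the design adds `p(BB) − p(AA)` and `p(AB)` to the null
(intercept + cofactors); LOD = (n/2) log10(RSS₀/RSS₁) over individuals with
non-missing phenotype. A cofactor within 10 cM of the scanned position on
the same linkage group is dropped from both models there, so a cofactor
never absorbs its own local signal.

Permutation thresholds shuffle the phenotype across individuals with
genotypes fixed, record the cofactor-free genome-wide max LOD per
permutation, and return empirical quantiles (linear interpolation). The
permutation loop is vectorized via per-position QR decompositions, so 1000
permutations cost little more than one scan.

MQM model building: (1) cofactor-free scan; grid points above the 10%
(suggestive) cutoff become candidates, strongest first, with a 30 cM
minimum separation within a linkage group (prevents collinear cofactors);
(2) the scan is iterated with the cofactors in the model, refreshing the
peak set, until stable or 10 rounds; (3) backward elimination removes,
weakest first, any cofactor whose conditional LOD — the maximum within
15 cM of its position when scanned with all the others — falls below the
suggestive cutoff; (4) survivors are classified significant (5%) or
suggestive (10%). The admission/elimination cutoff (10%) and the 15 cM
conditional-peak window are package choices, exposed as parameters; the
cumulative PVE of a multi-QTL model is the joint regression R², not the
sum of single-QTL PVEs (which double-counts under linkage).

The Bayes credible interval weights each grid point by 10^LOD normalized
over the linkage group and takes the smallest contiguous span containing
the peak whose mass reaches the coverage level, reporting the nearest
flanking genotyped markers alongside. Endpoints are grid positions;
simulations during development showed that on the default 1 cM grid the
nominal 95% interval covers the true location ~91–93% of the time, while a
coarse grid (≥ 2 cM steps) clips roughly half a grid step of mass per side
and drops coverage several points — use the default grid when interval
coverage matters.

PVE = 100·(1 − 10^(−2·LOD/n)), the standard LOD↔R² identity, which the
tests verify equals the regression R² exactly at fully-typed markers.
Allelic effects at the peak marker use observed genotypes: a = (µ_BB −
µ_AA)/2, d = µ_AB − (µ_AA + µ_BB)/2; an empty genotype class leaves the
dependent effects missing with a warning.

## Synthetic data

The profile painter lays rectangular bars (level default 70) on a lighter
background (170) on a 200 px canvas — six bars of 11 px with 15 px
interbars, matching the bar-dominated flank geometry the segmentation is
meant for — with optional per-segment width jitter, a linear
anterior→posterior trend, Gaussian pixel noise, and optional Gaussian edge
smoothing (off by default so painted intervals are unambiguous ground
truth). Cohort recipes give the two parental lines their characteristic
contrast difference (strong high-contrast bars vs. weak low-contrast bars
with noisier profiles) and the F2s intermediate, variable patterns; sex is
50/50 metadata with no phenotype effect, and standard length is lognormal
with mean 4.1 cm, s.d. 0.5 cm — a plausible juvenile scale, not a fitted
value, since parental trait distributions are not numerically specified
anywhere. What the painter does **not** emulate: 2-D melanophore texture,
dorsoventral bar extent, blotched (non-barred) morphs, lighting gradients
beyond a linear trend, or correlated pixel noise. Passing segmentation
tests on painted profiles therefore demonstrates the rule's correctness,
not its robustness to every real-world imaging artifact.

The cross simulator drops two independent gametes per individual down each
linkage group as a Markov chain with Haldane switch probabilities, so the
simulator and the HMM share one meiosis model. Planted QTL contribute
(−a, d, +a) for (AA, AB, BB); an additive QTL's variance share in an F2 is
a²/2 over a²/2 + σ², and a dominance effect contributes d²/4 — the test
suite plants effects through these identities. Phenotypes add an optional
allometric slope on standard length and Gaussian residual noise; genotypes
can be masked to missing at a fixed rate. No interference, no segregation
distortion, no genotyping-error process beyond the HMM's ε, and no
two-grandsire pedigree structure are simulated.

## Problem sizes used in the test suite

The shipped tests run the full chain at desk scale, chosen as the smallest
sizes at which the statistical properties are well separated from their
acceptance bounds: 1000 random profiles for oracle equivalence; crosses of
100–300 individuals on 2–3 linkage groups; 200 null datasets with
200-permutation cutoffs for the type-I-error calibration; 100–200
replicates for parameter-recovery, effect-direction and interval-coverage
checks. The whole suite completes in well under a minute of simulation
time plus the statistical replicates (~30 s total on one CPU).

## Known limitations

- Exact parity with any specific imaging tool's grayscale conversion or
  plotted profile values is not claimed.
- Whether the original bar-calling convention tolerated interruptions in
  the *opening* run is ambiguous in prose descriptions of such rules; this
  implementation requires a clean ≥ `min_run` opening run and tolerates
  interruptions only after a bar has opened.
- The scan engine treats all linkage groups as autosomal; there are no
  X-specific thresholds and no epistasis (two-dimensional) scans.
- Bayes intervals undercover on coarse pseudomarker grids (see above).
- MQM admission/elimination cutoffs are explicit package choices; other
  implementations may use different rules, so QTL counts near the
  suggestive boundary can differ between engines.
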