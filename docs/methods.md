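# Methods

`semcomp` re-implements, as a tested and reusable pipeline, the four
computational procedures of a two-word MEG paradigm that crosses strength of
association (low/high, from embedding cosine similarity) with
compositionality (word list vs adjective–noun phrase), plus a single-word
visual control: (i) embedding-based association scoring, (ii) two-stage
mass-univariate regression with spatiotemporal TFCE permutation inference,
(iii) searchlight pairwise decoding with pseudo-trial averaging, and (iv)
RDM-based directed connectivity between two functional regions.  A synthetic
source-estimate generator supplies trial-level inputs with planted,
recoverable effects so every stage can be exercised and calibrated without
access to raw MEG recordings.

## Data model

All analyses start from per-subject `TrialTensor`s: dense trials × sources ×
time arrays in arbitrary dSPM-like units, with a condition label
(`HA-comp`, `LA-comp`, `HA-list`, `LA-list`, `single`) and two word
log-frequency covariates per trial.  Geometry is a `SourceSpace`: an
undirected adjacency graph over source indices plus named masks (the
analysis mask, fROIs, control regions).  Nothing in the pipeline needs
cortical coordinates; a real source space plugs in through its triangulation
adjacency and atlas masks.  Times are milliseconds relative to first-word
onset with a half-open epoch `[-100, 1200)` at 1000 Hz (1300 samples; 260
after ×5 decimation); the second word appears at 600 ms.

## Mass-univariate two-stage regression

Stage one fits, per subject, an OLS at every source in the mask and every
sample in the window, with predictors intercept, association, composition,
their interaction, number of words, and the two word log-frequencies as
controls.  Factors are dummy coded (the single-word condition at the
origin); ±0.5 effect coding is available and leaves the planted 2×2
interaction contrast (HAc − LAc − HAl + LAl) identical.  Frequency
covariates are centered across trials, so condition coefficients are
evaluated at mean frequency.  Stage two tests each predictor's coefficient
stack with a one-sample t across subjects at every grid point, enhanced with
TFCE and referred to a permutation null.

### TFCE and permutation inference

TFCE(p) = ∫₀^{stat(p)} e(h)^E h^H dh, where e(h) is the extent of the
connected component containing p after thresholding the map at h.
Connectivity is spatial graph neighbors at the same sample plus the same
source at adjacent samples (no diagonal space–time edges); for t × dt flow
grids it is the 4-neighborhood of the matrix.  Exponents default to E = 0.5,
H = 2 — the standard pairing for this enhancement — and the integral is
discretized at dh = (max stat)/100 per map with midpoint evaluation
(the midpoint rule converges faster than an endpoint sum against the
continuous integral; the test suite checks agreement with an independent
threshold-sweep oracle at 10× finer steps to 1% of each point's value).
The enhancement is computed by an incremental union-find sweep over
descending thresholds, JIT-compiled with numba, with a scipy
connected-components fallback.

The group null flips each subject's deviation from the population mean
independently per permutation (the conventional one-sample sign-flip scheme;
a literal "replace the coefficient with zero" variant is available via
`null="zero"` for sensitivity analysis).  Family-wise control uses the
permutation distribution of the maximum TFCE score over the grid
(`correction="max"`; per-point uncorrected p-values optional).  P-values use
the add-one rule (1 + exceedances)/(1 + n_perm) and never return 0.
Regression tests are two-sided by default; the decoding test is explicitly
one-tailed against chance.  Degenerate zero-variance points give signed
infinite t-values, which are clipped to the map's finite maximum before
enhancement.

## Searchlight decoding

Shared pattern preprocessing regresses out the fitted contribution of the
two frequency columns at every source/time and decimates time by 5
(subsampling; the upstream data are low-passed, and a block-mean variant
exists).  Within each condition, trials are randomly partitioned into 15
pseudo-trials and block-averaged (60 trials → 15 × 4; 45 → 15 × 3; remainders
round-robin).  Four pairwise linear SVMs (unit cost, features standardized
by training-fold statistics only) are trained per searchlight — the k = 100
graph-nearest sources (BFS hop distance, ties by index) × 5 consecutive
decimated samples — under leave-one-stimulus-pair-out cross-validation:
each of the default 100 repetitions re-partitions the pseudo-trials and
holds out one per class.  Group inference submits accuracy − 0.5 to the
one-tailed TFCE permutation test within the 600–1200 ms window.

## RDM-based directed connectivity

At each decimated sample, a region's dissimilarity vector D(R, t) holds
1 − Pearson r between item source patterns.  Items default to the four
two-word condition means computed over pseudo-trials (6 entries, pair order
`itertools.combinations`); a pseudo-trial granularity (4 × 15 items, 1770
entries) is exposed as an option but couples the grid through the shared
condition-block structure, so the condition granularity is the default.
Directed flow A→B at lag dt is the partial correlation between D(A, t−dt)
and D(B, t), partialling out D(B, t−dt), computed per subject on a t ×
dt grid (t from second-word onset to +600 ms; dt = 5, 10, …, 600 ms) and
then tested: the per-subject direction contrast (A→B − B→A) goes through
the TFCE permutation machinery on the grid.  Undefined correlations
(constant vectors) map to 0 with a logged warning instead of propagating
missingness; cells whose lag precedes the epoch are excluded from the grid.
A helper (`froi_union`) assembles fROIs as the union of sources significant
in the regression or decoding results at a chosen α.

## Association scoring

Word-pair association is the cosine similarity between GloVe-style
embedding vectors (whitespace text, one token + d floats per line).  Pairs
with cosine > 0.3 are labeled high-associative, < 0.15 low-associative, and
the closed band in between is excluded.  A PCA variant scores pairs on the
first 30 components of a PCA fitted on the stimulus vocabulary (centered);
the fitting population is recorded in the output provenance.  A small
deterministic toy embedding table ships for offline tests; scores on real
embedding releases are version-dependent.

## Synthetic data generator

Per trial the generator sums: a shared evoked response (smooth positive
spatial pattern × Gaussian bumps after each word onset; absent for word 1 in
the single-word condition), a frequency contribution (negative slope × the
trial's centered log₁₀ frequency × a fixed spatial pattern × a bump ~200–350
ms after the word onset — more frequent words give weaker responses),
planted effects, lagged couplings, and noise.  Defaults: 42 subjects (two
cohorts of 21 via `DesignSpec.experiment1/2`), 60 or 45 trials per
condition, log-frequency ~ Normal(3.0, 0.8).

Design choices worth knowing:

* **Frequency covariates are re-centered within each condition cell** before
  entering the signal, mirroring frequency-matched stimulus lists.  This
  makes noiseless condition-mean contrasts reproduce planted amplitudes to
  machine precision and keeps the covariates orthogonal to the condition
  factors by construction.
* **Univariate effects** add `amplitude × coding value` uniformly inside
  their region × window, where the coding value is the trial's dummy-coded
  regressor (so an interaction plant affects only HA-comp trials).
* **Multivariate effects** draw i.i.d. Gaussian spatiotemporal patterns per
  condition that are **subject-specific** (seeded from `(pattern_seed,
  subject)`) — idiosyncratic neural codes that are decodable within subject
  while leaving group-level univariate contrasts mean-zero with honest
  between-subject variance.  `pattern:C1|C2` plants ±P on one pair;
  `pattern:per-condition` plants an independent pattern per two-word
  condition.  Because the four tested pairs form a cycle over the 2×2
  conditions, no plant can make exactly one pair decodable; recovery tests
  therefore assert detection of the planted pair and silence of the
  untouched opposite pair.
* **Couplings** add a gain-scaled random linear mixing (fixed matrix,
  entries ~ N(0, 1/n_src)) of the source region's *signal* at t − lag to the
  target region inside the coupling window.  The mixing scrambles source
  identity, so the lag is visible in pattern geometry (RDMs, pattern norms)
  rather than raw source-wise correlation — which is what the connectivity
  statistic measures.
* **Noise** is white Gaussian, optionally graph-diffusion smoothed
  (`spatial_corr_length` averaging steps over the adjacency) and temporally
  Gaussian-smoothed, then rescaled so the realized trial SD equals
  `sensor_sd` exactly.  Subject random effects are additive scalar offsets.
  An optional per-trial dropout rate emulates epoch rejection.

What the generator does **not** emulate: realistic cortical geometry or
forward/inverse modeling (no field spread or point-spread correlation
between regions), 1/f spectra, trial-order or habituation effects,
subject-specific spatial deformation of effects.  Passing recovery tests
therefore demonstrate the statistical machinery is correct and calibrated
under the stated generative assumptions, not that the original biological
effects would be recovered at these sample sizes.

## Desk-scale study conditions

The package's tests and the acceptance script run everything at reduced
scale, chosen once as the package's demonstration conditions: lattice source
spaces of 54–80 sources standing in for the ~755-source hemisphere mask,
8–12 subjects, 8–15 trials per condition, 200–500 permutations instead of
10,000, thinned searchlight centers, and dt grids to 150–300 ms.  The full
study-scale settings (10,000 permutations, 100-source lights, dt to 600 ms)
remain the library defaults.  Family-wise error calibration is checked
against the 95% binomial band around α = 0.05 over 200 simulated null
datasets; planted-effect recovery uses amplitudes derived analytically from
the OLS variance formula to target a group t ≈ 5.

## Numerical and degenerate-input conventions

Rank-deficient designs raise an error naming the collinear columns (pivoted
QR).  Zero-variance t inputs warn and return signed infinity.  Constant
inputs to correlations return 0 with a warning.  Pseudo-trial partitioning,
searchlight tiling, and all permutation draws are deterministic given seeds;
containers are written as deterministic `.npz` + JSON sidecars (frozen zip
timestamps) so a rerun of the same configuration is bit-identical.
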