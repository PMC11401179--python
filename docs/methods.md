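# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind `edgentropy`, in the order the pipeline runs.

## Preprocessing and windowed connectivity

Input is one frames × parcels matrix per subject (TR in seconds). Three
steps precede windowing:

1. **Bandpass** 0.017–0.1 Hz with a zero-phase 4th-order Butterworth
   (forward–backward `sosfiltfilt`). Only the band is a scientific choice;
   zero-phase filtering is ours, to avoid lag distortion of window
   boundaries. The effective attenuation of the two-pass filter is double
   the nominal order.
2. **Cross-parcel mean regression** (a version of global-signal
   regression): each parcel is regressed on the cross-parcel mean (OLS
   with intercept) and the residuals kept.
3. **Trimming** of 10 frames at each end against filter edge transients.

Sliding-window correlation uses a rectangular window of 60 s
(`round(60 / TR)` frames; 75 at TR = 0.8 s) slid in steps of one TR.
Pearson correlations for all parcel pairs per window are clipped to
±(1 − 1e−12) and Fisher-transformed. At the default geometry
(410 frames − 2×10 trim − 75-frame window + 1) this yields 316 windows.
A note on run length: a ~5 min 47 s run at TR 0.8 s has ~434 frames,
which with this window arithmetic would give ~340 windows; 316 windows
correspond to 410 input frames. The pipeline treats the frame count as
data-driven and never hard-codes a window count; the synthetic default of
410 frames is chosen so the default geometry reproduces 316 windows.

Edges are indexed canonically: all pairs (i, j), i < j, lexicographic.
116 parcels → 6670 edges.

## Edge sample entropy

SampEn(m, eps) follows the boundary-inclusive convention: a Chebyshev
distance exactly equal to r = eps·σ counts as a match (Θ(0) = 1), both
match counts run over the same N − m templates with self-matches excluded,
and σ is the population (1/N) standard deviation. Defaults m = 2,
eps = 0.20. Consequences worth knowing:

* a constant signal has σ = 0, r = 0, and SampEn exactly 0 (all
  distances are 0 and still "within" tolerance);
* the statistic is invariant to affine rescaling of the signal;
* when no (m+1)-length match exists the value is undefined; we return NaN
  rather than +∞, and template construction drops edges undefined in more
  than half of the reference group (logged).

The vectorized implementation is count-identical to a double-loop
evaluation (enforced by test, tolerance zero).

## Templates, similarity, and the density sweep

HEN/LEN templates keep the `floor(density · E)` largest/smallest entries
of the control-group mean ESE vector. Floor rounding is conservative and
monotone in density; ties at the cutoff break by canonical edge order.
Template roles are parameterized: any group can serve as template group
or analysis group.

The similarity matrix is the subjects × subjects Pearson correlation of
template-masked ESE vectors, diagonal set to 1 (hence τ = 1 before
projection). NaN entries trigger pairwise-complete correlation (logged).

The operating density per tail is selected by sweeping a grid of 16
densities (default: evenly spaced in (0.01, 0.16]; the grid is
configurable) and ranking candidates on four criteria — mean per-measure
variance explained (higher better), p-Wald (lower), p-Perm (lower), and
|p-Perm − p-Wald| (lower; parametric/nonparametric agreement indicates the
model assumptions hold). The winner maximizes the average rank; ties break
toward the sparser template. On synthetic data, planted-density recovery
requires competing (behavior-irrelevant) subject structure on the
complement edges — with pure noise outside the informative set the
estimator self-normalizes and the ranking is nearly flat in density,
which is a property of the estimator, not a bug.

## Variance-component model

With the behavioral table quantile-normalized column-wise (rank-based
inverse normal, offset (rank − 0.5)/N, ties averaged; behavioral missing
values median-imputed, missing medication dose set to 0), the model is
fitted in three steps:

1. **Projection.** An orthonormal basis U of the orthogonal complement of
   span([1 X]) (dimension N − rank, i.e. N − q − 1 for q independent
   covariates plus our always-appended intercept) gives the transformed
   pair (UᵀY, UᵀRU) with no fixed effects. Any XB added to Y leaves all
   estimates unchanged to machine precision.
2. **Moment matching.** Sigma_c = Yᵀ(R − τI)Y/ν and
   Sigma_e = Yᵀ(κI − τR)Y/ν on the projected pair. Both are unbiased
   (E[Yᵀ A Y] = Tr(AR)·Sigma_c + Tr(A)·Sigma_e, and the two A-matrices
   are built so the nuisance trace vanishes). Fractions are clipped to
   [0, 1] for reporting; raw values are retained (`m_raw_`,
   `m_per_measure_raw_`) and used wherever unbiasedness matters
   (recovery studies, permutation reference). ν ≤ 1e−8 (R ≈ scalar·I)
   raises an unidentifiable-model error.
3. **Inference.** Both tests are one-sided for M > 0.
   *Wald:* the exact Gaussian covariance of the two quadratic forms,
   Cov(TrYᵀAY, TrYᵀBY) = 2[Tr(Sc²)Tr(ARBR) + 2Tr(ScSe)Tr(ARB)
   + Tr(Se²)Tr(AB)], is combined by the delta method for the trace ratio.
   Two plug-ins are used for two purposes: the **test** variance evaluates
   the covariance at the null configuration (Sigma_c = 0, Sigma_e =
   empirical total covariance) — a score-test-style choice that is
   consistent under the null, makes p-Wald uniform there, and tracks the
   permutation distribution; the **reporting** SE (`se_overall_`,
   `se_per_measure_`, used for error bars and recovery intervals)
   evaluates it at the PSD-clipped estimates, which follows the sampling
   spread under signal. Evaluating at the estimates under the null
   inflates the variance (noise enters the Tr(Sc²) terms), which is why
   the two roles are separated; both were validated against Monte-Carlo
   draws of the quadratic forms.
   *Permutation:* rows and columns of the projected R are permuted
   jointly; because τ, κ, ν are permutation-invariant each permutation
   needs only q = Tr(YᵀR_perm Y), making 10⁴ permutations cheap. p-values
   use the add-one estimator and never return 0.

Resampled contrasts of two templates rebuild both similarity matrices and
refit both models per replicate. The bootstrap uses bias-corrected (BC)
percentile intervals at level alpha/n_tests (Bonferroni); degenerate
resamples (ν ≈ 0) are redrawn up to 10 times. The jackknife uses
leave-one-subject-out estimates with the standard (N−1)/N variance and a
normal interval. Duplicated subjects in a bootstrap resample produce
off-diagonal similarity 1; BC intervals are rank-based, so this is
accepted.

The edgewise variant uses, per edge, the rank-one kernel z zᵀ of the
patient-standardized entropy values with the diagonal replaced by 1, fits
each measure univariately, and averages the P clipped fractions. The
rank-one construction is a documented reconstruction: it is the simplest
kernel whose off-diagonal entries are the products of subject deviations,
and the planted-edge dilution test (an edge driving one of P measures at
fraction f scores ≈ f/P) behaves as expected.

## Network statistics

Edgewise values are averaged within/between the 8 systems (7 cortical
networks + subcortex; synthetic labeling assigns contiguous blocks with
the subcortex at its empirical share, 16/116). Two nulls:

* **Edge shuffle** relocates the template's edges uniformly among all
  P(P−1)/2 positions, values attached (size- and density-matched). An
  equivalent value-permutation variant over the fixed topology is
  provided and agrees distributionally for exchangeable fields.
* **Rewire** performs degree-preserving double-edge swaps (10·|E| swaps
  per permutation) and reassigns values by matching the original
  nodal-strength ranking (edges sorted by endpoint strength receive the
  sorted values). Degrees are preserved exactly; strength preservation is
  approximate and reported (Spearman of nodal strengths, typically
  > 0.9). Graphs with no swappable pairs (stars) raise an error.

Block p-values are one-sided (greater), add-one estimated, and corrected
with Benjamini–Hochberg over all 36 blocks (the widest, most conservative
family). Detection of a planted block enrichment at p ≤ 0.001 requires
the template to be dense enough that null relocations place several edges
in the tested block — with sparse templates a single relocated high value
can tie the block mean, flooring the achievable p around 10⁻².

Degree-centrality is the binary degree normalized by the null-mean degree
of the relocation ensemble (expectation 2|E|/P, matched by the ensemble
within 2%). Node-Entropy is the HEN − LEN normalized-degree difference on
cortical parcels, min-max rescaled to [0, 1]; a constant difference is
degenerate and raises an error.

## Spatial surrogate maps

Annotation-map correlations are tested against surrogates that preserve
the map's value multiset exactly and its variogram approximately: permute
the map, smooth with Gaussian distance kernels over a bandwidth grid
(plus two-scale blends of a coarse and a fine field — a single kernel
cannot reproduce fields that are steep at short range yet smooth at long
range), pick the candidate minimizing the relative variogram mismatch,
and rank-remap the source's sorted values onto the candidate's ranks.
Variograms use equal-count (quantile) distance bins restricted to pairs
below the 60th distance percentile: the longest lags in a finite domain
carry boundary-induced anticorrelation that smoothing surrogates cannot
reproduce and that carries no autocorrelation information.

Tests are two-sided on |r| with the add-one estimator; surrogates are
generated for the annotation map, not for Node-Entropy. Maps with
|r| < 0.2 are dropped before testing and BH-FDR runs over the retained
set. Two caveats are worth stating plainly:

* the screen-then-test structure concentrates small p-values among
  retained maps by construction, so under a global null the retained
  family is anticonservative; the retention threshold is a descriptive
  screen, not an error-controlled step;
* for *extremely* smooth maps (few effective spatial degrees of freedom)
  the surrogate null remains somewhat narrow and residual inflation
  survives (false-positive rates of ~0.1–0.2 where the naive parametric
  test shows ~0.3–0.4). This is a known property of smoothing-based
  surrogate families.

## Cognitive integration structure

The first principal component of the measures' correlation matrix is
oriented to a positive loading sum; its variance fraction is λ₁/P.
Group contrasts of mean loadings use a percentile bootstrap over subjects
(default 2000 replicates) with per-replicate re-orientation, which keeps
the bootstrap distribution unimodal.

## Synthetic data

The generator's defaults mirror a realistic study: 53 controls, 97
patients, 116 parcels, 410 frames at TR 0.8 s, 7 measures, 5 covariates
(age ~ Normal(22.65, 3.36) years, sex ~ Bernoulli(0.37), antipsychotic
dose ~ half-Normal with mean ≈ 175 mg, mean framewise displacement ~
logNormal with mean 0.12 mm, phenotype ~ Bernoulli(24/97)). All outputs
are deterministic given the config seed.

**Edge dynamics.** Windowed-correlation series of *uncoupled* bandpassed
signal pairs are already at the roughness ceiling this pipeline can
express — the 75-frame window with step 1 imposes the smoothness floor,
and any pairwise coupling adds structure that *lowers* ESE. The planted
contrast is therefore built around that ceiling: baseline nodes share one
slow source with a sinusoid-modulated amplitude and exactly sign-balanced
loadings (invisible to the global-mean regression), placing background
edges mid-scale; regular edges are node-disjoint pairs driven by a
private AR(1) source whose sign on one member switches as a slow
telegraph process (deep square-wave correlation — the lowest-ESE
mechanism found); irregular nodes are whitened and decoupled, so every
edge incident to them sits at the ceiling. Because high ESE is physically
a node property (roughness contaminates all incident edges), the planted
irregular set is node-induced — all edges incident to the designated
nodes. Template recovery sharpens with the number of reference subjects
(group-mean ESE noise scales as 1/√n); the planted-recovery experiments
use 100 reference subjects at 40 parcels, where both planted sets are
recovered with Jaccard ≳ 0.9.

**Behavior.** Y = XB + L_R Z L_cᵀ + E with L_R L_Rᵀ = R and
L_c L_cᵀ = Sigma_c draws exact Kronecker-covariance samples; helper
constructors plant an overall fraction (isotropic Sigma_c = f·I,
Sigma_e = (1−f)·I) or a mixture of several kernels at given fractions.
The trace-ratio estimator recovers planted fractions with |bias| < 0.01
at N = 100.

**Annotation maps** are Gaussian fields with exponential covariance
exp(−d/range) on parcel centroids (uniform in a 100-unit cube),
standardized. **Entropy features** (`generate_entropy_features`) are an
entropy-scaled shortcut for model-level experiments: a positive baseline
with independent low-rank subject structure per informative edge set;
they skip the timeseries stage deliberately and are not a substitute for
the full pipeline where edge dynamics matter.

What passing tests on these data do *not* show: robustness to
hemodynamic variability, scanner noise spectra, motion artifacts, or
empirical ESE distributions; the generator's planted contrast is designed
to be recoverable, not to imitate the full messiness of real recordings.

## Problem sizes used in validation

Simulation-based checks use sizes chosen for statistical power of the
check itself: 500 replicates for estimator bias and test calibration
(N = 100, P = 7, rank-8 correlation kernel, 5 covariates); 100 runs ×
1000 bootstrap replicates for the planted HEN/LEN contrast (N = 97,
250-edge templates, rank-20 kernels); 100 reference subjects × 40 parcels
× 410 frames for end-to-end template recovery; 10⁴ permutations for the
planted block enrichment; 10³ surrogates for map fidelity. The
acceptance script regenerates all of these from scratch.
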