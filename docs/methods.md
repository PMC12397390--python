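# Methods

## Signal model and feature definitions

The analysis operates on the per-sample magnitude of the 3-axis
acceleration vector, m_i = √(x² + y² + z²), which removes dependence on
sensor orientation. A resting animal reads ≈ 1 g (g = 9.81 m/s² exactly,
by convention throughout the package); movement appears as excursions,
predominantly above 1 g. Recordings are trimmed to a common 12 h
active-phase window (19:45 onset, I = 1,080,000 samples at f_s = 25 Hz);
partial seconds at the window edge are truncated toward the window
interior, and input must be gap-free (timestamps uniform at 1/f_s within
1e-6 s — packet loss is not modelled and is rejected at parse time).

The magnitude series is split into non-overlapping segments of S = 1500
samples (one minute), dropping any trailing remainder, so a full 12 h
trace yields N = 720 segments. Each segment is summarized by four
moments:

- mean μ = (1/S) Σ m_s
- variance σ² = 1/(S−1) Σ (m_s − μ)²  (unbiased)
- skewness γ = [(1/S) Σ (m_s − μ)³] / (σ²)^{3/2}
- kurtosis κ = [(1/S) Σ (m_s − μ)⁴] / (σ²)²  (plain, no −3)

Note the estimator mix: the third/fourth central moments use a 1/S
numerator while the denominator is built from the unbiased variance.
This is neither the textbook biased nor bias-corrected estimator; it is
implemented verbatim because downstream reference values depend on it
(a unit test asserts it differs from both scipy conventions, and a
brute-force loop oracle pins it to 1e-12 relative tolerance). Kurtosis
is non-excess — pooled segment-mean values around 50 only make sense on
that convention.

g-normalization divides each statistic by the order-matched power of g
(μ/g, σ²/g², |γ|/g³, κ/g⁴), with skewness entering as its absolute value
so it survives log-binning. For γ and κ, which are already
dimensionless, this normalization is dimensionally inconsistent; both
raw and normalized values are therefore carried, and every group
comparison and reported class mean uses the raw scale.

Constant (zero-variance) segments get σ² = 0 with γ, κ undefined; they
are flagged, counted, and excluded from the per-animal means. Real
recordings never contain them (sensor noise alone prevents it) but
synthetic edge cases do.

Per-animal summaries are the arithmetic means of the segmental
statistics (μ̄_d, σ̄²_d, γ̄_d as the mean of |γ|, κ̄_d) plus the overall
variance σ²_d of the full magnitude series (1/(I−1) convention; at
I ≈ 10⁶ the 1/I alternative is indistinguishable).

## Outlier screening

The overall variances σ²_d are screened per condition class with the
MAD-median rule: flag dataset d when

    |σ²_d − median(σ²)| / (MAD(σ²)/0.6745) > K,  K = √χ²₀.₉₇₅,₁ ≈ 2.2414

where MAD is the median absolute deviation from the median and 0.6745
makes MAD/0.6745 a consistent normal-scale estimate. K is evaluated from
the χ² quantile at runtime, never hard-coded. Even-count medians average
the two central order statistics. A class with MAD = 0 (all variances
equal) is reported as degenerate and nothing is flagged there, rather
than dividing by zero. Under normality the rule flags ≈ 2.5% of ordinary
datasets — so in finite cohorts an occasional borderline animal is
flagged alongside genuine defects; an injected 10×-variance animal
scores an order of magnitude above any ordinary one and is always
caught. Exclusion is automated by the MAD rule alone; the 2-D PCA
projection of the cohort magnitude matrix (column-mean-centered, scores
U·Σ, per scikit-learn's convention) is produced as a visual diagnostic,
since the visual-inspection half of a combined screen cannot be
automated.

## Hypothesis testing

Group differences in σ̄²_d and γ̄_d are assessed with three nonparametric
two-sample tests: Mann-Whitney U (exact null when the pooled size is
≤ 25 and tie-free, normal approximation with tie correction otherwise),
two-sample Kolmogorov-Smirnov (exact at small n), and
Baumgartner-Weiß-Schindler. The BWS statistic B averages two weighted
squared rank-discrepancy sums, up-weighting the distribution tails by
1/(t(1−t)); p-values come from full permutation enumeration whenever
C(n1+n2, n1) ≤ 10⁵ (the 5-vs-10 study shape gives 3003 splits), Monte
Carlo above that, and an asymptotic path for pooled sizes ≥ 20. The
asymptotic null of B is the Anderson-Darling limiting distribution (the
same weighted Brownian-bridge integral); we evaluate it with the
Marsaglia-Marsaglia polynomial approximation, which reproduces the
90/95/99% critical values 1.933/2.492/3.857 to ≈ 1e-4. Ties are handled
by midranks and flagged. All tests are two-sided.

Multiple testing uses the literal Holm-Bonferroni multiplier
p̃_i = p_i (N_HT + 1 − i) on ascending p-values, deliberately without the
cumulative-maximum monotonization of the textbook step-down (the
adjusted sequence may be non-monotone; the largest raw p is returned
unchanged). Significance decisions follow the sequential rule — the
first sorted test with p̃ > α and all later ones are non-significant —
so the inference is identical to standard Holm. Adjusted values are
capped at 1 with a flag.

Because the exact tests are discrete at 5-vs-10, their attainable levels
differ: under the null the rejection probability at α = 0.05 is ≈ 0.040
for MWU, ≈ 0.042 for BWS, but exactly 58/3003 ≈ 0.019 for the exact KS —
a well-known conservativeness of the discrete KS null. The test suite
asserts each empirical rate against its enumerated attainable level
rather than pretending all three sit at 5%.

Welch's unequal-variance t-test (two-sided) validates the
apomorphine-rotation separation of the cohorts. The severity correlation
(Pearson and Spearman, both reported since neither is canonical here)
relates σ̄²_d to rotation rate **within the lesioned group only**:
rotation rpm grades the dopaminergic deficit among lesioned animals,
and pooling classes would manufacture a between-class correlation that
says nothing about severity grading.

## Histograms

Per-class distributions of m̃ and the pooled normalized segmental
statistics use logarithmically spaced bins (default 100; range
auto-set to [min positive value, max]) to amplify right-tail
differences, where the classes separate. Non-positive values (|γ| = 0)
cannot be log-binned and are excluded with a count. Geometric edges mean
doubling the bin count refines each bin exactly in two, so coarse
histograms are recoverable by merging — a tested invariant.

## Synthetic cohorts

The generator emulates the minimal structure the analysis relies on:

- **gravity**: exactly 1 g along a unit vector whose spherical angles
  perform a Brownian walk (orientation_drift_rate, default 0.02 rad/√s).
  Rotation preserves the norm, so drift changes per-axis signals (needed
  for the directional transforms) without touching magnitude statistics.
- **bouts**: an alternating rest/active two-state process with
  exponential durations (defaults 60 s / 60 s, stationary start), gating
- **bursts**: zero-mean white Gaussian per-axis noise during active
  bouts (burst_sd_sham / burst_sd_pd), plus an always-on sensor noise
  floor (default 0.03 m/s² per axis), and
- **quantization**: optional 16-bit ±4 g rounding/clamping.

With equal rest/active bout means the expected mean segmental variance
is ≈ ½·burst_sd² + sensor_noise_sd², so the defaults burst_sd_sham =
0.747 and burst_sd_pd = 0.571 m/s² place the class means near the
reference calibration targets 0.279 and 0.163 m²/s⁴ (measured ≈ 0.28 /
0.16 on full-length runs); these defaults were fixed from that
calibration and are not tuned per experiment. Rotation rates are drawn
per class (sham 0.16 ± 0.51, lesioned 7.18 ± 1.20 rpm, matching the
reference table's location and spread) independently of burst variance —
the generator encodes no severity gradient, so a near-zero within-class
severity correlation is the expected outcome. Designated outlier animals
have their burst variance multiplied by outlier_variance_multiplier
(default 10), emulating pathologically hyperactive datasets.

What the generator does **not** emulate: circadian structure beyond a
single active phase, autocorrelated or heavy-tailed burst dynamics, gait
periodicity, posture-dependent noise. Consequently the achieved
segmental skewness (≈ 0.25–0.3) and kurtosis (≈ 10) are smaller than the
reference class means (0.57/0.34 and ≈ 50): those values require rarer,
spikier movement bursts than white Gaussian gating produces. The
variance calibration — the feature that carries the discrimination — is
faithful; passing tests therefore demonstrate the pipeline's behavior
under the assumed variance structure, not that the generator reproduces
every moment of real rat accelerometry. Heavier-tailed burst mixtures
are the natural extension if kurtosis-level realism is ever needed.

Per-animal random streams derive from (seed, animal_id), making cohorts
bit-reproducible and invariant under reordering or subsetting.

## Numerical and design choices

- On-disk format: `time,x,y,z` CSV plus a YAML metadata sidecar and a
  YAML cohort manifest; units m_s2, g, or raw_counts (scale
  4·9.81/32768 per count). One text format keeps fixtures and diffs
  trivial; an HDF5 mirror was considered and dropped at these cohort
  sizes.
- Full SVD/randomized choice for the PCA is delegated to scikit-learn's
  solver policy; an eigendecomposition oracle pins the scores to 1e-10
  on test sizes.
- Permutation p-values count the observed split (exact enumeration) or
  use the (count+1)/(n+1) estimator (Monte Carlo); B comparisons use a
  1e-12 tolerance so enumeration oracles match to float precision.
- Degenerate inputs raise typed errors (constant Welch input, constant
  correlation input, sub-minimum class sizes for the MAD rule) rather
  than returning NaN.
- The pipeline caches the per-animal summary table keyed by a config
  hash and reuses it only when PCA and histograms are disabled (those
  need the raw series); all report tables are written deterministically,
  and byte-identical reruns are a tested property.
- Printed-table arithmetic (reference rotation means) is done in exact
  rational arithmetic with half-up rounding, because binary floats plus
  banker's rounding misprint 7.175 as 7.17.

## Problem sizes used by the test suite and acceptance script

Single-cohort end-to-end acceptance runs use full-scale recordings
(12 h, 1,080,000 samples, 18 animals). Repeated-cohort properties use
shorter recordings chosen for stable summary statistics at manageable
cost: 30 min × 20 cohorts for the class-separation rate, 10 min cohorts
for pipeline unit tests, and 2000 summary-level simulations for the
type-I/FWER calibration. The statistical conclusions these support are
about per-animal summary distributions, which the shorter recordings
estimate with proportionally fewer segments.

## Known limitations

- The generator's skewness/kurtosis shortfall described above.
- The MAD rule's ≈ 2.5% nominal false-flag rate means simulated cohorts
  occasionally exclude an ordinary animal; the pipeline reports scores
  and IDs so such exclusions are auditable.
- The asymptotic BWS path inherits the ≈ 1e-4 absolute error of the
  polynomial CDF approximation and is refused below pooled size 20.
- Group testing assumes independent animals and exchangeability under
  the null; no covariates (weight, sensor identity, recording night)
  are modelled.
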