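# Methods

This note documents the models, estimators, numerical choices and
limitations behind `gswave`.  The package analyzes regional BOLD time
series collected across six sequences per participant in two independent
cohorts (a training and a testing scanner), and validates every stage on
synthetic cohorts with known ground truth.

## Wavelet machinery

The maximal overlap discrete wavelet transform (MODWT) is implemented as
the standard pyramid algorithm with the 8-tap Daubechies least-asymmetric
filter ("la8"; the quadrature-mirror wavelet filter is
`h_l = (-1)^l g_{L-1-l}`).  Boundaries are handled by reflection: the
series is mirror-extended to length 2N, circularly transformed, and the
first N coefficients kept; the additive multiresolution components are
synthesized on the extension and truncated, so the reconstruction identity
`x = sum_j D_j + S_J` is exact to machine precision.  Scale `j` nominally
covers `[f_N/2^j, f_N/2^(j-1)]` with `f_N = 1/(2·TR)`.

**Wavelet variance.**  The unbiased estimator averages squared
coefficients over the `N_hat_j = N − L_j + 1` non-boundary positions
(`L_j = (2^j − 1)(L − 1) + 1`).  At scale 6, `L_6 = 442` exceeds every
realistic sequence length (180–504 volumes), so whenever `N_hat_j < 8` the
estimator falls back to all N coefficients and flags itself `biased=True`.
Callers that need strictness can check the flag; the degenerate error path
is reserved for series too short to decompose at all.

**Wavelet correlation and Fisher z.**  `r` is the Pearson correlation of
the scale-j coefficients; `z = atanh(r)·sqrt(df − 3)`.  MODWT coefficients
are serially correlated, which inflates the variance of `r` by the
Bartlett factor `C_j = sum_k rho_j(k)^2` (≈ 0.63·2^j for la8, computed
once per scale from the equivalent filter's autocorrelation via FFT).  The
default df convention is therefore the effective sample size
`N_hat_j / C_j`, under which the null z is standard normal (checked by
simulation); `nonboundary` (`N_hat_j` itself) and `conservative`
(`N_hat_j / 2^j`) conventions are exposed for users who want the
uncorrected or a deliberately pessimistic count.  `|r| = 1` returns a
signed-infinite z rather than an arbitrary cap.

## Synthetic cohorts

Each subject × sequence matrix is a low-rank spatial process: one global
mode with positive regional weights (the GS topography), ten local modes,
and per-region noise.  All temporal sources — including the noise — are
built by re-weighting the MODWT bands of white noise with a common
1/f-shaped gain profile, so the per-band signal-to-noise ratio is constant
across frequencies.  That choice is what makes the planted group effect a
*pure scaling* phenomenon: the low-frequency (scales 4–6 + smooth) content
of the complete series (signal and noise alike) is multiplied by
`group_lowfreq_scale` in group 1, leaving the inter-regional correlation
structure untouched, so per-region z-scoring abolishes the effect — the
behaviour the scaled/unscaled eigenvalue comparison is designed to expose.

Planted-effect sizing is closed-form: subjects carry a lognormal amplitude
multiplier with log-sd `sigma_a = 0.25`, giving log low-frequency variance
a between-subject sd of `2·sigma_a`; a scale factor `s = exp(d·sigma_a)`
therefore plants a population Cohen's d of `d`
(`lowfreq_scale_for_cohens_d`).  Defaults emulate the study conditions:
sequence lengths 330/330/240/240/504/180 at TR = 1.5 s (1824 volumes),
278 regions, 55 subjects per group, 26 z-scored questionnaire scales from
a 4-factor model plus age/group/education (29 analysis columns).

Motion traces are gamma-marginal (shape 2, scale 0.1 mm) with AR(1)
temporal structure through a Gaussian copula; group 1 receives a larger
white-noise share in the latent process, raising its high/low-frequency
wavelet-variance ratio by `hf_motion_ratio_effect` on the log scale.
Subjects differ in overall magnitude (lognormal gamma-scale multiplier,
sd 0.4), shape, autocorrelation and spectral mix — heterogeneity that
gives the 12-metric covariance the dominant general-magnitude factor plus
frequency-content and persistence factors that the cohort PCA summarizes,
and that makes its loadings reproducible across independently seeded
cohorts.  `motion_heterogeneity=0` disables all of it for
marginal-recovery tests.  FWD is generated directly (length T−1, padded
with a leading zero when aligned to frames) rather than derived from the
six rigid-body series, which are independent smooth plumbing.

Every latent component (global mode, structured signal, its low-frequency
part, artifact, noise, spike frames) is stored on the subject, so
downstream estimators are tested against ground truth rather than against
themselves.

What the generator does *not* emulate: spatial autocorrelation within
parcels, hemodynamic response shapes, physiological (cardiac/respiratory)
quasi-periodicity, scanner drift nonstationarity, and heavy-tailed BOLD
noise.  Passing tests therefore demonstrate correctness of the estimators
and calibration of the inference under the stated generative model, not
robustness to every property of real data.

## Nuisance correction

Stage 1 isolates transients: PCA of the noise pool (top 30 components);
components with raw kurtosis > 4.5 (Gaussian = 3) containing any
|z| > 4.5 excursion contribute spike series that keep only their |z| > 3
entries; frames whose detrended FWD exceeds 1 mm contribute one-frame
regressors.  "Detrended" means the trace minus its zero-phase Butterworth
*low-pass* estimate (cutoff 0.01 Hz): subtracting the trend rather than
applying a high-pass filter preserves single-frame spike amplitudes
against the 1 mm threshold.  The joint spike set is reduced by an
*uncentered* SVD keeping eigenvalues above 1e-8 of the trace — uncentered
so the regressors remain exactly zero off-spike.

Stage 2 regressors: top 7 noise-pool PCs plus first differences
(zero-padded, length-preserving), and the motion block — six rigid-body
parameters + detrended FWD, very-low-frequency content removed by
discrete-cosine projection below 0.001 Hz (recursive filters with such
cutoffs have impulse responses longer than a sequence and are
ill-conditioned), expanded to basic + sqrt-of-absolute series (14), plus
first and second differences (42), z-scored, PCA, top 7 scores.  The
final regression runs the spike/task design first and then the full joint
design, so residuals are orthogonal to every column despite the two-stage
order.  Rank-deficient designs are resolved by least squares with a
warning.

## GS metrics and inference

Per scale: mean inter-regional correlation (averaged on the Fisher-z
scale — z can be negative, so no log transform is applied to it; the two
variance metrics are log-transformed), median regional wavelet variance,
and the wavelet variance of the global series.  Raw-mode GS variance uses
the pre-nuisance global series.  Sequence-averaged values are z-scored
across subjects into the 18-column analysis matrix.  Order effects use the
centered unit-spacing contrast (±2.5 … ∓2.5); the default sign convention
is increase-positive, since the package's planted drifts (and the
reported variance trends) increase across the session — the
first-sequence-weighted convention is a sign flip away.  Group inference
is per-measure OLS with five motion-PC covariates, Bonferroni α/54 in the
training cohort and α/(training hits) in testing; thresholds are reported
rounded to 4 decimals (0.0009, 0.0028, 0.0071, …) alongside arbitrary
precision in `bonferroni_exact`.

## Eigenvalue scaling

For each sequence the regional series are split into their six wavelet
bands (the smooth folded into band 6); each band's time × region PCA
eigenvalue spectrum is fit by `EVM = a·#EV^b + c` with multi-start
nonlinear least squares (`b0 ∈ {−0.5, −1, −2}`, first
`min(n_regions, 100)` eigenvalues), and parameters are averaged across
bands/sequences ("fit per band, then average"; "all" = bands 1–6, "low" =
4–6).  Fitting per band matters: within one band a group amplitude
difference is a constant multiplier, which z-scoring cancels exactly —
fitting the unfiltered series instead leaves an effective-degrees-of-
freedom signature that survives z-scoring and mimics a complexity
difference.  `a` is log-transformed for group tests (it scales
multiplicatively, and `log a` shifts by exactly `2·ln s` under series
scaling by `s`).

## Topography, reliability, PLS

Regional GS association is the slope t of region-on-GS regression after a
128-s discrete-cosine high-pass, mapped through the normal quantile of the
t CDF and capped at |z| = 8.  Group and order inference use max-|t|
permutation (label permutation and sign-flips respectively, default 1000
permutations) for parcel-level family-wise error control; there is no
parcel analog of voxelwise spatial smoothing, so none is applied.

ICC(3,1) is computed vectorized from two-way mean squares,
`(BMS − EMS)/(BMS + (k−1)·EMS)`, treating the six sequences as fixed
raters (consistency, single measurement); zero between-subject variance
yields a defined non-positive value.  Measures missing any sequence are
excluded, not imputed.

PLS is the symmetric PLS-SVD of the column-standardized cross-covariance;
component strength is the (sign-aligned, hence non-negative) correlation
of paired X/Y scores, with p-values from permuting the rows of Y
(`p = (1 + #{perm ≥ obs})/(n_perm + 1)`, default 5000 permutations,
seeded).  Feature selection (30 measures after excluding |skewness| > 1)
offers correlation, ICC, combined (sum of z-scores), and dynamic methods;
the dynamic score is the largest across behaviors of the max-minus-min
sequence-wise correlation, and the frozen feature value is the FC change
between the extreme sequences.  Ties break by measure id (stable sort).
Selections fitted on the training cohort are frozen before test-cohort
evaluation; the package's calibration suite demonstrates the
anti-conservativeness of training-cohort inference under correlation-based
selection and the calibration of frozen-feature testing.

Correspondence reports correlate train/test saliences per component after
sign alignment (the flip that maximizes |r| on the X side is applied to
the component as a whole), with offset-by-one comparisons and explained-
variance profiles; PCA loading correspondence is computed the same way.

## Problem sizes

Tests and the acceptance script run at reduced scale chosen by the
package: end-to-end detection uses 50 subjects per group, 12 regions and
two 256-volume sequences over 8–10 replicates; calibration suites use
150–300 replicates at 150–500 permutations; MODWT and ICC oracles run at
full stated precision (1e-10).  These sizes keep the whole validation
reproducible on a single CPU while leaving the planted-effect detectors
comfortably powered.

## Known limitations

* Voxel-level operations (masks, cluster-level random-field inference,
  spatial smoothing) have no parcel analog here by design.
* The scale-6 wavelet variance is necessarily the biased estimator at
  realistic sequence lengths (documented flag).
* The per-component permutation p-values test each component's score
  correlation against its own permuted rank; no step-down correction
  across components is applied beyond the replication-threshold rule.
* The generator's closed-form effect sizing (`d = ln s / sigma_a`) is
  exact for the latent low-frequency variance; measured effect sizes are
  slightly diluted by estimation noise at short sequence lengths.
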