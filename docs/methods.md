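# Methods

This package implements, end to end, the analysis of a value-based dietary
self-control fMRI experiment, exercised on synthetic data with known ground
truth. This note documents the generative model, the analysis procedures,
the numerical choices, and what the verification experiments do and do not
demonstrate.

## The task and the behavioral model

Participants rate 50 food images on healthiness and on tastiness (5-point
scales coded −2..+2), then decide on each food whether they would eat it
rather than a neutral reference item (−2 "strong no" .. +2 "strong yes";
the decision rating is the food's *goal value*, GV). Each trial shows the
stimulus for at most 4 s (the regressor duration is the reaction time),
followed by 0.5 s feedback (never modeled) and a uniform 4–15 s
inter-trial interval. Each block is one functional run (TR 2.0 s, 343
volumes at full scale, 3 mm isotropic voxels); rating-block order is
counterbalanced across subjects and the decision block comes last.

The simulator draws per-stimulus latent healthiness/tastiness traits from
a bivariate normal whose marginal moments are solved (by moment matching
through the discretization) so the discretized ratings reproduce the
task's stimulus statistics: mean health −0.35 (SD 1.41), mean taste 0.57
(SD 1.10), with ≈0 health–taste correlation. Subject ratings add normal
noise (SD 0.3) on the latent scale before discretization at fixed
symmetric cut points ±0.5, ±1.5 — the same cut points used to map the
decision utility

    u = w_h · H + w_t · T + ε,   ε ~ logistic(scale 0.6)

onto the 5-point decision scale. Self-controllers (SC) weight health over
taste (w_h = 1.0, w_t = 0.2) and non-self-controllers (NSC) the reverse
(w_h = 0.3, w_t = 0.9). The SC taste weight is deliberately below 0.25 so
that with all noise switched off the decision sign equals the health sign
on every conflict trial, making the classifier-closure property exact.
The NSC weights and the logistic noise scale are set so that most NSC
subjects still show *some* self-control (mirroring a cohort in which ~59
of 80 participants exhibit any), yes-proportions to liked-unhealthy foods
separate strongly between groups, and between-group per-stimulus rating
correlations are ≈.99/.96 — the behavioral fingerprint the analysis
expects. Each response is independently missing with probability 0.01.
The full-scale defaults (80 subjects, SC fraction 15/80, 50 stimuli, 343
volumes) are the package defaults; tests and the verification experiments
run scaled-down conditions (16 stimuli, 130 volumes, 12³ grid) chosen so
the task timing still fits the run with wide margin.

Classification implements both rule sets. Three-criteria: (1) self-control
succeeded on strictly more than 50% of conflict trials (declining
liked-unhealthy or choosing disliked-healthy; neutral decisions count as
failures; missing decisions are excluded from numerator and denominator);
(2) in the joint OLS of GV on H and T the standardized health coefficient
exceeds the standardized taste coefficient in magnitude; (3) the simple-
regression R² of health exceeds that of taste. All three → SC, none →
NSC, otherwise unclassified. One-criterion: success rate **at least** 50%
→ SC, else NSC. Whether the original criterion 2 compared signed, absolute
or standardized coefficients is ambiguous; we compare standardized
magnitudes (H and T share the −2..+2 scale, so raw ≈ standardized).
Profiles are canonically sorted by stimulus id before fitting so the
classification is bit-identical under any row order.

## BOLD forward model

Each labeled region (vmPFC, caudate, dlPFC, IFG, white matter,
background — disjoint boxes on the common grid) carries a sum of signal
channels: condition boxcars and mean-centered rating modulators built by
the *same* microtime convolution code the analysis uses, so that with
noise off the first-level GLM recovers the simulated amplitudes exactly.
The default truth encodes the study's hypotheses: vmPFC carries goal
value during decisions plus group-dependent health/taste attribute
signals (health in SC only), caudate a weaker value signal, dlPFC an
unhealthy-food response (the PPI seed), and IFG a coupling to the dlPFC
neural series specific to unhealthy trials. White matter accepts no
amplitudes by construction — the configuration validator rejects any —
so it is a guaranteed null region for the circularity control.

The dlPFC *neural* series is its task drive plus an intrinsic AR(1)
fluctuation (SD 1.0, lag coefficient 0.5 at TR resolution); the IFG
interaction channel is the HRF convolution of (centered seed neural ×
unhealthy indicator). Nuisance structure: low-frequency cosine drift
drawn exactly from the discrete-cosine basis below the 1/128 Hz cutoff
(so high-pass filtering removes it exactly, making the filter testable),
stationary AR(1) Gaussian noise per voxel (default ρ = 0.3, SD 1.0 on a
baseline of 100), and six AR(1) motion traces that are pure nuisance
(they never couple into the signal). Amplitudes are in noise-SD units per
unit regressor height. The "strong" preset (vmPFC goal-value amplitude
2.0, no other channels) defines the recovery experiments' effect size.

What the simulator does **not** emulate: scanner artifacts,
motion-induced signal, susceptibility dropout, spatial autocorrelation of
the noise (noise is iid across voxels before optional smoothing),
region-internal heterogeneity, and anatomically realistic geometry.
Passing tests therefore demonstrate the correctness and calibration of
the *analysis machinery* under the assumed generative model, not
robustness to real-data artifacts.

## First-level GLMs

Five task GLMs plus a PPI seed localizer, all with boxcar duration equal
to the reaction time, six motion regressors, and one constant per run;
feedback is unmodeled. GLM1 (all runs): three block boxcars, each times a
goal-value parametric modulator, plus a boxcar for trials with missing
ratings. GLM2 (decision run): one boxcar per decision level. GLM3a/3b
(all runs): health and taste modulators per block boxcar, entered in the
two orders. GLM4 (decision run): successful self-control, unsuccessful
self-control, no-conflict, neutral-response, and missing-rating boxcars
(neutral and missing take precedence; the unsuccessful class is modeled
so the success-vs-failure contrasts of the ROI analyses are estimable).
GLM5 (decision run): liked-unhealthy, disliked-healthy, no-conflict,
neutral, missing.

Parametric modulators are mean-centered within condition and
**sequentially orthogonalized** on the microtime grid — each modulator
residualized against its condition boxcar and all earlier modulators —
*before* HRF convolution, mirroring the SPM default that makes the
entering order matter when modulators correlate. Convolution uses the
canonical double-gamma HRF (response gamma peak 6 s, undershoot 16 s,
dispersions 1, ratio 1:6, truncated at 32 s, unit peak) on a microtime
grid of 16 bins per TR, sampled at the middle bin. Empty conditions are
dropped with a warning and flagged; contrasts referencing them raise.

High-pass filtering projects the per-run discrete-cosine basis below
1/128 Hz out of both data and design; residual degrees of freedom are
reduced by the number of basis functions. Fitting is a two-pass pooled
AR(1) scheme: OLS residuals give a lag-1 ratio pooled over the mask; a
trace-based correction inverts the attenuation induced by the combined
design+drift projector (solving E[lag-1 ratio | ρ] = observed by fixed
point), and data and design are prewhitened with the (1, −ρ̂) difference
filter per run before the final least-squares pass. The correction
matters: projection alone biases the raw ratio from 0.30 to ≈0.13 at
desk scale. Note that unmodeled smooth signal (e.g. intrinsic neural
fluctuations) legitimately inflates ρ̂ above the noise value, exactly as
in real data; prewhitening at the pooled ρ̂ leaves estimates unbiased.

Smoothing is isotropic Gaussian (default FWHM 8 mm) applied to the BOLD
before fitting, with an off switch; the calibration experiments run
unsmoothed so that voxelwise false-positive counts are independent.

Group inference: voxelwise one-sample t against zero, or pooled-variance
two-sample t (df = n₁ + n₂ − 2, matching t(78)-style reporting for 15 vs
65 subjects). Maps are thresholded at p < .001 / p < .005 uncorrected or
Benjamini–Hochberg FDR q = .05 over in-mask voxels; clusters use
18-connectivity with peak coordinates in mm from the RAS affine.

## ROI extraction and the circularity control

Two strategies, both operating on subject-level betas (mirroring
beta bar plots): *peak* selects each subject's maximal voxel on a
selection contrast inside a mask (ties broken by smallest linear index)
and reads the test-contrast betas there; *mean* averages test-contrast
betas over the mask. When selection and test share data, peak extraction
is circular: `selection_bias_experiment` draws per-subject null beta
pairs (successful/unsuccessful), selects each subject's peak on the
difference, and runs the paired t test at those self-selected voxels —
the rejection rate on a 50-voxel null region exceeds 50% (it is ≈100% at
default noise with 20 subjects, mean spurious effect ≈3 noise SDs, the
expected maximum of 50 standard-normal differences) while mean extraction
stays at the nominal 5%. The experiment accepts a custom beta sampler so
it can be driven from fitted noise statistics as well as the default iid
model.

## PPI

Stage 1: a decision-run localizer GLM (healthy/unhealthy boxcars +
motion) finds each subject's strongest positive unhealthy-food voxel
inside the supplied dlPFC mask; the BOLD average over a 4 mm sphere at
that peak is residualized against motion and deconvolved to a neural
series. Deconvolution is ridge-regularized inversion of the causal HRF
Toeplitz operator at TR resolution, with the penalty chosen by
generalized cross-validation (documented fallback λ = 1). The final ~8 s
of a run are structurally unidentified (the causal HRF has not yet
transduced that activity into in-run signal), so round-trip accuracy is
quoted over the identified range, where the error on band-limited
signals is <2%. The exact deconvolution algorithm of SPM-style pipelines
is not reproduced; only these qualitative properties are claimed.

The PPI regression per voxel contains (a) the HRF-convolved interaction
of the neural series with the centered psychological variable, (b) the
convolved unhealthy-trial indicator, (c) the observed seed series, plus
the convolved any-trial indicator, motion, and a constant. The
psychological variable is coded +½ during unhealthy trials, −½ during
other trials, 0 at rest; including both indicator main effects makes the
interaction beta exactly invariant to constant shifts of the seed series
(tested). Stimuli with neutral health ratings are excluded from the
unhealthy indicator by default (flag provided). A variance-inflation
check warns when the interaction is nearly spanned by the main effects.
Stage 2 reseeds from the peak of a stage-1 group cluster (4 mm sphere)
and repeats the regression. Positive interaction betas mean coupling to
the seed is stronger on unhealthy trials; the generative IFG coupling
g > 0 is recovered with the correct group-level sign in ≥95% of
simulations at desk scale, and a null-coupling world rejects at the
nominal rate.

## Verification experiments and problem sizes

`selfcontrol_fmri.experiments` (driven by `analysis/04_…` and
`scripts/acceptance.py`) runs: classifier closure (50 noise-free
subjects plus the rate-0.5 boundary case), the OLS normal-equation oracle
(100 random instances), the modulator-order check (exactly orthogonal
modulators agree to <1e-6 by construction — equal durations and
decorrelated ratings make the microtime columns orthogonal — and at
correlation 0.6 the first-entered modulator absorbs the shared signal),
amplitude recovery (20 repetitions × 30 subjects, unsmoothed, ROI-level
one-sample t at p < .001, with white-matter voxelwise false positives
pooled over repetitions), peak-vs-mean circularity (1000 simulations, 20
subjects, 50 voxels), BH-FDR calibration (500 null group maps of 400
voxels; on all-null maps the false-discovery proportion is the rejection
indicator, so its mean sits at q up to Monte-Carlo error), PPI recovery
and null calibration (20 small group studies each), and the
deconvolution round trip. All randomness flows through seeds derived
from a single integer.

## Known limitations

* Regions are homogeneous boxes; peak-voxel analyses on *true* effects
  therefore understate the peak-vs-mean difference seen with
  heterogeneous real signals (the null-region circularity result is
  unaffected).
* The pooled-AR(1) prewhitener uses one ρ̂ per fit (SPM-like global
  approximation), not voxelwise or spectral noise models.
* The two-sample group test assumes equal variances (chosen to reproduce
  pooled-df reporting conventions); no Welch branch is exposed at the
  group-map level.
* GLM3-style analyses default to decision-run modulators; the all-trials
  variant is available through the design builder but the pipeline
  reports the decision-trials branch.
* The deconvolution is a transparent ridge inversion, not an
  empirical-Bayes scheme; only sign/shape properties of PPI estimates
  are claimed, not equivalence to any specific software.
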