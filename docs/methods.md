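# Methods

## The model

White matter sampled with a multi-echo gradient-recalled echo (mGRE)
sequence does not decay mono-exponentially: water between the myelin
lamellae, inside axons, and in the extra-axonal space experiences different
local fields and relaxes at different rates. The complex signal is modelled
as the superposition of three pools,

    S(t) = f_a exp(i ω_a t − R2*_a t) + f_e exp(−R2*_e t)
         + f_m exp(i ω_m t − R2*_m t),

with `t` the echo time, `f` the signal fractions, `ω` the angular frequency
offsets relative to the extra-axonal pool (the zero reference), and `R2*`
the effective transverse relaxation rates. Two derived quantities carry the
myelin information: the myelin water signal fraction `f_m` (a proxy for
myelin content) and the myelin–axonal frequency split `Δω = ω_m − ω_a`
(sensitive to the susceptibility of the sheath and the g-ratio). The model
assumes negligible exchange between pools, myelin as the dominant
susceptibility source, and fibres perpendicular to B0 — a good
approximation for the mid-sagittal corpus callosum, which is why that
structure is the target ROI. There is no T1/flip-angle weighting (fractions
are relative) and no orientation dispersion.

Units at the interface follow acquisition conventions: echo times in ms
(converted to seconds inside the exponentials), frequency offsets accepted
and reported in Hz (`ω/2π`), rates in 1/s.

## Frequency difference mapping (FDM)

Measured phase mixes three terms: a TE-independent offset (RF/receive
chain), a linear-in-TE term from the macroscopic B0 field, and the
microstructural non-linearity of interest. The FDM operator used everywhere
in this package:

1. temporally unwrap the per-pixel phase across echoes (no spatial
   unwrapping — at ΔTE = 1.23 ms per-echo increments stay far from π at
   tissue frequencies);
2. subtract the line through the first two echoes,
   `φ_lin(TE) = φ₁ + (φ₂ − φ₁)(TE − TE₁)/(TE₂ − TE₁)`;
3. report `FDM_n = (φ_n − φ_lin(TE_n)) / (2π (TE_n − TE₁))` in Hz for
   n ≥ 3, with the first two echoes identically zero.

Any static phase map and any linear-in-TE frequency map are absorbed by the
linear reference exactly, which is the defining invariance of the method.
The choice of the first two echoes as the anchor and of `TE_n − TE₁` as the
normalizer is one of several defensible conventions; because the *same*
operator is applied to the model curve inside the fit, the estimated
parameters carry no operator-choice bias, but absolute FDM amplitudes are
convention-dependent and should not be compared across packages. A
practical consequence of the two-point anchor: phase noise on the first two
echoes propagates into a common-mode FDM error of roughly
`√2 / (2π ΔTE SNR)` Hz, which sets the precision floor of the fit (see
"Noise" below).

Residual eddy-current structure is removed by a per-echo 2-D polynomial of
total degree ≤ 3 (monomials in centred, scaled pixel coordinates, ordinary
least squares). The polynomial is *fitted* on pixels outside the corpus
callosum and *subtracted* everywhere: the eddy residual is global and
smooth, and excluding the ROI from the fit support prevents the polynomial
from absorbing genuine callosal signal (fitting on the ROI itself was
measured to bias posterior `f_m` by ~0.018 on the synthetic phantom;
off-ROI fitting removes the bias entirely). The detrend is a linear
projection: idempotent, linear, and exact on polynomial inputs.

## Pre-processing chain

Bipolar acquisition alternates the read-gradient polarity between echoes,
leaving an echo-parity phase offset that inverts with the polarity of the
readout train. Complex multiplication of the two polarity groups and
halving the phase, `φ = angle(S⁺S⁻)/2`, cancels every polarity-odd term
exactly; the ±π half-angle ambiguity is resolved toward the phase of `S⁺`.
Coil sensitivities are estimated image-based — the first-echo complex image
per channel smoothed with an 8 mm Gaussian and normalized to unit
root-sum-of-squares — and combined as `Σ conj(ŝ_c) S_c / Σ |ŝ_c|²`. With
exact sensitivities this reproduces the object signal identically; with
estimated ones the combination leaves a smooth, TE-independent phase
residue that FDM removes by construction.

The corpus callosum mask is split into anterior / mid / posterior thirds
along its principal axis: pixel coordinates are projected onto the leading
eigenvector of their covariance, quantized at pixel resolution, and the
distinct positions are divided into three contiguous runs of equal count,
remainder positions going to the anterior bin. Magnitude and FDM values are
averaged per segment per echo; the magnitude curve is normalized to its
first echo.

## The fit

The three-pool model is fitted to each segment's joint (magnitude, FDM)
curve by bounded trust-region least squares (`scipy.optimize.least_squares`,
TRF), minimizing

    Σ_n (mag_n − |S|_n/|S|₁)² + λ Σ_n ((fdm_n − fdm_model_n)/s_hz)²

with λ = 1 and s_hz = 1 Hz by default (the two blocks are of comparable
scale for callosal curves; the weighting is exposed in `FitConfig`).
Initial values and bounds are the literature-standard relaxometry ranges:
fractions start at 0.5 in [0, 1]; `ω_a/2π` starts at −8 Hz in [−30, 0];
`ω_m/2π` starts at 30 Hz in [0, 50]; `R2*_m` starts at 150 in [50, 300]
1/s; `R2*_e` starts at 25 in [0, 100] 1/s. `R2*_a` is held fixed at zero:
with a maximum TE near 31 ms the slow intra-axonal decay is not
identifiable, and freeing it mainly inflates variance. The cost of the
constraint is quantified by `r2a_constraint_bias`: for a true
`R2*_a` = 10 1/s the constrained fit under-estimates `f_a` by ~0.20 and
over-estimates `f_e` by ~0.21, while the `f_m` bias stays below 0.01 — the
myelin fraction is robust to the constraint, the intra/extra split is not.

**Fraction identifiability.** The objective is exactly invariant to a
common rescaling of `(f_m, f_a, f_e)`: the magnitude curve is normalized to
its own first echo and FDM depends only on phase. Only relative fractions
are identified, so `FitResult` reports fractions rescaled to unit sum —
the convention the generating model uses, and the scale on which published
fraction estimates in this field live — with the solver's raw fraction sum
retained as a diagnostic.

Optional multi-start (off by default, the single literature start is used)
pre-screens a seeded pool of 16 candidates per extra start by objective
value and polishes the best few; the frequency directions of the objective
are multimodal and this raises noiseless round-trip recovery across the
full bound box from ~92% to ~99% of draws. Ties between starts break toward
the lower residual, then the lower `f_m`. Non-convergence is reported in
`FitResult.converged`, never raised.

## Synthetic data

The generator emulates the acquisition the analysis was designed for: a
single mid-sagittal 5 mm slice, 256 × 256 grid at 1 × 1 mm², 25 bipolar
echoes with TE₁/ΔTE/TR = 1.62/1.23/100 ms, 20 repeats with read polarity
inverted half-way (repeats are averaged within each polarity group at
generation time), multi-channel reception (4 channels by default — enough
to exercise the combination logic; the study protocol's 32 channels enter
through the ROI-level SNR, below), smooth polynomial background field and
RF phase maps, an eddy-current phase offset alternating with echo parity
and inverting with read polarity, and complex Gaussian noise per channel
and repeat.

The phantom's corpus callosum is a half-ellipse arc band labelled into
thirds of equal anterior–posterior extent. Segment tissue parameters
default to the reproducibility-study segment means (`f_m` 0.15/0.15/0.16,
`ω_a/2π` −8.5/−7.9/−8.5 Hz, `ω_m/2π` 31.4/27.1/27.3 Hz for
anterior/mid/posterior), with small between-pixel variation and fractions
renormalized to sum to one per pixel. Non-CC tissue is mono-exponential
(zero FDM), giving the spatial detrend a clean null reference. Every
nuisance is stored with the output, so tests can divide it out and recover
the clean signal exactly.

Study-level simulation works at the ROI-curve level (the image chain is
exercised separately; running it per subject × visit would add nothing but
time): per subject, segment and visit the generator draws true tissue
parameters, synthesizes the complex ROI curve, adds complex noise at the
ROI SNR, and runs the same FDM + fit path as the data. Key defaults and
their reasoning:

* cohorts: 19 gene carriers / 21 controls, one visit, for the group
  analysis; 6 subjects × 5 visits for reproducibility; ages uniform 21–71;
  CAG repeats uniform on 37–45;
* group effect on `f_m`: −0.04 at the mean age with a flatter age slope in
  carriers (−0.0002 vs −0.0008 per year), between-subject SD 0.015 — a
  clearly detectable but not overwhelming effect at n = 40;
* no group effect on `Δω`; age slope +0.05 Hz/year;
* between-visit SDs per segment are the reproducibility study's observed
  across-visit SDs (`f_m`: 0.08/0.04/0.02; `ω_a`: 2.0/1.1/0.6 Hz; `ω_m`:
  10.2/4.4/2.1 Hz anterior/mid/posterior) — these produce the
  posterior < mid < anterior CV gradient by construction. They are *total*
  across-visit variability, so measurement noise must stay subdominant:
  with pixel SNR ~20 per repeat and channel, 20 repeats, 32 channels and
  ~400 pixels per segment, the ROI-curve SNR is ~7000, at which the fit
  contributes ~0.006 SD to `f_m` — small against 0.02. `roi_snr = 7000`
  is therefore the default;
* a synthetic scalar "executive score" stands in for the first principal
  component of a cognitive battery: intercept 5, group offset +1.9, age
  slope 0.004/year, group × age interaction −0.06/year, noise SD 1, plus a
  coupling of 30 × the subject's `f_m` deviation so that myelin–cognition
  correlations exist to exercise the correlation machinery.

What the generator does **not** emulate: in-flow artifacts from the
anterior cerebral artery (the physical cause of anterior irreproducibility
in vivo — here the anterior segment is simply assigned the larger visit
noise), k-space effects, motion, through-slice dephasing, iron
contributions to susceptibility, and real cognitive scores. Passing tests
therefore demonstrate that the *pipeline* recovers what it models, not that
the biological interpretation of `f_m` is correct.

## Reproducibility statistics

Curve similarity across visits uses the discrete Fréchet distance on
(TE in ms, FDM in Hz) point sequences, computed by the standard dynamic
program over monotone couplings; axis weights are configurable and default
to none. Parameter repeatability uses the coefficient of variation with
sample (n−1) SD; the per-segment summary is the mean of per-subject CVs
(the CV of pooled values is available via `pooled=True`). For metrics with
negative means (`ω_a`) comparisons use |CV|.

Equality of CVs across the three segments is tested with the modified
signed-likelihood ratio test for k coefficients of variation under a
normal model: the profile likelihood over a common CV is maximized by
alternating closed-form updates (the per-group mean solves
`n τ² μ² + T μ − SS = 0` for fixed τ; the common τ² is the pooled
normalized residual variance for fixed means), and the likelihood-ratio
statistic is moment-corrected against `n_sim = 2000` parametric
simulations under the fitted null so that its mean and variance match the
chi-square reference with k − 1 degrees of freedom. Groups with negative
sample means are sign-flipped first. Measured calibration: type-I error
0.046 at α = 0.05 for k = 3 groups of n = 6 (2000 simulations), and
agreement with the uncorrected large-sample LRT p-value to < 0.01 at
n = 500 per group.

## Group statistics

The group analysis is ordinary least squares of the outcome on a group
indicator (0 = control, 1 = carrier), age, and their product. Age is
uncentered by default, matching the convention the effect sizes were
reported under; `center_age=True` re-expresses the group coefficient as the
difference at the mean age (used by the replicate studies, where the
mid-cohort difference is the quantity of interest — with uncentered age the
"group" coefficient is an extrapolation to age 0). Disease burden is
`DBS = age × (CAG − 35.5)`. Brain–behaviour associations use Spearman's
rho; partial correlation controlling for age is the Spearman correlation of
the residuals of rank(x) and rank(y) each regressed on rank(age) (the
paper-trail for which partial-correlation variant to use is thin; the rank
residual form is the natural Spearman analogue). A degenerate case is
handled explicitly: if residualizing removes all variation the partial
correlation is reported as 0 with p = 1. Multiple-comparison control is
Bonferroni over the declared family (default: the two correlations of the
`f_m` × {executive score, DBS} family).

One calibration note: in a conjunction of "significant effect A" and
"non-significant effect B" where B is a true null tested at α = 0.05, the
per-replicate probability of showing the full pattern is bounded above by
0.95; over 100 replicates the expected pattern count is ~93–94 even with
perfect power elsewhere. The acceptance suite reports the component rates
alongside the joint rate for this reason.

## Problem sizes and numerical choices

Defaults keep every analysis on a laptop scale: the image chain runs one
256 × 256 slice (tests use 96 × 96 with a proportionally smaller arc);
study replicates fit 130 ROI curves each; solver tolerances are 1e−12
(xtol/ftol/gtol) with at most 5000 function evaluations; the detrend design
is pre-factorized once per mask; MSLRT inner simulation is vectorized over
replicates. All randomness flows from explicit seeds through
`numpy.random.default_rng` / `SeedSequence`; identical seeds give
bit-identical outputs, including byte-identical CSV artifacts from the
pipeline.

## Known limitations

* Only relative signal fractions are identifiable; comparisons with
  absolute-fraction conventions require care.
* FDM amplitudes are operator-convention dependent (two-point anchor).
* The MSLRT assumes normal within-group data; fitted parameters are only
  approximately normal across visits.
* The synthetic executive score is a stand-in scalar, not a PCA of real
  cognitive data; correlation magnitudes involving it are illustrative.
* The anterior-segment irreproducibility is emulated by inflated visit
  noise, not by a physical artifact model.
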