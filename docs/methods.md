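# Methods

## The statistical model

Each analysed trial contributes one time–frequency image per temporal-pole
electrode (two hemispheres), so a full dataset of P participants with T
artifact-free trials each yields N = 2·P·T observation images. These enter
a single fixed-effects GLM with cell-means coding over the eight cells of
stimulus type (eyes/mosaic) × stimulus direction (averted/straight) ×
hemisphere (left/right); participant is not a factor — the error is pooled
over all trials of all participants, so inference generalizes to trials,
not to a population of participants. First- and second-presentation
responses are analysed separately: second-presentation epochs are re-locked
to the second-stimulus onset (+500 ms) and use their own −200…0 ms
baseline, with the direction factor taken from the second stimulus.

Errors are not i.i.d.: trial-wise log power has condition-dependent
variance, and the two hemisphere observations from the same trial covary.
The error covariance is modelled as V = Σᵢ λᵢQᵢ with nine components —
one variance per design cell and one dependence component with unit
entries linking the two observations of each trial. The hyperparameters
are estimated by restricted maximum likelihood (Fisher scoring on the
restricted log-likelihood), pooled over a pixel subsample of the in-mask
image (one V for the whole image, per the usual mass-univariate
convention; per-pixel residual variance carries the scale, so V is
normalized to tr V = N). Because every component is block-diagonal over
trials with 2×2 blocks, all ReML traces are computed block-wise; no step
exceeds O(N) and a paper-scale design (N = 2016) converges in tens of
milliseconds. Data and design are whitened by W = V^(−1/2) and fitted by
per-pixel OLS; since the whitened covariance is the identity by
construction, the Satterthwaite effective df equals N − rank(X). A dense
`satterthwaite_df(X, V)` helper is kept for unwhitened cross-checks (it is
strictly decreasing in variance heterogeneity, as verified in tests).

Contrasts are T-type over cell means: the main effect of stimulus type and
the two- and three-way interactions involving it, one-sided positive by
default. The type × hemisphere interaction is inclusively masked by the
positive main effect of stimulus type at p < 0.05 uncorrected (the masking
threshold is configurable; no value is standard). The explicit search
region is 0–500 ms × 4–300 Hz.

## Wavelet decomposition

Complex Morlet kernels with n = 7 cycles, σ_t = n/(2πf), truncated at
±5σ_t and normalized to unit L2 norm (Σ|w|²Δt = 1); convolution by FFT
multiplication with zero padding (edge samples are later discarded by the
−200…500 ms crop). Optional integer time decimation is exact: the product
spectrum is alias-folded before the inverse FFT, returning precisely every
d-th sample of the full convolution (verified against the undecimated
path to 1e-9). The frequency grid is linear, 4–300 Hz, step configurable
(1 Hz native). Single-trial maps are log-transformed and corrected by the
log of the trial's own mean baseline power per frequency (log power
ratio, natural log). Note that the grand mean of single-trial log-ratio
maps is not zero even for stationary noise (Jensen's inequality gives a
constant ≈ −γ offset for exponentially distributed power); the offset is
identical across conditions and cancels in every contrast, so only
post-vs-baseline and between-condition differences are meaningful.

## Cluster-level inference

Suprathreshold clusters (height p < 0.001 under t with the effective df;
8-connectivity, 4 optional) receive FWE-corrected p-values from the
T-field expected Euler characteristic densities ρ_d(u) for d ≤ 2, with
Em = ΣR_d ρ_d(u), expected cluster size En = ρ₀/ρ_D resels, extent
survivor exp(−βk^(2/D)), β = (Γ(D/2+1)/En)^(2/D), and the Poisson
clumping heuristic 1 − exp(−Em·P(extent ≥ k)).

Smoothness is estimated from the spatial gradients of unit-normalized
standardized GLM residuals (a subsample of 64 residual images; they are
re-standardized within the subsample). Wavelet decompositions make
smoothness strongly nonstationary — temporal FWHM ∝ 1/f, spectral FWHM ∝
f — and a global FWHM badly mis-calibrates cluster extents (measured null
FWE ≈ 0.10 at nominal 0.05). We therefore apply the standard
resels-per-voxel correction: the local resel density
rpv = Π_d √(λ_d/4ln2) is computed per pixel (clamped at 1 resel/pixel), a
cluster's extent in resels is the sum of rpv over its pixels, and the
top-dimension resel count is the rpv sum over the search region. On a
linear frequency grid the product of the two wavelet FWHMs is constant in
pixels (the 1/f and f dependences cancel), which keeps the resel density
well estimated; measured null FWE is ≈ 0.04 under the study design. The
stationary (global-FWHM) path is retained for externally smoothed fields
and verified separately on Gaussian nulls.

Grid resolution is a validity parameter: RFT needs FWHM ≳ 2–3 pixels. At
8 ms × 8 Hz the wavelet smoothness stays near or above 2 pixels per
dimension over most of the plane; the simulation batches (calibration,
recovery, permutation comparison) use this resolution, with 4 ms for the
permutation comparison's smaller design. The native 1 ms × 1 Hz grid is
the default for single-dataset analyses.

The permutation oracle permutes trial-level (type, direction) labels
within participant (hemisphere stays attached to its channel), refits the
OLS cell-means model per permutation, and ranks observed cluster pixel
counts in the permutation null of the maximum extent with
p = (1 + #{null ≥ k})/(n_perm + 1). The ≥ convention is kept even in
degenerate cases (identity-only permutation ⇒ p = 1): with tied integer
extents a strict inequality would be anti-conservative.

## Synthetic data

The generator emulates the paradigm's statistics, not its biophysics:

- **Design** — 7 + 7 model identities × 3 repetitions × 4 condition
  sequences (each type shown averted→straight and straight→averted) + 15
  target trials = 183 trials/participant, uniformly shuffled; ITI uniform
  on 2–5 s; fixation 500 ms, first stimulus 500 ms, second 1000 ms.
  Mirror-image stimuli are not distinct entries ("averted" collapses
  left/right) and breaks every 45 trials are metadata only.
- **Background** — Gaussian noise spectrally shaped to S(f) ∝ 1/f^α
  (α = 1 default), SD 30 μV, scaled analytically so the marginal SD is
  exact in expectation; optional line noise.
- **Induced bursts** — Gaussian-envelope carriers (defaults: 226 ms,
  121 Hz, 22 ms FWHM envelope, 40 Hz FWHM carrier jitter) with a uniform
  random phase per trial, so they raise trial-wise power without
  surviving the ERP average; amplitude jitter CV 0.2 (the real
  inter-trial variability structure is unknown; this is a free
  parameter). `burst_amplitude_for_log_effect` calibrates the amplitude so
  that ln((P₀ + gA²)/P₀) equals a target log-power effect at the locus,
  with P₀ the background Morlet power there and g the deterministic
  wavelet gain of a unit burst; the realized mean log effect is slightly
  smaller (concavity of the log).
- **Evoked components** — fixed-latency, fixed-polarity Gaussian
  deflections for exercising the ERP arm.
- **Artifacts** — additive transient spikes of configurable peak for
  exercising the ±800 μV rule.

What the generator does *not* emulate: dipolar forward models,
inter-electrode spatial correlation beyond the single shared-trial
dependence term, non-Gaussian background, heavy-tailed artifacts, or
drifting line noise. Passing calibration here shows the inferential
machinery is correct under the modelled statistics, not that real iEEG
satisfies them.

Participant schedules share one label sequence per dataset (epoched
analyses are order-blind); noise and phases are independent per
participant via seed-sequence spawning, and every stage is bit-reproducible
from its seed.

## Preprocessing decisions

The distributional rejection rule compares each trial's peak absolute
amplitude per electrode against its across-trial distribution, rejecting
beyond center + 5 SD with *both* mean and median centers (strictest
reading of "mean or median"); it runs once on the survivors of the
±800 μV rule, a degenerate SD = 0 rejects nothing, and a trial flagged on
any channel is dropped whole so hemisphere pairs stay intact.

## Sizes used by the shipped batches

Calibration and recovery run at paper scale (6 participants × 168
analysed trials × 2 electrodes = 2016 observations): 200 null datasets for
FWE calibration and 50 burst datasets for recovery in the test suite (60
and 15 in the acceptance script), both at 8 Hz × 8 Hz × 8 ms; the
RFT-vs-permutation comparison uses a 2-participant, 16-trials-per-sequence
design with the burst calibrated to a peak T near 5 — comparable to
strong real-data effects — since agreement between two inference methods
is only informative away from the detection boundary.

## Known limitations

- Fixed-effects pooling: conclusions apply to these trials/participants;
  no random-effects generalization.
- RFT validity degrades below ~2 pixels FWHM; very coarse grids
  (≥16 ms/16 Hz steps) push small clusters outside the theory and are not
  used for inference in the shipped configurations.
- The cluster tables report cluster-level inference only (no peak- or
  set-level p-values); F-contrasts are out of scope.
- The second-presentation crop (−200…500 ms around the +500 ms onset)
  approaches the epoch end at the lowest frequencies; the 4–8 Hz band of
  the second analysis carries mild edge attenuation, as it does in any
  pipeline with this epoch length.
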