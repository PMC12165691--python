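# Methods

This note documents the models, estimators and numerical choices behind
`alphaprf`, the assumptions they rest on, and what the synthetic validation
does and does not establish about real recordings.

## Signal model and decomposition

The pipeline treats a visual-cortex field potential as a superposition of a
broadband (aperiodic) process with a 1/f-like spectrum, a narrowband alpha
rhythm, a phase-locked evoked potential, and nuisance components (line
noise, an occasional beta rhythm). Visual stimulation multiplies broadband
power by a factor that follows a positive Difference-of-Gaussians (DoG)
spatial profile over the stimulus aperture, and multiplies alpha power by a
factor below one that follows a second, larger DoG profile at a similar
center.

Because the broadband elevation extends through the alpha band, raw
alpha-band power confounds the two effects; the stimulus/blank spectral
ratio over 3–26 Hz is therefore decomposed in log-power/log-frequency
coordinates into a linear broadband term and a Gaussian at the alpha peak:

    log10(P_S/P_B)(k) = (β_bb_low − n (k − μ)) + β_alpha G(k | μ, σ)

with `10^μ` bounded to 8–13 Hz. The fit is bounded least squares
(trust-region reflective) with a multi-start grid over (μ, σ); the
electrode-level fit uses the geometric-mean stimulus spectrum over all
aperture steps, and per-trial fits then constrain μ to the electrode peak
±1 Hz. An optional second Gaussian with `10^μ₂` in 15–30 Hz (fit range
extended to 3–32 Hz) absorbs a beta bump as a nuisance term.

Key parameter choices:

- **σ ∈ [0.01, 0.2] log10-Hz.** The upper bound keeps the Gaussian from
  absorbing the broadband shift; it also accommodates the substantial
  spectral smearing introduced by 200 ms analysis windows (below).
- **Slope n free in [−2, 3]**, anchored at μ so the broadband term and the
  Gaussian share a reference frequency; μ co-varies during optimization.
- **Per-trial fits in the pipeline use a windowed shape**: trial σ may move
  within ±30% of the electrode-level value (μ within ±1 Hz). A fully free
  per-trial shape is noisy — one trial barely constrains the bump width —
  while a fully pinned shape is biased, because the *measured* bump narrows
  as suppression deepens (the alpha peak only dominates the ratio where its
  power still exceeds the broadband floor). The ±30% window balances the
  two; the free and fully-pinned variants remain available on
  `decompose_trial`.
- **High-band broadband power** is the ratio of geometric means over
  70–180 Hz, excluding line-harmonic bands by recording-site convention
  (116–125 & 176–180 Hz for 60 Hz mains; 96–105 & 146–155 Hz for 50 Hz).
  Its frequency range is disjoint from the decomposition band, so alpha and
  broadband summaries are independent measurements.

## Spectra

Power spectra are computed on the 0–500 ms stimulus window of each epoch by
Welch's method with 200 ms Hann windows at 50% overlap, each segment
zero-padded to one second so estimates land on an exact 1 Hz grid
(1–250 Hz). Consequences worth knowing:

- Bins are correlated (the window bandwidth exceeds the bin spacing), and a
  pure tone spreads over roughly ±5 Hz. All downstream statistics are
  ratios or averages over bands wider than the mainlobe, so this smearing
  costs resolution, not validity — but it does limit the precision of the
  electrode-level alpha-peak estimate to roughly ±1.5 Hz on synthetic data.
- Density normalization is used; every downstream quantity is a ratio, so
  the normalization convention cancels.
- The blank baseline `P_B` is the per-frequency geometric mean over blank
  epochs; repeated runs are combined as per-trial geometric means, matching
  the log-domain model.

## Preprocessing

Epochs span [−0.2, 0.8) s around each step onset (exactly 512 samples at
512 Hz; the onset sample is index 102) and are baseline-corrected by the
pre-stimulus mean. Evoked potentials are estimated separately for stimulus
and blank epochs and removed from each epoch by scalar least-squares
projection (plain subtraction is exposed as an option); with strong
infra-slow noise the fitted amplitude is itself noisy, which injects a
small per-epoch perturbation — the projection still guarantees residual
power never exceeds the original.

Artifact exclusion follows a two-step rule: per electrode, the maxima of
squared voltage over 0–500 ms of non-blank epochs are fitted with an
inverse Gaussian by closed-form maximum likelihood (mean from the sample
mean, shape from the mean reciprocal difference — deterministic, no
optimizer), the evoked average is projected out of every epoch, and any
epoch whose residual peak power lies in the upper 0.01% tail is dropped.
The fit uses pre-removal maxima and the test post-removal residuals — an
intentional asymmetry, implemented as described. A caveat found during
validation: a single epoch carrying a large fraction of total power (a
~100× amplitude outlier among a few hundred epochs) can dominate the evoked
average and the tail fit simultaneously and escape exclusion; at realistic
corpus sizes and outlier magnitudes (~10×) the rule works as intended.
Electrodes whose across-trial variance exceeds the across-electrode mean by
three standard deviations are flagged; the rule is invariant to common
rescaling. A cross-correlation lag estimator (maximum of |xcorr|, bootstrap
CI over electrode pairs) aligns recording sites with a clock offset.

## pRF model and fitting

The pRF is a circular Gaussian center with an infinite surround,
`PRF = g1 G(x, y, σ) − g2`; the predicted response to an aperture is the
mask–pRF dot product. Both the per-trial summary series (224 points) and
the binary aperture sequence are low-passed with a zero-phase Chebyshev-I
order-3 filter (cutoff 0.8 × Nyquist / 3) and decimated to 75 points; the
odd filter order makes the DC gain exactly one. Summary series are log10
power ratios normalized to the mean blank value, so blanks sit near zero
and exponentiation recovers ratio units.

Fitting is bounded nonlinear least squares (|x|, |y| ≤ 16.6°, σ ∈ [0.1,
25]°, gains ≥ 0) seeded by a coarse (x, y, σ) lattice at which the two
gains are solved in closed form — a cheap, deterministic multi-start that
removes the local-minimum risk of a single solver call. For fitting, the
aperture masks are block-summed 2× spatially (50×50); the dot product is
preserved up to the Gaussian's within-block variation (~0.1% parameter
error) at a quarter of the cost. Accuracy is the uncentered R²
(denominator Σ data², no mean subtraction), reported as printed — it can be
negative. Cross-validation splits the 75 points into first 38 / last 37;
the sweep order (horizontal, vertical, four diagonals, reversed vertical,
reversed horizontal) guarantees each half contains one full horizontal and
one full vertical sweep, the second half in reversed direction. Alpha
series are fitted on the negated convention (negative center, positive
surround); an unconstrained-gain mode exists for the no-correction control,
whose fitted gains come out with mixed signs on synthetic cohorts — the
signature of the confound the decomposition removes.

## Selection and cohort statistics

Accuracy thresholds come from a shuffle null: each electrode's summary
series is scored (uncentered R², no refit) against the pRF predictions
fitted to other electrodes (derangements, so an electrode never meets its
own prediction), and the 95th percentile of the pooled scores is the
threshold. Electrodes are kept when both signals strictly exceed their
thresholds and both centers lie within the 8.3° stimulus extent. On
pure-noise electrodes the procedure admits ≈5%, as designed. pRF pairs are
compared by exact circle–circle overlap at 1σ, a normalized frame that puts
the broadband center at (0, 1), shuffled re-pairing controls, bootstraps
with probabilistic visual-area assignment (68% ellipses via the χ²(2 dof)
scaling of the covariance; polar angles wrapped, circular correlation), and
bootstrapped size–eccentricity regressions with 16–84% bands.

## Coherence

Cross- and auto-spectra use 500 ms Hann windows at 75% overlap over the
full −200–800 ms epoch, after ERP regression (so coherence cannot reflect
shared stimulus-locked responses). The magnitude-squared coherence
`|P_xy|²/(P_x P_y)` is formed per trial and run *after* Welch-averaging the
windows within the epoch — with a single un-averaged window the ratio is
identically one — and then averaged across runs. The estimator's bias floor
for independent signals is roughly one over the number of effectively
independent windows; with five 75%-overlapping windows per epoch the
measured floor is ~0.3, and for narrowband signals (coherence time
comparable to the epoch) the floor at the alpha bin is higher still. This
floor, not zero, is the baseline `b` that the distance-decay fit
`a exp(−d/λ) + b` converges to. Pairs are binned at multiples of 3 mm
(`round(d/3)·3`); the decay fit bootstraps pairs with replacement and
reports median parameters, flagging λ as unidentifiable when the amplitude
is negligible or λ exceeds twice the sampled distance span.

## Synthetic data: what it emulates, and what it does not

The generator writes continuous voltage per electrode and run: 1/f^χ
Gaussian noise (χ = 1.5, high-passed at 0.16 Hz like a clinical
acquisition chain — without this the diverging infra-slow drift dominates),
a narrowband alpha process (Gaussian spectral profile), an exponentially
damped 10 Hz evoked template at stimulus onsets, and optional line noise
and beta bump. Stimulus steps multiply broadband amplitude by
`10^(r_bb/2)` and alpha amplitude by `10^(−r_α/2)` during the 500 ms
stimulus-on period, where `r` are the DoG responses to that step's
aperture. The grid simulator mixes per-electrode alpha sources with weights
`exp(−d/L)` (rows normalized to preserve RMS) while broadband noise stays
independent.

Default study conditions for the validation cohort, chosen to land in the
regime the method is designed for (each matters, and the reasoning is
recorded here because the conclusions depend on it):

- **Alpha bandwidth 2 Hz.** Real occipital alpha peaks are a few Hz wide. A
  1 Hz line would leave each 500 ms trial with roughly one independent
  amplitude sample, and that trial-power noise — not the fitting machinery —
  then dominates pRF-size scatter.
- **Alpha RMS 0.55× broadband RMS**, putting the blank-spectrum alpha peak
  a few times above the 1/f background.
- **Broadband elevation 0.4 and alpha suppression 0.7 log10 units at the
  pRF center** (×2.5 up, ×5 down — within reported visual-cortex ranges).
  Jointly with the alpha prominence these make raw alpha-band power nearly
  cancel, which is precisely the published phenomenology and the reason a
  model-based estimate is needed; much weaker broadband responses make the
  no-correction control spuriously competitive, much stronger alpha makes
  the cancellation vanish.
- **Broadband pRF σ ∈ [0.8, 1.8]°, alpha σ = 2×, shared centers within 5°;
  six repeated runs** (sessions contribute 2–6 in this kind of experiment).

What passing the validation shows: the pipeline inverts its own generative
model — it recovers planted decomposition parameters to machine precision
without noise and to |Δβ_alpha| ≈ 0.03 median under realistic spectral
noise; detects suppression that band power cannot see; recovers pRF centers,
sizes and the alpha/broadband size ratio through the entire measurement
chain; and controls selection false positives. What it does not show: the
generator's broadband process is stationary within conditions, its alpha
rhythm is unimodal and spatially simple, there are no eye movements,
epileptiform transients, electrode drift or referencing artifacts, and the
alpha/broadband coupling is exactly multiplicative — real recordings can
violate any of these, so performance numbers here are upper bounds on what
identical analysis settings achieve on clinical data.

## Problem sizes

The validation suites run at desk scale by design: 40-electrode cohorts
with 6 runs for the end-to-end recovery, 40 pure-noise electrodes for the
null calibration, a 3×3 grid with 2 runs for coherence, 500 trials for the
noisy-decomposition check, and 5000-draw shuffle nulls (bootstrap loops in
unit tests use a few hundred draws). These sizes give stable percentages
while keeping the full validation in the minutes range on one CPU.

## Known limitations

- The alpha-peak frequency estimated from the stimulus/blank ratio carries
  ±1–2 Hz error because of the 200 ms-window smearing; the blank spectrum
  itself locates the peak more sharply.
- The artifact-exclusion rule's blind spot for single dominant outliers
  (above) is inherited from its design; a corpus-level outlier screen would
  catch it.
- The measured alpha-suppression profile is a mildly saturating transform
  of the true one (the alpha bin's floor is the broadband power), biasing
  fitted alpha pRF sizes by roughly −5% in the noiseless limit; no
  correction is applied.
- DoG size estimates for pRFs approaching the stimulus radius are weakly
  identified (σ trades against the surround offset); fits can escape to the
  σ bound on noisy electrodes, which the selection stage usually removes.
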