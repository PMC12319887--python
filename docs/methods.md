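# Methods

`dyadcoh` implements a complete analysis chain for dual-participant
(mother–child) continuous-wave fNIRS hyperscanning: raw two-wavelength
intensities → haemoglobin concentration changes → wavelet transform
coherence (WTC) between the partners → surrogate-based and mixed-model
statistics.  Because the kind of data it targets is typically available only
on request, the package ships a synthetic dyad generator with known ground
truth; every downstream stage is validated against that ground truth.

## The measurement model

Continuous-wave fNIRS resolves *changes* in oxy- and deoxyhaemoglobin
(ΔHbO₂, ΔHbR) from optical-density changes at two wavelengths via the
modified Beer–Lambert law

    ΔOD_λ(t) = (ε_HbO₂,λ ΔHbO₂(t) + ε_HbR,λ ΔHbR(t)) · d · DPF_λ ,

with `d` the source–detector separation and `DPF_λ` the differential
pathlength factor.  Defaults: tabulated molar extinction coefficients at
760/850 nm (HbO₂: 586, 1058; HbR: 1548.52, 691.32 cm⁻¹·M⁻¹), DPFs of
(5.4, 4.7) for children and (6.0, 6.0) for mothers.  The package assigns the
larger child DPF to 760 nm because pathlength decreases with wavelength; the
pairing is a configuration default (`DpfTable`) and can be overridden.
Absolute baselines are unidentified (a continuous-wave limitation); all
concentration tracks are mean-referenced, and the forward/inverse maps are
exact inverses only up to a per-channel constant.

## Preprocessing

The chain follows the standard order and records provenance flags so the
order is assertable: optical density (−ln(I/mean I)) → wavelet motion
correction → zero-phase band-pass (third-order Butterworth, 0.01–0.5 Hz,
applied forward–backward so coherence phase is undistorted; effective
amplitude response |H|²) → concentration conversion.

Motion correction uses a stationary (undecimated) db4 wavelet transform with
the decomposition depth chosen so the coarsest detail scale exceeds 10 s,
keeping the analysis band largely in the untouched approximation.  At each
detail level, coefficients outside `[Q1 − α·IQR, Q3 + α·IQR]` are zeroed
(α = 0.8 for children, 1.5 for mothers — children move more).  Two
implementation choices matter:

* the *stationary* transform is used rather than the decimated one because
  decimation makes coefficient envelopes of clean oscillations beat
  (shift-variance), which the quartile rule then misreads as outliers;
* the record is reflect-padded by the full coefficient support and a
  per-level guard zone excludes pad-junction transients from both the
  quartile estimate and the zeroing, so boundary responses are not treated
  as artifacts.  The cost is that artifacts inside the guard zones
  (≤ filter-support × 2^level samples at each end) are corrected only at
  finer levels.

## Wavelet transform coherence

The continuous wavelet transform uses the analytic Morlet wavelet (ω₀ = 6;
Fourier factor ≈ 1.033) computed by FFT with zero padding.  Squared
coherence is

    R²(s,t) = |S(W_xy/s)|² / ( S(|W_x|²/s) · S(|W_y|²/s) ),

with the smoothing operator S a Gaussian in time (σ = scale) followed by a
boxcar across scale (0.6 octave), the conventions of the widely used
cross-wavelet toolbox.  The auto-spectra are deliberately routed through the
same complex smoothing code path as the cross-spectrum so that self-coherence
is *exactly* 1 in floating point.  The scale grid runs from 2·dt at 12
voices per octave out to periods ≥ 64 s (covering 0.02 Hz); pipeline runs
restrict it to periods 6–90 s around the analysis band, with margin for the
cross-scale smoother.  The cone of influence uses the Morlet e-folding time
√2·s; per time sample the map records the lowest trustworthy frequency.

Band/condition reduction averages unweighted over scales whose equivalent
frequency lies in 0.02–0.10 Hz (endpoints inclusive), then over the samples
of each task epoch; rest epochs never contribute.  COI handling defaults to
`include` (the common practice in this literature); `exclude` drops
edge-contaminated cells and records the per-epoch sample count.  Trials are
kept as separate rows because trial number enters the statistical models.

Pairing is the Cartesian product of valid long channels (child × mother), or
of valid ROIs after averaging valid long channels within each region; short
channels and QC-failed channels never enter.  A ROI is valid with ≥ 2 valid
long channels.

## Superficial signal regression

The average of the valid short-separation channels forms one global
regressor per chromophore; each long channel is replaced by the OLS residual
of `y ~ 1 + regressor` over the whole recording.  Residuals are orthogonal
to the regressor, never gain energy, and the operation is idempotent.
Recordings without a valid short channel pass through with
`applied = False`, so cohorts can mix regressed and unregressed dyads, and
`ssr_applied` is available as a model covariate.  SSR operates on the
band-passed concentration signals (after preprocessing, before coherence).

## Pseudodyad surrogates

The null for "same task and environment, no coordinated interaction" phase-
scrambles only the mother's analysis-ready tracks: FFT, uniform random
phases on the positive-frequency bins, Hermitian symmetry restored (DC and
Nyquist kept real), inverse FFT.  The amplitude spectrum is preserved
exactly and the child's signal is untouched.  Per iteration, coherence is
computed and band/condition-averaged exactly as for true dyads; per-pair
ensembles record the per-iteration seeds (derived from a master seed via
`SeedSequence.spawn`) for exact replay.  Default 100 iterations; phases are
drawn independently per channel, with a `shared_phases` switch for a single
phase vector across channels.  The child's wavelet transforms are computed
once and cached across iterations.

## Statistics

Coherence tables are modelled with a linear mixed model with a random
intercept per dyad, fit by maximum likelihood (not REML) so likelihood-ratio
tests between nested fixed-effect structures are valid.  Model complexity
grows stepwise in a fixed candidate order (age, trial, data type, condition,
interactions); a term is retained iff its LRT reaches p < .05 against the
current best model.  Condition uses treatment coding with "individual" as
the reference, so collaboration coefficients are directly the contrasts of
interest.  Several optimisers are tried in sequence and fits with non-finite
likelihoods are rejected — variance components on the boundary otherwise
produce silently degenerate fits.

Post hoc contrasts are one-sided paired t-tests on within-dyad differences
(t = mean(d)/(sd(d)/√n), df = n − 1).  The "paired Welch" phrasing common in
this literature is internally inconsistent (the Welch correction applies to
unpaired unequal-variance samples); the paired t is the default and an
unpaired Welch option is provided.  Multiplicity is controlled with
Benjamini–Hochberg FDR.  The parental-stress questionnaire is scored as the
sum of 18 items on a 1–5 scale (range 18–90) with cohort-level outlier flags
at mean ± 2 SD, computed before modelling.

Inclusion rules: a dyad enters analysis iff each participant contributes at
least one valid ROI and at least two trials of every condition are present.

## The synthetic dyad generator

The generator emulates the acquisition: 25 Hz, 760/850 nm, 16 long channels
(25 mm child, 30 mm mother) in four ROIs plus two 10 mm short channels, and
the session timeline (rest-bracketed, randomly ordered task epochs).

*Cerebral coupling.*  Each dyad shares a band-limited (0.02–0.10 Hz)
Gaussian latent oscillation z(t).  During an epoch with coupling strength
c ∈ [0, 1], each partner's cerebral HbO₂ is √c·z + √(1−c)·(own independent
band-limited track), scaled to ~0.1 µM.  Cross-partner band coherence is
then ≈ c², monotone in c, and exactly at the surrogate floor for c = 0.
This additive-mixture mechanism replaces a phase-jitter formulation: the
mixture's coherence is analytically controlled, whereas mapping jitter
variance to a target coherence is indirect and harder to verify.  HbR is
−0.4 × HbO₂ plus independent band-limited noise.

*Extracerebral physiology.*  Cardiac (≈1.4–2.3 Hz, role-dependent) and
respiratory (≈0.3 Hz) quasi-sinusoids, Mayer-wave narrowband noise
(0.06–0.12 Hz), slower low-frequency-oscillation noise (0.015–0.08 Hz), and
low-pass drift, combined with relative weights (1.0, 0.6, 0.8, 1.0, 1.5)
and scaled so the extracerebral mixture is `extracerebral_gain` (default 10)
times the cortical amplitude.  A fraction `systemic_share` of each
oscillatory component is common to both partners — physiological rhythms
synchronise during interaction — which is exactly the in-band contaminant
that superficial regression removes.  Short channels carry the extracerebral
component *exactly* (assertable against ground truth); long channels add the
cerebral signal and white measurement noise.

*Artifacts.*  Poisson-timed (default 0.5/min) spikes (0.3–1 s, 5–15× signal
SD) and step baseline shifts (2–5× SD), added as a participant-global track
— a cap shift moves all channels together.

*What it does not emulate:* optode-specific coupling losses, heterogeneous
per-channel haemodynamics, task-evoked response shapes, spatially varying
scalp physiology, or behaviour.  Passing tests therefore demonstrate that
the pipeline recovers known coupling under realistic noise magnitudes and
spectra, not that it reproduces any particular empirical cohort.

## Simulation-study sizes

Cohort-level validation uses 20 dyads on a scaled montage (4 long + 2 short
channels, one long channel per ROI), 2 trials per condition (1280 s
sessions), coherence computed on concentrations decimated to 2.5 Hz (the
band of interest tops out at 0.10 Hz, a 12-fold margin below the new
Nyquist), and 40 scrambling iterations per pseudodyad ensemble (the package
default is 100).  The zero-coupling null check uses 10 replicate cohorts of
8 dyads with 12 iterations.  These are the package's simulation-study sizes,
chosen to keep each study in the minutes range on one core; the generator's
own defaults remain the full-cap acquisition values.

## Numerical notes and edge cases

* WTC values are clipped to [0, 1]; cells with zero smoothed power are 0.
* Coherence maps of identical inputs are exactly 1 (shared code path).
* Phase scrambling keeps the DC bin untouched and the Nyquist bin real, so
  means are preserved to rounding error and surrogates are real-valued.
* A zero-variance SSR regressor skips the regression for that chromophore
  and records β = 0; no valid short channel yields a pass-through with
  `applied = False`.
* Degenerate paired tests (zero-variance differences) raise instead of
  returning an arbitrary p-value.
* Epochs emptied by COI exclusion yield NaN means, recorded rather than
  fatal, and drop out of group averages.

## Known limitations

* Channel QC replaces the field's visual inspection with a thresholded
  automated proxy (cardiac-peak prominence in 1.0–2.5 Hz, saturation,
  artifact fraction); thresholds are conventions, recorded in the report's
  `method` field, not reproductions of any manual protocol.
* The IQR-threshold motion correction attenuates genuinely heavy-tailed
  narrowband signals, not only artifacts; with the child multiplier (0.8)
  this removes a noticeable share of in-band Gaussian power.  That is a
  property of the method itself, shared by its reference implementations.
* Partner-scrambled (dyad-shuffled) pseudodyads are intentionally out of
  scope; phase scrambling is the appropriate null for heterogeneous
  per-dyad timelines.
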