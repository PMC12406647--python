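# Methods

This note documents the models, algorithmic conventions and design
choices behind `fracatten`, in the spirit of a statistical software
methods appendix. It states no empirical claim that the test suite does
not itself compute.

## Detrended fluctuation analysis

For a series of length *N* (512 in the canonical configuration: 525
keypresses give 524 intervals, the first 12 are discarded as startup
transients), DFA proceeds as: subtract the series mean; cumulatively sum
to an integrated profile; for each window size *n*, tile the profile
into ⌊N/n⌋ non-overlapping windows starting at index 0, discarding the
tail remainder (a single forward pass — no reversed second pass);
detrend each window with an OLS line on the within-window index; take
each window's RMS residual and average these RMS values into *F(n)*
(mean of RMS, not RMS of the pooled residuals); finally regress
log *F(n)* on log *n* by OLS. Natural logarithms are used; the slope α
is base-invariant.

**Window ladder.** Sizes start at 4 and grow geometrically by a factor
of 1.2 on the *unrounded* value; each value is floored to an integer and
duplicates are dropped; growth stops once the unrounded value exceeds
*N*/10. For *N* = 512 this yields 4, 5, 6, 8, 9, 11, 14, 17, 20, 24, 29,
35, 42 (13 sizes). Applying the 10% cap to the floored value instead
would admit 51 (⌊51.36⌋ ≤ 51.2) and a 14-size ladder; the unrounded-cap
dialect is pinned because it reproduces the canonical 13-size list.

**Classification.** α < 0.5 anti-persistent; 0.5 ≤ α ≤ 1 persistent;
1 < α ≤ 1.2 "elevated" but still treated as stationary (the estimator
has a known positive bias on short series, so only α > 1.2 is flagged
nonstationary). Boundary values (exactly 0.5 or 1.0) go to the
higher-persistence bin — a documented convention, since windowed-mean
estimators make exact boundaries measure-zero events.

**Degenerate input.** A zero-variance series yields *F(n)* = 0 and an
undefined log; this raises `DegenerateSeriesError` rather than
returning a sentinel.

**Known bias.** With this exact algorithm (windows down to 4 samples,
ladder capped at *N*/10, mean-of-RMS), the estimator carries a positive
finite-size bias at *N* = 512: the mean α̂ over 100 generator draws is
approximately 0.39/0.56/0.75/0.94 for true H = 0.3/0.5/0.7/0.9, as the
acceptance suite measures. The bias is largest for anti-persistent
series and shrinks with persistence; it is a property of the canonical
small-window protocol, not of the generator (whose autocovariance is
exact, see below). No bias correction is applied, because the windowed
protocol itself is the object under study.

## Fractional Gaussian noise generator

fGn with Hurst parameter H ∈ (0, 1) is synthesized by exact circulant
(Davies–Harte) embedding: the autocovariance
γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) is embedded in a 2N
circulant whose DFT eigenvalues scale complex Gaussian spectral weights.
The construction is exact in distribution — the theoretical
autocovariance holds at every lag in expectation — making the generator
a valid oracle for the DFA estimator (for stationary fGn, the DFA
exponent equals H). If the embedding has materially negative eigenvalues
(possible at extreme H with short series) the generator raises rather
than truncating the spectrum. Requested exponents ≥ 1 are rejected:
they correspond to fBm-type nonstationary processes outside this
generator's family, and observed α > 1 values are treated as estimation
outcomes, never generation targets.

IKI series are an affine transform `mean + sd · fGn`; values below a
1 ms physical floor are clipped there with the count logged (zero
clipping at realistic parameters, e.g. mean 0.85 s, SD 0.16 s). Note
two estimator facts that tests account for: under long-range dependence
the SE of the sample mean is sd·n^{H−1} (not sd/√n), and the
mean-subtracted sample variance is biased low by ≈ n^{2H−2}.

## Shuffle-surrogate test

Uniform random permutation destroys sequential order while preserving
the value multiset — hence per-cell mean and SD exactly, which is the
point: any surviving condition effect on α cannot be an artifact of
marginal IKI differences. Per iteration, every series is independently
permuted, DFA recomputed (vectorized over all series at once), and the
2×3 within-subject ANOVA rerun. The uncorrected F is used inside the
loop, since F values (not p values) are compared. The equivalent p is
`count(F_surr ≥ F_obs) / n_shuffles` — ties count against the observed
effect, and the (k+1)/(n+1) convention is deliberately **not** used, so
1 exceedance in 500 gives exactly p = 0.002 and 19 give 0.038. A master
`SeedSequence` spawns one independent stream per iteration, making runs
reproducible and order-independent. Default 500 shuffles (100 at desk
scale).

## ERP simulation and analysis chain

Synthetic epochs are Σ components + noise, where each component is a
Gaussian bump in time (σ in ms) scaled by a per-channel topography and a
signed amplitude = polarity × (base + per-condition offset), and the
noise has a 1/f^1 amplitude spectrum normalized to a per-epoch RMS of
10 μV (a realistic single-trial EEG scale; effects of ~1 μV then demand
hundreds of trials, as in real studies). The default session carries an
N1-type bump (negative, 90 ms, σ 14 ms), a P2-type bump (positive,
160 ms, σ 22 ms), and a motor bump at −100 ms present only in keypress
conditions; motor-only cells carry no auditory components. Gaussian
shape is a free choice — windowed means near the bump center are
shape-insensitive, and the closed form for a bump's windowed mean is
exported for exact tests. What the generator does **not** emulate:
ocular/muscle artifacts, channel drift and bridging, trial-order
nonstationarities, and latency jitter across trials — so green tests
show the chain's arithmetic is right, not that it is robust to real
recording pathologies.

The analysis chain order is fixed: filter → rereference →
extract_epochs → baseline_correct → reject_epochs → drop_initial →
average_erp → motor_correct → collapsed_localizer → mean_amplitude.
Conventions:

- Filter: order-1 Butterworth band-pass (0.1–30 Hz) per edge, applied
  forward-backward (zero-phase, 12 dB/octave asymptotic), plus a
  bidirectional 50 Hz IIR notch (Q = 30). The contract is attenuation
  (in-band ±5%, notch ≤ 10%, DC removed), verified on synthetic
  sinusoids.
- Epochs: [−200, 400) ms half-open on the sampling grid; sample count =
  round(0.6·fs); events whose window leaves the recording are dropped
  and counted. The keypress marker sits at −100 ms in MA/MO epochs (the
  tone follows the keypress by 100 ms).
- Rejection: an epoch is removed iff any channel's peak-to-peak range
  *strictly* exceeds 200 μV ("exceeding" read literally; a range of
  exactly 200 μV is retained).
- Collapsed localizer: equal-weight average over all supplied condition
  ERPs, pooled over electrodes *first*, then the grid arg-extremum
  (minimum for N1, maximum for P2) inside the search range; ties break
  to the earliest latency; a boundary peak warns of truncation. Search
  ranges default to 50–150 ms (N1) and 120–220 ms (P2) — analysis
  defaults, not reported values.
- Windowed mean: 30 ms half-open window centered on the localized peak,
  electrode pool averaged before time averaging (order irrelevant on a
  fixed grid).

ICA-based artifact correction is out of scope: the threshold rule is
the only rejection implemented, and synthetic data contains no ocular
activity to clean.

## Statistical layer

**Within-subject ANOVA.** Classical univariate decomposition with
subject, A, B, A×B and the three subject-interaction error strata;
verified against an independent projection-matrix oracle and pingouin.
Greenhouse–Geisser ε comes from the doubly-centered covariance of the
per-subject condition scores (marginal means for main effects,
Kronecker-contrast scores for the interaction), bounded to
[1/(k−1), 1]; Mauchly's W uses the orthonormal-contrast covariance with
the standard chi-square approximation. Both corrected and uncorrected p
are always reported; the headline `p_reported` is GG-corrected only
when Mauchly p < 0.05. Degenerate strata (zero error SS in exactly
additive data) yield F = ∞ with p = 0, and partial η² is defined as 0
when both SS vanish.

**Contrasts.** Paired t with Cohen's d = mean(diff)/SD(diff) (consistent
with d = t/√n). BH adjustment is the exact step-up
(p·m/rank, min-accumulated from the largest p, capped at 1). The
step-up map is *not* idempotent — reapplying it to adjusted values can
only increase them — so families must be adjusted once, from raw p
values.

**Mixed model.** `y = Xβ + u_group + ε` with a single random intercept,
fitted by maximum likelihood with the likelihood profiled analytically
over β and σ²_e, leaving a 1-D bounded optimization over
λ = σ²_u/σ²_e (per-group Woodbury identities; cost linear in N). ML
rather than REML because BICs of models with different fixed effects
must be comparable for the Bayes-factor approximation. BIC counts
fixed effects plus both variance components, also at the λ = 0
boundary, where the fit returns var_u = 0 with a `boundary` flag
instead of raising. Fixed-effect inference is Wald
(normal-approximation CI and p); Satterthwaite degrees of freedom are
not implemented — at the linking scale (63 observations, 21 groups)
the difference is small but the p values here are mildly liberal
relative to df-adjusted software. ICC = σ²_u/(σ²_u + σ²_e).
BF₁₀ = exp((BIC_without-term − BIC_with-term)/2).

## Pipeline and problem sizes

Desk-scale defaults: 8 participants, 64 epochs per cell, 100 shuffles,
full 525-keypress bookkeeping (524 IKIs, 512 analyzed). A
`paper_scale` constructor switches to 21 participants, 525 epochs and
500 shuffles. All randomness descends from one seed through fixed
`SeedSequence` spawns, so identical configs reproduce every report
number bit for bit; the JSON report embeds its config, a config hash,
library versions, stage seeds and a schema version.

The test suite's heavier checks use sizes chosen as the smallest that
leave the assertions statistically meaningful: the surrogate null
calibration runs 200 datasets at 8 participants × 100 shuffles on
512-sample series (the nominal false-positive band 0.05 ± 0.04 follows
the discreteness of a 100-shuffle p, whose null exceedance probability
is 6/101 ≈ 0.059); the ERP recovery check uses 21 participants × 128
epochs per cell, where the Monte-Carlo SD of the recovered attenuation
is ≈ 0.13 μV and the assertion band of ±0.4 μV is ≈ 3 SD; the
mixed-model coverage check uses 500 replicates at the 63-observation
design.

## Known limitations

- DFA is the plain first-order variant: no multifractal extension, no
  unbiased-estimator variant, no higher-order detrending.
- The generator cannot produce α > 1 series; nonstationary behavior can
  only be *observed* (via estimates) on stationary inputs, not injected.
- The ERP front end reads arrays, CSV and HDF5; BDF/EDF ingestion is an
  extension point, not implemented.
- Surrogates are plain shuffles; phase-randomization/AAFT surrogates,
  which preserve the spectrum as well as the marginal, are out of scope.
- The LMM supports exactly one random intercept — no random slopes,
  crossed or nested structures.
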