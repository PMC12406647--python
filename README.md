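# fracatten

Analysis toolkit linking **fractal structure in action timing** to
**sensory attenuation of auditory ERP components**.

In the self-stimulation paradigm, participants press a key at a target
pace (a stimulus onset asynchrony, SOA, of 0.8, 1.6 or 3.2 s per press);
in the motor-auditory (MA) condition each press triggers a tone, in the
motor-only (MO) condition it does not, and in the auditory-visual (AV)
condition the same tone sequence is replayed passively. The package is
written for researchers who want to quantify, from such recordings (or
from its own synthetic stand-ins):

1. **How much timing control a participant exerts**, via detrended
   fluctuation analysis (DFA) of the inter-keypress-interval (IKI)
   series. DFA centers the series, integrates it, tiles the profile into
   non-overlapping windows of size *n* (a geometric ladder from 4 up to
   10% of the series length), detrends each window with an OLS line,
   averages the per-window RMS residuals into *F(n)*, and estimates the
   scaling exponent α as the slope of log *F(n)* against log *n*.
   α < 0.5 is anti-persistent, 0.5–1 persistent, > 1.2 treated as
   nonstationary.
2. **Whether α effects are order effects**, via a shuffle-surrogate
   control: every series is repeatedly permuted (preserving its mean and
   SD exactly), DFA and the 2 (production) × 3 (SOA) within-subject
   ANOVA are recomputed per shuffle, and an *equivalent p* per main
   effect is the fraction of surrogate *F* values at or above the
   observed *F*.
3. **How strongly the auditory response is attenuated**, via an ERP
   chain: band-pass + notch filtering, mastoid re-referencing, 600 ms
   epoching (−200 to 400 ms around sound onset), baseline correction,
   200 μV peak-to-peak rejection, removal of the first 13 epochs, trial
   averaging, motor correction (C-MA = MA − MO), collapsed-localizer
   window placement, and 30 ms windowed mean amplitudes for N1
   (Fz/FCz/Cz) and P2 (FCz/Cz/CPz).
4. **Whether timing control predicts attenuation**, via within-subject
   ANOVAs (Mauchly's test, Greenhouse–Geisser correction, partial η²),
   Benjamini–Hochberg-adjusted paired contrasts with Cohen's
   *d* = mean(diff)/SD(diff), a random-intercept linear mixed model
   (`P2_CMA ~ 1 + α_MA + P2_AV + IKI_MA + (1 | participant)`, fitted by
   profiled maximum likelihood) with its ICC, and the BIC approximation
   to the Bayes factor, BF₁₀ = exp(ΔBIC/2).

A synthetic-data module generates fractional Gaussian noise by exact
circulant embedding (so the target Hurst exponent is the ground truth
for DFA) and multichannel ERP epochs with known component amplitudes
over 1/f noise, giving every stage a testable oracle.

## Worked example

Simulate one persistent IKI series and estimate its exponent:

```bash
$ fracatten simulate iki --alpha 0.7 --mean 0.85 --sd 0.16 --n 512 --seed 3 --out iki.csv
wrote 512 intervals to iki.csv (clipped: 0)
$ fracatten dfa --in iki.csv --out dfa.csv
$ cat dfa.csv
participant,production,soa,alpha,r_squared,classification
sim,MA,0.8,0.7758374611409985,0.9910072099011119,persistent
```

The estimated α of 0.776 sits in the persistent band (long intervals
tend to follow long intervals), close to the 0.7 used to generate the
series; the log–log fit is nearly linear (R² = 0.991), as expected for
stationary fractional Gaussian noise.

A full synthetic run (8 participants, 64 epochs per condition cell, 100
shuffles — the desk-scale defaults):

```bash
$ fracatten run --seed 7 --out report.json
wrote report.json
P2 alpha term b = -1.969 (p = 0.4874), BF10 = 0.26
```

Inside `report.json`:

- the α ANOVA finds the SOA gradient the generator injects
  (targets 0.68/0.75/0.82): `soa: F = 23.06, p_reported = 0.0009,
  partial η² = 0.77`, and the surrogate control confirms it is an order
  effect (`equivalent_p: soa = 0.0, production = 0.35` at 100 shuffles);
- the collapsed localizer recovers the component latencies
  (N1 window centered at 90.0 ms, P2 at 159.4 ms);
- the P2 contrasts mirror the injected attenuation profile (0 μV at
  SOA 0.8, 1 μV at 1.6 and 3.2): `AV-1.6 vs C-MA-1.6: t = 2.97,
  p_adj = 0.031, d = 1.05`; `AV-3.2 vs C-MA-3.2: t = 4.97,
  p_adj = 0.005, d = 1.76`; the SOA-0.8 contrast is null (p = 0.952);
- the linking model reports the α slope with its Wald CI and the
  BIC Bayes factor for including the α term (here BF₁₀ = 0.26: the
  default generator ties attenuation to SOA, not to each individual's α,
  so the null is expected).

`--paper-scale` switches to 21 participants, 525 keypresses/epochs per
block and 500 shuffles.

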