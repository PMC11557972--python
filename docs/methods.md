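# Methods

## The scientific setting

Honey bee foragers show strong circadian sleep rhythms. Kept in cages under
a 12 h light : 12 h dark cycle (LD) they stay entrained at 24 h; under
constant dark (DD) or constant light (LL) the rhythm free-runs at its
intrinsic period, which in this species ranges roughly from 20 to 26 h.
Constant light — the caged analogue of artificial light at night — is
associated with a lengthening free-running period, loss of rhythm
amplitude, reduced late-trial sleep, more disturbance contacts from
non-sleeping nestmates, and a preference for sleeping in the dimmer lower
half of the cage. This package provides the full analysis chain for such
experiments: hourly ethogram tables in, period estimates, alignment
metrics, disruption summaries and group tests out, plus a generative
simulator so the whole chain is testable without any recorded colony data.

## Generative model (synth)

Each cage is an independent realisation of:

* **Sleep oscillation.** Expected proportion asleep
  `p(t) = baseline + A(t) cos(2*pi (t - phase0) / tau_eff(t))`, clipped to
  [0, 1]. `tau_eff` is constant per condition except under LL, where it
  lengthens by `drift_ll` hours per elapsed day; `A(t)` decays
  geometrically by `amplitude_decay` per day under the two free-running
  conditions (LL and DD) and stays at `amplitude0` under LD. Entrainment
  under LD is treated as instantaneous because foragers arrive
  pre-entrained to the natural photoperiod; `phase0` therefore locks the LD
  acrophase to the middle of the dark phase (hour 18 with lights on at
  hour 0).
* **Counts.** `n_sleeping ~ Binomial(n_alive, p(t))` per hour;
  `deaths ~ Binomial(n_alive, mortality_hazard)` per hour (applied after
  the scored window, so `n_alive` is non-increasing and dead bees never
  sleep); `contacts ~ Poisson(n_sleeping * rate)`, with the rate switching
  from `disturb_rate_base` to `disturb_rate_ll_late` under LL from
  `onset_hour` (default 90) onward;
  `n_sleeping_lower ~ Binomial(n_sleeping, p_lower)` with a higher
  lower-half probability under LL.
* **Seeding.** Each cage draws from
  `default_rng(master_seed + condition_stride + replicate - 1)` with a
  fixed stride per condition, so adding replicates or conditions never
  reshuffles existing cages, and identical seed + config is bit-identical.

Defaults (3 cages/condition, 23 bees, 120 h, taus 24.0/24.0/24.5 h for
LD/DD/LL, drift 0.25 h/day, baseline 0.45, amplitude 0.35, amplitude decay
0.10/day, hazard 0.002/bee/h, contact rates 0.31 and 1.09 per sleeper per
5-min window, lower-half probabilities 0.35 and 0.80) describe a typical
five-day caged-forager trial. The baseline/amplitude pair encodes the large
day-night sleep contrast of foragers — roughly 10% asleep at the daytime
trough against 80% at the nocturnal peak; the contact rates are the
reported light- and dark-treatment means. Periods outside 20-26 h are
accepted with a warning rather than rejected, since the range is empirical,
not logical.

What the simulator does **not** emulate: posture-level scoring (the three
sleep markers and the 30-s re-sleep rule define what a sleeping count
means, they are not simulated), within-cage correlation beyond the shared
`p(t)` (bees are conditionally independent), cohort effects between
replicates, spatial structure beyond the single lower-half probability, and
any feedback of disturbance on subsequent sleep. Passing tests therefore
demonstrate that the analysis chain recovers the structure this model puts
in; they cannot certify behaviour on colony data with, say, overdispersed
counts or socially synchronised arousal.

## Period estimation (rhythm)

For each candidate period P on a dense grid (20-28 h, 0.05 h steps) the
harmonic regression
`y(t) ~ b0 + b_s sin(2*pi t / P) + b_c cos(2*pi t / P)`
is fitted by least squares and tau is the candidate minimising the residual
sum of squares — the least-squares periodogram. The fitted amplitude is
`sqrt(b_s^2 + b_c^2)` and the acrophase `atan2(b_s, b_c) * tau / (2*pi)`,
reduced to [0, tau). An FFT is not used because 120 hourly samples put the
discrete Fourier bins at 30, 24, 20 h — far too coarse for the 20-26 h
free-running range.

Two numerical choices matter:

* **Ranking by residual, not amplitude.** On a finite record the candidate
  grid is not orthogonal: long candidate periods absorb trend-like variance
  through spectral leakage and report inflated amplitudes, so an
  amplitude-argmax rule is biased (measured at about -0.13 h median on
  simulated entrained cages). Minimising the RSS — equivalent to maximising
  explained variance, and identical to the amplitude rule in the
  orthogonal limit — is unbiased.
* **Sub-grid refinement.** A parabola through the RSS minimum and its two
  grid neighbours moves tau below the 0.05 h quantisation; the refinement
  is clamped to one grid step.

Exact ties in fit quality break toward the candidate nearest 24 h. A series
is flagged arrhythmic when the fitted amplitude falls below `k` times the
residual SD (default k = 1); a constant series gets NaN tau/phase sentinels
instead of an exception. Under the default simulation the estimator
recovers tau for entrained cages with a median absolute error near 0.07 h
(close to the information bound for this noise level) and free-running
periods across 20-26 h to well under 0.5 h.

## Alignment metrics (rhythm)

Each free-running cage is paired with the LD control cage of the same
replicate index; the difference curve is control minus condition per hour.
Day 4 — hours [72, 96) from onset — is the analysis window: by then period
drift has accumulated maximal phase divergence without diluting it across
the earlier, still-aligned days. Three numbers summarise a pair:

* signed trapezoidal AUC of the difference over the window;
* absolute AUC (the integrand in absolute value), which cannot be cancelled
  by sign changes and bounds the signed AUC from above;
* peak distance: each curve's windowed "midpoint peak" is the temporal
  midpoint of the longest contiguous run of hours at or above half of the
  windowed range above the minimum, after a centered 3-h moving average
  (ties between runs break toward higher mean height, then earlier time);
  the metric is the absolute difference of the two midpoints. The half-max
  run-midpoint is used because it is robust on plateaued curves where a
  pointwise argmax is not; flat windows give a NaN sentinel that
  propagates.

## Disruption analyses (disruption)

Restricted to hours >= 90, where the light/dark divergence in disturbance
is clear. The contact rate is per sleeping bee per scored 5-min window
(cells without sleepers contribute no rate observation), and the light/dark
fold ratio is the ratio of condition means. The vertical light gradient is
tested with a pooled-variance two-sample t-test (df = n1 + n2 - 2,
consistent with df 28 for 15 + 15 readings) and summarised as the
top/bottom fold ratio of means, which is invariant to rescaling all
readings. Position preference is the pooled proportion of sleepers in the
lower half per cage; its repeated-measures comparison between conditions is
delegated to the mixed model with response `prop_lower`.

## Group-level inference (stats)

* **Mixed models.** `response ~ treatment + time + treatment x time`, REML,
  random intercept for cage (cage identifiers are unique within treatment,
  so the intercept is equivalently nested within treatment). F statistics
  are Wald chi-square divided by the term's df; the denominator df is the
  residual approximation n_obs - n_fixed_coefficients, recorded in the
  method string (a Satterthwaite or Kenward-Roger correction would shrink
  df at small cage numbers; with hourly data the residual df is large and
  the difference is immaterial). Zero cage variance or non-convergence is
  reported via a `singular` flag, never an exception.
* **Wilcoxon rank-sum.** Two-sided. For combined n <= 12 the p-value is
  exact: every labeling of the pooled sample is enumerated and the
  deviation of the rank sum from its null mean compared with the observed
  one, which handles ties through midranks with no approximation. Above the
  cutover the tie-corrected, continuity-corrected normal approximation is
  used; the two paths agree within 0.02 at the cutover. The path taken is
  recorded in the result.
* **Kruskal-Wallis survival test.** Percent alive at the trial endpoint per
  cage (hour `t_end - 1` carries the final census), tie-corrected H,
  chi-square p with df = groups - 1.
* Two-sided tests throughout; no multiplicity correction is applied.

## Calibration design

Type-I-error checks of the interaction and survival tests run on a
dedicated null configuration (`null_calibration_config`): identical
generative parameters in every arm, the oscillation switched off, and 8
cages of 100 bees per condition. The oscillation must be off because the
shared circadian waveform is outside the treatment + linear-time mean
family; it inflates the residual variance identically in every arm and
makes the interaction test arbitrarily conservative — a property of the
model family, not of the implementation under test. The larger cage counts
and cage sizes are needed because at 3 cages of 23 bees the chi-square
reference for H and the heavy ties in percent-alive make the attainable
significance levels coarse and conservative. At the calibration sizes both
tests reject at 5% within binomial sampling bounds. Power is checked by
injecting a known arm-specific sleep-loss ramp (binomial thinning of LL
sleeping counts to 60% across the late window) into otherwise identical
arms, which the interaction test detects at p < 0.01 in >= 18/20 seeds.

## Problem sizes and determinism

The shipped test-suite and acceptance-script sizes — 50 cages for period
recovery, 50 experiments for the directional day-4 comparisons, 200 null
seeds for calibration — were chosen as the smallest designs at which the
binomial/KS-style tolerances used are meaningful. Every stochastic step
derives from an explicit seed; re-running the pipeline from its manifest
reproduces all CSV outputs byte-identically.

## Known limitations

* The mixed-model denominator df is a residual approximation; reported df
  will not match software using Satterthwaite/KR conventions at small n.
* The linear treatment x time interaction is nearly blind to pure phase
  misalignment (it projects an oscillatory difference onto a line); the
  alignment metrics, not the mixed model, are the instruments for period
  drift.
* The half-max midpoint peak is biased toward the window centre when a peak
  sits within half a run-width of the window edge.
* Fold ratios are reported without uncertainty; they summarise means, not
  sampling distributions.
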