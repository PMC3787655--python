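# Methods

## Model

Time allocation (TA) to lever-holding for brain stimulation reward is
modelled with a matching-law stage applied to the scalar payoff of the
experimenter-controlled reward relative to everything else the animal
could do. With reward intensity `U ∈ [0, 1]` and subjective price `SP`,

    TA = (TAmax − TAmin) · V^a / (V^a + 1) + TAmin,   V = U·SPe / SP,

where `a` is the payoff-sensitivity exponent, `TAmin` the floor set by
competing activities, `TAmax` the per-duration ceiling (motoric
side-effects can lower it at long train durations), and `SPe` the
subjective price at which a maximal reward yields halfway performance.
Reward intensity grows with the induced firing frequency as
`U = FF^g/(FF^g + FFhm^g)`.

Two fixed psychophysical transforms connect the controlled variables to
`FF` and `SP` (values from prior published estimates; they are *not*
fitted here): a softplus-saturation map from pulse frequency to induced
firing (bend 20.63 pps, transition midpoint 342.9 pps, plateau ≈ 343
spikes/s) and a softplus floor map from objective to subjective price
(floor 1.75 s, bend 0.57 s). Both are evaluated through the stabilised
identity `ln(1+e^x) = max(x,0) + ln(1+e^{−|x|})`; the printed forms
overflow for arguments a few hundred units above the bend. Their
inverses have no closed form and are solved by bracketed Brent root
finding to 1e−10; a firing demand at or above the plateau has no
preimage and is returned as a tagged "unreachable" value rather than an
exception, because that regime carries the dual-integrator mechanism.

The strength–duration law `FFhm(D) = FFhmR·(1 + C/D)` links the half-max
firing requirement to train duration through rheobase `FFhmR` and
chronaxie `C`.

### Dual-integrator variant

The dual surface pools two integrators with separate strength–duration
laws: `I = w·u₁ + (1−w)·u₂`, each `uᵢ` a `g`-power saturation against
`FFhmᵢ(D)`. The payoff is written `V = I·price_scale/SP` with a single
`price_scale` (seconds of subjective price per unit of maximal pooled
reward) shared across durations. This is the minimal parameterisation
that reduces algebraically to the single surface at `w = 1` with
`price_scale = SPe`; the bookkeeping of which price normaliser survives
in the original derivation is not recoverable from the source text, so
the choice is isolated in one payoff expression and can be swapped.

Location parameters of a dual surface are *derived*, not stored:
`f_hm_effective` is the pulse frequency at which pooled intensity
reaches half its **achievable** maximum at that duration (the intensity
at the frequency-following plateau), and `p_e_effective` is the
objective price at which TA for that achievable-maximal reward crosses
halfway between floor and ceiling. Using the achievable rather than the
notional (unit) maximum is what makes the price location
duration-dependent when an integrator drops out; for single surfaces the
two conventions coincide whenever `FF(Fhm)` is well below the plateau,
and exactly so as the plateau is pushed to infinity.

## Time allocation from lever events

Work time is total lever-hold time plus released gaps whose length is
strictly below the 1 s tap threshold; the denominator runs from the
first reward delivery to trial end; blackout intervals (2 s after each
reward, lever retracted) are excluded from both. Edge rules, chosen
where the protocol description is silent:

* a gap of exactly 1 s is leisure (the rule is "less than 1 s");
* the pre-first-reward span is removed from numerator and denominator;
* gaps are classified by their total non-blackout length, even when they
  span a reward delivery (such gaps are logged);
* presses inside a blackout are a protocol violation and raise an error
  (the lever is retracted then);
* trials with no reward have undefined TA, returned as NaN and dropped
  from fitting with a logged count.

The implementation is validated against an independent interval-sweep
oracle that classifies every elementary sub-interval of 1000 random
event streams.

## Synthetic data

No behavioural data accompany the analysis, so the generator *is* the
study population. It reproduces the survey design exactly: per train
duration (0.25 s, 1 s) three pseudo-sweeps of nine log-equispaced
points — frequency-parallel at a constant low price, price-parallel at a
constant high frequency, and radial through `(Fhm, Pe)` in log-log
space — with the five central points of each sweep entering the urn
twice per survey and the four extremes once, drawn without replacement;
eight surveys give 16/8 replicates per point (672 observations).
Defaults the protocol leaves qualitative: the frequency sweep's price
anchor is 3.5 s (twice the subjective-price floor — low, but clear of
the strongly compressive region), the price sweep's frequency anchor is
310 pps (high, just under the frequency-following breakdown), and both
sweep spans are one decade centred on the location point, which places
roughly three points on each asymptote and three on the rise.

Observation noise is beta-distributed on [0, 1] with mean equal to the
surface value and concentration κ (variance μ(1−μ)/(κ+1)); TA is a
bounded proportion and no noise law is prescribed, so a two-parameter
bounded family is the natural choice. The default κ = 40 gives a
standard deviation of ≈ 0.08 at mid-surface — the scatter visible in
published pseudo-sweep data — and an optional heteroscedastic flag
inflates dispersion on the rising portion, where real performance is
most variable. The root seed is split into independent child streams
per survey.

The event-level simulator goes one layer deeper: an alternating
work/leisure dwell process (exponential work bouts; leisure bouts of
1 s plus an exponential tail so no leisure bout is misread as a tap)
whose stationary work fraction equals the target TA, with bout means
rescaled when mixing within a short trial would otherwise fail.
Lever-available trial time is 25 × price; rewards fire when cumulative
hold reaches the price, followed by a 2 s blackout; each test trial is
flanked by leading (strong, near-continuously worked) and trailing
(weak, mostly ignored) bracket trials. Simulated event streams do not
emulate satiation, priming effects, post-reinforcement pauses, or
within-session drift, so passing tests show the estimator chain is
correct under the stated noise model — not that real rats obey it.

## Fitting

The surface is fitted to individual observations (not point means) by
bounded trust-region nonlinear least squares, jointly across durations:
`a`, `g`, `TAmin` shared; `Fhm`, `Pe`, `TAmax` per duration. Location
parameters and exponents are optimised on the log scale and reported in
natural units; all power expressions go through `expit`/`log_expit` so
large exponents cannot overflow. Default boxes: `a, g ∈ [0.5, 50]`,
`TAmin ∈ [0, 0.45]`, `TAmax ∈ [0.5, 1]`, `Fhm ∈ [5, 5000]` pps,
`Pe ∈ [0.2, 500]` s. Starts are data-driven (`Fhm` at the frequency
sweep's half-rise, `Pe` at the price sweep's half-fall, quantiles for
the floors/ceilings) with 8 seeded log-uniform jittered restarts;
ties break by objective then lexicographic parameter order. Residual
weighting across sweeps is uniform.

The constrained dual fit follows the reference procedure: `a`, `g`,
`TAmax`, `TAmin` frozen at single-fit values, chronaxies capped at 6 s,
free parameters `C₁, C₂, R₁, R₂, w, price_scale`; integrators are
identified by ordering `C₁ ≤ C₂` (relabelling `w ↔ 1−w`), removing
label switching. An unconstrained dual fit (shape parameters free) is
also available, because information-criterion comparison is only
meaningful when neither model borrows parameters from the other:
the constrained dual has fewer *free* parameters than the single model
and would win any penalised comparison trivially. `compare_models`
reports Gaussian-likelihood AIC/BIC (`n·ln(RSS/n) + penalty`), lower is
better.

## Bootstrap and shift inference

Uncertainty comes from a case bootstrap at the design-point level: every
point's replicate set (8 or 16) is resampled with replacement at its own
size — implemented as multinomial replicate counts, which conserves the
sizes exactly — and the surface is refitted, warm-started at the
full-data estimates. Failed refits are redrawn with a logged count and a
configurable ceiling. The 95% interval drops the ⌈0.025·B⌉ smallest and
largest estimates and reports the adjacent order statistics (exactly 25
per tail at B = 1000, no interpolation). Duration shifts are computed
per resample as long-minus-short differences of the same joint fit,
summarised by their median and percentile interval; a shift is
significant when that interval excludes zero, and the secondary
non-overlap criterion on the two parameters' own intervals is reported
alongside. The whole chain is bit-reproducible under a seed.

Calibration: resampling *within* points of size n understates the
variance of a point mean by the factor (n−1)/n, so with n = 8/16 the
percentile intervals are mildly anticonservative — the null rejection
rate of the shift test sits near 6–9% rather than 5% in simulation.
The acceptance band in the calibration test ([0, 13%] over 100
experiments at B = 200) covers the nominal rate, this known procedural
bias, and binomial noise. Power against a strength–duration-consistent
frequency shift (chronaxie 1 s, i.e. a 2.5× requirement ratio between
0.25 s and 1 s trains) is essentially complete at the reference design
and noise.

## Problem sizes in the test suite

Simulation-backed tests use the full 8-survey design (672 observations)
throughout. Scaled sizes chosen for the heavier Monte Carlo checks:
parameter recovery uses 20 replicate experiments (plus 2 noiseless);
shift-test calibration uses 100 null experiments at B = 200 and power
uses 30 experiments at B = 200; the percentile-rule check runs one full
B = 1000 bootstrap. The noiseless limit is κ = 10⁷.

## Known limitations

* The dual fit with only two train durations cannot identify the
  long-chronaxie integrator's (C, R) pair separately (only its firing
  demands at the tested durations); estimates of `w` and of the
  integrator-1 parameters are nonetheless stable in simulation.
* The percentile bootstrap inherits the small anticonservatism noted
  above; no BCa or studentised correction is attempted.
* The event-level simulator's finite trials start the scoring window at
  a reward (inside a work bout), which biases event-derived TA slightly
  upward for short trials; the bias vanishes as trial length grows and
  is covered by the Monte Carlo tolerances in the tests.
* Bracket trials are quality control only; they never enter fits.
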