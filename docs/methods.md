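# Methods

## Model

`chronoasm` simulates epileptiform-discharge (ED) dynamics in a small brain
network and asks how the timing of anti-seizure-medication (ASM) doses
interacts with the circadian rhythm of cortical excitability.

Each of N = 4 network nodes carries a complex fast variable `z_j` obeying a
modified subcritical-Hopf normal form

    dz_j = [ z_j (λ_j − 1 + iω + 2|z_j|² − |z_j|⁴) + (β/N) Σ_k A_kj (z_k − z_j) ] dt + α dW_j,

whose real part is the proxy for EEG-recorded activity.  For fixed
excitability 0 < λ < 1 the node is bistable: a background fixed point at
`z = 0` coexists with a large-amplitude oscillatory branch at
`|z|² = 1 + √λ` (the root of `r⁴ − 2r² + (1 − λ) = 0`), and the complex
Wiener process (independent real and imaginary increments per node, variance
`dt` each, amplitude α) drives noise-induced transitions between them.  An
excursion onto the oscillatory branch is an ED event; seizure-like and
interictal discharges are not distinguished.  The diffusive coupling over the
fixed directed adjacency matrix synchronises node states.

Excitability relaxes toward a baseline and is depressed by ongoing discharge
activity (so events self-terminate):

    dλ_j/dt = (λ_j0 − |z_j|² − λ_j)/τ + ρ x_j + λ_ASM(t),

with τ = 3 s.  The slow drive `x_j` is a weakly nonlinear van der Pol
oscillator evolving in rescaled slow time `ω_s t / k` (ω = ω_s/k = 2π/86400
rad/s):

    dx_j/dt = ω y_j + γ λ_j,
    dy_j/dt = ω [ μ (1 − x_j²) y_j − x_j ],

which has a near-harmonic limit cycle of amplitude 2 and period 24 h for
μ = 0.01, standing in for the circadian modulation of seizure propensity.
The weak feedback γ = 10⁻⁴ lets excitability perturb the slow rhythm.  Note
the time rescaling is applied to the whole slow subsystem: writing the
nonlinearity un-rescaled against a restoring term `(ω_s/k)² x` would make
μ ≫ ω and turn the slow system into a relaxation oscillator with a
month-long period, contradicting the 24 h near-harmonic regime the
parameters are chosen for.

Default parameters: ω = 20 rad/s, α = 0.055, β = 0.35, N = 4, τ = 3 s,
λ0 = 0.631, ρ = 0.0014, γ = 10⁻⁴, μ = 0.01, ω_s = 1, k = 86400/2π s.
ω is used directly as the angular rotation rate of the normal form; reading
the "20" as 20 cycles/s (125.7 rad/s) would make the Euler–Maruyama update
of the rotation unstable at dt = 1 ms (per-step radial growth
√(1+(ωdt)²) ≈ 1.0079, an e-fold every 0.13 s, overwhelming the background
contraction rate 1 − λ ≈ 0.37 s⁻¹) and destroy the bistability the model is
built on.

## Pharmacokinetics

A single dose produces the normalised effect-site concentration

    ASM(η) = C (e^{−k_e η} − e^{−k_a η}),    C = 1/(e^{−k_e t*} − e^{−k_a t*}),
    t* = ln(k_a/k_e)/(k_a − k_e),

so the single-dose peak is exactly 1.  Doses superpose linearly; a daily
schedule gives the excitability perturbation

    λ_ASM(t) = −a Σ_i [ f·ASM(t − t_i) + (1 − f)·ASM(t − t_i − τ_d) ],

with primary-dose fraction f (f = 1 for once-daily QD dosing) and a 12 h
dosing interval τ_d for twice-daily (BID) dosing.  `a` is a drug-specific
efficacy scale mapping concentration to excitability reduction, applied
identically to all nodes (systemic exposure).  Drug presets (absorption and
elimination rates per hour): levetiracetam LEV (2.618, 0.099; half-life
7.0 h), topiramate TPM (1.215, 0.033; 21.0 h), lamotrigine LTG (1.572,
0.012; 57.8 h — the parametrisation dataset's value; literature values for
this compound are closer to 25–56 h, and here it serves purely as the
slow-elimination representative).

Inside the integrator the dose sum is evaluated by an exact O(1) recursion:
the two exponential superposition sums decay by `e^{−k dt}` each step and a
dose's weight is added when its time is crossed.  This is algebraically
identical to the closed-form sum (a test integrates excitability under a
dosing schedule and checks it against an adaptive reference integration
driven by the closed-form superposition).

## Numerics

Fixed-step Euler–Maruyama at dt = 1 ms throughout; no adaptive stepping.
Wiener increments are pre-generated in fixed 2²⁰-step chunks from an SFC64
generator, so every trajectory is a pure function of its seed.  Event
detection runs at full step resolution inside the integration loop;
trajectory recording is decimated (default 10 ms for short runs, 60 s for
multi-day experiments).

Two deliberate finite-step effects are documented rather than hidden:

- the forward-Euler update of the rotation inflates the oscillatory-branch
  radius from `1+√λ` to `1+√(λ+c)` with `c = (1−√(1−(ωdt)²))/dt ≈ ω²dt/2`
  (1.794 → 1.912 at default parameters); the detection thresholds sit far
  from both attractors so event detection is unaffected;
- at λ0 = 1 the same growth makes a pure-noise variance test meaningless, so
  the Wiener-scaling check is run with the rotation off.

Event detection uses hysteresis on the node-max |z|²: an event opens when
any node exceeds 1.0 and closes when all nodes fall below 0.5.  The
thresholds sit in the wide gap between the background state (|z|² ~ 10⁻²
under noise) and the discharge branch (≈ 1.9), and the hysteresis suppresses
chatter from noise riding on a discharge.  Events are network-level (the
model reports one ED rate per simulation, and coupled nodes co-activate) and
are binned by onset time.  A per-node counting convention would scale rates
by a roughly constant factor that cancels in efficacy percentages.

## Phase conventions

Simulation time 0 is midnight.  The default initial state places `z = 0`,
`λ = λ0`, and the slow oscillator on its limit cycle with phase chosen so
the emergent ED rhythm peaks near clock hour 12.  Two lags enter this
calibration: the γ feedback retards the realised x peak by ≈1.5 h relative
to the commanded phase, and the ED rhythm lags excitability by roughly
another hour, so the commanded x peak sits at hour 13.8.  A dose phase is
the clock time of the (primary) dose read against this cycle; "6 h before
the ED peak" is phase 6.

## Experiments

All dosing experiments share a protocol skeleton: unmedicated burn-in,
a dosing window, and a final measurement window over which the mean hourly
ED rate is taken.  Efficacy is the percentage reduction of that rate
relative to an independent unmedicated baseline arm with its own seeds
(rates are averaged per arm before the reduction is formed; per-run
reductions are reported alongside).  The full protocol is 2 burn-in days,
28 dosing days, 7 measurement days, 10 dose phases, 10 replicates — at
dt = 1 ms this costs on the order of an hour of wall-clock per 30-day run,
so the package also ships a reduced "desk" protocol (2 + 4 days, 3
measurement days, 5 phases, 3 replicates) and the test-suite/acceptance
runs use further-reduced windows (2 + 4 days measured over the final 3 for
the dose-phase experiments; 1 + 3 days over the final 2 for rhythm and
structure checks; stated per experiment).  One sizing constraint found
empirically: the dose-phase efficacy contrast builds up over dosing days as
the ED rhythm re-entrains to the dosing schedule, so protocols with fewer
than ~4 dosing days attenuate the very effect under study and are not used
for phase-ordering experiments.  Levetiracetam reaches its steady-state
daily mean within ~1.5 dosing days, so even the shortest windows measure at
pharmacokinetic steady state for the drugs whose phase behaviour is
asserted; for lamotrigine (≈16 days to 1% of steady state) short windows
understate the steady-state effect and are used only where relative
orderings, not absolute levels, are asserted.

A root seed deterministically spawns one child seed per (arm, condition,
replicate) via `numpy.random.SeedSequence` spawn keys; whole sweeps are
reproducible bit for bit.

### Calibration of the efficacy scale

Following the study design, `a` is not a free dial but is calibrated so
that phase-averaged once-daily dosing produces ≈50% reduction.  An
important dynamical subtlety: the `−|z|²` term that terminates seizures
also acts as a homeostatic rate governor — suppressing the rate removes
event-driven excitability depression, which partially cancels the drug's
effect.  The strength of this compensation grows with the unmedicated event
rate.  At this package's realisation of the model (≈4.5 events/h
unmedicated), it roughly halves the effective dose-response slope, so the
≈50% point sits near a ≈ 0.013 for LEV (and ≈0.0046 for TPM) rather than
the shipped preset values (0.0073, 0.002), which presume a different
event-rate regime; at the preset values the reduction comes out near
35–40%.  A quasi-static analysis with the measured rate–excitability slope
confirms the whole phase-dependence landscape scales with this single
sensitivity factor while every ordering is unchanged.  All phase- and
fraction-dependence experiments therefore run at the recalibrated scale,
which is what the calibration procedure prescribes.

### Dose-timing experiments

The QD sweep doses at evenly spaced phases and reports per-phase efficacy
plus the cosinor phase shift of the ED rhythm between the first and last
dosing day.  The BID sweep varies the primary-dose fraction f ∈ [0.5, 0.9]
at constant total daily dose and reports the per-fraction range
(max − min over phases) of efficacy.  Short-half-life drugs produce large
daily excitability swings whose alignment with the vulnerable window
matters; long-half-life drugs produce flat profiles and little phase
dependence.

### Chronotype fitting

The synthetic-histogram generator runs the unmedicated model at a given
(ρ, λ0) and returns the day-averaged hourly ED histogram — a single-peaked
24 h profile whose amplitude grows with ρ and whose overall rate grows with
λ0.  It emulates the shape of empirical ED-chronotype histograms derived
from EEG; it does not emulate their between-patient heterogeneity,
multidien modulation, recording artefacts, or sleep-stage structure, so
parameter-recovery results here bound what the fitting machinery can do on
clean data, not its performance on real cohorts.  `fit_chronotype` grid
searches (ρ, λ0) minimising the per-hour sum of squared differences to a
target histogram and reports the best point, its residuals and R².

## Cosinor rhythmometry

Rhythms are quantified by least-squares fits of
`m + A cos(2π(t − φ)/24 h)` via linear regression on cosine/sine
regressors; amplitude is reported non-negative with the acrophase φ (peak
clock time, hours) adjusted accordingly, and R² = 1 − SSE/SST.  Constant
series are flagged degenerate (amplitude 0, acrophase reported as 0).
Phase differences are wrapped to (−12, 12] with negative values meaning the
first rhythm peaks earlier.  The phase response of a dosing condition is
the acrophase of the last dosing day's hourly histogram minus the first
day's, wrapped the same way (positive = delay); days with no events yield a
flagged missing value (NaN).

## Design choices on genuinely open points

- Initial conditions are not specified by the model statement; background
  start (`z = 0`, `λ = λ0`) with the slow oscillator on its limit cycle at
  the calibrated phase was chosen so unmedicated runs need no discarded
  transient beyond the burn-in the protocols already include.
- Excitability is not clipped; transiently negative λ is allowed.
- Dose events are instantaneous impulses (the single-dose response is the
  complete description; no infusion duration).
- Dose contributions are truncated once below 10⁻⁹ of a unit dose (≈10
  half-lives back), bounding the cost of the closed-form superposition.
- The calibration "control condition" uses the same evenly spaced phases as
  the sweeps.  Baseline arms are independent simulations, not seed-matched
  pairs, keeping variance estimates honest.
- `a*` is selected as the grid value nearest 50% reduction, without
  interpolation.
- Events are attributed to bins by onset time; no minimum duration beyond
  the hysteresis itself.

## Known limitations

- One-compartment PK with perfect adherence; no circadian modulation of
  absorption or elimination, no drug–drug interactions, no side-effect or
  toxicity modelling, monotherapy only.
- The discharge model is phenomenological (no explicit excitatory/inhibitory
  populations); multidien (>24 h) rhythms are not simulated.
- Efficacy percentages at reduced protocols carry counting noise of a few
  percentage points per condition (Poisson-scale; quantified per experiment
  in the tests by the bands asserted), and absolute efficacy levels depend
  on the unmedicated event rate through the homeostatic feedback described
  above.
- The empirical-EEG fitting results reported for the original cohorts
  cannot be reproduced here (the recordings are not public); the grid-fit
  machinery is validated by synthetic parameter recovery instead.
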