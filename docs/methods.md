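# Methods

`plumewalk` implements a stochastic-decision account of how walking flies
navigate spatiotemporally complex odor plumes: navigation emerges from three
stochastic behavioral components — saccadic turns, stop decisions, and walk
decisions — whose probabilities are modulated by the recent *timing* of
discrete odor encounters rather than by odor intensity. This note records
the models, the conventions and numerical choices behind the implementation,
what the synthetic world does and does not emulate, and the known
limitations.

## Signals and encounters

An observer (a tracked fly or a simulated agent) perceives the plume
through a virtual antenna: an elliptical patch (semi-axes 0.77 × 0.23 mm,
major axis perpendicular to the heading) centered 2.16 mm ahead of the body
center. The patch-mean intensity s(t) is sampled at 90 Hz on a 0–255 camera
scale. The odor-free signal is modeled as a Gaussian (fit robustly to the
dominant histogram mode); an *encounter* is a contiguous interval with
s(t) above mean + 2.5 σ. Detection uses symmetric persistence: both onset
and offset require the signal to stay on its side of the threshold for at
least 50 ms; shorter excursions in either direction are ignored
(sub-minimum dips merge neighboring intervals; the merged event must itself
clear the minimum). Partial sample coverage rounds up: at 90 Hz a 50 ms
minimum requires 5 full samples, so a 44 ms pulse is rejected.

Three causal exponential filters (timescale τ = 2 s, zero state before the
record) summarize encounter history:

* `W_freq` — filtered onset impulses, normalized by 1/τ so a steady onset
  rate r Hz reads as r (units Hz);
* `W_dur` — Riemann-sum filtered binary exposure d(t) (units s; saturates
  at τ);
* `W_conc` — Riemann-sum filtered raw signal (intensity units).

## The saccade model

While walking, turns fire as a Poisson process with rate
λ_F = 1/τ_T (+ optional linear modulation by W_freq and W_dur; disabled by
default because those coefficients are not robust — on unmodulated
synthetic data their subset estimates straddle zero). Each turn draws a
magnitude |Δθ| ~ |N(30°, 10°²)| and is directed upwind with probability

    p_T = 1 / (1 + exp(−α · S(t))),

falling back to a fair coin at S = 0. Between turns the orientation
accumulates white jitter of 0.22° per time step. Orientation is
wind-relative: θ = 0 faces upwind (the −x direction, toward the source),
and the reflected deviation is θ⁺ = min(θ, 360 − θ) ∈ [0°, 180°].

**Sigmoid drive convention.** S(t) is the *raw* causal exponential sum of
onset impulses (steady value τ·r), i.e. S = τ·W_freq, and α = 0.242 is
expressed per unit of that sum. The alternative — feeding the Hz-normalized
W_freq to the sigmoid — rescales α by τ and produces an
orientation-versus-frequency slope of only ≈ −15.5°/Hz, inconsistent with
the ≈ −21.6°/Hz the full model is known to produce together with its
≈ 88.6° zero-frequency intercept; the raw-sum drive reproduces both. Plots
and regressions always use the Hz-normalized W_freq.

**Likelihood.** Each walking time step contributes one term: straight steps
contribute exp(−Δt·λ_F)·N(dθ; 0, 0.22°); the midpoint step of each detected
turn contributes Δt·λ_F·exp(−Δt·λ_F) times the direction probability (p_T
or 1 − p_T, classified by whether the observed dθ reduces θ⁺) times a
Gaussian around ±30° (sign set by the orientation half-plane). At the
reflection boundaries (θ exactly 0 or 180) the direction is undefined and
the two direction terms are mixed with weight ½ (simulation draws the
direction uniformly there). Fitting maximizes the summed log-likelihood by
L-BFGS-B with numerical gradients over 500 random subsets, each holding 20%
of the trajectories; τ_T is optimized as log(1/τ_T) to avoid bound
singularities, and per-parameter medians over converged subsets are
reported. With modulation disabled the likelihood collapses onto sufficient
statistics (walking-step count, turn count, and the drive at each turn),
which the fitter exploits; the fast path is tested against the general
per-step likelihood.

## Walk–stop transition models

Walk→stop and stop→walk transitions are independent inhomogeneous Poisson
processes. Three rate families per direction:

* **last encounter** (reset): λ(t) = λ₀ + Δλ·exp(−ΔT(t)/τ), ΔT = time since
  the most recent onset; before the first onset ΔT = +∞ so λ = λ₀. The
  fitted stopping model has λ₀ = 0.78 s⁻¹, Δλ = −0.61 s⁻¹, τ = 0.25 s — the
  hazard drops to 0.17 s⁻¹ at each onset.
* **accumulated evidence**: for stopping λ(t) = λ₀ + λ₁/(1 + λ₂·F(t)), for
  walking λ(t) = λ₀ + Δλ·F(t), with F the *raw* (unnormalized) exponential
  filter of onsets so the coefficients absorb scale. The fitted walking
  model has λ₀ = 0.29 s⁻¹, Δλ = 0.41 s⁻¹, τ = 0.52 s.
* **encounter duration**: λ(t) = λ_enc·d(t) + λ_blank·(1 − d(t)).

**Likelihood.** Every step in the source state contributes a survival
factor exp(−Δt·λ); each observed transition adds Δt·λ·exp(−Δt·λ) at its
onset step; the final bout of every trajectory is censored and contributes
survival only. The per-step Poisson approximation requires Δt·λ ≪ 1 and is
asserted at simulation time (rejected above Δt·λ = 0.2). Fitting is
L-BFGS-B on log-transformed positive parameters (the reset model's onset
rate λ₀ + Δλ is optimized as a positive quantity so Δλ carries either
sign), with box bounds spanning two orders of magnitude around an
empirical-rate initializer; estimates landing within 5% of a bound are
flagged bound-hugging (non-robust).

**Model comparison.** Models are fit on training trajectories and scored on
held-out trajectories. The selection score is the held-out log-likelihood —
the natural cross-validated predictive score for point-process models. A
curve-based discrepancy (summed squared deviation between model-simulated
and empirical conditioned survival curves: time-to-transition after all /
isolated / clump-member onsets and after matched random times) is also
computed and reported, but it is not used for selection: on synthetic
recovery experiments it identifies the generating stopping family in well
under half of replicates, because a refit accumulated-evidence model mimics
the reset model's unconditioned curves. AIC/BIC are reported for reference;
they track the in-sample likelihood and do not weight the informative
high-frequency episodes. An *isolated* onset has no neighbor within ±1 s; a
*clump* member has ≥ 3 onsets within ±1 s (both windows configurable).

**Probe trains.** Under Poisson encounter trains the reset and accumulation
families are nearly indistinguishable (≈ 1.2 nats per 1000 transitions), so
recovery and comparison experiments use `generate_clumped_train`: events
arrive at a Poisson rate and are either isolated onsets or fixed-size
clumps (default 8 onsets, 100 ms apart). Reset-type rates respond
identically to both; accumulation-type rates scale with clump size, which
makes the families separable at realistic data sizes.

## Kinematics and event segmentation

Raw (t, x, y, θ) trajectories are smoothed with a Savitzky–Golay filter
(order 4, 9-sample window); speed comes from the analytic derivative of the
smoothed positions. Angular velocity is never computed from the wrapped
angle: θ is mapped to (cos θ, sin θ), each component is smoothed and
differentiated, and ω = −θ̇ₓ/θ_y when |θ_y| ≥ |θₓ|, else ω = θ̇_y/θₓ — the
quotient with the larger denominator, which is branch-cut-free. Samples
within half a window of the ends are flagged invalid.

Stops are intervals with v < 2 mm/s persisting ≥ 300 ms; walks tile the
complement; saccades are intervals with |ω| > 200 deg/s persisting ≥ 20 ms,
kept only inside walks. The signed turn angle is measured over a 200 ms
window centered on the turn midpoint (an onset-to-offset mode is available;
the window is the default because the windowed angle plateaus once the
window covers the saccade plus the smoothing support, which the
discreteness analysis verifies). Empirical hazards assign each
walk-then-stop snippet the constant rate 1/T_walk (and symmetrically),
updating at bout onsets.

## The synthetic plume

The generator emulates the walking-arena apparatus — a 300 × 180 mm arena,
150 mm/s mean flow, lateral jets (1500 mm/s) switching sides at 10 s⁻¹ —
with the simplest mechanism that reproduces a conical intermittency map and
clumpy encounter statistics: discrete packets emitted at the source at a
Poisson rate, advected downwind, laterally displaced by a shared two-state
telegraph cross-wind velocity (magnitude = lateral_gain × jet speed), with
radius growing linearly in age and peak intensity decaying as 1/r² (2D mass
conservation). Intensity is the sum of Gaussian blobs; shot noise
(N(3, 1.5²) intensity units) is added at sampling time. A burn-in of one
full packet transit precedes frame 0. Rendering to a pixel grid happens
only on demand; agents sample the packet field analytically through the
antenna quadrature, so long runs need no frame stack. Analysis-scale
movies are rendered at 1 mm/px (the packets are ≥ 2.5 mm wide); the
camera-resolution default (0.154 mm/px) is reserved for small crops.

**Calibration.** Emission rate (13 s⁻¹), growth rate (2.8 mm/s), initial
radius (2.5 mm), peak intensity (150), and lateral gain (0.065) were tuned
against the full agent protocol (500 agents × 11,690 steps) so that
(i) centerline intermittency 20 mm downwind falls in the 0.12–0.39 band
(measured 0.35–0.37 across seeds), (ii) full-model agents perceive
encounters of ≈ 230 ms mean duration, and (iii) the onset-weighted mean
perceived encounter frequency is ≈ 3.1–3.2 Hz. The frequency target of
~4 Hz is operationalized as the
mean of W_freq sampled at encounter onsets — the frequency perceived *at*
encounters, which is the quantity the conditioning analyses bin on. This is
deliberate: a plain onsets-per-unit-time rate of 4 Hz together with 200 ms
mean durations would force a duty cycle of 0.8, which no plume inside the
stated intermittency band can deliver; encounters instead arrive in clumps
whose internal frequency is high while the overall duty stays near 0.2–0.35.

## The agent navigator

Agents are point walkers (speed 10.1 mm/s, instantaneous turns) with four
behavioral states (walk, stop, left/right saccade), initialized along the
downwind wall with uniform headings. Per 1/90 s step each agent samples its
antenna (deterministic elliptical quadrature plus one shot-noise draw),
registers an onset when the signal is above threshold and no onset occurred
in the past 100 ms (the refractory period — a continuous exposure registers
at most one onset per 100 ms), updates its filter states, and draws
stop/walk transitions and saccades from the fitted models. Walls are
reflective in effect (position clamped, heading resampled into the inward
half-plane); arrival is the first entry into a 20 × 20 mm source box, and
arrived agents keep navigating. Ablations replace one component by its
ensemble-average constant from a reference run: the stop (or walk) hazard
by the reciprocal exponential-fit timescale of the reference walk (stop)
durations — the exponential MLE timescale is the sample mean — and the turn
bias by the reference's overall upwind-turn fraction. With all three
ablated the agent is odor-blind (its statistics are invariant to odor), but
not unbiased: the frozen upwind-turn fraction retains a fixed drift.

## Orientation analyses

Post-encounter orientation change is measured 2 s after each onset,
partitioned by the number of onsets following within the window (0, 1–3,
4+), with a matched random-walking-time baseline curve subtracted per
orientation bin. The delay analysis regresses θ⁺ at steps whose most
recent onset is a given delay old on W_freq at that onset, with
trajectory-clustered standard errors (per-timestep samples are strongly
autocorrelated; plain OLS errors are anti-conservative by an order of
magnitude here). The trilinear regression standardizes W_freq, W_dur, and
W_conc to zero mean/unit variance over included walking steps, fits OLS
with plain two-tailed t-tests, reports the condition number of the
regressor moment matrix (flagged above 10), and optionally adds
trajectory-level block-bootstrap standard errors.

Power-law tail exponents of duration distributions are reported for the
probability density (a survival index a corresponds to density exponent
−(a+1)), fit by least squares over log-spaced bins spanning 1.5 decades
ending at the 99.5th-percentile duration — the quantile anchor keeps the
window off the extreme order statistics, which dominate heavy-tailed
samples. The quadratic log-log coefficient is reported as a curvature
diagnostic; strongly concave tails (e.g. exponentials) flag a poor
power-law fit.

## Problem sizes and reproducibility

Recovery experiments use 500 trajectories × 60 s (turn and stop/walk
parameter recovery), 8 encounter rates × 20 × 400 s runs (the orientation
slope), 500 agents × 11,690 steps (plume calibration), and 50 replicates of
70 × 100 s probe-train ensembles (model selection) — sizes at which the
estimator spread sits comfortably inside the stated tolerances. All
randomness derives from a single seed through labeled child streams
(`plumewalk.config.derive_seed`), so every generator, fit, and simulation
is bit-reproducible.

## Limitations

* The packet plume is a phenomenological stand-in, not fluid dynamics: its
  fixed-point encounter durations span about 1.5 decades (blanks span > 2),
  whereas real turbulent plumes have heavier encounter tails approaching
  the t^(−3/2) law; conclusions about tail exponents from the synthetic
  plume are qualitative.
* The perceived-frequency calibration sits at ≈ 3.1–3.2 Hz against the
  ~4 Hz target — a structural consequence of the duty-cycle cap imposed by
  the intermittency band together with the 100 ms refractory; pushing the
  frequency higher drives either the mean duration or the centerline
  intermittency out of its own band.
* Arrival fractions and ablation effect magnitudes depend on the synthetic
  plume; only directional claims (full model beats ablated controls) are
  asserted.
* Agents loop the plume movie in time when the run outlasts it; the 60 s
  default field is long compared to the 2 s filter memory, so looping
  artifacts are negligible.
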