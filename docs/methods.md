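# Methods

## The model

The controller is a fully connected Kuramoto network of N = 3 phase
oscillators (no self-coupling).  Oscillator *i* has phase θ_i and natural
frequency ω_i ∈ [0, 5] rad/s:

    dθ_i/dt = ω_i + I_i + Σ_j K_ij sin(θ_j − θ_i)

Sensory drive I reaches only oscillators 1 (light type A) and 2 (type B);
oscillator 3 is the effector.  Each oscillator monitors its *relational
phase*, the angle of the coupling-weighted sum of phase differences to its
neighbours:

    φ_i = ∠ Σ_j K_ij exp(i(θ_j − θ_i))

Homeostatic plasticity compares φ_i with a preferred relation φ0_i ∈
[−π/2, π/2].  The plastic activation p(x) of the wrapped error x = φ_i −
φ0_i is 0 for |x| < H1, ramps linearly on (H1, H2) and is 1 beyond H2; both
thresholds are fixed at 0.2π, so in practice p is a step and the
*homeostatic region* |x| < 0.2π freezes all incoming weights exactly.  We
use |x|: the plastic function is symmetric, matching its graphical
definition.  Outside the region the raw weights integrate

    d(δK_ij)/dt = η_ij · p(φ_i − φ0_i) · sin((θ_j − θ_i) − φ0_i)

with evolvable rates η_ij ∈ [0, 0.9] 1/s.  Raw weights map to effective
couplings through K_ij = α_i · F(δK_ij) with per-oscillator gains α_i ∈
[0, 5].  F is a sinusoidal lobe gated by a positive square wave of half its
frequency — F(x) = (1 − cos x)/2 where sin(x/2) > 0, else 0 — giving a
continuous, non-monotonic, period-4π map whose exact-zero half-periods make
total disconnection reachable.  (A gated (1 + sin x)/2 lobe would jump at
the gate boundaries; starting the lobe at its zero keeps F continuous, as
the construction requires.)  The gain is implemented per-oscillator,
following the genome layout; a scalar α is broadcast for the shared-gain
variant.

## Embodiment

The body is a massless circle of radius 4 with two diametrically opposed
motors.  Motor speeds read out the effector's relational phase through
evolvable bias phases: M_r = 2 sin(φ_3 − φ_r), M_l = 2 sin(φ_3 − φ_l).
Translational speed is (M_r + M_l)/2 along the heading and angular speed
(M_r − M_l)/diameter, bounding speed at 2 units/s and turning at 0.25 rad/s
per unit motor difference.  Two sensor pairs (right/left at ±π/3 on the
body perimeter, pointing outward) respond to their light type with cosine
angular tuning gated at |angle| > π/2 and a logistic distance falloff
1/(1 + e^{0.03(d−100)}), scaled by evolvable gains in [−8, 8]; same-type
sensors sum into their oscillator's input.  Distances and angles are
measured from the sensor positions on the perimeter, not the body center.

Lights spawn at distance U[100, 150] from the robot; pairs subtend a random
angle U[π/2, 3π/2] from the robot's viewpoint.  A blinking light is re-drawn
lit with probability 0.15 on every control step, so blink statistics are
dt-dependent by construction.  The arena is unbounded.

## Integration

Forward Euler at dt = 0.05 s (configurable), the convention of this
minimal-evolutionary-robotics lineage; the dt-halving test bounds the
end-of-trial phase error of a 10 s run below 10⁻² rad.  Per control step the
sensor drives, relational phases, plasticity levels and motor speeds are all
evaluated at time t, then phases, weights and pose advance simultaneously to
t + dt.  Phases are kept wrapped to [0, 2π); when an oscillator's complex
sum is degenerate (modulus < 10⁻¹², e.g. all incoming couplings gated to
zero) its relational phase holds its previous value so plasticity sees no
spurious error.  Initial conditions per trial/run: θ_i ~ U[0, 2π) and
δK_ij ~ U over one full period (4π) of F.

## Evolution

22 parameters (ω×3, sensor gains×4, α×3, η×6, φ_r, φ_l, φ0×3) are encoded
as 5-bit genes mapping linearly onto their ranges.  Population 20,
elitism 4; parents are drawn with probability proportional to fitness
(a rank-proportional switch is provided); offspring take each gene from a
random parent (uniform per-gene crossover) and with probability 0.03 per
gene one random bit of that gene flips.  "3% per gene" is read literally as
a per-gene event, not per-bit.  Fitness per trial is
F_trial = (F_D + F_p)·F_H with F_D = max(0, 1 − d_f/d_i) clamped so
proportional selection stays non-negative, F_p the fraction of steps within
16 units of the target light, and F_H the time-and-oscillator mean of 1 − p.
Each agent runs 3 runs × 4 tasks, 8 trials of 125 s per run with weights
re-randomized per run, scoring only the last 3 trials.  An all-zero-fitness
generation falls back to uniform parent selection.

The packaged reference agent is the best individual of the final generation
of this GA (seed and generation count recorded in the agent's metadata);
`scripts/evolve_fixture.py` regenerates it.  Evolved runs differ widely in
phenotype — some best-fitness agents lock onto one light, others alternate
every trial; the packaged agent was selected among best-fitness agents of
independent GA seeds as one displaying the task's target phenotype, stable
but switching preferences.

## Conditions

*Situated*: closed-loop trials with two equal, always-lit lights (one A,
one B — a configuration never used during evolution).  Long fractal runs
chain capture-terminated trials (capture radius 16, timeout 1250 s)
back-to-back for 125 000 s; behavioural and pattern analyses use fixed
125 s trials.  The trial's decision is the captured light, else the type
closer at trial end, ties broken at random.

*Decoupled*: the environment is removed and each of the four sensor
channels receives i.i.d. Gaussian(0, σ) noise every step before the evolved
gains, σ = 1 — large enough to trip the plasticity thresholds, the regime
in which the isolated network departs from white noise.

*Frozen*: all η set to zero.  Weight configurations are snapshots taken at
the midpoint of a chosen trial of a 60-trial reference run: freezing inside
a long same-choice streak yields *committed* agents (≥ 95% one light over
100 verification trials), freezing at a preference switch yields *pliable*
(undecided) agents.  Candidates failing verification are discarded and the
next candidate tried.

*Perturbations*: random permutation of φ0, ω, or the six η values, or
multiplication of all α_i, or of H1, by 2^r with r ~ U[−1, 1].  When the
scaled H1 exceeds H2 the upper threshold follows it, keeping the plastic
step well defined at the scaled threshold.

## Fractal battery

The analysed signal is Φ = |analytic((1/3) Σ sin θ_i)|, the Hilbert
amplitude envelope of the mean activation, computed at the 20 Hz control
rate and decimated (anti-aliased) to 10 Hz.

*DFA*: profile = cumulative sum of the mean-removed series; non-overlapping
boxes, order-1 least-squares detrending, ~20 log-spaced box sizes per
decade; α from the log-log slope of the RMS fluctuation, β = 2α − 1.  Fit
ranges follow the protocol: [1, 10^3.5] s and [10, 10^2.5] s for
situated/decoupled runs, [10², 10^3.5] s for frozen agents, [10, 10^3.5] s
for perturbation runs.

*Spectral slope*: Welch periodograms (Hann, 50% overlap, segment length 1/8
of the series), averaged across independent runs before fitting −β over
[10^−3.5, 10^−1] Hz.

*Multifractality*: the series (decimated by a further factor 10) is
integrated and transformed with an analytic Morlet CWT (ω₀ = 6, FFT
implementation, L2 normalization, 30 log-spaced scales from 4 samples to
N/16, cone-of-influence edges trimmed at 2a).  Structure functions
S_q(a) = mean_b |W(a, b)|^q over q ∈ {0.5, 1, …, 10} are fitted for their
scaling exponents ζ(q), from which two exponent families follow: the
generalized Hurst exponents h(q) = ζ(q)/q − 1/2, and the local singularity
exponents dζ/dq − 1/2 of the Legendre-consistent transform, whose spread
over the q grid defines the spectrum width Δh.  Only positive moments are
used — CWT moduli make negative moments unstable.  Under these conventions
monofractal fGn with Hurst H returns h(q) ≡ H with Δh ≤ 0.06 at N = 2^16,
and the binomial cascade returns h(q) = (τ(q) + 1)/q and singularity
exponents τ′(q), with τ(q) = −log₂(p^q + (1 − p)^q), matched within ~0.1 —
the oracles that anchor the estimator.

*Decision autocorrelation*: γ(n) = Σ_τ D(τ)D(τ + n) on the ±1 decision
series, exactly as defined (no mean removal), plus the normalized variant
γ(n)/(N − |n|).  The preference span is the longest initial run of lags
whose normalized autocorrelation exceeds the i.i.d. null band
z/√(N − n), z = 2.  Without mean removal a series with an overall bias
toward one light keeps γ positive at long lags, so this statistic is
sensitive to the agent's overall choice balance, not only to its local
persistence.

*Pattern correlation*: 125 s windows slid by 25 s over the 10 Hz phase
traces; each window is summarized by the joint density of
(sin(θ₁ − θ₃), sin(θ₂ − θ₃)) on [−1, 1]² via an averaged shifted histogram
(100 bins, 8 shifts, implemented as a fine 800-bin histogram smoothed with
a triangular kernel and block-averaged back to 100 × 100 — output size is
deliberately grid-convention-agnostic); Pearson correlations between
flattened densities form the window-pair matrix.

## Surrogate generators

White: i.i.d. standard Gaussian.  Pink/brown: Fourier-domain shaping of
white noise to 1/f^β, unit variance.  fGn: exact Davies–Harte circulant
embedding.  Binomial cascade: conservative multiplicative splitting with
weight p (random side assignment), so the series sums to 1 at every depth.
These surrogates emulate only the scaling structure of the model's signals
— they are stationary, Gaussian (except the cascade) and free of the
envelope's non-negativity and trial-boundary seams — so estimator tests on
them validate the estimators, not the simulator.

## Problem sizes and numerical choices

Long runs are 125 000 s (2.5 × 10⁶ control steps; 1.25 × 10⁶ envelope
samples at 10 Hz).  Condition averages use 25 runs; run-averaged Welch
spectra use 10 independent runs; the decision series uses 1000 fixed
trials.  The demonstration examples use shorter runs (stated in each
script).  DFA requires ≥ 4 boxes at the largest box size; constant series
are rejected as degenerate by DFA and the multifractal estimator rather
than returning an undefined slope.  The simulation kernels are compiled
(numba) and are verified step-for-step against the readable numpy reference
implementation.

## Known limitations

The frozen-agent exponents depend on which weight snapshot is frozen;
committed/pliable variants are re-verified by classification before use.
Capture-mode runs of some evolved agents can fall into long non-capturing
episodes from unlucky initial conditions — a real feature of the dynamics.
Exponents are properties of a particular evolved agent: different GA seeds
produce phenotypes from always-committed to trial-by-trial alternation,
with correspondingly different β and Δh.  The decision-autocorrelation span
inherits the bias sensitivity noted above and is the least stable statistic
of the battery.
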