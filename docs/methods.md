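# Methods

## Model

The network is a triad of Kuramoto phase oscillators: auditory A (phase
θ1, intrinsic frequency ω1), visual V (θ2, ω2) and multisensory AV (θ3,
ω3). A and V are each coupled bidirectionally to AV with strengths κ1
and κ2; there is no direct A–V edge. The audiovisual onset asynchrony is
a transmission delay τ ≥ 0 placed on the V–AV edge when the visual
stream leads (positive AV lag) or on the A–AV edge when the auditory
stream leads (negative lag). A negative delay is never used — dynamics
must not depend on the future — so the lag sign is a discrete switch
between two vector fields that are similar in form but not mirror
images, because the intrinsic frequencies differ. Phases are stored
unwrapped (plain reals), which makes instantaneous frequencies ordinary
finite differences and frequency locking a tail-spread test.

Model time is dimensionless. The mapping from the delay parameter to
experimental milliseconds of AV lag is qualitative: the delay sweep's
synchronization island is compared with behavioral lag-tuning curves on
shared normalized axes, and no fitted time scale is claimed.

Parameters of record (used throughout tests and the acceptance script):
theta-band intrinsic frequencies ω = (3, 4, 5); balanced coupling κ = 5
for the reference states; κ ∈ [3, 20] for sweeps; beta-band variant
ω = (15, 16, 17); delays τ ∈ [0, 1.5] in steps of 0.01.

## Numerical integration

The delayed system is integrated with a fixed-step classical RK4 scheme.
Delayed phases at off-grid times come from cubic Hermite interpolation
of the stored trajectory (values and derivatives at grid nodes), which
is fourth-order accurate and keeps the whole scheme at its nominal
order; an empirical step-halving test shows order ≈ 4. The step must
satisfy h ≤ min(τ/10, 0.01), so every delayed stage time lies at least
nine steps in the past and interpolation never reads unwritten nodes.
A fixed step was chosen over adaptive stepping because bit-for-bit
reproducibility across platforms matters more than speed at this problem
size; at τ = 0 the integrator agrees with an adaptive ODE oracle to
~1e−11 at t = 50.

The initial history is linear: θ_i(t ≤ 0) = θ_i(0) + r_i·t. The default
rates r = 0 give the constant history that randomized initial phases
naturally induce; setting all rates to a branch's collective frequency
seeds the integrator exactly on a locked state, which is how analytic
branches are confirmed dynamically. Default horizon is 200 time units
with the first 75% discarded as transient; this is comfortably beyond
the slowest convergence observed at κ ≥ 1 on the default grids.

## Synchronized branches and stability

For balanced coupling the locked ansatz θ_i = Ωt + ψ_i reduces the
system to three algebraic equations in (Ω, φ1, φ2) with φ1 = θ3−θ1,
φ2 = θ3−θ2. Summing them eliminates the phase shift on the undelayed
edge and leaves a transcendental equation for Ω alone; its roots are
found by sign-change scanning (2000 grid points over
[min ω − 2κ, max ω + 2κ], which provably contains all roots) followed by
bracketed Brent polishing to residual < 1e−10, with duplicates merged at
1e−8. Both arcsin branches (x and π − x) of each phase shift are
enumerated, since the principal branch alone would silently miss fixed
points; candidates that fail the full three-equation residual (< 1e−9)
are discarded. Unbalanced coupling has no analytic reduction here, and
the branch module refuses it explicitly rather than extrapolating.

Linearizing about a locked state gives a delay differential equation
with instantaneous coefficient A = κ cos(φ_inst) on the undelayed edge
and delayed coefficients B = κ cos(φ_del − Ωτ), C = κ cos(φ_del + Ωτ),
where φ_inst/φ_del are the phase shifts on the instantaneous and delayed
edges. Two verdicts are implemented:

* **cubic** — drop the e^{−λτ} factors from the characteristic function,
  leaving λ·(λ² + (2A+B+C)λ + A(2B+C)) = 0. Cheap, and exact at τ = 0.
* **spectral** (default) — eigenvalues of a Chebyshev-collocation
  discretization of the linearized DDE's generator on 33 nodes over
  [−τ, 0]; the rightmost characteristic roots, which decide stability,
  converge spectrally fast in the node count.

The two agree wherever Ωτ is small, but the cubic over-reports stability
in the large-delay regime: e.g. at ω = (3, 4, 5), κ = 5, τ = 0.95 it
marks a branch with R ≈ 0.77 stable that direct perturbation of the
nonlinear DDE shows decaying onto the R = 0.3326 state. The spectral
verdict matches the perturbation oracle on randomized (κ, τ) points
(tested), so it is the default; the cubic form remains available as
`stability(..., mode="cubic")` for comparison. In both modes the
structural zero eigenvalue from global phase invariance (the root
closest to the origin, numerically zero) is excluded from the verdict.

The locked order parameter has closed form
R = |1 + e^{−iφ1} + e^{−iφ2}|/3. Reference values at ω = (3, 4, 5),
κ = 5, visual-leads: the stable branch at τ = 0.07 has Ω = 3.2503 and
R = 0.9995; at τ = 0.95 the stable branches are (Ω = 3.4740,
R = 0.3326) and the high-coherence continuation (Ω = 5.9377,
R = 0.9336). Both are reproduced by integration to ~1e−4.

## Sweeps, plateaus and the synchronization island

Sweeps draw initial phases uniformly from [0, 2π)³ with per-run seeds
derived from (sweep seed, grid indices), so results are reproducible
row-for-row regardless of execution order. Locked steady states across
the κ = 5 delay sweep occupy two dominant plateaus, near R = 1 and near
R = 1/3. The lower "plateau" is not a single number: the underlying
branch R varies continuously from ≈ 0.33 to ≈ 0.42 through the
transition region, each value matching an analytic branch exactly. A
plateau is therefore operationalized as a cluster (greedy 1-D
clustering, radius 0.05) holding at least 5% of the locked runs; tiny
satellite clusters produced by clustering a continuum of branch values
are not plateaus. The lower plateau center computed this way is ≈ 0.34.

The synchronization island is measured on the in-phase-seeded curve:
integrate from θ = 0 at each delay and find the first grid delay where
the attained R_ss drops below the threshold (default 0.9). The island
width is the contiguous above-threshold run starting at the smallest
grid delay; re-entrant synchronized windows at larger delays (which do
occur) are deliberately not counted, since the island of interest is the
one around zero lag. Trend checks (critical delay non-decreasing in κ;
beta-band frequencies shrinking the island; island non-decreasing in κ2
with κ1 = 3 fixed) use a τ grid of step 0.05 — coarse enough to run in
seconds, fine enough that the trends are well resolved.

Hysteresis is traced by continuation: stepping τ up or down and reusing
the previous final phases (mod 2π) as the next initial condition. The
up-sweep holds the high-coherence state deep into the coexistence
region; the down-sweep stays on the low branch — a loop of width ≈ 0.35
delay units at κ = 5.

## Synthetic behavioral cohort

The generator emulates the structure of McGurk-style lag-response data:
34 subjects by default, AV lags {−300, −150, 0, 150, 300, 450} ms, up to
40 responses per (subject, lag) cell, categories {/ta, /pa, other}. Per
cell, responses are multinomial with p_ta a bell over lag peaking at
0 ms — subject peak drawn around 0.85 (SD 0.10), width 220 ms, and a
positive-lag side 1.6× wider, reflecting the reported dominance of
illusory perception at positive lags — p_other small and flat (0.10),
p_pa the remainder. An optional per-trial response rate below 1 creates
incomplete cells for exercising the ≥ 35-response filter. These defaults
were chosen once as a realistic cohort; the classification and filtering
rules themselves (≥ 35 responses per cell; perceiver ⇔ /ta ≥ 60% at some
lag) are exact integer rules tested against brute-force enumeration.

What the generator does not emulate: response correlations across lags
within a subject beyond the shared peak parameter, lapses/bias drift
over the session, and the /ka or fused sub-categories sometimes folded
into "other". Passing tests therefore validate the pipeline's rules and
descriptive statistics, not any claim about real human cohorts. Group
curves carry percentile-bootstrap 95% intervals over subjects — a
reproducible descriptive convention, not an inferential test; ANOVA on
real subject data is out of scope.

## Numerical choices and degenerate inputs

* Frequency-lock tolerance: max pairwise spread of tail-mean
  frequencies < 1e−3 (model units).
* Steady-state R is the tail mean (final 25%); the tail SD is reported
  so oscillating (unlocked) tails are detectable.
* κ = 0: no locked states — the root finder returns nothing rather than
  reporting the meaningless common-frequency root, scans report no
  clusters, and the island is empty.
* τ = 0: the spectral stability mode reduces to the eigenvalues of the
  summed Jacobian (exact); the root equation reduces to Ω = ω̄.
* Branch confirmation tolerance 0.02 between closed-form R and
  integrated R_ss; observed agreement is ~1e−4 away from marginal
  stability.
* The stability-vs-perturbation oracle skips points whose leading
  nonzero eigenvalue has |Re λ| < 0.02: a finite-horizon dynamical test
  cannot resolve rates slower than its horizon, and such points sit at
  bifurcation boundaries by construction.

## Problem sizes

Default test and demonstration sizes: horizon 200, τ grids of step
0.02–0.05 with 6 initial conditions for sweep structure tests, 51-point
grids for analytic–numeric equivalence, 20–24 initial conditions for
basin scans, 20+ random points for the stability oracle. The acceptance
script runs the full sweep of record (τ step 0.01, 24 initial conditions
per delay, single κ = 5). These sizes resolve every structure they are
used to demonstrate; enlarging them changes results only at the quoted
tolerances.

## Known limitations

* The analytic machinery covers balanced coupling only; unbalanced
  scenarios are numerical.
* No continuation/bifurcation tracking beyond grid scans, and no
  normal-form analysis near the critical delay.
* The triad is fixed at N = 3; no generalization to larger networks.
* The model-to-behavior comparison is qualitative (shared normalized
  axes); no fitted mapping from model delay to experimental
  milliseconds.
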