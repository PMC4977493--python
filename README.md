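# avsync

Simulation and analysis of a minimal dynamical model of audiovisual
speech integration: three delay-coupled Kuramoto phase oscillators
representing the auditory (A), visual (V) and multisensory (AV) systems.
The package is aimed at computational neuroscientists studying how the
audiovisual onset asynchrony (AV lag) of McGurk-style stimuli constrains
the temporal binding window, and at anyone who needs a reproducible,
tested implementation of delay-coupled phase-oscillator triads.

## Model

Each node carries a phase θ_n with intrinsic frequency ω_n; A and V are
bidirectionally coupled to AV through sines of phase differences (no
direct A–V link), and the AV lag enters as a transmission delay τ ≥ 0 on
one sensory edge. For positive lag (lip movement leads the sound) the
V–AV edge is delayed in both directions:

    dθ1/dt = ω1 + κ1 sin(θ3(t) − θ1(t))
    dθ2/dt = ω2 + κ2 sin(θ3(t−τ) − θ2(t))
    dθ3/dt = ω3 + κ1 sin(θ1(t) − θ3(t)) + κ2 sin(θ2(t−τ) − θ3(t))

For negative lag the A–AV edge is the delayed one instead. Collective
behavior is measured by the Kuramoto order parameter
Z(t) = (1/3) Σ_n e^{iθ_n(t)} = R(t) e^{iΦ(t)}: R = 1 is full phase
coherence, R = 0 maximal dispersion.

For balanced coupling (κ1 = κ2 = κ) the frequency-locked states
θ_i = Ωt + ψ_i are found analytically: Ω solves the transcendental
equation Ω = ω̄ − (2κ/3) sin(Ωτ) cos(φ₂) (ω̄ the mean intrinsic
frequency, φ₁ = θ3−θ1 and φ₂ = θ3−θ2 the locked phase shifts, given by
arcsin expressions), each root's linear stability is classified from the
delayed linearization, and the locked order parameter has the closed form
R = |1 + e^{−iφ₁} + e^{−iφ₂}| / 3. The library cross-checks every
analytic branch against direct integration of the delay differential
equations.

## What's in the box

| module | contents |
| --- | --- |
| `avsync.model` | `NetworkParams`, the two delayed vector fields |
| `avsync.integrator` | fixed-step RK4 DDE integrator with cubic Hermite history |
| `avsync.metrics` | order parameter, instantaneous frequencies, steady-state summaries |
| `avsync.branches` | collective-frequency roots, phase shifts, stability, closed-form R |
| `avsync.experiments` | coupling/delay sweeps, multistability scans, critical delay, hysteresis |
| `avsync.behavior` | McGurk-style response tables: filtering, percentages, perceiver rule, synthetic cohorts |
| `avsync.cli` | `avsync simulate / branches / sweep / multistability / behavior / make-fixtures` |

## Worked example

```python
>>> import numpy as np, avsync as av
>>> p = av.NetworkParams(omega1=3, omega2=4, omega3=5,
...                      kappa1=5, kappa2=5, tau=0.07,
...                      lag_sign="visual_leads")
>>> for b in av.stable_branches(p):
...     print(f"Omega={b.Omega:.4f}  phi1={b.phi1:.4f}  phi2={b.phi2:.4f}  R={b.R:.4f}")
Omega=3.2503  phi1=0.0501  phi2=0.0770  R=0.9995
>>> traj = av.integrate(p, np.random.default_rng(0).uniform(0, 2*np.pi, 3))
>>> ss = av.steady_state(av.order_parameter(traj), traj)
>>> round(ss.R_ss, 4), ss.synchronized, round(ss.Omega_hat, 4)
(0.9995, True, 3.2503)
```

At a small delay (τ = 0.07) the only stable synchronized state is
nearly in-phase: the three oscillators lock at the collective frequency
Ω = 3.2503 with tiny phase shifts, and both the closed form and the
integrated trajectory give R = 0.9995. At a large delay the picture
changes:

```python
>>> for b in av.stable_branches(p.replace(tau=0.95)):
...     print(f"Omega={b.Omega:.4f}  R={b.R:.4f}")
Omega=3.4740  R=0.3326
Omega=5.9377  R=0.9336
```

Two states coexist: a partially synchronized one (R = 0.3326, the visual
oscillator out of phase with the other two) and a high-coherence
continuation branch — the multistability that makes the attained percept
depend on initial conditions. Which one a run reaches can be scanned
with `avsync.experiments.multistability_scan`, and the hysteresis loop
with `hysteresis_trace`.

The same model can be run from the shell:

```sh
avsync make-fixtures -o fixtures
avsync simulate -c fixtures/example_config.yaml -o out
# INFO avsync: params={...'tau': 0.07...} seed=0 R_ss=0.9995 Omega_hat=3.2503
```

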