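# Methods

## The problem

Multiscale models in cellular neuroscience couple subsystems whose intrinsic
timescales differ by many orders of magnitude: a Hodgkin–Huxley neuron reacts
on microseconds-to-milliseconds, a signaling cascade on seconds-to-minutes.
Solving the coupled system monolithically forces the global step size down to
the fastest timescale.  In a co-simulation setting the components are solved
by separate integrators that exchange *transformation-function outputs*
(`g_r(x_r)`) only at discrete communication points, so a further constraint
applies: no intermediate communication inside a step.

`mrcosim` implements a multirate coupling scheme for this setting: every
component advances with its own adaptive, non-uniform grid; communication
happens at macro time steps set by the slowest component; and a coupled error
rule keeps the splitting error controlled.

## Decoupled BDF2 on non-uniform grids

Each component is advanced by the second-order backward differentiation
formula written for variable steps,

    x_{n+1} = α₁ x_n + α₂ x_{n-1} + β h_{n+1} f(t_{n+1}, x_{n+1}),
    γ = h_{n+1}/h_n,   α₂ = −γ²/(2γ+1),   α₁ = 1 − α₂,   β = (γ+1)/(2γ+1),

which reduces to the classic `(4/3, −1/3, 2/3)` scheme at γ = 1 and is exact
for solutions that are polynomials of degree ≤ 2 on any grid.  The formula is
*decoupled*: partner states enter only through exchanged variables frozen at
`t_{n+1}`, approximated by a quadratic polynomial through the partner's newest
three published samples (Newton divided-difference form for conditioning on
non-uniform spacings).  The same quadratic serves interpolation (partner
already advanced) and extrapolation (partner not yet advanced); a query at a
sample endpoint counts as interpolation.

The implicit relation is solved by a damped Newton iteration: one
forward-difference Jacobian per step (perturbation `√ε·max(|x_j|, scale_j)`),
reused across iterations, at most 10 iterations, convergence when the scaled
update norm falls below 0.1 — an order below the unit acceptance threshold of
the step-error estimate, so the nonlinear-solve error never contaminates step
control.  The first step of every component is backward Euler (BDF2 needs two
history points).  Every rhs evaluation, including the n evaluations of each
finite-difference Jacobian, is counted; cost is reported both inclusive and
exclusive of Jacobian work because the literature is not consistent about
what an "ODE call" includes.

## Error control and the coupled rule

The local error estimate is predictor–corrector: the predictor is the
quadratic extrapolation of the component's own history, the corrector the
implicit BDF2 solution, normalized per variable by `relTOL·|x| + absTOL`.
The *combined* error of a component that still has faster components beneath
it is the maximum of its own local error and the largest accepted error of
the next-faster component over the overlapping micro steps (in asynchronous
mode the overlap includes the micro step that overshoots the interval end).
A step is accepted iff the combined error is ≤ 1; a rejection rolls back the
component *and* all faster components' micro steps inside the rejected
interval, bitwise (snapshots at micro boundaries).

The next step is predicted by the elementary controller
`h⁺ = h·clamp(0.9·err^(−1/3), 0.2, 2.0)` (exponent 1/(order+1)); an
H211b-style digital filter is selectable by configuration for smoother step
sequences.  The clamp bounds consecutive accepted step ratios, keeping the
variable-step BDF2 coefficients well conditioned.  The initial step is
`min(10⁻⁴·T_total, 0.01·d₀/d₁)` with `d₀, d₁` the scaled norms of the state
and its derivative.  A per-component maximum step (`h_max`, default ∞) guards
against stepping over brief stimulus pulses; the neuron test case sets it to
half the pulse width.  At most 20 consecutive rejections abort the run with a
diagnostic; the partial result is returned flagged.

An important emergent property of feeding the *combined* error into the
controller: the slower component's step is pinned to a small multiple
(~3–5×) of the faster component's step, because the faster component's
accepted errors hover near the controller's equilibrium.  The multirate gain
therefore comes from avoiding the fast component's *work* on the slow side
(Jacobians, Newton solves over many shared steps), not from arbitrarily large
macro steps.

## Organization and communication

Components are kept in a list ordered slowest → fastest by predicted step
(stable insertion order on ties), re-sorted before each outermost interval;
a change of order increments the switch counter.  `SOLVE_INTERVAL` is
recursive: the current (slowest remaining) component takes adaptive micro
steps across the interval handed down by its parent; within each micro step
the remaining faster subset is advanced across the step by a recursive call.

* **fast-first**: the faster subset is solved to the micro endpoint first,
  using extrapolated values of the not-yet-advanced slower components; the
  result is communicated backward and the current component then takes its
  corrector step with interpolated fast values.
* **slow-first**: the current component steps first, extrapolating its faster
  partners, and the faster subset then advances across the step interpolating
  the fresh slow values.

With **synchronous** communication every component shrinks its last micro
step to land exactly on the interval endpoint, so slower grids are subsets of
faster grids.  With **asynchronous** communication the innermost (fastest)
component may overshoot the endpoint by at most one predicted step; endpoint
values are obtained by quadratic interpolation, and the overshooting step is
kept for the next interval (no recomputation).  Asynchronous is the default:
shrinking produces sharp step-size reductions the controller must recover
from.  In systems with more than two components, middle components land
exactly even in asynchronous mode — a simplification; all study problems here
have two components.

A **singlerate** mode forces one shared adaptive step: all components sweep
Gauss-Seidel over the same interval (fastest first under the fast-first
strategy), the shared error is the maximum over components, and one shared
controller predicts the next step.  With a single component the engine
degenerates to a plain adaptive BDF2 solver and reproduces the standalone
solver bitwise — both facts are tested.

## The neuron test case

The electrical component is a 17-compartment neuron: a spherical soma (20 µm)
with the minimal regular-spiking channel set (fast Na⁺, delayed-rectifier K⁺,
slow non-inactivating M-type K⁺, leak; kinetics and densities after
Pospischil et al. 2008, `V_T = −56.2 mV`, time constants in seconds), fifteen
passive dendritic segments (25 µm × 3 µm, `R_a = 150 Ω·cm`) and a spine
(1 µm², thin neck).  The spine carries a high-threshold Ca²⁺ current
(`m²` gating, `V_½ = −35 mV`, τ = 0.3 ms), a phenomenological single-pool
calcium concentration `d[Ca]/dt = −([Ca]−[Ca]_rest)/τ_Ca + φ·(−I_Ca)`
(τ_Ca = 0.1 s, [Ca]_rest = 0.08 µM), and a K⁺ conductance scaled by the
biochemical availability signal.  Morphology and spine/calcium parameters are
package defaults chosen for physiologically sensible backpropagation
(~45 mV spine depolarization per somatic spike) and micromolar calcium
transients; all are overridable (shipped parameter files
`src/mrcosim/data/tc_{slow,fast}.yaml`).

The stimulus is a two-phase pulse-current protocol into the soma, *defined*
by its target regimes: 0–4 s, one 0.35 nA / 5 ms pulse every 0.5 s, each
eliciting exactly one spike (regular spiking at 2 Hz); 4–5 s, a sustained
0.15 nA step driving ~100 Hz repetitive firing.  The amplitudes were chosen
from the model's f-I curve so the protocol meets its definition.  Spikes are
upward 0 mV crossings of the soma potential; phase rates are spike counts
over phase durations.

The biochemical component is a reduced MAPK cascade (concentrations in µM,
rates in /s, totals 1 µM each): calcium activates an upstream kinase through
a Hill term (n = 4, K = 0.35 µM); active kinase phosphorylates MAPK under
saturating (near zero-order) Michaelis–Menten kinetics against a constant
phosphatase; phosphorylated MAPK (P-MAPK) feeds back on the activator —
ultrasensitivity plus positive feedback make the cascade bistable (basal
calcium → P-MAPK ≈ 0.002 µM; 1 µM calcium → ≈ 0.95 µM; the switched state
persists after calcium returns to basal).  P-MAPK phosphorylates
(inactivates) the spine K⁺ channel; `A+Ap`, `M+Mp`, `K_A+K_P` are conserved
by construction.  Rates of 0.1–0.4 /s put the response time at tens of
seconds.

Coupling: the biochemical→electrical signal is always the availability
fraction `C₁·[K_A]` with `C₁ = 1/K_total`.  The electrical→biochemical signal
distinguishes the variants: **TC-slow** solves [Ca] on the electrical side
and communicates the concentration (smooth, millisecond signal); **TC-fast**
communicates the instantaneous flux `−I_Ca·N_A/(2F)` (molecules/s, spiking
signal), and the calcium pool lives on the biochemical side with a
per-molecule conversion chosen so that a given Ca²⁺ current feeds both pools
at identical rates.

Because the concentration pool is driven directly by the flux, its maximum
slope is tied to the flux peak; the smoothness contrast between the two
signals is about an order of magnitude (max-slope and total-variation
relative to range), not more — a structural property of the single-pool
model.

## The synthetic two-rate benchmark

A linear system used wherever an analytically controlled two-rate problem is
preferable to the neuron:

    slow:  dx₁/dt = (−x₁ + c·u₂)/τ_s                      τ_s = 1 s
    fast:  dy/dt  = (−y + b·x₁ + F(t))/τ_f                τ_f = τ_s/ratio, ratio = 1000
           dz/dt  = (y − z)/τ_z                           τ_z = 0.2 s

with `u₂ = y` (flux-like, `signal_speed="fast"`) or `u₂ = z`
(concentration-like, `"slow"`), `c = 0.5`, `b = 1`.  The forcing combines two
sinusoids (amplitude 1 at ω = 200 and 3 rad/s) with a train of narrow
Gaussian pulses (amplitude 0.3, period 20 ms, width σ = 10⁻⁴ s) that stands
in for the spike-shaped flux: the pulses are narrower than the slow
component's accepted steps, so the raw fast signal carries features the slow
component's endpoint sampling cannot see, while the filtered signal `z`
pre-integrates them.  Without pulses the system is a linear ODE with
sinusoidal forcing and the exact solution (eigendecomposition plus complex
particular solutions) is used as the reference; with pulses the reference is
a monolithic BDF solve at tolerance 10⁻¹², cross-checked for self-consistency
against 10⁻¹⁰.

This design reproduces the two regimes of interest at desk scale
(T = 0.5 s, relTOL from 10⁻⁴ to 10⁻⁷ in half-decades):

* slow-first strategy with the smooth signal: log-log slope of slow-component
  error versus total ODE calls ≈ 2 (second order);
* fast-first strategy with the raw fast signal: slope ≈ 0.9 — the order
  reduction.  The mechanism is the one sketched above: the missed pulse areas
  form an error component that declines much more slowly than the
  second-order part, and the measured decline is their crossover.  The
  decline is genuinely shallower, but the fitted slope depends on where the
  crossover sits in the tolerance window; the generator defaults place it
  centrally.

## Evaluation

Accuracy is the relative error `|x̌ − x|/|x̌|·100 %` of a named observable at a
fixed evaluation time against the monolithic reference — asymmetric by
design, normalized by the reference.  Observables address state entries by
name→index maps (spine V, Ca, K_A, P-MAPK for the neuron; the slow and fast
states for the benchmark).  Cost is total rhs evaluations.  Convergence order
is the least-squares slope of log error versus log cost, reported as a
positive decline order.  Sweeps run one engine instance per tolerance,
recording errors, call counts, micro/macro/rejected step counts and order
switches, and are exactly reproducible (no randomness anywhere in the stack).

## Problem sizes used

The shipped studies use: 5 s of the electrical component at relTOL 10⁻⁴
(~28 000 accepted steps); synthetic sweeps over seven tolerances at
T = 0.5 s (~10⁴–10⁵ accepted steps per run); 5 s of the biochemical component
and 400 s calcium-clamp runs for conservation and bistability.  These sizes
were chosen so the full study suite re-runs in a few minutes on one core
while keeping every measured quantity in its asymptotic regime.

## Known limitations

* No waveform relaxation (one Gauss-Seidel iteration per interval), no event
  detection, no distributed execution, no reaction–diffusion calcium.
* All-to-all coupling is assumed; sparse-coupling communication savings are
  not implemented.
* In asynchronous mode with three or more components, middle components land
  on interval endpoints instead of overshooting.
* The synthetic benchmark is linear; conclusions about the nonlinear neuron
  test case transfer qualitatively (the same strategy/signal ranking) but not
  quantitatively.
* Jacobians are dense finite differences; for systems much larger than the
  17-compartment neuron an analytic or sparse Jacobian would be preferable.
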