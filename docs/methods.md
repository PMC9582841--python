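# Methods

This note documents the model as implemented: its assumptions, the
numerical choices, the places where the design was genuinely open, and
what the test suite does and does not establish.

## Biochemical model

The four pathway species interact as a Lotka–Volterra system whose
interaction graph is triangular (IGF1 → AKT → {FOXO, mTOR}, FOXO → mTOR).
At the resting inputs (a₁ = a₁₀, a₂ = a₂₀) the positive fixed point
follows in closed form by cascading the zero-rate conditions; with the
default rate constants it lands on the myofibril thresholds to within
0.1% (x₃* = 0.43394 vs x₃⁰ = 0.4340, x₄* = 0.46899 vs x₄⁰ = 0.4690), so a
resting muscle neither grows nor atrophies.  The shipped initial
conditions place x₄(0) = 0.4692 slightly *above* its threshold; a resting
run started from those values therefore accumulates a ~0.1% CSA drift
while x₄ relaxes.  The homeostasis test starts exactly on the fixed point,
where the drift is identically zero.

The myofibril law ż = f(x₃, x₄) is piecewise linear with both branches
vanishing on their threshold lines, so it is globally Lipschitz
(constants k₁, k₂); ties at the thresholds need no special casing.  The
rate is hard zero once z reaches its bounds [0.5, 1.3]; the bound is
enforced by post-step projection rather than event detection, with an
O(dt·f) ≤ 2.5e-3 a.u. overshoot per step at worst, negligible at
dt = 0.05 h.

### Training signals

a₁(t) is two-state: βIF_max during a session (β = 2/50 (h·kgf)⁻¹), a₁₀
otherwise.  F_max is the maximal isometric force of the *initial*
structure, measured once at full activation and held fixed — the model
trains at a fixed load, as discussed for fixed-load protocols.

a₂(t) follows the printed pulse ODE, whose exact integral is
a₂ = a₂₀ − ½(u·eᵘ − u₀·e^{u₀}) with u = (t − t₁)/τ_h, τ_h = 6 h,
t₁ = 17 h.  As printed the expression is unbounded past t₁, so the pulse
is applied on a window of length t₁ after each session start and a₂ is
then held at a₂₀; the divergent tail is treated as a typesetting loss of
a sign.  The pulse restarts at each session start (sessions are never
closer than 24 h, farther apart than the 17 h window, so restart vs
superposition is moot for all shipped schedules).  Because the integral is
available in closed form, the "pulse step" is evaluated exactly rather
than discretized.

### Integration

Classical fixed-step RK4 on the five-state system, dt = 0.05 h, with the
drivers re-evaluated at substage times; session boundaries are snapped to
step boundaries.  A dt-halving study on the smooth-driver system shows the
expected fourth-order convergence (observed order ≥ 3.8; the test sits
away from the threshold kinks of the myofibril law, which would otherwise
degrade the observed order).

## Mechanical model

Energies are in MPa, lengths in cm, areas in cm²; 1 MPa·cm² = 100 N and
1 kgf = 9.80665 N.  Collagen and muscle fibers share the axial direction
(single-family fusiform idealization).  The active stretch is held at
λ_a = λ_opt = 1 during isometric evaluation: the protocol is isometric,
and the force–velocity factor is f₂ ≡ 1, so no λ_a dynamics exist to
track.  Growth is a stress-free change of reference: only F_e = F·F_g⁻¹
generates stress (standard multiplicative-growth convention).

Cauchy stress is the exact push-forward of the energy derivative
(pressure 2(1/D)(J−1)I plus (2/J)dev[·] isochoric terms) and is verified
against central finite differences of the energy to 1e-6 relative and
against frame indifference to 1e-10 on randomized states.  One consequence
worth stating explicitly: for this strain energy the full-activation axial
Cauchy stress at the reference is ≈ 2σ_o, not σ_o, because the fiber-
invariant term pushes forward as (2/J)·J̄₄·∂Ψ_a/∂J̄₄ and ∂Ψ_a/∂J̄₄ = σ_o
at J̄₄ = 1.  The maximal isometric force of the initial structure is
therefore ≈ 2σ_o·A(0) = 663 N = 67.6 kgf.  σ_o is the energy scale of the
active term; calling it the peak tension would be off by the push-forward
factor.

### Reduced-order organ mechanics

The published organ-scale solution used an 832-element hexahedral
finite-element model; this package deliberately replaces it with a
homogeneous reduced-order solve at the mid-belly section, which keeps
every run under a second and the full scan suite under a minute.  With
both ends fixed the total axial stretch is 1; the transverse stretch λ_t
solves the single scalar condition σ_transverse(λ_t) = 0 (traction-free
lateral surface) by bracketed Brent iteration to 1e-12 in λ_t, bracket
widened up to [0.5, 2.0]·√G before aborting.  The residual uses a
closed-form specialization to the axisymmetric diagonal state,
cross-checked in the tests against the general tensor stress.

Two consequences of the reduction:

* Purely transverse growth is exactly compatible with fixed ends, so a
  grown, inactive muscle is stress-free with CSA = 𝒢·A(0).  The
  compatibility gap between normalized CSA and the myofibril population
  arises solely through the growth-multiplier denominator (each increment
  is diluted by the already-grown area, giving CSA ≈ √(2z−1) ≤ z), and is
  ~0.1% at the end of the protocol — smaller than the gap a constrained
  3-D solve would produce.
* The force–activation relation is essentially bilinear, F ≈ σ(β)·A, so
  the required activation for a fixed load is β_req ≈ A(0)/A.  The
  feedback-slope magnitude of k₁/k₁₀ versus CSA is then pinned near
  d₁·A(0)/⟨A²⟩ ≈ 5.7e3 per m².  The published finite-element value
  (3440 per m²) implies an activation curve about half as sensitive to
  CSA; reproducing it would require the 3-D force–activation family,
  which the reduced model cannot represent.  The fitted slope is reported
  as computed, and the early-training window over which CSA is insensitive
  to the feedback slope is correspondingly shorter here (~2 weeks rather
  than 20 days).

### Feedback

The activation feedback k₁ = k₁₀(d₁β(A,F) − d₂) with d₁ = 20.40,
d₂ = 18.907 is evaluated once per session, immediately before it, and
floored at zero (a negative synthesis rate would invert the hypertrophy
branch).  The force target of β(A,F) is the fixed pre-training 1-RM proxy
F_max, not the session load 0.8·F_max: with the printed d₁, d₂ the
feedback is positive only for β_req > 0.9268, and β_req(A(0)) = 1 gives
exactly the published initial boost k₁/k₁₀ = d₁ − d₂ = 1.493.  (Had the
session load been the target, β_req ≈ 0.8 would floor k₁ at zero for the
whole protocol and no hypertrophy could occur.)  The intensity fraction
I = 0.8 scales the biochemical drive a₁ only.  The linear surrogate
k₁/k₁₀ = b − mA fixes b so the ratio at A(0) matches the feedback value
there; A is in m².

## Study conditions and scans

Defaults are the published constants throughout: Table-level pathway
rates, material constants (1/D = 100 MPa, c₁ = 0.01, c₃ = 0.0543,
c₄ = 6.86, Ī₄⁰ = 1.2544, σ_o = 0.1 MPa, λ_opt = 1, α = 0.83616), geometry
(20 cm × 6.5 cm mid-belly; the 2.34 cm tendon-end diameter is kept in the
configuration but unused by the reduced solver), protocol (24 × 1 h,
days 1/3/5, 8 weeks, I = 0.8, dt = 0.05 h, Δt = 1 h) and κ = z(0)/A(0).
The sensitivity scan perturbs the twelve rate/coupling constants ±1%, one
at a time (25 runs, ~10 s total); the CSA-change metric is
|max_t Ā_pert − max_t Ā_base| × 100 percentage points, with the relative
variant also reported.  RMSE is computed against the baseline simulated
CSA curve: the external experimental series the published errors refer to
exists only as a figure.

At these conditions the baseline run reaches +7.6% CSA with the growth
rate decaying through the protocol; a 1% smaller a₄ (or larger b₄)
removes roughly half the growth rather than all of it.  The sustained
mTOR elevation produced by the windowed a₂ pulse (~5.4e-3 a.u.) exceeds
the 4.6e-3 fixed-point shift of a 1% a₄ change, which is why hypertrophy
is attenuated, not abolished; a complete shutdown would require a weaker
sustained AKT response than the printed pulse produces.  This, together
with the feedback-slope item above, is an acknowledged discrepancy with
the published perturbation outcomes, kept visible (not papered over) in
the acceptance tests.

## What the tests show — and do not

The suite establishes internal correctness (integrator order, exact
growth kinematics, stress–energy consistency, frame indifference, solver
inverses and round trips, determinism of the pipeline) and the published
qualitative structure (homeostasis on the thresholds, saturating
hypertrophy with a decaying growth rate, the k₁/k₁₀ = 1.493 initial
boost, frequency ordering daily ≥ every-2-days ≥ 3/week ≥ every-3-days,
CSA decreasing in κ, CSA ≤ z).  It does not validate the model against
experimental anatomy: no real CSA series is consumed anywhere, the
geometry is an idealized fusiform cylinder, and edema, neural adaptation,
fatigue, fiber-type differentiation, force–velocity effects and
volume-equated protocol logic are all outside the model.  Simulated
muscle is homogeneous along its length; spatial growth variation and
tendon compliance are not represented.

## Numerical choices

* ODE step dt = 0.05 h; growth step Δt = 1 h (an integer multiple of dt
  is enforced); hourly output records.
* Growth samples f(x₃, x₄) at the end of each growth interval; the
  CSA-vs-z ordering therefore admits O(Δt·df/dt) ≈ 2e-5 transients, and
  the corresponding tests use a 5e-5 tolerance.
* Equilibrium root finding: Brent, xtol 1e-12; activation inverse: Brent
  on [0, 1], xtol 1e-8, with loads at the maximum resolved to 1e-9
  relative before declaring a load unreachable.
* z clamping by projection after each RK4 step; populations remain
  positive by construction of the logistic forms at this step size.
* All scans are single-threaded and deterministic; reports embed a
  configuration hash so any table can be regenerated bit-identically.
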