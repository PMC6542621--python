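# Methods

## Model

The network is a set of `n` rate-coded point neurons, all-to-all connected
by plastic excitatory synapses and (by default static) inhibitory synapses,
with autapses included. Two disjoint populations of `n_P` neurons each
receive structured external input through per-population pools of `n_Pex`
input neurons; the remaining `n − 2 n_P` neurons form an unstimulated
background population that only ever receives noise. All rates are
normalized by the maximal rate `F_max` and all weights by the maximal
weight `ω_max = μ F_max² / (γ (F_max − F_T F_max))`, the fixed point of the
plasticity rule at saturated rates. The normalized dynamics are

    τ   dF_i/dt = (1 − F_i) F_i [ ln(1/F_i − 1) + g_i − K n_ε (1 − θ) ]
    τ_w dw_ij/dt = F_i F_j + (F_T − F_i)/(1 − F_T) w_ij² ,

the first being the combined membrane-plus-sigmoid rate equation (logistic
prefactors pin the rates inside (0,1)), the second Hebbian growth balanced
by quadratic synaptic scaling toward the target rate `F_T`.

**Drive convention.** The dimensionless drive is

    g_i = K [ Σ_j (w_ij − w⁻_ij) F_j + Σ_{k∈pool(i)} w_ex F_k^ex ],
    K = β R ω_max ,

i.e. normalized rates inside the drive absorb one factor of `F_max`, and
the sigmoid inflexion enters as `K n_ε (1 − θ)` (the inflexion `ε = n_ε
u_max` counts maximally-wired, maximally-active presynaptic partners,
`u_max = R ω_max (1 − θ)`). This is the convention under which the
phenomenology of the inflexion parameter is quantitatively consistent: at
zero input the no-memory band spans `n_ε ∈ [9, 15]`, the resting rate is
closest to `F_min = 2 F_T` at `n_ε = 13`, and at maximal input the
high-activity branch is lost above `n_ε = 24` and memory above `n_ε = 28`.
A literal variant carrying the extra `F_max` factor in both the drive and
the inflexion term is retained behind `drive_convention="literal"` for
comparison; it produces a far steeper effective activation and is not used
by any preset.

**Inhibitory plasticity** (optional) drives each inhibitory synapse toward
an up-state `θ_u` when the pre/post rate difference exceeds a tolerance
`δF` **or** the rate sum is below a threshold `θ_F`, and toward a
down-state `θ_d` when the sum is large **and** the difference small, with
a multiplicative `F_i F_j` rate gate and exact-equality boundaries
activating neither branch. Because co-active neurons of one stimulated
population have similar rates while the two populations are driven at
different amplitudes, this rule autonomously produces weak inhibition
within populations (`θ_d`) and strong inhibition between them (`θ_u`) —
the configuration that makes discrimination possible.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| n, n_P, n_Pex | 100, 10, 10 | network / population / input-pool sizes |
| τ | 1 s | rate relaxation time |
| R | 0.1 | membrane resistance (enters only via K and u_max) |
| F_max | 100 Hz | maximal rate (normalization) |
| β | 3.5e-4 mV⁻¹ | sigmoid steepness |
| n_ε | 12 | sigmoid inflexion in units of u_max (20 in the association preset) |
| μ, γ | 1/60, 1/5400 s⁻¹ | Hebbian and scaling rates |
| F_T | 0.05 | homeostatic target rate (normalized) |
| θ | 0.5 | baseline inhibitory weight (normalized) |
| θ_P | = θ | within-population inhibitory weight |
| w_ex | 1 | external synapse weight |
| δ, σ (OU) | 0.025, 0.0125 | drift/diffusion per 1-ms reference step |
| dt | 1 ms | Euler step |
| θ_u, θ_d | 0.8, 0.5 | inhibitory up-/down-state |
| θ_F, δF | 2·F_min = 0.2, 0.05 | inhibitory gates |
| ρ_u, ρ_d | 1, 1 | inhibitory learning rates |

Derived: `ω_max ≈ 9473.7`, `K ≈ 0.33158`, `F_min = 2 F_T`.

**Weight timescale.** The normalized weight equation carries a single
timescale; we set `τ_w = 1/μ` (60 s at defaults). Every equilibrium
quantity is independent of `τ_w` — only transients change — which the test
suite asserts by integrating the clamped-rate weight dynamics at different
rates μ, γ with fixed ratio.

**Protocol clock.** Durations are stated in seconds; the natural protocol
time unit is `1/μ = 60 s`, so the standard tuning phase of 10 units is
600 s.

## Stimulation protocol and integration

Runs start with a **tuning phase**: every neuron receives i.i.d. Gaussian
noise (`N(0.25, 0.025)` for the association presets, `N(0.05, 0.025)`
otherwise, clipped to [0,1], redrawn each step) through its `n_Pex` input
neurons. In the subsequent **stimulation phase** the two populations'
input pools follow Ornstein–Uhlenbeck processes with population-specific
means while background neurons keep their noise drive. The OU constants
(δ, σ) are per 1-ms reference step, so other step sizes rescale drift by
`dt/dt₀` and diffusion by `sqrt(dt/dt₀)`; processes start at their means
and are clipped to [0,1].

Integration is simultaneous explicit Euler (all derivatives from the
pre-step state, `dt = 1 ms`); rates are clipped to `[1e-6, 1−1e-6]` and
excitatory weights floored at 0. Initial weights are `N(θ, 0.025)` floored
at 0, initial rates `N(0.07, 0.005)`; under inhibitory plasticity the
inhibitory weights start at `N(θ, 0.025)` clipped to `[θ_d, θ_u]` (their
initial distribution is a modelling choice; the attracting up/down states
make the equilibrium insensitive to it). Three independent RNG streams
(initialization, tuning noise, OU inputs) are spawned from the master
seed. A compiled (numba) kernel integrates chunks between samples; it
implements the identical scheme as the reference numpy step and a test
asserts bit-level agreement on deterministic protocols.

**Equilibrium detection.** A stimulation phase ends early when every
class-mean weight drifts slower than 1e-5 s⁻¹ over a trailing 100-s window
(both scaled by the acceleration factor, below). Because the OU input
imprints stochastic wiggle on the class means, the windowed samples are
averaged into ten equal time blocks before differencing; block averaging
preserves any systematic slope while suppressing the wiggle.

**Timescale acceleration.** Long protocols are shortened by multiplying μ
and γ by a common factor (presets: `accel`). The ratio μ/γ, hence
`ω_max`, `K` and every equilibrium, is invariant; only transients
contract. Acceptance-style runs use ×10; the reduced-versus-full agreement
sweep uses ×50 with a 12-s tuning phase and a 180-s stimulation cap, sizes
chosen so the whole suite stays cheap while all runs still reach detected
equilibrium.

## Reduced two-population model

Since all neurons of a stimulated population share input statistics and
connectivity, the population is summarized by its mean rate `𝔉_p`. Slow
weights are adiabatically slaved to rates via the clamped-rate equilibrium

    w(F_pre, F_post) = sqrt( F_pre F_post (1 − F_T) / (F_post − F_T) ),

defined for `F_post > F_T` (below the target rate, scaling only
up-regulates and no equilibrium exists; this regime is excluded from the
domain). The remaining fixed-point condition per population is

    ln(1/𝔉_p − 1) + K n_P [ I_p + Σ_{p'} (w_{p,p'} − θ_eff) 𝔉_{p'} ]
      − K n_ε (1 − θ) = 0 ,

with folded input `I_p` and `θ_eff = θ_P` within populations, `θ`
otherwise. The background population is folded into the input as
`I_p = F_p^ex w_ex + (n_B/n_Pex) F_B w_pB`; a configuration flag
(`background_inhibition_corrected`) replaces `w_pB` by `w_pB − θ`, the
form consistent with the network's net (excitation-minus-inhibition)
drive. The comparison of full-network runs against the reduced model uses
the corrected fold — at baseline the background's net drive is ≈ 0, and
the uncorrected fold would attribute to it a spurious input of ≈ +0.4.

**Fixed-point finder.** Both residual surfaces are evaluated on a 200×200
grid over `(F_T, 1)²`; their zero level sets are traced by marching
squares, candidate intersections (pairwise segment crossings of the two
contour families) are polished by Newton iteration to residuals < 1e-10,
deduplicated at 1e-6, and classified by the numerical Jacobian of the
adiabatic activity dynamics `d𝔉_p/dt ∝ (1−𝔉_p)𝔉_p·residual_p`. Contour
intersection is used instead of a per-cell double-sign-change bracket
because the latter misses fixed points where a nullcline runs nearly
parallel to a grid axis (verified on the bistable input sweep).
Non-converged candidates are kept and flagged rather than dropped.
Boundary roots of the logistic prefactor at 0 and 1 are not reported as
equilibria.

**Reachability.** In bistable regimes the attained state depends on
history; `reachable_fixed_point` integrates the adiabatic dynamics from
(0.07, 0.07) — the simulator's initial rates — with Euler steps, handing
over to a Newton polish once the motion slows, and reports the attractor
with its label. This is one explicit convention for state selection, not
the only defensible one.

## Classification and analytic structures

A population is a **memory representation** when its intra-population
equilibrium weight exceeds its inhibitory reference; memory failure of
either population labels the pair `nm` regardless of the inter-population
weights. Otherwise the directed inter-population weights against the
baseline inhibition give `disc`, `s12`, `s21`, or `asc`. Ties (weight
within 1e-9 of its reference) resolve to the non-exceeding side. Inputs
with ≥ 2 stable fixed points are labeled `bs` whether or not the two
attractors share a label.

Closed forms (all derived from the weight equilibrium above, which carries
a square root):

- memory bounds: roots of `(1−F_T) F² − θ_P² F + θ_P² F_T = 0`; the band
  between them is the no-memory interval of width `θ_P √D/(1−F_T)`,
  `D = θ_P² − 4 F_T (1−F_T)`;
- separatrices: `S(F_other) = θ² (1 − F_T/F_other)/(1−F_T)`, the
  presynaptic rate at which a directed inter-population weight equals θ;
- regime measures: `D` (no-memory band exists iff D > 0) and
  `S = θ² − 2 F_T` (separatrices reach into the plasticity-dominated
  square iff S > 0) partition the `(F_T, θ)` plane into regime I (only
  associations), II (+ sequences), III (+ no-memory);
- plasticity-dominated area `A^SP = (1 − 2 F_T)²` for `F_T < 1/2`, else 0;
- discrimination area `A^disc`: fraction of the admissible activity square
  `(F_T, 1)²` labeled `disc`, computed by uniform-grid integration
  (grid ≥ 200²; the admissible-square normalization is a reporting choice,
  the qualitative shape is normalization-independent).

Two structural results hold by construction and are verified exhaustively
in tests: the lower memory interval always ends below `F_min = 2 F_T`
(with equality only in the degenerate tangent case `D = 0`), and with
uniform inhibition (`θ_P = θ`) no activity pair ever classifies as
discrimination — the memory condition and the discrimination condition
contradict each other, which is why either predefined local disinhibition
(`θ_P < θ`) or inhibitory plasticity is needed.

**Three populations.** Pairwise label sets over products of per-population
activity intervals are computed by dense grid plus corner sampling (60²
per pair); all label boundaries are monotone curves, so sampling is exact
to grid resolution.

## What the generator emulates, and what not

The synthetic protocols reproduce the study conditions: noise-tuned
initialization near the balanced state, OU-driven stimulation with
population-specific means, all-to-all connectivity, rate coding. They do
not emulate spiking, sparse or structured connectivity, overlapping
assemblies, conduction delays, or stimulus timing structure beyond the OU
mean — so passing tests support the equilibrium-level claims (which weight
classes end above which inhibitory references) rather than any
spike-timing or transient-dynamics property of real circuits.

## Numerical choices and limitations

- Euler at `dt = 1 ms` is far inside the stability region of every
  timescale used (fastest: τ = 1 s; accelerated τ_w ≥ 0.12 s).
- Fixed-point polish tolerance 1e-10, duplicate merge 1e-6, nullcline
  bisection to 1e-10; 1-D nullclines are validated against brute-force
  sign scans at 10× resolution.
- The integer `n_ε` landmarks depend on the drive convention's constant;
  with the convention above the reconstructed boundaries are 9/15 (zero
  input) and 24/28 (maximal input) — the inflexion phenomenology is robust
  but individual integers shift by ±1–2 under nearby conventions, so tests
  assert them only within those margins.
- Reported stability is asymptotic (Jacobian eigenvalues of the reduced
  adiabatic system); stochastic switching between attractors under OU
  noise is not analyzed.
- The reduced model assumes within-population rate homogeneity; near label
  boundaries (within 0.02 in activity) finite-size fluctuations of the
  full network legitimately flip labels, and the agreement analysis
  excludes such cells.
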