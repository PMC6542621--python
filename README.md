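# memnet

Rate-based modelling of how recurrent networks form **memory
representations** and organize them into **discriminations, sequences, and
associations**, driven purely by the statistics of their inputs.

`memnet` is aimed at computational neuroscientists studying the interaction
of Hebbian plasticity with homeostatic synaptic scaling (and, optionally,
inhibitory synaptic plasticity). It provides:

- a full *n*-neuron recurrent network simulator (all-to-all, rate-coded,
  plastic excitatory synapses, Ornstein–Uhlenbeck external inputs),
- a reduced two-population equilibrium framework that replaces the
  *O(n²)*-dimensional problem by a two-dimensional fixed-point problem in
  the plane of population activities,
- analytic classification machinery: memory bounds, separatrices,
  regime measures, phase diagrams, and feasibility analysis for webs of
  three populations,
- a CLI (`memnet simulate | equilibrium | phase-input | phase-param |
  nepsilon-scan | area-disc | triple`).

## Model

Normalized rates `F_i ∈ (0,1)` (fractions of the maximal rate `F_max`) and
normalized weights `w_ij ∈ [0,1]` (fractions of the maximal weight
`ω_max = μ F_max² / (γ (F_max − F_T F_max))`) evolve as

    τ   dF_i/dt = (1−F_i) F_i [ ln(1/F_i − 1) + g_i − K n_ε (1−θ) ]
    τ_w dw_ij/dt = F_i F_j + (F_T − F_i)/(1 − F_T) · w_ij²

with the dimensionless drive
`g_i = K [ Σ_j (w_ij − w⁻_ij) F_j + Σ_k w_ex F_k^ex ]`, `K = β R ω_max`.
The weight rule combines a Hebbian correlation term with quadratic synaptic
scaling toward the target rate `F_T`; the sigmoid inflexion is counted in
units `n_ε` of the maximal single-synapse potential. Inhibitory weights
`w⁻` are constant (`θ`) or follow a gated rule attracted to an up-state
`θ_u` (uncorrelated or weakly active pairs) or down-state `θ_d`
(co-active, similar-rate pairs).

At clamped rates the plasticity rule has the closed-form equilibrium

    w(F_pre, F_post) = sqrt( F_pre F_post (1−F_T) / (F_post − F_T) ),

which is the backbone of the reduced model: comparing the implied
equilibrium weights with the inhibitory references labels every activity
pair `(𝔉₁, 𝔉₂)` as
`nm` (no memory), `disc`, `s12`/`s21` (sequence), `asc` (association), and
`bs` marks inputs with two or more stable fixed points.

## Worked example

Where does the system settle for folded population inputs
`(I₁, I₂) = (0.9, 0.4)` at default parameters?

```bash
memnet equilibrium --I1 0.9 --I2 0.4
```

```json
{
  "I1": 0.9, "I2": 0.4, "bistable": false,
  "points": [
    {
      "F1": 0.9814, "F2": 0.9106, "stable": true, "label": "asc",
      "w11": 0.9912, "w22": 0.9567, "w21": 0.9932, "w12": 0.9547
    }
  ]
}
```

Both populations settle at high rates; all four equilibrium weight classes
exceed the inhibitory baseline `θ = 0.5`, so the two memories are
**associated**. Scanning the sigmoid inflexion at zero input instead,

```python
import memnet as m
df = m.nepsilon_scan(m.build_parameters({}), m.InputPoint(0, 0), range(8, 18))
```

| n_eps | F1 (=F2) | label |
|------:|---------:|:------|
| 8     | 0.2132   | asc   |
| 9     | 0.1814   | nm    |
| 12    | 0.1155   | nm    |
| 13    | 0.1000   | nm    |
| 15    | 0.0754   | nm    |
| 16    | 0.0660   | asc   |

shows the three zero-input regimes: too-excitable neurons associate
input-independently (low `n_ε`), a no-memory band follows, and at high
`n_ε` low activities trigger scaling-driven (up-scaled) associations.
`n_ε ≈ 12–13` puts the resting activity right at the homeostatic boundary
`F_min = 2 F_T = 0.1`, which is the regime in which organizations are
input-driven.

Full-network runs use presets, e.g. the association-formation protocol
(tuning noise, then OU inputs with means 0.9/0.75):

```bash
memnet simulate --preset fig2 --seed 1 --accel 10 --out runs/fig2
```

`--accel 10` multiplies μ and γ by a common factor, contracting transients
without moving any equilibrium.

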