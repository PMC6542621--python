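"""Model parameters, derived constants, and validation.

The network couples rate-coded neurons through plastic excitatory synapses
(Hebbian correlation term plus homeostatic synaptic scaling toward a target
rate ``F_T``) and inhibitory synapses that are either constant or governed by
a gated up/down-state plasticity rule.  All rates are normalized to the
maximal firing rate ``F_max`` and all weights to the maximal excitatory
weight ``omega_max``, so the dynamical variables live in (0, 1).

Two conventions for the dimensionless synaptic drive are supported:

``"normalized"`` (default)
    g = K * [sum (w - w_inh) * F + external], with K = beta * R * omega_max.
    Normalized rates inside the drive absorb one factor of ``F_max``; the
    sigmoid inflexion enters as K * n_eps * (1 - theta).
``"literal"``
    the drive scale carries the extra factor ``F_max`` (kept for
    comparison; it produces a much steeper effective activation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

__all__ = [
    "InhibitoryPlasticity",
    "ModelParameters",
    "DerivedConstants",
    "build_parameters",
    "derive_constants",
    "validate",
    "accelerate",
]


@dataclass
class InhibitoryPlasticity:
    """Gated up/down-state rule for inhibitory weights.

    A synapse is attracted toward the up-state ``theta_u`` when the rate
    difference of its pre-/postsynaptic neurons exceeds the tolerance
    ``delta_F`` or their rate sum falls below ``theta_F``; toward the
    down-state ``theta_d`` when the sum is large and the difference small.
    """

    enabled: bool = False
    theta_u: float = 0.8
    theta_d: float = 0.5
    theta_F: float = 0.2  # 2 * F_min = 4 * F_T at the default target rate
    delta_F: float = 0.05
    rho_u: float = 1.0
    rho_d: float = 1.0


@dataclass
class ModelParameters:
    """Complete parameter set of the network model (normalized units)."""

    n: int = 100                 # total neurons
    n_P: int = 10                # neurons per stimulated population
    n_Pex: int = 10              # input neurons per population
    tau: float = 1.0             # membrane time constant [s]
    R: float = 0.1               # membrane resistance (enters via products)
    F_max: float = 100.0         # maximal firing rate [Hz]
    beta: float = 0.00035        # sigmoid steepness [1/mV]
    n_eps: float = 12            # sigmoid inflexion in units of u_max
    mu: float = 1.0 / 60.0       # Hebbian rate [1/s]
    gamma: float = 1.0 / 5400.0  # scaling rate [1/s]
    F_T: float = 0.05            # normalized target rate
    theta: float = 0.5           # normalized baseline inhibitory weight
    theta_P: Optional[float] = None  # within-population inhibitory weight
    w_ex: float = 1.0            # normalized external synapse weight
    ou_delta: float = 0.025      # OU drift constant (per 1 ms step)
    ou_sigma: float = 0.0125     # OU diffusion constant (per 1 ms step)
    dt: float = 1e-3             # integration step [s]
    drive_convention: str = "normalized"
    background_inhibition_corrected: bool = False
    inhibitory: InhibitoryPlasticity = field(default_factory=InhibitoryPlasticity)

    @property
    def theta_P_eff(self) -> float:
        """Within-population inhibitory weight, defaulting to ``theta``."""
        return self.theta if self.theta_P is None else self.theta_P

    @property
    def n_B(self) -> int:
        return self.n - 2 * self.n_P


@dataclass(frozen=True)
class DerivedConstants:
    """Scales derived from :class:`ModelParameters`.

    omega_max : maximal synaptic weight mu*F_max^2 / (gamma*(F_max - F_T*F_max))
    u_max     : maximal single-synapse-evoked potential R*omega_max*(1-theta)
    epsilon   : sigmoid inflexion n_eps * u_max
    F_min     : plasticity-dominance activity threshold 2*F_T
    K         : dimensionless drive constant
    tau_w     : weight-dynamics time constant 1/mu [s]
    """

    omega_max: float
    u_max: float
    epsilon: float
    F_min: float
    K: float
    tau_w: float


_CONFIG_ERROR_TEMPLATE = "invalid configuration: {}"


class ConfigurationError(ValueError):
    """A parameter value violates a model invariant."""


def validate(params: ModelParameters) -> list[str]:
    """Return a list of invariant violations (empty iff valid)."""
    v: list[str] = []
    if params.n <= 0:
        v.append("n must be positive")
    if params.n_P <= 0:
        v.append("n_P must be positive")
    if 2 * params.n_P > params.n:
        v.append("2·n_P exceeds n")
    if params.n_Pex <= 0:
        v.append("n_Pex must be positive")
    if not (0.0 < params.F_T < 1.0):
        v.append("F_T out of (0,1)")
    if not (0.0 < params.theta < 1.0):
        v.append("theta out of (0,1)")
    if params.theta_P is not None and not (0.0 < params.theta_P < 1.0):
        v.append("theta_P out of (0,1)")
    if not (params.mu > params.gamma > 0.0):
        v.append("requires mu > gamma > 0")
    if params.dt <= 0.0:
        v.append("dt must be positive")
    if params.tau <= 0.0:
        v.append("tau must be positive")
    if params.F_max <= 0.0:
        v.append("F_max must be positive")
    if params.beta <= 0.0:
        v.append("beta must be positive")
    if params.drive_convention not in ("normalized", "literal"):
        v.append("drive_convention must be 'normalized' or 'literal'")
    inh = params.inhibitory
    if inh.theta_d > inh.theta_u:
        v.append("requires theta_d <= theta_u")
    if inh.delta_F < 0.0 or inh.theta_F < 0.0:
        v.append("inhibitory gates must be non-negative")
    return v


_INH_FIELDS = {f.name for f in fields(InhibitoryPlasticity)}


def build_parameters(overrides: Optional[dict] = None) -> ModelParameters:
    """Build a validated parameter set from defaults plus ``overrides``.

    Keys of ``overrides`` must name :class:`ModelParameters` fields or
    inhibitory-plasticity fields (flat, e.g. ``{"theta_u": 0.8}``).
    Raises :class:`ConfigurationError` on unknown names or invariant
    violations.
    """
    params = ModelParameters()
    known = {f.name for f in fields(ModelParameters)}
    inh_overrides = {}
    theta_F_set = False
    for key, value in (overrides or {}).items():
        if key in _INH_FIELDS:
            inh_overrides[key] = value
            if key == "theta_F":
                theta_F_set = True
        elif key in known and key != "inhibitory":
            setattr(params, key, value)
        elif key == "inhibitory" and isinstance(value, dict):
            for k, val in value.items():
                if k not in _INH_FIELDS:
                    raise ConfigurationError(
                        _CONFIG_ERROR_TEMPLATE.format(f"unknown field '{k}'"))
                inh_overrides[k] = val
                if k == "theta_F":
                    theta_F_set = True
        else:
            raise ConfigurationError(
                _CONFIG_ERROR_TEMPLATE.format(f"unknown field '{key}'"))
    if inh_overrides:
        params.inhibitory = replace(params.inhibitory, **inh_overrides)
    # theta_F tracks 2*F_min = 4*F_T unless the user pinned it explicitly
    if not theta_F_set and params.F_T != 0.05:
        params.inhibitory = replace(params.inhibitory, theta_F=4.0 * params.F_T)
    violations = validate(params)
    if violations:
        raise ConfigurationError(_CONFIG_ERROR_TEMPLATE.format("; ".join(violations)))
    return params


def derive_constants(params: ModelParameters) -> DerivedConstants:
    """Compute the derived scales for a valid parameter set."""
    omega_max = (params.mu * params.F_max ** 2
                 / (params.gamma * (params.F_max - params.F_T * params.F_max)))
    scale = params.F_max if params.drive_convention == "literal" else 1.0
    u_max = params.R * omega_max * (1.0 - params.theta) * scale
    K = params.beta * params.R * omega_max * scale
    return DerivedConstants(
        omega_max=omega_max,
        u_max=u_max,
        epsilon=params.n_eps * u_max,
        F_min=2.0 * params.F_T,
        K=K,
        tau_w=1.0 / params.mu,
    )


def beta_epsilon(params: ModelParameters, consts: Optional[DerivedConstants] = None) -> float:
    """The constant K * n_eps * (1 - theta) entering the activity equation."""
    if consts is None:
        consts = derive_constants(params)
    return consts.K * params.n_eps * (1.0 - params.theta)


def accelerate(params: ModelParameters, factor: float) -> ModelParameters:
    """Speed up the synaptic timescales by a common factor.

    Multiplies ``mu`` and ``gamma`` by ``factor``; their ratio and hence
    ``omega_max`` and all equilibrium quantities are unchanged, only
    transients contract.  Used to shorten simulations.
    """
    if factor <= 0:
        raise ConfigurationError(_CONFIG_ERROR_TEMPLATE.format("factor must be positive"))
    out = replace(params, mu=params.mu * factor, gamma=params.gamma * factor)
    out.inhibitory = replace(params.inhibitory)
    return out
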