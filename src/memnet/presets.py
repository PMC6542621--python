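"""Run presets reproducing the study protocols.

Each preset bundles a parameter set and a stimulation protocol: a tuning
phase in which every neuron receives i.i.d. noise through its input pool,
followed (where applicable) by an Ornstein-Uhlenbeck stimulation phase with
per-population mean amplitudes.  Protocol durations are stated on the
baseline plasticity timescale (mu = 1/60 s^-1, so a protocol time unit of
1/mu = 60 s); passing ``accel`` speeds mu and gamma up by a common factor
and contracts the phase durations accordingly, which leaves all equilibria
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import ModelParameters, build_parameters, accelerate
from .network import Phase, StimulusProtocol

__all__ = ["RunSpec", "preset", "PRESET_NAMES"]

TUNING_DURATION = 600.0      # 10 protocol time units of 1/mu = 60 s
STIMULATION_MAX = 9000.0     # OU phase cap; equilibrium detection stops earlier


@dataclass(frozen=True)
class RunSpec:
    """Parameters plus protocol (plus sweep metadata for analysis presets)."""

    name: str
    params: ModelParameters
    protocol: Optional[StimulusProtocol] = None
    meta: dict = field(default_factory=dict)


def _sim_spec(name: str, n_eps: float, noise_mean: float,
              ou_means: tuple[float, float], accel: float,
              inhibitory_plasticity: bool) -> RunSpec:
    overrides: dict = {"n_eps": n_eps}
    if inhibitory_plasticity:
        overrides["enabled"] = True
    params = build_parameters(overrides)
    if accel != 1.0:
        params = accelerate(params, accel)
    protocol = StimulusProtocol(phases=(
        Phase(duration=TUNING_DURATION / accel, mode="noise",
              noise_mean=noise_mean, noise_sd=0.025),
        Phase(duration=STIMULATION_MAX / accel, mode="ou",
              noise_mean=noise_mean, noise_sd=0.025,
              ou_means=ou_means, stop_at_equilibrium=True),
    ))
    return RunSpec(name=name, params=params, protocol=protocol,
                   meta={"accel": accel})


def preset(name: str, accel: float = 1.0) -> RunSpec:
    """Build a named run specification.

    Known presets: ``fig2`` (association formation, n_eps=20, OU means
    0.9/0.75), ``fig3_grid`` (full-network input sweep at fig2 parameters),
    ``fig4_scan`` (inflexion-point scans at zero and maximal input),
    ``fig5_regimes`` (parameter-plane regime partition), ``fig6_areadisc``
    (discrimination-area sweep at theta=0.8), ``fig7`` (inhibitory
    plasticity, n_eps=12, OU means 0.85/0.7).
    """
    if name == "fig2":
        return _sim_spec("fig2", n_eps=20, noise_mean=0.25,
                         ou_means=(0.9, 0.75), accel=accel,
                         inhibitory_plasticity=False)
    if name == "fig7":
        return _sim_spec("fig7", n_eps=12, noise_mean=0.05,
                         ou_means=(0.85, 0.7), accel=accel,
                         inhibitory_plasticity=True)
    if name == "fig3_grid":
        spec = _sim_spec("fig3_grid", n_eps=20, noise_mean=0.25,
                         ou_means=(0.0, 0.0), accel=accel,
                         inhibitory_plasticity=False)
        grid = np.round(np.linspace(0.1, 0.9, 5), 3).tolist()
        return RunSpec(name=spec.name, params=spec.params,
                       protocol=spec.protocol,
                       meta={**spec.meta, "ou_mean_grid": grid})
    if name == "fig4_scan":
        params = build_parameters({})
        return RunSpec(name="fig4_scan", params=params,
                       meta={"inputs": [(0.0, 0.0), (1.0, 1.0)],
                             "n_eps_range": list(range(1, 33))})
    if name == "fig5_regimes":
        params = build_parameters({})
        return RunSpec(name="fig5_regimes", params=params,
                       meta={"F_T_grid": np.linspace(0.01, 0.49, 25).tolist(),
                             "theta_grid": np.linspace(0.05, 0.95, 25).tolist()})
    if name == "fig6_areadisc":
        params = build_parameters({"theta": 0.8})
        return RunSpec(name="fig6_areadisc", params=params,
                       meta={"theta_P_grid": np.linspace(0.1, 0.8, 15).tolist()})
    raise KeyError(f"unknown preset '{name}'")


PRESET_NAMES = ("fig2", "fig3_grid", "fig4_scan", "fig5_regimes",
                "fig6_areadisc", "fig7")
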