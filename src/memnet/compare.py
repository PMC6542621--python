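"""Reduced-model versus full-network comparison.

Runs the full simulator over a grid of stimulation amplitudes, folds each
run onto the population-input plane, and compares the end-state
organization label of the network against the label of the reduced model's
reachable fixed point.  Cells whose reduced fixed point lies close to a
label boundary (separatrix or memory-bound crossing) are flagged, since
there finite-size fluctuations legitimately flip the label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .params import ModelParameters
from .network import Phase, StimulusProtocol, simulate, build_layout, population_averages
from .organization import classify_weights, memory_bounds, separatrix
from .population import map_network_inputs, reachable_fixed_point

__all__ = ["boundary_distance", "reduced_full_grid"]


def boundary_distance(F1: float, F2: float, params: ModelParameters) -> float:
    """Distance of a rate pair to the nearest classification boundary."""
    th, thP, F_T = params.theta, params.theta_P_eff, params.F_T
    dists = [abs(F1 - separatrix(F2, th, F_T)),
             abs(F2 - separatrix(F1, th, F_T))]
    mb = memory_bounds(thP, F_T)
    if mb.exists:
        dists += [abs(F1 - mb.F_bar), abs(F1 - mb.F_underbar),
                  abs(F2 - mb.F_bar), abs(F2 - mb.F_underbar)]
    return min(dists)


def reduced_full_grid(params: ModelParameters, amplitudes: Sequence[float],
                      seed: int, tuning_duration: float,
                      stimulation_max: float, noise_mean: float = 0.05,
                      sample_every: float = 0.2,
                      boundary_tol: float = 0.02) -> pd.DataFrame:
    """Label agreement over the grid of OU mean-amplitude pairs.

    The fold onto the input plane uses the inhibition-corrected background
    term, which is the form consistent with the reduced model's derivation
    (the background's net drive enters through w - theta).
    """
    params_fold = replace(params, background_inhibition_corrected=True)
    layout = build_layout(params)
    rows = []
    for f1 in amplitudes:
        for f2 in amplitudes:
            protocol = StimulusProtocol(phases=(
                Phase(duration=tuning_duration, mode="noise",
                      noise_mean=noise_mean, noise_sd=0.025),
                Phase(duration=stimulation_max, mode="ou",
                      noise_mean=noise_mean, noise_sd=0.025,
                      ou_means=(f1, f2), stop_at_equilibrium=True),
            ))
            traj = simulate(protocol, params, seed, sample_every=sample_every)
            fin = population_averages(traj.final_state, layout)
            full_label = str(classify_weights(fin.w11, fin.w22, fin.w21,
                                              fin.w12, params.theta))
            inp = map_network_inputs(f1, f2, fin.FB, (fin.w1B, fin.w2B),
                                     params_fold)
            red = reachable_fixed_point(inp, params)
            rows.append({
                "F1ex": f1, "F2ex": f2, "I1": inp.I1, "I2": inp.I2,
                "full_label": full_label, "reduced_label": str(red.label),
                "F1_full": fin.F1, "F2_full": fin.F2,
                "F1_reduced": red.F1, "F2_reduced": red.F2,
                "near_boundary": boundary_distance(red.F1, red.F2, params)
                < boundary_tol,
                "match": full_label == str(red.label),
            })
    return pd.DataFrame(rows)
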