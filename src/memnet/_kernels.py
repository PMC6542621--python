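"""Compiled inner loop of the Euler integration.

The kernel advances the full network by a chunk of steps with pre-drawn
noise, updating all state arrays in place.  It implements exactly the same
simultaneous explicit-Euler scheme as :func:`memnet.network.step`
(asserted by an equivalence test); it exists only to make long protocols
cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_chunk"]


@njit(cache=True)
def run_chunk(F, W, W_inh, F_ex,
              ext_noise, ou_z, ou_target1, ou_target2, mode_ou,
              n_P, K, beta_eps, tau, tau_w, F_T, dt, w_ex,
              inh_on, theta_u, theta_d, theta_F, delta_F, rho_u, rho_d,
              ou_drift, ou_sd):  # pragma: no cover - exercised via simulate
    steps = ext_noise.shape[0]
    n = F.shape[0]
    n2P = 2 * n_P
    dF = np.empty(n)
    q = 1.0 - F_T
    for s in range(steps):
        if mode_ou:
            e1 = w_ex * F_ex[0].sum()
            e2 = w_ex * F_ex[1].sum()
        else:
            e1 = 0.0
            e2 = 0.0
        # drive and activity derivative from the pre-step state
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += (W[i, j] - W_inh[i, j]) * F[j]
            if mode_ou:
                if i < n_P:
                    acc += e1
                elif i < n2P:
                    acc += e2
                else:
                    acc += ext_noise[s, i - n2P]
            else:
                acc += ext_noise[s, i]
            g = K * acc
            dF[i] = ((1.0 - F[i]) * F[i]
                     * (np.log(1.0 / F[i] - 1.0) + g - beta_eps) / tau)
        # excitatory weights (pre-step rates), floored at zero
        for i in range(n):
            sc = (F_T - F[i]) / q
            Fi = F[i]
            for j in range(n):
                w = W[i, j] + dt * (Fi * F[j] + sc * W[i, j] * W[i, j]) / tau_w
                W[i, j] = w if w > 0.0 else 0.0
        if inh_on:
            for i in range(n):
                Fi = F[i]
                for j in range(n):
                    Fj = F[j]
                    ssum = Fi + Fj
                    diff = Fi - Fj if Fi >= Fj else Fj - Fi
                    drift = 0.0
                    if diff > delta_F or ssum < theta_F:
                        drift = rho_u * (theta_u - W_inh[i, j])
                    elif diff < delta_F and ssum > theta_F:
                        drift = rho_d * (theta_d - W_inh[i, j])
                    W_inh[i, j] += dt * Fi * Fj * drift / tau_w
        if mode_ou:
            for k in range(F_ex.shape[1]):
                v1 = (F_ex[0, k] + ou_drift * (ou_target1 - F_ex[0, k])
                      + ou_sd * ou_z[s, 0, k])
                v2 = (F_ex[1, k] + ou_drift * (ou_target2 - F_ex[1, k])
                      + ou_sd * ou_z[s, 1, k])
                F_ex[0, k] = min(max(v1, 0.0), 1.0)
                F_ex[1, k] = min(max(v2, 0.0), 1.0)
        for i in range(n):
            f = F[i] + dt * dF[i]
            F[i] = min(max(f, 1e-6), 1.0 - 1e-6)
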