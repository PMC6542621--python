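"""Full recurrent-network simulation.

Explicit-Euler integration of the normalized rate dynamics

    tau * dF_i/dt = (1 - F_i) * F_i * [ln(1/F_i - 1) + g_i - K*n_eps*(1-theta)]

with dimensionless drive ``g_i = K * [sum_j (w_ij - w^inh_ij) F_j + ext_i]``,
of the excitatory weight dynamics (Hebbian term + synaptic scaling)

    tau_w * dw_ij/dt = F_i F_j + (F_T - F_i) / (1 - F_T) * w_ij^2

and, optionally, of the gated up/down-state inhibitory plasticity rule.
External input arrives through per-population pools of input neurons that
fire i.i.d. noise during a tuning phase and follow Ornstein-Uhlenbeck
processes during stimulation.  All updates are fully simultaneous (all
derivatives evaluated on the pre-step state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .params import ModelParameters, DerivedConstants, derive_constants, beta_epsilon

__all__ = [
    "PopulationLayout",
    "NetworkState",
    "Phase",
    "StimulusProtocol",
    "PopulationAverages",
    "Trajectory",
    "build_layout",
    "init_state",
    "ou_step",
    "total_drive",
    "activity_derivative",
    "exc_weight_derivative",
    "inh_weight_derivative",
    "step",
    "population_averages",
    "equilibrium_reached",
    "simulate",
]

F_CLIP_LO = 1e-6
F_CLIP_HI = 1.0 - 1e-6

AVERAGE_COLUMNS = ["t", "F1", "F2", "FB", "w11", "w22", "w21", "w12",
                   "wB_mean", "inh_11", "inh_22", "inh_12", "inh_21"]


@dataclass(frozen=True)
class PopulationLayout:
    """Index sets of the two stimulated populations and the background."""

    pop1: np.ndarray
    pop2: np.ndarray
    background: np.ndarray
    n_Pex: int

    def members(self, p: int) -> np.ndarray:
        return (self.pop1, self.pop2)[p - 1]


@dataclass
class NetworkState:
    """Instantaneous state of the network."""

    t: float
    F: np.ndarray        # normalized rates, shape (n,)
    W: np.ndarray        # excitatory weights, (n, n), row = postsynaptic
    W_inh: np.ndarray    # inhibitory weights, (n, n)
    F_ex: np.ndarray     # OU input-neuron rates, (2, n_Pex)


@dataclass(frozen=True)
class Phase:
    """One stimulation-protocol phase.

    ``mode="noise"``: every network neuron receives i.i.d. Gaussian noise
    input through its pool of ``n_Pex`` input neurons (redrawn each step).
    ``mode="ou"``: the two stimulated populations receive OU-process input
    with per-population means; background neurons keep the noise drive.
    """

    duration: float
    mode: Literal["noise", "ou"]
    noise_mean: float = 0.05
    noise_sd: float = 0.025
    ou_means: tuple[float, float] = (0.0, 0.0)
    stop_at_equilibrium: bool = False


@dataclass(frozen=True)
class StimulusProtocol:
    phases: tuple[Phase, ...]

    def __post_init__(self):
        if any(p.duration < 0 for p in self.phases):
            raise ValueError("phase durations must be non-negative")


@dataclass(frozen=True)
class PopulationAverages:
    """Population-averaged rates and class-mean weights at one instant."""

    t: float
    F1: float
    F2: float
    FB: float
    w11: float
    w22: float
    w21: float   # pre in 1, post in 2
    w12: float
    w1B: float   # background -> population 1
    w2B: float
    inh_11: float
    inh_22: float
    inh_12: float  # pre in 2, post in 1
    inh_21: float

    def row(self) -> list[float]:
        return [self.t, self.F1, self.F2, self.FB, self.w11, self.w22,
                self.w21, self.w12, 0.5 * (self.w1B + self.w2B),
                self.inh_11, self.inh_22, self.inh_12, self.inh_21]


@dataclass
class Trajectory:
    """Sampled population averages plus the final microscopic state."""

    table: pd.DataFrame
    final_state: NetworkState
    seed: int
    params: ModelParameters
    protocol: StimulusProtocol

    @property
    def times(self) -> np.ndarray:
        return self.table["t"].to_numpy()

    def final_averages(self, layout: PopulationLayout) -> PopulationAverages:
        return population_averages(self.final_state, layout)


def build_layout(params: ModelParameters) -> PopulationLayout:
    """Contiguous index blocks: population 1, population 2, background."""
    n, n_P = params.n, params.n_P
    return PopulationLayout(
        pop1=np.arange(0, n_P),
        pop2=np.arange(n_P, 2 * n_P),
        background=np.arange(2 * n_P, n),
        n_Pex=params.n_Pex,
    )


def init_state(params: ModelParameters, layout: PopulationLayout,
               rng: np.random.Generator, weight_sd: float = 0.025,
               rate_mean: float = 0.07, rate_sd: float = 0.005) -> NetworkState:
    """Draw the initial state around the balanced configuration.

    Weights start near the inhibitory baseline, w ~ N(theta, weight_sd)
    floored at 0; rates near F ~ N(rate_mean, rate_sd); OU input-neuron
    rates are set to their target means when the first OU phase begins
    (initialized to 0 here).
    """
    n = params.n
    W = rng.normal(params.theta, weight_sd, size=(n, n))
    np.maximum(W, 0.0, out=W)
    F = np.clip(rng.normal(rate_mean, rate_sd, size=n), 0.001, 0.999)
    inh = params.inhibitory
    if inh.enabled:
        W_inh = np.clip(rng.normal(params.theta, weight_sd, size=(n, n)),
                        inh.theta_d, inh.theta_u)
    else:
        W_inh = np.full((n, n), params.theta)
    F_ex = np.zeros((2, layout.n_Pex))
    return NetworkState(t=0.0, F=F, W=W, W_inh=W_inh, F_ex=F_ex)


OU_DT0 = 1e-3  # reference step [s] at which (ou_delta, ou_sigma) are stated


def ou_step(F_ex: np.ndarray, targets: Sequence[float],
            params: ModelParameters, rng: np.random.Generator,
            dt: Optional[float] = None) -> np.ndarray:
    """One Euler-Maruyama step of the input-neuron OU processes.

    The drift/diffusion constants are per 1-ms reference step, so the update
    is F += delta*(target-F)*(dt/dt0) + sigma*sqrt(dt/dt0)*N(0,1), clipped
    to [0, 1].
    """
    dt = params.dt if dt is None else dt
    ratio = dt / OU_DT0
    t = np.asarray(targets, dtype=float).reshape(-1, 1)
    out = (F_ex + params.ou_delta * (t - F_ex) * ratio
           + params.ou_sigma * math.sqrt(ratio) * rng.standard_normal(F_ex.shape))
    return np.clip(out, 0.0, 1.0)


def external_drive(state: NetworkState, phase: Phase, params: ModelParameters,
                   layout: PopulationLayout, rng: np.random.Generator) -> np.ndarray:
    """Summed input-pool rates (times w_ex) per network neuron."""
    n = params.n
    ext = np.empty(n)
    if phase.mode == "noise":
        pools = np.clip(rng.normal(phase.noise_mean, phase.noise_sd,
                                   size=(n, layout.n_Pex)), 0.0, 1.0)
        ext[:] = params.w_ex * pools.sum(axis=1)
    else:
        ext[layout.pop1] = params.w_ex * state.F_ex[0].sum()
        ext[layout.pop2] = params.w_ex * state.F_ex[1].sum()
        nB = layout.background.size
        if nB:
            pools = np.clip(rng.normal(phase.noise_mean, phase.noise_sd,
                                       size=(nB, layout.n_Pex)), 0.0, 1.0)
            ext[layout.background] = params.w_ex * pools.sum(axis=1)
    return ext


def total_drive(state: NetworkState, params: ModelParameters,
                consts: DerivedConstants, ext: Optional[np.ndarray] = None) -> np.ndarray:
    """Dimensionless drive g_i = K * [(W - W_inh) @ F + ext]."""
    rec = (state.W - state.W_inh) @ state.F
    if ext is not None:
        rec = rec + ext
    return consts.K * rec


def activity_derivative(F: np.ndarray, g: np.ndarray,
                        params: ModelParameters,
                        consts: Optional[DerivedConstants] = None) -> np.ndarray:
    """dF/dt of the normalized rate equation."""
    if not np.all(np.isfinite(F)):
        raise FloatingPointError("non-finite rates in activity_derivative")
    be = beta_epsilon(params, consts)
    return (1.0 / params.tau) * (1.0 - F) * F * (np.log(1.0 / F - 1.0) + g - be)


def exc_weight_derivative(F: np.ndarray, W: np.ndarray,
                          params: ModelParameters,
                          consts: DerivedConstants) -> np.ndarray:
    """dW/dt: Hebbian outer product plus quadratic synaptic scaling."""
    scaling = ((params.F_T - F) / (1.0 - params.F_T))[:, None] * W ** 2
    return (np.outer(F, F) + scaling) / consts.tau_w


def inh_weight_derivative(F: np.ndarray, W_inh: np.ndarray,
                          params: ModelParameters,
                          consts: DerivedConstants) -> np.ndarray:
    """Gated drift of inhibitory weights toward the up-/down-state.

    Up-state gate: rate difference above tolerance OR rate sum below
    threshold; down-state gate: difference below tolerance AND sum above
    threshold.  Exact-equality boundaries activate neither branch.
    """
    inh = params.inhibitory
    S = F[:, None] + F[None, :]
    D = np.abs(F[:, None] - F[None, :])
    up = (D > inh.delta_F) | (S < inh.theta_F)
    down = (D < inh.delta_F) & (S > inh.theta_F)
    gain = np.outer(F, F) / consts.tau_w
    return gain * (inh.rho_u * (inh.theta_u - W_inh) * up
                   + inh.rho_d * (inh.theta_d - W_inh) * down)


def step(state: NetworkState, phase: Phase, params: ModelParameters,
         consts: DerivedConstants, layout: PopulationLayout,
         rng: np.random.Generator) -> NetworkState:
    """One simultaneous explicit-Euler step of the full system."""
    dt = params.dt
    ext = external_drive(state, phase, params, layout, rng)
    g = total_drive(state, params, consts, ext)
    dF = activity_derivative(state.F, g, params, consts)
    dW = exc_weight_derivative(state.F, state.W, params, consts)
    F = np.clip(state.F + dt * dF, F_CLIP_LO, F_CLIP_HI)
    W = np.maximum(state.W + dt * dW, 0.0)
    if params.inhibitory.enabled:
        dWi = inh_weight_derivative(state.F, state.W_inh, params, consts)
        W_inh = state.W_inh + dt * dWi
    else:
        W_inh = state.W_inh
    if phase.mode == "ou":
        F_ex = ou_step(state.F_ex, phase.ou_means, params, rng, dt)
    else:
        F_ex = state.F_ex
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(W))):
        raise FloatingPointError(f"non-finite state at t={state.t + dt:.3f}")
    return NetworkState(t=state.t + dt, F=F, W=W, W_inh=W_inh, F_ex=F_ex)


def _class_mean(M: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> float:
    return float(M[np.ix_(rows, cols)].mean())


def population_averages(state: NetworkState, layout: PopulationLayout) -> PopulationAverages:
    """Arithmetic class means over the population index blocks.

    Intra-population means run over all ordered pairs including autapses,
    matching the definition of the within-population inhibitory average.
    """
    p1, p2, B = layout.pop1, layout.pop2, layout.background
    FB = float(state.F[B].mean()) if B.size else float("nan")
    wB1 = _class_mean(state.W, p1, B) if B.size else float("nan")
    wB2 = _class_mean(state.W, p2, B) if B.size else float("nan")
    return PopulationAverages(
        t=state.t,
        F1=float(state.F[p1].mean()),
        F2=float(state.F[p2].mean()),
        FB=FB,
        w11=_class_mean(state.W, p1, p1),
        w22=_class_mean(state.W, p2, p2),
        w21=_class_mean(state.W, p2, p1),
        w12=_class_mean(state.W, p1, p2),
        w1B=wB1,
        w2B=wB2,
        inh_11=_class_mean(state.W_inh, p1, p1),
        inh_22=_class_mean(state.W_inh, p2, p2),
        inh_12=_class_mean(state.W_inh, p1, p2),
        inh_21=_class_mean(state.W_inh, p2, p1),
    )


WEIGHT_CLASS_COLUMNS = ["w11", "w22", "w21", "w12", "wB_mean",
                        "inh_11", "inh_22", "inh_12", "inh_21"]


def equilibrium_reached(times: np.ndarray, weights: np.ndarray,
                        window: float = 100.0, tol: float = 1e-5,
                        blocks: int = 10) -> bool:
    """True iff all class-weight series drift slower than ``tol`` per second
    over the trailing ``window`` seconds.

    ``weights`` has one column per class-mean series.  To judge the slow
    drift rather than the stochastic wiggle that the OU input imprints on
    the class means, the windowed samples are averaged into ``blocks``
    equal time blocks before taking finite differences (block averaging
    preserves any systematic slope).  Raises on an empty window; returns
    False while the sampled span is still shorter than the window.
    """
    times = np.asarray(times, dtype=float)
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if times.size == 0:
        raise ValueError("empty trajectory window")
    if times[-1] - times[0] < window:
        return False
    mask = times >= times[-1] - window
    t = times[mask]
    w = weights[mask]
    if t.size < 2:
        return False
    if t.size >= 2 * blocks:
        edges = np.linspace(t[0], t[-1], blocks + 1)
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, blocks - 1)
        t = np.array([t[idx == b].mean() for b in range(blocks)])
        w = np.array([w[idx == b].mean(axis=0) for b in range(blocks)])
    rates = np.abs(np.diff(w, axis=0) / np.diff(t)[:, None])
    rates = rates[:, ~np.all(np.isnan(rates), axis=0)]  # drop empty-class NaNs
    if rates.size == 0:
        return True
    return bool(np.max(rates) < tol)


def _draw_chunk_noise(phase: Phase, chunk: int, n_targets: int,
                      params: ModelParameters,
                      rng: np.random.Generator) -> np.ndarray:
    """Summed (clipped) input-pool noise, already scaled by w_ex."""
    pools = rng.normal(phase.noise_mean, phase.noise_sd,
                       size=(chunk, n_targets, params.n_Pex))
    np.clip(pools, 0.0, 1.0, out=pools)
    return params.w_ex * pools.sum(axis=2)


def simulate(protocol: StimulusProtocol, params: ModelParameters, seed: int,
             sample_every: float = 1.0,
             eq_window: Optional[float] = None,
             eq_tol: Optional[float] = None,
             use_kernel: bool = True) -> Trajectory:
    """Run the protocol phases in order and sample population averages.

    Three independent RNG streams (initialization, tuning noise, OU inputs)
    are spawned from the master seed.  An OU phase flagged
    ``stop_at_equilibrium`` terminates early once the class-mean weights
    drift slower than ``eq_tol`` per second over ``eq_window`` seconds;
    defaults scale with the synaptic rate ``mu`` so that accelerated runs
    use an equivalently strict criterion.

    ``use_kernel`` selects the compiled chunked integrator; the pure-numpy
    :func:`step` path implements the identical scheme and is kept for
    reference and cross-checking.
    """
    layout = build_layout(params)
    consts = derive_constants(params)
    rng_init, rng_noise, rng_ou = [np.random.default_rng(s)
                                   for s in np.random.SeedSequence(seed).spawn(3)]
    # scale the equilibrium criterion with the plasticity timescale
    # (baseline mu = 1/60 s^-1 -> window 100 s, tol 1e-5 /s)
    speed = params.mu * 60.0
    if eq_window is None:
        eq_window = 100.0 / speed
    if eq_tol is None:
        eq_tol = 1e-5 * speed

    state = init_state(params, layout, rng_init)
    rows: list[list[float]] = []
    sampled_t: list[float] = []
    sampled_w: list[list[float]] = []

    def sample(st: NetworkState):
        avg = population_averages(st, layout)
        r = avg.row()
        rows.append(r)
        sampled_t.append(st.t)
        sampled_w.append(r[4:])  # weight-class columns

    def at_equilibrium(phase_start: int) -> bool:
        return (sampled_t[-1] - sampled_t[phase_start] >= eq_window
                and equilibrium_reached(np.array(sampled_t[phase_start:]),
                                        np.array(sampled_w[phase_start:]),
                                        eq_window, eq_tol))

    sample(state)
    inh = params.inhibitory
    be = beta_epsilon(params, consts)
    ratio = params.dt / OU_DT0
    for phase in protocol.phases:
        if phase.mode == "ou":
            state.F_ex = np.tile(np.asarray(phase.ou_means, dtype=float)[:, None],
                                 (1, layout.n_Pex))
        n_steps = int(round(phase.duration / params.dt))
        stride = max(1, int(round(sample_every / params.dt)))
        phase_start = len(sampled_t)  # equilibrium judged on this phase only
        if not use_kernel:
            rng = rng_ou if phase.mode == "ou" else rng_noise
            for k in range(n_steps):
                state = step(state, phase, params, consts, layout, rng)
                if (k + 1) % stride == 0 or k == n_steps - 1:
                    sample(state)
                    if phase.stop_at_equilibrium and at_equilibrium(phase_start):
                        break
            continue
        from ._kernels import run_chunk
        mode_ou = phase.mode == "ou"
        done = 0
        while done < n_steps:
            chunk = min(stride, n_steps - done)
            if mode_ou:
                ext = _draw_chunk_noise(phase, chunk, layout.background.size,
                                        params, rng_noise)
                ou_z = rng_ou.standard_normal((chunk, 2, layout.n_Pex))
            else:
                ext = _draw_chunk_noise(phase, chunk, params.n, params, rng_noise)
                ou_z = np.zeros((1, 2, layout.n_Pex))
            run_chunk(state.F, state.W, state.W_inh, state.F_ex,
                      ext, ou_z, phase.ou_means[0], phase.ou_means[1], mode_ou,
                      params.n_P, consts.K, be, params.tau, consts.tau_w,
                      params.F_T, params.dt, params.w_ex,
                      inh.enabled, inh.theta_u, inh.theta_d, inh.theta_F,
                      inh.delta_F, inh.rho_u, inh.rho_d,
                      params.ou_delta * ratio,
                      params.ou_sigma * math.sqrt(ratio))
            done += chunk
            state.t += chunk * params.dt
            if not (np.all(np.isfinite(state.F)) and np.all(np.isfinite(state.W))):
                raise FloatingPointError(f"non-finite state at t={state.t:.3f}")
            sample(state)
            if phase.stop_at_equilibrium and at_equilibrium(phase_start):
                break
    table = pd.DataFrame(rows, columns=AVERAGE_COLUMNS)
    return Trajectory(table=table, final_state=state, seed=seed,
                      params=params, protocol=protocol)
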