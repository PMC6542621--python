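"""Reduced two-population equilibrium framework.

Because every neuron of a stimulated population sees the same input
statistics and the network is all-to-all, the population can be described by
its mean rate F_p at equilibrium.  Slow weights are eliminated
adiabatically: each class-mean excitatory weight is slaved to the rates via
the closed-form equilibrium of the plasticity rule,

    w(F_pre, F_post) = sqrt(F_pre * F_post * (1 - F_T) / (F_post - F_T)),

which exists only for postsynaptic rates above the target rate F_T.  The
remaining two-dimensional fixed-point problem

    ln(1/F_p - 1) + g_p(F_1, F_2; I_p) - K * n_eps * (1 - theta) = 0

is solved over the (F_1, F_2) plane for a folded input point (I_1, I_2);
the background population is folded into the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from skimage import measure

from .params import ModelParameters, derive_constants, beta_epsilon

__all__ = [
    "DomainError",
    "InputPoint",
    "EquilibriumPoint",
    "FixedPointSet",
    "weight_equilibrium",
    "population_drive",
    "residual",
    "nullcline",
    "find_fixed_points",
    "reachable_fixed_point",
    "map_network_inputs",
]


class DomainError(ValueError):
    """No synaptic fixed point exists below the target rate."""


@dataclass(frozen=True)
class InputPoint:
    """Folded population inputs (external drive plus background term)."""

    I1: float
    I2: float

    def __post_init__(self):
        if not (math.isfinite(self.I1) and math.isfinite(self.I2)):
            raise ValueError("inputs must be finite")
        if self.I1 < 0 or self.I2 < 0:
            raise ValueError("inputs must be non-negative")


@dataclass(frozen=True)
class EquilibriumPoint:
    """A fixed point of the reduced activity system with implied weights."""

    F1: float
    F2: float
    w11: float
    w22: float
    w21: float
    w12: float
    stable: bool
    label: str
    converged: bool = True

    @property
    def rates(self) -> tuple[float, float]:
        return (self.F1, self.F2)


@dataclass(frozen=True)
class FixedPointSet:
    points: tuple[EquilibriumPoint, ...]
    input: InputPoint

    @property
    def stable_points(self) -> tuple[EquilibriumPoint, ...]:
        return tuple(p for p in self.points if p.stable)

    @property
    def bistable(self) -> bool:
        return len(self.stable_points) >= 2


def weight_equilibrium(F_pre: float, F_post: float, F_T: float) -> float:
    """Equilibrium class-mean excitatory weight at clamped rates.

    Root of the plasticity rule F_pre*F_post + (F_T-F_post)/(1-F_T)*w^2 = 0;
    requires F_post > F_T (below the target rate scaling only up-regulates
    and no fixed point exists).
    """
    if F_post <= F_T:
        raise DomainError("no fixed point below the target rate")
    return math.sqrt(F_pre * F_post * (1.0 - F_T) / (F_post - F_T))


def population_drive(F1: float, F2: float, inp: InputPoint,
                     params: ModelParameters) -> tuple[float, float]:
    """Dimensionless drives (g_1, g_2) with adiabatically slaved weights.

    g_p = K * n_P * [I_p + sum_p' (w_{p,p'} - theta_eff) * F_p'], where the
    inhibitory reference is the within-population value theta_P for p'=p and
    the baseline theta otherwise.
    """
    K = derive_constants(params).K
    F_T = params.F_T
    th, thP = params.theta, params.theta_P_eff
    w11 = weight_equilibrium(F1, F1, F_T)
    w22 = weight_equilibrium(F2, F2, F_T)
    w12 = weight_equilibrium(F2, F1, F_T)  # post 1, pre 2
    w21 = weight_equilibrium(F1, F2, F_T)  # post 2, pre 1
    g1 = K * params.n_P * (inp.I1 + (w11 - thP) * F1 + (w12 - th) * F2)
    g2 = K * params.n_P * (inp.I2 + (w21 - th) * F1 + (w22 - thP) * F2)
    return g1, g2


def residual(F_p: float, F_other: float, I_p: float,
             params: ModelParameters, which: int = 1) -> float:
    """Value of the nontrivial fixed-point factor for population ``which``.

    Zero at an interior equilibrium; the boundary roots of the (1-F)F
    prefactor at 0 and 1 are not equilibria of the weight-coupled system.
    """
    if which == 1:
        inp = InputPoint(I_p, 0.0)
        g, _ = population_drive(F_p, F_other, inp, params)
    else:
        inp = InputPoint(0.0, I_p)
        _, g = population_drive(F_other, F_p, inp, params)
    return math.log(1.0 / F_p - 1.0) + g - beta_epsilon(params)


def nullcline(F_other: float, I_p: float, params: ModelParameters,
              grid_n: int = 400, which: int = 1) -> list[float]:
    """All roots F_p of the residual at fixed other-population rate.

    Sign-change bracketing on a uniform grid over (F_T, 1), refined by
    bisection to 1e-10.
    """
    if grid_n < 100:
        raise ValueError("grid_n must be at least 100")
    lo, hi = params.F_T + 1e-6, 1.0 - 1e-6
    grid = np.linspace(lo, hi, grid_n)
    vals = np.array([residual(f, F_other, I_p, params, which) for f in grid])
    roots = []
    for i in range(grid_n - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(optimize.brentq(
                residual, grid[i], grid[i + 1],
                args=(F_other, I_p, params, which), xtol=1e-12, rtol=8.9e-16))
    return roots


def _residual_vec(F1: float, F2: float, inp: InputPoint,
                  params: ModelParameters, be: float, K_nP: float,
                  th: float, thP: float, F_T: float) -> tuple[float, float]:
    # scalar fast path used by the finder and the reachability integrator
    q = 1.0 - F_T
    w11 = math.sqrt(F1 * F1 * q / (F1 - F_T))
    w22 = math.sqrt(F2 * F2 * q / (F2 - F_T))
    w12 = math.sqrt(F2 * F1 * q / (F1 - F_T))
    w21 = math.sqrt(F1 * F2 * q / (F2 - F_T))
    g1 = K_nP * (inp.I1 + (w11 - thP) * F1 + (w12 - th) * F2)
    g2 = K_nP * (inp.I2 + (w21 - th) * F1 + (w22 - thP) * F2)
    return (math.log(1.0 / F1 - 1.0) + g1 - be,
            math.log(1.0 / F2 - 1.0) + g2 - be)


def _solver_context(params: ModelParameters):
    consts = derive_constants(params)
    return (beta_epsilon(params, consts), consts.K * params.n_P,
            params.theta, params.theta_P_eff, params.F_T)


def _adiabatic_rhs(F1, F2, inp, params, ctx):
    r1, r2 = _residual_vec(F1, F2, inp, params, *ctx)
    return ((1.0 - F1) * F1 * r1, (1.0 - F2) * F2 * r2)


def _stability(F1: float, F2: float, inp: InputPoint,
               params: ModelParameters, ctx, h: float = 1e-7) -> bool:
    lo, hi = ctx[4] + 1e-9, 1.0 - 1e-9
    F1 = min(max(F1, lo + h), hi - h)
    F2 = min(max(F2, lo + h), hi - h)
    J = np.zeros((2, 2))
    for k, (d1, d2) in enumerate(((h, 0.0), (0.0, h))):
        fp = _adiabatic_rhs(F1 + d1, F2 + d2, inp, params, ctx)
        fm = _adiabatic_rhs(F1 - d1, F2 - d2, inp, params, ctx)
        J[:, k] = [(fp[0] - fm[0]) / (2 * h), (fp[1] - fm[1]) / (2 * h)]
    return bool(np.all(np.real(np.linalg.eigvals(J)) < 0.0))


def _segment_intersection(p1, p2, p3, p4):
    d1, d2 = p2 - p1, p4 - p3
    den = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(den) < 1e-14:
        return None
    t = ((p3[0] - p1[0]) * d2[1] - (p3[1] - p1[1]) * d2[0]) / den
    u = ((p3[0] - p1[0]) * d1[1] - (p3[1] - p1[1]) * d1[0]) / den
    if 0.0 <= t <= 1.0 and 0.0 <= u <= 1.0:
        return p1 + t * d1
    return None


def find_fixed_points(inp: InputPoint, params: ModelParameters,
                      grid_n: int = 200, merge_tol: float = 1e-6) -> FixedPointSet:
    """Locate all interior fixed points over the (F_1, F_2) plane.

    The zero level sets of both residual surfaces are traced by marching
    squares on a ``grid_n`` x ``grid_n`` grid; candidate nullcline
    intersections (pairwise segment crossings) are polished by Newton
    iteration, deduplicated, stability-classified from the Jacobian of the
    adiabatic activity dynamics, and labeled by the weight-based
    organization rules.
    """
    from .organization import classify_activities  # deferred: cyclic import

    ctx = _solver_context(params)
    lo, hi = params.F_T + 1e-4, 1.0 - 1e-4
    grid = np.linspace(lo, hi, grid_n)
    F1g, F2g = np.meshgrid(grid, grid, indexing="ij")
    q = 1.0 - params.F_T
    with np.errstate(all="ignore"):
        w11 = np.sqrt(F1g * F1g * q / (F1g - params.F_T))
        w22 = np.sqrt(F2g * F2g * q / (F2g - params.F_T))
        w12 = np.sqrt(F2g * F1g * q / (F1g - params.F_T))
        w21 = np.sqrt(F1g * F2g * q / (F2g - params.F_T))
        be, K_nP, th, thP, F_T = ctx
        g1 = K_nP * (inp.I1 + (w11 - thP) * F1g + (w12 - th) * F2g)
        g2 = K_nP * (inp.I2 + (w21 - th) * F1g + (w22 - thP) * F2g)
        R1 = np.log(1.0 / F1g - 1.0) + g1 - be
        R2 = np.log(1.0 / F2g - 1.0) + g2 - be
    scale = (hi - lo) / (grid_n - 1)
    c1 = measure.find_contours(R1, 0.0)
    c2 = measure.find_contours(R2, 0.0)
    candidates = []
    for a in c1:
        A = lo + a * scale
        for b in c2:
            B = lo + b * scale
            for i in range(len(A) - 1):
                near = np.hypot(B[:, 0] - A[i, 0], B[:, 1] - A[i, 1])
                if near.min() > 3 * scale:
                    continue
            # only scan segment pairs in proximity of this vertex
                for j in np.flatnonzero(near[:-1] < 3 * scale):
                    p = _segment_intersection(A[i], A[i + 1], B[j], B[j + 1])
                    if p is not None:
                        candidates.append(p)
    points: list[EquilibriumPoint] = []
    seen: list[np.ndarray] = []

    def fun(x):
        return _residual_vec(
            float(np.clip(x[0], F_T + 1e-9, 1 - 1e-9)),
            float(np.clip(x[1], F_T + 1e-9, 1 - 1e-9)), inp, params, *ctx)

    for c in candidates:
        sol = optimize.root(fun, c, method="hybr")
        x = sol.x
        ok = (sol.success and np.max(np.abs(sol.fun)) < 1e-10
              and F_T < x[0] < 1.0 and F_T < x[1] < 1.0)
        if not ok:
            x = c  # keep the unpolished candidate, flagged below
        if any(np.hypot(x[0] - s[0], x[1] - s[1]) < merge_tol for s in seen):
            continue
        seen.append(np.array(x, dtype=float))
        F1, F2 = float(x[0]), float(x[1])
        points.append(EquilibriumPoint(
            F1=F1, F2=F2,
            w11=weight_equilibrium(F1, F1, F_T),
            w22=weight_equilibrium(F2, F2, F_T),
            w21=weight_equilibrium(F1, F2, F_T),
            w12=weight_equilibrium(F2, F1, F_T),
            stable=_stability(F1, F2, inp, params, ctx) if ok else False,
            label=classify_activities(F1, F2, params),
            converged=bool(ok),
        ))
    return FixedPointSet(points=tuple(points), input=inp)


def reachable_fixed_point(inp: InputPoint, params: ModelParameters,
                          init: tuple[float, float] = (0.07, 0.07),
                          dt: float = 0.01, max_steps: int = 400_000,
                          dtol: float = 1e-10) -> EquilibriumPoint:
    """Forward-integrate the reduced adiabatic dynamics to its attractor.

    The default initial condition matches the full simulation's initial
    rates.  The Euler integration selects the basin; once the motion has
    slowed it hands over to a Newton polish that drives the derivative
    below ``dtol``.  Raises if the integration has not settled after
    ``max_steps``.
    """
    from .organization import classify_activities

    ctx = _solver_context(params)
    F_T = params.F_T
    lo, hi = F_T + 1e-9, 1.0 - 1e-9
    F1 = min(max(init[0], lo), hi)
    F2 = min(max(init[1], lo), hi)
    if not (F_T < init[0] < 1.0 and F_T < init[1] < 1.0):
        raise DomainError("initial rates must lie in (F_T, 1)")

    def fun(x):
        return _residual_vec(
            float(np.clip(x[0], lo, hi)), float(np.clip(x[1], lo, hi)),
            inp, params, *ctx)

    settled = False
    next_try = 0
    for k in range(max_steps):
        d1, d2 = _adiabatic_rhs(F1, F2, inp, params, ctx)
        F1 = min(max(F1 + dt * d1, lo), hi)
        F2 = min(max(F2 + dt * d2, lo), hi)
        slow = abs(d1) < 1e-6 and abs(d2) < 1e-6
        if (slow and k >= next_try) or (k + 1) % 50_000 == 0:
            next_try = k + 2_000
            sol = optimize.root(fun, [F1, F2], method="hybr")
            if (sol.success and np.max(np.abs(sol.fun)) < 1e-12
                    and F_T < sol.x[0] < 1.0 and F_T < sol.x[1] < 1.0
                    and abs(sol.x[0] - F1) < 0.02 and abs(sol.x[1] - F2) < 0.02
                    and _stability(sol.x[0], sol.x[1], inp, params, ctx)):
                F1, F2 = float(sol.x[0]), float(sol.x[1])
                settled = True
                break
        if slow and abs(d1) < dtol and abs(d2) < dtol:
            settled = True
            break
    if not settled:
        raise RuntimeError("reduced dynamics did not settle within t_max")
    return EquilibriumPoint(
        F1=F1, F2=F2,
        w11=weight_equilibrium(F1, F1, F_T),
        w22=weight_equilibrium(F2, F2, F_T),
        w21=weight_equilibrium(F1, F2, F_T),
        w12=weight_equilibrium(F2, F1, F_T),
        stable=_stability(F1, F2, inp, params, ctx),
        label=classify_activities(F1, F2, params),
    )


def map_network_inputs(F1ex: float, F2ex: float, F_B: float,
                       w_pB: tuple[float, float], params: ModelParameters) -> InputPoint:
    """Fold full-network inputs onto the (I_1, I_2) plane.

    I_p = F_p^ex * w_ex + (n_B / n_Pex) * F_B * w_pB, optionally correcting
    the background term by the inhibitory baseline
    (``background_inhibition_corrected``).
    """
    ratio = params.n_B / params.n_Pex
    corr = params.theta if params.background_inhibition_corrected else 0.0
    I1 = F1ex * params.w_ex + ratio * F_B * (w_pB[0] - corr)
    I2 = F2ex * params.w_ex + ratio * F_B * (w_pB[1] - corr)
    return InputPoint(max(I1, 0.0), max(I2, 0.0))
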