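"""Memory-state classification and analytic structures.

A population is a memory representation when its equilibrium intra-population
excitatory weight exceeds its inhibitory reference.  Two representations are
then organized as discrimination, sequence (either direction), or
association according to which directed inter-population weights exceed the
baseline inhibition; bistable inputs get their own label.  This module
implements the label rules, the closed-form memory bounds and separatrices
in the activity plane, the regime measures over the (theta, F_T) parameter
plane, phase-diagram sweeps, inflexion-point scans, and the pairwise
feasibility analysis for three populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .params import ModelParameters
from .population import (DomainError, InputPoint, FixedPointSet,
                         find_fixed_points, reachable_fixed_point,
                         weight_equilibrium)

__all__ = [
    "OrganizationLabel",
    "MemoryBounds",
    "RegimeMeasures",
    "PhaseDiagram",
    "ActivityBox",
    "memory_bounds",
    "separatrix",
    "classify_weights",
    "classify_activities",
    "regime_measures",
    "area_sp",
    "area_disc",
    "input_phase_diagram",
    "nepsilon_scan",
    "parameter_phase_diagram",
    "triple_feasibility",
]

TIE_TOL = 1e-9


class OrganizationLabel(str, Enum):
    """Functional organization of two populations."""

    nm = "nm"      # at least one population is not a memory
    disc = "disc"  # both inter-weights below inhibition
    s12 = "s12"    # sequence from 2 to 1 dominates (w12 above, w21 below)
    s21 = "s21"    # sequence from 1 to 2 dominates
    asc = "asc"    # both inter-weights above inhibition
    bs = "bs"      # bistable input (two or more stable fixed points)

    def __str__(self) -> str:  # serialize as the short code
        return self.value


@dataclass(frozen=True)
class MemoryBounds:
    """Edges of the no-memory activity band for one population.

    ``F_bar`` (upper edge of the lower memory interval) and ``F_underbar``
    (lower edge of the upper memory interval) are the roots of
    (1-F_T) F^2 - theta^2 F + theta^2 F_T = 0, i.e. the rates at which the
    intra-population equilibrium weight equals the inhibitory reference.
    """

    exists: bool
    F_bar: float = math.nan
    F_underbar: float = math.nan

    @property
    def nm_width(self) -> float:
        return self.F_underbar - self.F_bar if self.exists else 0.0


@dataclass(frozen=True)
class RegimeMeasures:
    """Discriminant and sequence measures over the parameter plane.

    D_disc = theta^2 - 4 F_T (1-F_T) decides whether the no-memory band
    exists; S = theta^2 - 2 F_T decides whether the separatrices reach into
    the plasticity-dominated activity square.  Regime I: only associations;
    II: associations and sequences; III: additionally the no-memory state.
    """

    D_disc: float
    S: float
    A_SP: float

    @property
    def D(self) -> float:
        return math.sqrt(self.D_disc) if self.D_disc >= 0 else math.nan

    @property
    def regime(self) -> str:
        if self.D_disc < 0 and self.S < 0:
            return "I"
        if self.D_disc < 0 and self.S > 0:
            return "II"
        if self.D_disc > 0 and self.S > 0:
            return "III"
        return "other"


@dataclass
class PhaseDiagram:
    """Labeled grid over an input or parameter plane."""

    x_name: str
    y_name: str
    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray           # dtype object, shape (len(x), len(y))
    n_stable: Optional[np.ndarray] = None
    F1: Optional[np.ndarray] = None
    F2: Optional[np.ndarray] = None
    params: Optional[ModelParameters] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, xv in enumerate(self.x):
            for j, yv in enumerate(self.y):
                row = {self.x_name: xv, self.y_name: yv,
                       "label": str(self.labels[i, j])}
                if self.n_stable is not None:
                    row["n_stable"] = int(self.n_stable[i, j])
                if self.F1 is not None:
                    row["F1"] = self.F1[i, j]
                    row["F2"] = self.F2[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ActivityBox:
    """Closed per-population rate interval inside (F_T, 1)."""

    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError("box requires lo <= hi")


def memory_bounds(theta_intra: float, F_T: float) -> MemoryBounds:
    """Roots of the intra-population weight-equals-inhibition condition."""
    if not (0.0 < theta_intra < 1.0 and 0.0 < F_T < 1.0):
        raise ValueError("parameters must lie in (0,1)")
    disc = theta_intra ** 2 - 4.0 * F_T * (1.0 - F_T)
    if disc < 0:
        return MemoryBounds(exists=False)
    s = theta_intra * math.sqrt(disc)
    den = 2.0 * (1.0 - F_T)
    lo = (theta_intra ** 2 - s) / den
    hi = (theta_intra ** 2 + s) / den
    if not (F_T < lo <= hi < 1.0):
        return MemoryBounds(exists=False)
    return MemoryBounds(exists=True, F_bar=lo, F_underbar=hi)


def separatrix(F_other: float, theta: float, F_T: float) -> float:
    """Presynaptic-rate threshold where the directed inter-population weight
    into the population firing at ``F_other`` equals ``theta``."""
    if F_other <= F_T:
        raise DomainError("no fixed point below the target rate")
    return theta ** 2 * (1.0 - F_T / F_other) / (1.0 - F_T)


def classify_weights(w11: float, w22: float, w21: float, w12: float,
                     theta_inter: float, theta_intra_1: Optional[float] = None,
                     theta_intra_2: Optional[float] = None) -> OrganizationLabel:
    """Label a weight configuration; memory failure takes precedence.

    Ties (weight within ``TIE_TOL`` of its reference) resolve to the
    non-exceeding side.
    """
    th1 = theta_inter if theta_intra_1 is None else theta_intra_1
    th2 = theta_inter if theta_intra_2 is None else theta_intra_2
    if w11 <= th1 + TIE_TOL or w22 <= th2 + TIE_TOL:
        return OrganizationLabel.nm
    above_21 = w21 > theta_inter + TIE_TOL
    above_12 = w12 > theta_inter + TIE_TOL
    if above_21 and above_12:
        return OrganizationLabel.asc
    if above_21:
        return OrganizationLabel.s21
    if above_12:
        return OrganizationLabel.s12
    return OrganizationLabel.disc


def classify_activities(F1: float, F2: float,
                        params: ModelParameters) -> OrganizationLabel:
    """Label an equilibrium activity pair via the implied weights."""
    F_T = params.F_T
    if not (F_T < F1 < 1.0 and F_T < F2 < 1.0):
        raise DomainError("activities must lie in (F_T, 1)")
    w11 = weight_equilibrium(F1, F1, F_T)
    w22 = weight_equilibrium(F2, F2, F_T)
    w21 = weight_equilibrium(F1, F2, F_T)
    w12 = weight_equilibrium(F2, F1, F_T)
    thP = params.theta_P_eff
    return classify_weights(w11, w22, w21, w12, params.theta, thP, thP)


def regime_measures(theta: float, F_T: float) -> RegimeMeasures:
    if not (0.0 < theta < 1.0 and 0.0 < F_T < 1.0):
        raise ValueError("parameters must lie in (0,1)")
    return RegimeMeasures(
        D_disc=theta ** 2 - 4.0 * F_T * (1.0 - F_T),
        S=theta ** 2 - 2.0 * F_T,
        A_SP=area_sp(F_T),
    )


def area_sp(F_T: float) -> float:
    """Area of the plasticity-dominated activity square [2 F_T, 1]^2."""
    if not (0.0 < F_T < 1.0):
        raise ValueError("F_T must lie in (0,1)")
    side = 1.0 - 2.0 * F_T
    return side * side if side > 0 else 0.0


def area_disc(theta: float, theta_P: float, F_T: float,
              grid_n: int = 400) -> float:
    """Fraction of the admissible activity square labeled discrimination.

    Uniform-grid integration over (F_T, 1)^2 with the within-population
    inhibitory reference ``theta_P``.
    """
    if grid_n < 200:
        raise ValueError("grid_n must be at least 200")
    centers = F_T + (np.arange(grid_n) + 0.5) * (1.0 - F_T) / grid_n
    q = 1.0 - F_T
    F1, F2 = np.meshgrid(centers, centers, indexing="ij")
    w11 = np.sqrt(F1 * F1 * q / (F1 - F_T))
    w22 = np.sqrt(F2 * F2 * q / (F2 - F_T))
    w21 = np.sqrt(F1 * F2 * q / (F2 - F_T))
    w12 = np.sqrt(F2 * F1 * q / (F1 - F_T))
    memory = (w11 > theta_P + TIE_TOL) & (w22 > theta_P + TIE_TOL)
    disc = memory & (w21 <= theta + TIE_TOL) & (w12 <= theta + TIE_TOL)
    return float(disc.mean())


def input_phase_diagram(params: ModelParameters,
                        I1_grid: Sequence[float], I2_grid: Sequence[float],
                        grid_n: int = 200) -> PhaseDiagram:
    """Classify the stable fixed-point structure per folded-input cell.

    A cell with two or more stable fixed points is labeled ``bs``; one
    stable point carries its own label; no interior fixed point means no
    memory can form (``nm``).
    """
    I1_grid = np.asarray(I1_grid, dtype=float)
    I2_grid = np.asarray(I2_grid, dtype=float)
    labels = np.empty((I1_grid.size, I2_grid.size), dtype=object)
    n_stable = np.zeros(labels.shape, dtype=int)
    F1 = np.full(labels.shape, np.nan)
    F2 = np.full(labels.shape, np.nan)
    for i, I1 in enumerate(I1_grid):
        for j, I2 in enumerate(I2_grid):
            fps = find_fixed_points(InputPoint(I1, I2), params, grid_n=grid_n)
            stable = fps.stable_points
            n_stable[i, j] = len(stable)
            if len(stable) >= 2:
                labels[i, j] = OrganizationLabel.bs
            elif len(stable) == 1:
                labels[i, j] = OrganizationLabel(stable[0].label)
                F1[i, j], F2[i, j] = stable[0].rates
            else:
                labels[i, j] = OrganizationLabel.nm
    return PhaseDiagram(x_name="I1", y_name="I2", x=I1_grid, y=I2_grid,
                        labels=labels, n_stable=n_stable, F1=F1, F2=F2,
                        params=params)


def nepsilon_scan(params: ModelParameters, inp: InputPoint,
                  n_eps_range: Iterable[float]) -> pd.DataFrame:
    """Reachable fixed point and label as a function of the inflexion point.

    Also reports, via DataFrame attrs, the n_eps minimizing the distance of
    the mean reachable rate to F_min = 2 F_T and the label-transition
    boundaries.
    """
    from dataclasses import replace

    rows = []
    for n_eps in n_eps_range:
        p = replace(params, n_eps=n_eps)
        pt = reachable_fixed_point(inp, p)
        rows.append({"n_eps": n_eps, "F1": pt.F1, "F2": pt.F2,
                     "label": str(pt.label)})
    df = pd.DataFrame(rows)
    F_min = 2.0 * params.F_T
    Fmean = 0.5 * (df["F1"] + df["F2"])
    df.attrs["argmin_Fmin"] = float(df["n_eps"].iloc[int((Fmean - F_min).abs().idxmin())])
    trans = []
    for k in range(1, len(df)):
        if df["label"].iloc[k] != df["label"].iloc[k - 1]:
            trans.append((float(df["n_eps"].iloc[k]),
                          df["label"].iloc[k - 1], df["label"].iloc[k]))
    df.attrs["transitions"] = trans
    return df


def parameter_phase_diagram(F_T_grid: Sequence[float],
                            theta_grid: Sequence[float],
                            marked_cells: Sequence[tuple[float, float]] = (),
                            input_grid: Optional[Sequence[float]] = None,
                            base_params: Optional[ModelParameters] = None,
                            ) -> tuple[PhaseDiagram, dict]:
    """Regime partition of the (F_T, theta) parameter plane.

    For each ``(F_T, theta)`` pair in ``marked_cells`` a nested
    input-plane diagram is computed over ``input_grid`` (default eleven
    cells over [0, 1]) at those parameters; returned in a dict keyed by the
    cell.
    """
    from dataclasses import replace as _replace

    F_T_grid = np.asarray(F_T_grid, dtype=float)
    theta_grid = np.asarray(theta_grid, dtype=float)
    labels = np.empty((F_T_grid.size, theta_grid.size), dtype=object)
    for i, F_T in enumerate(F_T_grid):
        for j, th in enumerate(theta_grid):
            labels[i, j] = regime_measures(th, F_T).regime
    diagram = PhaseDiagram(x_name="F_T", y_name="theta", x=F_T_grid,
                           y=theta_grid, labels=labels)
    nested: dict[tuple[float, float], PhaseDiagram] = {}
    if marked_cells:
        grid = (np.linspace(0.0, 1.0, 11) if input_grid is None
                else np.asarray(input_grid, dtype=float))
        base = base_params or ModelParameters()
        for F_T, th in marked_cells:
            p = _replace(base, F_T=F_T, theta=th)
            nested[(F_T, th)] = input_phase_diagram(p, grid, grid)
    return diagram, nested


def triple_feasibility(boxes: Sequence[ActivityBox], theta: float,
                       theta_P: float, F_T: float,
                       grid_n: int = 60) -> dict[tuple[int, int], set[str]]:
    """Label sets attainable between each ordered pair of three populations.

    Each pair's (F_p, F_p') box product is sampled on a ``grid_n`` x
    ``grid_n`` grid including the corners; the attained organization labels
    constrain which relations the three representations can realize
    simultaneously.
    """
    if len(boxes) != 3:
        raise ValueError("exactly three activity boxes required")
    for b in boxes:
        if not (F_T < b.lo and b.hi < 1.0):
            raise ValueError("boxes must lie within (F_T, 1)")
    p = ModelParameters(theta=theta, theta_P=theta_P, F_T=F_T)
    out: dict[tuple[int, int], set[str]] = {}
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            A, B = boxes[a], boxes[b]
            fa = np.unique(np.concatenate([np.linspace(A.lo, A.hi, grid_n),
                                           [A.lo, A.hi]]))
            fb = np.unique(np.concatenate([np.linspace(B.lo, B.hi, grid_n),
                                           [B.lo, B.hi]]))
            labels = {str(classify_activities(x, y, p))
                      for x in fa for y in fb}
            out[(a + 1, b + 1)] = labels
    return out
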