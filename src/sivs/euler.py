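"""Forward-Euler discretization of the continuous SIVS model.

Replacing the time derivatives of the continuous two-compartment system by
forward differences with step size Delta gives the map

    I_{t+1} = I_t + Delta * (beta S_t I_t/N - (mu+gamma) I_t)
    S_{t+1} = S_t + Delta * ([(1-q)mu + eps] N - beta S_t I_t/N
                             - (mu+p+eps) S_t + (gamma-eps) I_t)

whose fixed points are the same Q0 and Q* as the native discrete model for
every Delta, and which reduces to the native map exactly at Delta = 1.
Stability, however, depends on Delta: the disease-free point (R0 < 1) is
stable for Delta below an explicit bound, and the endemic point (R0 > 1)
is stable precisely for Delta below the critical step size Delta*, the
smaller root of b2 x^2 - 2 b1 x + 4 with b1 = (mu+p+eps) + beta I*/N and
b2 = (mu+eps) beta I*/N.  Past Delta* the Schur-Cohn condition P(-1) > 0
fails first: the discretization itself creates a spurious flip bifurcation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .equilibria import basic_reproduction_number, endemic_equilibrium
from .model import CompartmentState, ModelParams
from .stability import (
    Jacobian2x2,
    PERIOD_TOL_SCALE,
    ScanPoint,
    ScanResult,
    detect_period,
)


@dataclass(frozen=True)
class EulerParams:
    """Model parameters together with the Euler step size Delta (> 0)."""

    base: ModelParams
    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")


def _euler_step_xy(I: float, S: float, ep: EulerParams) -> tuple[float, float]:
    b = ep.base
    d = ep.delta
    inc = b.beta * S * I / b.N
    I1 = I + d * (inc - (b.mu + b.gamma) * I)
    S1 = S + d * (
        ((1 - b.q) * b.mu + b.epsilon) * b.N
        - inc
        - (b.mu + b.p + b.epsilon) * S
        + (b.gamma - b.epsilon) * I
    )
    return I1, S1


def euler_step(state: tuple[float, float] | CompartmentState, eparams: EulerParams):
    """One step of the Euler map; coincides with the native reduced map at Delta=1."""
    if isinstance(state, CompartmentState):
        I1, S1 = _euler_step_xy(state.I, state.S, eparams)
        return CompartmentState(I=I1, S=S1, V=None, t=state.t + 1)
    return _euler_step_xy(state[0], state[1], eparams)


def euler_jacobian(state: tuple[float, float], eparams: EulerParams) -> Jacobian2x2:
    """Jacobian of the Euler map at (I, S): identity plus Delta times the
    continuous-system Jacobian."""
    I, S = (state.I, state.S) if isinstance(state, CompartmentState) else state
    b = eparams.base
    d = eparams.delta
    return Jacobian2x2(
        a11=1 + d * (b.beta * S / b.N - (b.mu + b.gamma)),
        a12=d * b.beta * I / b.N,
        a21=d * (-b.beta * S / b.N + (b.gamma - b.epsilon)),
        a22=1 - d * ((b.mu + b.p + b.epsilon) + b.beta * I / b.N),
    )


def dfe_delta_bound(params: ModelParams) -> float:
    """Largest step size guaranteeing stability of the disease-free point.

    Requires R0 < 1.  Each eigenvalue of the Euler Jacobian at Q0 lies in
    (-1, 1) iff Delta is below 2/(mu+p+eps) resp. 2/((mu+gamma)(1-R0));
    both must hold simultaneously, so the guaranteed bound is the minimum
    of the two.  See :func:`dfe_delta_bound_printed` for the alternative
    grouping 2/min{...}, which is the larger of the per-eigenvalue bounds
    and therefore not sufficient on its own.
    """
    R0 = basic_reproduction_number(params)
    if R0 >= 1:
        raise ValueError("disease-free Delta bound applies only when R0 < 1")
    a = params.mu + params.p + params.epsilon
    b = (params.mu + params.gamma) * (1 - R0)
    return min(2 / a, 2 / b)


def dfe_delta_bound_printed(params: ModelParams) -> float:
    """The expression 2/min{mu+p+eps, (mu+gamma)(1-R0)} for comparison.

    This equals the larger of the two per-eigenvalue bounds; it is exposed
    alongside :func:`dfe_delta_bound` (the simultaneous, sufficient bound)
    so the two groupings can be compared directly.
    """
    R0 = basic_reproduction_number(params)
    if R0 >= 1:
        raise ValueError("disease-free Delta bound applies only when R0 < 1")
    a = params.mu + params.p + params.epsilon
    b = (params.mu + params.gamma) * (1 - R0)
    return 2 / min(a, b)


@dataclass(frozen=True)
class DeltaStarReport:
    """Critical Euler step size for the endemic equilibrium.

    r1 <= r2 are the roots of b2 x^2 - 2 b1 x + 4; the endemic point of the
    Euler map is stable iff Delta < delta_star = r1.  The discriminant
    b1^2 - 4 b2 is positive whenever R0 > 1, and r1 < b1/b2, so the
    P(-1) > 0 Schur-Cohn condition is always the first to fail.
    """

    b1: float
    b2: float
    r1: float
    r2: float

    @property
    def delta_star(self) -> float:
        return self.r1

    def to_dict(self) -> dict:
        return {"b1": self.b1, "b2": self.b2, "r1": self.r1, "r2": self.r2,
                "delta_star": self.delta_star}


def delta_star(params: ModelParams) -> DeltaStarReport:
    """Critical step size Delta* of the endemic point (requires R0 > 1)."""
    Qstar = endemic_equilibrium(params)
    if Qstar is None:
        raise ValueError("endemic equilibrium requires R0 > 1")
    beta_i = params.beta * Qstar[0] / params.N
    b1 = (params.mu + params.p + params.epsilon) + beta_i
    b2 = (params.mu + params.epsilon) * beta_i
    disc = b1 * b1 - 4 * b2
    if disc <= 0:
        raise ValueError("discriminant b1^2 - 4 b2 must be positive")
    root = math.sqrt(disc)
    return DeltaStarReport(b1=b1, b2=b2, r1=(b1 - root) / b2, r2=(b1 + root) / b2)


def euler_scan_delta(
    params: ModelParams,
    delta_grid,
    init: tuple[float, float] | CompartmentState,
    n_transient: int = 2000,
    n_sample: int = 200,
) -> ScanResult:
    """Bifurcation scan of the Euler map over an ascending grid of Delta.

    Same orbit sampling and period detection as the native-map scans; the
    detected ``period1_loss`` bracket contains Delta* when R0 > 1.
    """
    grid = np.asarray(delta_grid, dtype=float)
    if len(grid) == 0:
        raise ValueError("empty grid")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    if isinstance(init, CompartmentState):
        init = (init.I, init.S)

    tol = PERIOD_TOL_SCALE * params.N
    points: list[ScanPoint] = []
    positive_onset = period2_onset = period1_loss = None
    for value in grid:
        ep = EulerParams(base=params, delta=float(value))
        I, S = init
        diverged = False
        for _ in range(n_transient):
            I, S = _euler_step_xy(I, S, ep)
            if not (math.isfinite(I) and math.isfinite(S)):
                diverged = True
                break
        samples = np.empty(0)
        if not diverged:
            samples = np.empty(n_sample)
            for k in range(n_sample):
                I, S = _euler_step_xy(I, S, ep)
                if not (math.isfinite(I) and math.isfinite(S)):
                    samples = samples[:k]
                    diverged = True
                    break
                samples[k] = I
        period = None if diverged or len(samples) == 0 else detect_period(samples, tol)
        points.append(ScanPoint(value=float(value), samples=samples,
                                period=period, diverged=diverged))
        if not diverged and len(samples):
            if positive_onset is None and samples.mean() > tol:
                positive_onset = float(value)
            if period2_onset is None and period == 2:
                period2_onset = float(value)
            if period1_loss is None and period != 1:
                period1_loss = float(value)
    return ScanResult(
        param_name="delta", grid=grid, points=points,
        n_transient=n_transient, n_sample=n_sample,
        positive_I_onset=positive_onset, period2_onset=period2_onset,
        period1_loss=period1_loss,
    )
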