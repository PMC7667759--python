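"""Stability classification, bifurcation thresholds and numerical scans.

Local stability of the reduced (I, S) map is read off its 2x2 Jacobian.
For a 2x2 matrix the Jury (Schur-Cohn) conditions

    |tr J| < 1 + det J < 2

are equivalent to both eigenvalues lying strictly inside the unit disk.
The disease-free point is stable iff R0 < 1; the endemic point, when the
sufficient nonnegativity conditions hold, is stable whenever it exists.
Relaxing beta beyond those conditions the endemic point loses stability
through an eigenvalue crossing -1 (a period-doubling / flip bifurcation);
the analytic threshold comes from requiring P(-1) = 0 of the endemic
characteristic polynomial.  A Neimark-Sacker bifurcation cannot occur at
the endemic point: the discriminant b1^2 - 4 b2 is always positive, so the
eigenvalues are real.

Numerical counterparts: parameter scans that iterate the raw map past a
transient and detect the attractor period by value recurrence, and
Lyapunov exponents by the Benettin QR-reorthonormalization scheme.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np

from .equilibria import (
    basic_reproduction_number,
    disease_free_equilibrium,
    endemic_equilibrium,
)
from .model import CompartmentState, ModelParams, _step_reduced_xy

#: |R0 - 1| below which a verdict is "marginal" rather than stable/unstable.
MARGINAL_TOL = 1e-9

#: Orbit-recurrence tolerance for period detection is PERIOD_TOL_SCALE * N.
PERIOD_TOL_SCALE = 1e-6

#: Longest attractor period searched for before reporting "aperiodic".
MAX_PERIOD = 64


@dataclass(frozen=True)
class Jacobian2x2:
    """A 2x2 Jacobian with its spectral quantities.

    The characteristic polynomial is written P(lambda) = lambda^2 + a1*lambda + a2
    with a1 = -trace and a2 = determinant.
    """

    a11: float
    a12: float
    a21: float
    a22: float

    @property
    def trace(self) -> float:
        return self.a11 + self.a22

    @property
    def det(self) -> float:
        return self.a11 * self.a22 - self.a12 * self.a21

    @property
    def char_coeffs(self) -> tuple[float, float]:
        """(a1, a2) of P(lambda) = lambda^2 + a1 lambda + a2."""
        return (-self.trace, self.det)

    @property
    def eigenvalues(self) -> tuple[complex, complex]:
        """Roots of the characteristic polynomial, sorted by modulus descending."""
        tr, d = self.trace, self.det
        disc = cmath.sqrt(tr * tr - 4 * d)
        lam1 = (tr + disc) / 2
        lam2 = (tr - disc) / 2
        return tuple(sorted((lam1, lam2), key=abs, reverse=True))

    @property
    def spectral_radius(self) -> float:
        return abs(self.eigenvalues[0])

    def as_array(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]])


def jacobian_reduced(state: tuple[float, float], params: ModelParams) -> Jacobian2x2:
    """Jacobian of the reduced map at (I, S)."""
    I, S = state
    mu, beta, gamma, eps, p, N = (
        params.mu, params.beta, params.gamma, params.epsilon, params.p, params.N,
    )
    return Jacobian2x2(
        a11=1 - (mu + gamma) + beta * S / N,
        a12=beta * I / N,
        a21=-beta * S / N + (gamma - eps),
        a22=1 - (mu + p + eps) - beta * I / N,
    )


def jury_stable(trace: float, det: float) -> bool:
    """Jury test for a 2x2 map: both eigenvalues strictly inside the unit disk.

    True iff |trace| < 1 + det and 1 + det < 2.
    """
    return abs(trace) < 1 + det and 1 + det < 2


@dataclass(frozen=True)
class StabilityReport:
    """Stability classification of one equilibrium of the reduced map."""

    equilibrium: str  # "disease-free" | "endemic"
    point: tuple[float, float]
    eigenvalues: tuple[complex, complex]
    jury_satisfied: bool
    verdict: str  # "stable" | "unstable" | "marginal"
    R0: float
    b1: float | None = None  # (mu+p+eps) + beta I*/N, endemic only
    b2: float | None = None  # (mu+eps) beta I*/N, endemic only

    def to_dict(self) -> dict:
        return {
            "equilibrium": self.equilibrium,
            "point": {"I": self.point[0], "S": self.point[1]},
            "eigenvalues": [[lam.real, lam.imag] for lam in self.eigenvalues],
            "jury_satisfied": self.jury_satisfied,
            "verdict": self.verdict,
            "R0": self.R0,
            "b1": self.b1,
            "b2": self.b2,
        }


def classify_dfe(params: ModelParams) -> StabilityReport:
    """Classify the disease-free equilibrium.

    The Jacobian there is lower-triangular with eigenvalues
    lambda1 = 1 - (mu+gamma) + (mu+gamma) R0 and lambda2 = 1 - (mu+p+eps),
    so (under the nonnegativity conditions) stability holds iff R0 < 1.
    """
    R0 = basic_reproduction_number(params)
    Q0 = disease_free_equilibrium(params)
    J = jacobian_reduced(Q0, params)
    if abs(R0 - 1) < MARGINAL_TOL:
        verdict = "marginal"
    elif J.spectral_radius < 1:
        verdict = "stable"
    else:
        verdict = "unstable"
    return StabilityReport(
        equilibrium="disease-free",
        point=Q0,
        eigenvalues=J.eigenvalues,
        jury_satisfied=jury_stable(J.trace, J.det),
        verdict=verdict,
        R0=R0,
    )


def classify_endemic(params: ModelParams) -> StabilityReport | None:
    """Classify the endemic equilibrium; None when it does not exist (R0 <= 1).

    The Jury conditions are evaluated honestly: within the nonnegativity
    conditions they always hold (the endemic point is stable whenever it
    exists), but for relaxed beta the flip threshold can be crossed and the
    verdict becomes unstable.
    """
    Qstar = endemic_equilibrium(params)
    if Qstar is None:
        return None
    R0 = basic_reproduction_number(params)
    J = jacobian_reduced(Qstar, params)
    beta_i = params.beta * Qstar[0] / params.N
    b1 = (params.mu + params.p + params.epsilon) + beta_i
    b2 = (params.mu + params.epsilon) * beta_i
    rho = J.spectral_radius
    if abs(rho - 1) < MARGINAL_TOL:
        verdict = "marginal"
    elif rho < 1:
        verdict = "stable"
    else:
        verdict = "unstable"
    return StabilityReport(
        equilibrium="endemic",
        point=Qstar,
        eigenvalues=J.eigenvalues,
        jury_satisfied=jury_stable(J.trace, J.det),
        verdict=verdict,
        R0=R0,
        b1=b1,
        b2=b2,
    )


def transcritical_beta(params: ModelParams) -> float:
    """Contact rate beta at which R0 = 1 (transcritical bifurcation of Q0)."""
    num = (1 - params.q) * params.mu + params.epsilon
    if num <= 0:
        raise ValueError("no finite threshold: (1-q)mu + epsilon must be positive")
    return (params.mu + params.p + params.epsilon) * (params.mu + params.gamma) / num


def period_doubling_beta(params: ModelParams) -> float:
    """Contact rate beta at which the endemic point undergoes a flip bifurcation.

    Solves R0(beta) = 1 + (2[2-(mu+p+eps)]/(2-(mu+eps))) * ((mu+eps)/((mu+p+eps)(mu+gamma))),
    the condition for the endemic Jacobian to have eigenvalue -1.  Requires
    beta above 1, i.e. the nonnegativity conditions relaxed.
    """
    mu, eps, p, gamma = params.mu, params.epsilon, params.p, params.gamma
    if mu + eps >= 2 or mu + p + eps >= 2:
        raise ValueError("flip threshold formula needs mu+epsilon < 2 and mu+p+epsilon < 2")
    r0_flip = 1 + (2 * (2 - (mu + p + eps)) / (2 - (mu + eps))) * (
        (mu + eps) / ((mu + p + eps) * (mu + gamma))
    )
    return r0_flip * transcritical_beta(params)


def no_neimark_sacker_certificate(params: ModelParams) -> bool:
    """Certificate that the endemic eigenvalues are real (discriminant > 0).

    True iff b1^2 - 4 b2 > 0 at the endemic point, which rules out a
    Neimark-Sacker bifurcation there; this holds for every parameter set
    with R0 > 1.
    """
    Qstar = endemic_equilibrium(params)
    if Qstar is None:
        raise ValueError("endemic equilibrium requires R0 > 1")
    beta_i = params.beta * Qstar[0] / params.N
    b1 = (params.mu + params.p + params.epsilon) + beta_i
    b2 = (params.mu + params.epsilon) * beta_i
    return b1 * b1 - 4 * b2 > 0


def detect_period(samples: np.ndarray, tol: float, max_period: int = MAX_PERIOD) -> int | None:
    """Attractor period from post-transient orbit samples by value recurrence.

    Returns the smallest k <= max_period with |x[t+k] - x[t]| < tol for all
    sampled t, or None ("aperiodic") if no such k exists.
    """
    n = len(samples)
    for k in range(1, min(max_period, n - 1) + 1):
        if np.all(np.abs(samples[k:] - samples[:-k]) < tol):
            return k
    return None


@dataclass
class ScanPoint:
    """Orbit diagnostics at a single parameter value of a scan."""

    value: float
    samples: np.ndarray  # post-transient I_t values
    period: int | None  # None = aperiodic (or diverged)
    lyapunov: tuple[float, float] | None = None
    diverged: bool = False


@dataclass
class ScanResult:
    """Result of a one-parameter bifurcation scan.

    Holds post-transient I_t samples per grid value, the detected attractor
    period, optional Lyapunov exponents, and the detected thresholds:
    ``positive_I_onset`` (first grid value whose mean post-transient
    infection exceeds PERIOD_TOL_SCALE*N — the numerical transcritical
    onset), ``period2_onset`` (first grid value with a period-2 attractor)
    and ``period1_loss`` (first grid value whose attractor is not a fixed
    point).
    """

    param_name: str
    grid: np.ndarray
    points: list[ScanPoint]
    n_transient: int
    n_sample: int
    positive_I_onset: float | None = None
    period2_onset: float | None = None
    period1_loss: float | None = None

    @property
    def periods(self) -> list[int | None]:
        return [pt.period for pt in self.points]

    def summary_dict(self) -> dict:
        return {
            "param_name": self.param_name,
            "grid": {"min": float(self.grid[0]), "max": float(self.grid[-1]),
                     "n": int(len(self.grid))},
            "n_transient": self.n_transient,
            "n_sample": self.n_sample,
            "positive_I_onset": self.positive_I_onset,
            "period2_onset": self.period2_onset,
            "period1_loss": self.period1_loss,
            "periods": [p if p is not None else "aperiodic" for p in self.periods],
            "lyapunov": [None if pt.lyapunov is None else list(pt.lyapunov)
                         for pt in self.points],
        }


def _orbit_samples(
    params: ModelParams,
    init: tuple[float, float],
    n_transient: int,
    n_sample: int,
) -> tuple[np.ndarray, bool]:
    """Post-transient I_t samples of the reduced map; flags divergence."""
    I, S = init
    for _ in range(n_transient):
        I, S = _step_reduced_xy(I, S, params)
        if not (math.isfinite(I) and math.isfinite(S)):
            return np.array([]), True
    out = np.empty(n_sample)
    for k in range(n_sample):
        I, S = _step_reduced_xy(I, S, params)
        if not (math.isfinite(I) and math.isfinite(S)):
            return out[:k], True
        out[k] = I
    return out, False


def bifurcation_scan(
    params: ModelParams,
    param_name: str,
    grid,
    init: tuple[float, float] | CompartmentState,
    n_transient: int = 2000,
    n_sample: int = 200,
    compute_lyapunov: bool = False,
    lyapunov_iter: int = 500,
) -> ScanResult:
    """Scan one parameter of the reduced map over an ascending grid.

    At each grid value the map is iterated from ``init`` for ``n_transient``
    steps, then ``n_sample`` values of I_t are recorded and the attractor
    period detected by recurrence within PERIOD_TOL_SCALE*N.  Non-finite
    orbits are flagged and the scan continues.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ValueError("empty grid")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    if n_transient < 1 or n_sample < 1:
        raise ValueError("n_transient and n_sample must be >= 1")
    if isinstance(init, CompartmentState):
        init = (init.I, init.S)

    tol = PERIOD_TOL_SCALE * params.N
    points: list[ScanPoint] = []
    positive_onset = period2_onset = period1_loss = None
    for value in grid:
        pset = params.with_(**{param_name: float(value)})
        samples, diverged = _orbit_samples(pset, init, n_transient, n_sample)
        period = None if diverged or len(samples) == 0 else detect_period(samples, tol)
        lyap = None
        if compute_lyapunov and not diverged:
            try:
                lyap = lyapunov_exponents(pset, init, n_transient, lyapunov_iter)
            except ValueError:
                lyap = None
        points.append(ScanPoint(value=float(value), samples=samples,
                                period=period, lyapunov=lyap, diverged=diverged))
        if not diverged and len(samples):
            if positive_onset is None and samples.mean() > tol:
                positive_onset = float(value)
            if period2_onset is None and period == 2:
                period2_onset = float(value)
            if period1_loss is None and period != 1:
                period1_loss = float(value)
    return ScanResult(
        param_name=param_name, grid=grid, points=points,
        n_transient=n_transient, n_sample=n_sample,
        positive_I_onset=positive_onset, period2_onset=period2_onset,
        period1_loss=period1_loss,
    )


def lyapunov_exponents(
    params: ModelParams,
    init: tuple[float, float] | CompartmentState,
    n_transient: int = 2000,
    n_iter: int = 1000,
    jacobian=jacobian_reduced,
    step=None,
) -> tuple[float, float]:
    """Both Lyapunov exponents of an orbit, sorted descending.

    Benettin scheme: the tangent-space product of Jacobians along the
    post-transient orbit is QR-reorthonormalized every step and the
    exponents are the averaged logarithms of the R diagonal.  For an orbit
    settling onto a stable fixed point the leading exponent converges to
    ln(max |eig J|) at that point.

    Raises ValueError if the orbit leaves the finite range.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if isinstance(init, CompartmentState):
        init = (init.I, init.S)
    if step is None:
        step = lambda xy, p: _step_reduced_xy(xy[0], xy[1], p)

    x = init
    for _ in range(n_transient):
        x = step(x, params)
        if not (math.isfinite(x[0]) and math.isfinite(x[1])):
            raise ValueError("orbit diverged during transient")
    Q = np.eye(2)
    logs = np.zeros(2)
    for _ in range(n_iter):
        J = jacobian(x, params).as_array()
        A = J @ Q
        Q, R = np.linalg.qr(A)
        diag = np.abs(np.diag(R))
        if np.any(diag == 0) or not np.all(np.isfinite(diag)):
            raise ValueError("tangent dynamics degenerate or non-finite")
        logs += np.log(diag)
        x = step(x, params)
        if not (math.isfinite(x[0]) and math.isfinite(x[1])):
            raise ValueError("orbit diverged")
    exps = logs / n_iter
    return (float(max(exps)), float(min(exps)))
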