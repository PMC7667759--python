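"""Core types and update maps for the discrete-time SIVS epidemic model.

The model tracks susceptible (S), infected (I) and vaccinated (V)
individuals in a closed population of constant size N.  Infection follows
standard incidence beta*S*I/N; infected individuals recover back into the
susceptible class at rate gamma (no lasting immunity); a fraction q of the
mu*N newcomers per step is vaccinated at entry, susceptibles are vaccinated
at rate p, and vaccine immunity wanes at rate epsilon.  One step of the map
advances the population by one unit of time.

Because the full three-compartment map conserves N exactly, V can be
eliminated (V = N - S - I) giving an equivalent two-dimensional map, and
dividing through by N gives the same dynamics on fractions (i, s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and population size of the SIVS model.

    Parameters
    ----------
    mu : float
        Natural death rate (= birth rate, keeping N constant) per unit time.
    beta : float
        Contact rate per unit time.
    gamma : float
        Cure rate per unit time.
    epsilon : float
        Rate of losing vaccine-induced immunity per unit time.
    p : float
        Vaccination rate of susceptibles per unit time.
    q : float
        Vaccinated fraction of newcomers, dimensionless in [0, 1].
    N : float
        Total population size (constant; real-valued, e.g. millions).
    """

    mu: float
    beta: float
    gamma: float
    epsilon: float
    p: float
    q: float
    N: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu", "beta", "gamma", "epsilon", "p", "q", "N"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.N <= 0:
            raise ValueError(f"N must be positive, got {self.N}")
        if self.q > 1:
            raise ValueError(f"q must be at most 1, got {self.q}")

    def with_(self, **kwargs) -> "ModelParams":
        """Copy with some fields replaced (e.g. ``params.with_(beta=2.7)``)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CompartmentState:
    """Population counts (I, S[, V]) at an integer time step.

    V may be None when working with the reduced two-dimensional map; it is
    then implicitly N - S - I.
    """

    I: float
    S: float
    V: float | None = None
    t: int = 0

    @property
    def total(self) -> float:
        if self.V is None:
            raise ValueError("state has no V compartment; total requires all three")
        return self.I + self.S + self.V

    def admissible(self, N: float) -> bool:
        """Whether the state lies in the invariant region I,S >= 0, I+S <= N."""
        return self.I >= 0 and self.S >= 0 and self.I + self.S <= N


@dataclass(frozen=True)
class FractionState:
    """Infected and susceptible fractions (i, s) = (I/N, S/N)."""

    i: float
    s: float
    t: int = 0


@dataclass(frozen=True)
class ConditionsCheck:
    """Outcome of the sufficient nonnegativity conditions.

    cond_a: mu + p + epsilon + beta < 1
    cond_b: mu + gamma < 1

    Jointly sufficient (not necessary) for orbits started in the admissible
    region to remain nonnegative.  Violations are informative, never fatal:
    the bifurcation analysis deliberately relaxes cond_a to take beta well
    above 1.
    """

    cond_a: bool
    cond_b: bool

    @property
    def satisfied(self) -> bool:
        return self.cond_a and self.cond_b


def validate_conditions(params: ModelParams) -> ConditionsCheck:
    """Check the sufficient conditions for nonnegativity of solutions."""
    return ConditionsCheck(
        cond_a=params.mu + params.p + params.epsilon + params.beta < 1,
        cond_b=params.mu + params.gamma < 1,
    )


def step_full(state: CompartmentState, params: ModelParams) -> CompartmentState:
    """One step of the full three-compartment map.

    Uses the state's own total N_t for the standard-incidence term, so the
    map conserves I + S + V exactly (the next total equals the current one
    up to floating round-off).
    """
    if state.V is None:
        raise ValueError("step_full requires all three compartments")
    N = state.total
    if N <= 0:
        raise ValueError("total population must be positive")
    mu, beta, gamma, eps, p, q = (
        params.mu, params.beta, params.gamma, params.epsilon, params.p, params.q,
    )
    inc = beta * state.S * state.I / N
    I1 = inc + (1 - (mu + gamma)) * state.I
    S1 = (1 - q) * mu * N - inc + (1 - (mu + p)) * state.S + gamma * state.I + eps * state.V
    V1 = q * mu * N + p * state.S + (1 - (mu + eps)) * state.V
    return CompartmentState(I=I1, S=S1, V=V1, t=state.t + 1)


def step_reduced(state: CompartmentState, params: ModelParams) -> CompartmentState:
    """One step of the reduced two-dimensional (I, S) map with V eliminated."""
    I1, S1 = _step_reduced_xy(state.I, state.S, params)
    return CompartmentState(I=I1, S=S1, V=None, t=state.t + 1)


def _step_reduced_xy(I: float, S: float, params: ModelParams) -> tuple[float, float]:
    """Float-only reduced-map step; the inner kernel for scans and orbits."""
    mu, beta, gamma, eps, p, q, N = (
        params.mu, params.beta, params.gamma, params.epsilon,
        params.p, params.q, params.N,
    )
    inc = beta * S * I / N
    I1 = inc + (1 - (mu + gamma)) * I
    S1 = ((1 - q) * mu + eps) * N - inc + (1 - (mu + p + eps)) * S + (gamma - eps) * I
    return I1, S1


def step_fraction(state: FractionState, params: ModelParams) -> FractionState:
    """One step of the fraction system on (i, s) = (I/N, S/N)."""
    mu, beta, gamma, eps, p, q = (
        params.mu, params.beta, params.gamma, params.epsilon, params.p, params.q,
    )
    inc = beta * state.s * state.i
    i1 = inc + (1 - (mu + gamma)) * state.i
    s1 = ((1 - q) * mu + eps) - inc + (1 - (mu + p + eps)) * state.s + (gamma - eps) * state.i
    return FractionState(i=i1, s=s1, t=state.t + 1)


@dataclass
class Trajectory:
    """A simulated orbit: n_steps+1 states including the initial one.

    first_violation is the first step index at which the state left the
    admissible region (I < 0, S < 0 or I + S > N), or None if it never did.
    States are never clipped; the map is iterated as written.
    """

    states: list[CompartmentState] = field(default_factory=list)
    first_violation: int | None = None

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[CompartmentState]:
        return iter(self.states)

    def __getitem__(self, idx):
        return self.states[idx]

    @property
    def I(self) -> list[float]:
        return [s.I for s in self.states]

    @property
    def S(self) -> list[float]:
        return [s.S for s in self.states]


def simulate(
    params: ModelParams,
    init: CompartmentState,
    n_steps: int,
) -> Trajectory:
    """Iterate the model for n_steps steps from ``init``.

    Uses the full three-compartment map when ``init`` carries V, otherwise
    the reduced map with N taken from ``params``.  The trajectory includes
    the initial state, so its length is n_steps + 1.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be nonnegative")
    step = step_full if init.V is not None else step_reduced
    N = init.total if init.V is not None else params.N
    traj = Trajectory(states=[init])
    if not init.admissible(N):
        traj.first_violation = init.t
    state = init
    for _ in range(n_steps):
        state = step(state, params)
        traj.states.append(state)
        if traj.first_violation is None and not state.admissible(N):
            traj.first_violation = state.t
    return traj
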