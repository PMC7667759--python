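"""Reproducible random parameter fixtures for property tests.

Parameter sets are drawn by rejection sampling into one of four regimes:

- ``conditions-3-satisfied``: the sufficient nonnegativity conditions hold
  (mu+p+eps+beta < 1 and mu+gamma < 1);
- ``R0-below-1`` / ``R0-above-1``: nonnegativity conditions hold and the
  basic reproduction number is below / above one;
- ``beta-relaxed``: only mu+gamma < 1 is enforced and beta ranges up to 4,
  the regime of the bifurcation diagrams.

Each fixture comes with an admissible initial state (all compartments
positive, summing to N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import basic_reproduction_number
from .model import CompartmentState, ModelParams, validate_conditions

REGIMES = ("conditions-3-satisfied", "R0-below-1", "R0-above-1", "beta-relaxed")


@dataclass(frozen=True)
class FixtureSpec:
    """How many parameter sets to draw, in which regime, with which seed."""

    n: int
    regime: str
    seed: int
    max_draws: int = 100_000

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _in_regime(params: ModelParams, regime: str) -> bool:
    check = validate_conditions(params)
    if regime == "conditions-3-satisfied":
        return check.satisfied
    if regime == "R0-below-1":
        return check.satisfied and basic_reproduction_number(params) < 1
    if regime == "R0-above-1":
        return check.satisfied and basic_reproduction_number(params) > 1
    if regime == "beta-relaxed":
        return check.cond_b
    raise ValueError(regime)


def generate_fixtures(spec: FixtureSpec) -> list[tuple[ModelParams, CompartmentState]]:
    """Draw parameter sets and admissible initial states in the given regime.

    Deterministic for a given seed.  Raises RuntimeError if rejection
    sampling fails to fill the request within ``spec.max_draws`` draws.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[tuple[ModelParams, CompartmentState]] = []
    draws = 0
    while len(out) < spec.n:
        if draws >= spec.max_draws:
            raise RuntimeError(
                f"rejection sampling exhausted {spec.max_draws} draws "
                f"for regime {spec.regime!r} ({len(out)}/{spec.n} found)"
            )
        draws += 1
        beta_hi = 4.0 if spec.regime == "beta-relaxed" else 1.0
        params_kw = dict(
            mu=rng.uniform(0.01, 0.3),
            beta=rng.uniform(0.0, beta_hi),
            gamma=rng.uniform(0.0, 0.5),
            epsilon=rng.uniform(0.0, 0.4),
            p=rng.uniform(0.0, 0.4),
            q=rng.uniform(0.0, 1.0),
            N=rng.uniform(0.5, 10.0),
        )
        params = ModelParams(**params_kw)
        if not _in_regime(params, spec.regime):
            continue
        # admissible initial state: positive compartments summing to N
        w = rng.dirichlet([1.0, 1.0, 1.0])
        init = CompartmentState(
            I=w[0] * params.N, S=w[1] * params.N, V=w[2] * params.N, t=0
        )
        out.append((params, init))
    return out
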