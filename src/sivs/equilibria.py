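"""Equilibria, basic reproduction number and vaccination sensitivity.

Closed forms for the reduced (I, S) map:

    disease-free point  Q0 = (0, [(1-q)mu + eps] N / (mu + p + eps))
    endemic point       Q* = (I*, (mu+gamma) N / beta)
    I* = (mu+p+eps)(mu+gamma) N / ((mu+eps) beta) * (R0 - 1)

with

    R0 = beta [(1-q)mu + eps] / ((mu+p+eps)(mu+gamma)).

The endemic point exists (has I* > 0) exactly when R0 > 1; R0 does not
depend on the population size N.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .model import ModelParams


def basic_reproduction_number(params: ModelParams) -> float:
    """R0 = beta[(1-q)mu + eps] / ((mu+p+eps)(mu+gamma))."""
    denom = (params.mu + params.p + params.epsilon) * (params.mu + params.gamma)
    if denom <= 0:
        raise ValueError("degenerate parameters: (mu+p+epsilon)(mu+gamma) must be positive")
    return params.beta * ((1 - params.q) * params.mu + params.epsilon) / denom


def disease_free_equilibrium(params: ModelParams) -> tuple[float, float]:
    """Disease-free fixed point (0, S0) of the reduced map."""
    denom = params.mu + params.p + params.epsilon
    if denom <= 0:
        raise ValueError("mu + p + epsilon must be positive")
    S0 = ((1 - params.q) * params.mu + params.epsilon) * params.N / denom
    return (0.0, S0)


def endemic_equilibrium(params: ModelParams) -> tuple[float, float] | None:
    """Endemic fixed point (I*, S*), or None when R0 <= 1.

    Existence is gated strictly: at R0 exactly 1 the formula gives I* = 0,
    the point coincides with the disease-free one and None is returned.
    """
    R0 = basic_reproduction_number(params)
    if R0 <= 1:
        return None
    return endemic_equilibrium_formula(params)


def endemic_equilibrium_formula(params: ModelParams) -> tuple[float, float]:
    """Evaluate the (I*, S*) closed form unconditionally.

    I* is negative when R0 < 1 and zero at R0 = 1; sign(I*) = sign(R0 - 1).
    """
    mu, beta, gamma, eps, p = (
        params.mu, params.beta, params.gamma, params.epsilon, params.p,
    )
    R0 = basic_reproduction_number(params)
    I_star = (mu + p + eps) * (mu + gamma) * params.N / ((mu + eps) * beta) * (R0 - 1)
    S_star = (mu + gamma) * params.N / beta
    return (I_star, S_star)


def r0_without_vaccination(params: ModelParams) -> float:
    """R0 of the same model with the vaccination program removed (p = q = 0).

    Equals beta/(mu+gamma); relates to the vaccinated model through
    R0 = [((1-q)mu + eps)/(mu+p+eps)] * R0_novacc, which is strictly
    smaller whenever p > 0 or q > 0.
    """
    denom = params.mu + params.gamma
    if denom <= 0:
        raise ValueError("mu + gamma must be positive")
    return params.beta / denom


@dataclass(frozen=True)
class SensitivityIndices:
    """Normalized forward sensitivity of R0 to the vaccination parameters.

    psi_x = (x / R0) * dR0/dx.  Both indices are nonpositive: increasing
    either the newcomer vaccination fraction q or the susceptible
    vaccination rate p lowers R0.
    """

    psi_q: float
    psi_p: float


def sensitivity_indices(params: ModelParams) -> SensitivityIndices:
    """Closed-form sensitivity indices psi_q and psi_p of R0."""
    mu, eps, p, q = params.mu, params.epsilon, params.p, params.q
    denom_q = (1 - q) * mu + eps
    denom_p = mu + p + eps
    if denom_q <= 0 or denom_p <= 0:
        raise ValueError("sensitivity indices need (1-q)mu+epsilon > 0 and mu+p+epsilon > 0")
    return SensitivityIndices(
        psi_q=-q * mu / denom_q,
        psi_p=-p / denom_p,
    )


@dataclass(frozen=True)
class EquilibriumSet:
    """Both equilibria of the reduced map together with R0."""

    R0: float
    Q0: tuple[float, float]
    Qstar: tuple[float, float] | None

    def to_dict(self) -> dict:
        return {
            "R0": self.R0,
            "Q0": {"I": self.Q0[0], "S": self.Q0[1]},
            "Qstar": None if self.Qstar is None else {"I": self.Qstar[0], "S": self.Qstar[1]},
        }


def equilibria(params: ModelParams) -> EquilibriumSet:
    """Compute R0 and both fixed points (endemic one only when R0 > 1)."""
    return EquilibriumSet(
        R0=basic_reproduction_number(params),
        Q0=disease_free_equilibrium(params),
        Qstar=endemic_equilibrium(params),
    )


def equilibrium_report(params: ModelParams) -> dict:
    """JSON-serializable report: R0, both equilibria, sensitivity indices."""
    eq = equilibria(params)
    psi = sensitivity_indices(params)
    rep = eq.to_dict()
    rep["psi_p"] = psi.psi_p
    rep["psi_q"] = psi.psi_q
    return rep
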