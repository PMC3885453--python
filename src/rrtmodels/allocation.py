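"""Optimal allocation of the total sample across the two subsamples.

The objective is a convex combination k*Var(mu_hat) + (1-k)*Var(W_hat) of
the two estimator variances, which for the two-subsample designs has the
form C1/n1 + C2/n2.  Minimising under n1 + n2 = n (Lagrange / Cauchy-Schwarz)
gives the Neyman-type square-root allocation

    n1* = n * sqrt(C1) / (sqrt(C1) + sqrt(C2)),
    v_min = (sqrt(C1) + sqrt(C2))^2 / n.

The cost coefficients depend on the unknown W through the response
variances, so in practice a pilot estimate or an informed guess of W is
plugged in; ``allocation_with_guess`` reports how sensitive the split is to
that guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import moments as mm
from .designs import Population, ThreeStageParams, TwoSampleDesign

__all__ = [
    "combined_objective",
    "cost_coefficients",
    "optimal_allocation",
    "allocation_with_guess",
    "AllocationResult",
]


@dataclass
class AllocationResult:
    """Integer allocation (n1, n2), the continuous-optimum objective value
    and the weight used."""

    n1_opt: int
    n2_opt: int
    v_min: float
    weight_k: float
    sensitivity: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.n1_opt + self.n2_opt


def combined_objective(k: float, var_mean: float, var_sens: float) -> float:
    """k*Var(mu_hat) + (1-k)*Var(W_hat)."""
    if not 0.0 <= k <= 1.0:
        raise ValueError("k must lie in [0, 1]")
    return k * var_mean + (1.0 - k) * var_sens


def cost_coefficients(
    k: float, design: TwoSampleDesign, pop: Population, params: ThreeStageParams
) -> tuple[float, float]:
    """Per-subsample coefficients (C1, C2) of the objective C1/n1 + C2/n2.

    C_i = sigma_Zi^2 * [k*theta_j^2 + (1-k)/(1-T-F)^2] / denom^2 with j the
    other subsample and denom the design's moment-solution divisor.
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError("k must lie in [0, 1]")
    rest = 1.0 - params.truth_T - params.forced_F
    if rest <= 0:
        raise ValueError("requires T + F < 1")
    a = params.scramble_probability
    s1 = mm.response_variance(pop.var_x, a, design.theta1, design.scrambler1.gamma_sq)
    s2 = mm.response_variance(pop.var_x, a, design.theta2, design.scrambler2.gamma_sq)
    denom_sq = design.denom**2
    c1 = s1 * (k * design.theta2**2 + (1.0 - k) / rest**2) / denom_sq
    c2 = s2 * (k * design.theta1**2 + (1.0 - k) / rest**2) / denom_sq
    return c1, c2


def optimal_allocation(
    k: float, n: int, design: TwoSampleDesign, pop: Population, params: ThreeStageParams
) -> AllocationResult:
    """Square-root-rule allocation of n across the two subsamples.

    The continuous optimum is rounded half-up toward n1; both subsamples are
    kept nonempty.  ``v_min`` is the objective value at the continuous
    optimum, the floor that any integer split can only approach.
    """
    if n < 4:
        raise ValueError("n must be at least 4")
    c1, c2 = cost_coefficients(k, design, pop, params)
    if c1 == 0 and c2 == 0:
        raise ValueError("degenerate objective: both cost coefficients vanish")
    r1, r2 = math.sqrt(c1), math.sqrt(c2)
    n1 = int(math.floor(n * r1 / (r1 + r2) + 0.5))  # ties toward n1
    n1 = min(max(n1, 1), n - 1)
    return AllocationResult(n1, n - n1, v_min=(r1 + r2) ** 2 / n, weight_k=k)


def allocation_with_guess(
    k: float,
    n: int,
    design: TwoSampleDesign,
    pop_guess: Population,
    params_guess: ThreeStageParams,
) -> AllocationResult:
    """Allocation computed at guessed (pilot) parameter values, with a
    sensitivity report for the guessed W perturbed by +/-0.1 (clipped to
    [0, 1])."""
    base = optimal_allocation(k, n, design, pop_guess, params_guess)
    rows = []
    w0 = params_guess.sensitivity_W
    for w in (max(0.0, w0 - 0.1), w0, min(1.0, w0 + 0.1)):
        alt = optimal_allocation(k, n, design, pop_guess, params_guess.with_w(w))
        rows.append({"guessed_W": w, "n1": alt.n1_opt, "n2": alt.n2_opt,
                     "v_min": alt.v_min})
    base.sensitivity = pd.DataFrame(rows)
    return base
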