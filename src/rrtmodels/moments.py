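"""Method-of-moments estimators for ORR designs and their variances.

All point estimators are linear in the subsample means and therefore exactly
unbiased (the combined-scrambling comparator is the exception: its solution
is a ratio and only consistency holds).  The functions accept scalars or
NumPy arrays and broadcast, so the Monte Carlo engine can apply them to
thousands of replicate means in one call.

Notation: subsample means zbar1, zbar2; scrambler means theta1, theta2 and
variances gamma_sq1, gamma_sq2; stage probabilities T (truth) and F (forced
scrambling); scramble probability A = F + (1-T-F)W.

Estimator algebra (split-sample design, subsample 2 subtractive):

    E(zbar1) = mu + A*theta1,   E(zbar2) = mu - A*theta2
    mu_hat = (theta2*zbar1 + theta1*zbar2) / (theta1 + theta2)
    A_hat  = (zbar1 - zbar2) / (theta1 + theta2)
    W_hat  = (A_hat - F) / (1 - T - F)

The additive-additive (three-stage / two-stage) design replaces the sums by
differences: mu_hat = (theta2*zbar1 - theta1*zbar2)/(theta2 - theta1) and
A_hat = (zbar1 - zbar2)/(theta1 - theta2).  The double-response design uses
the split-sample algebra on the paired response means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .designs import (
    DoubleResponseDesign,
    HuangDesign,
    Population,
    ResponseSample,
    ThreeStageParams,
    TwoSampleDesign,
)

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "MomentSummary",
    "mean_split",
    "sensitivity_split",
    "mean_mehta",
    "sensitivity_mehta",
    "mean_gupta",
    "sensitivity_gupta",
    "mean_double",
    "sensitivity_double",
    "mean_huang",
    "sensitivity_huang",
    "huang_solve",
    "response_variance",
    "huang_response_variance",
    "var_mean_split",
    "var_sensitivity_split",
    "var_mean_mehta",
    "var_sensitivity_mehta",
    "var_mean_double",
    "var_sensitivity_double",
    "double_pair_covariance",
    "unbiased_var_estimates",
    "unbiased_A_functions",
    "estimate_sigma_x",
]


@dataclass
class MomentSummary:
    """First two sample moments of a two-vector response sample.

    Sample variances use divisor n-1 so that plug-in variance estimators
    remain unbiased.  For paired (double-response) data ``cov12`` holds the
    sample covariance of the pair.
    """

    zbar1: float
    zbar2: float
    s_sq_1: float
    s_sq_2: float
    n1: int
    n2: int
    cov12: Optional[float] = None
    paired: bool = False

    @classmethod
    def from_sample(cls, sample: ResponseSample) -> "MomentSummary":
        r1, r2 = sample.responses1, sample.responses2
        cov = None
        if sample.paired:
            cov = float(np.cov(r1, r2, ddof=1)[0, 1]) if r1.size > 1 else 0.0
        return cls(
            zbar1=float(r1.mean()),
            zbar2=float(r2.mean()),
            s_sq_1=float(r1.var(ddof=1)) if r1.size > 1 else 0.0,
            s_sq_2=float(r2.var(ddof=1)) if r2.size > 1 else 0.0,
            n1=r1.size,
            n2=r2.size,
            cov12=cov,
            paired=sample.paired,
        )


# ---------------------------------------------------------------------------
# point estimators
# ---------------------------------------------------------------------------


def _check_tf(truth_T: float, forced_F: float) -> float:
    rest = 1.0 - truth_T - forced_F
    if rest <= 0:
        raise ValueError("sensitivity is not estimable when T + F >= 1")
    return rest


def mean_split(zbar1: ArrayLike, zbar2: ArrayLike, theta1: float, theta2: float) -> ArrayLike:
    """Unbiased mean estimator of the split-sample (additive/subtractive)
    design: (theta2*zbar1 + theta1*zbar2)/(theta1+theta2)."""
    if theta1 + theta2 <= 0:
        raise ValueError("theta1 + theta2 must be positive")
    return (theta2 * np.asarray(zbar1) + theta1 * np.asarray(zbar2)) / (theta1 + theta2)


def sensitivity_split(
    zbar1: ArrayLike,
    zbar2: ArrayLike,
    theta1: float,
    theta2: float,
    truth_T: float,
    forced_F: float,
) -> ArrayLike:
    """Unbiased sensitivity estimator of the split-sample design.

    A_hat = (zbar1-zbar2)/(theta1+theta2); W_hat = (A_hat-F)/(1-T-F).  The
    raw value is returned even if it falls outside [0, 1].
    """
    rest = _check_tf(truth_T, forced_F)
    a_hat = (np.asarray(zbar1) - np.asarray(zbar2)) / (theta1 + theta2)
    return (a_hat - forced_F) / rest


def mean_mehta(zbar1: ArrayLike, zbar2: ArrayLike, theta1: float, theta2: float) -> ArrayLike:
    """Unbiased mean estimator of the additive-additive three-stage design:
    (theta2*zbar1 - theta1*zbar2)/(theta2-theta1).  Requires theta1 != theta2."""
    if np.isclose(theta1, theta2):
        raise ValueError("additive-additive design unidentifiable when theta1 == theta2")
    return (theta2 * np.asarray(zbar1) - theta1 * np.asarray(zbar2)) / (theta2 - theta1)


def sensitivity_mehta(
    zbar1: ArrayLike,
    zbar2: ArrayLike,
    theta1: float,
    theta2: float,
    truth_T: float,
    forced_F: float,
) -> ArrayLike:
    """Unbiased sensitivity estimator of the additive-additive design:
    A_hat = (zbar1-zbar2)/(theta1-theta2), W_hat = (A_hat-F)/(1-T-F)."""
    if np.isclose(theta1, theta2):
        raise ValueError("additive-additive design unidentifiable when theta1 == theta2")
    rest = _check_tf(truth_T, forced_F)
    a_hat = (np.asarray(zbar1) - np.asarray(zbar2)) / (theta1 - theta2)
    return (a_hat - forced_F) / rest


def mean_gupta(zbar1: ArrayLike, zbar2: ArrayLike, theta1: float, theta2: float) -> ArrayLike:
    """Two-stage special case (F = 0) of the additive-additive mean
    estimator; identical algebra, kept as its own entry point."""
    return mean_mehta(zbar1, zbar2, theta1, theta2)


def sensitivity_gupta(
    zbar1: ArrayLike, zbar2: ArrayLike, theta1: float, theta2: float, truth_T: float
) -> ArrayLike:
    """Two-stage sensitivity estimator: the F=0 specialisation."""
    return sensitivity_mehta(zbar1, zbar2, theta1, theta2, truth_T, 0.0)


# The double-response design has the same expected responses as the split
# design, so the estimators share the algebra, applied to paired means.
def mean_double(ybar1: ArrayLike, ybar2: ArrayLike, theta1: float, theta2: float) -> ArrayLike:
    """Unbiased mean estimator for paired double responses."""
    return mean_split(ybar1, ybar2, theta1, theta2)


def sensitivity_double(
    ybar1: ArrayLike,
    ybar2: ArrayLike,
    theta1: float,
    theta2: float,
    truth_T: float,
    forced_F: float,
) -> ArrayLike:
    """Unbiased sensitivity estimator for paired double responses."""
    return sensitivity_split(ybar1, ybar2, theta1, theta2, truth_T, forced_F)


def huang_solve(
    zbar1: ArrayLike,
    zbar2: ArrayLike,
    design: HuangDesign,
) -> tuple[ArrayLike, ArrayLike]:
    """Solve the combined-scrambling moment system for (mu, W).

    The system is z_i = mu + W[(mu_Ti - 1) mu + theta_i], i = 1, 2.  With a
    common multiplicative mean mu_T1 = mu_T2 the difference of the equations
    is linear in W and the solution is closed-form (a ratio, hence consistent
    but not exactly unbiased).  Otherwise W is eliminated, leaving a
    quadratic in mu solved numerically; the admissible root (real, with the
    implied W closest to [0, 1]) is returned.
    """
    mt1, mt2 = design.mult1.theta, design.mult2.theta
    th1, th2 = design.add1.theta, design.add2.theta
    z1 = np.asarray(zbar1, dtype=float)
    z2 = np.asarray(zbar2, dtype=float)
    if np.isclose(mt1, mt2):
        if np.isclose(th1, th2):
            raise ValueError("moment system unidentifiable")
        w = (z1 - z2) / (th1 - th2)
        mu = (z1 - w * th1) / (1.0 + w * (mt1 - 1.0))
        return (float(mu), float(w)) if mu.ndim == 0 else (mu, w)

    scalar = z1.ndim == 0
    z1v, z2v = np.atleast_1d(z1), np.atleast_1d(z2)
    mu_out = np.empty_like(z1v)
    w_out = np.empty_like(z1v)
    # eliminate W: (z1-mu)[(mt2-1)mu+th2] = (z2-mu)[(mt1-1)mu+th1]
    a = (mt1 - 1.0) - (mt2 - 1.0)
    for i, (u1, u2) in enumerate(zip(z1v, z2v)):
        b = u1 * (mt2 - 1.0) - u2 * (mt1 - 1.0) - th2 + th1
        c = u1 * th2 - u2 * th1
        roots = np.roots([a, b, c]) if abs(a) > 1e-14 else np.array([-c / b])
        real = roots[np.abs(roots.imag) < 1e-9].real
        if real.size == 0:
            raise ValueError(
                f"no real solution for (mu, W); moments zbar1={u1}, zbar2={u2}"
            )
        best, best_pen = None, np.inf
        for mu in real:
            den = (mt1 - 1.0) * mu + th1
            if abs(den) < 1e-12:
                continue
            w = (u1 - mu) / den
            pen = max(0.0, -w) + max(0.0, w - 1.0)
            if pen < best_pen:
                best, best_pen = (mu, w), pen
        if best is None:
            raise ValueError("degenerate moment system: no admissible root")
        mu_out[i], w_out[i] = best
    if scalar:
        return float(mu_out[0]), float(w_out[0])
    return mu_out, w_out


def mean_huang(zbar1: ArrayLike, zbar2: ArrayLike, design: HuangDesign) -> ArrayLike:
    """Mean estimate from the combined-scrambling moment system."""
    return huang_solve(zbar1, zbar2, design)[0]


def sensitivity_huang(zbar1: ArrayLike, zbar2: ArrayLike, design: HuangDesign) -> ArrayLike:
    """Sensitivity estimate from the combined-scrambling moment system."""
    return huang_solve(zbar1, zbar2, design)[1]


# ---------------------------------------------------------------------------
# theoretical variances
# ---------------------------------------------------------------------------


def response_variance(sigma_sq_x: float, a: ArrayLike, theta: float, gamma_sq: float) -> ArrayLike:
    """Variance of one scrambled response Z = X +/- S*J:

        sigma_Z^2 = sigma_X^2 + A*gamma^2 + A(1-A)*theta^2.
    """
    a = np.asarray(a, dtype=float)
    out = sigma_sq_x + a * gamma_sq + a * (1.0 - a) * theta**2
    return float(out) if out.ndim == 0 else out


def huang_response_variance(
    pop: Population, mult_mean: float, mult_var: float, theta: float, gamma_sq: float, w: float
) -> float:
    """Variance of a combined-scrambling response Z = X (prob 1-W) or
    T*X + S (prob W), from the first two moments of X, T and S."""
    ex2 = pop.var_x + pop.mean_x**2
    et2 = mult_var + mult_mean**2
    es2 = gamma_sq + theta**2
    ez = pop.mean_x + w * ((mult_mean - 1.0) * pop.mean_x + theta)
    ez2 = (1.0 - w) * ex2 + w * (et2 * ex2 + 2.0 * mult_mean * pop.mean_x * theta + es2)
    return ez2 - ez**2


def _two_sample_sigmas(design: TwoSampleDesign, pop: Population, a: float) -> tuple[float, float]:
    s1 = response_variance(pop.var_x, a, design.theta1, design.scrambler1.gamma_sq)
    s2 = response_variance(pop.var_x, a, design.theta2, design.scrambler2.gamma_sq)
    return s1, s2


def _var_mean_two_sample(
    sigma_z1: ArrayLike, sigma_z2: ArrayLike, n1: int, n2: int, theta1: float, theta2: float, denom: float
) -> ArrayLike:
    return (theta2**2 * np.asarray(sigma_z1) / n1 + theta1**2 * np.asarray(sigma_z2) / n2) / denom**2


def _var_sens_two_sample(
    sigma_z1: ArrayLike, sigma_z2: ArrayLike, n1: int, n2: int, denom: float, rest: float
) -> ArrayLike:
    return (np.asarray(sigma_z1) / n1 + np.asarray(sigma_z2) / n2) / (denom**2 * rest**2)


def var_mean_split(design: TwoSampleDesign, pop: Population, a: float) -> float:
    """Var(mu_hat) of the split design:
    [theta2^2 sZ1^2/n1 + theta1^2 sZ2^2/n2] / (theta1+theta2)^2."""
    s1, s2 = _two_sample_sigmas(design, pop, a)
    return float(
        _var_mean_two_sample(s1, s2, design.n1, design.n2, design.theta1, design.theta2,
                             design.theta1 + design.theta2)
    )


def var_sensitivity_split(
    design: TwoSampleDesign, pop: Population, a: float, truth_T: float, forced_F: float
) -> float:
    """Var(W_hat) of the split design:
    [sZ1^2/n1 + sZ2^2/n2] / [(theta1+theta2)^2 (1-T-F)^2]."""
    rest = _check_tf(truth_T, forced_F)
    s1, s2 = _two_sample_sigmas(design, pop, a)
    return float(
        _var_sens_two_sample(s1, s2, design.n1, design.n2, design.theta1 + design.theta2, rest)
    )


def var_mean_mehta(design: TwoSampleDesign, pop: Population, a: float) -> float:
    """Var(mu_hat) of the additive-additive design; the split formula with
    divisor (theta2-theta1)^2."""
    s1, s2 = _two_sample_sigmas(design, pop, a)
    return float(
        _var_mean_two_sample(s1, s2, design.n1, design.n2, design.theta1, design.theta2,
                             design.theta2 - design.theta1)
    )


def var_sensitivity_mehta(
    design: TwoSampleDesign, pop: Population, a: float, truth_T: float, forced_F: float
) -> float:
    """Var(W_hat) of the additive-additive design."""
    rest = _check_tf(truth_T, forced_F)
    s1, s2 = _two_sample_sigmas(design, pop, a)
    return float(
        _var_sens_two_sample(s1, s2, design.n1, design.n2, design.theta2 - design.theta1, rest)
    )


def double_pair_covariance(design: DoubleResponseDesign, pop: Population, a: float) -> float:
    """Cov(Y1, Y2) under the shared-indicator double design:
    sigma_X^2 - A(1-A) theta1 theta2."""
    if not design.shared_indicator:
        raise ValueError("covariance formula assumes a shared scramble indicator")
    return pop.var_x - a * (1.0 - a) * design.theta1 * design.theta2


def var_mean_double(design: DoubleResponseDesign, pop: Population, a: float) -> float:
    """Var(mu_hat) of the shared-indicator double-response design:

        sigma_X^2/n + A(theta2^2 gamma1^2 + theta1^2 gamma2^2) /
                      [n (theta1+theta2)^2]

    The combination (theta2*Y1 + theta1*Y2)/(theta1+theta2) = X +
    (theta2 S1 - theta1 S2) J/(theta1+theta2) has a mean-zero scrambling
    term, so pairing removes the Bernoulli component entirely.
    """
    if not design.shared_indicator:
        raise ValueError("variance formula assumes a shared scramble indicator")
    th1, th2 = design.theta1, design.theta2
    g1, g2 = design.scrambler1.gamma_sq, design.scrambler2.gamma_sq
    return pop.var_x / design.n + a * (th2**2 * g1 + th1**2 * g2) / (design.n * (th1 + th2) ** 2)


def var_sensitivity_double(
    design: DoubleResponseDesign, pop: Population, a: float, truth_T: float, forced_F: float
) -> float:
    """Var(W_hat) of the shared-indicator double-response design:

        [A(gamma1^2+gamma2^2) + A(1-A)(theta1+theta2)^2] /
        [n (theta1+theta2)^2 (1-T-F)^2]

    X cancels in Y1 - Y2 = (S1 + S2) J, so the population variance drops out.
    """
    if not design.shared_indicator:
        raise ValueError("variance formula assumes a shared scramble indicator")
    rest = _check_tf(truth_T, forced_F)
    th, g = design.theta1 + design.theta2, design.scrambler1.gamma_sq + design.scrambler2.gamma_sq
    return (a * g + a * (1.0 - a) * th**2) / (design.n * th**2 * rest**2)


# ---------------------------------------------------------------------------
# unbiased data-based estimators of the variances, of A-functions and of
# sigma_X^2
# ---------------------------------------------------------------------------


def _design_denom(design) -> float:
    if isinstance(design, TwoSampleDesign):
        return design.denom
    if isinstance(design, DoubleResponseDesign):
        return design.theta1 + design.theta2
    raise TypeError(f"unsupported design {type(design).__name__}")


def unbiased_var_estimates(
    m: MomentSummary, design, params: ThreeStageParams
) -> tuple[float, float]:
    """Unbiased plug-in estimates (V_hat(mu_hat), V_hat(W_hat)).

    The theoretical variances are linear in the response variances
    sigma_Zi^2, so substituting the (n-1)-divisor sample variances preserves
    unbiasedness.  Requires n1, n2 >= 2.
    """
    if m.n1 < 2 or m.n2 < 2:
        raise ValueError("variance estimation requires at least 2 responses per subsample")
    rest = _check_tf(params.truth_T, params.forced_F)
    denom = _design_denom(design)
    th1, th2 = design.theta1, design.theta2
    if isinstance(design, DoubleResponseDesign):
        # paired means: Var(mu_hat) is the variance of the per-respondent
        # combination, estimated by its sample variance / n
        u_var = (
            th2**2 * m.s_sq_1 + th1**2 * m.s_sq_2 + 2.0 * th1 * th2 * (m.cov12 or 0.0)
        ) / denom**2
        v_var = (m.s_sq_1 + m.s_sq_2 - 2.0 * (m.cov12 or 0.0)) / denom**2
        return u_var / m.n1, v_var / (m.n1 * rest**2)
    v_mu = float(_var_mean_two_sample(m.s_sq_1, m.s_sq_2, m.n1, m.n2, th1, th2, denom))
    v_w = float(_var_sens_two_sample(m.s_sq_1, m.s_sq_2, m.n1, m.n2, denom, rest))
    return v_mu, v_w


def unbiased_A_functions(
    m: MomentSummary, design, params: ThreeStageParams
) -> tuple[float, float, float]:
    """Unbiased estimates of (A, A^2, A(1-A)).

    A_hat is the moment estimate; since E(A_hat^2) = A^2 + Var(A_hat), the
    bias-corrected square is A_hat^2 - V_hat(A_hat) with
    V_hat(A_hat) = (s1^2/n1 + s2^2/n2)/denom^2 (or the paired analogue), and
    A(1-A) is estimated by A_hat - A_hat^2 + V_hat(A_hat).
    """
    if m.n1 < 2 or m.n2 < 2:
        raise ValueError("requires at least 2 responses per subsample")
    denom = _design_denom(design)
    if isinstance(design, DoubleResponseDesign):
        a_hat = (m.zbar1 - m.zbar2) / denom
        v_a = (m.s_sq_1 + m.s_sq_2 - 2.0 * (m.cov12 or 0.0)) / (denom**2 * m.n1)
    else:
        sign = -1.0 if design.sign2 == -1 else 1.0
        a_hat = (m.zbar1 - m.zbar2) / (design.theta1 - sign * design.theta2)
        v_a = (m.s_sq_1 / m.n1 + m.s_sq_2 / m.n2) / denom**2
    a_sq = a_hat**2 - v_a
    return float(a_hat), float(a_sq), float(a_hat - a_sq)


def estimate_sigma_x(
    m: MomentSummary, design, params: ThreeStageParams, k: float = 0.5
) -> float:
    """Unbiased estimator of sigma_X^2 as a convex combination of the two
    per-subsample corrected components

        sigma_hat_X^2(i) = s_i^2 - A_hat*gamma_i^2 - [A(1-A)]_hat * theta_i^2

    weighted k and 1-k.  Each component subtracts unbiased estimates of the
    scrambling contributions from the sample variance, so any fixed
    k in [0, 1] gives an unbiased estimator; k = 1/2 recovers the pooled
    equal-moments form.  The raw (possibly negative) value is returned.
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError("k must lie in [0, 1]")
    a_hat, _, a1ma = unbiased_A_functions(m, design, params)
    g1, g2 = design.scrambler1.gamma_sq, design.scrambler2.gamma_sq
    comp1 = m.s_sq_1 - a_hat * g1 - a1ma * design.theta1**2
    comp2 = m.s_sq_2 - a_hat * g2 - a1ma * design.theta2**2
    return float(k * comp1 + (1.0 - k) * comp2)
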