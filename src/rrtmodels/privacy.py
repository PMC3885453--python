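"""Privacy-protection measures for ORR designs.

The measure is the expected squared distance between the reported and the
true response, Delta = E(Z - X)^2: larger means more privacy, zero means the
design reveals the true value.  For additive or subtractive scrambling with
scramble probability A,

    Delta = A * (theta^2 + gamma^2),

identical for both signs since the sign squares away — so the split-sample
design protects exactly as much as the additive-additive design with the
same parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .designs import (
    DoubleResponseDesign,
    HuangDesign,
    Population,
    Scrambler,
    ThreeStageParams,
    TwoSampleDesign,
)

__all__ = [
    "privacy_additive",
    "privacy_huang",
    "privacy_double",
    "PrivacyReport",
    "privacy_two_sample",
    "privacy_table",
]


@dataclass
class PrivacyReport:
    """Per-subsample privacy measures Delta (units of X squared)."""

    design_id: str
    delta1: float
    delta2: float
    params: dict = field(default_factory=dict)


def privacy_additive(a: float, theta: float, gamma_sq: float) -> float:
    """Delta = A*(theta^2 + gamma^2) for one additively or subtractively
    scrambled response; Delta = 0 iff A = 0."""
    if not 0 <= a <= 1:
        raise ValueError("scramble probability must lie in [0, 1]")
    return a * (theta**2 + gamma_sq)


def privacy_two_sample(
    design: TwoSampleDesign, params: ThreeStageParams, design_id: str | None = None
) -> PrivacyReport:
    """Per-subsample Delta for any two-subsample additive/subtractive design.

    The value depends only on A and the scrambler moments, not on the sign,
    so split-sample and additive-additive reports coincide exactly.
    """
    a = params.scramble_probability
    if design_id is None:
        design_id = "split" if design.sign2 == -1 else (
            "gupta" if params.forced_F == 0 else "mehta")
    return PrivacyReport(
        design_id=design_id,
        delta1=privacy_additive(a, design.theta1, design.scrambler1.gamma_sq),
        delta2=privacy_additive(a, design.theta2, design.scrambler2.gamma_sq),
        params={"A": a, "truth_T": params.truth_T, "forced_F": params.forced_F,
                "sensitivity_W": params.sensitivity_W},
    )


def _huang_subsample_delta(
    pop: Population, mult: Scrambler, add: Scrambler, w: float
) -> float:
    # Delta = W * E[((T-1)X + S)^2], expanded in the known second moments
    ex2 = pop.var_x + pop.mean_x**2
    e_tm1_sq = mult.gamma_sq + (mult.theta - 1.0) ** 2
    es2 = add.gamma_sq + add.theta**2
    return w * (e_tm1_sq * ex2 + 2.0 * (mult.theta - 1.0) * pop.mean_x * add.theta + es2)


def privacy_huang(design: HuangDesign, pop: Population, sensitivity_w: float) -> PrivacyReport:
    """Per-subsample Delta for the combined-scrambling comparator; depends on
    the population moments because the multiplicative term scales X."""
    if not 0 <= sensitivity_w <= 1:
        raise ValueError("W must lie in [0, 1]")
    return PrivacyReport(
        design_id="huang",
        delta1=_huang_subsample_delta(pop, design.mult1, design.add1, sensitivity_w),
        delta2=_huang_subsample_delta(pop, design.mult2, design.add2, sensitivity_w),
        params={"sensitivity_W": sensitivity_w},
    )


def privacy_double(
    design: DoubleResponseDesign,
    params: ThreeStageParams,
    convention: str = "per_response",
) -> float:
    """Privacy of the double-response design under one of two conventions.

    ``per_response`` (default): the average single-response measure
    (Delta1 + Delta2)/2 = A*(theta1^2+gamma1^2+theta2^2+gamma2^2)/2.

    ``pair_midpoint``: an intruder averaging the pair,
    E[((Y1+Y2)/2 - X)^2] = A*(gamma1^2+gamma2^2+(theta1-theta2)^2)/4,
    which is small when the two scramblers have similar means because the
    additive and subtractive perturbations nearly cancel in the midpoint.
    """
    a = params.scramble_probability
    th1, th2 = design.theta1, design.theta2
    g1, g2 = design.scrambler1.gamma_sq, design.scrambler2.gamma_sq
    if convention == "per_response":
        return 0.5 * a * (th1**2 + g1 + th2**2 + g2)
    if convention == "pair_midpoint":
        return 0.25 * a * (g1 + g2 + (th1 - th2) ** 2)
    raise ValueError("convention must be 'per_response' or 'pair_midpoint'")


def privacy_table(
    pop: Population,
    params: ThreeStageParams,
    two_sample: TwoSampleDesign,
    double: DoubleResponseDesign | None = None,
    huang: HuangDesign | None = None,
) -> pd.DataFrame:
    """Tidy comparison of Delta across designs at common parameters.

    The additive-additive and split rows use the same scramblers; the
    two-stage row re-evaluates A at F = 0.
    """
    rows = []
    scr1, scr2 = two_sample.scrambler1, two_sample.scrambler2

    def add_row(design_id, rep: PrivacyReport):
        rows.append({"design": design_id, "subsample": 1, "delta": rep.delta1})
        rows.append({"design": design_id, "subsample": 2, "delta": rep.delta2})

    mehta_design = TwoSampleDesign(scr1, scr2, +1, two_sample.n1, two_sample.n2) \
        if two_sample.sign2 == -1 else two_sample
    split_design = TwoSampleDesign(scr1, scr2, -1, two_sample.n1, two_sample.n2) \
        if two_sample.sign2 == +1 else two_sample
    add_row("mehta", privacy_two_sample(mehta_design, params, "mehta"))
    gupta_params = ThreeStageParams(params.truth_T, 0.0, params.sensitivity_W)
    add_row("gupta", privacy_two_sample(mehta_design, gupta_params, "gupta"))
    add_row("split", privacy_two_sample(split_design, params, "split"))
    if double is not None:
        d = privacy_double(double, params)
        rows.append({"design": "double", "subsample": 0, "delta": d})
    if huang is not None:
        add_row("huang", privacy_huang(huang, pop, params.sensitivity_W))
    df = pd.DataFrame(rows)
    df["A"] = params.scramble_probability
    df.loc[df["design"] == "gupta", "A"] = gupta_params.scramble_probability
    return df
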