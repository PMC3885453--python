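"""Seed-controlled response simulators for all five ORR designs.

Every public simulator accepts an integer ``seed`` and is bit-reproducible.
Two-subsample designs derive one independent child stream per subsample from
``numpy.random.SeedSequence(seed).spawn(2)``, so subsample 1's draws never
depend on subsample 2's size or parameters.

Each simulator has a vectorised core that generates a (reps, n) matrix of
responses in one call; the public single-sample functions are the reps=None
case of the same code path.  The Monte Carlo engine reuses the matrix cores,
so tested simulator behaviour and study behaviour cannot diverge.

Draw order within a stream is fixed and documented: X first, then the
scrambling value(s), then the Bernoulli scramble indicator.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .designs import (
    DoubleResponseDesign,
    HuangDesign,
    Population,
    ResponseSample,
    Scrambler,
    ThreeStageParams,
    TwoSampleDesign,
)

__all__ = [
    "simulate_three_stage_subsample",
    "simulate_two_sample",
    "simulate_double",
    "simulate_huang",
    "subsample_rngs",
]


def subsample_rngs(seed: int, k: int = 2) -> list[np.random.Generator]:
    """Return ``k`` independent generators deterministically derived from
    ``seed`` (one per subsample) via SeedSequence spawning."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(k)]


def _three_stage_matrix(
    pop: Population,
    scr: Scrambler,
    params: ThreeStageParams,
    sign: int,
    shape,
    rng: np.random.Generator,
) -> np.ndarray:
    """Core sampler: Z = X + sign * S * J with J ~ Bernoulli(A), all mutually
    independent."""
    x = pop.draw(shape, rng)
    s = scr.draw(shape, rng)
    j = rng.random(shape) < params.scramble_probability
    return x + sign * s * j


def simulate_three_stage_subsample(
    pop: Population,
    scr: Scrambler,
    params: ThreeStageParams,
    sign: int,
    n: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate one subsample of n three-stage optional randomized responses.

    Each respondent reports X + sign*S if their Bernoulli(A) indicator fires
    and X otherwise, with A = F + (1-T-F)W.
    """
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return _three_stage_matrix(pop, scr, params, sign, (n,), rng)


def _two_sample_matrices(
    design: TwoSampleDesign,
    pop: Population,
    params: ThreeStageParams,
    seed: int,
    reps: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    rng1, rng2 = subsample_rngs(seed)
    shape1 = (design.n1,) if reps is None else (reps, design.n1)
    shape2 = (design.n2,) if reps is None else (reps, design.n2)
    z1 = _three_stage_matrix(pop, design.scrambler1, params, +1, shape1, rng1)
    z2 = _three_stage_matrix(pop, design.scrambler2, params, design.sign2, shape2, rng2)
    return z1, z2


def simulate_two_sample(
    design: TwoSampleDesign,
    pop: Population,
    params: ThreeStageParams,
    seed: int,
) -> ResponseSample:
    """Simulate both subsamples of a two-subsample design.

    Subsample 1 always scrambles additively; subsample 2 scrambles with
    ``design.sign2``.  With sign2=+1 and F=0 this is exactly the two-stage
    design code path (the three-stage mechanism with the forced group empty),
    so the two-stage special case is bit-identical for identical seeds.
    """
    z1, z2 = _two_sample_matrices(design, pop, params, seed)
    kind = "split" if design.sign2 == -1 else ("gupta" if params.forced_F == 0 else "mehta")
    return ResponseSample(
        z1,
        z2,
        design_kind=kind,
        paired=False,
        seed=seed,
        meta={
            "theta1": design.theta1,
            "theta2": design.theta2,
            "gamma_sq1": design.scrambler1.gamma_sq,
            "gamma_sq2": design.scrambler2.gamma_sq,
            "sign2": design.sign2,
            "truth_T": params.truth_T,
            "forced_F": params.forced_F,
        },
    )


def _double_matrices(
    design: DoubleResponseDesign,
    pop: Population,
    params: ThreeStageParams,
    seed: int,
    reps: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    shape = (design.n,) if reps is None else (reps, design.n)
    x = pop.draw(shape, rng)
    s1 = design.scrambler1.draw(shape, rng)
    s2 = s1 if design.shared_scramble_value else design.scrambler2.draw(shape, rng)
    a = params.scramble_probability
    j1 = rng.random(shape) < a
    j2 = j1 if design.shared_indicator else (rng.random(shape) < a)
    return x + s1 * j1, x - s2 * j2


def simulate_double(
    design: DoubleResponseDesign,
    pop: Population,
    params: ThreeStageParams,
    seed: int,
) -> ResponseSample:
    """Simulate paired double responses Y1 = X + S1*J, Y2 = X - S2*J.

    Under the default shared indicator, respondents who do not scramble
    report the identical value twice; scrambling respondents report a pair
    from which X cannot be reconstructed because S1 and S2 are independent.
    """
    y1, y2 = _double_matrices(design, pop, params, seed)
    return ResponseSample(
        y1,
        y2,
        design_kind="double",
        paired=True,
        seed=seed,
        meta={
            "theta1": design.theta1,
            "theta2": design.theta2,
            "gamma_sq1": design.scrambler1.gamma_sq,
            "gamma_sq2": design.scrambler2.gamma_sq,
            "shared_indicator": design.shared_indicator,
            "shared_scramble_value": design.shared_scramble_value,
            "truth_T": params.truth_T,
            "forced_F": params.forced_F,
        },
    )


def _huang_subsample_matrix(
    pop: Population,
    mult: Scrambler,
    add: Scrambler,
    w: float,
    shape,
    rng: np.random.Generator,
) -> np.ndarray:
    x = pop.draw(shape, rng)
    t = mult.draw(shape, rng)
    s = add.draw(shape, rng)
    j = rng.random(shape) < w
    return np.where(j, t * x + s, x)


def _huang_matrices(
    design: HuangDesign,
    pop: Population,
    sensitivity_w: float,
    seed: int,
    reps: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    rng1, rng2 = subsample_rngs(seed)
    shape1 = (design.n1,) if reps is None else (reps, design.n1)
    shape2 = (design.n2,) if reps is None else (reps, design.n2)
    z1 = _huang_subsample_matrix(pop, design.mult1, design.add1, sensitivity_w, shape1, rng1)
    z2 = _huang_subsample_matrix(pop, design.mult2, design.add2, sensitivity_w, shape2, rng2)
    return z1, z2


def simulate_huang(
    design: HuangDesign,
    pop: Population,
    sensitivity_w: float,
    seed: int,
) -> ResponseSample:
    """Simulate the combined multiplicative-additive comparator design:
    with probability W a respondent reports T_i*X + S_i, otherwise X."""
    if not 0 <= sensitivity_w <= 1:
        raise ValueError("sensitivity_w must lie in [0, 1]")
    z1, z2 = _huang_matrices(design, pop, sensitivity_w, seed)
    return ResponseSample(
        z1,
        z2,
        design_kind="huang",
        paired=False,
        seed=seed,
        meta={
            "mu_t1": design.mult1.theta,
            "tau_sq1": design.mult1.gamma_sq,
            "theta1": design.add1.theta,
            "gamma_sq1": design.add1.gamma_sq,
            "mu_t2": design.mult2.theta,
            "tau_sq2": design.mult2.gamma_sq,
            "theta2": design.add2.theta,
            "gamma_sq2": design.add2.gamma_sq,
        },
    )
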