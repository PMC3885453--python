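"""Domain types for optional randomized response (ORR) survey designs.

An ORR design asks each respondent about a sensitive quantitative variable X.
Respondents who regard the question as sensitive perturb ("scramble") their
answer with a positive-valued scrambling variable S whose mean and variance
are known to the analyst; the proportion who scramble is the unknown
sensitivity level W.  The three-stage variant additionally fixes a truth
proportion T (always answer honestly) and a forced-scrambling proportion F
(always scramble), so the total scramble probability is

    A = F + (1 - T - F) * W.

The types below carry the population, the scrambling devices and the sampling
plan for five designs: the three-stage two-subsample additive design, its
two-stage special case (F = 0), the additive/subtractive split-sample design,
the paired double-response design, and the combined multiplicative-additive
comparator design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Population",
    "Scrambler",
    "ThreeStageParams",
    "TwoSampleDesign",
    "DoubleResponseDesign",
    "HuangDesign",
    "ResponseSample",
    "scramble_probability",
]

_POP_FAMILIES = ("normal", "gamma", "uniform")
_SCR_FAMILIES = ("gamma", "uniform", "point_mass")


@dataclass(frozen=True)
class Population:
    """Distribution of the sensitive study variable X.

    Parameterised by its mean and variance; ``family`` selects the shape used
    by the simulators.  The gamma family requires a positive mean.
    """

    mean_x: float
    var_x: float
    family: str = "gamma"

    def __post_init__(self) -> None:
        if self.var_x <= 0:
            raise ValueError(f"var_x must be > 0, got {self.var_x}")
        if self.family not in _POP_FAMILIES:
            raise ValueError(f"family must be one of {_POP_FAMILIES}")
        if self.family == "gamma" and self.mean_x <= 0:
            raise ValueError("gamma population requires mean_x > 0")
        if self.family == "uniform" and self.mean_x - math.sqrt(3 * self.var_x) < 0:
            # uniform support [mean - h, mean + h]; negative support is allowed
            # for X in principle, but keep the gamma-like convention of a
            # nonnegative study variable for the uniform family too.
            pass

    def draw(self, shape, rng: np.random.Generator) -> np.ndarray:
        if self.family == "normal":
            return rng.normal(self.mean_x, math.sqrt(self.var_x), size=shape)
        if self.family == "gamma":
            k = self.mean_x**2 / self.var_x
            scale = self.var_x / self.mean_x
            return rng.gamma(k, scale, size=shape)
        h = math.sqrt(3 * self.var_x)
        return rng.uniform(self.mean_x - h, self.mean_x + h, size=shape)


@dataclass(frozen=True)
class Scrambler:
    """Positive-valued scrambling variable S with known mean and variance.

    ``theta`` is E(S), ``gamma_sq`` is Var(S).  Every supported family has
    strictly positive support; the uniform family therefore requires
    theta > sqrt(3 * gamma_sq).
    """

    theta: float
    gamma_sq: float = 0.0
    family: str = "gamma"

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if self.gamma_sq < 0:
            raise ValueError(f"gamma_sq must be >= 0, got {self.gamma_sq}")
        if self.family not in _SCR_FAMILIES:
            raise ValueError(f"family must be one of {_SCR_FAMILIES}")
        if self.family == "gamma" and self.gamma_sq == 0:
            object.__setattr__(self, "family", "point_mass")
        if self.family == "point_mass" and self.gamma_sq != 0:
            raise ValueError("point_mass scrambler requires gamma_sq == 0")
        if self.family == "uniform":
            if self.theta - math.sqrt(3 * self.gamma_sq) <= 0:
                raise ValueError(
                    "uniform scrambler support must be positive: "
                    "requires theta > sqrt(3*gamma_sq)"
                )

    def draw(self, shape, rng: np.random.Generator) -> np.ndarray:
        if self.family == "point_mass":
            return np.full(shape, self.theta)
        if self.family == "gamma":
            k = self.theta**2 / self.gamma_sq
            scale = self.gamma_sq / self.theta
            return rng.gamma(k, scale, size=shape)
        h = math.sqrt(3 * self.gamma_sq)
        return rng.uniform(self.theta - h, self.theta + h, size=shape)


@dataclass(frozen=True)
class ThreeStageParams:
    """Stage probabilities of the three-stage ORR mechanism.

    truth_T: proportion instructed to answer truthfully.
    forced_F: proportion instructed to scramble regardless of opinion.
    sensitivity_W: unknown proportion of the optional group who scramble.
    """

    truth_T: float
    forced_F: float
    sensitivity_W: float

    def __post_init__(self) -> None:
        if not (0 <= self.truth_T and 0 <= self.forced_F):
            raise ValueError("T and F must be nonnegative")
        if self.truth_T + self.forced_F > 1 + 1e-12:
            raise ValueError("T + F must not exceed 1")
        if not 0 <= self.sensitivity_W <= 1:
            raise ValueError("W must lie in [0, 1]")

    @property
    def scramble_probability(self) -> float:
        """Total probability A = F + (1-T-F)W that a response is scrambled."""
        return self.forced_F + (1 - self.truth_T - self.forced_F) * self.sensitivity_W

    def with_w(self, w: float) -> "ThreeStageParams":
        return ThreeStageParams(self.truth_T, self.forced_F, w)


def scramble_probability(params: ThreeStageParams) -> float:
    """Return A = F + (1-T-F)*W for a valid parameter set."""
    return params.scramble_probability


@dataclass(frozen=True)
class TwoSampleDesign:
    """Two independent subsamples with additive scrambling in subsample 1 and
    additive (sign2=+1) or subtractive (sign2=-1) scrambling in subsample 2.

    sign2=+1 encodes the classical three-stage (and, with F=0, two-stage)
    additive design, which needs theta1 != theta2 to identify (mu, A).
    sign2=-1 encodes the split-sample additive/subtractive design, identified
    whenever theta1 + theta2 > 0 (always, by positivity).
    """

    scrambler1: Scrambler
    scrambler2: Scrambler
    sign2: int = -1
    n1: int = 100
    n2: int = 100

    def __post_init__(self) -> None:
        if self.sign2 not in (+1, -1):
            raise ValueError("sign2 must be +1 or -1")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("subsample sizes must be positive")
        if self.sign2 == +1 and math.isclose(
            self.scrambler1.theta, self.scrambler2.theta
        ):
            raise ValueError(
                "additive-additive design is unidentifiable when theta1 == theta2"
            )

    @property
    def theta1(self) -> float:
        return self.scrambler1.theta

    @property
    def theta2(self) -> float:
        return self.scrambler2.theta

    @property
    def denom(self) -> float:
        """theta2 - theta1 (additive pair) or theta1 + theta2 (split pair):
        the divisor of the moment solution."""
        return (
            self.theta1 + self.theta2
            if self.sign2 == -1
            else self.theta2 - self.theta1
        )

    def with_sizes(self, n1: int, n2: int) -> "TwoSampleDesign":
        return TwoSampleDesign(self.scrambler1, self.scrambler2, self.sign2, n1, n2)


@dataclass(frozen=True)
class DoubleResponseDesign:
    """One sample, two responses per respondent: the first additively and the
    second subtractively scrambled.

    With ``shared_indicator`` (default) a single scramble/no-scramble decision
    per respondent governs both responses, so an honest respondent reports the
    same value twice.  The two scrambling values are drawn independently
    unless ``shared_scramble_value`` is set, so the true X cannot be recovered
    by averaging a scrambled pair.
    """

    scrambler1: Scrambler
    scrambler2: Scrambler
    n: int = 100
    shared_indicator: bool = True
    shared_scramble_value: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")

    @property
    def theta1(self) -> float:
        return self.scrambler1.theta

    @property
    def theta2(self) -> float:
        return self.scrambler2.theta


@dataclass(frozen=True)
class HuangDesign:
    """Two-subsample comparator design with combined multiplicative-additive
    scrambling: a scrambling respondent in subsample i reports T_i*X + S_i.

    ``mult_i`` holds the multiplicative scrambler T_i (mean mu_T, variance
    tau^2), ``add_i`` the additive scrambler S_i.  The two subsamples' moment
    equations z_i = mu + W[(mu_Ti - 1) mu + theta_i] must not be proportional.
    """

    mult1: Scrambler
    add1: Scrambler
    mult2: Scrambler
    add2: Scrambler
    n1: int = 100
    n2: int = 100

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("subsample sizes must be positive")
        same_mult = math.isclose(self.mult1.theta, self.mult2.theta)
        same_add = math.isclose(self.add1.theta, self.add2.theta)
        if same_mult and same_add:
            raise ValueError(
                "moment equations are proportional: the two subsamples need "
                "different multiplicative means or different additive means"
            )


@dataclass
class ResponseSample:
    """Observed (or simulated) scrambled responses with design metadata.

    ``paired`` marks double-response data, where responses1[i] and
    responses2[i] come from the same respondent.
    """

    responses1: np.ndarray
    responses2: np.ndarray
    design_kind: str
    paired: bool = False
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.responses1 = np.asarray(self.responses1, dtype=float)
        self.responses2 = np.asarray(self.responses2, dtype=float)
        if self.paired and self.responses1.shape != self.responses2.shape:
            raise ValueError("paired samples need equal-length response vectors")

    @property
    def n1(self) -> int:
        return self.responses1.size

    @property
    def n2(self) -> int:
        return self.responses2.size
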