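"""Monte Carlo engine for relative-efficiency studies and simulation oracles.

A :class:`Scenario` fixes the population, the stage probabilities, the two
additive scramblers and the subsample sizes; the engine simulates every
design under that scenario, applies the matching estimators replicate by
replicate (vectorised) and summarises their empirical moments.  Relative
efficiency is the variance ratio

    RE = Var(competitor) / Var(proposed),

so RE > 1 favours the proposed (split-sample or double-response) design.
Closed-form variances exist for the split, additive-additive, two-stage and
double designs; the combined-scrambling comparator is evaluated empirically
only.

Fairness convention: the double-response design interviews a single sample
of n1 + n2 respondents (two responses each, no extra sampling cost), so its
comparisons use the same total sample size as the two-subsample designs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import moments as mm
from .designs import (
    DoubleResponseDesign,
    HuangDesign,
    Population,
    Scrambler,
    ThreeStageParams,
    TwoSampleDesign,
)
from .simulate import _double_matrices, _huang_matrices, _two_sample_matrices

__all__ = [
    "Scenario",
    "REResult",
    "empirical_moments",
    "analytic_variance",
    "relative_efficiency",
    "scenario_grid",
    "re_study",
    "mu_invariance_check",
    "plot_re_curves",
    "DESIGN_IDS",
]

DESIGN_IDS = ("split", "mehta", "gupta", "double", "huang")
_PARAMS = ("mean", "sensitivity")
_DESIGN_STREAM = {k: i for i, k in enumerate(DESIGN_IDS)}

#: default multiplicative scrambler of the comparator design: mean 1 keeps
#: its moment system linear while the variance 0.25 contributes realistic
#: multiplicative noise
DEFAULT_HUANG_MULT = Scrambler(1.0, 0.25, "gamma")


@dataclass(frozen=True)
class Scenario:
    """One fully specified simulation condition."""

    pop: Population
    params: ThreeStageParams
    scrambler1: Scrambler
    scrambler2: Scrambler
    n1: int = 100
    n2: int = 100
    reps: int = 5000
    seed: int = 0
    huang_mult1: Scrambler = DEFAULT_HUANG_MULT
    huang_mult2: Scrambler = DEFAULT_HUANG_MULT

    def __post_init__(self) -> None:
        if self.reps < 100:
            raise ValueError("replicate count must be at least 100")

    # -- designs under this scenario -------------------------------------
    def two_sample_design(self, sign2: int) -> TwoSampleDesign:
        return TwoSampleDesign(self.scrambler1, self.scrambler2, sign2, self.n1, self.n2)

    def double_design(self) -> DoubleResponseDesign:
        return DoubleResponseDesign(self.scrambler1, self.scrambler2, self.n1 + self.n2)

    def huang_design(self) -> HuangDesign:
        return HuangDesign(self.huang_mult1, self.scrambler1,
                           self.huang_mult2, self.scrambler2, self.n1, self.n2)

    def gupta_params(self) -> ThreeStageParams:
        return ThreeStageParams(self.params.truth_T, 0.0, self.params.sensitivity_W)

    def design_seed(self, design_id: str) -> int:
        """Deterministic per-design simulation seed derived from the scenario
        seed so design streams are independent but reproducible."""
        ss = np.random.SeedSequence([self.seed, _DESIGN_STREAM[design_id]])
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _parse_estimator_id(estimator_id: str) -> tuple[str, str]:
    design_id, _, param = estimator_id.rpartition("_")
    if design_id not in DESIGN_IDS or param not in _PARAMS:
        raise ValueError(
            f"estimator id must be '<design>_<parameter>' with design in "
            f"{DESIGN_IDS} and parameter in {_PARAMS}; got {estimator_id!r}"
        )
    return design_id, param


@lru_cache(maxsize=512)
def _replicate_estimates(scenario: Scenario, design_id: str) -> dict:
    """Per-replicate (mean, sensitivity) estimates for one design, simulated
    once per (scenario, design) and shared by both parameters."""
    seed = scenario.design_seed(design_id)
    pop, params, reps = scenario.pop, scenario.params, scenario.reps
    t, f = params.truth_T, params.forced_F
    if design_id in ("split", "mehta", "gupta"):
        sign2 = -1 if design_id == "split" else +1
        p = scenario.gupta_params() if design_id == "gupta" else params
        design = scenario.two_sample_design(sign2)
        z1, z2 = _two_sample_matrices(design, pop, p, seed, reps=reps)
        zb1, zb2 = z1.mean(axis=1), z2.mean(axis=1)
        if design_id == "split":
            mu = mm.mean_split(zb1, zb2, design.theta1, design.theta2)
            w = mm.sensitivity_split(zb1, zb2, design.theta1, design.theta2, t, f)
        else:
            mu = mm.mean_mehta(zb1, zb2, design.theta1, design.theta2)
            w = mm.sensitivity_mehta(zb1, zb2, design.theta1, design.theta2, t,
                                     0.0 if design_id == "gupta" else f)
    elif design_id == "double":
        design = scenario.double_design()
        y1, y2 = _double_matrices(design, pop, params, seed, reps=reps)
        yb1, yb2 = y1.mean(axis=1), y2.mean(axis=1)
        mu = mm.mean_double(yb1, yb2, design.theta1, design.theta2)
        w = mm.sensitivity_double(yb1, yb2, design.theta1, design.theta2, t, f)
    elif design_id == "huang":
        design = scenario.huang_design()
        z1, z2 = _huang_matrices(design, pop, params.sensitivity_W, seed, reps=reps)
        mu, w = mm.huang_solve(z1.mean(axis=1), z2.mean(axis=1), design)
    else:  # pragma: no cover - guarded by _parse_estimator_id
        raise ValueError(design_id)
    return {"mean": np.asarray(mu), "sensitivity": np.asarray(w)}


def empirical_moments(estimator_id: str, scenario: Scenario) -> tuple[float, float, float]:
    """(MC mean, MC variance, MC standard error of the mean) of one
    estimator over ``scenario.reps`` simulated replicates."""
    design_id, param = _parse_estimator_id(estimator_id)
    est = _replicate_estimates(scenario, design_id)[param]
    var = float(est.var(ddof=1))
    return float(est.mean()), var, float(np.sqrt(var / est.size))


def analytic_variance(estimator_id: str, scenario: Scenario) -> Optional[float]:
    """Closed-form estimator variance under the scenario's true parameters,
    or None where no closed form exists (the combined-scrambling design)."""
    design_id, param = _parse_estimator_id(estimator_id)
    pop, params = scenario.pop, scenario.params
    t, f = params.truth_T, params.forced_F
    a = params.scramble_probability
    if design_id == "split":
        d = scenario.two_sample_design(-1)
        return (mm.var_mean_split(d, pop, a) if param == "mean"
                else mm.var_sensitivity_split(d, pop, a, t, f))
    if design_id in ("mehta", "gupta"):
        d = scenario.two_sample_design(+1)
        if design_id == "gupta":
            a, f = scenario.gupta_params().scramble_probability, 0.0
        return (mm.var_mean_mehta(d, pop, a) if param == "mean"
                else mm.var_sensitivity_mehta(d, pop, a, t, f))
    if design_id == "double":
        d = scenario.double_design()
        return (mm.var_mean_double(d, pop, a) if param == "mean"
                else mm.var_sensitivity_double(d, pop, a, t, f))
    return None


@dataclass
class REResult:
    """Relative efficiency Var(numerator)/Var(denominator) for one scenario."""

    scenario: Scenario
    numerator: str
    denominator: str
    re_empirical: float
    mc_se: float
    re_analytic: Optional[float] = None

    @property
    def comparison(self) -> str:
        num = self.numerator.rsplit("_", 1)[0]
        den = self.denominator.rsplit("_", 1)[0]
        return f"{den}_vs_{num}"


def _var_of_sample_variance(estimates: np.ndarray) -> float:
    # Var(s^2) ~ (m4 - s^4)/reps to first order
    c = estimates - estimates.mean()
    m4 = float((c**4).mean())
    s2 = float(c.var(ddof=1))
    return max(m4 - s2**2, 0.0) / estimates.size


def relative_efficiency(
    numerator_estimator: str,
    denominator_estimator: str,
    scenario: Scenario,
    mode: str = "both",
) -> REResult:
    """Relative efficiency of two estimators of the same parameter.

    ``mode='analytic'`` uses closed forms only (error if unavailable);
    ``'empirical'`` simulates; ``'both'`` (default) reports both where
    possible.  The MC standard error of the empirical ratio comes from the
    delta method on the two independent variance estimates.
    """
    n_design, n_param = _parse_estimator_id(numerator_estimator)
    d_design, d_param = _parse_estimator_id(denominator_estimator)
    if n_param != d_param:
        raise ValueError("both estimators must target the same parameter")
    if mode not in ("analytic", "empirical", "both"):
        raise ValueError("mode must be 'analytic', 'empirical' or 'both'")

    re_analytic = None
    if mode in ("analytic", "both"):
        v_num = analytic_variance(numerator_estimator, scenario)
        v_den = analytic_variance(denominator_estimator, scenario)
        if v_num is not None and v_den is not None:
            if v_den == 0:
                raise ZeroDivisionError("denominator variance is zero")
            re_analytic = v_num / v_den
        elif mode == "analytic":
            raise ValueError(
                "no closed-form variance for "
                f"{n_design if v_num is None else d_design}; use empirical mode"
            )

    re_empirical, mc_se = np.nan, np.nan
    if mode in ("empirical", "both"):
        est_num = _replicate_estimates(scenario, n_design)[n_param]
        est_den = _replicate_estimates(scenario, d_design)[d_param]
        v_num_e = float(est_num.var(ddof=1))
        v_den_e = float(est_den.var(ddof=1))
        if v_den_e == 0:
            raise ZeroDivisionError("empirical denominator variance is zero")
        re_empirical = v_num_e / v_den_e
        rel1 = _var_of_sample_variance(est_num) / v_num_e**2
        rel2 = _var_of_sample_variance(est_den) / v_den_e**2
        mc_se = re_empirical * float(np.sqrt(rel1 + rel2))
    return REResult(scenario, numerator_estimator, denominator_estimator,
                    re_empirical, mc_se, re_analytic)


def scenario_grid(
    base: Scenario,
    w_grid: Sequence[float],
    t_values: Sequence[float],
    f_values: Sequence[float],
    theta_pairs: Sequence[tuple[float, float]],
) -> list[Scenario]:
    """Cartesian product of the grids, each scenario with its own seed
    deterministically spawned from the base seed."""
    if not (len(w_grid) and len(t_values) and len(f_values) and len(theta_pairs)):
        raise ValueError("all grids must be nonempty")
    combos = list(itertools.product(w_grid, t_values, f_values, theta_pairs))
    children = np.random.SeedSequence(base.seed).spawn(len(combos))
    out = []
    for (w, t, f, (th1, th2)), child in zip(combos, children):
        seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        out.append(replace(
            base,
            params=ThreeStageParams(t, f, w),
            scrambler1=replace(base.scrambler1, theta=th1),
            scrambler2=replace(base.scrambler2, theta=th2),
            seed=seed,
        ))
    return out


DEFAULT_W_GRID = tuple(round(0.05 * i, 2) for i in range(21))
DEFAULT_T_VALUES = (0.2, 0.4)
DEFAULT_F_VALUES = (0.1, 0.2)
DEFAULT_THETA_PAIRS = ((1.0, 2.0), (1.0, 3.0), (2.0, 5.0))

#: comparison families of the efficiency study: competitor (numerator)
#: against proposed design (denominator)
DEFAULT_COMPARISONS = (
    ("mehta", "split"), ("gupta", "split"), ("huang", "split"),
    ("mehta", "double"), ("gupta", "double"), ("huang", "double"),
)


def re_study(
    base: Scenario,
    w_grid: Sequence[float] = DEFAULT_W_GRID,
    t_values: Sequence[float] = DEFAULT_T_VALUES,
    f_values: Sequence[float] = DEFAULT_F_VALUES,
    theta_pairs: Sequence[tuple[float, float]] = DEFAULT_THETA_PAIRS,
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
    parameters: Sequence[str] = _PARAMS,
    mode: str = "both",
) -> pd.DataFrame:
    """Run the full relative-efficiency study over a scenario grid.

    Returns one tidy row per scenario x comparison x parameter with the
    analytic and/or empirical RE, its MC standard error, and the scenario
    coordinates.
    """
    scenarios = scenario_grid(base, w_grid, t_values, f_values, theta_pairs)
    rows = []
    for sid, sc in enumerate(scenarios):
        for num_design, den_design in comparisons:
            for param in parameters:
                res = relative_efficiency(
                    f"{num_design}_{param}", f"{den_design}_{param}", sc, mode=mode
                )
                rows.append({
                    "scenario": sid,
                    "W": sc.params.sensitivity_W,
                    "T": sc.params.truth_T,
                    "F": sc.params.forced_F,
                    "theta1": sc.scrambler1.theta,
                    "theta2": sc.scrambler2.theta,
                    "gamma_sq1": sc.scrambler1.gamma_sq,
                    "gamma_sq2": sc.scrambler2.gamma_sq,
                    "comparison": res.comparison,
                    "parameter": param,
                    "re_analytic": res.re_analytic,
                    "re_empirical": res.re_empirical,
                    "mc_se": res.mc_se,
                    "reps": sc.reps,
                    "seed": sc.seed,
                })
        _replicate_estimates.cache_clear()
    return pd.DataFrame(rows)


def mu_invariance_check(scenarios: Sequence[Scenario],
                        comparison: tuple[str, str] = ("mehta", "split"),
                        parameter: str = "mean") -> dict:
    """Verify that relative efficiencies do not depend on the population
    mean: the scenarios must be identical except for mu_X.  Analytic REs are
    exactly equal (mu_X cancels in every variance ratio); empirical REs
    scatter within MC noise."""
    for a, b in zip(scenarios, scenarios[1:]):
        if replace(a, pop=replace(a.pop, mean_x=1.0), seed=0) != replace(
            b, pop=replace(b.pop, mean_x=1.0), seed=0
        ):
            raise ValueError("scenarios may differ only in mu_X (and seed)")
    num, den = comparison
    results = [
        relative_efficiency(f"{num}_{parameter}", f"{den}_{parameter}", sc)
        for sc in scenarios
    ]
    analytic = [r.re_analytic for r in results]
    empirical = np.array([r.re_empirical for r in results])
    ses = np.array([r.mc_se for r in results])
    analytic_constant = (
        all(a is None for a in analytic)
        or max(analytic) - min(analytic) <= 1e-12 * max(map(abs, analytic))
    )
    spread_ok = bool(empirical.max() - empirical.min()
                     <= 4.0 * float(np.hypot(ses.max(), ses.max()))) \
        if len(scenarios) > 1 else True
    return {
        "mu_values": [sc.pop.mean_x for sc in scenarios],
        "re_analytic": analytic,
        "re_empirical": empirical.tolist(),
        "mc_se": ses.tolist(),
        "analytic_constant": bool(analytic_constant),
        "empirical_within_noise": spread_ok,
    }


def plot_re_curves(table: pd.DataFrame, path=None):
    """Plot RE against W, one panel per comparison, one line per parameter
    and (T, F, theta) combination.  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = sorted(table["comparison"].unique())
    fig, axes = plt.subplots(1, len(comps), figsize=(4 * len(comps), 3.5),
                             squeeze=False, sharey=False)
    for ax, comp in zip(axes[0], comps):
        sub = table[table["comparison"] == comp]
        keys = ["parameter", "T", "F", "theta1", "theta2"]
        for lab, grp in sub.groupby(keys):
            grp = grp.sort_values("W")
            col = "re_empirical" if grp["re_analytic"].isna().all() else "re_analytic"
            ax.plot(grp["W"], grp[col], label=f"{lab[0]} T={lab[1]} F={lab[2]}")
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("sensitivity level W")
        ax.set_ylabel("relative efficiency")
        ax.set_title(comp)
        ax.legend(fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
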