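"""Model/Results interface over the moment estimators.

Mirrors the statsmodels convention: a model object is constructed from data
plus known design constants, ``fit()`` performs the moment estimation and
returns an :class:`RRTResults` carrying point estimates, their unbiased
variance estimates, diagnostics and a ``summary()`` table.

    >>> sample = simulate_two_sample(design, pop, params, seed=7)
    >>> res = SplitSampleModel(sample, design, truth_T=0.3, forced_F=0.1).fit()
    >>> res.params["mean"], res.params["sensitivity"]

Sensitivity estimates outside [0, 1] and negative variance estimates are
reported raw with a warning flag; truncation (``fit(truncate=True)``) is
available but destroys unbiasedness and is never the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import moments as mm
from .designs import (
    DoubleResponseDesign,
    HuangDesign,
    Population,
    ResponseSample,
    ThreeStageParams,
    TwoSampleDesign,
)

__all__ = [
    "SplitSampleModel",
    "MehtaModel",
    "GuptaModel",
    "DoubleResponseModel",
    "HuangModel",
    "RRTResults",
]


@dataclass
class RRTResults:
    """Estimation results for one ORR design.

    ``params`` holds the point estimates (mean, sensitivity and, where
    defined, the population variance); ``var_estimates`` the unbiased
    data-based estimates of the estimator variances (raw, possibly
    negative); ``bse`` their square roots (NaN where the raw estimate is
    negative).
    """

    model: object
    params: pd.Series
    var_estimates: pd.Series
    nobs: tuple[int, int]
    estimator_id: str
    warnings: list[str] = field(default_factory=list)
    moment_summary: Optional[mm.MomentSummary] = None

    @property
    def bse(self) -> pd.Series:
        v = self.var_estimates.reindex(self.params.index)
        return np.sqrt(v.where(v >= 0))

    def theoretical_variances(self, pop: Population, sensitivity_w: float) -> pd.Series:
        """Closed-form estimator variances at known true parameters."""
        return self.model.theoretical_variances(pop, sensitivity_w)

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} estimation results",
            "=" * 52,
            f"design: {self.estimator_id}    n1={self.nobs[0]}  n2={self.nobs[1]}",
            "-" * 52,
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
        ]
        bse = self.bse
        for name, val in self.params.items():
            se = bse.get(name, np.nan)
            se_s = f"{se:12.5g}" if np.isfinite(se) else f"{'--':>12}"
            lines.append(f"{name:<14}{val:12.5g}{se_s}")
        if self.warnings:
            lines.append("-" * 52)
            for w in self.warnings:
                lines.append(f"warning: {w}")
        lines.append("=" * 52)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimator_id": self.estimator_id,
            "n1": int(self.nobs[0]),
            "n2": int(self.nobs[1]),
            "params": {k: float(v) for k, v in self.params.items()},
            "var_estimates": {k: float(v) for k, v in self.var_estimates.items()},
            "warnings": list(self.warnings),
        }

    def to_json(self, path=None) -> Optional[str]:
        text = json.dumps(self.to_dict(), indent=2)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def to_csv_row(self) -> pd.DataFrame:
        d = self.to_dict()
        row = {"estimator_id": d["estimator_id"], "n1": d["n1"], "n2": d["n2"]}
        row.update({k: v for k, v in d["params"].items()})
        row.update({f"var_{k}": v for k, v in d["var_estimates"].items()})
        row["warnings"] = ";".join(d["warnings"])
        return pd.DataFrame([row])


def _as_sample(data, paired: bool, kind: str) -> ResponseSample:
    if isinstance(data, ResponseSample):
        return data
    r1, r2 = data
    return ResponseSample(np.asarray(r1, float), np.asarray(r2, float),
                          design_kind=kind, paired=paired)


class _TwoSampleModelBase:
    """Shared machinery for the two-subsample additive designs."""

    _kind = ""
    _sign2 = +1

    def __init__(self, data, design: TwoSampleDesign, truth_T: float, forced_F: float):
        if design.sign2 != self._sign2:
            raise ValueError(
                f"{type(self).__name__} requires a design with sign2={self._sign2}"
            )
        self.sample = _as_sample(data, paired=False, kind=self._kind)
        self.design = design.with_sizes(self.sample.n1, self.sample.n2)
        self.truth_T = float(truth_T)
        self.forced_F = float(forced_F)
        if self.truth_T + self.forced_F >= 1:
            raise ValueError("T + F must be < 1 for sensitivity estimation")

    @classmethod
    def from_csv(cls, path, design: TwoSampleDesign, truth_T: float, forced_F: float = 0.0):
        from .io import read_sample

        return cls(read_sample(path), design, truth_T, forced_F)

    def _point(self, m: mm.MomentSummary) -> tuple[float, float]:
        raise NotImplementedError

    def fit(self, k: float = 0.5, truncate: bool = False) -> RRTResults:
        """Moment estimation of (mean, sensitivity, population variance).

        ``k`` weights the two per-subsample components of the variance
        estimator.  ``truncate`` clips the sensitivity into [0, 1] and the
        variance estimate at 0 (not unbiased; off by default).
        """
        m = mm.MomentSummary.from_sample(self.sample)
        mu, w = self._point(m)
        params_ts = ThreeStageParams(self.truth_T, self.forced_F, min(max(w, 0.0), 1.0))
        warnings = []
        if not 0.0 <= w <= 1.0:
            warnings.append(f"sensitivity estimate {w:.4g} outside [0, 1]")
        sig = v_mu = v_w = np.nan
        if m.n1 >= 2 and m.n2 >= 2:
            sig = mm.estimate_sigma_x(m, self.design, params_ts, k=k)
            v_mu, v_w = mm.unbiased_var_estimates(m, self.design, params_ts)
            if sig < 0:
                warnings.append(f"variance estimate {sig:.4g} below 0")
        if truncate:
            w = min(max(w, 0.0), 1.0)
            sig = max(sig, 0.0) if np.isfinite(sig) else sig
        params = pd.Series({"mean": mu, "sensitivity": w, "var_x": sig})
        var_est = pd.Series({"mean": v_mu, "sensitivity": v_w})
        return RRTResults(
            model=self,
            params=params,
            var_estimates=var_est,
            nobs=(m.n1, m.n2),
            estimator_id=self._kind,
            warnings=warnings,
            moment_summary=m,
        )

    def theoretical_variances(self, pop: Population, sensitivity_w: float) -> pd.Series:
        params = ThreeStageParams(self.truth_T, self.forced_F, sensitivity_w)
        a = params.scramble_probability
        if self._sign2 == -1:
            v_mu = mm.var_mean_split(self.design, pop, a)
            v_w = mm.var_sensitivity_split(self.design, pop, a, self.truth_T, self.forced_F)
        else:
            v_mu = mm.var_mean_mehta(self.design, pop, a)
            v_w = mm.var_sensitivity_mehta(self.design, pop, a, self.truth_T, self.forced_F)
        return pd.Series({"mean": v_mu, "sensitivity": v_w})


class SplitSampleModel(_TwoSampleModelBase):
    """Additive scrambling in subsample 1, subtractive in subsample 2.

    The opposite scrambling signs make the moment solution divide by
    theta1 + theta2 instead of theta2 - theta1, which is the source of the
    design's efficiency gain over the additive-additive designs.
    """

    _kind = "split"
    _sign2 = -1

    def _point(self, m):
        d = self.design
        mu = float(mm.mean_split(m.zbar1, m.zbar2, d.theta1, d.theta2))
        w = float(mm.sensitivity_split(m.zbar1, m.zbar2, d.theta1, d.theta2,
                                       self.truth_T, self.forced_F))
        return mu, w


class MehtaModel(_TwoSampleModelBase):
    """Three-stage additive-additive design (truth, forced and optional
    scrambling stages), requiring theta1 != theta2."""

    _kind = "mehta"
    _sign2 = +1

    def _point(self, m):
        d = self.design
        mu = float(mm.mean_mehta(m.zbar1, m.zbar2, d.theta1, d.theta2))
        w = float(mm.sensitivity_mehta(m.zbar1, m.zbar2, d.theta1, d.theta2,
                                       self.truth_T, self.forced_F))
        return mu, w


class GuptaModel(MehtaModel):
    """Two-stage additive design: the three-stage mechanism with F = 0."""

    _kind = "gupta"

    def __init__(self, data, design: TwoSampleDesign, truth_T: float, forced_F: float = 0.0):
        if forced_F != 0.0:
            raise ValueError("the two-stage design has no forced-scrambling stage (F = 0)")
        super().__init__(data, design, truth_T, 0.0)


class DoubleResponseModel:
    """Paired double-response design: each respondent reports once with
    additive and once with subtractive scrambling, one sample of size n."""

    _kind = "double"

    def __init__(self, data, design: DoubleResponseDesign, truth_T: float, forced_F: float):
        self.sample = _as_sample(data, paired=True, kind="double")
        if not self.sample.paired:
            raise ValueError("double-response estimation requires paired data")
        if self.sample.n1 != self.sample.n2:
            raise ValueError("paired responses must have equal length")
        self.design = DoubleResponseDesign(
            design.scrambler1, design.scrambler2, self.sample.n1,
            design.shared_indicator, design.shared_scramble_value,
        )
        self.truth_T = float(truth_T)
        self.forced_F = float(forced_F)
        if self.truth_T + self.forced_F >= 1:
            raise ValueError("T + F must be < 1 for sensitivity estimation")

    @classmethod
    def from_csv(cls, path, design: DoubleResponseDesign, truth_T: float, forced_F: float = 0.0):
        from .io import read_sample

        return cls(read_sample(path), design, truth_T, forced_F)

    def fit(self, k: float = 0.5, truncate: bool = False) -> RRTResults:
        m = mm.MomentSummary.from_sample(self.sample)
        d = self.design
        mu = float(mm.mean_double(m.zbar1, m.zbar2, d.theta1, d.theta2))
        w = float(mm.sensitivity_double(m.zbar1, m.zbar2, d.theta1, d.theta2,
                                        self.truth_T, self.forced_F))
        params_ts = ThreeStageParams(self.truth_T, self.forced_F, min(max(w, 0.0), 1.0))
        warnings = []
        if not 0.0 <= w <= 1.0:
            warnings.append(f"sensitivity estimate {w:.4g} outside [0, 1]")
        sig = v_mu = v_w = np.nan
        if m.n1 >= 2:
            sig = mm.estimate_sigma_x(m, d, params_ts, k=k)
            v_mu, v_w = mm.unbiased_var_estimates(m, d, params_ts)
            if sig < 0:
                warnings.append(f"variance estimate {sig:.4g} below 0")
        if truncate:
            w = min(max(w, 0.0), 1.0)
            sig = max(sig, 0.0) if np.isfinite(sig) else sig
        params = pd.Series({"mean": mu, "sensitivity": w, "var_x": sig})
        var_est = pd.Series({"mean": v_mu, "sensitivity": v_w})
        return RRTResults(
            model=self, params=params, var_estimates=var_est,
            nobs=(m.n1, m.n2), estimator_id="double",
            warnings=warnings, moment_summary=m,
        )

    def theoretical_variances(self, pop: Population, sensitivity_w: float) -> pd.Series:
        params = ThreeStageParams(self.truth_T, self.forced_F, sensitivity_w)
        a = params.scramble_probability
        return pd.Series({
            "mean": mm.var_mean_double(self.design, pop, a),
            "sensitivity": mm.var_sensitivity_double(
                self.design, pop, a, self.truth_T, self.forced_F),
        })


class HuangModel:
    """Combined multiplicative-additive comparator design.

    The moment solution is a ratio, so only consistency (not exact
    unbiasedness) holds; no population-variance estimator is defined."""

    _kind = "huang"

    def __init__(self, data, design: HuangDesign):
        self.sample = _as_sample(data, paired=False, kind="huang")
        self.design = design

    @classmethod
    def from_csv(cls, path, design: HuangDesign):
        from .io import read_sample

        return cls(read_sample(path), design)

    def fit(self) -> RRTResults:
        m = mm.MomentSummary.from_sample(self.sample)
        mu, w = mm.huang_solve(m.zbar1, m.zbar2, self.design)
        warnings = []
        if not 0.0 <= w <= 1.0:
            warnings.append(f"sensitivity estimate {w:.4g} outside [0, 1]")
        params = pd.Series({"mean": mu, "sensitivity": w, "var_x": np.nan})
        return RRTResults(
            model=self, params=params,
            var_estimates=pd.Series(dtype=float),
            nobs=(m.n1, m.n2), estimator_id="huang",
            warnings=warnings, moment_summary=m,
        )

    def theoretical_variances(self, pop: Population, sensitivity_w: float) -> pd.Series:
        raise NotImplementedError(
            "no closed-form variances for the ratio-form solution; "
            "use the Monte Carlo engine"
        )
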