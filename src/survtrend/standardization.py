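"""Predictions on a standard population: predictive margins and logit CIs.

Rather than reporting raw (weighted) sample means, every estimate the
pipeline outputs is a model prediction averaged over a fixed *standard
population* — census-style joint counts over sex x age group x education.
This direct standardization makes estimates comparable across time (the
demographic mix of the monthly samples varies) and across subgroups.

For a fitted regression with parameters theta and predictions
``g(r, Z_i, theta)``, the predictive margin over the S distinct covariate
combinations of the standard population is

    PM_r = sum_i w_i g(r, Z_i, theta) / sum_i w_i ,

where ``w_i`` are the population counts.  Two subgroup modes exist:

* *counterfactual* (standardized): every population row is treated as
  belonging to subgroup r — the subgroup variable is overridden, the full
  weights are kept.  Subgroups then differ only through the model
  coefficients, not through their demographic composition.
* *non-counterfactual* (unstandardized): the weights are restricted to the
  population rows actually in subgroup r.

Standard errors come from the delta method on the margin's gradient with
respect to theta; for proportions, confidence intervals are constructed on
the logit scale so the bounds stay strictly inside (0, 1) even at very low
prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "StandardPopulation", "MarginEstimate", "load_standard_population",
    "predictive_margin", "margin_se", "logit_ci",
]

REQUIRED_COLUMNS = ("sex", "age_group", "education", "count")


@dataclass
class StandardPopulation:
    """Joint counts over sex x age group x education.

    All predictions are averaged over this table; replacing it changes the
    whole time series (that is the point of standardization).
    """

    rows: pd.DataFrame
    source_year: int | None = None

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"standard population lacks columns {missing}")
        if (self.rows["count"] < 0).any():
            raise ValueError("standard population counts must be >= 0")
        if not (self.rows["count"] > 0).any():
            raise ValueError("standard population needs at least one positive count")
        dup = self.rows.duplicated(subset=["sex", "age_group", "education"])
        if dup.any():
            logger.warning("standard population: %d duplicated cells, counts summed",
                           int(dup.sum()))
            self.rows = (self.rows
                         .groupby(["sex", "age_group", "education"], as_index=False)["count"]
                         .sum())
        self.rows = self.rows.reset_index(drop=True)

    @property
    def total(self) -> float:
        return float(self.rows["count"].sum())

    def levels(self, var: str) -> list:
        return list(dict.fromkeys(self.rows[var]))

    def collapse_age(self, mapping: dict[str, str]) -> "StandardPopulation":
        """Aggregate age groups (e.g. 7 fine groups -> 3 coarse ones)."""
        rows = self.rows.copy()
        rows["age_group"] = rows["age_group"].map(lambda a: mapping.get(a, a))
        rows = rows.groupby(["sex", "age_group", "education"], as_index=False)["count"].sum()
        return StandardPopulation(rows, self.source_year)


def load_standard_population(path, source_year: int | None = None,
                             sep: str = ",") -> StandardPopulation:
    """Read a delimited standard-population file (sex, age_group, education, count)."""
    df = pd.read_csv(path, sep=sep)
    return StandardPopulation(df, source_year)


@dataclass
class MarginEstimate:
    estimate: float
    se: float | None
    ci_low: float | None
    ci_high: float | None
    subgroup: str
    standardized: bool


def _margin_rows(standpop: StandardPopulation, subgroup, counterfactual: bool):
    """Covariate rows and weights entering the PM formula."""
    rows = standpop.rows.copy()
    if subgroup is None:
        return rows, rows["count"].to_numpy(dtype=float)
    var, level = subgroup
    if counterfactual:
        rows[var] = level
        return rows, rows["count"].to_numpy(dtype=float)
    mask = rows[var] == level
    if not mask.any():
        raise ValueError(f"subgroup {level!r} absent from standard population column {var!r}")
    rows = rows.loc[mask]
    return rows, rows["count"].to_numpy(dtype=float)


def predictive_margin(model, standpop: StandardPopulation,
                      subgroup: tuple[str, str] | None = None,
                      counterfactual: bool = False,
                      level: float = 0.95,
                      with_se: bool = True) -> MarginEstimate:
    """Predictive margin PM_r with delta-method CI.

    ``model`` must expose ``design_matrix(df)``, ``params``, ``cov``, and
    ``family`` ("gaussian" or "binomial"); the window-regression wrapper in
    :mod:`survtrend.window_estimation` does.
    """
    rows, w = _margin_rows(standpop, subgroup, counterfactual)
    X = model.design_matrix(rows)
    eta = X @ model.params
    if model.family == "binomial":
        mu = _expit(eta)
        dmu = mu * (1.0 - mu)
    else:
        mu = eta
        dmu = np.ones_like(eta)
    wsum = w.sum()
    est = float((w * mu).sum() / wsum)

    se = ci_low = ci_high = None
    if with_se and getattr(model, "cov", None) is not None:
        grad = (w[:, None] * dmu[:, None] * X).sum(axis=0) / wsum
        var = float(grad @ model.cov @ grad)
        if var < 0 or not np.isfinite(var):
            logger.warning("margin variance not finite/positive; SE reported as missing")
        else:
            se = float(np.sqrt(var))
            if model.family == "binomial" and 0.0 < est < 1.0:
                ci_low, ci_high = logit_ci(est, se, level)
            else:
                z = norm.ppf(0.5 + level / 2.0)
                ci_low, ci_high = est - z * se, est + z * se
    name = "overall" if subgroup is None else f"{subgroup[0]}={subgroup[1]}"
    return MarginEstimate(estimate=est, se=se, ci_low=ci_low, ci_high=ci_high,
                          subgroup=name, standardized=counterfactual)


def margin_se(model, standpop: StandardPopulation,
              subgroup: tuple[str, str] | None = None,
              counterfactual: bool = False) -> float | None:
    """Delta-method standard error of the predictive margin."""
    return predictive_margin(model, standpop, subgroup, counterfactual).se


def _expit(x):
    from scipy.special import expit
    return expit(np.asarray(x, dtype=float))


def logit_ci(p: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a proportion via the logit transform.

    The estimate and its SE are mapped to the logit scale
    (eta = log(p/(1-p)), SE_eta = se / (p(1-p))), a normal interval is
    formed there, and the bounds are mapped back — guaranteeing bounds
    strictly inside (0, 1).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("logit CI requires 0 < p < 1; report the point estimate "
                         "without an interval for boundary proportions")
    if se < 0:
        raise ValueError("se must be non-negative")
    if se == 0.0:
        return (p, p)
    z = norm.ppf(0.5 + level / 2.0)
    eta = np.log(p / (1.0 - p))
    se_eta = se / (p * (1.0 - p))
    lo = float(_expit(eta - z * se_eta))
    hi = float(_expit(eta + z * se_eta))
    # extreme SEs can round the back-transform onto the boundary
    lo = min(max(lo, np.nextafter(0.0, 1.0)), p)
    hi = max(min(hi, np.nextafter(1.0, 0.0)), p)
    return lo, hi
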