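"""Moving three-month windows with weighted regressions per window.

Monthly samples are too small for direct monthly estimates, so the
estimate for month t pools the observations of months t-1, t, t+1
(centered moving window).  Within each window a weighted regression of the
indicator on sex, age group, and education is fitted:

* metric indicators: weighted least squares with the *full* three-way
  interaction of the covariates (the cell-mean model),
* binary indicators: weighted logistic regression with two-way
  interactions only, because full interactions make empty cells — and
  hence inestimable margins — far more likely at low prevalence.

The fitted model is then turned into standardized and unstandardized
monthly predictions via the predictive-margins machinery in
:mod:`survtrend.standardization`.

Window rules: if only two of the three months have observations (series
edges, data gaps) the window uses two months; with fewer, the month is a
gap in the output.  Windows whose data leave a covariate cell empty, or
that separate the logistic fit, yield status ``degenerate`` instead of an
estimate — mirroring the sparser published proportion series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .standardization import StandardPopulation, predictive_margin

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec", "WindowModel", "assemble_window", "fit_window_model",
    "estimate_series",
]

_FORMULAS = {
    "three-way": "C(sex) * C(age_group) * C(education)",
    "two-way": "(C(sex) + C(age_group) + C(education)) ** 2",
}


@dataclass
class ModelSpec:
    """Outcome, family, and interaction structure of the window regressions."""

    outcome: str
    family: str = "gaussian"  # or "binomial"
    interaction_order: str | None = None

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.interaction_order is None:
            self.interaction_order = "three-way" if self.family == "gaussian" else "two-way"
        if self.interaction_order not in _FORMULAS:
            raise ValueError(f"unknown interaction order {self.interaction_order!r}")

    @property
    def formula_rhs(self) -> str:
        return _FORMULAS[self.interaction_order]


@dataclass
class WindowModel:
    """Fitted window regression: parameters, covariance, design builder."""

    params: np.ndarray
    cov: np.ndarray | None
    design_info: object
    family: str
    n_obs: int = 0

    def design_matrix(self, df: pd.DataFrame) -> np.ndarray:
        (X,) = patsy.build_design_matrices([self.design_info], df)
        return np.asarray(X)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        eta = self.design_matrix(df) @ self.params
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def assemble_window(records: pd.DataFrame, t: int,
                    month_col: str = "month_index") -> tuple[pd.DataFrame | None, int]:
    """Records of months {t-1, t, t+1} that exist; gap if fewer than 2 months.

    Returns ``(window, months_used)``; window is None for a gap.
    """
    sub = records[records[month_col].isin([t - 1, t, t + 1])]
    months_present = sub[month_col].nunique()
    if months_present < 2:
        return None, months_present
    return sub, int(months_present)


class DegenerateFit(Exception):
    """Window data cannot support the model (empty cell / separation)."""


def _check_cells(window: pd.DataFrame, spec: ModelSpec,
                 required_cells: pd.DataFrame | None) -> None:
    cells = window.groupby(["sex", "age_group", "education"], observed=True)
    sizes = cells.size()
    if required_cells is not None:
        need = set(map(tuple, required_cells[["sex", "age_group", "education"]]
                       .itertuples(index=False, name=None)))
        have = set(sizes.index)
        missing = need - have
        if missing:
            raise DegenerateFit(f"{len(missing)} empty covariate cell(s), e.g. {sorted(missing)[:2]}")
    if spec.family == "binomial":
        y = cells[spec.outcome]
        degenerate = (y.max() == y.min())
        if degenerate.any():
            bad = list(degenerate[degenerate].index[:2])
            raise DegenerateFit(f"constant outcome in covariate cell(s) {bad} (separation)")


def fit_window_model(window: pd.DataFrame, spec: ModelSpec,
                     weight_col: str = "adjusted_weight",
                     required_cells: pd.DataFrame | None = None,
                     cov_type: str = "robust") -> WindowModel:
    """Weighted regression on one window; raises DegenerateFit when the data
    cannot identify the margins.

    ``cov_type="robust"`` (default) uses the sandwich covariance of the
    weighted score — the appropriate variance when adjustment weights are
    probability weights; ``"model"`` gives the naive model-based covariance.
    """
    data = window.dropna(subset=[spec.outcome, "sex", "age_group", "education"]).copy()
    if data.empty:
        raise DegenerateFit("no usable observations after exclusions")
    _check_cells(data, spec, required_cells)

    y, X = patsy.dmatrices(f"{spec.outcome} ~ {spec.formula_rhs}", data,
                           return_type="dataframe")
    w = data.loc[X.index, weight_col].to_numpy(dtype=float)
    yv = np.asarray(y).ravel()
    Xv = np.asarray(X)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise DegenerateFit("rank-deficient design (empty interaction cell)")

    fit_kw = {"cov_type": "HC1"} if cov_type == "robust" else {}
    if spec.family == "gaussian":
        res = sm.WLS(yv, Xv, weights=w).fit(**fit_kw)
        params, cov = res.params, res.cov_params()
    else:
        model = sm.GLM(yv, Xv, family=sm.families.Binomial(), var_weights=w)
        try:
            res = model.fit(maxiter=100, **fit_kw)
        except Exception as exc:  # perfect separation and friends
            raise DegenerateFit(f"logistic fit failed: {exc}") from exc
        if not res.converged:
            raise DegenerateFit("logistic fit did not converge in 100 iterations")
        if np.abs(res.params).max() > 30:
            raise DegenerateFit("diverging coefficients (quasi-separation)")
        params, cov = res.params, res.cov_params()
    return WindowModel(params=np.asarray(params), cov=np.asarray(cov),
                       design_info=X.design_info, family=spec.family,
                       n_obs=len(data))


def _month_labels(records: pd.DataFrame) -> dict[int, str]:
    """month_index -> label map covering gap months too."""
    have = records.drop_duplicates("month_index").set_index("month_index")["month_label"]
    if have.empty:
        return {}
    i0 = int(have.index.min())
    y, m = (int(p) for p in have.loc[i0].split("-"))
    ordinal0 = y * 12 + (m - 1) - i0
    t_max = int(records["month_index"].max())
    return {t: f"{(ordinal0 + t) // 12}-{(ordinal0 + t) % 12 + 1:02d}"
            for t in range(0, t_max + 1)}


def estimate_series(records: pd.DataFrame, spec: ModelSpec,
                    standpop: StandardPopulation,
                    strata: tuple[str, ...] = ("sex", "age_group", "education"),
                    weight_col: str = "adjusted_weight",
                    level: float = 0.95) -> pd.DataFrame:
    """Monthly standardized and unstandardized predictions with CIs.

    One row per month x stratum x standardization mode, tidy format.  Gap
    and degenerate months keep their rows with empty estimate fields so the
    output time axis is complete.
    """
    labels = _month_labels(records)
    required = standpop.rows[["sex", "age_group", "education"]]
    combos: list[tuple[str, str, bool]] = [("overall", "overall", True)]
    for var in strata:
        for lev in standpop.levels(var):
            combos.append((var, str(lev), True))
            combos.append((var, str(lev), False))

    rows = []
    for t in range(int(records["month_index"].max()) + 1):
        window, months_used = assemble_window(records, t)
        base = {"month_index": t, "month_label": labels.get(t, ""),
                "indicator": spec.outcome, "months_used": months_used}
        if window is None:
            for var, lev, std in combos:
                rows.append({**base, "stratum_var": var, "stratum_level": lev,
                             "standardized": std, "status": "gap",
                             "estimate": np.nan, "se": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "n_obs": 0})
            continue
        try:
            model = fit_window_model(window, spec, weight_col, required_cells=required)
        except DegenerateFit as exc:
            logger.info("month %d (%s): degenerate window — %s", t, spec.outcome, exc)
            for var, lev, std in combos:
                rows.append({**base, "stratum_var": var, "stratum_level": lev,
                             "standardized": std, "status": "degenerate",
                             "estimate": np.nan, "se": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan,
                             "n_obs": len(window)})
            continue
        for var, lev, std in combos:
            subgroup = None if var == "overall" else (var, lev)
            est = predictive_margin(model, standpop, subgroup=subgroup,
                                    counterfactual=std, level=level)
            rows.append({**base, "stratum_var": var, "stratum_level": lev,
                         "standardized": std, "status": "ok",
                         "estimate": est.estimate, "se": est.se,
                         "ci_low": est.ci_low, "ci_high": est.ci_high,
                         "n_obs": model.n_obs})
    return pd.DataFrame(rows)
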