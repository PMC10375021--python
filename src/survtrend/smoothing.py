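"""Weekly trend curves from a penalized thin-plate-spline GAM.

The moving-window estimates use temporal information only through window
membership.  To exploit the full weekly resolution, the indicator is also
modelled as a smooth function of continuous week number with a generalized
additive model:

    y ~ s(week, by = interaction(age group, sex, education))
        + age group * sex * education

i.e. one penalized smooth of week per demographic cell (factor-by-curve
interaction) on top of a full-factorial parametric term.  The smooths use
low-rank thin-plate regression splines (radial basis |r|^3/12 in one
dimension, eigen-truncated to ``basis_dim`` functions, second-order
wiggliness penalty whose null space is the constant-plus-linear trend).
Each smooth carries its own smoothing parameter, selected by maximizing
the restricted likelihood (REML); generalized cross-validation tends to
undersmooth these series.

Weekly *point* predictions on the standard population are produced with
the same predictive-margins formula as the window estimates; no intervals
are attached to the smooth curve.

A restricted cubic spline (linear beyond its boundary knots, knots at
fixed quantiles) is provided as the comparison baseline, and
:func:`stability_experiment` replays the update behaviour of the curves as
new weeks of data arrive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, null_space

logger = logging.getLogger(__name__)

__all__ = [
    "GamSpec", "TPRSBasis", "FittedGAM", "SmoothedSeries",
    "build_penalized_basis", "fit_gam", "predict_weekly",
    "fit_restricted_cubic_baseline", "stability_experiment",
]


# --------------------------------------------------------------------------
# thin-plate regression spline basis
# --------------------------------------------------------------------------

def _eta(r: np.ndarray) -> np.ndarray:
    # 1-D thin-plate (order-2) radial basis: Green's function |r|^3 / 12
    return np.abs(r) ** 3 / 12.0


class TPRSBasis:
    """Low-rank thin-plate regression spline basis on one covariate.

    The full thin-plate system on the ``n`` unique covariate values is
    eigen-truncated to the ``k`` leading (largest-magnitude) eigenvectors;
    the polynomial-orthogonality constraint is absorbed, leaving ``k - 2``
    penalized columns plus one unpenalized linear column.  The constant is
    intentionally absent: identifiability inside a GAM is enforced by
    centering, handled by the caller.
    """

    def __init__(self, x: np.ndarray, basis_dim: int):
        xu = np.unique(np.asarray(x, dtype=float))
        if len(xu) < 4:
            raise ValueError(f"need >= 4 distinct covariate values, got {len(xu)}")
        k = int(basis_dim)
        if k > len(xu):
            logger.warning("basis_dim %d exceeds %d distinct values; reduced", k, len(xu))
            k = len(xu)
        if k < 4:
            k = 4
        self.k = k
        self.x_min, self.x_max = float(xu[0]), float(xu[-1])
        self._knots = (xu - self.x_min) / (self.x_max - self.x_min)

        E = _eta(self._knots[:, None] - self._knots[None, :])
        vals, vecs = np.linalg.eigh(E)
        order = np.argsort(np.abs(vals))[::-1][:k]
        U, lam = vecs[:, order], vals[order]
        T = np.column_stack([np.ones_like(self._knots), self._knots])
        Z = null_space(T.T @ U)          # k x (k-2)
        self._UZ = U @ Z                 # n x (k-2): delta = UZ @ beta_pen
        S = Z.T @ (lam[:, None] * Z)
        S = (S + S.T) / 2.0
        # numerically PSD-ify (truncation can leave tiny negative ripple)
        w, V = np.linalg.eigh(S)
        self.S = (V * np.clip(w, 0.0, None)) @ V.T
        self.penalty_rank = int((np.clip(w, 0.0, None) > 1e-10 * max(w.max(), 1.0)).sum())
        self.logdet_S = float(np.sum(np.log(w[w > 1e-10 * max(w.max(), 1.0)])))

    @property
    def n_columns(self) -> int:
        return self.k - 1  # penalized block + linear column

    def _scale(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.x_min) / (self.x_max - self.x_min)

    def evaluate(self, x) -> np.ndarray:
        """Design columns [penalized block | linear] at new covariate values."""
        xs = self._scale(x)
        E = _eta(xs[:, None] - self._knots[None, :])
        return np.column_stack([E @ self._UZ, xs])

    def full_penalty(self) -> np.ndarray:
        """Penalty over all columns (zero row/col for the linear term)."""
        p = self.n_columns
        S = np.zeros((p, p))
        S[: self.k - 2, : self.k - 2] = self.S
        return S


def build_penalized_basis(weeks, basis_dim: int = 10) -> TPRSBasis:
    """Thin-plate regression spline basis + wiggliness penalty for a week axis."""
    return TPRSBasis(np.asarray(weeks, dtype=float), basis_dim)


# --------------------------------------------------------------------------
# GAM
# --------------------------------------------------------------------------

@dataclass
class GamSpec:
    family: str = "gaussian"
    basis_dim: int = 10
    penalty_order: int = 2
    smoothing_selection: str = "REML"  # or "GCV"
    group_vars: tuple[str, ...] = ("age_group", "sex", "education")

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.basis_dim < 4:
            raise ValueError("basis_dim must be >= 4")
        if self.penalty_order != 2:
            raise ValueError("only the standard second-order wiggliness penalty is implemented")
        if self.smoothing_selection not in ("REML", "GCV"):
            raise ValueError("smoothing_selection must be 'REML' or 'GCV'")


@dataclass
class SmoothedSeries:
    """Weekly point predictions for one stratum (no interval fields)."""

    points: pd.DataFrame  # columns: week, stratum_var, stratum_level, standardized, estimate
    fitted_lambda: dict
    edf: dict


@dataclass
class FittedGAM:
    spec: GamSpec
    beta: np.ndarray
    lambdas: dict
    edf_per_smooth: dict
    edf_total: float
    scale: float
    design_info: object
    para_cols: np.ndarray
    groups: dict          # group key -> (basis, centering means, col slice)
    week_range: tuple[float, float]
    outcome: str
    week_col: str = "week_index"

    def _group_key(self, row) -> tuple:
        return tuple(row[v] for v in self.spec.group_vars)

    def linear_predictor(self, newdata: pd.DataFrame) -> np.ndarray:
        (Xp,) = patsy.build_design_matrices([self.design_info], newdata)
        Xp = np.asarray(Xp)[:, self.para_cols]
        p_total = len(self.beta)
        X = np.zeros((len(newdata), p_total))
        X[:, : Xp.shape[1]] = Xp
        weeks = newdata[self.week_col].to_numpy(dtype=float)
        if self.spec.group_vars:
            keys = list(zip(*[newdata[v] for v in self.spec.group_vars]))
        else:
            keys = [()] * len(newdata)
        for key, (basis, means, sl) in self.groups.items():
            idx = [i for i, k in enumerate(keys) if k == key]
            if idx:
                X[idx, sl] = basis.evaluate(weeks[idx]) - means
        return X @ self.beta

    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        eta = self.linear_predictor(newdata)
        if self.spec.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def _assemble_design(data: pd.DataFrame, spec: GamSpec, week_col: str):
    """Parametric block + per-group centered smooth blocks."""
    if spec.group_vars:
        rhs = " * ".join(f"C({v})" for v in spec.group_vars)
    else:
        rhs = "1"
    Xp_df = patsy.dmatrix(rhs, data, return_type="dataframe")
    Xp = np.asarray(Xp_df)
    keep = np.linalg.norm(Xp, axis=0) > 1e-12
    # guard against exact collinearity from sparse cells
    if keep.all():
        r = np.linalg.matrix_rank(Xp)
        if r < Xp.shape[1]:
            _, R = np.linalg.qr(Xp)
            keep = np.abs(np.diag(R)) > 1e-8 * np.abs(np.diag(R)).max()
    Xp = Xp[:, keep]

    weeks = data[week_col].to_numpy(dtype=float)
    if spec.group_vars:
        keys = list(zip(*[data[v] for v in spec.group_vars]))
    else:
        keys = [()] * len(data)
    order = list(dict.fromkeys(keys))

    blocks, groups = [], {}
    col = Xp.shape[1]
    for key in order:
        idx = [i for i, k in enumerate(keys) if k == key]
        wk = weeks[idx]
        if len(np.unique(wk)) < 4:
            logger.warning("group %s has <4 distinct weeks; smooth omitted", key)
            continue
        basis = TPRSBasis(wk, spec.basis_dim)
        B = basis.evaluate(wk)
        means = B.mean(axis=0)
        sl = slice(col, col + basis.n_columns)
        groups[key] = (basis, means, sl, idx, B - means)
        col += basis.n_columns

    n, p = len(data), col
    X = np.zeros((n, p))
    X[:, : Xp.shape[1]] = Xp
    for key, (basis, means, sl, idx, Bc) in groups.items():
        X[idx, sl] = Bc
    groups = {k: (b, m, sl) for k, (b, m, sl, _i, _B) in groups.items()}
    for key, (basis, means, sl) in groups.items():
        blocks.append((key, sl, basis))
    return X, Xp_df.design_info, keep, groups, blocks


def _penalized_solve(XtWX, XtWy, blocks, rho):
    p = XtWX.shape[0]
    A = XtWX.copy()
    for j, (_key, sl, basis) in enumerate(blocks):
        pen = slice(sl.start, sl.start + basis.k - 2)
        A[pen, pen] += np.exp(rho[j]) * basis.S
    try:
        c = cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        A = A + np.eye(p) * 1e-8 * np.trace(A) / p
        c = cho_factor(A, lower=True)
    beta = cho_solve(c, XtWy)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    return beta, c, logdet


def _reml_criterion(rho, XtWX, XtWy, yWy, n, blocks, Mp, scale=None):
    """Negative restricted log-likelihood (up to constants) and gradient.

    ``scale=None`` profiles the Gaussian scale; a fixed scale of 1 gives the
    working-model criterion used inside the binomial PIRLS loop.
    """
    beta, c, logdetA = _penalized_solve(XtWX, XtWy, blocks, rho)
    D = max(float(yWy - beta @ XtWy), 1e-300)
    val = logdetA
    grads = np.zeros(len(blocks))
    for j, (_key, sl, basis) in enumerate(blocks):
        val -= basis.penalty_rank * rho[j] + basis.logdet_S
        pen = slice(sl.start, sl.start + basis.k - 2)
        bSb = float(beta[pen] @ basis.S @ beta[pen])
        cols = np.zeros((XtWX.shape[0], basis.k - 2))
        cols[pen] = basis.S
        tr = float(np.trace(cho_solve(c, cols)[pen]))
        lam = np.exp(rho[j])
        if scale is None:
            grads[j] = (n - Mp) * lam * bSb / D + lam * tr - basis.penalty_rank
        else:
            grads[j] = lam * bSb / scale + lam * tr - basis.penalty_rank
    if scale is None:
        val += (n - Mp) * np.log(D)
    else:
        val += D / scale
    return val, grads, beta, c, D


def _gcv_criterion(rho, XtWX, XtWy, yWy, n, blocks):
    beta, c, _ = _penalized_solve(XtWX, XtWy, blocks, rho)
    D = max(float(yWy - beta @ XtWy), 1e-300)
    edf = XtWX.shape[0]
    for j, (_key, sl, basis) in enumerate(blocks):
        pen = slice(sl.start, sl.start + basis.k - 2)
        cols = np.zeros((XtWX.shape[0], basis.k - 2))
        cols[pen] = basis.S
        edf -= np.exp(rho[j]) * float(np.trace(cho_solve(c, cols)[pen]))
    return n * D / (n - edf) ** 2


def _optimize_lambda(XtWX, XtWy, yWy, n, blocks, Mp, criterion="REML",
                     scale=None, rho0=None):
    G = len(blocks)
    if G == 0:
        return np.zeros(0)
    x0 = np.zeros(G) if rho0 is None else np.asarray(rho0, dtype=float)
    if criterion == "REML":
        def fun(rho):
            val, grads, *_ = _reml_criterion(rho, XtWX, XtWy, yWy, n, blocks, Mp, scale)
            return val, grads
        res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                                bounds=[(-12.0, 18.0)] * G,
                                options={"maxiter": 400, "ftol": 1e-12})
    else:
        res = optimize.minimize(lambda r: _gcv_criterion(r, XtWX, XtWy, yWy, n, blocks),
                                x0, method="L-BFGS-B",
                                bounds=[(-12.0, 18.0)] * G,
                                options={"maxiter": 400})
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise RuntimeError(f"smoothing-parameter optimization failed: {res.message}")
    return res.x


def fit_gam(records: pd.DataFrame, spec: GamSpec, outcome: str = "score",
            weight_col: str | None = "adjusted_weight",
            week_col: str = "week_index") -> FittedGAM:
    """Fit the factor-by-curve GAM with per-smooth penalties.

    Observation weights enter as likelihood weights.  Smoothing parameters
    are chosen by REML (default) or GCV; the binomial family is fitted by
    penalized IRLS with the smoothing parameters re-selected on the working
    model until joint convergence.
    """
    cols = [outcome, week_col, *spec.group_vars]
    data = records.dropna(subset=cols).reset_index(drop=True)
    if data.empty:
        raise ValueError("no usable observations")
    y = data[outcome].to_numpy(dtype=float)
    w = (data[weight_col].to_numpy(dtype=float) if weight_col
         else np.ones(len(data)))
    X, design_info, para_cols, groups, blocks = _assemble_design(data, spec, week_col)
    n, p = X.shape
    Mp = p - sum(b.k - 2 for _k, _sl, b in blocks)

    def moments(wts, resp):
        WX = X * wts[:, None]
        return X.T @ WX, X.T @ (wts * resp), float(resp @ (wts * resp))

    if spec.family == "gaussian":
        XtWX, XtWy, yWy = moments(w, y)
        rho = _optimize_lambda(XtWX, XtWy, yWy, n, blocks, Mp,
                               criterion=spec.smoothing_selection)
        val, grads, beta, c, D = _reml_criterion(rho, XtWX, XtWy, yWy, n, blocks, Mp)
        scale = D / max(n - Mp, 1)
    else:
        mu = np.clip((w * y + 0.5) / (w + 1.0), 0.01, 0.99)
        eta = np.log(mu / (1 - mu))
        rho = np.zeros(len(blocks))
        for it in range(40):
            mu = 1.0 / (1.0 + np.exp(-eta))
            var = np.clip(mu * (1.0 - mu), 1e-6, None)
            z = eta + (y - mu) / var
            ww = w * var
            XtWX, XtWy, yWy = moments(ww, z)
            rho = _optimize_lambda(XtWX, XtWy, yWy, n, blocks, Mp,
                                   criterion="REML", scale=1.0, rho0=rho)
            beta, c, _ = _penalized_solve(XtWX, XtWy, blocks, rho)
            eta_new = X @ beta
            if np.max(np.abs(eta_new - eta)) < 1e-7:
                eta = eta_new
                break
            eta = eta_new
        else:
            raise RuntimeError("penalized IRLS did not converge")
        scale = 1.0

    # effective degrees of freedom
    edf_total = p
    edf_per = {}
    for j, (key, sl, basis) in enumerate(blocks):
        pen = slice(sl.start, sl.start + basis.k - 2)
        cols_m = np.zeros((p, basis.k - 2))
        cols_m[pen] = basis.S
        shrink = np.exp(rho[j]) * float(np.trace(cho_solve(c, cols_m)[pen]))
        edf_total -= shrink
        edf_per[key] = basis.n_columns - shrink
    lambdas = {key: float(np.exp(rho[j])) for j, (key, _sl, _b) in enumerate(blocks)}

    weeks = data[week_col].to_numpy(dtype=float)
    return FittedGAM(spec=spec, beta=beta, lambdas=lambdas,
                     edf_per_smooth=edf_per, edf_total=float(edf_total),
                     scale=float(scale), design_info=design_info,
                     para_cols=para_cols, groups=groups,
                     week_range=(float(weeks.min()), float(weeks.max())),
                     outcome=outcome, week_col=week_col)


# --------------------------------------------------------------------------
# weekly standardized predictions
# --------------------------------------------------------------------------

def predict_weekly(gam: FittedGAM, standpop, weeks,
                   stratum: tuple[str, str] | None = None,
                   standardized: bool = True) -> SmoothedSeries:
    """Weekly point predictions on the standard population (PM formula).

    No extrapolation: all requested weeks must lie inside the observed
    week range of the fitted series.
    """
    weeks = np.asarray(weeks, dtype=float)
    lo, hi = gam.week_range
    if weeks.min() < lo or weeks.max() > hi:
        raise ValueError(f"requested weeks outside observed range [{lo}, {hi}]; "
                         "the smoother does not forecast")
    rows = standpop.rows.copy()
    if stratum is not None:
        var, level = stratum
        if standardized:
            rows[var] = level
        else:
            rows = rows[rows[var] == level]
            if rows.empty:
                raise ValueError(f"subgroup {level!r} absent from standard population")
    wts = rows["count"].to_numpy(dtype=float)
    grid = rows.loc[rows.index.repeat(len(weeks))].reset_index(drop=True)
    grid[gam.week_col] = np.tile(weeks, len(rows))
    mu = gam.predict(grid).reshape(len(rows), len(weeks))
    est = (wts[:, None] * mu).sum(axis=0) / wts.sum()
    var_name, level_name = ("overall", "overall") if stratum is None else (stratum[0], str(stratum[1]))
    points = pd.DataFrame({
        "week": weeks, "stratum_var": var_name, "stratum_level": level_name,
        "standardized": standardized, "estimate": est,
    })
    return SmoothedSeries(points=points, fitted_lambda=gam.lambdas, edf=gam.edf_per_smooth)


# --------------------------------------------------------------------------
# restricted cubic spline baseline
# --------------------------------------------------------------------------

def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Harrell-parameterized restricted cubic spline columns [x, f_1..f_{k-2}].

    Linear before the first and after the last knot by construction.
    """
    k = len(knots)
    t = knots
    scale = (t[-1] - t[0]) ** 2

    def pp3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        f = (pp3(x - t[j])
             - pp3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
             + pp3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2]))
        cols.append(f / scale)
    return np.column_stack(cols)


@dataclass
class RCSCurve:
    knots: np.ndarray
    coefs: np.ndarray  # intercept + basis coefficients
    week_range: tuple[float, float]

    def predict(self, weeks) -> np.ndarray:
        x = np.asarray(weeks, dtype=float)
        B = _rcs_basis(x, self.knots)
        return self.coefs[0] + B @ self.coefs[1:]

    def basis(self, weeks) -> np.ndarray:
        return _rcs_basis(np.asarray(weeks, dtype=float), self.knots)


#: Harrell's recommended knot quantiles for five knots
RCS_QUANTILES_5 = (0.05, 0.275, 0.5, 0.725, 0.95)


def fit_restricted_cubic_baseline(records: pd.DataFrame, n_knots: int = 5,
                                  outcome: str = "score",
                                  week_col: str = "week_index",
                                  weight_col: str | None = "adjusted_weight") -> RCSCurve:
    """Weighted restricted-cubic-spline fit of the outcome on week number."""
    data = records.dropna(subset=[outcome, week_col])
    x = data[week_col].to_numpy(dtype=float)
    if len(np.unique(x)) < n_knots:
        raise ValueError(f"need >= {n_knots} distinct weeks for {n_knots} knots")
    y = data[outcome].to_numpy(dtype=float)
    w = (data[weight_col].to_numpy(dtype=float) if weight_col and weight_col in data
         else np.ones(len(data)))
    q = (RCS_QUANTILES_5 if n_knots == 5
         else tuple(np.linspace(0.05, 0.95, n_knots)))
    knots = np.unique(np.quantile(x, q))
    if len(knots) < n_knots:
        raise ValueError("tied knot quantiles; too few distinct weeks")
    B = np.column_stack([np.ones_like(x), _rcs_basis(x, knots)])
    WB = B * w[:, None]
    coefs = np.linalg.solve(B.T @ WB, B.T @ (w * y))
    return RCSCurve(knots=knots, coefs=coefs,
                    week_range=(float(x.min()), float(x.max())))


# --------------------------------------------------------------------------
# update-stability experiment
# --------------------------------------------------------------------------

def stability_experiment(records: pd.DataFrame, spec: GamSpec,
                         schedule: list[int], outcome: str = "score",
                         weight_col: str | None = "adjusted_weight",
                         week_col: str = "week_index",
                         fitter: str = "gam") -> pd.DataFrame:
    """Refit the curve at each cutoff week and track changes to past weeks.

    Emulates periodic surveillance updates: the series is truncated at each
    cutoff in ``schedule`` (increasing), the smoother refitted, and for
    every week already covered by the previous fit the absolute change of
    the predicted value is recorded.  ``fitter`` selects the thin-plate GAM
    or the restricted-cubic baseline.
    """
    if list(schedule) != sorted(schedule):
        raise ValueError("schedule of cutoff weeks must be increasing")
    if fitter == "gam" and spec.group_vars:
        raise ValueError("stability_experiment runs on an overall curve; "
                         "use group_vars=() in the spec")
    prev: pd.Series | None = None
    out = []
    for i, cutoff in enumerate(schedule):
        sub = records[records[week_col] <= cutoff]
        weeks = np.arange(int(sub[week_col].min()), int(sub[week_col].max()) + 1)
        if fitter == "gam":
            g = fit_gam(sub, spec, outcome=outcome, weight_col=weight_col,
                        week_col=week_col)
            grid = pd.DataFrame({week_col: weeks})
            pred = g.predict(grid)
        elif fitter == "rcs":
            curve = fit_restricted_cubic_baseline(sub, outcome=outcome,
                                                  week_col=week_col,
                                                  weight_col=weight_col)
            pred = curve.predict(weeks)
        else:
            raise ValueError(f"unknown fitter {fitter!r}")
        cur = pd.Series(pred, index=weeks)
        if prev is not None:
            shared = prev.index.intersection(cur.index)
            change = (cur.loc[shared] - prev.loc[shared]).abs()
        else:
            shared, change = cur.index, pd.Series(np.nan, index=cur.index)
        for wkk in cur.index:
            out.append({"update": i, "cutoff": cutoff, "week": int(wkk),
                        "estimate": float(cur.loc[wkk]),
                        "abs_change": float(change.loc[wkk]) if wkk in change.index else np.nan})
        prev = cur
    return pd.DataFrame(out)
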