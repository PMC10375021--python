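import numpy as np
import pandas as pd
import pytest

from survtrend.smoothing import (
    GamSpec, _assemble_design, _eta, _penalized_solve, _reml_criterion,
    build_penalized_basis, fit_gam, fit_restricted_cubic_baseline,
    predict_weekly, stability_experiment,
)
from survtrend.standardization import StandardPopulation


def _sp(levels=("18-29", "30-59", "60+")):
    return StandardPopulation(pd.DataFrame(
        [{"sex": s, "age_group": a, "education": e, "count": 7.0}
         for s in ["female", "male"] for a in levels
         for e in ["low", "medium", "high"]]))


# --------------------------------------------------------------------------
# basis and penalty construction
# --------------------------------------------------------------------------

def test_penalty_is_psd_with_unpenalized_linear_column():
    basis = build_penalized_basis(np.arange(30.0), basis_dim=10)
    S = basis.full_penalty()
    assert np.allclose(S, S.T)
    eig = np.linalg.eigvalsh(S)
    assert eig.min() > -1e-10                      # positive semi-definite
    assert basis.penalty_rank == basis.k - 2       # penalized block has full rank
    lin = np.zeros(basis.n_columns)
    lin[-1] = 1.0
    assert lin @ S @ lin == 0.0                    # linear trend is not penalized


def test_basis_dim_reduced_for_short_series():
    basis = build_penalized_basis(np.arange(6.0), basis_dim=10)
    assert basis.k == 6
    with pytest.raises(ValueError):
        build_penalized_basis(np.arange(3.0), basis_dim=10)


def test_constant_data_shrinks_smooth_to_its_null_space():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"week_index": rng.integers(0, 60, 2000).astype(float),
                       "score": 2.0 + rng.normal(0, 1.0, 2000)})
    g = fit_gam(df, GamSpec(group_vars=()), outcome="score", weight_col=None)
    assert g.edf_per_smooth[()] == pytest.approx(1.0, abs=0.15)
    assert g.edf_total == pytest.approx(2.0, abs=0.2)


def test_interpolating_limit_matches_dense_thin_plate_oracle():
    # with k = n and lambda -> 0, the fit reproduces the exact interpolating
    # thin-plate spline from the dense saddle-point system
    xs = np.linspace(0.0, 1.0, 10)
    y = np.sin(3 * xs)
    E = _eta(xs[:, None] - xs[None, :])
    T = np.column_stack([np.ones(10), xs])
    M = np.block([[E, T], [T.T, np.zeros((2, 2))]])
    sol = np.linalg.solve(M, np.r_[y, 0.0, 0.0])
    delta, alpha = sol[:10], sol[10:]
    xstar = np.array([0.17, 0.53, 0.88])
    oracle = _eta(xstar[:, None] - xs[None, :]) @ delta + alpha[0] + alpha[1] * xstar

    basis = build_penalized_basis(xs, basis_dim=10)
    B = np.column_stack([np.ones(10), basis.evaluate(xs)])
    Sf = np.zeros((B.shape[1],) * 2)
    Sf[1:basis.k - 1, 1:basis.k - 1] = basis.S
    beta = np.linalg.solve(B.T @ B + 1e-10 * Sf, B.T @ y)
    ours = np.column_stack([np.ones(3), basis.evaluate(xstar)]) @ beta
    assert np.abs(ours - oracle).max() < 1e-6


# --------------------------------------------------------------------------
# REML selection
# --------------------------------------------------------------------------

def test_reml_optimum_matches_grid_search_oracle():
    rng = np.random.default_rng(5)
    n = 200
    w = rng.integers(0, 40, n).astype(float)
    y = 0.5 + 0.05 * w + 0.3 * np.sin(w / 5) + rng.normal(0, 0.5, n)
    df = pd.DataFrame({"week_index": w, "score": y})
    spec = GamSpec(group_vars=())
    g = fit_gam(df, spec, outcome="score", weight_col=None)

    X, _di, _keep, _groups, blocks = _assemble_design(df, spec, "week_index")
    XtWX, XtWy, yWy = X.T @ X, X.T @ y, float(y @ y)
    Mp = X.shape[1] - sum(b.k - 2 for _k, _sl, b in blocks)
    step = 0.25
    grid = np.arange(-12.0, 18.0 + step, step)
    vals = [_reml_criterion(np.array([r]), XtWX, XtWy, yWy, n, blocks, Mp)[0]
            for r in grid]
    best = grid[int(np.argmin(vals))]
    fitted = np.log(list(g.lambdas.values())[0])
    assert abs(fitted - best) <= step


def test_sine_trend_beats_raw_weekly_means():
    rng = np.random.default_rng(6)
    n, sd = 2000, 1.0
    w = rng.integers(0, 104, n).astype(float)
    truth = 1.5 + 0.4 * np.sin(2 * np.pi * w / 104)
    y = truth + rng.normal(0, sd, n)
    df = pd.DataFrame({"week_index": w, "score": y})
    g = fit_gam(df, GamSpec(group_vars=()), outcome="score", weight_col=None)
    grid = np.arange(104.0)
    pred = g.predict(pd.DataFrame({"week_index": grid}))
    t_grid = 1.5 + 0.4 * np.sin(2 * np.pi * grid / 104)
    rmse = float(np.sqrt(np.mean((pred - t_grid) ** 2)))
    means = df.groupby("week_index")["score"].mean()
    rmse_raw = float(np.sqrt(np.mean(
        (means.to_numpy() - (1.5 + 0.4 * np.sin(2 * np.pi * means.index / 104))) ** 2)))
    assert rmse < 0.5 * sd
    assert rmse < rmse_raw


def test_lambda_to_infinity_reduces_to_parametric_fit():
    rng = np.random.default_rng(7)
    n = 400
    w = rng.integers(0, 50, n).astype(float)
    y = 1.0 + 0.02 * w + 0.2 * np.sin(w / 3) + rng.normal(0, 0.3, n)
    df = pd.DataFrame({"week_index": w, "score": y})
    spec = GamSpec(group_vars=())
    X, _di, _keep, _groups, blocks = _assemble_design(df, spec, "week_index")
    beta, _c, _ld = _penalized_solve(X.T @ X, X.T @ y, blocks, np.array([30.0]))
    # at giant lambda only intercept + linear survive: ordinary straight line
    line = np.polyfit(w, y, 1)
    pred = X @ beta
    assert np.abs(pred - np.polyval(line, w)).max() < 1e-4


def test_factor_by_curve_recovers_group_trends():
    rng = np.random.default_rng(8)
    n = 6000
    w = rng.integers(0, 80, n).astype(float)
    age = rng.choice(["18-29", "30-59", "60+"], n)
    sex = rng.choice(["female", "male"], n)
    edu = rng.choice(["low", "medium", "high"], n)
    base = {"18-29": 2.0, "30-59": 1.5, "60+": 1.0}
    sd = 1.0
    truth = (np.vectorize(base.get)(age)
             + 0.4 * np.sin(2 * np.pi * w / 80) * (age == "18-29"))
    df = pd.DataFrame({"week_index": w, "age_group": age, "sex": sex,
                       "education": edu,
                       "score": truth + rng.normal(0, sd, n),
                       "adjusted_weight": 1.0})
    g = fit_gam(df, GamSpec(basis_dim=8), outcome="score")
    grid = np.arange(80.0)
    for a in ["18-29", "60+"]:
        gg = pd.DataFrame({"week_index": grid, "age_group": a,
                           "sex": "female", "education": "medium"})
        pred = g.predict(gg)
        t = base[a] + 0.4 * np.sin(2 * np.pi * grid / 80) * (a == "18-29")
        assert np.sqrt(np.mean((pred - t) ** 2)) < 0.5 * sd


def test_sparse_group_smooth_omitted_with_surviving_fit():
    rng = np.random.default_rng(9)
    n = 500
    w = rng.integers(0, 30, n).astype(float)
    age = np.array(["30-59"] * (n - 3) + ["18-29"] * 3)
    w[-3:] = [1.0, 1.0, 2.0]  # only two distinct weeks in the tiny group
    df = pd.DataFrame({"week_index": w, "age_group": age,
                       "score": rng.normal(1.0, 0.5, n)})
    g = fit_gam(df, GamSpec(group_vars=("age_group",)), outcome="score",
                weight_col=None)
    assert ("18-29",) not in g.lambdas
    assert ("30-59",) in g.lambdas


# --------------------------------------------------------------------------
# weekly standardized predictions
# --------------------------------------------------------------------------

def _grouped_fit(seed=10, n=4000):
    rng = np.random.default_rng(seed)
    w = rng.integers(0, 60, n).astype(float)
    age = rng.choice(["18-29", "30-59", "60+"], n)
    sex = rng.choice(["female", "male"], n)
    edu = rng.choice(["low", "medium", "high"], n)
    y = 1.0 + 0.3 * (age == "18-29") + 0.01 * w + rng.normal(0, 0.8, n)
    df = pd.DataFrame({"week_index": w, "age_group": age, "sex": sex,
                       "education": edu, "score": y,
                       "pos": (y > 1.5).astype(float), "adjusted_weight": 1.0})
    return df


def test_overall_prediction_is_population_average_of_cells():
    df = _grouped_fit()
    g = fit_gam(df, GamSpec(basis_dim=6), outcome="score")
    sp = _sp()
    weeks = np.array([5.0, 30.0, 55.0])
    series = predict_weekly(g, sp, weeks)
    for i, wk in enumerate(weeks):
        grid = sp.rows.assign(week_index=wk)
        mu = g.predict(grid)
        oracle = float((sp.rows["count"] * mu).sum() / sp.rows["count"].sum())
        assert series.points["estimate"].iloc[i] == pytest.approx(oracle, abs=1e-10)


def test_binomial_weekly_predictions_stay_in_unit_interval():
    df = _grouped_fit()
    g = fit_gam(df, GamSpec(family="binomial", basis_dim=6), outcome="pos")
    series = predict_weekly(g, _sp(), np.arange(60.0))
    est = series.points["estimate"]
    assert ((est > 0) & (est < 1)).all()


def test_no_extrapolation_beyond_observed_weeks():
    df = _grouped_fit()
    g = fit_gam(df, GamSpec(basis_dim=6), outcome="score")
    with pytest.raises(ValueError, match="forecast"):
        predict_weekly(g, _sp(), [70.0])


def test_standardized_and_restricted_subgroup_predictions_differ_as_expected():
    df = _grouped_fit()
    g = fit_gam(df, GamSpec(basis_dim=6), outcome="score")
    sp = _sp()
    std = predict_weekly(g, sp, [30.0], stratum=("age_group", "18-29"),
                         standardized=True)
    unstd = predict_weekly(g, sp, [30.0], stratum=("age_group", "18-29"),
                           standardized=False)
    # age composition is degenerate within the subgroup: both modes must
    # agree for the *stratifying* variable itself up to other covariates
    assert std.points["estimate"].iloc[0] == pytest.approx(
        unstd.points["estimate"].iloc[0], abs=0.05)


# --------------------------------------------------------------------------
# restricted cubic baseline
# --------------------------------------------------------------------------

def test_rcs_is_linear_everywhere_on_linear_data():
    w = np.linspace(0, 100, 400)
    df = pd.DataFrame({"week_index": w, "score": 0.5 + 0.03 * w})
    curve = fit_restricted_cubic_baseline(df, weight_col=None)
    probe = np.array([-20.0, 5.0, 50.0, 95.0, 130.0])  # includes extrapolation
    assert np.allclose(curve.predict(probe), 0.5 + 0.03 * probe, atol=1e-8)


def test_rcs_basis_has_expected_columns():
    w = np.linspace(0, 100, 300)
    df = pd.DataFrame({"week_index": w, "score": np.sin(w / 10)})
    for k in (4, 5, 6):
        curve = fit_restricted_cubic_baseline(df, n_knots=k, weight_col=None)
        assert curve.basis(w).shape[1] == k - 1
        assert len(curve.knots) == k


def test_rcs_smoother_than_thin_plate_on_sine_data():
    rng = np.random.default_rng(11)
    n = 3000
    w = rng.integers(0, 104, n).astype(float)
    y = 1.5 + 0.5 * np.sin(2 * np.pi * w / 52) + rng.normal(0, 0.8, n)
    df = pd.DataFrame({"week_index": w, "score": y})
    curve = fit_restricted_cubic_baseline(df, weight_col=None)
    g = fit_gam(df, GamSpec(group_vars=()), outcome="score", weight_col=None)
    grid = np.arange(104.0)

    def curvature(pred):
        return float(np.sum(np.diff(pred, 2) ** 2))

    assert curvature(curve.predict(grid)) < curvature(
        g.predict(pd.DataFrame({"week_index": grid})))


# --------------------------------------------------------------------------
# update stability
# --------------------------------------------------------------------------

def _break_series(seed=12, n=4000, n_weeks=60, break_week=45, size=0.6):
    rng = np.random.default_rng(seed)
    w = rng.integers(0, n_weeks, n).astype(float)
    y = 1.0 + size * (w > break_week) + rng.normal(0, 1.0, n)
    return pd.DataFrame({"week_index": w, "score": y})


def test_refit_without_new_data_changes_nothing():
    df = _break_series()
    tab = stability_experiment(df, GamSpec(group_vars=()), [40, 40],
                               outcome="score", weight_col=None)
    assert tab.loc[tab["update"] == 1, "abs_change"].max() == pytest.approx(0.0, abs=1e-10)


def test_old_weeks_move_less_than_recent_weeks():
    df = _break_series()
    tab = stability_experiment(df, GamSpec(group_vars=()),
                               list(range(20, 60, 4)),
                               outcome="score", weight_col=None)
    ch = tab.dropna(subset=["abs_change"])
    horizon = ch["week"].max()
    old = ch[ch["week"] <= horizon / 3]["abs_change"].mean()
    new = ch[ch["week"] > 2 * horizon / 3]["abs_change"].mean()
    assert old < new


def test_thin_plate_adapts_to_break_no_slower_than_rcs():
    df = _break_series(seed=13, n=8000)
    schedule = list(range(42, 60, 2))
    probe_week, size = 47, 0.6  # first full post-break week on the grid

    def first_adaptive_update(fitter):
        tab = stability_experiment(df, GamSpec(group_vars=()), schedule,
                                   outcome="score", weight_col=None,
                                   fitter=fitter)
        at_break = tab[tab["week"] == probe_week]
        moved = at_break[at_break["estimate"] >= 1.0 + size / 2]
        return moved["update"].min() if len(moved) else np.inf

    assert first_adaptive_update("gam") <= first_adaptive_update("rcs")
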