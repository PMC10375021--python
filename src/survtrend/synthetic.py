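"""Synthetic survey microdata with known ground truth.

The restricted telephone-survey microdata the surveillance pipeline was
designed for cannot be shipped, so this module generates tables with the
same statistical structure: interview dates inside mid-month field periods,
demographics drawn from a census-style joint distribution *tilted* by a
nonresponse model (participation multipliers per demographic cell),
month-to-month sample-size variation, whole-month data gaps, design weights
from a simple simulated selection mechanism, a 0-6 screening score with a
binary screen-positive flag, and missingness in the variables the real data
has missingness in.

Every generated scenario comes with its analytically computed ground truth
(:func:`true_values`), so estimator bias can be measured exactly rather
than against another simulation.

The metric indicator emulates a two-item screener (PHQ-2-like): a latent
Gaussian ``trend(week, cell) + noise`` is *rounded* to the nearest integer
and clipped to the 0-6 score range; the binary indicator is ``score >
cutoff`` (default cutoff 2, the conventional screen-positive threshold).
Because of the rounding convention, the true mean and true proportion are
exact Gaussian-cell probabilities and are computed in closed form.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import timegrid
from .groups import (
    AGE7, EDUCATION, MUNICIPALITY_SIZES, NIELSEN_AREAS, SEXES, STATE_GROUPS,
    coarse_of_age7,
)

__all__ = [
    "SimulationConfig", "GroundTruth", "generate_survey", "true_values",
    "default_population_joint", "raking_targets", "standard_population",
    "write_scenario",
]

_AGE7_BANDS = {
    "18-29": (18, 29), "30-39": (30, 39), "40-49": (40, 49),
    "50-59": (50, 59), "60-69": (60, 69), "70-79": (70, 79), "80+": (80, 94),
}

_AGE7_SHARE = {
    "18-29": 0.17, "30-39": 0.16, "40-49": 0.15, "50-59": 0.19,
    "60-69": 0.15, "70-79": 0.11, "80+": 0.07,
}
_SEX_SHARE = {"female": 0.51, "male": 0.49}
_EDU_SHARE = {"low": 0.30, "medium": 0.50, "high": 0.20}

_NIELSEN_SHARE = dict(zip(NIELSEN_AREAS, [0.15, 0.21, 0.15, 0.08, 0.09, 0.16, 0.16]))
_STATE_SHARE = dict(zip(STATE_GROUPS, [0.065, 0.105, 0.215, 0.075, 0.061,
                                       0.133, 0.157, 0.044, 0.050, 0.095]))

#: selection probabilities by municipality size; design weight = 1/p
_SELECTION_PROB = {"rural": 1.3, "small-town": 1.1, "medium-town": 0.9,
                   "metropolitan": 0.7}

#: default participation multipliers: older and more educated respondents
#: are easier to reach and more willing, the classic telephone-survey tilt
_NONRESP_AGE = {"18-29": 0.55, "30-39": 0.65, "40-49": 0.80, "50-59": 1.00,
                "60-69": 1.25, "70-79": 1.45, "80+": 1.60}
_NONRESP_EDU = {"low": 0.80, "medium": 1.00, "high": 1.30}

#: default trend shapes per coarse age group: a late level break for the
#: youngest, a slow rise for the middle, a flat line for the oldest.
_DEFAULT_TRENDS = {
    "18-29": ("break", {"level": 1.6, "size": 0.5, "break_frac": 0.7, "ramp_weeks": 4}),
    "30-59": ("linear", {"level": 1.3, "total_rise": 0.4}),
    "60+": ("flat", {"level": 1.0}),
}

_SEX_EFFECT = {"female": 0.20, "male": 0.0}
_EDU_EFFECT = {"low": 0.15, "medium": 0.0, "high": -0.15}

_DEFAULT_MISSING = {"sex": 0.005, "age": 0.005, "education": 0.03,
                    "state_group": 0.02, "municipality_size": 0.02,
                    "indicator": 0.02}


def default_population_joint(total: float = 100_000.0) -> pd.DataFrame:
    """Census-style joint counts over sex x 7 age groups x 3 education levels."""
    rows = []
    for sex in SEXES:
        for ag in AGE7:
            for edu in EDUCATION:
                rows.append({
                    "sex": sex, "age_group": ag, "education": edu,
                    "count": total * _SEX_SHARE[sex] * _AGE7_SHARE[ag] * _EDU_SHARE[edu],
                })
    return pd.DataFrame(rows)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic scenario.

    Defaults describe the shipped reference scenario: 36 monthly periods at
    roughly 1,000 interviews each with a two-month gap, three coarse-age
    trend shapes, and the standard nonresponse tilt.
    """

    months: int = 36
    n_per_month: int | list[int] = 1000
    start_month: str = "2020-01"
    gap_months: list[int] = field(default_factory=lambda: [18, 19])
    population_joint: pd.DataFrame | None = None
    nonresponse_age: dict = field(default_factory=lambda: dict(_NONRESP_AGE))
    nonresponse_education: dict = field(default_factory=lambda: dict(_NONRESP_EDU))
    trend_functions: dict = field(default_factory=lambda: dict(_DEFAULT_TRENDS))
    sex_effects: dict = field(default_factory=lambda: dict(_SEX_EFFECT))
    education_effects: dict = field(default_factory=lambda: dict(_EDU_EFFECT))
    cutoff: int = 2
    noise_sd: float = 1.3
    missing_rates: dict = field(default_factory=lambda: dict(_DEFAULT_MISSING))
    seed: int = 0

    def __post_init__(self):
        if self.population_joint is None:
            self.population_joint = default_population_joint()
        if isinstance(self.n_per_month, int):
            self.n_per_month = [self.n_per_month] * self.months
        if len(self.n_per_month) != self.months:
            raise ValueError("n_per_month list must have one entry per month")
        for d in (self.nonresponse_age, self.nonresponse_education):
            if any(v <= 0 for v in d.values()):
                raise ValueError("participation multipliers must be > 0")
        if any(not (0 <= r < 1) for r in self.missing_rates.values()):
            raise ValueError("missing rates must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        missing = set(self.nonresponse_age) ^ set(_AGE7_SHARE)
        if missing:
            raise ValueError(f"nonresponse_age keys must be the 7 age groups; mismatch: {missing}")

    def replace(self, **kw) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(self)}
        bad = set(kw) - known
        if bad:
            raise TypeError(f"unknown config fields: {sorted(bad)}")
        base = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        base.update(kw)
        if isinstance(base["n_per_month"], list) and "months" in kw and \
                len(base["n_per_month"]) != base["months"] and "n_per_month" not in kw:
            base["n_per_month"] = base["n_per_month"][0]
        return SimulationConfig(**base)

    # --- time anchors -----------------------------------------------------
    @property
    def start_period(self) -> timegrid.MonthPeriod:
        return timegrid.period_from_label(self.start_month)

    @property
    def anchor_monday(self) -> dt.date:
        """Monday of the ISO week containing the first period start."""
        return timegrid.iso_week_start(self.start_period.start_date)

    def week_of(self, date) -> int:
        return (timegrid.iso_week_start(date) - self.anchor_monday).days // 7

    def period(self, m: int) -> timegrid.MonthPeriod:
        ordinal = self.start_period.index + m
        return timegrid.period_from_label(f"{ordinal // 12}-{ordinal % 12 + 1:02d}")

    @property
    def n_weeks(self) -> int:
        return self.week_of(self.period(self.months - 1).end_date) + 1


def _trend_value(shape: str, params: dict, week, n_weeks: int):
    week = np.asarray(week, dtype=float)
    if shape == "flat":
        return np.full_like(week, params["level"])
    if shape == "linear":
        slope = params.get("slope_per_week", params.get("total_rise", 0.0) / max(n_weeks - 1, 1))
        return params["level"] + slope * week
    if shape == "break":
        bw = params.get("break_week", params.get("break_frac", 0.7) * (n_weeks - 1))
        ramp = max(params.get("ramp_weeks", 4), 1e-9)
        frac = np.clip((week - bw) / ramp, 0.0, 1.0)
        return params["level"] + params["size"] * frac
    raise ValueError(f"unknown trend shape {shape!r}")


def cell_mean(config: SimulationConfig, sex, age_group7, education, week):
    """Latent mean of the metric score for one demographic cell at a week."""
    shape, params = config.trend_functions[coarse_of_age7(age_group7)]
    base = _trend_value(shape, params, week, config.n_weeks)
    return base + config.sex_effects[sex] + config.education_effects[education]


def _discretized_moments(mu, sd):
    """Exact mean of clip(round(mu+eps), 0, 6) under Gaussian eps."""
    mu = np.asarray(mu, dtype=float)
    if sd == 0:
        return np.clip(np.round(mu), 0, 6)
    mean = np.zeros_like(mu)
    for s in range(7):
        lo = -np.inf if s == 0 else s - 0.5
        hi = np.inf if s == 6 else s + 0.5
        p = norm.cdf((hi - mu) / sd) - (0.0 if s == 0 else norm.cdf((lo - mu) / sd))
        mean += s * p
    return mean


def _true_prop(mu, sd, cutoff):
    # score > cutoff  <=>  latent > cutoff + 0.5 under the rounding convention
    mu = np.asarray(mu, dtype=float)
    if sd == 0:
        return (mu > cutoff + 0.5).astype(float)
    return norm.sf((cutoff + 0.5 - mu) / sd)


@dataclass
class GroundTruth:
    """Analytic standardized truth per week/month, stratum, and overall."""

    weekly: pd.DataFrame
    monthly: pd.DataFrame
    #: expected values of the *unweighted* sample mean under the nonresponse
    #: tilt, for quantifying naive-estimator bias
    naive_weekly: pd.DataFrame


def _cell_table(config: SimulationConfig) -> pd.DataFrame:
    pop = config.population_joint.copy()
    pop["mult"] = [config.nonresponse_age[a] * config.nonresponse_education[e]
                   for a, e in zip(pop["age_group"], pop["education"])]
    pop["tilted"] = pop["count"] * pop["mult"]
    return pop


def true_values(config: SimulationConfig) -> GroundTruth:
    """Ground truth computed analytically from the trend functions.

    Standardized (counterfactual) subgroup truth re-weights every population
    cell as if it belonged to the subgroup; unstandardized truth restricts
    to the subgroup's own cells.  Monthly truth is the average of weekly
    truths over the ISO weeks whose Monday falls in the period, which is
    what a centered window estimator targets under uniform interviewing.
    """
    pop = _cell_table(config)
    weeks = np.arange(config.n_weeks)
    # matrix of latent means: cells x weeks
    mu = np.stack([
        cell_mean(config, r.sex, r.age_group, r.education, weeks)
        for r in pop.itertuples()
    ])
    mean_mat = _discretized_moments(mu, config.noise_sd)
    prop_mat = _true_prop(mu, config.noise_sd, config.cutoff)
    counts = pop["count"].to_numpy()
    tilted = pop["tilted"].to_numpy()

    def avg(mat, w):
        return (w[:, None] * mat).sum(axis=0) / w.sum()

    rows = []

    def emit(var, level, standardized, w):
        m, p = avg(mean_mat, w), avg(prop_mat, w)
        for wk in weeks:
            rows.append({"week": int(wk), "stratum_var": var, "stratum_level": level,
                         "standardized": standardized, "mean": m[wk], "prop": p[wk]})

    emit("overall", "overall", True, counts)
    for var in ("sex", "age_group", "education"):
        for level in pop[var].unique():
            # counterfactual: override var -> level for all cells
            over = pop.assign(**{var: level})
            mu_c = np.stack([
                cell_mean(config, r.sex, r.age_group, r.education, weeks)
                for r in over.itertuples()
            ])
            m = avg(_discretized_moments(mu_c, config.noise_sd), counts)
            p = avg(_true_prop(mu_c, config.noise_sd, config.cutoff), counts)
            for wk in weeks:
                rows.append({"week": int(wk), "stratum_var": var, "stratum_level": level,
                             "standardized": True, "mean": m[wk], "prop": p[wk]})
            emit(var, level, False, counts * (pop[var] == level).to_numpy())
    weekly = pd.DataFrame(rows)

    mrows = []
    for m in range(config.months):
        per = config.period(m)
        w0, w1 = config.week_of(per.start_date), config.week_of(per.end_date)
        in_per = [w for w in range(w0, w1 + 1)
                  if per.start_date <= config.anchor_monday + dt.timedelta(weeks=w) <= per.end_date]
        sub = weekly[weekly["week"].isin(in_per)]
        g = sub.groupby(["stratum_var", "stratum_level", "standardized"], as_index=False)[["mean", "prop"]].mean()
        g.insert(0, "month_label", per.label)
        g.insert(1, "month_index", m)
        mrows.append(g)
    monthly = pd.concat(mrows, ignore_index=True)

    nrows = [{"week": int(wk), "mean": avg(mean_mat, tilted)[wk],
              "prop": avg(prop_mat, tilted)[wk]} for wk in weeks]
    return GroundTruth(weekly=weekly, monthly=monthly, naive_weekly=pd.DataFrame(nrows))


def generate_survey(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic microdata table; byte-reproducible under the seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pop = _cell_table(config)
    p_cell = (pop["tilted"] / pop["tilted"].sum()).to_numpy()
    states = list(_STATE_SHARE)
    p_state = np.array(list(_STATE_SHARE.values()))
    p_state = p_state / p_state.sum()
    areas = list(_NIELSEN_SHARE)
    p_area = np.array(list(_NIELSEN_SHARE.values()))
    p_area = p_area / p_area.sum()

    frames = []
    for m in range(config.months):
        if m in config.gap_months:
            continue
        n = int(config.n_per_month[m])
        per = config.period(m)
        ndays = (per.end_date - per.start_date).days + 1
        day = rng.integers(0, ndays, size=n)
        dates = [per.start_date + dt.timedelta(days=int(d)) for d in day]
        cell = rng.choice(len(pop), size=n, p=p_cell)
        sex = pop["sex"].to_numpy()[cell]
        ag = pop["age_group"].to_numpy()[cell]
        edu = pop["education"].to_numpy()[cell]
        lo = np.array([_AGE7_BANDS[a][0] for a in ag])
        hi = np.array([_AGE7_BANDS[a][1] for a in ag])
        age = lo + (rng.random(n) * (hi - lo + 1)).astype(int)
        state = rng.choice(states, size=n, p=p_state)
        area = rng.choice(areas, size=n, p=p_area)
        msize = np.array([
            rng.choice(MUNICIPALITY_SIZES, p=municipality_distribution(s)) for s in state
        ])
        dw = np.array([1.0 / _SELECTION_PROB[s] for s in msize])
        dw = dw / dw.mean()
        week = np.array([config.week_of(d) for d in dates], dtype=float)
        mu = np.array([
            cell_mean(config, s, a, e, w)
            for s, a, e, w in zip(sex, ag, edu, week)
        ], dtype=float)
        raw = mu + rng.normal(0.0, config.noise_sd, size=n)
        score = np.clip(np.round(raw), 0, 6).astype(float)
        frames.append(pd.DataFrame({
            "interview_date": [d.isoformat() for d in dates],
            "sex": sex, "age": age.astype(float), "education": edu,
            "state_group": state, "nielsen_area": area,
            "municipality_size": msize, "design_weight": dw,
            "score": score,
        }))
    df = pd.concat(frames, ignore_index=True)

    mr = config.missing_rates
    n = len(df)
    for col, key in [("sex", "sex"), ("age", "age"), ("education", "education"),
                     ("state_group", "state_group"),
                     ("municipality_size", "municipality_size"),
                     ("score", "indicator")]:
        rate = mr.get(key, 0.0)
        mask = rng.random(n) < rate
        if mask.any():
            df.loc[mask, col] = np.nan
    df["screen_positive"] = (df["score"] > config.cutoff).astype(float)
    df.loc[df["score"].isna(), "screen_positive"] = np.nan
    df["source_id"] = "sim"
    return df


def municipality_distribution(state_group: str) -> np.ndarray:
    """Municipality-size distribution within a federal-state group.

    A deterministic tilt makes city-dominated groups more metropolitan so
    the state-conditional imputation path is exercised.
    """
    base = np.array([0.30, 0.30, 0.25, 0.15])
    shift = {"BE": 0.8, "SH+HH": 0.35, "NI+HB": 0.15}.get(state_group, 0.0)
    p = base * np.array([1 - shift, 1 - shift / 2, 1.0, 1.0]) + np.array([0, 0, 0, shift * 0.7])
    return p / p.sum()


# --- tables consumed by the weighting / standardization modules ----------

def standard_population(config: SimulationConfig) -> pd.DataFrame:
    """The (untilted) joint distribution used as the standard population."""
    return config.population_joint[["sex", "age_group", "education", "count"]].copy()


def state_distribution() -> pd.Series:
    s = pd.Series(_STATE_SHARE, name="proportion")
    return s / s.sum()


def municipality_by_state() -> pd.DataFrame:
    rows = []
    for sg in STATE_GROUPS:
        for ms, p in zip(MUNICIPALITY_SIZES, municipality_distribution(sg)):
            rows.append({"state_group": sg, "municipality_size": ms, "proportion": p})
    return pd.DataFrame(rows)


def raking_targets(config: SimulationConfig) -> dict[int, pd.DataFrame]:
    """Population margin tables for the four adjustment levels.

    Derived from the same joint distribution the generator samples from
    (before the nonresponse tilt), so raking can undo the tilt exactly in
    expectation.
    """
    pop = config.population_joint
    tot = pop["count"].sum()

    t1 = (pop.groupby(["sex", "age_group"], as_index=False)["count"].sum()
          .rename(columns={"age_group": "age7"}))
    t1["proportion"] = t1.pop("count") / tot

    p2 = pop.assign(age3a=[coarse_of_age7(a) for a in pop["age_group"]])
    t2 = p2.groupby(["age3a", "education"], as_index=False)["count"].sum()
    t2["proportion"] = t2.pop("count") / tot

    mbs = municipality_by_state()
    sd = state_distribution()
    ms_overall = (mbs.assign(p=[sd[s] for s in mbs["state_group"]])
                  .assign(joint=lambda d: d["p"] * d["proportion"])
                  .groupby("municipality_size")["joint"].sum())
    rows = [{"nielsen_area": a, "municipality_size": m,
             "proportion": _NIELSEN_SHARE[a] * ms_overall[m]}
            for a in NIELSEN_AREAS for m in MUNICIPALITY_SIZES]
    t3 = pd.DataFrame(rows)
    t3["proportion"] /= t3["proportion"].sum()

    age3b_share = {}
    for ag, share in _AGE7_SHARE.items():
        key = "18-39" if ag in ("18-29", "30-39") else ("40-59" if ag in ("40-49", "50-59") else "60+")
        age3b_share[key] = age3b_share.get(key, 0.0) + share
    rows = [{"state_group": s, "age3b": a, "proportion": sd[s] * age3b_share[a]}
            for s in STATE_GROUPS for a in ["18-39", "40-59", "60+"]]
    t4 = pd.DataFrame(rows)
    t4["proportion"] /= t4["proportion"].sum()
    return {1: t1[["sex", "age7", "proportion"]], 2: t2[["age3a", "education", "proportion"]],
            3: t3, 4: t4}


def write_scenario(outdir, config: SimulationConfig) -> dict[str, str]:
    """Write microdata, targets, standard population, and truth as CSV."""
    import pathlib

    out = pathlib.Path(outdir)
    (out / "data").mkdir(parents=True, exist_ok=True)
    paths = {}
    df = generate_survey(config)
    paths["microdata"] = str(out / "data" / "microdata_sim.csv")
    df.to_csv(paths["microdata"], index=False)
    paths["standard_population"] = str(out / "standard_population.csv")
    standard_population(config).to_csv(paths["standard_population"], index=False)
    for lv, tab in raking_targets(config).items():
        paths[f"targets_level{lv}"] = str(out / f"targets_level{lv}.csv")
        tab.to_csv(paths[f"targets_level{lv}"], index=False)
    truth = true_values(config)
    paths["truth_weekly"] = str(out / "truth_weekly.csv")
    truth.weekly.to_csv(paths["truth_weekly"], index=False)
    paths["truth_monthly"] = str(out / "truth_monthly.csv")
    truth.monthly.to_csv(paths["truth_monthly"], index=False)
    return paths
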