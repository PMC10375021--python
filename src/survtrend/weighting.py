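"""Adjustment weighting by iterative raking to population margins.

Telephone-survey samples over- and under-represent demographic groups
because willingness to participate and reachability differ by age, sex,
education, and region.  Starting from the design weights (inverse selection
probabilities, supplied as input), the sample is calibrated per monthly
period by *raking*: the weights are repeatedly scaled within the cells of
several cross-classifications ("adjustment levels") until every weighted
margin matches its known population proportion.

Four default adjustment levels are used:

1. sex x 7 age groups,
2. 3 coarse age groups x education (collapsed ISCED),
3. Nielsen area x municipality-size class,
4. combined federal-state group x 3 coarse age groups.

Sparse cells destabilize raking, so the scheme carries guard rules: when a
target cell holds fewer than ten observations and produces adjustment
factors of (near) zero or above ten times the design weight — or when the
iteration cap of 300 full cycles is hit — adjacent age-group categories of
the affected level are merged and the level is re-raked.  Missing values in
the weighting variables are imputed first: education to the middle
category, federal state from the national distribution, municipality size
from the state-specific distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .groups import derive_group_columns

logger = logging.getLogger(__name__)

__all__ = [
    "AdjustmentLevel", "RakingConfig", "WeightedSample",
    "filter_eligible", "impute_weighting_vars", "rake",
    "check_and_collapse", "weight_all_periods", "default_levels",
]


@dataclass
class AdjustmentLevel:
    """One cross-classification with its target marginal distribution.

    ``target`` has one column per variable plus ``proportion``.  Collapsing
    of age categories is recorded in ``category_maps`` (original category ->
    merged label) and applied on the fly, so the original records are never
    modified.
    """

    level_id: int
    variables: list[str]
    target: pd.DataFrame
    category_maps: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        missing = [v for v in self.variables if v not in self.target.columns]
        if missing:
            raise ValueError(f"target table lacks columns {missing}")
        p = self.target["proportion"]
        if (p < 0).any():
            raise ValueError("target proportions must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"level {self.level_id} target proportions sum to {p.sum()}, not 1")

    @property
    def age_var(self) -> str | None:
        for v in self.variables:
            if v.startswith("age"):
                return v
        return None

    def mapped(self, records: pd.DataFrame, var: str) -> pd.Series:
        col = records[var].astype(object)
        m = self.category_maps.get(var)
        return col.map(lambda x: m.get(x, x)) if m else col

    def effective_target(self) -> pd.DataFrame:
        """Target with category merges applied (proportions summed)."""
        t = self.target.copy()
        for var, m in self.category_maps.items():
            t[var] = t[var].map(lambda x: m.get(x, x))
        return t.groupby(self.variables, as_index=False)["proportion"].sum()

    def age_categories(self) -> list[str]:
        """Current (possibly merged) age categories in target order."""
        av = self.age_var
        if av is None:
            return []
        t = self.effective_target()
        return list(dict.fromkeys(t[av]))

    def merge_age(self, category: str) -> bool:
        """Merge ``category`` with its adjacent age group; False if impossible."""
        av = self.age_var
        if av is None:
            return False
        cats = self.age_categories()
        if len(cats) <= 1 or category not in cats:
            return False
        i = cats.index(category)
        j = i + 1 if i + 1 < len(cats) else i - 1
        a, b = (cats[i], cats[j]) if i < j else (cats[j], cats[i])
        merged = f"{a}+{b}"
        m = self.category_maps.setdefault(av, {})
        for orig in list(self.target[av].unique()):
            if m.get(orig, orig) in (a, b):
                m[orig] = merged
        return True


@dataclass
class RakingConfig:
    max_iterations: int = 300
    convergence_tol: float = 1e-6
    min_cell_n: int = 10
    extreme_factor: float = 10.0
    zero_weight_tol: float = 1e-12
    weight_normalization: str = "mean-one"  # or "sum-n" (same thing per period)
    max_collapse_rounds: int = 12

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.extreme_factor <= 1:
            raise ValueError("extreme_factor must be > 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class WeightedSample:
    """Records of one period with adjusted weights and raking diagnostics."""

    records: pd.DataFrame
    period: str
    converged: bool
    iterations: int
    max_margin_deviation: float
    collapse_actions: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def weights(self) -> np.ndarray:
        return self.records["adjusted_weight"].to_numpy()


def filter_eligible(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only interviews with non-missing sex and age."""
    ok = records["sex"].notna() & records["age"].notna()
    dropped = int((~ok).sum())
    if dropped:
        logger.info("filter_eligible: dropped %d of %d records missing sex or age",
                    dropped, len(records))
    if ok.sum() == 0:
        logger.warning("filter_eligible: no eligible records remain")
    return records.loc[ok].copy()


def impute_weighting_vars(records: pd.DataFrame,
                          state_distribution: pd.Series,
                          municipality_by_state: pd.DataFrame,
                          seed: int) -> pd.DataFrame:
    """Fill missing weighting variables.

    Education goes to the middle category; federal-state group is drawn from
    the national distribution; municipality size is drawn from the
    distribution within the (possibly just-imputed) state.  Draws are
    reproducible under ``seed``.
    """
    p = state_distribution / state_distribution.sum()
    if (p < 0).any():
        raise ValueError("state distribution must be non-negative")
    rng = np.random.default_rng(seed)
    out = records.copy()
    for col in ("education", "state_group", "municipality_size"):
        if out[col].isna().any():
            out[col] = out[col].astype(object)

    miss_edu = out["education"].isna()
    if miss_edu.any():
        out.loc[miss_edu, "education"] = "medium"

    miss_state = out["state_group"].isna()
    if miss_state.any():
        out.loc[miss_state, "state_group"] = rng.choice(
            p.index.to_numpy(), size=int(miss_state.sum()), p=p.to_numpy())

    miss_ms = out["municipality_size"].isna()
    if miss_ms.any():
        mbs = municipality_by_state.set_index(["state_group", "municipality_size"])["proportion"]
        for state, idx in out.loc[miss_ms].groupby("state_group").groups.items():
            cond = mbs.loc[state]
            cond = cond / cond.sum()
            out.loc[idx, "municipality_size"] = rng.choice(
                cond.index.to_numpy(), size=len(idx), p=cond.to_numpy())
    return out


def _cell_ids(records: pd.DataFrame, level: AdjustmentLevel,
              target: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Map each record to its row index in the effective target (or -1)."""
    key_cols = [level.mapped(records, v) for v in level.variables]
    keys = list(zip(*[c.to_numpy() for c in key_cols]))
    lut = {tuple(row): i for i, row in
           enumerate(target[level.variables].itertuples(index=False, name=None))}
    ids = np.array([lut.get(k, -1) for k in keys], dtype=int)
    return ids, target["proportion"].to_numpy()


def _ipf(records: pd.DataFrame, w0: np.ndarray, levels: list[AdjustmentLevel],
         config: RakingConfig) -> tuple[np.ndarray, bool, int, float]:
    """Cycle the levels, scaling weights within target cells, until the
    worst weighted-margin deviation falls below tolerance."""
    w = w0.copy()
    prepared = []
    for lv in levels:
        tgt = lv.effective_target()
        ids, props = _cell_ids(records, lv, tgt)
        if (ids < 0).any():
            bad = records.loc[ids < 0, lv.variables].drop_duplicates()
            raise ValueError(
                f"level {lv.level_id}: record categories missing from target: "
                f"{bad.to_dict('records')}")
        # a target cell without observations cannot be fitted; exclude it
        # and renormalize the remaining margin (the collapse workflow merges
        # it away afterwards where the level has an age variable)
        occupied = np.bincount(ids, minlength=len(props)) > 0
        if not occupied.all():
            logger.info("level %d: %d empty target cell(s) excluded from margin",
                        lv.level_id, int((~occupied).sum()))
            props = np.where(occupied, props, 0.0)
            props = props / props.sum()
        prepared.append((ids, props))

    maxdev = np.inf
    for it in range(1, config.max_iterations + 1):
        for ids, props in prepared:
            cur = np.bincount(ids, weights=w, minlength=len(props))
            share = cur / w.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(share > 0, props / np.where(share > 0, share, 1.0), 1.0)
            w = w * factor[ids]
        maxdev = 0.0
        for ids, props in prepared:
            cur = np.bincount(ids, weights=w, minlength=len(props))
            maxdev = max(maxdev, float(np.abs(cur / w.sum() - props).max()))
        if maxdev < config.convergence_tol:
            return w, True, it, maxdev
    return w, False, config.max_iterations, maxdev


def check_and_collapse(records: pd.DataFrame, level: AdjustmentLevel,
                       weights: np.ndarray, config: RakingConfig,
                       design_weights: np.ndarray | None = None,
                       cap_hit: bool = False) -> tuple[AdjustmentLevel, list[str]]:
    """Apply the small-cell guard rules to one level.

    Cells with fewer than ``min_cell_n`` observations whose adjustment
    factors are (near) zero or exceed ``extreme_factor`` — and empty target
    cells, and a hit iteration cap — trigger merging of adjacent age
    groups, youngest-first among the flagged cells.  Returns the (possibly
    modified) level plus a log of actions.
    """
    actions: list[str] = []
    if design_weights is None:
        design_weights = np.ones_like(weights)
    factor = weights / np.where(design_weights > 0, design_weights, 1.0)

    for _round in range(config.max_collapse_rounds):
        tgt = level.effective_target()
        ids, props = _cell_ids(records, level, tgt)
        counts = np.bincount(np.clip(ids, 0, None), minlength=len(props))
        av = level.age_var
        flagged: list[str] = []
        for c in range(len(props)):
            n = int(counts[c]) if c < len(counts) else 0
            if props[c] <= 0:
                continue
            in_cell = ids == c
            if n == 0:
                flagged.append(f"empty:{c}")
            elif n < config.min_cell_n:
                f = factor[in_cell]
                if (f < config.zero_weight_tol).any() or (f > config.extreme_factor).any():
                    flagged.append(f"extreme:{c}")
        if cap_hit and not flagged:
            flagged.append("cap")
        if not flagged:
            break
        if av is None:
            msg = (f"level {level.level_id}: flagged cells {flagged} but no age "
                   "variable to collapse; level left unchanged")
            logger.warning(msg)
            actions.append(msg)
            break
        # merge the youngest flagged age category (or youngest overall if
        # only the iteration cap fired)
        cats = level.age_categories()
        if len(cats) <= 1:
            actions.append(f"level {level.level_id}: single age category left, cannot collapse further")
            break
        cat_to_merge = None
        for flag in flagged:
            if ":" in flag:
                c = int(flag.split(":")[1])
                cat = tgt.iloc[c][av]
                if cat_to_merge is None or cats.index(cat) < cats.index(cat_to_merge):
                    cat_to_merge = cat
        if cat_to_merge is None:
            cat_to_merge = cats[0]
        if not level.merge_age(cat_to_merge):
            break
        actions.append(f"level {level.level_id}: merged age category {cat_to_merge!r} "
                       f"with its neighbour (flags: {flagged})")
        cap_hit = False  # a cap-triggered merge is applied once per attempt
    return level, actions


def rake(records: pd.DataFrame, levels: list[AdjustmentLevel],
         config: RakingConfig | None = None,
         design_weight_col: str = "design_weight",
         period: str = "all") -> WeightedSample:
    """Rake one period's records to the adjustment-level targets.

    Runs IPF, applies the collapse workflow to any level violating the
    small-cell rules, and re-rakes until the rules clear (or no further
    collapse is possible).  Weights are normalized to mean one.
    """
    if config is None:
        config = RakingConfig()
    if records.empty:
        raise ValueError("cannot rake an empty record table")
    dw = records[design_weight_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(dw)) or (dw < 0).any() or dw.sum() <= 0:
        raise ValueError("design weights must be non-negative with positive sum")
    dw_norm = dw / dw.mean()

    levels = [AdjustmentLevel(lv.level_id, list(lv.variables), lv.target.copy(),
                              {k: dict(v) for k, v in lv.category_maps.items()})
              for lv in levels]
    all_actions: list[str] = []
    warnings: list[str] = []

    # pre-pass: merge away empty target cells so IPF has something to fit
    for lv in levels:
        lv2, acts = check_and_collapse(records, lv, dw_norm, config,
                                       design_weights=dw_norm, cap_hit=False)
        all_actions.extend(acts)

    for attempt in range(config.max_collapse_rounds + 1):
        w, converged, iters, maxdev = _ipf(records, dw_norm, levels, config)
        any_change = False
        for lv in levels:
            before = {k: dict(v) for k, v in lv.category_maps.items()}
            _, acts = check_and_collapse(records, lv, w, config,
                                         design_weights=dw_norm,
                                         cap_hit=not converged)
            all_actions.extend(acts)
            if lv.category_maps != before:
                any_change = True
        if not any_change:
            break
    else:
        warnings.append("collapse workflow did not stabilize")

    if not converged:
        warnings.append(f"raking stopped at the {config.max_iterations}-cycle cap "
                        f"(max margin deviation {maxdev:.2e})")
        logger.warning("period %s: %s", period, warnings[-1])

    w = w / w.mean()  # mean-one normalization per period
    out = records.copy()
    out["adjusted_weight"] = w
    return WeightedSample(records=out, period=period, converged=converged,
                          iterations=iters, max_margin_deviation=maxdev,
                          collapse_actions=all_actions, warnings=warnings)


def default_levels(targets: dict[int, pd.DataFrame]) -> list[AdjustmentLevel]:
    """The four standard adjustment levels from per-level target tables."""
    spec = {1: ["sex", "age7"], 2: ["age3a", "education"],
            3: ["nielsen_area", "municipality_size"], 4: ["state_group", "age3b"]}
    return [AdjustmentLevel(i, spec[i], targets[i]) for i in sorted(targets)]


def weight_all_periods(records: pd.DataFrame, levels: list[AdjustmentLevel],
                       config: RakingConfig | None = None,
                       period_col: str = "month_label") -> list[WeightedSample]:
    """Run raking independently per monthly period (or survey wave)."""
    if period_col not in records.columns:
        raise ValueError(f"records lack a {period_col!r} column")
    recs = derive_group_columns(records) if "age7" not in records.columns else records
    out = []
    for period, sub in recs.groupby(period_col, sort=True):
        elig = filter_eligible(sub)
        if elig.empty:
            logger.warning("period %s: no eligible records, skipped", period)
            continue
        out.append(rake(elig, levels, config, period=str(period)))
    return out
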