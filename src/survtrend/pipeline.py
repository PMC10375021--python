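"""Automated orchestration: registry scan, preparation, estimation, output.

The surveillance workflow is file-driven.  A source registry records every
survey data file with a content fingerprint; on each run the input folders
are scanned, new or changed files are flagged, and — only if something
changed — the full chain executes:

    scan -> prepare per source -> combine -> adjustment weighting per month
         -> moving-window estimates (every indicator x stratum,
            standardized and unstandardized) -> weekly GAM curve
         -> tidy delimited outputs + diagnostics

Unchanged inputs skip all computation; identical inputs and configuration
produce byte-identical outputs (all randomness flows from one root seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import synthetic, timegrid, weighting
from .groups import coarse_of_age7, derive_group_columns
from .smoothing import GamSpec, fit_gam, predict_weekly
from .standardization import StandardPopulation, load_standard_population
from .window_estimation import ModelSpec, estimate_series

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "scan_registry", "prepare_source", "combine_sources",
           "run_all", "PREPARERS"]

REGISTRY_COLUMNS = ["path", "source_id", "preparer", "fingerprint", "last_processed"]

STANDARD_COLUMNS = ["interview_date", "sex", "age", "education", "state_group",
                    "nielsen_area", "municipality_size", "design_weight"]


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

def _fingerprint(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def scan_registry(folders, registry: pd.DataFrame | None = None,
                  default_preparer: str = "standard") -> tuple[pd.DataFrame, list[str]]:
    """Scan folders for survey data files; return updated registry + changes.

    A file is flagged when it is new or its content fingerprint changed.
    Touching a file without changing content does not flag it.
    """
    if registry is None:
        registry = pd.DataFrame(columns=REGISTRY_COLUMNS)
    registry = registry.copy()
    changed: list[str] = []
    for folder in folders:
        folder = pathlib.Path(folder)
        if not folder.is_dir():
            raise FileNotFoundError(f"input folder not readable: {folder}")
        for f in sorted(folder.glob("*.csv")):
            fp = _fingerprint(f)
            key = str(f)
            match = registry["path"] == key
            if not match.any():
                registry.loc[len(registry)] = [key, f.stem, default_preparer, fp, ""]
                changed.append(key)
            elif registry.loc[match, "fingerprint"].iloc[0] != fp:
                registry.loc[match, "fingerprint"] = fp
                changed.append(key)
    return registry, changed


# --------------------------------------------------------------------------
# per-source preparation
# --------------------------------------------------------------------------

def _prepare_standard(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STANDARD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"source lacks required column(s): {missing}")
    out = df.copy()
    out["interview_date"] = pd.to_datetime(out["interview_date"]).dt.date.astype(str)
    return out


def _prepare_month_coded(df: pd.DataFrame) -> pd.DataFrame:
    """Sources coding the interview time as YYYYMM plus a day-of-month column."""
    need = ["interview_yyyymm", "interview_day"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"source lacks required column(s): {missing}")
    out = df.copy()
    ym = out.pop("interview_yyyymm").astype(int)
    day = out.pop("interview_day").astype(int)
    out["interview_date"] = [f"{v // 100:04d}-{v % 100:02d}-{d:02d}"
                             for v, d in zip(ym, day)]
    return _prepare_standard(out)


PREPARERS = {"standard": _prepare_standard, "month_coded": _prepare_month_coded}


def prepare_source(path, preparer: str = "standard") -> pd.DataFrame:
    """Read one source file and map it to the standard record schema."""
    if preparer not in PREPARERS:
        raise KeyError(f"unknown preparation function {preparer!r}; "
                       f"registered: {sorted(PREPARERS)}")
    df = pd.read_csv(path)
    out = PREPARERS[preparer](df)
    if "source_id" not in out.columns:
        out["source_id"] = pathlib.Path(path).stem
    return out


def combine_sources(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate prepared sources and add the gap-aware time variables."""
    if not tables:
        raise ValueError("no source tables to combine")
    cols = set(tables[0].columns)
    for t in tables[1:]:
        if set(t.columns) != cols:
            raise ValueError("source tables do not share the standard schema")
    combined = pd.concat(tables, ignore_index=True)
    combined, _axis = timegrid.annotate_time(combined)
    return combined


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    standard_population: str
    targets: dict[int, str]
    indicators: list[dict] = field(default_factory=lambda: [
        {"name": "score", "family": "gaussian"},
        {"name": "screen_positive", "family": "binomial"},
    ])
    strata: tuple[str, ...] = ("sex", "age_group", "education")
    seed: int = 0
    raking: dict = field(default_factory=dict)
    smoothing: dict = field(default_factory=lambda: {
        "enabled": True, "basis_dim": 10, "age_grouping": "age3a",
    })
    log_level: str = "INFO"

    def __post_init__(self):
        self.targets = {int(k): v for k, v in self.targets.items()}
        if sorted(self.targets) != [1, 2, 3, 4]:
            raise ValueError("targets must provide the four adjustment levels 1-4")
        for ind in self.indicators:
            if ind.get("family") not in ("gaussian", "binomial"):
                raise ValueError(f"indicator {ind} needs family gaussian|binomial")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        base = pathlib.Path(path).parent
        for key in ("input_dir", "output_dir", "standard_population"):
            if key in raw and not pathlib.Path(raw[key]).is_absolute():
                raw[key] = str(base / raw[key])
        if "targets" in raw:
            raw["targets"] = {int(k): (v if pathlib.Path(v).is_absolute() else str(base / v))
                              for k, v in raw["targets"].items()}
        if "strata" in raw:
            raw["strata"] = tuple(raw["strata"])
        return cls(**raw)


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

_CSV_KW = dict(index=False, float_format="%.10g")


def _load_targets(config: RunConfig) -> dict[int, pd.DataFrame]:
    return {lv: pd.read_csv(p) for lv, p in config.targets.items()}


def run_all(config: RunConfig, force: bool = False) -> dict:
    """Execute the full pipeline; skip cleanly when nothing changed.

    Returns a machine-readable run summary (also written to
    ``output_dir/run_summary.json``).
    """
    t0 = time.time()
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    reg_path = out / "registry.csv"
    registry = pd.read_csv(reg_path, dtype=str) if reg_path.exists() else None

    registry, changes = scan_registry([pathlib.Path(config.input_dir)], registry)
    monthly_path = out / "monthly.csv"
    if not changes and not force and monthly_path.exists():
        summary = {"status": "skipped", "reason": "no new or updated data",
                   "n_sources": int(len(registry))}
        logger.info("run_all: %s", summary["reason"])
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        return {**summary, "elapsed_s": round(time.time() - t0, 3)}
    if registry.empty:
        raise ValueError(f"no source files found under {config.input_dir}")

    logger.info("stage prepare: %d source file(s), %d new/changed",
                len(registry), len(changes))
    tables = [prepare_source(r.path, r.preparer) for r in registry.itertuples()]
    records = combine_sources(tables)

    logger.info("stage weighting: %d records", len(records))
    records = derive_group_columns(records)
    records = weighting.filter_eligible(records)
    records = weighting.impute_weighting_vars(
        records, synthetic.state_distribution(), synthetic.municipality_by_state(),
        seed=config.seed)
    levels = weighting.default_levels(_load_targets(config))
    rconfig = weighting.RakingConfig(**config.raking)
    samples = weighting.weight_all_periods(records, levels, rconfig)
    weighted = pd.concat([s.records for s in samples], ignore_index=True)
    weighted["age_group"] = weighted["age7"]

    diagnostics = pd.DataFrame([{
        "period": s.period, "n": len(s.records), "converged": s.converged,
        "iterations": s.iterations, "max_margin_deviation": s.max_margin_deviation,
        "collapse_actions": "; ".join(s.collapse_actions),
        "warnings": "; ".join(s.warnings),
    } for s in samples])
    diagnostics.to_csv(out / "weighting_diagnostics.csv", **_CSV_KW)

    standpop = load_standard_population(config.standard_population)

    logger.info("stage windows: %d indicator(s)", len(config.indicators))
    monthly_parts = []
    for ind in config.indicators:
        spec = ModelSpec(outcome=ind["name"], family=ind["family"],
                         interaction_order=ind.get("interaction_order"))
        monthly_parts.append(estimate_series(weighted, spec, standpop,
                                             strata=config.strata))
    monthly = (pd.concat(monthly_parts, ignore_index=True) if monthly_parts
               else pd.DataFrame(columns=["month_index", "month_label", "indicator",
                                          "stratum_var", "stratum_level", "standardized",
                                          "status", "estimate", "se", "ci_low",
                                          "ci_high", "n_obs", "months_used"]))
    monthly.to_csv(monthly_path, **_CSV_KW)

    weekly_rows = 0
    if config.smoothing.get("enabled", True):
        logger.info("stage smoothing")
        grouping = config.smoothing.get("age_grouping", "age3a")
        gam_records = weighted.copy()
        gam_standpop = standpop
        if grouping == "age3a":
            gam_records["age_group"] = gam_records["age7"].map(coarse_of_age7)
            gam_standpop = standpop.collapse_age(
                {a: coarse_of_age7(a) for a in standpop.levels("age_group")})
        gspec = GamSpec(basis_dim=int(config.smoothing.get("basis_dim", 10)))
        weekly_parts = []
        for ind in config.indicators:
            fam = ind["family"]
            spec = GamSpec(family=fam, basis_dim=gspec.basis_dim)
            try:
                gam = fit_gam(gam_records, spec, outcome=ind["name"])
            except (RuntimeError, ValueError) as exc:
                logger.warning("GAM for %s failed: %s", ind["name"], exc)
                continue
            weeks = sorted(gam_records["week_index"].dropna().unique())
            series = [predict_weekly(gam, gam_standpop, weeks).points]
            for var in config.strata:
                for levl in gam_standpop.levels(var):
                    for std in (True, False):
                        series.append(predict_weekly(gam, gam_standpop, weeks,
                                                     stratum=(var, levl),
                                                     standardized=std).points)
            part = pd.concat(series, ignore_index=True)
            part.insert(1, "indicator", ind["name"])
            weekly_parts.append(part)
        if weekly_parts:
            weekly = pd.concat(weekly_parts, ignore_index=True)
            weekly.to_csv(out / "weekly.csv", **_CSV_KW)
            weekly_rows = len(weekly)

    registry["last_processed"] = pd.Timestamp.now("UTC").strftime("%Y-%m-%dT%H:%M:%SZ")
    registry.to_csv(reg_path, index=False)
    summary = {
        "status": "ok",
        "n_sources": int(len(registry)),
        "n_records": int(len(records)),
        "n_periods": len(samples),
        "monthly_rows": int(len(monthly)),
        "weekly_rows": int(weekly_rows),
        "non_converged_periods": int((~diagnostics["converged"]).sum()),
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    logger.info("run_all finished in %.1fs: %s", time.time() - t0, summary)
    return {**summary, "elapsed_s": round(time.time() - t0, 3)}
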