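import numpy as np
import pandas as pd
import pytest

from survtrend import synthetic as syn
from survtrend import timegrid, weighting
from survtrend.standardization import StandardPopulation


@pytest.fixture(scope="session")
def sim_config():
    """Small scenario: five fully observed months at n=600/month."""
    return syn.SimulationConfig(months=5, n_per_month=600, gap_months=[], seed=11)


@pytest.fixture(scope="session")
def survey(sim_config):
    df = syn.generate_survey(sim_config)
    df, _ = timegrid.annotate_time(df)
    return df


@pytest.fixture(scope="session")
def weighted_records(sim_config, survey):
    recs = weighting.filter_eligible(survey)
    recs = weighting.impute_weighting_vars(
        recs, syn.state_distribution(), syn.municipality_by_state(), seed=5)
    levels = weighting.default_levels(syn.raking_targets(sim_config))
    samples = weighting.weight_all_periods(recs, levels)
    out = pd.concat([s.records for s in samples], ignore_index=True)
    out["age_group"] = out["age7"]
    return out


@pytest.fixture(scope="session")
def standpop(sim_config):
    return StandardPopulation(syn.standard_population(sim_config))


def make_cell_records(values_by_month, weights=None):
    """Records covering every standard-population cell with a shared score
    per month — handy for noise-free window-estimation identities."""
    rows = []
    cells = [(s, a, e)
             for s in ["female", "male"]
             for a in ["18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+"]
             for e in ["low", "medium", "high"]]
    for t, val in enumerate(values_by_month):
        for j, (s, a, e) in enumerate(cells):
            w = 1.0 if weights is None else weights[j % len(weights)]
            rows.append({"month_index": t, "month_label": f"2020-{t + 1:02d}",
                         "sex": s, "age_group": a, "education": e,
                         "score": float(val), "adjusted_weight": w})
    return pd.DataFrame(rows)
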