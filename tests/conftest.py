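import numpy as np
import pandas as pd
import pytest

import survcea as sc


@pytest.fixture(scope="session")
def const_hazard_trial():
    """Two-arm trial, constant reference hazard 0.1/month, true HR 0.6,
    no dropout, n = 5000/arm."""
    spec = sc.TrialSpec(
        "bigtrial",
        5000,
        ((0.0,), (0.1,)),
        contrast_truth=(np.log(0.6), 0.0, -2.0),
        accrual_months=6.0,
        cutoff_months=30.0,
        dropout_rate=0.0,
        seed=20240917,
    )
    return spec, sc.simulate_trial(spec)


@pytest.fixture(scope="session")
def dropout_trial():
    """n = 300 with exponential dropout (~20% of subjects censored by
    dropout over follow-up)."""
    spec = sc.TrialSpec(
        "droptrial",
        300,
        ((0.0,), (0.1,)),
        contrast_truth=(0.0, 0.0, -2.0),
        accrual_months=6.0,
        cutoff_months=30.0,
        dropout_rate=0.03,
        seed=55,
    )
    return spec, sc.simulate_trial(spec)


@pytest.fixture(scope="session")
def weibull_ipd():
    """n = 5000 uncensored draws from Weibull(shape 1.5, scale 10)."""
    rng = np.random.default_rng(1)
    t = 10.0 * rng.weibull(1.5, 5000)
    return pd.DataFrame({"time": t, "event": 1})


def click_per_step_artifacts(ipd, n_risk_rows=8, coarsen=True):
    """Digitization emulation: one curve point per KM step plus a sparse
    published-style numbers-at-risk table."""
    ev = np.sort(ipd.loc[ipd["event"] == 1, "time"].unique())
    grid = np.unique(np.concatenate([[0.0], ev]))
    risk_grid = np.linspace(0.0, float(ipd["time"].max()), n_risk_rows)
    return sc.make_km_artifacts(ipd, grid, coarsen=coarsen, risk_grid=risk_grid)
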