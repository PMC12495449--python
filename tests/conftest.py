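"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from nfdrift import (SimulationConfig, band_power_table, preprocess_trial,
                     simulate_cohort, zscore_powers)


@pytest.fixture(scope="session")
def small_cohort():
    """4-subject cohort at default (study) settings."""
    return simulate_cohort(SimulationConfig(n_subjects=4, seed=11))


@pytest.fixture(scope="session")
def small_band_table(small_cohort):
    recs = [preprocess_trial(r) for r in small_cohort]
    return zscore_powers(band_power_table(recs))


@pytest.fixture(scope="session")
def quiet_trial():
    """One effect-free trial (no dB machinery), for signal-level tests."""
    cfg = SimulationConfig(n_subjects=1, alpha_trend=0.0, theta_condition_effect=0.0,
                           subject_intercept_db_sd=0.0, trial_power_db_sd=0.0, seed=7)
    return simulate_cohort(cfg)[0]


def make_lmm_table(n_subjects=8, n_trials=32, slope=0.0, sigma=0.2,
                   slope_sd=0.0, intercept_sd=0.3, seed=0):
    """Band-power-table-shaped data drawn directly from the multilevel model
    (a cheap generative oracle for the fitting machinery)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        b0 = rng.normal(0, intercept_sd)
        b1 = slope + rng.normal(0, slope_sd)
        for t in range(1, n_trials + 1):
            cond = ["Control", "1Hz", "5Hz", "10Hz"][(t - 1) // (n_trials // 4)]
            rows.append({"subject": f"S{s:02d}", "condition": cond,
                         "trial_index": (t - 1) % (n_trials // 4) + 1,
                         "global_trial_index": t, "electrode": "Fz", "band": "alpha",
                         "power_db": 0.0,
                         "power_z": b0 + b1 * (t - 1) + rng.normal(0, sigma)})
    return pd.DataFrame(rows)
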