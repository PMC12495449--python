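"""Synthetic cohort generator: design structure, determinism, spectral content."""

import numpy as np
import pytest

from nfdrift.preprocess import preprocess_trial
from nfdrift.simulate import (ConfigurationError, SimulationConfig, assign_orders,
                              latin_square_orders, simulate_cohort)
from nfdrift.spectral import welch_psd


def test_latin_square_quadruplets_exact():
    assert latin_square_orders() == [(2, 1, 4, 3), (1, 4, 3, 2), (3, 2, 1, 4), (4, 3, 2, 1)]


def test_each_quadruplet_is_a_permutation():
    for q in latin_square_orders():
        assert sorted(q) == [1, 2, 3, 4]


def test_every_condition_in_every_position():
    cols = list(zip(*latin_square_orders()))
    for position in cols:
        assert sorted(position) == [1, 2, 3, 4]


def test_even_assignment_of_32_subjects():
    orders = assign_orders(32)
    for q in latin_square_orders():
        assert orders.count(q) == 8


def test_cohort_structure(small_cohort):
    assert len(small_cohort) == 4 * 32
    one = [r for r in small_cohort if r.subject_id == "S01"]
    assert [r.global_trial_index for r in one] == list(range(1, 33))
    # block order follows the subject's quadruplet; 8 trials per condition
    conds = [r.condition for r in one]
    assert conds[:8] == ["1Hz"] * 8            # order (2,1,4,3) starts with 1Hz
    for r in one:
        assert r.n_samples == 15000 and r.sampling_rate == 250.0


def test_same_seed_byte_identical():
    cfg = SimulationConfig(n_subjects=2, seed=21)
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    for x, y in zip(a, b):
        assert np.array_equal(x.samples, y.samples)


def test_different_seeds_differ():
    a = simulate_cohort(SimulationConfig(n_subjects=1, seed=1))[0]
    b = simulate_cohort(SimulationConfig(n_subjects=1, seed=2))[0]
    assert not np.array_equal(a.samples, b.samples)


def test_psd_maximum_in_alpha_band_every_channel(small_cohort):
    rec = preprocess_trial(small_cohort[0])
    for ch, psd in welch_psd(rec).items():
        m = psd.frequencies >= 1.0
        fmax = psd.frequencies[m][np.argmax(psd.power[m])]
        assert 8.0 <= fmax < 12.0, ch


def test_no_oscillation_limit_is_aperiodic_background():
    """With all band amplitudes at zero the PSD follows the smooth 1/f-like
    background: no alpha peak, and the mid-range log-log slope matches the
    configured exponent."""
    zero = tuple((b, 0.0) for b in ("theta", "alpha", "smr", "beta"))
    cfg = SimulationConfig(n_subjects=1, band_amplitudes=zero, ssvep_amplitude=0.0,
                           alpha_trend=0.0, theta_condition_effect=0.0,
                           subject_intercept_db_sd=0.0, trial_power_db_sd=0.0, seed=3)
    psd = welch_psd(preprocess_trial(simulate_cohort(cfg)[0]))["Cz"]
    m = (psd.frequencies >= 20) & (psd.frequencies <= 80)
    slope = np.polyfit(np.log10(psd.frequencies[m]), np.log10(psd.power[m]), 1)[0]
    assert -1.25 < slope < -0.75
    # no local alpha prominence: alpha mean density below theta-range density
    def mean_density(lo, hi):
        sel = (psd.frequencies >= lo) & (psd.frequencies < hi)
        return psd.power[sel].mean()
    assert mean_density(8, 12) < mean_density(4, 8)


def test_ssvep_peak_mirrors_stimulation_frequency():
    """The 5 and 10 Hz conditions show excess spectral density at their own
    stimulation frequency relative to Control; the 1 Hz condition does not."""
    cfg = SimulationConfig(n_subjects=1, ssvep_amplitude=2.0, seed=2,
                           alpha_trend=0.0, theta_condition_effect=0.0)
    recs = simulate_cohort(cfg)

    def mean_density(cond, f0):
        out = []
        for rec in (r for r in recs if r.condition == cond):
            for psd in welch_psd(preprocess_trial(rec)).values():
                i = int(np.argmin(np.abs(psd.frequencies - f0)))
                out.append(psd.power[i - 1:i + 2].max())
        return np.mean(out)

    assert mean_density("5Hz", 5.0) > 1.5 * mean_density("Control", 5.0)
    assert mean_density("10Hz", 10.0) > 1.4 * mean_density("Control", 10.0)
    assert mean_density("1Hz", 1.0) < 1.2 * mean_density("Control", 1.0)


def test_alpha_trend_raises_band_power_over_trials(small_band_table):
    """The injected drift is visible as a positive alpha power/trial
    correlation pooled across the cohort, and is absent for beta."""
    alpha = small_band_table[small_band_table.band == "alpha"]
    r_alpha = np.corrcoef(alpha["global_trial_index"], alpha["power_z"])[0, 1]
    beta = small_band_table[small_band_table.band == "beta"]
    r_beta = np.corrcoef(beta["global_trial_index"], beta["power_z"])[0, 1]
    assert r_alpha > 0.1
    assert abs(r_beta) < abs(r_alpha)


def test_theta_effect_localized_to_configured_channel(small_band_table):
    theta = small_band_table[small_band_table.band == "theta"]
    gaps = {}
    for ch in ("Fz", "Cz", "Pz"):
        cell = theta[theta.electrode == ch]
        exp = cell[cell.condition != "Control"]["power_z"].mean()
        ctl = cell[cell.condition == "Control"]["power_z"].mean()
        gaps[ch] = exp - ctl
    assert gaps["Pz"] > max(abs(gaps["Fz"]), abs(gaps["Cz"]))


@pytest.mark.parametrize("kwargs", [
    {"n_subjects": 0},
    {"n_conditions": 3},
    {"sampling_rate": 50.0},
    {"aperiodic_amplitude": -1.0},
    {"band_amplitudes": (("alpha", -2.0),)},
    {"trial_duration": 0.0},
])
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        SimulationConfig(**kwargs)
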