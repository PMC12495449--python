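"""Multilevel model fitting, Savage–Dickey Bayes factors, stability, sensitivity.

Most tests draw data directly from the model's own generative process (a
cheap, exact oracle) rather than from the EEG simulator, so the fitting
machinery is tested in isolation.
"""

import numpy as np
import pytest
from scipy import stats

from nfdrift.bayes import (BFError, ModelError, ModelSpec, bayes_factor,
                           classify_evidence, directional_bf, fit_multilevel,
                           sensitivity_sweep, stability_protocol)
from nfdrift.contrasts import encode_design

from conftest import make_lmm_table

FAST = ModelSpec(n_burn=250, n_steps=200, seed=0, on_nonconvergence="warn")


def closed_form_bf(ybar, n, sigma, prior_sd):
    """Conjugate normal–normal marginal-likelihood ratio for a point null."""
    se2 = sigma**2 / n
    return stats.norm.pdf(ybar, 0, np.sqrt(prior_sd**2 + se2)) / \
        stats.norm.pdf(ybar, 0, np.sqrt(se2))


class TestSavageDickey:
    def test_matches_conjugate_oracle(self):
        """KDE Savage–Dickey vs closed form on seeded conjugate posteriors."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, sigma, prior_sd = 40, 1.0, 1.0
            y = rng.normal(0.2, sigma, n)
            ybar = y.mean()
            v = 1.0 / (n / sigma**2 + 1 / prior_sd**2)
            m = v * n * ybar / sigma**2
            draws = rng.normal(m, np.sqrt(v), 200_000)
            bf = bayes_factor(draws, prior_sd)
            assert bf == pytest.approx(closed_form_bf(ybar, n, sigma, prior_sd),
                                       rel=0.05), f"seed {seed}"

    def test_posterior_equal_prior_gives_unit_bf(self):
        rng = np.random.default_rng(1)
        assert bayes_factor(rng.normal(0, 1, 40000), 1.0) == pytest.approx(1.0, rel=0.05)

    def test_too_few_draws_rejected(self):
        with pytest.raises(BFError):
            bayes_factor(np.zeros(50), 1.0)

    def test_directional_bf_half_prior_renormalization(self):
        rng = np.random.default_rng(2)
        sym = rng.normal(0, 0.5, 20000)
        assert directional_bf(sym, 1.0) == pytest.approx(bayes_factor(sym, 1.0), rel=0.1)
        positive = rng.normal(1.2, 0.2, 20000)  # entirely above 0
        assert directional_bf(positive, 1.0) == pytest.approx(
            2.0 * bayes_factor(positive, 1.0), rel=1e-6)


@pytest.mark.parametrize("bf,expected", [
    (7.642, "H1"), (0.065, "H0"), (2.219, "insensitive"),
    (3.0, "insensitive"), (1 / 3, "insensitive"), (np.inf, "H1"),
])
def test_evidence_classification(bf, expected):
    assert classify_evidence(bf) == expected


def test_classify_rejects_nonpositive():
    with pytest.raises(BFError):
        classify_evidence(0.0)


class TestFit:
    def test_recovers_known_slope_with_strong_evidence(self):
        tbl = make_lmm_table(n_subjects=10, slope=0.02, sigma=0.2,
                             slope_sd=0.005, seed=3)
        design = encode_design(tbl, trial_coding="whole_task")
        fit = fit_multilevel(design, FAST)
        s = fit.summaries["trial_c"]
        assert s.cri_lower < 0.02 < s.cri_upper
        assert bayes_factor(fit.draws("trial_c")) > 3

    def test_null_data_supports_null(self):
        tbl = make_lmm_table(n_subjects=10, slope=0.0, sigma=0.2, seed=4)
        design = encode_design(tbl, trial_coding="whole_task")
        fit = fit_multilevel(design, FAST)
        s = fit.summaries["trial_c"]
        assert s.cri_lower < 0.0 < s.cri_upper
        assert bayes_factor(fit.draws("trial_c")) < 1 / 3

    def test_deterministic_given_seed(self):
        tbl = make_lmm_table(n_subjects=6, slope=0.01, seed=5)
        design = encode_design(tbl, trial_coding="whole_task")
        a = fit_multilevel(design, FAST)
        b = fit_multilevel(design, FAST)
        assert np.array_equal(a.beta_draws.values, b.beta_draws.values)

    def test_requires_two_subjects(self):
        tbl = make_lmm_table(n_subjects=1, seed=6)
        with pytest.raises(ModelError):
            fit_multilevel(encode_design(tbl, trial_coding="whole_task"), FAST)

    def test_missing_response_column(self):
        tbl = make_lmm_table(n_subjects=3, seed=7).drop(columns=["power_z"])
        with pytest.raises(ModelError):
            fit_multilevel(encode_design(tbl, trial_coding="whole_task"), FAST)


class TestStability:
    def test_reporting_convention(self):
        tbl = make_lmm_table(n_subjects=8, slope=0.02, sigma=0.2, seed=8)
        design = encode_design(tbl, trial_coding="whole_task")
        res = stability_protocol(design, FAST, n_runs=3, parameters=("trial_c",))
        rep = res.reports["trial_c"]
        assert len(rep.bf10_runs) == 3
        assert rep.bf10_mean == pytest.approx(np.mean(rep.bf10_runs))
        # envelope contains every per-run interval
        for fit in res.fits:
            s = fit.summaries["trial_c"]
            assert rep.cri_lower <= s.cri_lower and rep.cri_upper >= s.cri_upper

    def test_runs_agree_closely(self):
        tbl = make_lmm_table(n_subjects=8, slope=0.02, sigma=0.2, seed=9)
        design = encode_design(tbl, trial_coding="whole_task")
        res = stability_protocol(design, FAST, n_runs=3, parameters=("trial_c",))
        ests = [f.summaries["trial_c"].estimate for f in res.fits]
        post_sd = np.std(res.fits[0].draws("trial_c"))
        assert np.ptp(ests) < 0.1 * post_sd


def test_sensitivity_sweep_grid_and_lindley_behavior():
    """On null data the BF10 should favor the null more strongly as the prior
    widens (Lindley/Bartlett behavior); failures stay isolated per cell."""
    tbl = make_lmm_table(n_subjects=8, slope=0.0, sigma=0.2, seed=10)
    design = encode_design(tbl, trial_coding="whole_task")
    out = sensitivity_sweep(design, FAST, prior_sds=(1.0, 0.2), n_runs=1,
                            parameters=("trial_c",))
    assert set(out["prior_sd"]) == {1.0, 0.2}
    wide = out[out.prior_sd == 1.0].bf10.iloc[0]
    narrow = out[out.prior_sd == 0.2].bf10.iloc[0]
    assert wide < narrow


def test_sweep_isolates_failing_cells():
    tbl = make_lmm_table(n_subjects=1, seed=11)   # too few subjects -> every cell fails
    design = encode_design(tbl, trial_coding="whole_task")
    out = sensitivity_sweep(design, FAST, prior_sds=(1.0, 0.5), n_runs=1)
    assert len(out) == 2 and (out["error"] != "").all()
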