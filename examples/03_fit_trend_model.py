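"""Fit the Bayesian multilevel trend model on one (electrode, band) response.

Simulates a cohort whose alpha log-power drifts up by 0.02 z per trial, fits
the whole-task trend model (power_z ~ 1 + trial + (1 + trial | subject),
N(0,1) priors) with the 3-repeat stability protocol, and prints the pooled
estimate, credible-interval envelope and Savage–Dickey Bayes factors.  A
BF10 above 3 is substantial evidence for a trend; the directional BF10+
quantifies the one-sided (positive drift) hypothesis.
"""

from nfdrift import (SimulationConfig, band_power_table, encode_design,
                     preprocess_trial, simulate_cohort, stability_protocol,
                     zscore_powers)
from nfdrift.bayes import ModelSpec

cfg = SimulationConfig(n_subjects=12, seed=7)
table = zscore_powers(band_power_table(
    [preprocess_trial(r) for r in simulate_cohort(cfg)]))

cell = table[(table.electrode == "Fz") & (table.band == "alpha")]
design = encode_design(cell, trial_coding="whole_task")

res = stability_protocol(design, ModelSpec(seed=0, on_nonconvergence="warn"),
                         n_runs=3, parameters=("trial_c",))
rep = res.reports["trial_c"]


def fmt(bf):
    # overwhelming evidence is conventionally printed "> 100": the
    # Savage-Dickey density at 0 underflows once the null is far in the tail
    return f"{bf:.2f}" if bf <= 100 else "> 100"


print("alpha @ Fz, whole-task trial slope (true value 0.02 z/trial):")
print(f"  estimate {rep.estimate:.4f} z/trial, "
      f"95% CrI envelope [{rep.cri_lower:.4f}, {rep.cri_upper:.4f}]")
print(f"  BF10 per run: {[fmt(b) for b in rep.bf10_runs]}")
print(f"  mean BF10 = {fmt(rep.bf10_mean)}, BF10+ = {fmt(rep.bf10_plus)} "
      f"-> evidence: {rep.evidence_class}")
print("\n(the credible interval should cover 0.02 and the BF10 exceed 3:")
print(" the model detects the spontaneous drift it was given)")
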