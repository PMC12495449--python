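"""Build the condition contrast matrix from the planned hypotheses.

Three hypotheses over the four conditions (Control and circle modification at
1/5/10 Hz): any-modification vs Control, 5 vs 1 Hz, 10 vs 5 Hz.  Because the
hypotheses are not orthogonal, the model's condition columns are the
generalized (Moore–Penrose) inverse of the hypothesis matrix — that way each
fitted coefficient estimates exactly its hypothesis quantity.
"""

import numpy as np

from nfdrift import build_hypothesis_matrix, contrast_from_hypotheses

h = build_hypothesis_matrix()
print("hypothesis matrix (hypotheses x conditions):")
print(h.to_frame().to_string(), "\n")

c = contrast_from_hypotheses(h)
print("contrast matrix = generalized inverse (conditions x contrasts):")
print(c.to_frame().to_string(), "\n")

# demonstration: regress arbitrary condition means on the contrast columns
rng = np.random.default_rng(0)
mu = rng.normal(size=4)  # Control, 1Hz, 5Hz, 10Hz means
beta = np.linalg.solve(c.as_float(), mu)
print("for condition means", np.round(mu, 3))
print("fitted coefficients:", np.round(beta, 3))
print("  ExpVsControl column recovers mean(exp) - control =",
      round(mu[1:].mean() - mu[0], 3))
print("  5v1 column recovers mu5 - mu1 =", round(mu[2] - mu[1], 3))
print("  10v5 column recovers mu10 - mu5 =", round(mu[3] - mu[2], 3))
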