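"""Simulate a DHS/MICS-style cluster-sampled ordinal survey.

Draws cluster locations uniformly over a 10°x10° domain, 25-30 households
per cluster, cluster-level covariates (two standardized continuous surfaces,
an urbanicity factor, and a log-time term), and a 4-category ordinal outcome
from the latent-variable model z = x'beta + u(s) + b_c with a Matern spatial
field u and iid cluster effects b.
"""

import numpy as np

import washord as w

config = w.SurveyConfig(n_clusters=150, K=4,
                        beta=np.array([0.8, -0.5, 0.6, 0.3]),
                        thresholds=np.array([-1.2, 0.0, 1.2]),
                        sigma_b=0.5, spatial_range=3.0, sigma_u=0.8,
                        seed=42)
data = w.simulate_survey(config)

counts = data.households.groupby("cluster_id").size()
freqs = np.bincount(data.households["y"], minlength=config.K)
print(f"households: {data.n_households}  clusters: {data.n_clusters}")
print(f"households per cluster: min {counts.min()}, max {counts.max()}")
print("category counts (0 = least improved service level):")
for k, c in enumerate(freqs):
    print(f"  y={k}: {c:5d}  ({c / data.n_households:.3f})")
print("design columns:", data.design_columns)
print("latent SD decomposition: spatial sigma_u =", config.sigma_u,
      " cluster sigma_b =", config.sigma_b)
# Frequencies are ordered-bin masses of the logistic latent variable; with
# positive beta on 'hdi' the upper categories concentrate where hdi is high.
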