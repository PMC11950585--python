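"""Fit an in-distribution reference profile and score test images against it.

The profile holds the mean feature vector, the covariance, and the mean/std
of the chosen OOD metric over the reference sample - the mu and sigma that
define the 3-sigma control limits.
"""

import numpy as np

from spcdrift import (
    ct_analogue_scenario,
    fit_reference,
    reference_embeddings,
    sample_cluster,
    score_matrix,
)
from spcdrift.presets import id_cluster, ood_cluster

scenario = ct_analogue_scenario(seed=2)
profile = fit_reference(reference_embeddings(scenario, n=1000), "cosine")
print(f"reference: n={profile.n_reference}, metric mu={profile.metric_mean:.4f}, "
      f"sigma={profile.metric_std:.5f}")
print(f"3-sigma band: [{profile.metric_mean - 3 * profile.metric_std:.4f}, "
      f"{profile.metric_mean + 3 * profile.metric_std:.4f}]")

id_scores = score_matrix(sample_cluster(id_cluster(), 500, 10), profile)
ood_scores = score_matrix(sample_cluster(ood_cluster(), 500, 11), profile)
print(f"ID test images:  cosine {id_scores.mean():.4f} +- {id_scores.std():.4f}")
print(f"OOD test images: cosine {ood_scores.mean():.4f} +- {ood_scores.std():.4f}")
lower = profile.metric_mean - 3 * profile.metric_std
print(f"fraction of OOD below the lower control limit: "
      f"{(ood_scores < lower).mean():.3f}")
# ID images score ~0.976 while OOD images score ~0, dozens of sigma below the
# lower limit - individual OOD images are flagged essentially every time.
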