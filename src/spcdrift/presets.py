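"""Ready-made study scenarios.

Two analogues of the monitoring studies the framework was designed around:

* the CT-stream analogue — a 60-day stream of 100 images/day; days 1–30 mix
  in 0–1% OOD images (the nominal trickle any production stream carries),
  days 31–60 jump to 3–5% (the induced drift);
* the CXR-stream analogue — identical except the drifted phase runs at 2–4%.

Feature clusters are synthetic stand-ins for encoder embeddings: 8-dim
diagonal Gaussians with the ID cluster at ``4.2·(1,…,1)`` and the OOD cluster
at the same radius in an orthogonal (alternating-sign) direction.  At unit
noise this puts the per-image cosine-similarity spread at ≈1.3% of the ID–OOD
similarity gap — strong separation, as a well-trained contrastive encoder
produces — so per-image 3σ detection is near-certain while the 0–1% nominal
contamination stays inside the CUSUM allowance.
"""

from __future__ import annotations

import numpy as np

from .features import EmbeddingMatrix
from .simulate import ClusterSpec, DriftScenario, Phase, sample_cluster

__all__ = [
    "FEATURE_DIM",
    "id_cluster",
    "ood_cluster",
    "drift_scenario",
    "ct_analogue_scenario",
    "cxr_analogue_scenario",
    "reference_embeddings",
    "SHIFT_DAY",
]

FEATURE_DIM = 8
_LEVEL = 4.2
SHIFT_DAY = 31  # first day of the drifted phase in the 60-day presets


def id_cluster(dim: int = FEATURE_DIM, level: float = _LEVEL) -> ClusterSpec:
    """In-distribution cluster: mean ``level·(1,…,1)``, unit scale."""
    return ClusterSpec(dim=dim, mean=np.full(dim, level), scale=1.0, label="ID")


def ood_cluster(dim: int = FEATURE_DIM, level: float = _LEVEL,
                subtype: str = "orthogonal") -> ClusterSpec:
    """OOD cluster at the same radius in an orthogonal direction."""
    signs = np.where(np.arange(dim) % 2 == 0, 1.0, -1.0)
    return ClusterSpec(dim=dim, mean=level * signs, scale=1.0, label="OOD",
                       subtype=subtype)


def drift_scenario(
    phase2_rates: tuple[float, float],
    n_days: int = 60,
    batch_size: int = 100,
    phase1_rates: tuple[float, float] = (0.0, 0.01),
    seed: int = 0,
    dim: int = FEATURE_DIM,
) -> DriftScenario:
    """Two-phase drift scenario with the shift midway (phase 2 from day N/2+1)."""
    half = n_days // 2
    return DriftScenario(
        n_days=n_days,
        batch_size=batch_size,
        phases=(
            Phase(1, half, *phase1_rates),
            Phase(half + 1, n_days, *phase2_rates),
        ),
        id_cluster=id_cluster(dim),
        ood_clusters=(ood_cluster(dim),),
        seed=seed,
    )


def ct_analogue_scenario(seed: int = 0, **kwargs) -> DriftScenario:
    """60 days × 100 images; OOD rate 0–1% then 3–5% from day 31."""
    return drift_scenario((0.03, 0.05), seed=seed, **kwargs)


def cxr_analogue_scenario(seed: int = 0, **kwargs) -> DriftScenario:
    """60 days × 100 images; OOD rate 0–1% then 2–4% from day 31."""
    return drift_scenario((0.02, 0.04), seed=seed, **kwargs)


def reference_embeddings(scenario: DriftScenario, n: int = 1000,
                         seed: int | None = None) -> EmbeddingMatrix:
    """Draw an in-distribution reference sample matching a scenario's ID cluster.

    Seeded independently of the stream (default: scenario seed + 1_000_003)
    so reference fitting and stream generation never share draws.
    """
    if seed is None:
        seed = scenario.seed + 1_000_003
    X = sample_cluster(scenario.id_cluster, n, seed)
    return EmbeddingMatrix(X, [f"ref{i:05d}" for i in range(n)])
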