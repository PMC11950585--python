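"""Post hoc OOD metrics over a learned feature space.

A :class:`ReferenceProfile` is fitted once on in-distribution embeddings: it
stores the mean feature vector (the reference point every test image is
compared against), the sample covariance (with a Cholesky factorization for
Mahalanobis solves), and the mean/std of the chosen metric over the reference
images themselves — the latter define the control limits used by the SPC
charts downstream.

Two metrics are supported:

* cosine similarity, ``a·b / (‖a‖‖b‖)`` — non-parametric, in [-1, 1]; for a
  drifting stream it moves *down*;
* Mahalanobis distance, ``sqrt((x−μ)ᵀ S⁻¹ (x−μ))`` — covariance-aware, it
  moves *up*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import (
    DegenerateProfileError,
    ParameterError,
    ShapeError,
    ZeroVectorError,
)
from .features import EmbeddingMatrix
from .simulate import StreamRecord

__all__ = [
    "ReferenceProfile",
    "fit_reference",
    "cosine_similarity",
    "mahalanobis",
    "score_matrix",
    "score_stream",
    "save_profile",
    "load_profile",
]

COSINE = "cosine"
MAHALANOBIS = "mahalanobis"


@dataclass
class ReferenceProfile:
    """In-distribution reference statistics fitted by :func:`fit_reference`.

    ``metric_mean`` / ``metric_std`` are the μ and σ of the chosen OOD metric
    over the reference images; they set the SPC control limits.  ``covariance``
    already includes the ridge ``regularization · I``.
    """

    mean_vector: np.ndarray
    covariance: np.ndarray
    metric_mean: float
    metric_std: float
    metric_name: str
    n_reference: int
    regularization: float
    _factor: tuple = field(default=None, repr=False, compare=False)

    @property
    def dim(self) -> int:
        return self.mean_vector.shape[0]

    @property
    def covariance_factor(self):
        """Cholesky factorization of the (regularized) covariance, cached."""
        if self._factor is None:
            self._factor = cho_factor(self.covariance, lower=True)
        return self._factor


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two vectors, in [-1, 1].

    Raises :class:`ZeroVectorError` if either vector has zero magnitude: a
    zero embedding signals an upstream extractor fault rather than "no
    similarity".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ZeroVectorError("cosine similarity undefined for zero-magnitude vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def mahalanobis(x, profile: ReferenceProfile) -> float:
    """Mahalanobis distance of ``x`` from the profile mean.

    Solved through the stored Cholesky factorization; no explicit matrix
    inverse is formed.  Zero iff ``x`` equals the mean vector (for a
    positive-definite covariance).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (profile.dim,):
        raise ShapeError(f"expected vector of dim {profile.dim}, got shape {x.shape}")
    d = x - profile.mean_vector
    q = float(d @ cho_solve(profile.covariance_factor, d))
    return float(np.sqrt(max(q, 0.0)))


def _cosine_many(X: np.ndarray, mean: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    nm = np.linalg.norm(mean)
    if nm == 0.0 or np.any(norms == 0.0):
        bad = "reference mean" if nm == 0.0 else f"row {int(np.flatnonzero(norms == 0.0)[0])}"
        raise ZeroVectorError(f"zero-magnitude vector in cosine scoring ({bad})")
    return np.clip(X @ mean / (norms * nm), -1.0, 1.0)


def _mahalanobis_many(X: np.ndarray, profile: ReferenceProfile) -> np.ndarray:
    D = X - profile.mean_vector
    solved = cho_solve(profile.covariance_factor, D.T)
    return np.sqrt(np.maximum(np.einsum("ij,ji->i", D, solved), 0.0))


def score_matrix(X: np.ndarray, profile: ReferenceProfile) -> np.ndarray:
    """Vectorized metric of each row of ``X`` against the profile."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != profile.dim:
        raise ShapeError(f"expected (n, {profile.dim}) matrix, got shape {X.shape}")
    if profile.metric_name == COSINE:
        return _cosine_many(X, profile.mean_vector)
    return _mahalanobis_many(X, profile)


def fit_reference(
    embeddings: EmbeddingMatrix | np.ndarray,
    metric_name: str = COSINE,
    regularization: float | None = None,
) -> ReferenceProfile:
    """Fit the in-distribution reference profile.

    ``mean_vector`` is the columnwise mean; ``covariance`` is the sample
    covariance plus ``regularization · I`` (default ridge
    ``1e-6 · trace(S)/p``, which guarantees a solvable system without
    materially shifting the large eigenvalues).  ``metric_mean``/``metric_std``
    are computed by scoring each reference image against the profile itself.

    Raises :class:`DegenerateProfileError` when all reference metrics are
    identical (``metric_std = 0``): control limits would be undefined.
    """
    X = embeddings.values if isinstance(embeddings, EmbeddingMatrix) else np.asarray(embeddings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ParameterError("fit_reference needs a 2-D matrix with at least 2 rows")
    if metric_name not in (COSINE, MAHALANOBIS):
        raise ParameterError(f"unknown metric {metric_name!r}")
    if regularization is not None and regularization < 0:
        raise ParameterError("regularization must be >= 0")

    n, p = X.shape
    mean_vector = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    if regularization is None:
        regularization = 1e-6 * float(np.trace(S)) / p
    S_reg = S + regularization * np.eye(p)

    profile = ReferenceProfile(
        mean_vector=mean_vector,
        covariance=S_reg,
        metric_mean=0.0,
        metric_std=0.0,
        metric_name=metric_name,
        n_reference=n,
        regularization=float(regularization),
    )
    try:
        scores = score_matrix(X, profile)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - singular with reg=0
        raise DegenerateProfileError(
            "covariance not positive definite; increase regularization"
        ) from exc
    profile.metric_mean = float(scores.mean())
    profile.metric_std = float(scores.std(ddof=1))
    if profile.metric_std == 0.0:
        raise DegenerateProfileError(
            "all reference metrics identical (metric_std = 0): control limits "
            "undefined; supply more varied reference data"
        )
    return profile


def score_stream(records: Sequence[StreamRecord], profile: ReferenceProfile) -> np.ndarray:
    """Per-image metric for a stream, order-preserving.

    Metric errors are re-raised with the offending ``image_id`` attached.
    """
    if len(records) == 0:
        return np.empty(0)
    X = np.vstack([r.features for r in records])
    try:
        return score_matrix(X, profile)
    except ZeroVectorError:
        # slow path only to identify the culprit
        norms = np.linalg.norm(X, axis=1)
        bad = records[int(np.flatnonzero(norms == 0.0)[0])]
        raise ZeroVectorError(
            f"zero-magnitude embedding for image {bad.image_id!r}"
        ) from None


# ---------------------------------------------------------------------------
# serialization — profiles travel as JSON so monitoring can run in a
# separate process from fitting


def save_profile(profile: ReferenceProfile, path) -> None:
    payload = {
        "mean_vector": profile.mean_vector.tolist(),
        "covariance": profile.covariance.tolist(),
        "metric_mean": profile.metric_mean,
        "metric_std": profile.metric_std,
        "metric_name": profile.metric_name,
        "n_reference": profile.n_reference,
        "regularization": profile.regularization,
    }
    Path(path).write_text(json.dumps(payload))


def load_profile(path) -> ReferenceProfile:
    d = json.loads(Path(path).read_text())
    return ReferenceProfile(
        mean_vector=np.asarray(d["mean_vector"], dtype=float),
        covariance=np.asarray(d["covariance"], dtype=float),
        metric_mean=float(d["metric_mean"]),
        metric_std=float(d["metric_std"]),
        metric_name=d["metric_name"],
        n_reference=int(d["n_reference"]),
        regularization=float(d["regularization"]),
    )
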