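"""Image feature extractors.

Four interchangeable extractors turn grayscale images into feature vectors:

* ``stats_baseline`` — first-order statistics (mean, std, skewness, kurtosis)
  plus eight gray-level co-occurrence texture summaries; no training.
* ``autoencoder`` — an unsupervised dense autoencoder; the bottleneck
  activations are the embedding.
* ``supervised_bce`` — a dense classifier trained with binary cross-entropy
  on ID/OOD (or proxy) labels; embedding from the penultimate layer or the
  logits, per configuration.
* ``contrastive`` — a dense encoder trained with a pairwise margin loss that
  pulls same-label embeddings together and pushes different-label embeddings
  apart.

The monitoring framework downstream is deliberately encoder-agnostic: all
extractors emit an :class:`EmbeddingMatrix` and the SPC machinery never looks
inside.  The networks here are small dense models sized for CPU use; swap in
any external embedding by writing its matrix to the stream CSV layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from skimage.feature import graycomatrix, graycoprops
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .errors import ConfigurationError, NotFittedError, ParameterError

__all__ = [
    "EmbeddingMatrix",
    "FeatureExtractor",
    "StatsBaselineExtractor",
    "AutoencoderExtractor",
    "BCEExtractor",
    "ContrastiveExtractor",
    "basic_image_stats",
    "make_extractor",
    "fit_extractor",
    "extract",
    "save_extractor",
    "load_extractor",
]

STATS_DIM = 12
_GLCM_PROPS = ("contrast", "homogeneity", "energy", "correlation")
_GLCM_ANGLES = (0.0, np.pi / 2)
_GLCM_LEVELS = 16


@dataclass
class EmbeddingMatrix:
    """Feature vectors (one row per image) with aligned identifiers."""

    values: np.ndarray
    image_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.image_ids), -1)
        if self.values.shape[0] != len(self.image_ids):
            raise ParameterError(
                f"{self.values.shape[0]} rows but {len(self.image_ids)} image ids"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ParameterError("embedding matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def basic_image_stats(image: np.ndarray) -> np.ndarray:
    """First-order + texture statistics of one grayscale image.

    Returns a 12-vector: mean, std, skewness, kurtosis (Fisher), then
    contrast/homogeneity/energy/correlation of the gray-level co-occurrence
    matrix at distance 1 for horizontal and vertical neighbor pairs.
    Skewness and kurtosis of a constant image are 0 by convention so that a
    blank frame cannot poison downstream control limits with NaN.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ParameterError("empty image")
    flat = image.ravel()
    mean = float(flat.mean())
    std = float(flat.std())
    if std == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(sps.skew(flat))
        kurt = float(sps.kurtosis(flat))

    # co-occurrence summaries on a 16-level quantization of [0, 1]
    q = np.clip(image, 0.0, 1.0)
    q = np.minimum((q * _GLCM_LEVELS).astype(np.uint8), _GLCM_LEVELS - 1)
    glcm = graycomatrix(
        q, distances=[1], angles=list(_GLCM_ANGLES), levels=_GLCM_LEVELS,
        symmetric=True, normed=True,
    )
    texture = [float(graycoprops(glcm, p)[0, a]) for p in _GLCM_PROPS for a in range(len(_GLCM_ANGLES))]
    return np.array([mean, std, skew, kurt, *texture])


def _as_matrix(images) -> np.ndarray:
    """Stack images into an (n, pixels) float matrix."""
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 2 and len(images) and np.asarray(images[0]).ndim == 2:
        arr = arr[np.newaxis]  # a single bare image
    return arr.reshape(arr.shape[0], -1) if arr.size else arr.reshape(0, 0)


def _forward(stack, X: np.ndarray) -> np.ndarray:
    """Apply a list of (W, b, activation) layers."""
    H = X
    for W, b, act in stack:
        H = H @ W + b
        if act == "relu":
            H = np.maximum(H, 0.0)
        elif act == "tanh":
            H = np.tanh(H)
        elif act != "identity":
            raise ConfigurationError(f"unknown activation {act!r}")
    return H


@dataclass
class FeatureExtractor:
    """Base extractor; subclasses fill ``_stack`` during :meth:`fit`.

    ``training_config`` records every knob that affects the fit so a run can
    be audited and reproduced.
    """

    name: str = "base"
    mode: str = "base"
    dim: int = 0
    fitted: bool = False
    training_config: dict = field(default_factory=dict)
    final_loss: float | None = None
    _stack: list = field(default_factory=list, repr=False)

    def fit(self, images, labels=None) -> "FeatureExtractor":
        raise NotImplementedError

    def transform(self, images, image_ids: Sequence[str] | None = None) -> EmbeddingMatrix:
        if not self.fitted:
            raise NotFittedError(f"extractor {self.name!r} is not fitted")
        X = _as_matrix(images)
        if image_ids is None:
            image_ids = [f"img{i:05d}" for i in range(X.shape[0])]
        if X.shape[0] == 0:
            return EmbeddingMatrix(np.empty((0, self.dim)), [])
        return EmbeddingMatrix(self._embed(X), list(image_ids))

    def _embed(self, X: np.ndarray) -> np.ndarray:
        return _forward(self._stack, X)


class StatsBaselineExtractor(FeatureExtractor):
    """Basic image statistics; always fitted, no parameters."""

    def __init__(self):
        super().__init__(name="stats_baseline", mode="stats_baseline",
                         dim=STATS_DIM, fitted=True)

    def fit(self, images, labels=None):
        return self

    def _embed(self, X: np.ndarray) -> np.ndarray:
        side = int(round(np.sqrt(X.shape[1])))
        return np.vstack([basic_image_stats(row.reshape(side, side)) for row in X])


class AutoencoderExtractor(FeatureExtractor):
    """Dense autoencoder; the bottleneck layer is the embedding.

    Trained to reconstruct its input, in-distribution images only — no labels
    are used.  Architecture hidden → bottleneck → hidden with ReLU units.
    """

    def __init__(self, embedding_dim: int = 32, hidden: int = 64,
                 epochs: int = 30, learning_rate: float = 1e-3, seed: int = 0):
        super().__init__(name="autoencoder", mode="autoencoder", dim=embedding_dim)
        self.training_config = {
            "embedding_dim": embedding_dim, "hidden": hidden, "epochs": epochs,
            "learning_rate": learning_rate, "seed": seed,
        }

    def fit(self, images, labels=None):
        cfg = self.training_config
        X = _as_matrix(images)
        model = MLPRegressor(
            hidden_layer_sizes=(cfg["hidden"], cfg["embedding_dim"], cfg["hidden"]),
            activation="relu", solver="adam",
            learning_rate_init=cfg["learning_rate"],
            max_iter=cfg["epochs"], random_state=cfg["seed"],
            tol=0.0, n_iter_no_change=cfg["epochs"] + 1,
        )
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warning at fixed epoch budget
            model.fit(X, X)
        self.loss_curve = list(model.loss_curve_)
        self.final_loss = float(model.loss_curve_[-1])
        # encoder = first two layers of the trained network
        self._stack = [
            (model.coefs_[0], model.intercepts_[0], "relu"),
            (model.coefs_[1], model.intercepts_[1], "relu"),
        ]
        self.fitted = True
        return self


class BCEExtractor(FeatureExtractor):
    """Dense classifier trained with binary cross-entropy on the labels.

    The embedding is read from the penultimate hidden layer by default, or
    from the logits when ``layer="logits"``.
    """

    def __init__(self, embedding_dim: int = 32, hidden: int = 64,
                 epochs: int = 30, learning_rate: float = 1e-3, seed: int = 0,
                 layer: str = "penultimate"):
        if layer not in ("penultimate", "logits"):
            raise ConfigurationError(f"layer must be 'penultimate' or 'logits', got {layer!r}")
        super().__init__(name="supervised_bce", mode="supervised_bce",
                         dim=embedding_dim if layer == "penultimate" else 1)
        self.training_config = {
            "embedding_dim": embedding_dim, "hidden": hidden, "epochs": epochs,
            "learning_rate": learning_rate, "seed": seed, "layer": layer,
        }

    def fit(self, images, labels=None):
        if labels is None:
            raise ConfigurationError("supervised_bce extractor requires labels")
        cfg = self.training_config
        X = _as_matrix(images)
        y = np.asarray(labels)
        model = MLPClassifier(
            hidden_layer_sizes=(cfg["hidden"], cfg["embedding_dim"]),
            activation="relu", solver="adam",
            learning_rate_init=cfg["learning_rate"],
            max_iter=cfg["epochs"], random_state=cfg["seed"],
            tol=0.0, n_iter_no_change=cfg["epochs"] + 1,
        )
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        self.final_loss = float(model.loss_)
        stack = [
            (model.coefs_[0], model.intercepts_[0], "relu"),
            (model.coefs_[1], model.intercepts_[1], "relu"),
        ]
        if cfg["layer"] == "logits":
            stack.append((model.coefs_[2], model.intercepts_[2], "identity"))
        self._stack = stack
        self.fitted = True
        return self


class ContrastiveExtractor(FeatureExtractor):
    """Dense encoder trained with a pairwise margin (contrastive) loss.

    For an embedding pair at Euclidean distance ``d``, same-label pairs
    contribute ``d**2`` and different-label pairs ``max(0, margin - d)**2``
    — embeddings of a class collapse together while classes are pushed at
    least ``margin`` apart.  Optimized with Adam on minibatches; fully
    deterministic given the seed.
    """

    def __init__(self, embedding_dim: int = 32, hidden: int = 64,
                 epochs: int = 30, learning_rate: float = 1e-2, seed: int = 0,
                 margin: float = 1.0, batch_size: int = 32):
        super().__init__(name="contrastive", mode="contrastive", dim=embedding_dim)
        self.training_config = {
            "embedding_dim": embedding_dim, "hidden": hidden, "epochs": epochs,
            "learning_rate": learning_rate, "seed": seed, "margin": margin,
            "batch_size": batch_size,
        }

    def fit(self, images, labels=None):
        if labels is None:
            raise ConfigurationError("contrastive extractor requires labels")
        cfg = self.training_config
        X = _as_matrix(images)
        y = np.asarray(labels)
        n, p = X.shape
        rng = np.random.default_rng(cfg["seed"])
        K, H = cfg["embedding_dim"], cfg["hidden"]
        W1 = rng.normal(0, np.sqrt(2.0 / p), (p, H))
        b1 = np.zeros(H)
        W2 = rng.normal(0, np.sqrt(2.0 / H), (H, K))
        b2 = np.zeros(K)
        params = [W1, b1, W2, b2]
        m_adam = [np.zeros_like(q) for q in params]
        v_adam = [np.zeros_like(q) for q in params]
        lr, beta1, beta2, eps = cfg["learning_rate"], 0.9, 0.999, 1e-8
        margin, bsz = cfg["margin"], min(cfg["batch_size"], n)
        steps_per_epoch = max(1, n // bsz)
        t = 0
        loss = np.nan
        for _epoch in range(cfg["epochs"]):
            order = rng.permutation(n)
            for s in range(steps_per_epoch):
                idx = order[s * bsz:(s + 1) * bsz]
                Xb, yb = X[idx], y[idx]
                Hh = np.tanh(Xb @ W1 + b1)
                E = Hh @ W2 + b2
                V = E[:, None, :] - E[None, :, :]          # (b, b, K)
                D = np.sqrt(np.maximum((V**2).sum(-1), 1e-12))
                same = (yb[:, None] == yb[None, :])
                iu = np.triu_indices(len(idx), k=1)
                pair_mask = np.zeros_like(same)
                pair_mask[iu] = True
                n_pairs = int(pair_mask.sum())
                if n_pairs == 0:
                    continue
                # scalar pair coefficients: grad wrt e_i is sum_j C[i,j] (e_i - e_j)
                C = np.zeros_like(D)
                sp = pair_mask & same
                dp = pair_mask & ~same
                C[sp] = 2.0
                active = dp & (D < margin)
                C[active] = -2.0 * (margin - D[active]) / D[active]
                loss = (
                    (D[sp] ** 2).sum()
                    + (np.maximum(0.0, margin - D[dp]) ** 2).sum()
                ) / n_pairs
                C = (C + C.T) / n_pairs
                G = C.sum(axis=1, keepdims=True) * E - C @ E
                # backprop
                gW2 = Hh.T @ G
                gb2 = G.sum(0)
                dH = (G @ W2.T) * (1.0 - Hh**2)
                gW1 = Xb.T @ dH
                gb1 = dH.sum(0)
                grads = [gW1, gb1, gW2, gb2]
                t += 1
                for q, g, mq, vq in zip(params, grads, m_adam, v_adam):
                    mq += (1 - beta1) * (g - mq)
                    vq += (1 - beta2) * (g**2 - vq)
                    q -= lr * (mq / (1 - beta1**t)) / (np.sqrt(vq / (1 - beta2**t)) + eps)
        self.final_loss = float(loss)
        self._stack = [(W1, b1, "tanh"), (W2, b2, "identity")]
        self.fitted = True
        return self


_MODES = {
    "stats_baseline": StatsBaselineExtractor,
    "autoencoder": AutoencoderExtractor,
    "supervised_bce": BCEExtractor,
    "contrastive": ContrastiveExtractor,
}


def make_extractor(mode: str, **config) -> FeatureExtractor:
    """Construct an extractor by mode name with keyword configuration."""
    if mode not in _MODES:
        raise ConfigurationError(f"unknown extractor mode {mode!r}; choose from {sorted(_MODES)}")
    return _MODES[mode]() if mode == "stats_baseline" else _MODES[mode](**config)


def fit_extractor(extractor: FeatureExtractor, images, labels=None) -> FeatureExtractor:
    """Fit an extractor in place and return it (deterministic given its seed)."""
    return extractor.fit(images, labels=labels)


def extract(extractor: FeatureExtractor, images,
            image_ids: Sequence[str] | None = None) -> EmbeddingMatrix:
    """Embed images with a fitted extractor; row order matches input order."""
    return extractor.transform(images, image_ids=image_ids)


def save_extractor(extractor: FeatureExtractor, path) -> None:
    """Serialize a fitted extractor (weights + config) to one .npz archive."""
    if not extractor.fitted:
        raise NotFittedError("cannot save an unfitted extractor")
    import json

    meta = {
        "mode": extractor.mode, "name": extractor.name, "dim": extractor.dim,
        "training_config": extractor.training_config,
        "final_loss": extractor.final_loss,
        "activations": [act for _, _, act in extractor._stack],
    }
    arrays = {}
    for i, (W, b, _) in enumerate(extractor._stack):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_extractor(path) -> FeatureExtractor:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        stack = [
            (data[f"W{i}"], data[f"b{i}"], act)
            for i, act in enumerate(meta["activations"])
        ]
    if meta["mode"] == "stats_baseline":
        return StatsBaselineExtractor()
    ext = make_extractor(meta["mode"], **meta["training_config"])
    ext._stack = stack
    ext.dim = meta["dim"]
    ext.final_loss = meta["final_loss"]
    ext.fitted = True
    return ext
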