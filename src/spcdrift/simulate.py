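"""Synthetic monitored streams with injected distribution drift.

The generator emulates the monitoring study design used throughout the
package: an in-distribution (ID) feature cluster, one or more shifted
out-of-distribution (OOD) clusters, and a day-indexed stream in which each
day is a batch of ``batch_size`` images whose OOD fraction is drawn from a
phase-specific uniform interval.  Drift is injected by switching to a phase
with a higher OOD rate partway through the horizon.

Feature vectors stand in for encoder embeddings: each cluster is a diagonal
multivariate Gaussian.  Toy grayscale images (centered discs vs. oriented
stripes) are provided so the feature-extraction pipeline can be exercised
end to end on raw pixels.

Randomness is hierarchical: the scenario seed spawns one child seed per day,
so day ``k``'s batch is invariant to every other day's parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError

__all__ = [
    "ClusterSpec",
    "Phase",
    "DriftScenario",
    "StreamRecord",
    "sample_cluster",
    "generate_stream",
    "generate_toy_images",
    "stream_to_frame",
    "frame_to_stream",
    "write_stream_csv",
    "read_stream_csv",
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario",
]

ID_LABEL = "ID"
OOD_LABEL = "OOD"


@dataclass(frozen=True)
class ClusterSpec:
    """A diagonal-Gaussian feature cluster.

    Parameters
    ----------
    dim : int
        Feature dimensionality, ``>= 1``.
    mean : sequence of float
        Cluster mean, length ``dim``.
    scale : float or sequence of float
        Per-dimension standard deviation, strictly positive.
    label : str
        ``"ID"`` or ``"OOD"``.
    subtype : str
        Free-text qualifier (e.g. ``"non-axial"``, ``"pediatric-like"``).
    """

    dim: int
    mean: tuple[float, ...]
    scale: tuple[float, ...]
    label: str = ID_LABEL
    subtype: str = ""

    def __init__(self, dim, mean, scale, label=ID_LABEL, subtype=""):
        dim = int(dim)
        if dim < 1:
            raise ParameterError(f"dim must be >= 1, got {dim}")
        mean = np.broadcast_to(np.asarray(mean, dtype=float), (dim,))
        scale = np.broadcast_to(np.asarray(scale, dtype=float), (dim,))
        if np.any(scale <= 0):
            raise ParameterError("scale must be strictly positive elementwise")
        if label not in (ID_LABEL, OOD_LABEL):
            raise ParameterError(f"label must be 'ID' or 'OOD', got {label!r}")
        object.__setattr__(self, "dim", dim)
        object.__setattr__(self, "mean", tuple(float(v) for v in mean))
        object.__setattr__(self, "scale", tuple(float(v) for v in scale))
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "subtype", subtype)

    @property
    def mean_array(self) -> np.ndarray:
        return np.asarray(self.mean)

    @property
    def scale_array(self) -> np.ndarray:
        return np.asarray(self.scale)


@dataclass(frozen=True)
class Phase:
    """A contiguous block of days sharing one OOD-rate interval.

    Rates are fractions in [0, 1]; each day in the phase draws its own rate
    uniformly from ``[rate_low, rate_high]``.
    """

    start_day: int
    end_day: int
    rate_low: float
    rate_high: float

    def __post_init__(self):
        if self.start_day < 1 or self.end_day < self.start_day:
            raise ParameterError(
                f"invalid phase day range [{self.start_day}, {self.end_day}]"
            )
        if not (0.0 <= self.rate_low <= self.rate_high <= 1.0):
            raise ParameterError(
                f"rates must satisfy 0 <= low <= high <= 1, got "
                f"[{self.rate_low}, {self.rate_high}]"
            )


@dataclass(frozen=True)
class DriftScenario:
    """Declarative description of a simulated monitored stream.

    ``phases`` must tile ``[1, n_days]`` without gaps or overlap.  When
    ``per_image_bernoulli`` is False (default) each day's OOD *count* is the
    drawn rate times ``batch_size``, rounded half-to-even; when True each
    image is independently OOD with the drawn rate.
    """

    n_days: int
    batch_size: int
    phases: tuple[Phase, ...]
    id_cluster: ClusterSpec
    ood_clusters: tuple[ClusterSpec, ...]
    seed: int = 0
    per_image_bernoulli: bool = False

    def __post_init__(self):
        if self.n_days < 1 or self.batch_size < 1:
            raise ParameterError("n_days and batch_size must be positive")
        object.__setattr__(self, "phases", tuple(self.phases))
        object.__setattr__(self, "ood_clusters", tuple(self.ood_clusters))
        if not self.ood_clusters:
            raise ParameterError("at least one OOD cluster is required")
        dims = {self.id_cluster.dim} | {c.dim for c in self.ood_clusters}
        if len(dims) != 1:
            raise ParameterError(f"cluster dims disagree: {sorted(dims)}")
        expected = 1
        for ph in self.phases:
            if ph.start_day != expected:
                raise ParameterError(
                    f"phases must tile [1, n_days]: expected start {expected}, "
                    f"got {ph.start_day}"
                )
            expected = ph.end_day + 1
        if expected != self.n_days + 1:
            raise ParameterError(
                f"phases end at day {expected - 1}, scenario has {self.n_days} days"
            )

    @property
    def dim(self) -> int:
        return self.id_cluster.dim

    def phase_for_day(self, day: int) -> Phase:
        for ph in self.phases:
            if ph.start_day <= day <= ph.end_day:
                return ph
        raise ParameterError(f"day {day} outside [1, {self.n_days}]")

    def with_seed(self, seed: int) -> "DriftScenario":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class StreamRecord:
    """One image in the monitored stream: its day, id, features and truth."""

    day: int
    image_id: str
    features: np.ndarray = field(repr=False)
    truth_label: str = ID_LABEL


def sample_cluster(spec: ClusterSpec, n: int, rng_seed) -> np.ndarray:
    """Draw ``n`` feature vectors from a cluster.

    ``rng_seed`` may be an int, a :class:`numpy.random.SeedSequence` or a
    :class:`numpy.random.Generator`.  Returns an ``(n, dim)`` array; identical
    seed gives identical output.
    """
    if n < 0:
        raise ParameterError(f"n must be >= 0, got {n}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    return rng.normal(spec.mean_array, spec.scale_array, size=(int(n), spec.dim))


def _day_records(scenario: DriftScenario, day: int, rng: np.random.Generator) -> list[StreamRecord]:
    phase = scenario.phase_for_day(day)
    rate = rng.uniform(phase.rate_low, phase.rate_high)
    b = scenario.batch_size
    if scenario.per_image_bernoulli:
        is_ood = rng.random(b) < rate
    else:
        # round-half-to-even keeps the expected count unbiased over uniform rates
        n_ood = int(np.round(rate * b))
        is_ood = np.zeros(b, dtype=bool)
        is_ood[:n_ood] = True
    n_ood = int(is_ood.sum())
    ood_choice = rng.integers(len(scenario.ood_clusters), size=n_ood)
    features = np.empty((b, scenario.dim))
    features[~is_ood] = sample_cluster(scenario.id_cluster, b - n_ood, rng)
    ood_rows = np.flatnonzero(is_ood)
    for j, row in enumerate(ood_rows):
        features[row] = sample_cluster(scenario.ood_clusters[ood_choice[j]], 1, rng)[0]
    order = rng.permutation(b)
    return [
        StreamRecord(
            day=day,
            image_id=f"d{day:03d}_i{i:03d}",
            features=features[order[i]],
            truth_label=OOD_LABEL if is_ood[order[i]] else ID_LABEL,
        )
        for i in range(b)
    ]


def generate_stream(scenario: DriftScenario) -> list[StreamRecord]:
    """Generate the full day-indexed stream for a scenario.

    Each day draws its OOD fraction from the active phase's interval, fills
    the batch with ID/OOD cluster draws and shuffles within the day.  Fully
    reproducible from ``scenario.seed``; day ``k`` depends only on the seed,
    ``k``, and that day's own parameters.
    """
    children = np.random.SeedSequence(scenario.seed).spawn(scenario.n_days)
    records: list[StreamRecord] = []
    for day in range(1, scenario.n_days + 1):
        records.extend(_day_records(scenario, day, np.random.default_rng(children[day - 1])))
    return records


# ---------------------------------------------------------------------------
# toy images


def generate_toy_images(kind: str, n: int, side: int, rng_seed) -> np.ndarray:
    """Toy grayscale images: noisy centered discs, ID vs. disc-plus-blob OOD.

    Both kinds share the same disc geometry (radius, jitter, noise); OOD
    images additionally carry one faint small Gaussian blob at a random
    angle on a background annulus outside the disc.  The blob is a
    low-variance cue: it
    barely moves global intensity or texture statistics (so simple image
    statistics separate the kinds above chance but imperfectly) and
    contributes little reconstruction variance (so an unsupervised
    autoencoder largely ignores it), while label-supervised encoders learn
    it and separate the kinds strongly.  Returns an ``(n, side, side)``
    float array in [0, 1], deterministic given the seed.
    """
    if side < 8:
        raise ParameterError(f"side must be >= 8, got {side}")
    if kind not in (ID_LABEL, OOD_LABEL):
        raise ParameterError(f"kind must be 'ID' or 'OOD', got {kind!r}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    yy, xx = np.mgrid[0:side, 0:side]
    images = np.empty((n, side, side))
    for i in range(n):
        radius = side * rng.uniform(0.22, 0.34)
        cy = side / 2 + rng.uniform(-1.5, 1.5)
        cx = side / 2 + rng.uniform(-1.5, 1.5)
        fg = ((yy - cy) ** 2 + (xx - cx) ** 2) <= radius**2
        img = np.where(fg, 0.8, 0.1)
        if kind == OOD_LABEL:
            # faint blob, radius ~2 px, random angle on a background annulus
            br = side * rng.uniform(0.36, 0.42)
            ba = rng.uniform(0, 2 * np.pi)
            by = side / 2 + br * np.sin(ba)
            bx = side / 2 + br * np.cos(ba)
            img = img + 0.35 * np.exp(-(((yy - by) ** 2 + (xx - bx) ** 2) / (2 * 1.8**2)))
        img = img + rng.normal(0.0, 0.08, size=(side, side))
        images[i] = np.clip(img, 0.0, 1.0)
    return images


# ---------------------------------------------------------------------------
# serialization


def stream_to_frame(records: Sequence[StreamRecord]) -> pd.DataFrame:
    """Tabulate a stream: columns day, image_id, truth_label, f0..f{dim-1}."""
    if not records:
        return pd.DataFrame(columns=["day", "image_id", "truth_label"])
    dim = len(records[0].features)
    data = {
        "day": [r.day for r in records],
        "image_id": [r.image_id for r in records],
        "truth_label": [r.truth_label for r in records],
    }
    features = np.vstack([r.features for r in records])
    for j in range(dim):
        data[f"f{j}"] = features[:, j]
    return pd.DataFrame(data)


def frame_to_stream(frame: pd.DataFrame) -> list[StreamRecord]:
    feat_cols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
    feat_cols.sort(key=lambda c: int(c[1:]))
    features = frame[feat_cols].to_numpy(dtype=float)
    return [
        StreamRecord(
            day=int(row.day),
            image_id=str(row.image_id),
            features=features[i],
            truth_label=str(row.truth_label),
        )
        for i, row in enumerate(frame.itertuples(index=False))
    ]


def write_stream_csv(records: Sequence[StreamRecord], path) -> None:
    stream_to_frame(records).to_csv(path, index=False)


def read_stream_csv(path) -> list[StreamRecord]:
    return frame_to_stream(pd.read_csv(path))


def _cluster_to_dict(c: ClusterSpec) -> dict:
    return {
        "dim": c.dim,
        "mean": list(c.mean),
        "scale": list(c.scale),
        "label": c.label,
        "subtype": c.subtype,
    }


def scenario_to_dict(s: DriftScenario) -> dict:
    return {
        "n_days": s.n_days,
        "batch_size": s.batch_size,
        "phases": [
            {
                "start_day": p.start_day,
                "end_day": p.end_day,
                "rate_low": p.rate_low,
                "rate_high": p.rate_high,
            }
            for p in s.phases
        ],
        "id_cluster": _cluster_to_dict(s.id_cluster),
        "ood_clusters": [_cluster_to_dict(c) for c in s.ood_clusters],
        "seed": s.seed,
        "per_image_bernoulli": s.per_image_bernoulli,
    }


def scenario_from_dict(d: dict) -> DriftScenario:
    return DriftScenario(
        n_days=d["n_days"],
        batch_size=d["batch_size"],
        phases=tuple(Phase(**p) for p in d["phases"]),
        id_cluster=ClusterSpec(**d["id_cluster"]),
        ood_clusters=tuple(ClusterSpec(**c) for c in d["ood_clusters"]),
        seed=d.get("seed", 0),
        per_image_bernoulli=d.get("per_image_bernoulli", False),
    )


def save_scenario(s: DriftScenario, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(s), sort_keys=False))


def load_scenario(path) -> DriftScenario:
    return scenario_from_dict(yaml.safe_load(Path(path).read_text()))
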