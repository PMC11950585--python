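"""Replication scaffold: CT-stream monitoring on a real organ-slice dataset.

This script is NOT part of the tested surface: it needs a locally supplied
export of an abdominal-CT slice dataset (e.g. the organ-slice subset of a
medical MNIST-style collection) as an .npz file with arrays:

    train_images  (n, 28, 28) float in [0, 1]   axial (ID) training slices
    train_labels  (n,) int, 0 = axial/ID, 1 = non-axial/OOD
    ref_images    (m, 28, 28)                    held-out ID slices
    stream_id     (p, 28, 28)                    ID pool for the stream
    stream_ood    (q, 28, 28)                    OOD pool (coronal/sagittal)

It trains the contrastive encoder, fits a cosine reference profile, builds a
60-day stream (100 images/day, OOD rate 0-1% then 3-5% from day 31) by
sampling the pools, and reports the CUSUM detection delay.

Usage: python examples/replicate_ct_monitoring.py data/organ_slices.npz
"""

import sys

import numpy as np

from spcdrift import (
    detection_delay,
    extract,
    fit_extractor,
    fit_reference,
    make_extractor,
    monitor,
)
from spcdrift.simulate import StreamRecord

SEED = 0
N_DAYS, BATCH, SHIFT_DAY = 60, 100, 31


def build_stream(emb_id, emb_ood, rng):
    records = []
    for day in range(1, N_DAYS + 1):
        lo, hi = ((0.0, 0.01) if day < SHIFT_DAY else (0.03, 0.05))
        n_ood = int(np.round(rng.uniform(lo, hi) * BATCH))
        rows = np.concatenate([
            emb_ood[rng.integers(len(emb_ood), size=n_ood)],
            emb_id[rng.integers(len(emb_id), size=BATCH - n_ood)],
        ])
        labels = ["OOD"] * n_ood + ["ID"] * (BATCH - n_ood)
        order = rng.permutation(BATCH)
        records += [StreamRecord(day, f"d{day:03d}_i{i:03d}", rows[j], labels[j])
                    for i, j in enumerate(order)]
    return records


def main(path):
    data = np.load(path)
    rng = np.random.default_rng(SEED)
    encoder = make_extractor("contrastive", epochs=20, seed=SEED)
    fit_extractor(encoder, data["train_images"], data["train_labels"])
    profile = fit_reference(extract(encoder, data["ref_images"]), "cosine")
    emb_id = extract(encoder, data["stream_id"]).values
    emb_ood = extract(encoder, data["stream_ood"]).values
    report = monitor(build_stream(emb_id, emb_ood, rng), profile)
    summary = detection_delay(report, SHIFT_DAY)
    print(f"first CUSUM alarm day: {report.first_alarm_day} "
          f"(shift day {SHIFT_DAY}, delay {summary.delay}, "
          f"false alarms {len(summary.false_alarm_days)})")


if __name__ == "__main__":
    main(sys.argv[1])
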