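"""Stream and toy-image generation: determinism, rate fidelity, day structure."""

import io

import numpy as np
import pytest

from spcdrift import (
    ClusterSpec,
    DriftScenario,
    ParameterError,
    Phase,
    generate_stream,
    generate_toy_images,
    sample_cluster,
)
from spcdrift.simulate import (
    frame_to_stream,
    load_scenario,
    save_scenario,
    stream_to_frame,
)


def _one_phase_scenario(rate, n_days=2, batch_size=5, seed=0):
    return DriftScenario(
        n_days=n_days, batch_size=batch_size,
        phases=(Phase(1, n_days, rate, rate),),
        id_cluster=ClusterSpec(2, (0.0, 0.0), 1.0, "ID"),
        ood_clusters=(ClusterSpec(2, (10.0, 10.0), 1.0, "OOD"),),
        seed=seed,
    )


class TestSampleCluster:
    def test_empty_draw(self):
        spec = ClusterSpec(2, (0, 0), 1.0)
        assert sample_cluster(spec, 0, 1).shape == (0, 2)

    def test_degenerate_scale_concentrates_on_mean(self):
        spec = ClusterSpec(3, (5, 5, 5), 1e-9)
        X = sample_cluster(spec, 4, 1)
        assert np.allclose(X, 5.0, atol=1e-6)

    def test_large_sample_moments(self):
        # law of large numbers: sample moments approach the spec's parameters
        spec = ClusterSpec(2, (0, 0), 1.0)
        X = sample_cluster(spec, 10_000, 3)
        assert np.all(np.abs(X.mean(axis=0)) < 0.05)
        assert np.all(np.abs(X.std(axis=0) - 1.0) < 0.05)

    def test_same_seed_same_output(self):
        spec = ClusterSpec(4, (1, 2, 3, 4), (0.5, 1, 2, 3))
        assert np.array_equal(sample_cluster(spec, 7, 9), sample_cluster(spec, 7, 9))

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ParameterError):
            ClusterSpec(2, (0, 0), 0.0)
        with pytest.raises(ParameterError):
            ClusterSpec(2, (0, 0), (1.0, -1.0))


class TestGenerateStream:
    @pytest.mark.parametrize("rate,label", [(0.0, "ID"), (1.0, "OOD")])
    def test_extreme_rates(self, rate, label):
        records = generate_stream(_one_phase_scenario(rate))
        assert len(records) == 10
        assert all(r.truth_label == label for r in records)

    def test_day_partition(self):
        scen = _one_phase_scenario(0.3, n_days=5, batch_size=17)
        frame = stream_to_frame(generate_stream(scen))
        assert frame.groupby("day").size().eq(17).all()
        assert frame["day"].is_monotonic_increasing

    def test_ct_scenario_daily_ood_counts(self):
        # 0-1% rate on 100 images/day gives counts {0,1}; 3-5% gives {3,4,5}
        from spcdrift import ct_analogue_scenario

        frame = stream_to_frame(generate_stream(ct_analogue_scenario(seed=5)))
        counts = frame[frame.truth_label == "OOD"].groupby("day").size()
        counts = counts.reindex(range(1, 61), fill_value=0)
        assert set(counts[counts.index <= 30]) <= {0, 1}
        assert set(counts[counts.index >= 31]) <= {3, 4, 5}

    def test_reproducible_serialization(self):
        scen = _one_phase_scenario(0.4, n_days=3, batch_size=8, seed=11)
        out1, out2 = io.StringIO(), io.StringIO()
        stream_to_frame(generate_stream(scen)).to_csv(out1, index=False)
        stream_to_frame(generate_stream(scen)).to_csv(out2, index=False)
        assert out1.getvalue() == out2.getvalue()

    def test_day_invariant_to_other_days(self):
        # hierarchical seeding: day 1 data identical whether the stream has 1 or 3 days
        scen1 = _one_phase_scenario(0.5, n_days=1, batch_size=6, seed=2)
        scen3 = _one_phase_scenario(0.5, n_days=3, batch_size=6, seed=2)
        day1_a = [r.features for r in generate_stream(scen1) if r.day == 1]
        day1_b = [r.features for r in generate_stream(scen3) if r.day == 1]
        assert np.array_equal(np.vstack(day1_a), np.vstack(day1_b))

    def test_rate_fidelity_over_replicates(self):
        # mean realized OOD fraction within 2 MC standard errors of phase midpoint
        n_rep, midpoint, batch = 200, 0.3, 50
        scen = DriftScenario(
            n_days=2, batch_size=batch,
            phases=(Phase(1, 2, 0.2, 0.4),),
            id_cluster=ClusterSpec(2, (0, 0), 1.0, "ID"),
            ood_clusters=(ClusterSpec(2, (8, 8), 1.0, "OOD"),),
        )
        fracs = []
        for i in range(n_rep):
            frame = stream_to_frame(generate_stream(scen.with_seed(i)))
            fracs.append((frame.truth_label == "OOD").mean())
        se = np.std(fracs, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(fracs) - midpoint) < 2 * se + 1e-12

    def test_per_image_bernoulli_option(self):
        from dataclasses import replace

        scen = replace(_one_phase_scenario(0.5, n_days=40, batch_size=10),
                       per_image_bernoulli=True)
        frame = stream_to_frame(generate_stream(scen))
        counts = frame[frame.truth_label == "OOD"].groupby("day").size()
        # binomial counts vary across days, unlike the deterministic rounding
        assert counts.nunique() > 1

    def test_phase_tiling_enforced(self):
        cluster = ClusterSpec(2, (0, 0), 1.0, "ID")
        ood = (ClusterSpec(2, (5, 5), 1.0, "OOD"),)
        with pytest.raises(ParameterError):
            DriftScenario(n_days=10, batch_size=5,
                          phases=(Phase(1, 4, 0, 0), Phase(6, 10, 0, 0)),
                          id_cluster=cluster, ood_clusters=ood)
        with pytest.raises(ParameterError):
            DriftScenario(n_days=10, batch_size=5,
                          phases=(Phase(1, 10, 0, 0), Phase(5, 10, 0, 0)),
                          id_cluster=cluster, ood_clusters=ood)


class TestToyImages:
    def test_deterministic(self):
        a = generate_toy_images("ID", 3, 28, 1)
        b = generate_toy_images("ID", 3, 28, 1)
        assert np.array_equal(a, b)

    def test_kinds_differ_in_intensity_histograms(self):
        ids = generate_toy_images("ID", 100, 28, 5)
        oods = generate_toy_images("OOD", 100, 28, 5)
        bins = np.linspace(0, 1, 17)
        h_id = np.mean([np.histogram(im, bins=bins, density=True)[0] for im in ids], axis=0)
        h_ood = np.mean([np.histogram(im, bins=bins, density=True)[0] for im in oods], axis=0)
        assert np.abs(h_id - h_ood).mean() > 0

    def test_range_and_shape(self):
        imgs = generate_toy_images("OOD", 4, 16, 0)
        assert imgs.shape == (4, 16, 16)
        assert imgs.min() >= 0.0 and imgs.max() <= 1.0

    def test_too_small_side_rejected(self):
        with pytest.raises(ParameterError):
            generate_toy_images("ID", 1, 7, 0)


class TestSerialization:
    def test_stream_csv_round_trip(self, tmp_path):
        scen = _one_phase_scenario(0.5, n_days=2, batch_size=4, seed=3)
        records = generate_stream(scen)
        path = tmp_path / "stream.csv"
        from spcdrift import read_stream_csv, write_stream_csv

        write_stream_csv(records, path)
        back = read_stream_csv(path)
        assert [r.image_id for r in back] == [r.image_id for r in records]
        assert np.allclose(np.vstack([r.features for r in back]),
                           np.vstack([r.features for r in records]))

    def test_scenario_yaml_round_trip(self, tmp_path):
        scen = _one_phase_scenario(0.25, seed=42)
        path = tmp_path / "scenario.yaml"
        save_scenario(scen, path)
        assert load_scenario(path) == scen

    def test_frame_round_trip(self):
        records = generate_stream(_one_phase_scenario(0.5, seed=8))
        assert frame_to_stream(stream_to_frame(records))[0].day == records[0].day
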