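"""Reference profile fitting and the two OOD metrics, with analytic oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from spcdrift import (
    ClusterSpec,
    DegenerateProfileError,
    ShapeError,
    ZeroVectorError,
    cosine_similarity,
    fit_reference,
    mahalanobis,
    sample_cluster,
    score_matrix,
    score_stream,
)
from spcdrift.ood_metrics import ReferenceProfile, load_profile, save_profile
from spcdrift.simulate import StreamRecord


def _profile(mean, cov, metric="mahalanobis"):
    return ReferenceProfile(
        mean_vector=np.asarray(mean, dtype=float),
        covariance=np.asarray(cov, dtype=float),
        metric_mean=0.0, metric_std=1.0, metric_name=metric,
        n_reference=2, regularization=0.0,
    )


class TestCosine:
    def test_identical_orientation(self):
        assert cosine_similarity((3, 4), (3, 4)) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity((1, 0), (0, 1)) == pytest.approx(0.0)

    def test_45_degrees(self):
        assert cosine_similarity((1, 1), (1, 0)) == pytest.approx(np.sqrt(0.5))

    def test_zero_vector_raises(self):
        with pytest.raises(ZeroVectorError):
            cosine_similarity((0, 0), (1, 1))

    @given(arrays(float, 4, elements=st.floats(-100, 100)))
    def test_self_similarity_is_one(self, a):
        if np.linalg.norm(a) > 1e-6:
            assert cosine_similarity(a, a) == pytest.approx(1.0, abs=1e-12)

    @given(arrays(float, 3, elements=st.floats(-50, 50)),
           arrays(float, 3, elements=st.floats(-50, 50)))
    def test_range_and_symmetry(self, a, b):
        if np.linalg.norm(a) > 1e-6 and np.linalg.norm(b) > 1e-6:
            c = cosine_similarity(a, b)
            assert -1.0 <= c <= 1.0
            assert c == pytest.approx(cosine_similarity(b, a))


class TestMahalanobis:
    def test_distance_to_own_mean_is_zero(self):
        p = _profile((1.0, 2.0), np.eye(2))
        assert mahalanobis((1.0, 2.0), p) == 0.0

    def test_diagonal_covariance_example(self):
        p = _profile((0.0, 0.0), np.diag([4.0, 1.0]))
        assert mahalanobis((2.0, 0.0), p) == pytest.approx(1.0)

    def test_identity_covariance_is_euclidean(self, rng):
        p = _profile(np.zeros(5), np.eye(5))
        for _ in range(100):
            x = rng.normal(size=5)
            assert mahalanobis(x, p) == pytest.approx(np.linalg.norm(x))

    def test_matches_direct_solve_oracle(self, rng):
        for dim in range(2, 11):
            A = rng.normal(size=(dim, dim))
            S = A @ A.T + dim * np.eye(dim)
            mu = rng.normal(size=dim)
            p = _profile(mu, S)
            x = rng.normal(size=dim)
            expected = np.sqrt((x - mu) @ np.linalg.solve(S, x - mu))
            assert mahalanobis(x, p) == pytest.approx(expected, abs=1e-8)

    def test_affine_invariance(self, rng):
        # distance unchanged when data and profile transform by the same
        # invertible linear map
        X = rng.normal(size=(200, 3)) @ np.diag([1.0, 2.0, 0.5]) + 1.0
        prof = fit_reference(X, "mahalanobis", regularization=0.0)
        for _ in range(5):
            A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            prof_t = fit_reference(X @ A.T, "mahalanobis", regularization=0.0)
            for _ in range(10):
                x = rng.normal(size=3)
                assert mahalanobis(A @ x, prof_t) == pytest.approx(
                    mahalanobis(x, prof), abs=1e-8)

    def test_dimension_mismatch(self):
        p = _profile((0.0, 0.0), np.eye(2))
        with pytest.raises(ShapeError):
            mahalanobis((1.0, 2.0, 3.0), p)


class TestFitReference:
    def test_mean_vector_is_columnwise_mean(self):
        prof = fit_reference(np.array([[0.5, 0.5], [1.5, 1.5]]), "cosine")
        assert np.allclose(prof.mean_vector, [1.0, 1.0])

    def test_parameter_recovery(self, rng):
        mu = np.array([2.0, -1.0, 0.5])
        X = rng.normal(mu, 1.0, size=(10_000, 3))
        prof = fit_reference(X, "mahalanobis")
        assert np.all(np.abs(prof.mean_vector - mu) < 0.05)
        assert np.all(np.abs(prof.covariance - np.eye(3)) < 0.1)

    def test_duplicated_rows_degenerate(self):
        X = np.tile([1.0, 2.0], (10, 1))
        with pytest.raises(DegenerateProfileError):
            fit_reference(X, "mahalanobis", regularization=0.0)

    def test_default_regularization_scales_with_trace(self, rng):
        X = rng.normal(0, 10.0, size=(100, 4))
        prof = fit_reference(X, "mahalanobis")
        assert prof.regularization > 0
        assert prof.regularization == pytest.approx(
            1e-6 * np.trace(prof.covariance - prof.regularization * np.eye(4)) / 4)

    def test_metric_stats_match_rescoring(self, rng):
        X = rng.normal([4, 4, 4, 4], 1.0, size=(400, 4))
        prof = fit_reference(X, "cosine")
        scores = score_matrix(X, prof)
        assert prof.metric_mean == pytest.approx(scores.mean())
        assert prof.metric_std == pytest.approx(scores.std(ddof=1))


class TestScoreStream:
    def test_empty_stream(self, small_profile):
        assert score_stream([], small_profile).size == 0

    def test_records_at_mean_score_perfectly(self, small_profile):
        rec = StreamRecord(1, "a", small_profile.mean_vector.copy(), "ID")
        assert score_stream([rec], small_profile)[0] == pytest.approx(1.0)

    def test_separated_clusters_rank_correctly(self, small_profile):
        id_spec = ClusterSpec(4, (3, 3, 3, 3), 0.5, "ID")
        ood_spec = ClusterSpec(4, (3, -3, 3, -3), 0.5, "OOD")
        id_scores = score_matrix(sample_cluster(id_spec, 200, 0), small_profile)
        ood_scores = score_matrix(sample_cluster(ood_spec, 200, 0), small_profile)
        assert ood_scores.mean() < id_scores.mean()

    def test_error_names_offending_image(self, small_profile):
        recs = [
            StreamRecord(1, "good", small_profile.mean_vector.copy(), "ID"),
            StreamRecord(1, "bad_zero", np.zeros(4), "ID"),
        ]
        with pytest.raises(ZeroVectorError, match="bad_zero"):
            score_stream(recs, small_profile)


def test_profile_json_round_trip(tmp_path, small_profile):
    path = tmp_path / "profile.json"
    save_profile(small_profile, path)
    back = load_profile(path)
    assert np.allclose(back.mean_vector, small_profile.mean_vector)
    assert np.allclose(back.covariance, small_profile.covariance)
    assert back.metric_mean == small_profile.metric_mean
    assert back.metric_std == small_profile.metric_std
    assert back.metric_name == small_profile.metric_name
    x = small_profile.mean_vector + 0.3
    assert score_matrix(x[None, :], back)[0] == pytest.approx(
        score_matrix(x[None, :], small_profile)[0])
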