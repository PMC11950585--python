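"""Feature extractors: statistics oracle, training behavior, determinism."""

import numpy as np
import pytest

from spcdrift import (
    ConfigurationError,
    NotFittedError,
    basic_image_stats,
    extract,
    fit_extractor,
    generate_toy_images,
    load_extractor,
    make_extractor,
    save_extractor,
)


class TestBasicImageStats:
    def test_constant_image_is_all_zero_moments(self):
        v = basic_image_stats(np.zeros((8, 8)))
        assert v.shape == (12,)
        assert np.allclose(v[:4], 0.0)

    def test_two_point_image(self):
        img = np.zeros((4, 4))
        img[:, 2:] = 1.0
        v = basic_image_stats(img)
        assert v[0] == pytest.approx(0.5)
        assert v[1] == pytest.approx(0.5)

    def test_moments_match_direct_formulas(self, rng):
        # independent recomputation of each moment from its definition
        img = rng.random((28, 28))
        x = img.ravel()
        m = x.mean()
        s = np.sqrt(((x - m) ** 2).mean())
        skew = ((x - m) ** 3).mean() / s**3
        kurt = ((x - m) ** 4).mean() / s**4 - 3.0
        v = basic_image_stats(img)
        assert v[0] == pytest.approx(m)
        assert v[1] == pytest.approx(s)
        assert v[2] == pytest.approx(skew)
        assert v[3] == pytest.approx(kurt)

    def test_texture_matches_hand_derived_cooccurrence(self):
        # 2x2 image, top row 0 bottom row 1 -> quantized levels 0 and 15.
        # Horizontal neighbor pairs are identical, vertical pairs maximally
        # different; the symmetric normalized co-occurrence matrices are
        # worked out by hand below.
        img = np.array([[0.0, 0.0], [1.0, 1.0]])
        v = basic_image_stats(img)
        contrast_h, contrast_v = v[4], v[5]
        homog_h, homog_v = v[6], v[7]
        energy_h, energy_v = v[8], v[9]
        corr_h, corr_v = v[10], v[11]
        assert contrast_h == pytest.approx(0.0)
        assert contrast_v == pytest.approx(15.0**2)
        assert homog_h == pytest.approx(1.0)
        assert homog_v == pytest.approx(2 * 0.5 / (1 + 15**2))
        assert energy_h == pytest.approx(np.sqrt(0.5))
        assert energy_v == pytest.approx(np.sqrt(0.5))
        assert corr_h == pytest.approx(1.0)
        assert corr_v == pytest.approx(-1.0)

    def test_deterministic(self, rng):
        img = rng.random((16, 16))
        assert np.array_equal(basic_image_stats(img), basic_image_stats(img))


@pytest.fixture(scope="module")
def toy_data():
    ids = generate_toy_images("ID", 120, 16, 10)
    oods = generate_toy_images("OOD", 120, 16, 11)
    images = np.concatenate([ids, oods])
    labels = np.array([0] * 120 + [1] * 120)
    return images, labels


class TestExtractors:
    def test_stats_baseline_always_fitted(self):
        ext = make_extractor("stats_baseline")
        assert ext.fitted
        fit_extractor(ext, [])  # no-op

    def test_unfitted_extractor_raises(self):
        ext = make_extractor("autoencoder", epochs=1)
        with pytest.raises(NotFittedError):
            ext.transform(np.zeros((1, 16, 16)))

    @pytest.mark.parametrize("mode", ["supervised_bce", "contrastive"])
    def test_supervised_modes_require_labels(self, mode, toy_data):
        images, _ = toy_data
        with pytest.raises(ConfigurationError):
            fit_extractor(make_extractor(mode, epochs=1), images)

    def test_autoencoder_loss_decreases(self, toy_data):
        images, _ = toy_data
        ext = fit_extractor(make_extractor("autoencoder", epochs=5, seed=0), images)
        assert ext.loss_curve[-1] < ext.loss_curve[0]

    def test_contrastive_within_class_similarity_exceeds_between(self, toy_data):
        images, labels = toy_data
        ext = fit_extractor(make_extractor("contrastive", epochs=10, seed=0),
                            images, labels)
        E = extract(ext, images).values
        E = E / np.linalg.norm(E, axis=1, keepdims=True)
        sim = E @ E.T
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(len(labels), k=1)
        within = sim[iu][same[iu]].mean()
        between = sim[iu][~same[iu]].mean()
        assert within > between

    def test_extraction_is_pure_and_order_preserving(self, toy_data):
        images, labels = toy_data
        ext = fit_extractor(make_extractor("supervised_bce", epochs=3, seed=1),
                            images, labels)
        one = images[0]
        out = extract(ext, np.stack([one, one]))
        assert np.array_equal(out.values[0], out.values[1])
        again = extract(ext, np.stack([one, one]))
        assert np.array_equal(out.values, again.values)

    def test_empty_image_list_gives_empty_matrix(self):
        ext = make_extractor("stats_baseline")
        out = extract(ext, np.zeros((0, 16, 16)))
        assert out.n == 0

    def test_logits_layer_option(self, toy_data):
        images, labels = toy_data
        ext = fit_extractor(
            make_extractor("supervised_bce", epochs=3, seed=1, layer="logits"),
            images, labels)
        assert extract(ext, images[:5]).dim == 1

    def test_fit_deterministic_given_seed(self, toy_data):
        images, labels = toy_data
        a = fit_extractor(make_extractor("contrastive", epochs=3, seed=5), images, labels)
        b = fit_extractor(make_extractor("contrastive", epochs=3, seed=5), images, labels)
        assert np.array_equal(extract(a, images[:10]).values,
                              extract(b, images[:10]).values)

    @pytest.mark.parametrize("mode", ["stats_baseline", "autoencoder", "contrastive"])
    def test_save_load_round_trip(self, mode, toy_data, tmp_path):
        images, labels = toy_data
        if mode == "stats_baseline":
            ext = make_extractor(mode)
        elif mode == "autoencoder":
            ext = fit_extractor(make_extractor(mode, epochs=2, seed=0), images)
        else:
            ext = fit_extractor(make_extractor(mode, epochs=2, seed=0), images, labels)
        path = tmp_path / "ext.npz"
        save_extractor(ext, path)
        back = load_extractor(path)
        assert np.allclose(extract(ext, images[:8]).values,
                           extract(back, images[:8]).values)
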