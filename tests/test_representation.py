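"""Five-channel representation: position bins, PCA projection, normalization."""

import numpy as np
import pytest

from ubisent.corpus import E3Mention, Sentence
from ubisent.encoders import HashingTextEncoder
from ubisent.representation import (
    CHANNELS,
    PCAProjector,
    RepresentationBuilder,
    RepresentationConfig,
    build_representation,
    encode_e3,
    encode_semantic,
    expand_instances,
    fit_projectors,
    l2_normalize,
    position_feature,
    string_pattern_feature,
    syntactic_feature,
)


def _mention(text, surface):
    from ubisent.corpus import tokenize

    pos = text.find(surface)
    rank = next(
        i + 1 for i, t in enumerate(tokenize(text)) if surface.split()[0] in t
    )
    return E3Mention(
        surface=surface, canonical_id="X", char_start=pos,
        char_end=pos + len(surface), token_rank=rank,
    )


class TestPositionFeature:
    def test_third_word_of_ten_lands_in_bin_30(self):
        text = "w1 w2 Mdm2 w4 w5 w6 w7 w8 w9 w10"
        vec = position_feature(Sentence(text=text), _mention(text, "Mdm2"))
        assert vec[30 - 1] == 1.0 and vec.sum() == 1.0

    def test_last_word_lands_in_bin_100(self):
        text = "w1 w2 w3 Mdm2"
        vec = position_feature(Sentence(text=text), _mention(text, "Mdm2"))
        assert vec[100 - 1] == 1.0

    def test_single_word_sentence_is_bin_100(self):
        vec = position_feature(Sentence(text="Mdm2"), _mention("Mdm2", "Mdm2"))
        assert vec[100 - 1] == 1.0

    def test_exactly_one_nonzero_equal_to_one(self, small_corpus):
        for item in small_corpus[:40]:
            vec = position_feature(item.sentence, item.e3_mentions[0])
            assert np.count_nonzero(vec) == 1
            assert vec.max() == 1.0

    def test_rank_out_of_range_raises(self):
        bad = E3Mention(
            surface="Mdm2", canonical_id="X", char_start=0, char_end=4, token_rank=9,
        )
        with pytest.raises(ValueError):
            position_feature(Sentence(text="Mdm2 only"), bad)


class TestL2Normalize:
    def test_three_four_becomes_point_six_point_eight(self):
        np.testing.assert_allclose(l2_normalize(np.array([3.0, 4.0])), [0.6, 0.8])

    def test_zero_vector_is_preserved(self):
        np.testing.assert_array_equal(l2_normalize(np.zeros(5)), np.zeros(5))

    def test_unit_vector_is_fixed_point(self):
        v = np.array([1.0, 0.0, 0.0])
        np.testing.assert_allclose(l2_normalize(l2_normalize(v)), v)


class TestChannels:
    encoder = HashingTextEncoder(dim=64)

    def test_semantic_is_full_sentence_embedding(self):
        sent = Sentence(text="Mdm2 ubiquitylates p53")
        np.testing.assert_array_equal(
            encode_semantic(sent, self.encoder), self.encoder.encode(sent.text)
        )

    def test_e3_channel_embeds_bare_surface(self):
        m = _mention("Mdm2 ubiquitylates p53", "Mdm2")
        np.testing.assert_array_equal(
            encode_e3(m, self.encoder), self.encoder.encode("Mdm2")
        )

    def test_synonyms_of_same_e3_may_differ(self):
        a = encode_e3(_mention("Mdm2 acts", "Mdm2"), self.encoder)
        b = encode_e3(_mention("Hdm2 acts", "Hdm2"), self.encoder)
        assert not np.array_equal(a, b)

    def test_syntactic_match_is_nonzero_and_encodes_triple(self):
        text = "Cbl-b also targets active Src for degradation in cells."
        vec = syntactic_feature(Sentence(text=text), _mention(text, "Cbl-b"), self.encoder)
        np.testing.assert_array_equal(vec, self.encoder.encode("nsubj targets Cbl-b"))
        assert vec.any()

    def test_syntactic_no_match_is_zero(self):
        text = "Overexpression of Mdm2 enhanced the signal."
        vec = syntactic_feature(Sentence(text=text), _mention(text, "Mdm2"), self.encoder)
        assert not vec.any()

    def test_string_patterns_ubiquit_and_target(self):
        patterns = ("ubiquit", "target")
        v1 = string_pattern_feature(
            Sentence(text="Mdm2 ubiquitylates p53"), patterns, self.encoder
        )
        np.testing.assert_array_equal(v1, self.encoder.encode("ubiquit"))
        v2 = string_pattern_feature(
            Sentence(text="Cbl-b also targets active Src"), patterns, self.encoder
        )
        np.testing.assert_array_equal(v2, self.encoder.encode("target"))

    def test_no_pattern_gives_zero_vector(self):
        vec = string_pattern_feature(
            Sentence(text="Plain sentence"), ("ubiquit",), self.encoder
        )
        assert not vec.any()


class TestPCAProjector:
    def test_components_orthonormal_and_variance_ordered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 40)) * np.linspace(5, 0.1, 40)
        proj = PCAProjector(channel="semantic", n_components=10).fit(X)
        gram = proj.components_ @ proj.components_.T
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-6)
        scores = proj.project(X)
        variances = scores.var(axis=0)
        assert np.all(np.diff(variances) <= 1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 12))
        proj = PCAProjector(channel="e3", n_components=5).fit(X)
        C = np.cov(X, rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(C))[::-1][:5]
        np.testing.assert_allclose(proj.project(X).var(axis=0, ddof=1), eigvals, rtol=1e-8)

    def test_rank_deficient_input_zero_padded(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 30))  # rank <= 4 after centering
        proj = PCAProjector(channel="strings", n_components=10).fit(X)
        out = proj.project(X)
        assert out.shape == (5, 10)
        assert np.allclose(out[:, 4:], 0.0)

    def test_unfitted_projection_raises(self):
        with pytest.raises(RuntimeError):
            PCAProjector(channel="position", n_components=3).project(np.ones((2, 4)))

    def test_too_few_instances_raise(self):
        with pytest.raises(ValueError):
            PCAProjector(channel="semantic", n_components=2).fit(np.ones((1, 4)))


class TestBuildRepresentation:
    def test_default_width_is_500(self, small_corpus):
        instances, _ = expand_instances(small_corpus)
        config = RepresentationConfig(encoder=HashingTextEncoder(dim=64))
        projectors = fit_projectors(instances[:50], config)
        sent, mention = instances[0]
        vec = build_representation(sent, mention, projectors, config)
        assert vec.shape == (500,)
        assert abs(np.linalg.norm(vec) - 1.0) < 1e-9

    def test_channel_dim_20_gives_100(self, small_corpus):
        instances, _ = expand_instances(small_corpus)
        config = RepresentationConfig(encoder=HashingTextEncoder(dim=64), channel_dim=20)
        projectors = fit_projectors(instances[:50], config)
        vec = build_representation(*instances[0], projectors, config)
        assert vec.shape == (100,)

    def test_builder_matrix_shape_and_norms(self, small_corpus, small_features):
        X, y = small_features
        assert X.shape == (len(small_corpus), 5 * 8)
        np.testing.assert_allclose(np.linalg.norm(X, axis=1), 1.0, atol=1e-9)

    def test_row_order_follows_input_order(self, small_corpus):
        instances, _ = expand_instances(small_corpus)
        builder = RepresentationBuilder(channel_dim=6, encoder=HashingTextEncoder(dim=32))
        builder.fit(instances[:60])
        X = builder.transform(instances[:20])
        X_perm = builder.transform(instances[:20][::-1])
        np.testing.assert_allclose(X, X_perm[::-1])

    def test_bit_reproducible_across_builders(self, small_corpus):
        instances, _ = expand_instances(small_corpus)
        mats = []
        for _ in range(2):
            b = RepresentationBuilder(channel_dim=6, encoder=HashingTextEncoder(dim=32))
            mats.append(b.fit(instances).transform(instances))
        np.testing.assert_array_equal(mats[0], mats[1])

    def test_unfitted_builder_raises(self, small_corpus):
        with pytest.raises(RuntimeError):
            RepresentationBuilder().transform(small_corpus)

    def test_channel_order_is_documented_tuple(self):
        assert CHANNELS == ("semantic", "e3", "position", "syntactic", "strings")

    def test_per_mention_policy_expands_rows(self, small_corpus):
        instances_first, _ = expand_instances(small_corpus, "first_mention")
        instances_all, _ = expand_instances(small_corpus, "per_mention")
        assert len(instances_first) == len(small_corpus)
        assert len(instances_all) >= len(instances_first)
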