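"""Singleton feature templates: surface extractors, dictionaries, embedding
clusters, and the 5-token window expansion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugner.corpus import sentence_from_text
from drugner.features import (
    BOS,
    EOS,
    Dictionary,
    RuleBasedTagger,
    SentenceFeatureExtractor,
    default_template_registry,
    extract_affixes,
    extract_dictionary,
    extract_embedding_cluster,
    extract_orthographic,
    extract_word,
    fit_embedding_clusters,
    read_embeddings,
    word_shape,
)

tokens = st.text(
    alphabet=st.characters(codec="ascii", exclude_characters=" \t\n"),
    min_size=1,
    max_size=12,
)


class TestRegistry:
    def test_sixteen_default_templates(self):
        reg = default_template_registry()
        assert len(reg) == 16
        assert [t.id for t in reg] == [f"f{i}" for i in range(1, 17)]
        assert len({t.id for t in reg}) == 16


class TestWordFeature:
    @pytest.mark.parametrize("w", ["apigenin", "Aspirin1+", "β-blocker"])
    def test_value_is_the_surface_form(self, w):
        fs = extract_word(w)
        assert fs.value == w and str(fs) == f"f1[0]={w}"

    def test_empty_token_rejected(self):
        with pytest.raises(ValueError):
            extract_word("")


class TestOrthographic:
    @pytest.mark.parametrize(
        "w,cls,hyphen",
        [
            ("ABC", "All-capitalized", "N"),
            ("Bextra", "Is-capitalized", "N"),
            ("1234", "All-digits", "N"),
            ("interleukin-2", "Alphanumeric", "Y"),
            ("valdecoxib", "Other", "N"),
            ("beta-blockers", "Other", "Y"),
            ("Aspirin1+", "Is-capitalized", "N"),
        ],
    )
    def test_class_precedence_and_hyphen_flag(self, w, cls, hyphen):
        feats = extract_orthographic(w)
        assert feats[0].value == cls
        assert feats[1].value == f"hyphen:{hyphen}"


class TestAffixes:
    def test_interleukin2_affixes(self):
        vals = {(f.template[0], f.value) for f in extract_affixes("interleukin-2")}
        assert vals == {
            ("f9", "int"), ("f10", "inte"), ("f11", "inter"),
            ("f12", "n-2"), ("f13", "in-2"), ("f14", "kin-2"),
        }

    def test_aspirin_affixes(self):
        vals = {(f.template[0], f.value) for f in extract_affixes("aspirin")}
        assert vals == {
            ("f9", "asp"), ("f10", "aspi"), ("f11", "aspir"),
            ("f12", "rin"), ("f13", "irin"), ("f14", "pirin"),
        }

    def test_short_token_omits_all_affixes(self):
        assert extract_affixes("ab") == []

    def test_length_four_token_omits_only_length5(self):
        ids = {f.template[0] for f in extract_affixes("dose")}
        assert ids == {"f9", "f10", "f12", "f13"}


class TestWordShape:
    def test_reference_shapes(self):
        assert word_shape("Aspirin1+", "generalized").value == "Xxxxxxx0O"
        assert word_shape("Aspirin1+", "brief").value == "Xx0O"

    def test_all_caps(self):
        assert word_shape("ABC", "generalized").value == "XXX"
        assert word_shape("ABC", "brief").value == "X"

    @given(tokens)
    @settings(max_examples=200, deadline=None)
    def test_shape_invariants(self, w):
        gen = word_shape(w, "generalized").value
        brief = word_shape(w, "brief").value
        assert len(gen) == len(w)
        assert len(brief) <= len(gen)
        assert all(a != b for a, b in zip(brief, brief[1:]))
        assert set(gen) <= set("Xx0O")


class TestDictionary:
    @pytest.fixture()
    def fixture_dict(self):
        return Dictionary.from_terms("fixture", ["aspirin", "contrast media"])

    @pytest.mark.parametrize(
        "token,expected", [("aspirin", "Y"), ("the", "N"), ("ASPIRIN", "Y"), ("media", "Y")]
    )
    def test_membership_flag(self, fixture_dict, token, expected):
        assert extract_dictionary(token, fixture_dict, "f5").value == expected

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ValueError):
            Dictionary("empty", set())

    def test_from_file_roundtrip(self, tmp_path):
        p = tmp_path / "d.txt"
        p.write_text("aspirin\ncontrast media\n")
        d = Dictionary.from_file("d", p)
        assert "Aspirin" in d and "contrast" in d and "insulin" not in d


class TestEmbeddingClusters:
    @pytest.fixture()
    def gaussian_table(self):
        rng = np.random.default_rng(3)
        centers = np.array([[10.0] * 4, [-10.0] * 4])
        words, vecs = [], []
        for g, c in enumerate(centers):
            for i in range(8):
                words.append(f"w{g}_{i}")
                vecs.append(c + rng.normal(0, 0.3, 4))
        return words, np.array(vecs)

    def test_separated_groups_land_in_distinct_clusters(self, gaussian_table):
        words, vecs = gaussian_table
        model = fit_embedding_clusters(words, vecs, k=2, seed=0)
        c0 = {model.cluster_of(w) for w in words[:8]}
        c1 = {model.cluster_of(w) for w in words[8:]}
        assert len(c0) == 1 and len(c1) == 1 and c0 != c1
        # distance oracle: same-group pairs are closer than cross-group pairs
        intra = np.linalg.norm(vecs[0] - vecs[7])
        inter = np.linalg.norm(vecs[0] - vecs[8])
        assert intra < inter

    def test_k_equal_vocab_gives_singleton_clusters(self, gaussian_table):
        words, vecs = gaussian_table
        model = fit_embedding_clusters(words, vecs, k=len(words), seed=0)
        assert len({model.cluster_of(w) for w in words}) == len(words)

    def test_k_out_of_range_rejected(self, gaussian_table):
        words, vecs = gaussian_table
        with pytest.raises(ValueError):
            fit_embedding_clusters(words, vecs, k=1)
        with pytest.raises(ValueError):
            fit_embedding_clusters(words, vecs, k=len(words) + 1)

    def test_oov_word_gets_oov_id(self, gaussian_table):
        words, vecs = gaussian_table
        model = fit_embedding_clusters(words, vecs, k=2, seed=0)
        assert extract_embedding_cluster("unseen", model).value == "OOV"
        assert extract_embedding_cluster(words[0], model).value.startswith("c")

    def test_deterministic_under_seed(self, gaussian_table):
        words, vecs = gaussian_table
        a = fit_embedding_clusters(words, vecs, k=4, seed=9).assignments
        b = fit_embedding_clusters(words, vecs, k=4, seed=9).assignments
        assert a == b

    def test_read_embeddings_header_and_dim_check(self, tmp_path):
        p = tmp_path / "emb.txt"
        p.write_text("2 3\nfoo 1 2 3\nbar 4 5 6\n")
        words, vecs = read_embeddings(p)
        assert words == ["foo", "bar"] and vecs.shape == (2, 3)
        p.write_text("foo 1 2 3\nbar 4 5\n")
        with pytest.raises(ValueError, match="dimension"):
            read_embeddings(p)


class TestRuleBasedTagger:
    def test_lengths_and_determinism(self, world):
        tagger = RuleBasedTagger()
        words = world.corpus[0].words
        assert len(tagger.pos_tags(words)) == len(words)
        assert tagger.chunk_tags(words) == tagger.chunk_tags(words)


class TestWindowExpansion:
    def test_word_feature_covers_the_window(self, bare_extractor, fig_sentence):
        per_token = bare_extractor.extract(fig_sentence)
        mid = [str(f) for f in per_token[2] if f.template == ("f1",)]
        assert mid == [
            "f1[-2]=luteolin",
            "f1[-1]=and",
            "f1[0]=apigenin",
            "f1[1]=experienced",
            "f1[2]=extensive",
        ]

    def test_single_token_sentence_uses_sentinels(self, bare_extractor):
        s = sentence_from_text("aspirin")
        feats = [str(f) for f in bare_extractor.extract(s)[0]]
        for off, sentinel in ((-2, BOS), (-1, BOS), (1, EOS), (2, EOS)):
            assert f"f1[{off}]={sentinel}" in feats

    def test_disabling_a_template_removes_exactly_its_features(self, fig_sentence):
        full = SentenceFeatureExtractor()
        partial = SentenceFeatureExtractor(
            templates=[t for t in full.templates if t != "f15"]
        )
        for a, b in zip(full.extract(fig_sentence), partial.extract(fig_sentence)):
            a_strs, b_strs = {str(f) for f in a}, {str(f) for f in b}
            assert b_strs == {s for s in a_strs if not s.startswith("f15[")}

    def test_feature_count_by_enumeration(self, bare_extractor, fig_sentence):
        # enabled surface templates: f1-f4, f9-f16 (no dicts, no clusters)
        # mid-token window: all 5 positions in range; f4 adds one hyphen flag
        # per position; short tokens omit affixes.
        per_token = bare_extractor.extract(fig_sentence)
        n_templates = len(bare_extractor.templates)
        for i, feats in enumerate(per_token):
            expected = 5 * n_templates
            for off in range(-2, 3):
                j = i + off
                if 0 <= j < 5:
                    expected += 1  # hyphen flag rides along with f4
                    w = fig_sentence.words[j]
                    expected -= sum(
                        2 for length in (3, 4, 5) if len(w) < length
                    )
            assert len(feats) == expected

    def test_extraction_is_pure(self, world):
        s = world.corpus[0]
        a = [list(map(str, fs)) for fs in world.extractor.extract(s)]
        b = [list(map(str, fs)) for fs in world.extractor.extract(s)]
        assert a == b
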