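"""Chi-square / mutual-information / information-gain scoring and selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugner.corpus import TypedTag
from drugner.selection import (
    COARSE_TAGS,
    ContingencyTable,
    chi_square,
    collapse_tag,
    count_contingency,
    fraction_to_count,
    importance,
    information_gain,
    mutual_information,
    score_features,
    select_top_fraction,
    ImportanceTable,
)

# ---------------------------------------------------------------------------
# independent oracles (cell-by-cell definitions, no shortcuts)
# ---------------------------------------------------------------------------


def chi2_oracle(t: ContingencyTable) -> float:
    obs = {(1, 1): t.n11, (1, 0): t.n10, (0, 1): t.n01, (0, 0): t.n00}
    n = t.n
    row = {1: t.n11 + t.n10, 0: t.n01 + t.n00}
    col = {1: t.n11 + t.n01, 0: t.n10 + t.n00}
    if 0 in row.values() or 0 in col.values():
        return 0.0
    return sum(
        (obs[ef, et] - row[ef] * col[et] / n) ** 2 / (row[ef] * col[et] / n)
        for ef in (0, 1)
        for et in (0, 1)
    )


def mi_oracle(t: ContingencyTable) -> float:
    obs = {(1, 1): t.n11, (1, 0): t.n10, (0, 1): t.n01, (0, 0): t.n00}
    n = t.n
    pf = {1: (t.n11 + t.n10) / n, 0: (t.n01 + t.n00) / n}
    pt = {1: (t.n11 + t.n01) / n, 0: (t.n10 + t.n00) / n}
    total = 0.0
    for ef in (0, 1):
        for et in (0, 1):
            p = obs[ef, et] / n
            if p > 0:
                total += p * math.log2(p / (pf[ef] * pt[et]))
    return total


def entropy_oracle(counts) -> float:
    n = sum(counts)
    return -sum((c / n) * math.log2(c / n) for c in counts if c > 0)


class TestCollapse:
    @pytest.mark.parametrize(
        "tag,letter",
        [(TypedTag("B", "drug"), "B"), (TypedTag("O"), "O"), (TypedTag("U", "no-human"), "U")],
    )
    def test_drops_type_keeps_letter(self, tag, letter):
        assert collapse_tag(tag) == letter


class TestContingency:
    def test_hand_counted_fixture(self):
        feats = [{"f"}, {"f"}, {"f"}, set()]
        tags = ["U", "U", "O", "U"]
        t = count_contingency(feats, tags, "f", "U")
        assert (t.n11, t.n10, t.n01, t.n00) == (2, 1, 1, 0)

    def test_absent_feature(self):
        t = count_contingency([set(), {"g"}], ["B", "O"], "f", "B")
        assert t.n11 == 0 and t.n10 == 0 and t.n == 2

    def test_single_token(self):
        t = count_contingency([{"f"}], ["U"], "f", "U")
        assert (t.n11, t.n10, t.n01, t.n00) == (1, 0, 0, 0)


class TestChiSquare:
    def test_independent_table_scores_zero(self):
        assert chi_square(ContingencyTable(5, 5, 5, 5)) == 0.0

    def test_strong_association_value(self):
        # each |N-E| = 24, E in {25, 25, 25, 25}: 4 * 576 / 25 = 92.16
        assert chi_square(ContingencyTable(49, 1, 1, 49)) == pytest.approx(92.16)

    def test_degenerate_marginal_convention(self):
        assert chi_square(ContingencyTable(0, 0, 10, 90)) == 0.0

    @given(
        st.tuples(
            st.integers(0, 200), st.integers(0, 200),
            st.integers(0, 200), st.integers(0, 200),
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=1000, deadline=None)
    def test_agrees_with_four_cell_oracle(self, cells):
        table = ContingencyTable(*cells)
        assert chi_square(table) == pytest.approx(chi2_oracle(table), abs=1e-9)


class TestMutualInformation:
    def test_independent_table_is_zero(self):
        assert mutual_information(ContingencyTable(5, 5, 5, 5)) == pytest.approx(0.0)

    def test_perfect_association_is_one_bit(self):
        assert mutual_information(ContingencyTable(50, 0, 0, 50)) == pytest.approx(1.0)

    def test_near_perfect_association(self):
        # frozen from the independent plug-in oracle computed by hand
        assert mutual_information(ContingencyTable(49, 1, 1, 49)) == pytest.approx(
            0.8585594574581793
        )

    @given(
        st.tuples(
            st.integers(0, 100), st.integers(0, 100),
            st.integers(0, 100), st.integers(0, 100),
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=300, deadline=None)
    def test_nonnegative_and_matches_oracle(self, cells):
        table = ContingencyTable(*cells)
        val = mutual_information(table)
        assert val == pytest.approx(mi_oracle(table), abs=1e-9)
        assert val >= -1e-12


class TestInformationGain:
    def test_uninformative_feature_is_zero(self):
        feats = [{"f"}, set(), {"f"}, set()]
        tags = ["O", "O", "U", "U"]  # same tag split with and without f
        assert information_gain(feats, tags, "f") == pytest.approx(0.0)

    def test_perfect_binary_predictor_is_one_bit(self):
        feats = [{"f"}, {"f"}, set(), set()]
        tags = ["U", "U", "O", "O"]
        assert information_gain(feats, tags, "f") == pytest.approx(1.0)

    def test_ten_token_fixture_matches_entropy_oracle(self):
        # 4 tokens with f (tags U,U,U,B), 6 without (O,O,O,O,L,I);
        # frozen value from the plug-in entropy computation done beforehand
        feats = [{"f"}] * 4 + [set()] * 6
        tags = ["U", "U", "U", "B", "O", "O", "O", "O", "L", "I"]
        ig = information_gain(feats, tags, "f")
        assert ig == pytest.approx(0.9709505944546689)
        h_t = entropy_oracle([3, 1, 4, 1, 1])
        assert 0.0 <= ig <= h_t
        assert h_t == pytest.approx(2.0464393446710156)


class TestImportance:
    def test_single_informative_tag_gives_its_score(self):
        feats = [{"f"}, {"f"}, set(), set(), set()]
        tags = ["U", "U", "O", "B", "L"]
        by_hand = max(
            chi2_oracle(count_contingency(feats, tags, "f", t)) for t in COARSE_TAGS
        )
        assert importance(feats, tags, "f", "chi2") == pytest.approx(by_hand)

    def test_all_zero_scores_give_zero(self):
        feats = [{"f"}, {"f"}]
        tags = ["U", "U"]  # single tag: no contrast anywhere
        assert importance(feats, tags, "f", "chi2") == 0.0

    def test_max_is_taken_over_tags(self):
        feats = [{"f"}, {"f"}, {"f"}, set(), set(), set()]
        tags = ["U", "U", "B", "O", "O", "B"]
        per_tag = [
            mi_oracle(count_contingency(feats, tags, "f", t)) for t in COARSE_TAGS
        ]
        assert importance(feats, tags, "f", "mi") == pytest.approx(max(per_tag))


class TestScoreFeaturesVectorized:
    """The corpus-level (vectorized) scorer agrees with per-feature oracles."""

    @pytest.fixture()
    def events(self):
        rng = np.random.default_rng(5)
        feats, tags = [], []
        pool = [f"x{i}" for i in range(12)]
        for _ in range(120):
            feats.append({f for f in pool if rng.random() < 0.3})
            tags.append(COARSE_TAGS[rng.integers(5)])
        return feats, tags

    @pytest.mark.parametrize("statistic", ["chi2", "mi", "ig"])
    def test_matches_scalar_path(self, events, statistic):
        feats, tags = events
        table = score_features(feats, tags, statistic)
        for f in table.scores:
            assert table.scores[f] == pytest.approx(
                importance(feats, tags, f, statistic), abs=1e-9
            )

    def test_ig_bounded_by_tag_entropy(self, events):
        feats, tags = events
        table = score_features(feats, tags, "ig")
        h_t = entropy_oracle(np.bincount([COARSE_TAGS.index(t) for t in tags]))
        assert all(0.0 <= s <= h_t + 1e-12 for s in table.scores.values())


class TestSelection:
    def test_paper_scale_rounding(self):
        assert fraction_to_count(294782, 0.4) == 117913

    def test_full_fraction_keeps_everything(self):
        table = ImportanceTable("ig", {f"f{i}": float(i) for i in range(7)})
        assert len(select_top_fraction(table, 1.0)) == 7

    def test_top_two_of_five(self):
        scores = {"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5, "e": 0.1}
        assert select_top_fraction(ImportanceTable("mi", scores), 0.4) == ["a", "b"]

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_out_of_range_fraction_rejected(self, p):
        with pytest.raises(ValueError):
            select_top_fraction(ImportanceTable("mi", {"a": 1.0}), p)

    def test_nested_subsets_across_fractions(self):
        rng = np.random.default_rng(0)
        scores = {f"f{i}": float(rng.integers(0, 5)) for i in range(37)}  # many ties
        table = ImportanceTable("chi2", scores)
        prev: set = set()
        for p in np.arange(0.1, 1.01, 0.1):
            cur = set(select_top_fraction(table, float(p)))
            assert prev <= cur
            prev = cur

    def test_tsv_roundtrip(self, tmp_path):
        table = ImportanceTable("ig", {"f1[0]=a": 0.5, "f1[0]=b": 0.25})
        p = tmp_path / "imp.tsv"
        table.to_tsv(p)
        back = ImportanceTable.from_tsv(p)
        assert back.statistic == "ig"
        assert back.scores == pytest.approx(table.scores)


class TestPlantedSignalRanking:
    def test_all_statistics_prefer_predictive_over_noise(self):
        """A dictionary-like feature tied to drug tokens must outrank a coin-flip
        feature under chi2, MI and IG."""
        rng = np.random.default_rng(42)
        feats, tags = [], []
        for _ in range(600):
            is_drug = rng.random() < 0.3
            token_feats = set()
            if is_drug and rng.random() < 0.9:
                token_feats.add("dict=Y")
            if rng.random() < 0.5:
                token_feats.add("noise=Y")
            feats.append(token_feats)
            tags.append("U" if is_drug else "O")
        for statistic in ("chi2", "mi", "ig"):
            table = score_features(feats, tags, statistic)
            assert table.scores["dict=Y"] > table.scores["noise=Y"], statistic
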