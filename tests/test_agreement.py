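import math

import pandas as pd
import pytest

from ontocode.agreement import (
    EmptyComparisonError,
    cross_coder_concordance,
    distance_vs_rating,
    micro_average,
    pairwise_agreement,
    qualitative_summary,
)
from ontocode.annotations import (
    MULTI_FINDING,
    SINGLE_FINDING,
    AnnotationRecord,
    QualitativeRating,
    Rating,
)


def rec(item, coder, codes):
    return AnnotationRecord(str(item), coder, frozenset(codes))


class TestPairwiseAgreement:
    def test_coder_against_itself_is_all_exact(self, chain_graph):
        records = [
            rec(1, c, {"A"}) for c in ("X", "Y")
        ] + [rec(2, c, {"B", "C"}) for c in ("X", "Y")]
        table = pairwise_agreement(records, "X", "Y", chain_graph)
        for stratum in ("All", SINGLE_FINDING, MULTI_FINDING):
            row = table.row(stratum)
            assert (row.pct_exact, row.pct_le1, row.pct_le2, row.pct_le3) == (
                100,
                100,
                100,
                100,
            )

    def test_hand_counted_band_percentages(self, chain_graph):
        """Distances {0, 0, 1, 3} -> exact 50, <=1 75, <=2 75, <=3 100."""
        gold = [rec(i, "GS", {"A"}) for i in range(1, 5)]
        coder = [
            rec(1, "X", {"A"}),
            rec(2, "X", {"A"}),
            rec(3, "X", {"B"}),
            rec(4, "X", {"D"}),
        ]
        row = pairwise_agreement(gold + coder, "X", "GS", chain_graph).row("All")
        assert row.n_items == 4
        assert (row.pct_exact, row.pct_le1, row.pct_le2, row.pct_le3) == (
            50,
            75,
            75,
            100,
        )

    def test_empty_stratum_reports_n_zero_not_division_error(self, chain_graph):
        records = [rec(1, "GS", {"A"}), rec(1, "X", {"B"})]
        table = pairwise_agreement(records, "X", "GS", chain_graph)
        row = table.row(MULTI_FINDING)
        assert row.n_items == 0
        assert math.isnan(row.pct_exact)

    def test_invalid_items_are_excluded_and_counted(self, chain_graph):
        records = [
            rec(1, "GS", {"A"}),
            rec(1, "X", set()),
            rec(2, "GS", {"A"}),
            rec(2, "X", {"A"}),
        ]
        table = pairwise_agreement(records, "X", "GS", chain_graph)
        assert table.row("All").n_items == 1
        assert table.exclusions["invalid_code_set"] == 1

    def test_cumulative_monotonicity(self, chain_graph):
        gold = [rec(i, "GS", {"A"}) for i in range(8)]
        coder = [rec(i, "X", {c}) for i, c in enumerate("AABBCDDC")]
        table = pairwise_agreement(gold + coder, "X", "GS", chain_graph)
        for row in table.rows:
            if row.n_items:
                assert (
                    row.pct_exact <= row.pct_le1 <= row.pct_le2 <= row.pct_le3 <= 100
                )


class TestMicroAverage:
    def _records(self, chain_graph):
        # coder1: 4 usable items, 3 exact; coder2: 2 usable items, 1 exact
        gold = [rec(i, "GS", {"A"}) for i in range(1, 5)]
        coder1 = [rec(i, "C1", {"A"}) for i in range(1, 4)] + [rec(4, "C1", {"B"})]
        coder2 = [rec(1, "C2", {"A"}), rec(2, "C2", {"B"})]
        return gold + coder1 + coder2

    def test_micro_pools_counts_not_percentages(self, chain_graph):
        table = micro_average(self._records(chain_graph), ["C1", "C2"], "GS", chain_graph)
        row = table.row("All")
        assert row.n_items == 6
        assert row.pct_exact == pytest.approx(100 * 4 / 6)
        macro = (75 + 50) / 2
        assert row.pct_exact != pytest.approx(macro)

    def test_single_coder_equals_pairwise(self, chain_graph):
        records = self._records(chain_graph)
        micro = micro_average(records, ["C1"], "GS", chain_graph)
        pair = pairwise_agreement(records, "C1", "GS", chain_graph)
        assert micro.to_dataframe().drop(columns=[]).equals(
            pair.to_dataframe()
        )

    def test_equal_n_identical_outcomes_micro_equals_macro(self, chain_graph):
        gold = [rec(i, "GS", {"A"}) for i in range(1, 3)]
        c1 = [rec(1, "C1", {"A"}), rec(2, "C1", {"B"})]
        c2 = [rec(1, "C2", {"B"}), rec(2, "C2", {"A"})]
        micro = micro_average(gold + c1 + c2, ["C1", "C2"], "GS", chain_graph)
        assert micro.row("All").pct_exact == pytest.approx(50)


class TestQualitativeSummary:
    def test_all_good(self):
        ratings = [QualitativeRating(str(i), "A", Rating.GOOD) for i in range(5)]
        row = qualitative_summary(ratings, ["A"]).iloc[0]
        assert (
            row.pct_good,
            row.pct_acceptable,
            row.pct_good_or_acceptable,
            row.pct_not_acceptable,
        ) == (100, 0, 100, 0)

    def test_hand_counted_mix(self):
        levels = [Rating.GOOD, Rating.GOOD, Rating.ACCEPTABLE, Rating.NOT_ACCEPTABLE]
        ratings = [QualitativeRating(str(i), "A", r) for i, r in enumerate(levels)]
        row = qualitative_summary(ratings, ["A"]).iloc[0]
        assert (
            row.pct_good,
            row.pct_acceptable,
            row.pct_good_or_acceptable,
            row.pct_not_acceptable,
        ) == (50, 25, 75, 25)
        assert row.pct_good + row.pct_acceptable + row.pct_not_acceptable == 100

    def test_unrated_coder_gets_na_row(self):
        df = qualitative_summary([], ["A"])
        assert df.iloc[0].n_items == 0
        assert math.isnan(df.iloc[0].pct_good)


class TestDistanceVsRating:
    def test_all_good_and_exact(self, chain_graph):
        records = [rec(1, "GS", {"A"}), rec(1, "X", {"A"})]
        ratings = [QualitativeRating("1", "X", Rating.GOOD)]
        df = distance_vs_rating(records, ratings, "GS", chain_graph)
        good = df[df.rating == "Good"].iloc[0]
        assert (good.pct_exact, good.pct_le1, good.pct_le2, good.pct_le3) == (
            100,
            100,
            100,
            100,
        )

    def test_good_iff_exact_separation(self, chain_graph):
        gold = [rec(i, "GS", {"A"}) for i in range(4)]
        coder = [rec(i, "X", {c}) for i, c in enumerate("AABB")]
        ratings = [
            QualitativeRating(str(i), "X", Rating.GOOD if c == "A" else Rating.ACCEPTABLE)
            for i, c in enumerate("AABB")
        ]
        df = distance_vs_rating(gold + coder, ratings, "GS", chain_graph)
        df = df.set_index("rating")
        assert df.loc["Good"].pct_exact == 100
        assert df.loc["Acceptable"].pct_exact == 0
        assert df.loc["Acceptable"].pct_le1 == 100

    def test_rows_cover_all_three_levels(self, chain_graph):
        records = [rec(1, "GS", {"A"}), rec(1, "X", {"A"})]
        ratings = [QualitativeRating("1", "X", Rating.GOOD)]
        df = distance_vs_rating(records, ratings, "GS", chain_graph)
        assert list(df.rating) == ["Good", "Acceptable", "Not acceptable"]


class TestCrossCoderConcordance:
    def test_identical_coders_all_diagonal(self, chain_graph):
        gold = [rec(i, "GS", {"A"}) for i in range(4)]
        x = [rec(i, "X", {c}) for i, c in enumerate("AABB")]
        y = [rec(i, "Y", {c}) for i, c in enumerate("AABB")]
        table = cross_coder_concordance(gold + x + y, "X", "Y", "GS", chain_graph)
        assert table.loc["exact", "exact"] == 2
        assert table.loc["not exact", "not exact"] == 2
        assert table.loc["exact", "not exact"] == 0

    def test_hand_counted_margins(self, chain_graph):
        """Counts {{3,1},{0,2}} -> row margins {4,2}, column margins {3,3}."""
        gold = [rec(i, "GS", {"A"}) for i in range(6)]
        x = [rec(i, "X", {c}) for i, c in enumerate("AAAABB")]
        y = [rec(i, "Y", {c}) for i, c in enumerate("AAABBB")]
        table = cross_coder_concordance(gold + x + y, "X", "Y", "GS", chain_graph)
        assert table.loc["exact", "Total"] == 4
        assert table.loc["not exact", "Total"] == 2
        assert table.loc["Total", "exact"] == 3
        assert table.loc["Total", "not exact"] == 3
        assert table.loc["Total", "Total"] == 6

    def test_rating_mode_uses_rating_levels(self, chain_graph):
        gold = [rec(1, "GS", {"A"})]
        x, y = [rec(1, "X", {"A"})], [rec(1, "Y", {"B"})]
        ratings = [
            QualitativeRating("1", "X", Rating.GOOD),
            QualitativeRating("1", "Y", Rating.ACCEPTABLE),
        ]
        table = cross_coder_concordance(
            gold + x + y, "X", "Y", "GS", chain_graph, ratings=ratings
        )
        assert table.loc["Good", "Acceptable"] == 1

    def test_disjoint_item_sets_raise(self, chain_graph):
        records = [
            rec(1, "GS", {"A"}),
            rec(2, "GS", {"A"}),
            rec(1, "X", {"A"}),
            rec(2, "Y", {"A"}),
        ]
        with pytest.raises(EmptyComparisonError):
            cross_coder_concordance(records, "X", "Y", "GS", chain_graph)
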