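"""Density matrix, clone ranking and screen summary."""

import numpy as np
import pytest

from haloquant.screen import (
    DataError,
    HaloAreaRecord,
    build_density_matrix,
    rank_clones,
    summarize_screen,
)


def rec(clone, t, day, area):
    return HaloAreaRecord(clone=clone, temperature_c=t, day=day, area_cm2=area)


class TestDensityMatrix:
    def test_empty_records_give_zero_matrix(self):
        dm = build_density_matrix([], ["A", "B"], [(25, 1), (37, 1)])
        assert dm.shape == (2, 2)
        assert (dm.to_numpy() == 0).all()
        assert list(dm.columns) == ["T25_d1", "T37_d1"]

    def test_single_record_single_nonzero(self):
        dm = build_density_matrix(
            [rec("LP4", 37, 1, 0.50)], ["LP4", "LP11"], [(25, 1), (37, 1)]
        )
        assert dm.loc["LP4", "T37_d1"] == 0.50
        assert (dm.to_numpy() > 0).sum() == 1

    def test_duplicate_record_rejected(self):
        records = [rec("A", 25, 1, 0.1), rec("A", 25, 1, 0.2)]
        with pytest.raises(DataError):
            build_density_matrix(records, ["A"], [(25, 1)])

    def test_unknown_clone_rejected(self):
        with pytest.raises(DataError):
            build_density_matrix([rec("X", 25, 1, 0.1)], ["A"], [(25, 1)])

    def test_record_order_does_not_matter(self):
        records = [
            rec("A", 25, 1, 0.3),
            rec("B", 37, 1, 0.7),
            rec("A", 37, 1, 0.2),
        ]
        dm1 = build_density_matrix(records, ["A", "B"], [(25, 1), (37, 1)])
        dm2 = build_density_matrix(records[::-1], ["A", "B"], [(25, 1), (37, 1)])
        assert dm1.equals(dm2)


class TestRankClones:
    conditions = [(25, 1), (37, 1), (45, 1)]

    def build(self, areas):
        records = [
            rec(clone, t, 1, a)
            for clone, per_t in areas.items()
            for t, a in per_t.items()
            if a > 0
        ]
        return build_density_matrix(records, sorted(areas), self.conditions)

    def test_broad_responder_outranks_narrow(self):
        dm = self.build(
            {"A": {25: 0.2, 37: 0.5, 45: 0.1}, "B": {37: 0.9}}
        )
        ranked = rank_clones(dm, day=1, temperatures={25, 37, 45})
        assert [r.clone for r in ranked] == ["A", "B"]
        assert ranked[0].tier == 1 and ranked[1].tier == 2

    def test_two_tier1_clones_ordered_by_total_area(self):
        dm = self.build(
            {
                "LP11": {25: 0.2, 37: 0.4, 45: 0.2},  # total 0.8
                "LP4": {25: 0.3, 37: 0.6, 45: 0.3},   # total 1.2
            }
        )
        ranked = rank_clones(dm, day=1, temperatures={25, 37, 45})
        assert [r.clone for r in ranked] == ["LP4", "LP11"]
        assert all(r.tier == 1 for r in ranked)

    def test_all_zero_matrix_all_tier2_alphabetical(self):
        dm = self.build({"C": {}, "A": {}, "B": {}})
        ranked = rank_clones(dm, day=1, temperatures={25, 37, 45})
        assert [r.clone for r in ranked] == ["A", "B", "C"]
        assert all(r.tier == 2 for r in ranked)

    def test_deterministic_under_row_shuffle(self):
        dm = self.build(
            {"A": {25: 0.2, 37: 0.2, 45: 0.2}, "B": {37: 0.9}, "C": {25: 0.1, 37: 0.1, 45: 0.4}}
        )
        ranked1 = rank_clones(dm, day=1, temperatures={25, 37, 45})
        ranked2 = rank_clones(dm.sample(frac=1, random_state=0), day=1,
                              temperatures={25, 37, 45})
        assert ranked1 == ranked2

    def test_missing_condition_rejected(self):
        dm = self.build({"A": {25: 0.2}})
        with pytest.raises(ValueError):
            rank_clones(dm, day=4, temperatures={25})


class TestSummarizeScreen:
    @pytest.mark.parametrize(
        "n,positives,expected",
        [
            (563, [f"c{i}" for i in range(12)], 2.1),
            (100, [], 0.0),
            (8, list("abcdefgh"), 100.0),
            (3, ["a"], 33.3),
            (40, ["a"], 2.5),  # exact .x5: rounds away from zero
        ],
    )
    def test_hit_rate_one_decimal_half_up(self, n, positives, expected):
        assert summarize_screen(n, positives).hit_rate_percent == expected

    def test_zero_screened_rejected(self):
        with pytest.raises(ValueError):
            summarize_screen(0, [])

    def test_more_positives_than_screened_rejected(self):
        with pytest.raises(ValueError):
            summarize_screen(2, ["a", "b", "c"])

    def test_rate_rounds_back_to_count_exhaustively(self):
        # for every (n <= 1000, k <= n): round(rate * n / 100) == k
        for n in range(1, 1001):
            k = np.arange(n + 1)
            tenths = (2000 * k + n) // (2 * n)
            recovered = np.floor(tenths / 1000.0 * n + 0.5).astype(int)
            np.testing.assert_array_equal(recovered, k)

    def test_integer_rounding_matches_decimal_half_up(self):
        from decimal import Decimal, ROUND_HALF_UP

        for n in (7, 40, 563, 999):
            for k in range(0, n + 1, max(1, n // 23)):
                want = float(
                    (Decimal(100 * k) / Decimal(n)).quantize(
                        Decimal("0.1"), rounding=ROUND_HALF_UP
                    )
                )
                assert summarize_screen(n, ["x"] * k).hit_rate_percent == want
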