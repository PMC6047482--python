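import numpy as np
import pandas as pd
import pytest

from bwsurvey import (
    BlockDesign,
    PreferenceModel,
    apply_inclusion,
    bws_average,
    bws_set_scores,
    group_balance,
    simulate_survey,
    summarize_benefits,
    tally_tradeoff,
)
from bwsurvey.catalog import ResponseRecord
from bwsurvey.errors import ValidationError
from bwsurvey.scoring import score_harm_cohort
from .conftest import make_complete_record


def record_with_harm_ranks(rid, set_items, ranks, set_id=1):
    return ResponseRecord(
        respondent_id=rid,
        harm_set_id=set_id,
        harm_ranks=dict(zip(set_items, ranks)),
    )


class TestSummarizeBenefits:
    def test_identical_rankings_degenerate(self, catalog, benefit_ids, design21):
        cohort = [
            make_complete_record(f"r{i}", benefit_ids, design21.block_items(1), 1)
            for i in range(10)
        ]
        summary = summarize_benefits(cohort, catalog)
        for _, row in summary.table.iterrows():
            assert row["median_rank"] == cohort[0].benefit_ranks[row["item_id"]]
            assert row["iqr"] == 0.0

    def test_hand_median_and_iqr(self, catalog, benefit_ids, design21):
        """First item ranked 1, 1, 3 → median 1; IQR from the quantile rule."""
        base = list(range(1, 8))
        perm_a = dict(zip(benefit_ids, base))
        perm_c = dict(zip(benefit_ids, [3, 1, 2] + base[3:]))
        cohort = [
            make_complete_record("r1", benefit_ids, design21.block_items(1), 1,
                                 benefit_ranks=dict(perm_a)),
            make_complete_record("r2", benefit_ids, design21.block_items(1), 1,
                                 benefit_ranks=dict(perm_a)),
            make_complete_record("r3", benefit_ids, design21.block_items(1), 1,
                                 benefit_ranks=perm_c),
        ]
        summary = summarize_benefits(cohort, catalog)
        row = summary.table.set_index("item_id").loc[benefit_ids[0]]
        assert row["median_rank"] == 1.0
        expected_iqr = float(
            np.percentile([1, 1, 3], 75) - np.percentile([1, 1, 3], 25)
        )
        assert row["iqr"] == expected_iqr

    def test_ordering_by_median_then_iqr(self, catalog, benefit_ids, design21):
        cohort = [
            make_complete_record(f"r{i}", benefit_ids, design21.block_items(1), 1)
            for i in range(4)
        ]
        summary = summarize_benefits(cohort, catalog)
        meds = list(summary.table["median_rank"])
        assert meds == sorted(meds)
        assert summary.ordering()[0] == benefit_ids[0]

    def test_empty_cohort_rejected(self, catalog):
        with pytest.raises(ValidationError):
            summarize_benefits([], catalog)

    def test_incomplete_ranking_rejected(self, catalog, benefit_ids, design21):
        rec = make_complete_record("r", benefit_ids, design21.block_items(1), 1)
        del rec.benefit_ranks[benefit_ids[0]]
        with pytest.raises(ValidationError):
            summarize_benefits([rec], catalog)


class TestBwsSetScores:
    SET = ("A", "B", "C", "D", "E", "F", "G")

    def test_unanimity(self):
        cohort = [
            record_with_harm_ranks(f"r{i}", self.SET, (1, 2, 3, 4, 5, 6, 7))
            for i in range(5)
        ]
        scores = bws_set_scores(cohort, self.SET)
        assert scores["A"] == 1.0
        assert scores["G"] == -1.0
        assert all(scores[x] == 0.0 for x in "BCDEF")

    def test_two_respondent_hand_tally(self):
        """(best A, worst G) and (best A, worst B) → A 1.0, B −0.5, G −0.5."""
        cohort = [
            record_with_harm_ranks("r1", self.SET, (1, 2, 3, 4, 5, 6, 7)),
            record_with_harm_ranks("r2", self.SET, (1, 7, 2, 3, 4, 5, 6)),
        ]
        scores = bws_set_scores(cohort, self.SET)
        assert scores == {
            "A": 1.0, "B": -0.5, "C": 0.0, "D": 0.0, "E": 0.0, "F": 0.0, "G": -0.5,
        }
        assert sum(scores.values()) == 0.0

    def test_brute_force_oracle_equivalence(self):
        """Independent tally straight off the raw rank vectors."""
        rng = np.random.default_rng(17)
        rankings = [tuple(rng.permutation(7) + 1) for _ in range(200)]
        cohort = [
            record_with_harm_ranks(f"r{i}", self.SET, ranks)
            for i, ranks in enumerate(rankings)
        ]
        scores = bws_set_scores(cohort, self.SET)
        n = len(rankings)
        for pos, item in enumerate(self.SET):
            n_best = sum(1 for ranks in rankings if ranks[pos] == 1)
            n_worst = sum(1 for ranks in rankings if ranks[pos] == 7)
            assert scores[item] == pytest.approx(n_best / n - n_worst / n)

    def test_zero_sum_and_range(self):
        rng = np.random.default_rng(23)
        cohort = [
            record_with_harm_ranks(f"r{i}", self.SET, tuple(rng.permutation(7) + 1))
            for i in range(37)
        ]
        scores = bws_set_scores(cohort, self.SET)
        assert abs(sum(scores.values())) < 1e-12
        assert all(-1.0 <= s <= 1.0 for s in scores.values())

    def test_empty_set_identified(self):
        with pytest.raises(ValidationError, match="set 4"):
            bws_set_scores([], self.SET, set_id=4)

    def test_wrong_item_set_rejected(self):
        rec = record_with_harm_ranks("r", ("X", "Y"), (1, 2))
        with pytest.raises(ValidationError):
            bws_set_scores([rec], self.SET)


class TestBwsAverage:
    @staticmethod
    def _two_item_design():
        return BlockDesign(items=("x", "y"), blocks=(("x", "y"),) * 4)

    def test_arithmetic_mean(self):
        design = self._two_item_design()
        set_scores = {
            1: {"x": 0.2, "y": -0.2},
            2: {"x": 0.4, "y": -0.4},
            3: {"x": 0.0, "y": 0.0},
            4: {"x": 0.2, "y": -0.2},
        }
        result = bws_average(set_scores, design)
        by_id = {it.item_id: it for it in result.items}
        assert by_id["x"].averaged_score == pytest.approx(0.2)
        assert by_id["x"].final_rank == 1
        assert len(by_id["x"].set_scores) == 4

    def test_all_zero_tiebreak_lexicographic(self):
        design = self._two_item_design()
        set_scores = {s: {"x": 0.0, "y": 0.0} for s in range(1, 5)}
        result = bws_average(set_scores, design)
        assert result.ordering() == ["x", "y"]

    def test_missing_set_score_rejected(self):
        design = self._two_item_design()
        set_scores = {s: {"x": 0.0, "y": 0.0} for s in range(1, 4)}
        with pytest.raises(ValidationError):
            bws_average(set_scores, design)

    def test_replication_count_of_set_scores(self, catalog, design21, flat_model):
        records = simulate_survey(flat_model, catalog, design21, 1_200, seed=2)
        _, harm_cohort, _ = apply_inclusion(records, 2_400, catalog, design21)
        result = score_harm_cohort(harm_cohort, design21)
        for it in result.items:
            assert len(it.set_scores) == 4

    def test_dominant_item_attains_rank_one(self, catalog, design21):
        """One harm 3 utility units above the rest wins every set it is in."""
        model = PreferenceModel.for_catalog(catalog, overrides={"death": 3.0})
        records = simulate_survey(model, catalog, design21, 3_000, seed=4)
        _, harm_cohort, _ = apply_inclusion(records, 6_000, catalog, design21)
        result = score_harm_cohort(harm_cohort, design21)
        assert result.ordering()[0] == "death"

    def test_relabeling_symmetry(self):
        """Renaming items consistently permutes all outputs identically."""
        design = BlockDesign(items=("a", "b", "c"), blocks=(("a", "b"), ("b", "c"), ("a", "c")))
        rng = np.random.default_rng(5)
        cohorts = {
            s: [
                record_with_harm_ranks(
                    f"s{s}r{i}", design.block_items(s),
                    tuple(rng.permutation(2) + 1), set_id=s,
                )
                for i in range(20)
            ]
            for s in (1, 2, 3)
        }
        result = score_harm_cohort([r for c in cohorts.values() for r in c], design)

        mapping = {"a": "p", "b": "q", "c": "r"}
        design2 = BlockDesign(
            items=tuple(mapping[i] for i in design.items),
            blocks=tuple(tuple(mapping[i] for i in blk) for blk in design.blocks),
        )
        relabeled = [
            ResponseRecord(
                respondent_id=rec.respondent_id,
                harm_set_id=rec.harm_set_id,
                harm_ranks={mapping[k]: v for k, v in rec.harm_ranks.items()},
            )
            for c in cohorts.values()
            for rec in c
        ]
        result2 = score_harm_cohort(relabeled, design2)
        assert [mapping[i] for i in result.ordering()] == result2.ordering()
        for it, it2 in zip(result.items, result2.items):
            assert it.averaged_score == it2.averaged_score


class TestTradeoff:
    @staticmethod
    def _records(counts):
        records = []
        for answer, k in counts.items():
            records += [
                ResponseRecord(respondent_id=f"{answer}{i}", tradeoff=answer)
                for i in range(k)
            ]
        return records

    def test_printed_counts(self):
        tally = tally_tradeoff(
            self._records({"benefits": 231, "harms": 106, "equal": 46})
        )
        assert tally.n == 383
        assert tally.counts == {"benefits": 231, "harms": 106, "equal": 46}
        assert tally.proportions["benefits"] == pytest.approx(231 / 383)
        assert round(100 * tally.proportions["benefits"]) == 60
        assert round(100 * tally.proportions["harms"]) == 28
        assert round(100 * tally.proportions["equal"]) == 12
        assert sum(tally.proportions.values()) == pytest.approx(1.0)

    def test_unanimous(self):
        tally = tally_tradeoff(self._records({"benefits": 9}))
        assert tally.proportions == {"benefits": 1.0, "harms": 0.0, "equal": 0.0}

    def test_unanswered_skipped(self):
        records = self._records({"benefits": 2}) + [
            ResponseRecord(respondent_id="na")
        ]
        assert tally_tradeoff(records).n == 2

    def test_no_answers_rejected(self):
        with pytest.raises(ValidationError):
            tally_tradeoff([ResponseRecord(respondent_id="na")])

    def test_simulated_draw_within_binomial_error(self, catalog, design21):
        model = PreferenceModel.for_catalog(catalog, tradeoff_probs=(0.60, 0.28, 0.12))
        records = simulate_survey(model, catalog, design21, 4_000, seed=19)
        tally = tally_tradeoff(records)
        for answer, p in zip(("benefits", "harms", "equal"), (0.60, 0.28, 0.12)):
            se = np.sqrt(p * (1 - p) / 4_000)
            assert abs(tally.proportions[answer] - p) < 3 * se


class TestGroupBalance:
    def test_empty_cohort(self, design21):
        table = group_balance([], design21)
        per_set = table[table["set_id"] != "range"]
        assert len(per_set) == 12
        assert (per_set["n"] == 0).all()

    def test_one_respondent_per_set(self, catalog, benefit_ids, design21):
        cohort = [
            make_complete_record(f"r{s}", benefit_ids, design21.block_items(s), s)
            for s in range(1, 13)
        ]
        table = group_balance(cohort, design21)
        per_set = table[table["set_id"] != "range"]
        assert (per_set["n"] == 1).all()

    def test_homogeneous_cohort_balanced(self, catalog, design21, flat_model):
        records = simulate_survey(flat_model, catalog, design21, 3_600, seed=29)
        _, harm_cohort, _ = apply_inclusion(records, 7_200, catalog, design21)
        table = group_balance(harm_cohort, design21)
        per_set = table[table["set_id"] != "range"]
        global_pct = 100 * np.mean([r.gender == "female" for r in harm_cohort])
        assert (abs(per_set["pct_female"] - global_pct) < 5).all()
        assert table.iloc[-1]["set_id"] == "range"
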