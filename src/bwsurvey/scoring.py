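"""Rank summaries: benefit medians, best-worst scores, trade-off tally.

The best-worst scaling (BWS) score of an item within one ranking set is

    score = P(ranked 1) − P(ranked k)

among the respondents who ranked that set (k = block size, the "least
affects your decision" position). Scores within a set sum to zero because
every complete ranking contributes exactly one best and one worst. Per-item
scores are then averaged, unweighted, over the sets containing the item,
and the final ordering is by descending averaged score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import OutcomeItem, ResponseRecord, benefit_task_items
from .design import BlockDesign
from .errors import ValidationError


@dataclass(frozen=True)
class BenefitSummary:
    """Median/IQR of assigned ranks per benefit-task item, ordered best-first."""

    table: pd.DataFrame  # columns: item_id, median_rank, iqr, n
    n: int

    def ordering(self) -> list[str]:
        return list(self.table["item_id"])


@dataclass(frozen=True)
class BwsItemScore:
    item_id: str
    set_scores: Mapping[int, float]
    averaged_score: float
    final_rank: int


@dataclass(frozen=True)
class BwsResult:
    """Per-item per-set and averaged BWS scores with the final ordering."""

    items: tuple  # BwsItemScore, sorted by final_rank
    set_ns: Mapping[int, int]

    def ordering(self) -> list[str]:
        return [it.item_id for it in self.items]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "item_id": it.item_id,
                "averaged_score": it.averaged_score,
                "final_rank": it.final_rank,
                "n_sets": len(it.set_scores),
            }
            for it in self.items
        ]
        return pd.DataFrame(
            rows, columns=["item_id", "averaged_score", "final_rank", "n_sets"]
        )

    def by_set_frame(self) -> pd.DataFrame:
        rows = [
            {
                "set_id": set_id,
                "item_id": it.item_id,
                "score": score,
                "n": self.set_ns[set_id],
            }
            for it in sorted(self.items, key=lambda x: x.item_id)
            for set_id, score in sorted(it.set_scores.items())
        ]
        rows.sort(key=lambda r: (r["set_id"], r["item_id"]))
        return pd.DataFrame(rows, columns=["set_id", "item_id", "score", "n"])


@dataclass(frozen=True)
class TradeoffTally:
    counts: Mapping[str, int]
    proportions: Mapping[str, float]
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "answer": key,
                "count": self.counts[key],
                "proportion": self.proportions[key],
            }
            for key in ("benefits", "harms", "equal")
        ]
        return pd.DataFrame(rows, columns=["answer", "count", "proportion"])


def _quantile(values: np.ndarray, q: float, rule: str) -> float:
    return float(np.percentile(values, q, method=rule))


def summarize_benefits(
    cohort: Sequence[ResponseRecord],
    catalog: Sequence[OutcomeItem],
    quantile_rule: str = "linear",
) -> BenefitSummary:
    """Median and IQR (Q3 − Q1) of each item's assigned ranks.

    Items are ordered by ascending median, ties broken by ascending IQR
    then ``item_id``. Every cohort record must carry a complete ranking.
    """
    if not cohort:
        raise ValidationError("cannot summarize an empty benefit cohort")
    benefit_ids = benefit_task_items(catalog)
    for rec in cohort:
        if not rec.benefit_ranking_complete(benefit_ids):
            raise ValidationError(
                f"respondent {rec.respondent_id}: incomplete benefit ranking"
            )
    rows = []
    for item in benefit_ids:
        ranks = np.array([rec.benefit_ranks[item] for rec in cohort], dtype=float)
        q1 = _quantile(ranks, 25, quantile_rule)
        q3 = _quantile(ranks, 75, quantile_rule)
        rows.append(
            {
                "item_id": item,
                "median_rank": float(np.median(ranks)),
                "iqr": q3 - q1,
                "n": len(cohort),
            }
        )
    rows.sort(key=lambda r: (r["median_rank"], r["iqr"], r["item_id"]))
    return BenefitSummary(table=pd.DataFrame(rows), n=len(cohort))


def bws_set_scores(
    cohort: Sequence[ResponseRecord], set_items: Sequence[str], set_id: Optional[int] = None
) -> dict:
    """BWS scores for one ranking set: P(ranked 1) − P(ranked k) per item."""
    label = f"set {set_id}" if set_id is not None else "set"
    if not cohort:
        raise ValidationError(f"no respondents ranked {label}")
    k = len(set_items)
    best_counts = {item: 0 for item in set_items}
    worst_counts = {item: 0 for item in set_items}
    for rec in cohort:
        if not rec.harm_ranking_complete(set_items):
            raise ValidationError(
                f"respondent {rec.respondent_id}: ranking is not a bijection "
                f"over {label}"
            )
        for item, rank in rec.harm_ranks.items():
            if rank == 1:
                best_counts[item] += 1
            elif rank == k:
                worst_counts[item] += 1
    n = len(cohort)
    return {
        item: (best_counts[item] - worst_counts[item]) / n for item in set_items
    }


def bws_average(
    set_scores: Mapping[int, Mapping[str, float]],
    design: BlockDesign,
    set_ns: Optional[Mapping[int, int]] = None,
) -> BwsResult:
    """Average each item's set scores (unweighted) and rank items.

    Final rank is by descending averaged score, ties broken by ``item_id``;
    every item must have a score from each of its ``replication`` sets.
    """
    per_item: dict = {item: {} for item in design.items}
    for set_id in range(1, design.n_blocks + 1):
        members = design.block_items(set_id)
        if set_id not in set_scores:
            raise ValidationError(f"missing scores for set {set_id}")
        scores = set_scores[set_id]
        for item in members:
            if item not in scores:
                raise ValidationError(f"set {set_id} lacks a score for {item!r}")
            per_item[item][set_id] = float(scores[item])
    averaged = {
        item: float(np.mean(list(scores.values())))
        for item, scores in per_item.items()
    }
    order = sorted(design.items, key=lambda it: (-averaged[it], it))
    items = tuple(
        BwsItemScore(
            item_id=item,
            set_scores=dict(sorted(per_item[item].items())),
            averaged_score=averaged[item],
            final_rank=rank,
        )
        for rank, item in enumerate(order, start=1)
    )
    return BwsResult(items=items, set_ns=dict(set_ns or {}))


def score_harm_cohort(
    cohort: Sequence[ResponseRecord], design: BlockDesign
) -> BwsResult:
    """Full harms pipeline for one cohort: per-set scores, then averaging."""
    by_set: dict = {set_id: [] for set_id in range(1, design.n_blocks + 1)}
    for rec in cohort:
        if rec.harm_set_id is None:
            raise ValidationError(
                f"respondent {rec.respondent_id}: no harm set assigned"
            )
        by_set[rec.harm_set_id].append(rec)
    set_scores = {
        set_id: bws_set_scores(members, design.block_items(set_id), set_id)
        for set_id, members in by_set.items()
    }
    set_ns = {set_id: len(members) for set_id, members in by_set.items()}
    return bws_average(set_scores, design, set_ns=set_ns)


def tally_tradeoff(responses: Sequence[ResponseRecord]) -> TradeoffTally:
    """Counts and proportions of the benefit-vs-harm trade-off answer."""
    answered = [r.tradeoff for r in responses if r.tradeoff is not None]
    if not answered:
        raise ValidationError("no answered trade-off questions")
    counts = {key: answered.count(key) for key in ("benefits", "harms", "equal")}
    n = len(answered)
    proportions = {key: counts[key] / n for key in counts}
    return TradeoffTally(counts=counts, proportions=proportions, n=n)


def group_balance(
    cohort: Sequence[ResponseRecord],
    design: BlockDesign,
    quantile_rule: str = "linear",
    survey_year: int = 2015,
) -> pd.DataFrame:
    """Descriptive comparability of the per-set respondent groups.

    One row per set (n, % female, median/IQR age, median/IQR PPI) plus a
    final ``range`` row giving max − min of each statistic across non-empty
    sets. Empty sets get n = 0 with missing statistics.
    """
    columns = [
        "set_id",
        "n",
        "pct_female",
        "median_age",
        "iqr_age",
        "median_ppi",
        "iqr_ppi",
    ]
    rows = []
    for set_id in range(1, design.n_blocks + 1):
        members = [r for r in cohort if r.harm_set_id == set_id]
        row: dict = {"set_id": str(set_id), "n": len(members)}
        if members:
            genders = [r.gender for r in members if r.gender is not None]
            ages = np.array(
                [survey_year - r.birth_year for r in members if r.birth_year is not None],
                dtype=float,
            )
            ppis = np.array([r.ppi for r in members if r.ppi is not None], dtype=float)
            row["pct_female"] = (
                100.0 * sum(g == "female" for g in genders) / len(genders)
                if genders
                else np.nan
            )
            row["median_age"] = float(np.median(ages)) if ages.size else np.nan
            row["iqr_age"] = (
                _quantile(ages, 75, quantile_rule) - _quantile(ages, 25, quantile_rule)
                if ages.size
                else np.nan
            )
            row["median_ppi"] = float(np.median(ppis)) if ppis.size else np.nan
            row["iqr_ppi"] = (
                _quantile(ppis, 75, quantile_rule) - _quantile(ppis, 25, quantile_rule)
                if ppis.size
                else np.nan
            )
        else:
            row.update(
                {c: np.nan for c in columns if c not in ("set_id", "n")}
            )
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns)
    occupied = df[df["n"] > 0]
    range_row: dict = {"set_id": "range", "n": int(df["n"].max() - df["n"].min())}
    for col in columns[2:]:
        values = occupied[col].dropna()
        range_row[col] = float(values.max() - values.min()) if len(values) else np.nan
    return pd.concat([df, pd.DataFrame([range_row], columns=columns)], ignore_index=True)
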