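"""Inclusion-filter cascade and participant-flow accounting.

Filter order is fixed: qualifying condition → complete demographics
(age, sex, present pain intensity) → ranking completeness. The two ranking
criteria are a disjunction, so the benefit and harm cohorts overlap and the
final included count is the size of their union.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Sequence

import pandas as pd

from .catalog import OutcomeItem, ResponseRecord, benefit_task_items
from .design import BlockDesign
from .errors import ValidationError


@dataclass(frozen=True)
class FlowCounts:
    """Participant counts at each stage of the inclusion cascade."""

    invited: int
    responded: int
    excluded_non_tmj: int
    excluded_missing_demographics: int
    analyzable_base: int
    excluded_incomplete_benefits: int
    benefit_analysis_n: int
    excluded_incomplete_harms: int
    harm_analysis_n: int
    included_final: int

    def __post_init__(self) -> None:
        if self.responded > self.invited:
            raise ValidationError(
                f"responded ({self.responded}) exceeds invited ({self.invited})"
            )
        base = self.responded - self.excluded_non_tmj - self.excluded_missing_demographics
        checks = [
            ("analyzable_base", self.analyzable_base, base),
            (
                "benefit_analysis_n",
                self.benefit_analysis_n,
                self.analyzable_base - self.excluded_incomplete_benefits,
            ),
            (
                "harm_analysis_n",
                self.harm_analysis_n,
                self.analyzable_base - self.excluded_incomplete_harms,
            ),
        ]
        for name, got, expect in checks:
            if got != expect:
                raise ValidationError(f"{name} = {got}, expected {expect}")
        if not 0 <= self.included_final <= self.analyzable_base:
            raise ValidationError(
                f"included_final {self.included_final} outside "
                f"0–{self.analyzable_base}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": f.name, "count": getattr(self, f.name)} for f in fields(self)]
        return pd.DataFrame(rows, columns=["stage", "count"])


def apply_inclusion(
    responses: Sequence[ResponseRecord],
    invited: int,
    catalog: Sequence[OutcomeItem],
    design: Optional[BlockDesign] = None,
) -> tuple[list[ResponseRecord], list[ResponseRecord], FlowCounts]:
    """Split responses into the benefit and harm analysis cohorts.

    Returns ``(benefit_cohort, harm_cohort, flow)``. A record enters the
    benefit cohort with a qualifying condition, complete demographics and a
    complete 7-item benefit ranking; the harm cohort analogously with a
    complete ranking of its assigned harm set. When ``design`` is given,
    harm completeness additionally requires the ranked items to be exactly
    the assigned block.
    """
    if invited < len(responses):
        raise ValidationError(
            f"invited ({invited}) is less than responded ({len(responses)})"
        )
    benefit_ids = benefit_task_items(catalog)

    tmj = [r for r in responses if r.has_tmj_condition]
    with_demo = [r for r in tmj if r.demographics_complete()]

    def harm_complete(rec: ResponseRecord) -> bool:
        if rec.harm_set_id is None:
            return False
        set_items = design.block_items(rec.harm_set_id) if design is not None else None
        return rec.harm_ranking_complete(set_items)

    benefit_cohort = [r for r in with_demo if r.benefit_ranking_complete(benefit_ids)]
    harm_cohort = [r for r in with_demo if harm_complete(r)]
    included_ids = {id(r) for r in benefit_cohort} | {id(r) for r in harm_cohort}

    flow = FlowCounts(
        invited=invited,
        responded=len(responses),
        excluded_non_tmj=len(responses) - len(tmj),
        excluded_missing_demographics=len(tmj) - len(with_demo),
        analyzable_base=len(with_demo),
        excluded_incomplete_benefits=len(with_demo) - len(benefit_cohort),
        benefit_analysis_n=len(benefit_cohort),
        excluded_incomplete_harms=len(with_demo) - len(harm_cohort),
        harm_analysis_n=len(harm_cohort),
        included_final=len(included_ids),
    )
    return benefit_cohort, harm_cohort, flow
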