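"""Synthetic survey respondents with known ground truth.

Rankings are drawn from a Plackett–Luce model: rank position 1 is chosen
with probability proportional to exp(utility) among remaining items, and so
on. Sampling uses the Gumbel-max equivalence (sort utilities perturbed by
i.i.d. Gumbel noise), which is exact and vectorizes across respondents.

Demographics are simulation dressing only — they never feed back into the
utilities — and item-nonresponse is generated by four independent censoring
channels (non-qualifying condition, missing demographics, incomplete
benefit ranking, incomplete harm ranking) so the downstream inclusion
cascade has realistic exclusion categories to count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .catalog import OutcomeItem, ResponseRecord, benefit_task_items
from .design import BlockDesign, assign_set
from .errors import ConsistencyError, ValidationError


@dataclass(frozen=True)
class DemographicsModel:
    """Marginal distributions for the descriptive respondent columns."""

    proportion_female: float = 0.92
    age_median: float = 52.0
    age_iqr: float = 8.0
    ppi_scale_max: int = 10
    ppi_mean_fraction: float = 0.42  # binomial p; median 4 on a 0–10 scale
    comorbid_pain_mean: float = 3.0
    current_med_mean: float = 3.0
    past_med_mean: float = 6.0
    survey_year: int = 2015


@dataclass(frozen=True)
class MissingnessModel:
    """Independent censoring probabilities, one per exclusion category."""

    p_missing_demographics: float = 0.0
    p_incomplete_benefits: float = 0.0
    p_incomplete_harms: float = 0.0
    p_non_tmj: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "p_missing_demographics",
            "p_incomplete_benefits",
            "p_incomplete_harms",
            "p_non_tmj",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} = {p} outside [0, 1]")


@dataclass(frozen=True)
class PreferenceModel:
    """Latent log-worth utilities plus demographic and missingness settings."""

    utilities: Mapping[str, float]
    demographics: DemographicsModel = field(default_factory=DemographicsModel)
    missingness: MissingnessModel = field(default_factory=MissingnessModel)
    tradeoff_probs: tuple = (0.60, 0.28, 0.12)

    def __post_init__(self) -> None:
        for item, u in self.utilities.items():
            if not np.isfinite(u):
                raise ValidationError(f"utility for {item!r} is not finite: {u}")
        if abs(sum(self.tradeoff_probs) - 1.0) > 1e-9 or any(
            p < 0 for p in self.tradeoff_probs
        ):
            raise ValidationError(
                f"tradeoff_probs must be a probability vector, got {self.tradeoff_probs}"
            )

    @classmethod
    def for_catalog(
        cls,
        catalog: Sequence[OutcomeItem],
        default_utility: float = 0.0,
        overrides: Optional[Mapping[str, float]] = None,
        **kwargs,
    ) -> "PreferenceModel":
        utilities = {it.item_id: default_utility for it in catalog}
        for item, u in (overrides or {}).items():
            if item not in utilities:
                raise ConsistencyError(f"override for unknown item {item!r}")
            utilities[item] = u
        return cls(utilities=utilities, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PreferenceModel":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PreferenceModel":
        utilities = {str(k): float(v) for k, v in (raw.get("utilities") or {}).items()}
        demo = DemographicsModel(**(raw.get("demographics") or {}))
        miss = MissingnessModel(**(raw.get("missingness") or {}))
        probs = tuple(raw.get("tradeoff_probs", (0.60, 0.28, 0.12)))
        return cls(
            utilities=utilities,
            demographics=demo,
            missingness=miss,
            tradeoff_probs=probs,
        )

    def with_missingness(self, **kwargs) -> "PreferenceModel":
        return replace(self, missingness=replace(self.missingness, **kwargs))


def sample_ranking(utilities: Mapping[str, float], rng: np.random.Generator) -> dict:
    """Draw one complete Plackett–Luce ranking (1 = first choice)."""
    if not utilities:
        raise ValidationError("cannot rank an empty item set")
    items = list(utilities)
    u = np.asarray([utilities[i] for i in items], dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValidationError("utilities must be finite")
    ranks = _rank_matrix(u, 1, rng)[0]
    return {item: int(r) for item, r in zip(items, ranks)}


def _rank_matrix(u: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n Plackett–Luce rankings of k items: entry (r, j) = rank of item j."""
    perturbed = u[None, :] + rng.gumbel(size=(n, len(u)))
    order = np.argsort(-perturbed, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, len(u) + 1)[None, :], axis=1)
    return ranks


def simulate_survey(
    model: PreferenceModel,
    catalog: Sequence[OutcomeItem],
    design: BlockDesign,
    n: int,
    seed: int,
) -> list[ResponseRecord]:
    """Generate ``n`` respondents; same seed → identical table.

    Each respondent draws a uniform birth month, is assigned a harm set via
    :func:`~bwsurvey.design.assign_set`, ranks the 7 benefit-task items and
    the 7 harms of their set under the Plackett–Luce model, then passes
    through the independent censoring channels.
    """
    if n < 0:
        raise ValidationError("n must be nonnegative")
    benefit_ids = benefit_task_items(catalog)
    catalog_ids = {it.item_id for it in catalog}
    for item in design.items:
        if item not in catalog_ids:
            raise ConsistencyError(f"design item {item!r} not in catalog")
    missing_utils = [
        i for i in list(benefit_ids) + list(design.items) if i not in model.utilities
    ]
    if missing_utils:
        raise ConsistencyError(f"model lacks utilities for items: {missing_utils}")
    if n == 0:
        return []

    rng = np.random.default_rng(seed)
    demo, miss = model.demographics, model.missingness

    months = rng.integers(1, 13, size=n)
    set_ids = np.array([assign_set(int(m), design.n_blocks) for m in months])

    # demographics
    age_sd = demo.age_iqr / 1.349 if demo.age_iqr > 0 else 0.0  # IQR of a normal
    ages = np.clip(np.rint(rng.normal(demo.age_median, age_sd, size=n)), 18, 95)
    birth_years = (demo.survey_year - ages).astype(int)
    female = rng.random(n) < demo.proportion_female
    ppi = rng.binomial(demo.ppi_scale_max, demo.ppi_mean_fraction, size=n)
    comorbid = rng.poisson(demo.comorbid_pain_mean, size=n)
    current_meds = rng.poisson(demo.current_med_mean, size=n)
    past_meds = rng.poisson(demo.past_med_mean, size=n)
    tradeoffs = rng.choice(
        np.array(["benefits", "harms", "equal"]), size=n, p=list(model.tradeoff_probs)
    )

    # rankings
    u_benefit = np.array([model.utilities[i] for i in benefit_ids], dtype=float)
    benefit_rank_rows = _rank_matrix(u_benefit, n, rng)
    harm_rank_maps: list[dict] = [{} for _ in range(n)]
    for set_id in range(1, design.n_blocks + 1):
        members = design.block_items(set_id)
        rows = np.flatnonzero(set_ids == set_id)
        if rows.size == 0:
            continue
        u_set = np.array([model.utilities[i] for i in members], dtype=float)
        ranks = _rank_matrix(u_set, rows.size, rng)
        for r, row in enumerate(rows):
            harm_rank_maps[row] = {
                item: int(ranks[r, c]) for c, item in enumerate(members)
            }

    # censoring channels (independent)
    non_tmj = rng.random(n) < miss.p_non_tmj
    drop_demo = rng.random(n) < miss.p_missing_demographics
    which_demo = rng.integers(0, 3, size=n)  # birth_year | gender | ppi
    drop_benefit = rng.random(n) < miss.p_incomplete_benefits
    benefit_drop_idx = rng.integers(0, len(benefit_ids), size=n)
    drop_harm = rng.random(n) < miss.p_incomplete_harms
    harm_drop_idx = rng.integers(0, design.block_size, size=n)

    records: list[ResponseRecord] = []
    for r in range(n):
        benefit_ranks = {
            item: int(benefit_rank_rows[r, c]) for c, item in enumerate(benefit_ids)
        }
        if drop_benefit[r]:
            del benefit_ranks[benefit_ids[benefit_drop_idx[r]]]
        harm_ranks = harm_rank_maps[r]
        if drop_harm[r]:
            dropped = design.block_items(int(set_ids[r]))[harm_drop_idx[r]]
            harm_ranks = {k: v for k, v in harm_ranks.items() if k != dropped}
        rec = ResponseRecord(
            respondent_id=f"r{r + 1:06d}",
            birth_year=int(birth_years[r]),
            birth_month=int(months[r]),
            gender="female" if female[r] else "male",
            has_tmj_condition=not non_tmj[r],
            ppi=int(ppi[r]),
            comorbid_pain_count=int(comorbid[r]),
            current_med_count=int(current_meds[r]),
            past_med_count=int(past_meds[r]),
            benefit_ranks=benefit_ranks,
            harm_set_id=int(set_ids[r]),
            harm_ranks=harm_ranks,
            tradeoff=str(tradeoffs[r]),
        )
        if drop_demo[r]:
            if which_demo[r] == 0:
                rec.birth_year = None
            elif which_demo[r] == 1:
                rec.gender = None
            else:
                rec.ppi = None
        records.append(rec)
    return records
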