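"""Parameter-recovery diagnostics for the blocked best-worst pipeline.

Simulates respondents from a known preference model, runs the full
filter → score chain, and measures how well the final BWS ordering recovers
the true (descending-utility) ordering via Kendall's tau.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import OutcomeItem
from .design import BlockDesign
from .errors import BwsurveyError, ConsistencyError, ValidationError
from .filters import apply_inclusion
from .scoring import score_harm_cohort
from .simulate import PreferenceModel, simulate_survey


@dataclass(frozen=True)
class RecoveryReport:
    """Per-replicate tau values and per-n aggregates."""

    replicates: pd.DataFrame  # columns: n, replicate, kendall_tau, top_item_correct
    summary: pd.DataFrame  # columns: n, reps, mean_tau, frac_perfect


def kendall_tau(order_a: Sequence[str], order_b: Sequence[str]) -> float:
    """Rank correlation between two tie-free orderings of the same items.

    Computed as 1 − 2·(discordant pairs)/C(m, 2).
    """
    if set(order_a) != set(order_b) or len(set(order_a)) != len(order_a):
        raise ValidationError("orderings must be permutations of the same item set")
    m = len(order_a)
    if m < 2:
        raise ValidationError("need at least two items")
    pos_b = {item: i for i, item in enumerate(order_b)}
    discordant = sum(
        1
        for x, y in combinations(order_a, 2)  # x before y in order_a
        if pos_b[x] > pos_b[y]
    )
    return 1.0 - 2.0 * discordant / (m * (m - 1) / 2)


def true_ordering(utilities: Mapping[str, float], items: Sequence[str]) -> list[str]:
    """Descending latent utility, ties broken by item_id (the scorer's rule)."""
    return sorted(items, key=lambda it: (-utilities[it], it))


def recovery_experiment(
    model: PreferenceModel,
    design: BlockDesign,
    catalog: Sequence[OutcomeItem],
    ns: Sequence[int],
    reps: int,
    seed: int,
    invited_factor: int = 2,
) -> RecoveryReport:
    """Measure ordering recovery across sample sizes and replicates.

    Fully seeded: replicate (n, r) draws from an independent child stream of
    ``seed``, so reports are reproducible and incremental.
    """
    for item in design.items:
        if item not in model.utilities:
            raise ConsistencyError(f"model lacks a utility for design item {item!r}")
    truth = true_ordering(model.utilities, design.items)
    root = np.random.SeedSequence(seed)
    rows = []
    for n_idx, n in enumerate(ns):
        for rep in range(reps):
            child = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(n_idx, rep)
            )
            rep_seed = int(child.generate_state(1)[0])
            try:
                responses = simulate_survey(model, catalog, design, n, rep_seed)
                _, harm_cohort, _ = apply_inclusion(
                    responses, invited_factor * n, catalog, design
                )
                result = score_harm_cohort(harm_cohort, design)
                tau = kendall_tau(truth, result.ordering())
                top_ok = result.ordering()[0] == truth[0]
            except BwsurveyError as exc:
                raise BwsurveyError(
                    f"recovery replicate (n={n}, rep={rep}) failed: {exc}"
                ) from exc
            rows.append(
                {
                    "n": n,
                    "replicate": rep,
                    "kendall_tau": tau,
                    "top_item_correct": top_ok,
                }
            )
    replicates = pd.DataFrame(
        rows, columns=["n", "replicate", "kendall_tau", "top_item_correct"]
    )
    summary = (
        replicates.groupby("n")
        .agg(
            reps=("replicate", "size"),
            mean_tau=("kendall_tau", "mean"),
            frac_perfect=("kendall_tau", lambda t: float(np.mean(t == 1.0))),
        )
        .reset_index()
    )
    return RecoveryReport(replicates=replicates, summary=summary)
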