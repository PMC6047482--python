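"""End-to-end pipeline: design → simulate/ingest → filter → score → report."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .catalog import (
    default_catalog,
    harm_item_ids,
    load_catalog,
    read_responses,
    write_responses,
    write_table,
)
from .design import generate_design, load_design, save_design
from .errors import BwsurveyError, ValidationError
from .filters import apply_inclusion
from .scoring import (
    group_balance,
    score_harm_cohort,
    summarize_benefits,
    tally_tradeoff,
)
from .simulate import PreferenceModel, simulate_survey

log = logging.getLogger("bwsurvey")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; loadable from a single YAML file."""

    out_dir: Path
    seed: int = 0
    mode: str = "simulate"  # simulate | ingest
    n: int = 746
    invited: int = 4130
    n_items: int = 21
    n_blocks: int = 12
    block_size: int = 7
    catalog_path: Optional[Path] = None
    design_path: Optional[Path] = None  # pre-built design to load instead of generating
    responses_path: Optional[Path] = None  # required in ingest mode
    quantile_rule: str = "linear"
    model: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        design_block = raw.pop("design", {}) or {}
        raw.update({k: v for k, v in design_block.items() if k in
                    ("n_items", "n_blocks", "block_size")})
        for key in ("catalog_path", "design_path", "responses_path", "out_dir"):
            if raw.get(key):
                raw[key] = Path(raw[key])
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "out_dir" not in raw:
            raise ValidationError("pipeline config must set out_dir")
        return cls(**raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the artifact CSVs plus report.md.

    Returns a dict of the in-memory results. Outputs are deterministic for
    a fixed config (provenance headers carry version, seed and input
    digests, never timestamps).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.catalog_path is not None:
        catalog = load_catalog(config.catalog_path)
    else:
        catalog = default_catalog()
    harms = harm_item_ids(catalog)

    provenance = {"generator": f"bwsurvey {__version__}", "seed": config.seed}
    if config.catalog_path is not None:
        provenance["catalog_sha256"] = _digest(Path(config.catalog_path))

    # stage: design
    if config.design_path is not None:
        design = load_design(config.design_path, item_order=harms)
        provenance["design_sha256"] = _digest(Path(config.design_path))
    else:
        design = generate_design(
            config.n_items,
            config.n_blocks,
            config.block_size,
            config.seed,
            item_ids=harms[: config.n_items],
        )
    save_design(design, out / "design.csv")
    log.info("design: %d items in %d blocks of %d", design.n_items,
             design.n_blocks, design.block_size)

    # stage: simulate or ingest
    if config.mode == "simulate":
        model = PreferenceModel.from_dict(config.model) if config.model else None
        if model is None or not model.utilities:
            model = PreferenceModel.for_catalog(catalog)
        responses = simulate_survey(model, catalog, design, config.n, config.seed)
        write_responses(responses, out / "responses.csv", catalog)
    elif config.mode == "ingest":
        if config.responses_path is None:
            raise ValidationError("ingest mode requires responses_path")
        path = Path(config.responses_path)
        if not path.exists():
            raise ValidationError(f"responses file not found: {path}")
        provenance["responses_sha256"] = _digest(path)
        responses = read_responses(path, catalog, n_sets=design.n_blocks)
    else:
        raise ValidationError(f"unknown mode {config.mode!r}")
    log.info("responses: %d records", len(responses))

    # stage: filter
    benefit_cohort, harm_cohort, flow = apply_inclusion(
        responses, config.invited, catalog, design
    )
    write_table(flow.to_frame(), out / "flow.csv", provenance)
    write_responses(benefit_cohort, out / "benefit_cohort.csv", catalog)
    write_responses(harm_cohort, out / "harm_cohort.csv", catalog)
    log.info("filter: benefit cohort %d, harm cohort %d, included %d",
             flow.benefit_analysis_n, flow.harm_analysis_n, flow.included_final)

    # stage: score
    benefits = summarize_benefits(benefit_cohort, catalog, config.quantile_rule)
    write_table(benefits.table, out / "benefits_summary.csv", provenance)
    bws = score_harm_cohort(harm_cohort, design)
    write_table(bws.to_frame(), out / "bws.csv", provenance)
    write_table(bws.by_set_frame(), out / "bws_by_set.csv", provenance)
    tradeoff = tally_tradeoff(responses)
    write_table(tradeoff.to_frame(), out / "tradeoff.csv", provenance)
    balance = group_balance(harm_cohort, design, config.quantile_rule)
    write_table(balance, out / "balance.csv", provenance)

    # stage: report
    report = render_report(flow, benefits, bws, tradeoff, catalog)
    (out / "report.md").write_text(report, encoding="utf-8")
    return {
        "catalog": catalog,
        "design": design,
        "responses": responses,
        "benefit_cohort": benefit_cohort,
        "harm_cohort": harm_cohort,
        "flow": flow,
        "benefits": benefits,
        "bws": bws,
        "tradeoff": tradeoff,
        "balance": balance,
    }


def render_report(flow, benefits, bws, tradeoff, catalog) -> str:
    labels = {it.item_id: it.label for it in catalog}
    lines = ["# Outcome prioritization report", "", "## Participant flow", ""]
    lines += ["| stage | count |", "| --- | --- |"]
    for _, row in flow.to_frame().iterrows():
        lines.append(f"| {row['stage']} | {row['count']} |")
    lines += ["", "## Benefit ranking (best first)", ""]
    lines += ["| rank | item | median | IQR |", "| --- | --- | --- | --- |"]
    for pos, (_, row) in enumerate(benefits.table.iterrows(), start=1):
        lines.append(
            f"| {pos} | {labels.get(row['item_id'], row['item_id'])} "
            f"| {row['median_rank']:g} | {row['iqr']:g} |"
        )
    lines += ["", "## Harm ordering by averaged BWS score", ""]
    lines += ["| rank | item | BWS score |", "| --- | --- | --- |"]
    for it in bws.items:
        lines.append(
            f"| {it.final_rank} | {labels.get(it.item_id, it.item_id)} "
            f"| {it.averaged_score:+.3f} |"
        )
    lines += ["", "## Benefit vs harm trade-off", ""]
    lines += ["| answer | count | proportion |", "| --- | --- | --- |"]
    for _, row in tradeoff.to_frame().iterrows():
        lines.append(
            f"| {row['answer']} | {row['count']} | {row['proportion']:.3f} |"
        )
    lines.append("")
    return "\n".join(lines)
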