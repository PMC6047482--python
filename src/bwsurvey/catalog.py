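"""Outcome catalog and survey response tables: domain types and CSV I/O.

This module defines the on-disk schema every other stage consumes:

* the outcome catalog, ``item_id,label,kind`` CSV;
* the response table, one row per respondent with demographics columns and
  one ``rank_<item_id>`` column per catalog item.

Missing values are empty cells, never sentinel numbers, so bijection checks
on rankings stay meaningful.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

KINDS = ("benefit", "harm", "side_effects_aggregate")

#: Trade-off answer vocabulary: which side weighs more in the treatment decision.
TRADEOFF_VALUES = ("benefits", "harms", "equal")

_ID_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")

#: Demographic / bookkeeping columns of the response table, in write order.
RESPONSE_COLUMNS = (
    "respondent_id",
    "birth_year",
    "birth_month",
    "gender",
    "has_tmj",
    "ppi",
    "comorbid_pain_count",
    "current_med_count",
    "past_med_count",
    "harm_set_id",
    "tradeoff",
)


@dataclass(frozen=True)
class OutcomeItem:
    """One outcome domain a respondent may rank.

    Parameters
    ----------
    item_id
        Short stable token, unique within a catalog.
    label
        Free-text description shown to respondents.
    kind
        One of ``benefit``, ``harm`` or ``side_effects_aggregate`` (the
        single item standing in for all harms on the benefits task).
    """

    item_id: str
    label: str
    kind: str

    def __post_init__(self) -> None:
        if not _ID_RE.match(self.item_id):
            raise SchemaError(f"invalid item_id token: {self.item_id!r}")
        if self.kind not in KINDS:
            raise SchemaError(
                f"unknown kind {self.kind!r} for item {self.item_id!r}; "
                f"expected one of {KINDS}"
            )


@dataclass
class ResponseRecord:
    """One respondent: demographics, rankings and the trade-off answer.

    Rankings are stored exactly as given (1 = most affects the decision);
    a ranking may be partial, and completeness is a property of the record,
    never a silent repair.
    """

    respondent_id: str
    birth_year: Optional[int] = None
    birth_month: Optional[int] = None
    gender: Optional[str] = None
    has_tmj_condition: Optional[bool] = None
    ppi: Optional[int] = None
    comorbid_pain_count: Optional[int] = None
    current_med_count: Optional[int] = None
    past_med_count: Optional[int] = None
    benefit_ranks: dict = field(default_factory=dict)
    harm_set_id: Optional[int] = None
    harm_ranks: dict = field(default_factory=dict)
    tradeoff: Optional[str] = None

    def demographics_complete(self) -> bool:
        """Age (birth year), sex and present-pain-intensity all reported."""
        return (
            self.birth_year is not None
            and self.gender is not None
            and self.ppi is not None
        )

    def benefit_ranking_complete(self, benefit_items: Sequence[str]) -> bool:
        """True when ``benefit_ranks`` is a bijection onto 1..k over ``benefit_items``."""
        return _is_complete_ranking(self.benefit_ranks, benefit_items)

    def harm_ranking_complete(self, set_items: Optional[Sequence[str]] = None) -> bool:
        """True when ``harm_ranks`` bijectively ranks its 7-item set.

        When ``set_items`` is given (the block assigned to this respondent)
        the ranked items must be exactly that set; otherwise any 7 distinct
        items with ranks covering 1..7 count as complete.
        """
        if set_items is not None:
            return _is_complete_ranking(self.harm_ranks, set_items)
        k = len(self.harm_ranks)
        return k > 0 and sorted(self.harm_ranks.values()) == list(range(1, k + 1))


def _is_complete_ranking(ranks: Mapping[str, int], items: Sequence[str]) -> bool:
    if set(ranks) != set(items):
        return False
    return sorted(ranks.values()) == list(range(1, len(items) + 1))


# ---------------------------------------------------------------------------
# catalog I/O

def _parse_catalog(df: pd.DataFrame, source: str) -> list[OutcomeItem]:
    expected = ["item_id", "label", "kind"]
    if list(df.columns) != expected:
        raise SchemaError(
            f"{source}: catalog header must be {','.join(expected)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    items = [
        OutcomeItem(str(r.item_id), str(r.label), str(r.kind))
        for r in df.itertuples(index=False)
    ]
    dupes = [i for i, c in Counter(it.item_id for it in items).items() if c > 1]
    if dupes:
        raise SchemaError(f"{source}: duplicate item_id(s): {sorted(dupes)}")
    return items


def load_catalog(path) -> list[OutcomeItem]:
    """Read an outcome catalog CSV and validate it.

    Raises
    ------
    SchemaError
        On a bad header, duplicate ``item_id`` or unknown ``kind`` token.
    """
    df = pd.read_csv(path, dtype=str, comment="#", keep_default_na=False)
    return _parse_catalog(df, str(path))


def default_catalog() -> list[OutcomeItem]:
    """The packaged catalog: 6 benefits, 1 side-effects aggregate, 21 harms."""
    text = resources.files("bwsurvey").joinpath("data/default_catalog.csv").read_text()
    df = pd.read_csv(StringIO(text), dtype=str, keep_default_na=False)
    return _parse_catalog(df, "packaged default catalog")


def catalog_counts(catalog: Iterable[OutcomeItem]) -> dict:
    counts = Counter(it.kind for it in catalog)
    return {kind: counts.get(kind, 0) for kind in KINDS}


def benefit_task_items(catalog: Iterable[OutcomeItem]) -> list[str]:
    """Item ids of the benefits ranking task (benefits + the aggregate), catalog order."""
    return [
        it.item_id
        for it in catalog
        if it.kind in ("benefit", "side_effects_aggregate")
    ]


def harm_item_ids(catalog: Iterable[OutcomeItem]) -> list[str]:
    return [it.item_id for it in catalog if it.kind == "harm"]


# ---------------------------------------------------------------------------
# response-table I/O

def _parse_opt_int(token: str, *, row: int, column: str) -> Optional[int]:
    if token == "":
        return None
    try:
        return int(token)
    except ValueError:
        raise ValidationError(
            f"row {row}: column {column!r} has non-integer value {token!r}"
        ) from None


def _parse_opt_bool(token: str, *, row: int, column: str) -> Optional[bool]:
    if token == "":
        return None
    low = token.strip().lower()
    if low in ("1", "true", "yes"):
        return True
    if low in ("0", "false", "no"):
        return False
    raise ValidationError(f"row {row}: column {column!r} has non-boolean value {token!r}")


def _collect_ranks(
    row: pd.Series, item_ids: Sequence[str], *, row_no: int, task: str, max_rank: int
) -> dict:
    ranks: dict = {}
    for item_id in item_ids:
        col = f"rank_{item_id}"
        if col not in row.index:
            continue
        token = row[col]
        if token == "":
            continue
        value = _parse_opt_int(token, row=row_no, column=col)
        if not 1 <= value <= max_rank:
            raise ValidationError(
                f"row {row_no}: {task} rank for {item_id!r} is {value}, "
                f"outside 1–{max_rank}"
            )
        ranks[item_id] = value
    dup_ranks = [v for v, c in Counter(ranks.values()).items() if c > 1]
    if dup_ranks:
        raise ValidationError(
            f"row {row_no}: duplicate {task} rank(s) {sorted(dup_ranks)} "
            f"assigned to more than one item"
        )
    return ranks


def read_responses(
    path,
    catalog: Sequence[OutcomeItem],
    *,
    ppi_bounds: tuple[int, int] = (0, 10),
    n_sets: int = 12,
) -> list[ResponseRecord]:
    """Read and validate a survey response table.

    Rankings are validated as partial or complete — out-of-range ranks and
    duplicated ranks raise :class:`ValidationError` naming the row; nothing
    is coerced. The number of records returned always equals the number of
    data rows in the file.
    """
    df = pd.read_csv(path, dtype=str, comment="#", keep_default_na=False)
    if "respondent_id" not in df.columns:
        raise SchemaError(f"{path}: response table must have a respondent_id column")
    benefit_ids = benefit_task_items(catalog)
    harm_ids = harm_item_ids(catalog)

    records: list[ResponseRecord] = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=1):
        def col(name: str) -> str:
            return str(row[name]) if name in row.index else ""

        gender = col("gender") or None
        tradeoff = col("tradeoff") or None
        if tradeoff is not None and tradeoff not in TRADEOFF_VALUES:
            raise ValidationError(
                f"row {row_no}: tradeoff {tradeoff!r} not in {TRADEOFF_VALUES}"
            )
        ppi = _parse_opt_int(col("ppi"), row=row_no, column="ppi")
        if ppi is not None and not ppi_bounds[0] <= ppi <= ppi_bounds[1]:
            raise ValidationError(
                f"row {row_no}: ppi {ppi} outside scale {ppi_bounds}"
            )
        birth_month = _parse_opt_int(col("birth_month"), row=row_no, column="birth_month")
        if birth_month is not None and not 1 <= birth_month <= 12:
            raise ValidationError(f"row {row_no}: birth_month {birth_month} outside 1–12")
        harm_set_id = _parse_opt_int(col("harm_set_id"), row=row_no, column="harm_set_id")
        if harm_set_id is not None and not 1 <= harm_set_id <= n_sets:
            raise ValidationError(
                f"row {row_no}: harm_set_id {harm_set_id} outside 1–{n_sets}"
            )

        record = ResponseRecord(
            respondent_id=col("respondent_id"),
            birth_year=_parse_opt_int(col("birth_year"), row=row_no, column="birth_year"),
            birth_month=birth_month,
            gender=gender,
            has_tmj_condition=_parse_opt_bool(col("has_tmj"), row=row_no, column="has_tmj"),
            ppi=ppi,
            comorbid_pain_count=_parse_opt_int(
                col("comorbid_pain_count"), row=row_no, column="comorbid_pain_count"
            ),
            current_med_count=_parse_opt_int(
                col("current_med_count"), row=row_no, column="current_med_count"
            ),
            past_med_count=_parse_opt_int(
                col("past_med_count"), row=row_no, column="past_med_count"
            ),
            benefit_ranks=_collect_ranks(
                row, benefit_ids, row_no=row_no, task="benefit", max_rank=len(benefit_ids)
            ),
            harm_set_id=harm_set_id,
            harm_ranks=_collect_ranks(row, harm_ids, row_no=row_no, task="harm", max_rank=7),
            tradeoff=tradeoff,
        )
        records.append(record)
    return records


def responses_to_frame(
    records: Sequence[ResponseRecord], catalog: Sequence[OutcomeItem]
) -> pd.DataFrame:
    """Flatten records into the deterministic on-disk column layout."""
    rank_cols = [f"rank_{i}" for i in benefit_task_items(catalog)] + [
        f"rank_{i}" for i in harm_item_ids(catalog)
    ]

    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, bool):
            return "1" if value else "0"
        return str(value)

    rows = []
    for rec in records:
        row = {
            "respondent_id": fmt(rec.respondent_id),
            "birth_year": fmt(rec.birth_year),
            "birth_month": fmt(rec.birth_month),
            "gender": fmt(rec.gender),
            "has_tmj": fmt(rec.has_tmj_condition),
            "ppi": fmt(rec.ppi),
            "comorbid_pain_count": fmt(rec.comorbid_pain_count),
            "current_med_count": fmt(rec.current_med_count),
            "past_med_count": fmt(rec.past_med_count),
            "harm_set_id": fmt(rec.harm_set_id),
            "tradeoff": fmt(rec.tradeoff),
        }
        ranks = {**rec.benefit_ranks, **rec.harm_ranks}
        for col in rank_cols:
            item = col[len("rank_"):]
            row[col] = fmt(ranks.get(item))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(RESPONSE_COLUMNS) + rank_cols, dtype=str)


def write_responses(records, path, catalog) -> None:
    write_table(responses_to_frame(records, catalog), path)


def write_table(rows: pd.DataFrame, path, provenance: Optional[Mapping] = None) -> None:
    """Write a result table as UTF-8 CSV with LF line endings.

    ``provenance``, when given, is emitted as ``# key: value`` comment lines
    above the header; readers in this package skip them.
    """
    if rows is None:
        raise ValidationError("rows must not be None")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}: {value}\n")
        rows.to_csv(fh, index=False, lineterminator="\n")
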