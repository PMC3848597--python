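"""Plain-CSV interfaces: product catalogue, survey records, exclusion log.

Header contract for ``survey.csv`` (one row per outlet x product):

    outlet_id, outlet_level, outlet_type, product_id,
    stock1_packs, stock1_loose, stock1_tin_height, stock1_tin_height_full,
    stock1_tin_units_full, stock1_counted_flag, stock1_status,
    stock2_... (same layout),
    delivered_units, delivered_status,
    disposed_units, disposed_status,
    rc_sold_units, rc_status

Each ``*_status`` column is ``ok`` or one of the nonresponse codes
(``refused``, ``not_remembered``, ``missing``).  A status of ``ok`` with the
corresponding numeric fields blank is a hard validation error; with a
non-``ok`` status, numeric fields are ignored.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Sequence, Union

import pandas as pd

from .audit import STATUS_CODES, ExclusionRecord, SurveyRecord
from .products import Category, Form, ProductSpec, QuantityObservation

__all__ = [
    "read_products_csv", "write_products_csv",
    "read_survey_csv", "write_survey_csv",
    "write_exclusions_csv",
]

PathLike = Union[str, Path]

SURVEY_COLUMNS = [
    "outlet_id", "outlet_level", "outlet_type", "product_id",
    "stock1_packs", "stock1_loose", "stock1_tin_height", "stock1_tin_height_full",
    "stock1_tin_units_full", "stock1_counted_flag", "stock1_status",
    "stock2_packs", "stock2_loose", "stock2_tin_height", "stock2_tin_height_full",
    "stock2_tin_units_full", "stock2_counted_flag", "stock2_status",
    "delivered_units", "delivered_status",
    "disposed_units", "disposed_status",
    "rc_sold_units", "rc_status",
]


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == ""


def write_products_csv(specs: Sequence[ProductSpec], path: PathLike) -> None:
    rows = [
        {
            "product_id": s.product_id,
            "category": s.category.value,
            "drug_name": s.drug_name,
            "strength_mg": s.strength_mg,
            "form": s.form.value,
            "pack_size": s.pack_size,
            "units_per_aetd": s.units_per_aetd,
        }
        for s in specs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_products_csv(path: PathLike) -> Dict[str, ProductSpec]:
    """Load the catalogue; a blank ``units_per_aetd`` marks an anti-malarial
    as AETD-incomputable."""
    df = pd.read_csv(path)
    specs: Dict[str, ProductSpec] = {}
    for row in df.itertuples(index=False):
        spec = ProductSpec(
            product_id=str(row.product_id),
            category=Category(row.category),
            drug_name=str(row.drug_name),
            form=Form(row.form),
            pack_size=int(row.pack_size),
            strength_mg=None if _is_blank(row.strength_mg) else float(row.strength_mg),
            units_per_aetd=None if _is_blank(row.units_per_aetd) else float(row.units_per_aetd),
        )
        if spec.product_id in specs:
            raise ValueError(f"duplicate product_id {spec.product_id!r} in {path}")
        specs[spec.product_id] = spec
    return specs


def _stock_columns(prefix: str, value) -> dict:
    cols = {
        f"{prefix}_packs": "", f"{prefix}_loose": "",
        f"{prefix}_tin_height": "", f"{prefix}_tin_height_full": "",
        f"{prefix}_tin_units_full": "", f"{prefix}_counted_flag": "",
        f"{prefix}_status": "ok",
    }
    if isinstance(value, str):
        cols[f"{prefix}_status"] = value
        return cols
    obs: QuantityObservation = value
    cols[f"{prefix}_packs"] = obs.full_packs
    cols[f"{prefix}_loose"] = obs.loose_units
    cols[f"{prefix}_counted_flag"] = obs.counted_flag
    if obs.has_tin:
        cols[f"{prefix}_tin_height"] = obs.tin_height_measured
        cols[f"{prefix}_tin_height_full"] = obs.tin_height_full
        cols[f"{prefix}_tin_units_full"] = obs.tin_units_full
    return cols


def _count_columns(name: str, value) -> dict:
    if isinstance(value, str):
        return {f"{name}_units" if name != "rc_sold" else "rc_sold_units": "",
                f"{name}_status" if name != "rc_sold" else "rc_status": value}
    return {f"{name}_units" if name != "rc_sold" else "rc_sold_units": value,
            f"{name}_status" if name != "rc_sold" else "rc_status": "ok"}


def write_survey_csv(records: Sequence[SurveyRecord], path: PathLike) -> None:
    rows = []
    for rec in records:
        row = {
            "outlet_id": rec.outlet_id, "outlet_level": rec.outlet_level,
            "outlet_type": rec.outlet_type, "product_id": rec.product_id,
        }
        row.update(_stock_columns("stock1", rec.stock_sls1))
        row.update(_stock_columns("stock2", rec.stock_sls2))
        row.update(_count_columns("delivered", rec.delivered))
        row.update(_count_columns("disposed", rec.disposed))
        row.update(_count_columns("rc_sold", rec.rc_sold))
        rows.append(row)
    pd.DataFrame(rows, columns=SURVEY_COLUMNS).to_csv(path, index=False)


def _parse_status(raw, column: str, context: str) -> str:
    if _is_blank(raw):
        raise ValueError(f"{context}: {column} must be 'ok' or a status code, got blank")
    raw = str(raw)
    if raw == "ok":
        return raw
    if raw not in STATUS_CODES:
        raise ValueError(f"{context}: unknown status {raw!r} in {column}")
    return raw


def _parse_stock(row, prefix: str, context: str):
    status = _parse_status(getattr(row, f"{prefix}_status"), f"{prefix}_status", context)
    if status != "ok":
        return status
    packs = getattr(row, f"{prefix}_packs")
    loose = getattr(row, f"{prefix}_loose")
    if _is_blank(packs) or _is_blank(loose):
        raise ValueError(
            f"{context}: {prefix} has status 'ok' but missing pack/loose counts"
        )
    tin_h = getattr(row, f"{prefix}_tin_height")
    flag = getattr(row, f"{prefix}_counted_flag")
    kwargs = dict(
        full_packs=float(packs), loose_units=float(loose),
        counted_flag="counted" if _is_blank(flag) else str(flag),
    )
    if not _is_blank(tin_h):
        kwargs.update(
            tin_height_measured=float(tin_h),
            tin_height_full=float(getattr(row, f"{prefix}_tin_height_full")),
            tin_units_full=int(float(getattr(row, f"{prefix}_tin_units_full"))),
        )
    return QuantityObservation(**kwargs)


def _parse_count(row, value_col: str, status_col: str, context: str):
    status = _parse_status(getattr(row, status_col), status_col, context)
    if status != "ok":
        return status
    value = getattr(row, value_col)
    if _is_blank(value):
        raise ValueError(f"{context}: {value_col} has status 'ok' but no value")
    return float(value)


def read_survey_csv(path: PathLike) -> List[SurveyRecord]:
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing survey columns {missing}")
    records: List[SurveyRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        context = f"{path} row {idx + 2}"  # 1-based + header
        records.append(SurveyRecord(
            outlet_id=str(row.outlet_id),
            outlet_level=str(row.outlet_level),
            outlet_type=str(row.outlet_type),
            product_id=str(row.product_id),
            stock_sls1=_parse_stock(row, "stock1", context),
            stock_sls2=_parse_stock(row, "stock2", context),
            delivered=_parse_count(row, "delivered_units", "delivered_status", context),
            disposed=_parse_count(row, "disposed_units", "disposed_status", context),
            rc_sold=_parse_count(row, "rc_sold_units", "rc_status", context),
        ))
    return records


def write_exclusions_csv(exclusions: Sequence[ExclusionRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            {"outlet_id": e.outlet_id, "product_id": e.product_id,
             "reason": e.reason, "detail": e.detail}
            for e in exclusions
        ],
        columns=["outlet_id", "product_id", "reason", "detail"],
    ).to_csv(path, index=False)
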