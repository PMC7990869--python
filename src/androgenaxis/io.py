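"""CSV dialect for cohort tables and report serialisation helpers.

Input CSV header::

    id,age,bmi,hiv_duration,cart_duration,cd4_nadir,cd4_nadir_pct,
    symptomatic,tt_ngml,shbg_nmoll,lh_miuml,albumin_gdl

Missing values are empty cells.  The classification output adds the derived
``cft_pgml`` and the per-step calls and flags.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifiedRecord
from .hormones import HormonePanel, PatientRecord

logger = logging.getLogger(__name__)

INPUT_COLUMNS = [
    "id", "age", "bmi", "hiv_duration", "cart_duration", "cd4_nadir",
    "cd4_nadir_pct", "symptomatic", "tt_ngml", "shbg_nmoll", "lh_miuml",
    "albumin_gdl",
]

_NUMERIC = ["age", "bmi", "hiv_duration", "cart_duration", "cd4_nadir",
            "cd4_nadir_pct", "tt_ngml", "shbg_nmoll", "lh_miuml",
            "albumin_gdl"]


def _opt(value) -> Optional[float]:
    if value is None:
        return None
    v = float(value)
    return None if math.isnan(v) else v


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in ("1", "true", "yes", "y")


def records_to_dataframe(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "age": r.age, "bmi": r.bmi,
            "hiv_duration": r.hiv_duration,
            "cart_duration": r.cart_duration, "cd4_nadir": r.cd4_nadir,
            "cd4_nadir_pct": r.cd4_nadir_pct,
            "symptomatic": r.symptomatic,
            "tt_ngml": r.panel.tt, "shbg_nmoll": r.panel.shbg,
            "lh_miuml": r.panel.lh, "albumin_gdl": r.panel.albumin,
        })
    return pd.DataFrame(rows, columns=INPUT_COLUMNS)


def dataframe_to_records(df: pd.DataFrame,
                         strict: bool = False) -> list[PatientRecord]:
    """Build records from a cohort table; malformed rows are skipped and
    logged with their row number unless ``strict``."""
    records = []
    for i, row in df.iterrows():
        try:
            panel = HormonePanel(
                tt=float(row["tt_ngml"]),
                shbg=_opt(row.get("shbg_nmoll")),
                lh=_opt(row.get("lh_miuml")),
                albumin=_opt(row.get("albumin_gdl")),
            )
            records.append(PatientRecord(
                id=str(row["id"]),
                panel=panel,
                age=_opt(row.get("age")),
                bmi=_opt(row.get("bmi")),
                hiv_duration=_opt(row.get("hiv_duration")),
                cart_duration=_opt(row.get("cart_duration")),
                cd4_nadir=_opt(row.get("cd4_nadir")),
                cd4_nadir_pct=_opt(row.get("cd4_nadir_pct")),
                symptomatic=_as_bool(row.get("symptomatic", True)),
            ))
        except (ValueError, TypeError, KeyError) as exc:
            if strict:
                raise
            logger.warning("skipping malformed row %s: %s", i, exc)
    return records


def read_cohort_csv(path, strict: bool = False) -> list[PatientRecord]:
    df = pd.read_csv(path)
    missing = [c for c in ("id", "tt_ngml") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks required column(s): {missing}")
    return dataframe_to_records(df, strict=strict)


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def classified_to_dataframe(cohort: Sequence[ClassifiedRecord]
                            ) -> pd.DataFrame:
    df = records_to_dataframe([c.record for c in cohort])
    df["cft_pgml"] = [c.panel.cft for c in cohort]
    df["step_a"] = [c.status.step_a.value if c.status.step_a else ""
                    for c in cohort]
    df["step_b"] = [c.status.step_b.value if c.status.step_b else ""
                    for c in cohort]
    df["step_c"] = [c.status.step_c.value if c.status.step_c else ""
                    for c in cohort]
    df["flags"] = [";".join(sorted(c.status.flags)) for c in cohort]
    return df


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, dict):
        return {(k.value if isinstance(k, enum.Enum) else str(k)):
                _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2,
                                     sort_keys=True) + "\n")
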