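"""Cohort container and CSV round-tripping.

A cohort is one row per family: ``family_id``, ``disease``, ``timepoint``,
``sibling_applicable``, then one column per catalog item id holding 0, 1 or
empty (missing). Item columns are kept as floats internally (NaN = missing)
so pandas can carry missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .catalog import ItemCatalog
from .scoring import FamilyRecord

META_COLUMNS = ("family_id", "disease", "timepoint", "sibling_applicable")
DISEASES = ("ALL", "epilepsy", "asthma")


@dataclass
class Cohort:
    """A set of families with dichotomized PAT responses."""

    frame: pd.DataFrame
    catalog: ItemCatalog

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.frame)

    def validate(self) -> None:
        for col in META_COLUMNS:
            if col not in self.frame.columns:
                raise ValueError(f"cohort frame lacks required column {col!r}")
        unknown = [
            c for c in self.frame.columns
            if c not in META_COLUMNS and c not in self.catalog
        ]
        if unknown:
            raise ValueError(f"unknown item columns {unknown[:5]}")
        absent = [i for i in self.catalog.item_ids if i not in self.frame.columns]
        if absent:
            raise ValueError(f"cohort frame lacks item columns {absent[:5]}")
        items = self.frame[list(self.catalog.item_ids)].to_numpy(dtype=float)
        ok = np.isnan(items) | (items == 0) | (items == 1)
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise ValueError(
                f"non-binary response at row {r}, item "
                f"{self.catalog.item_ids[c]!r}: {items[r, c]!r}"
            )
        if self.frame["family_id"].duplicated().any():
            dup = self.frame.loc[self.frame["family_id"].duplicated(), "family_id"].iloc[0]
            raise ValueError(f"duplicate family_id {dup!r}")

    # -- conversions ------------------------------------------------------

    def records(self) -> list[FamilyRecord]:
        recs = []
        for _, row in self.frame.iterrows():
            responses: dict[str, Optional[int]] = {}
            for item_id in self.catalog.item_ids:
                v = row[item_id]
                responses[item_id] = None if (v is None or (isinstance(v, float) and math.isnan(v))) else int(v)
            recs.append(
                FamilyRecord(
                    family_id=str(row["family_id"]),
                    disease=str(row["disease"]),
                    responses=responses,
                    sibling_applicable=bool(row["sibling_applicable"]),
                    timepoint=str(row["timepoint"]),
                )
            )
        return recs

    @classmethod
    def from_records(cls, records: Iterable[FamilyRecord], catalog: ItemCatalog) -> "Cohort":
        rows = []
        for rec in records:
            rec.validate(catalog)
            row: dict = {
                "family_id": rec.family_id,
                "disease": rec.disease,
                "timepoint": rec.timepoint,
                "sibling_applicable": rec.sibling_applicable,
            }
            for item_id in catalog.item_ids:
                v = rec.responses[item_id]
                row[item_id] = float("nan") if v is None else float(v)
            rows.append(row)
        frame = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(catalog.item_ids))
        return cls(frame=frame, catalog=catalog)

    # -- persistence ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        frame = self.frame.copy()
        frame["sibling_applicable"] = frame["sibling_applicable"].astype(bool)
        for item_id in self.catalog.item_ids:
            frame[item_id] = frame[item_id].map(
                lambda v: "" if (v is None or (isinstance(v, float) and math.isnan(v))) else str(int(v))
            )
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, catalog: ItemCatalog) -> "Cohort":
        frame = pd.read_csv(path, dtype={"family_id": str}, keep_default_na=True)
        if "sibling_applicable" in frame:
            frame["sibling_applicable"] = frame["sibling_applicable"].astype(bool)
        for item_id in catalog.item_ids:
            if item_id in frame:
                frame[item_id] = pd.to_numeric(frame[item_id], errors="raise").astype(float)
        return cls(frame=frame, catalog=catalog)
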