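"""Dichotomous response matrices with person metadata.

The canonical layout is wide (persons × items) with values in {0, 1, NA}.
NA means the item was never administered to that person and is distinct
from a scored 0 (attempted/presented but not credited); fully scored
administrations have no NA cells.  Person metadata carries the language
form taken, the study arm and timepoint for longitudinal designs, and
numeric covariates (prefixed ``cov_`` on disk).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .bank import ItemBank

ARMS = ("intervention", "control", "none")
TIMEPOINTS = ("baseline", "m3", "m6", "m12", "none")

META_COLUMNS = ("person_id", "language", "arm", "timepoint")
MISSING = "NA"


@dataclass
class ResponseMatrix:
    """Wide persons × items response matrix plus aligned person metadata.

    ``values``: float DataFrame, one column per item id, entries 0.0 / 1.0 /
    NaN.  ``meta``: DataFrame with person_id, language, arm, timepoint and
    any number of ``cov_*`` numeric covariate columns; rows align with
    ``values`` positionally (person_id is not required to be unique — in
    longitudinal data a person appears once per timepoint).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.reset_index(drop=True).astype(float)
        self.meta = self.meta.reset_index(drop=True)
        if len(self.values) != len(self.meta):
            raise ValidationError(
                f"values has {len(self.values)} rows but meta has {len(self.meta)}"
            )
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise ValidationError(f"meta missing required column {col!r}")
        if self.meta["language"].isna().any() or (self.meta["language"] == "").any():
            bad = self.meta.index[
                self.meta["language"].isna() | (self.meta["language"] == "")
            ].tolist()
            raise ValidationError(f"persons at rows {bad} have no language code")
        arr = self.values.to_numpy()
        ok = np.isnan(arr) | (arr == 0.0) | (arr == 1.0)
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise ValidationError(
                f"non-binary response at row {r}, item {self.values.columns[c]!r}: "
                f"{arr[r, c]!r}"
            )

    # -- basic accessors ----------------------------------------------------

    @property
    def item_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_persons(self) -> int:
        return len(self.values)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def covariate_columns(self) -> list[str]:
        return [c for c in self.meta.columns if c.startswith("cov_")]

    def all_missing_rows(self) -> np.ndarray:
        """Row indices with no non-missing response (flagged, not dropped)."""
        return np.flatnonzero(np.isnan(self.to_numpy()).all(axis=1))

    def validate_against(self, bank: ItemBank) -> None:
        extra = sorted(set(self.item_ids) - set(bank.item_ids))
        if extra:
            raise ValidationError(f"response items absent from bank: {extra}")
        extra_langs = sorted(set(self.meta["language"]) - set(bank.languages))
        if extra_langs:
            raise ValidationError(f"languages absent from bank: {extra_langs}")

    # -- selection ----------------------------------------------------------

    def subset(
        self,
        language: str | None = None,
        arm: str | None = None,
        timepoint: str | None = None,
        items: Iterable[str] | None = None,
    ) -> "ResponseMatrix":
        mask = pd.Series(True, index=self.meta.index)
        if language is not None:
            mask &= self.meta["language"] == language
        if arm is not None:
            mask &= self.meta["arm"] == arm
        if timepoint is not None:
            mask &= self.meta["timepoint"] == timepoint
        cols = list(items) if items is not None else self.item_ids
        return ResponseMatrix(self.values.loc[mask, cols], self.meta.loc[mask])

    def sum_scores(self, items: Iterable[str] | None = None) -> np.ndarray:
        cols = list(items) if items is not None else self.item_ids
        return np.nansum(self.values[cols].to_numpy(), axis=1)

    def percent_scores(self, items: Iterable[str] | None = None) -> np.ndarray:
        """Percent-correct score over administered (non-missing) items."""
        cols = list(items) if items is not None else self.item_ids
        arr = self.values[cols].to_numpy()
        administered = (~np.isnan(arr)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * np.nansum(arr, axis=1) / administered

    def equals(self, other: "ResponseMatrix") -> bool:
        return (
            self.item_ids == other.item_ids
            and np.array_equal(self.to_numpy(), other.to_numpy(), equal_nan=True)
            and self.meta.reset_index(drop=True).equals(other.meta.reset_index(drop=True))
        )


# ---------------------------------------------------------------------------
# CSV round trip.  Layout: person_id, language, arm, timepoint, cov_*, then
# one 0/1/NA column per item id.  UTF-8, comma separated, "NA" sentinel.


def write_response_matrix(matrix: ResponseMatrix, path: str | Path) -> None:
    meta = matrix.meta.copy()
    vals = matrix.values.copy()
    out = pd.concat([meta.reset_index(drop=True), vals.reset_index(drop=True)], axis=1)
    for col in matrix.item_ids:
        out[col] = out[col].map(lambda v: MISSING if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False, encoding="utf-8", na_rep=MISSING)


def read_response_matrix(path: str | Path) -> ResponseMatrix:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise ValidationError(f"{path}: missing metadata columns {missing_meta}")
    cov_cols = [c for c in df.columns if c.startswith("cov_")]
    item_cols = [c for c in df.columns if c not in META_COLUMNS and c not in cov_cols]
    values = pd.DataFrame(index=df.index, columns=item_cols, dtype=float)
    for col in item_cols:
        raw = df[col].str.strip()
        bad = ~raw.isin(("0", "1", MISSING, ""))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path} row {row + 2}, item {col!r}: invalid value {raw.iloc[row]!r} "
                f"(expected 0, 1 or {MISSING})"
            )
        values[col] = raw.replace({MISSING: np.nan, "": np.nan}).astype(float)
    meta = df[list(META_COLUMNS) + cov_cols].copy()
    for col in cov_cols:
        meta[col] = pd.to_numeric(meta[col].replace({MISSING: np.nan, "": np.nan}))
    return ResponseMatrix(values, meta)


def from_long(
    long_df: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    person_col: str = "person_id",
    item_col: str = "item_id",
    value_col: str = "response",
) -> ResponseMatrix:
    """Import a long (person, item, response) table into the wide layout.

    ``meta`` supplies per-person metadata keyed by person_id; persons missing
    from ``meta`` get language/arm/timepoint defaults of ``none`` only if a
    language cannot be inferred, which is an error.
    """
    wide = long_df.pivot_table(
        index=person_col, columns=item_col, values=value_col, aggfunc="first"
    )
    wide = wide.sort_index()
    if meta is None:
        raise ValidationError("long import requires person metadata (language at minimum)")
    meta = meta.set_index(person_col).loc[wide.index].reset_index()
    for col, default in (("arm", "none"), ("timepoint", "none")):
        if col not in meta.columns:
            meta[col] = default
    return ResponseMatrix(wide.reset_index(drop=True), meta)
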