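"""Item banks and administration scoring for word-recognition literacy scales.

A word-recognition health literacy instrument (REALM-style) is a fixed,
ordered list of medical words the respondent reads aloud; the administrator
marks each word correct (+) or incorrect (−) and records the sum of correct
words.  Items carry a three-level expert-assigned difficulty stratum and one
word form per language version of the instrument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError

STRATA = ("low", "medium", "high")


class Mark(str, Enum):
    """Administrator's mark for one presented word."""

    CORRECT = "correct"
    INCORRECT = "incorrect"
    # "skipped" = the respondent exceeded the time allowance (administered
    # upstream by the interviewer); "not_attempted" = the word was never
    # attempted.  Both score 0; the distinction is preserved for audit only.
    SKIPPED = "skipped"
    NOT_ATTEMPTED = "not_attempted"


@dataclass(frozen=True)
class ItemRecord:
    """One word item: id, per-language word forms, difficulty stratum."""

    item_id: str
    words: Mapping[str, str]
    stratum: str

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValidationError(
                f"item {self.item_id!r}: unknown stratum {self.stratum!r}; "
                f"expected one of {STRATA}"
            )
        if not self.words or any(not w for w in self.words.values()):
            raise ValidationError(f"item {self.item_id!r}: empty word form")
        object.__setattr__(self, "words", dict(self.words))


@dataclass(frozen=True)
class ItemBank:
    """Ordered collection of items with one word form per declared language."""

    items: tuple[ItemRecord, ...]
    languages: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "languages", tuple(self.languages))
        if not self.items:
            raise ValidationError("no items")
        ids = [it.item_id for it in self.items]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate item ids: {dupes}")
        for it in self.items:
            missing = [lang for lang in self.languages if lang not in it.words]
            if missing:
                raise ValidationError(
                    f"item {it.item_id!r}: missing word form(s) for {missing}"
                )

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def strata(self) -> list[str]:
        return [it.stratum for it in self.items]

    def stratum_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in STRATA}
        for it in self.items:
            counts[it.stratum] += 1
        return counts

    def stratum_of(self) -> dict[str, str]:
        return {it.item_id: it.stratum for it in self.items}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.items:
            row = {"item_id": it.item_id, "stratum": it.stratum}
            for lang in self.languages:
                row[f"word_{lang}"] = it.words[lang]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class AdministrationRecord:
    """One person's marked administration, aligned to an ItemBank's order."""

    person_id: str
    marks: Sequence[Mark] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.marks = [Mark(m) for m in self.marks]


@dataclass(frozen=True)
class ScoredAdministration:
    person_id: str
    responses: np.ndarray  # 0/1 vector in bank order
    sum_score: int
    percent: float


def score_administration(
    record: AdministrationRecord, bank: ItemBank | None = None
) -> ScoredAdministration:
    """Score a marked administration: correct → 1, everything else → 0.

    Incorrect, skipped (time allowance exceeded) and not-attempted words all
    score 0, matching the +/− marking protocol; the sum score is the count of
    correct words and ``percent`` rescales it to 0–100.
    """
    if bank is not None and len(record.marks) != len(bank):
        raise ValidationError(
            f"person {record.person_id!r}: {len(record.marks)} marks for a "
            f"{len(bank)}-item bank"
        )
    vec = np.array([1 if m is Mark.CORRECT else 0 for m in record.marks], dtype=int)
    total = int(vec.sum())
    pct = 100.0 * total / len(vec) if len(vec) else float("nan")
    return ScoredAdministration(record.person_id, vec, total, pct)


# ---------------------------------------------------------------------------
# Readers / writers.  CSV layout: item_id, stratum, word_<lang> per language.


def read_item_bank(path: str | Path, format: str | None = None) -> ItemBank:
    """Read an item bank from CSV or JSON (format inferred from suffix)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if not payload.get("items"):
            raise ValidationError(f"{path}: no items")
        languages = tuple(payload["languages"])
        items = [
            ItemRecord(rec["item_id"], rec["words"], rec["stratum"])
            for rec in payload["items"]
        ]
        return ItemBank(tuple(items), languages)
    if fmt != "csv":
        raise ValidationError(f"unknown item bank format {fmt!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValidationError(f"{path}: no items")
    required = {"item_id", "stratum"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    word_cols = [c for c in df.columns if c.startswith("word_")]
    if not word_cols:
        raise ValidationError(f"{path}: no word_<language> columns")
    languages = tuple(c[len("word_"):] for c in word_cols)
    items = []
    for idx, row in df.iterrows():
        if row["stratum"] not in STRATA:
            raise ValidationError(
                f"{path} row {idx + 2}: unknown stratum {row['stratum']!r} "
                f"for item {row['item_id']!r}"
            )
        words = {lang: row[f"word_{lang}"] for lang in languages}
        items.append(ItemRecord(row["item_id"], words, row["stratum"]))
    return ItemBank(tuple(items), languages)


def write_item_bank(bank: ItemBank, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        payload = {
            "languages": list(bank.languages),
            "items": [
                {"item_id": it.item_id, "words": dict(it.words), "stratum": it.stratum}
                for it in bank.items
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False, indent=1)
    else:
        bank.to_frame().to_csv(path, index=False, encoding="utf-8")


def bank_from_frame(df: pd.DataFrame, languages: Iterable[str] | None = None) -> ItemBank:
    """Build an ItemBank from a dataframe with item_id/stratum/word_* columns."""
    word_cols = [c for c in df.columns if c.startswith("word_")]
    langs = tuple(languages) if languages else tuple(c[len("word_"):] for c in word_cols)
    items = [
        ItemRecord(
            str(row["item_id"]),
            {lang: str(row[f"word_{lang}"]) for lang in langs},
            str(row["stratum"]),
        )
        for _, row in df.iterrows()
    ]
    return ItemBank(tuple(items), langs)
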