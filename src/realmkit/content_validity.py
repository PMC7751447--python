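"""Content validity index (CVI) screening and expert difficulty assignment.

Experts rate each candidate word's relevance on a 4-point scale (1 = not
relevant … 4 = very relevant).  Lynn's item-level CVI (I-CVI) is the
proportion of experts rating the item 3 or 4; items with I-CVI above a
threshold (default .80) are retained.  The scale-level S-CVI reported here
is the average of item I-CVIs.  Experts also sort each word into three
difficulty strata (1 = low, 2 = medium, 3 = high); the modal rule takes the
most frequent category (ties resolve to medium), the mean-binned rule maps
the mean rating onto thirds of [1, 3].
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._errors import ValidationError


_STRATUM_FROM_LEVEL = {1: "low", 2: "medium", 3: "high"}


@dataclass(frozen=True)
class ContentValidityRecord:
    item_id: str
    n_experts: int
    i_cvi: float
    retained: bool
    difficulty_votes: dict[int, int]
    assigned_stratum: str | None


@dataclass(frozen=True)
class ContentValidityReport:
    records: list[ContentValidityRecord]
    s_cvi: float
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "item_id": r.item_id,
                    "n_experts": r.n_experts,
                    "i_cvi": r.i_cvi,
                    "retained": r.retained,
                    "assigned_stratum": r.assigned_stratum,
                }
                for r in self.records
            ]
        )

    def retained_ids(self) -> list[str]:
        return [r.item_id for r in self.records if r.retained]


def compute_cvi(
    ratings: pd.DataFrame,
    threshold: float = 0.80,
    difficulty_rule: str = "modal",
) -> ContentValidityReport:
    """Screen items by Lynn's I-CVI from an expert × item relevance table.

    ``ratings`` is long: expert_id, item_id, relevance (1–4) and optionally
    difficulty (1–3).  Items are returned in first-appearance order.
    """
    required = {"expert_id", "item_id", "relevance"}
    if not required.issubset(ratings.columns):
        raise ValidationError(
            f"ratings missing columns {sorted(required - set(ratings.columns))}"
        )
    rel = pd.to_numeric(ratings["relevance"])
    if not rel.isin((1, 2, 3, 4)).all():
        bad = ratings.loc[~rel.isin((1, 2, 3, 4)), "relevance"].iloc[0]
        raise ValidationError(f"relevance rating outside 1-4: {bad!r}")
    n_experts = ratings.groupby("item_id")["expert_id"].nunique()
    if (n_experts < 3).any():
        few = n_experts[n_experts < 3].index.tolist()
        raise ValidationError(f"fewer than 3 experts rated item(s) {few}")

    has_difficulty = "difficulty" in ratings.columns
    records = []
    for item_id in ratings["item_id"].drop_duplicates():
        sub = ratings[ratings["item_id"] == item_id]
        n = sub["expert_id"].nunique()
        relevant = int((pd.to_numeric(sub["relevance"]) >= 3).sum())
        i_cvi = relevant / len(sub)
        votes: dict[int, int] = {}
        stratum = None
        if has_difficulty:
            dvotes = pd.to_numeric(sub["difficulty"]).dropna()
            votes = {k: int((dvotes == k).sum()) for k in (1, 2, 3)}
            if dvotes.size:
                stratum = assign_difficulty(dvotes.tolist(), rule=difficulty_rule)
        records.append(
            ContentValidityRecord(
                item_id=str(item_id),
                n_experts=n,
                i_cvi=i_cvi,
                retained=i_cvi > threshold,
                difficulty_votes=votes,
                assigned_stratum=stratum,
            )
        )
    s_cvi = sum(r.i_cvi for r in records) / len(records) if records else float("nan")
    return ContentValidityReport(records, s_cvi, threshold)


def assign_difficulty(votes, rule: str = "modal") -> str:
    """Map expert difficulty votes (1/2/3) to a stratum label.

    modal: most frequent category, ties broken to the middle (medium).
    mean-binned: mean vote binned into thirds of [1, 3].
    """
    votes = [int(v) for v in votes]
    if not votes:
        raise ValidationError("empty difficulty votes")
    if any(v not in (1, 2, 3) for v in votes):
        raise ValidationError(f"difficulty votes outside 1-3: {votes}")
    if rule == "modal":
        counts = {k: votes.count(k) for k in (1, 2, 3)}
        top = max(counts.values())
        winners = [k for k, c in counts.items() if c == top]
        level = winners[0] if len(winners) == 1 else 2
        return _STRATUM_FROM_LEVEL[level]
    if rule == "mean-binned":
        mean = sum(votes) / len(votes)
        if mean < 1 + 2 / 3:
            return "low"
        if mean < 1 + 4 / 3:
            return "medium"
        return "high"
    raise ValidationError(f"unknown difficulty rule {rule!r}")


def trim_extreme_items(
    records: list[ContentValidityRecord],
    lower_pct: float | None = None,
    upper_pct: float | None = None,
) -> list[str]:
    """Optionally drop items whose mean difficulty vote is extreme.

    Returns ids of items whose mean difficulty rating falls outside the
    [lower_pct, upper_pct] percentile band of all items' means.  With both
    bounds None (the default) nothing is trimmed.
    """
    if lower_pct is None and upper_pct is None:
        return []
    means = {}
    for r in records:
        total = sum(k * v for k, v in r.difficulty_votes.items())
        n = sum(r.difficulty_votes.values())
        if n:
            means[r.item_id] = total / n
    if not means:
        return []
    s = pd.Series(means)
    lo = s.quantile(lower_pct / 100.0) if lower_pct is not None else -float("inf")
    hi = s.quantile(upper_pct / 100.0) if upper_pct is not None else float("inf")
    return sorted(s.index[(s < lo) | (s > hi)].tolist())
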