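"""Classical test theory statistics for dichotomous scales.

Percent correct is the CTT difficulty index (higher = easier item);
the corrected item-total correlation — Pearson correlation between an
item and the rest-score (total minus that item) — is the discrimination
index; Cronbach's alpha summarises internal consistency:

    alpha = k/(k-1) * (1 - sum_j var(X_j) / var(sum_j X_j))

with sample (n-1) variances.  On dichotomous data alpha coincides with
KR-20, so no separate code path exists.  Alpha uses listwise deletion
(its variance decomposition needs complete rows); per-item statistics use
the rows on which the item was administered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .responses import ResponseMatrix


@dataclass(frozen=True)
class ItemStatistics:
    item_id: str
    language: str | None
    percent_correct: float  # 0-100
    item_total_corr: float  # NaN when undefined (zero variance)
    n_used: int


@dataclass(frozen=True)
class ReliabilityReport:
    language: str | None
    k: int
    n: int
    alpha: float
    alpha_if_deleted: dict[str, float]
    r_it_median: float
    r_it_range: tuple[float, float]
    p_median: float
    p_range: tuple[float, float]


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, ResponseMatrix):
        return matrix.to_numpy()
    return np.asarray(matrix, dtype=float)


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha by the variance decomposition, listwise-complete rows.

    Returns NaN (undefined) when the total-score variance is zero.
    """
    arr = _as_array(matrix)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValidationError("alpha needs a 2-D matrix with >= 2 items")
    complete = ~np.isnan(arr).any(axis=1)
    arr = arr[complete]
    if arr.shape[0] < 2:
        raise ValidationError("alpha needs >= 2 complete rows")
    k = arr.shape[1]
    total_var = np.var(arr.sum(axis=1), ddof=1)
    if total_var == 0.0:
        return float("nan")
    item_vars = np.var(arr, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def item_statistics(
    matrix,
    item_ids: list[str] | None = None,
    language: str | None = None,
    corrected: bool = True,
) -> list[ItemStatistics]:
    """Per-item percent correct and (rest-score) item-total correlation.

    ``corrected=True`` (the default) correlates each item with the total of
    the *other* items, avoiding the self-correlation inflation of the raw
    total; ``corrected=False`` uses the full total.
    """
    if isinstance(matrix, ResponseMatrix):
        arr = matrix.to_numpy()
        ids = matrix.item_ids
    else:
        arr = np.asarray(matrix, dtype=float)
        ids = item_ids or [f"item_{j + 1}" for j in range(arr.shape[1])]
    if arr.ndim != 2:
        raise ValidationError("response matrix must be 2-D")
    observed = ~np.isnan(arr)
    totals = np.nansum(arr, axis=1)
    out = []
    for j, item_id in enumerate(ids):
        rows = observed[:, j]
        n_used = int(rows.sum())
        if n_used == 0:
            out.append(ItemStatistics(item_id, language, float("nan"), float("nan"), 0))
            continue
        xj = arr[rows, j]
        p = 100.0 * float(xj.mean())
        rest = totals[rows] - xj if corrected else totals[rows]
        r = _pearson(xj, rest) if n_used >= 3 else float("nan")
        out.append(ItemStatistics(item_id, language, p, r, n_used))
    return out


def summarize_scale(
    stats: list[ItemStatistics], alpha: float, n: int = 0, language: str | None = None
) -> ReliabilityReport:
    """Median and range of item statistics plus alpha, one scale/language."""
    if not stats:
        raise ValidationError("no item statistics to summarize")
    r = np.array([s.item_total_corr for s in stats], dtype=float)
    p = np.array([s.percent_correct for s in stats], dtype=float)
    r_ok = r[~np.isnan(r)]
    p_ok = p[~np.isnan(p)]
    if r_ok.size == 0 or p_ok.size == 0:
        raise ValidationError("all item statistics undefined")
    return ReliabilityReport(
        language=language,
        k=len(stats),
        n=n,
        alpha=alpha,
        alpha_if_deleted={},
        r_it_median=float(np.median(r_ok)),
        r_it_range=(float(r_ok.min()), float(r_ok.max())),
        p_median=float(np.median(p_ok)),
        p_range=(float(p_ok.min()), float(p_ok.max())),
    )


def alpha_if_deleted(matrix, item_ids: list[str] | None = None) -> dict[str, float]:
    """Alpha recomputed with each item removed in turn."""
    if isinstance(matrix, ResponseMatrix):
        arr = matrix.to_numpy()
        ids = matrix.item_ids
    else:
        arr = np.asarray(matrix, dtype=float)
        ids = item_ids or [f"item_{j + 1}" for j in range(arr.shape[1])]
    out = {}
    for j, item_id in enumerate(ids):
        sub = np.delete(arr, j, axis=1)
        out[item_id] = cronbach_alpha(sub) if sub.shape[1] >= 2 else float("nan")
    return out


def stats_to_frame(stats: list[ItemStatistics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "item_id": s.item_id,
                "language": s.language,
                "percent_correct": s.percent_correct,
                "item_total_corr": s.item_total_corr,
                "n_used": s.n_used,
            }
            for s in stats
        ]
    )
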