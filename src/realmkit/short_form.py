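"""Stratified short-form construction by residuals above a spline mean curve.

The reduction procedure plots each item's (corrected) item-total
correlation against its percent correct, fits a cubic smoothing spline
mean curve through the scatter, and prefers items lying *above* the curve
— more discriminating than expected at their difficulty.  Selecting the
top above-curve residuals within each expert difficulty stratum, with
stratum quotas proportional to the parent scale's stratum sizes
(largest-remainder apportionment), yields a shorter form that preserves
the original difficulty distribution while raising discrimination.
Nested forms (e.g. 82 → 40 → 20 items) restrict later rounds to the
previous selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline

from ._errors import ValidationError
from .bank import STRATA, ItemBank
from .ctt import ItemStatistics


@dataclass
class SelectionCurve:
    """Fitted mean curve f: percent correct -> expected item-total correlation."""

    spline: BSpline
    p_min: float
    p_max: float
    lam: float | None
    effective_df: float | None
    residuals: dict[str, float]  # item_id -> r_it - f(p)

    def __call__(self, p):
        return self.spline(np.clip(np.asarray(p, dtype=float), self.p_min, self.p_max))


@dataclass(frozen=True)
class QuotaAllocation:
    stratum_sizes: dict[str, int]
    target_length: int
    quotas: dict[str, int]


@dataclass
class SelectionResult:
    form_length: int
    selected: dict[str, list[str]]  # stratum -> item ids, rank order
    table: pd.DataFrame  # item_id, stratum, p, r_it, residual, rank, selected
    quotas: QuotaAllocation
    parent_length: int | None = None
    language: str | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def selected_ids(self) -> list[str]:
        return [i for s in STRATA for i in self.selected.get(s, [])]


def fit_mean_curve(
    stats: Sequence[ItemStatistics],
    lam: float | None = None,
    fixed_df: float = 4.0,
    gcv_min_points: int = 15,
) -> SelectionCurve:
    """Cubic smoothing spline of item-total correlation on percent correct.

    Smoothing is chosen by generalised cross-validation; below
    ``gcv_min_points`` usable points (or when GCV degenerates) the penalty
    is instead tuned so the smoother's effective degrees of freedom equal
    ``fixed_df``.  Tied percent-correct values are merged into weighted
    means, which is equivalent for the penalised least-squares fit.
    """
    usable = [
        s for s in stats if np.isfinite(s.item_total_corr) and np.isfinite(s.percent_correct)
    ]
    if len(usable) < 5:
        raise ValidationError(
            f"need >= 5 items with defined statistics (got {len(usable)}); "
            "consider a fixed-df linear fallback on more data"
        )
    p = np.array([s.percent_correct for s in usable])
    r = np.array([s.item_total_corr for s in usable])
    # collapse duplicate abscissae to weighted means
    order = np.argsort(p, kind="stable")
    p_sorted, r_sorted = p[order], r[order]
    px, inv, counts = np.unique(p_sorted, return_inverse=True, return_counts=True)
    ry = np.zeros_like(px)
    np.add.at(ry, inv, r_sorted)
    ry /= counts
    w = counts.astype(float)
    if px.size < 5:
        raise ValidationError("need >= 5 distinct percent-correct values for a cubic fit")

    use_gcv = lam is None and px.size >= gcv_min_points
    eff_df = None
    if lam is not None:
        spline = make_smoothing_spline(px, ry, w=w, lam=lam)
    elif use_gcv:
        spline = make_smoothing_spline(px, ry, w=w)  # GCV-chosen penalty
        lam = None
    else:
        lam, spline = _spline_at_df(px, ry, w, target_df=min(fixed_df, px.size - 1.0))
        eff_df = min(fixed_df, px.size - 1.0)
    residuals = {
        s.item_id: float(s.item_total_corr - spline(s.percent_correct)) for s in usable
    }
    return SelectionCurve(
        spline=spline,
        p_min=float(px.min()),
        p_max=float(px.max()),
        lam=lam,
        effective_df=eff_df,
        residuals=residuals,
    )


def _effective_df(px, w, lam) -> float:
    """Trace of the smoother matrix, column by column."""
    n = px.size
    tr = 0.0
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        tr += float(make_smoothing_spline(px, e, w=w, lam=lam)(px[i]))
    return tr


def _spline_at_df(px, ry, w, target_df: float):
    """Bisection on log-lambda to hit a target effective df."""
    lo, hi = -12.0, 12.0
    # df is decreasing in lambda; widen until bracketed
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        df = _effective_df(px, w, 10.0**mid)
        if abs(df - target_df) < 1e-3:
            break
        if df > target_df:
            lo = mid
        else:
            hi = mid
    lam = 10.0 ** (0.5 * (lo + hi))
    return lam, make_smoothing_spline(px, ry, w=w, lam=lam)


def allocate_quotas(stratum_sizes: dict[str, int], target_length: int) -> QuotaAllocation:
    """Largest-remainder apportionment of the form length across strata.

    Floors of the proportional shares are assigned first; remaining seats go
    to the largest fractional remainders, ties broken by stratum order
    low -> medium -> high.  Sizes (29, 28, 25) reproduce (14, 14, 12) at
    L = 40 and (7, 7, 6) at L = 20.
    """
    strata = [s for s in STRATA if s in stratum_sizes]
    sizes = {s: int(stratum_sizes[s]) for s in strata}
    if any(v <= 0 for v in sizes.values()):
        raise ValidationError(f"stratum sizes must be positive: {sizes}")
    total = sum(sizes.values())
    if target_length > total:
        raise ValidationError(f"target length {target_length} exceeds item count {total}")
    shares = {s: target_length * sizes[s] / total for s in strata}
    quotas = {s: int(np.floor(shares[s])) for s in strata}
    leftover = target_length - sum(quotas.values())
    by_remainder = sorted(
        strata, key=lambda s: (-(shares[s] - quotas[s]), strata.index(s))
    )
    for s in by_remainder[:leftover]:
        quotas[s] += 1
    return QuotaAllocation(sizes, target_length, quotas)


def select_items(
    stats: Sequence[ItemStatistics],
    curve: SelectionCurve,
    quotas: QuotaAllocation,
    item_bank: ItemBank,
    p_range: tuple[float, float] | None = None,
    parent: SelectionResult | None = None,
    language: str | None = None,
) -> SelectionResult:
    """Pick the top above-curve residuals per stratum, honouring quotas.

    Candidates are ranked within stratum by residual descending, ties by
    higher item-total correlation then input order.  Items with percent
    correct outside ``p_range`` are excluded.  If above-curve candidates
    cannot fill a quota, the best below-curve residuals top it up and the
    form is flagged ``below_curve_fill``.  With ``parent`` given, candidates
    are restricted to the parent's selection (nesting).
    """
    stratum_of = item_bank.stratum_of()
    order_of = {item_id: k for k, item_id in enumerate(item_bank.item_ids)}
    allowed = set(parent.selected_ids) if parent is not None else None
    rows = []
    for s in stats:
        if s.item_id not in stratum_of:
            raise ValidationError(f"item {s.item_id!r} not in the item bank")
        if allowed is not None and s.item_id not in allowed:
            continue
        resid = curve.residuals.get(s.item_id)
        if resid is None and np.isfinite(s.item_total_corr):
            resid = float(s.item_total_corr - curve(s.percent_correct))
        rows.append(
            {
                "item_id": s.item_id,
                "stratum": stratum_of[s.item_id],
                "p": s.percent_correct,
                "r_it": s.item_total_corr,
                "residual": np.nan if resid is None else resid,
                "order": order_of[s.item_id],
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("no candidate items")

    flags: set[str] = set()
    selected: dict[str, list[str]] = {}
    ranks: dict[str, int] = {}
    for stratum in STRATA:
        quota = quotas.quotas.get(stratum, 0)
        cand = df[df["stratum"] == stratum].copy()
        if p_range is not None:
            in_range = (cand["p"] >= p_range[0]) & (cand["p"] <= p_range[1])
            # never let the range filter make a quota unfillable
            if in_range.sum() >= quota:
                cand = cand[in_range]
            else:
                flags.add("p_range_relaxed")
        cand = cand[np.isfinite(cand["residual"])]
        cand = cand.sort_values(
            by=["residual", "r_it", "order"], ascending=[False, False, True],
            kind="stable",
        )
        if len(cand) < quota:
            raise ValidationError(
                f"stratum {stratum!r}: quota {quota} but only {len(cand)} candidates"
            )
        take = cand.head(quota)
        if (take["residual"] < 0).any():
            flags.add("below_curve_fill")
        selected[stratum] = take["item_id"].tolist()
        for rank, item_id in enumerate(selected[stratum], start=1):
            ranks[item_id] = rank

    df["selected"] = df["item_id"].isin([i for v in selected.values() for i in v])
    df["rank"] = df["item_id"].map(ranks).astype("Int64")
    df = df.drop(columns="order").reset_index(drop=True)
    return SelectionResult(
        form_length=quotas.target_length,
        selected=selected,
        table=df,
        quotas=quotas,
        parent_length=parent.form_length if parent is not None else None,
        language=language,
        flags=flags,
    )


def multi_language_review(
    selection: SelectionResult,
    stats_by_language: dict[str, Sequence[ItemStatistics]],
    curves_by_language: dict[str, SelectionCurve] | None = None,
) -> pd.DataFrame:
    """Advisory cross-language check of a reference-language selection.

    For every selected item and every other language, reports that
    language's residual from its own mean curve; items falling below the
    curve (negative residual) anywhere are marked review candidates.  No
    automatic swaps are made — the output is a review list.
    """
    curves = dict(curves_by_language or {})
    for lang, stats in stats_by_language.items():
        if lang not in curves:
            curves[lang] = fit_mean_curve(stats)
    rows = []
    for item_id in selection.selected_ids:
        ref_row = selection.table.loc[selection.table["item_id"] == item_id].iloc[0]
        for lang, stats in stats_by_language.items():
            stat = next((s for s in stats if s.item_id == item_id), None)
            resid = curves[lang].residuals.get(item_id) if stat else None
            rows.append(
                {
                    "item_id": item_id,
                    "stratum": ref_row["stratum"],
                    "reference_residual": ref_row["residual"],
                    "language": lang,
                    "residual": np.nan if resid is None else resid,
                    "review": bool(resid is not None and resid < 0),
                }
            )
    return pd.DataFrame(rows)


def plot_selection(
    stats: Sequence[ItemStatistics],
    curve: SelectionCurve,
    selection: SelectionResult | None = None,
    path=None,
    title: str = "Item-total correlation vs percent correct",
):
    """Scatter of (percent correct, item-total correlation) with the mean curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    p = [s.percent_correct for s in stats]
    r = [s.item_total_corr for s in stats]
    chosen = set(selection.selected_ids) if selection is not None else set()
    colors = ["tab:red" if s.item_id in chosen else "tab:gray" for s in stats]
    ax.scatter(p, r, c=colors, s=18)
    grid = np.linspace(curve.p_min, curve.p_max, 200)
    ax.plot(grid, curve(grid), "k-", lw=1.5, label="mean curve")
    ax.set_xlabel("percent correct")
    ax.set_ylabel("item-total correlation")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
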