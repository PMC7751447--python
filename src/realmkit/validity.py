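"""Convergent validity correlations and intervention-sensitivity analysis.

Convergent validity: pairwise Pearson correlations between form scores and
external criteria (functional literacy screeners such as the NVS, education
level, disease knowledge), with two-sided p-values from
t = r sqrt((n-2)/(1-r^2)) on n-2 df and pairwise-complete observations.

Sensitivity: for a two-arm longitudinal study, per-cell mean percent score
with standard error, then for each follow-up the between-arm difference in
mean change from baseline with a Welch two-sample test on per-person change
scores.  The baseline row reports the raw between-arm gap.  Stars: * p<.05,
** p<.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    n: int
    r: float
    p_value: float


def pearson_with_p(x, y) -> CorrelationResult:
    """Pearson r with two-sided p from the exact t reference distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {n}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return CorrelationResult("x", "y", n, float("nan"), float("nan"))
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult("x", "y", n, r, p)


def convergent_validity(table: pd.DataFrame) -> pd.DataFrame:
    """Lower-triangle correlation table over the columns of ``table``.

    Returns a long dataframe (var_x, var_y, n, r, p) over all unordered
    column pairs; constant or too-sparse pairs get NaN r/p with n reported.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValidationError("need >= 2 variables")
    rows = []
    for i in range(1, len(cols)):
        for j in range(i):
            x = table[cols[i]].to_numpy(dtype=float)
            y = table[cols[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            n = int(ok.sum())
            if n < 3 or np.std(x[ok]) == 0.0 or np.std(y[ok]) == 0.0:
                rows.append(
                    {"var_x": cols[i], "var_y": cols[j], "n": n,
                     "r": np.nan, "p": np.nan}
                )
                continue
            res = pearson_with_p(x[ok], y[ok])
            rows.append(
                {"var_x": cols[i], "var_y": cols[j], "n": n, "r": res.r, "p": res.p_value}
            )
    return pd.DataFrame(rows)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric matrix of r values (diagonal shown as NaN / '-')."""
    long = convergent_validity(table)
    cols = list(table.columns)
    mat = pd.DataFrame(np.nan, index=cols, columns=cols)
    for _, row in long.iterrows():
        mat.loc[row["var_x"], row["var_y"]] = row["r"]
        mat.loc[row["var_y"], row["var_x"]] = row["r"]
    return mat


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def sensitivity_analysis(
    scores: pd.DataFrame,
    baseline: str = "baseline",
    arms: tuple[str, str] = ("intervention", "control"),
    score_col: str = "percent",
) -> pd.DataFrame:
    """Between-arm difference in change from baseline, per follow-up timepoint.

    ``scores`` is long with columns person_id, arm, timepoint and the score
    column (percent scale).  Output rows: overall / per-arm cell means (SE),
    then a difference row whose baseline entry is the raw between-arm gap and
    whose follow-up entries are differences in mean change from baseline,
    each with a Welch two-sample SE, t, p and significance stars.
    """
    required = {"person_id", "arm", "timepoint", score_col}
    if not required.issubset(scores.columns):
        raise ValidationError(f"missing columns {sorted(required - set(scores.columns))}")
    tps = list(dict.fromkeys(scores["timepoint"]))
    if baseline not in tps:
        raise ValidationError(f"no baseline timepoint {baseline!r} in data")
    follow = [t for t in tps if t != baseline]
    if not follow:
        raise ValidationError("need at least one follow-up timepoint")
    a1, a2 = arms

    def cell(arm, tp):
        vals = scores.loc[
            (scores["arm"] == arm) & (scores["timepoint"] == tp), score_col
        ].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        n = vals.size
        mean = float(vals.mean()) if n else np.nan
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        return mean, se, n

    rows = []
    for label, arm_filter in (("overall", None), (a1, a1), (a2, a2)):
        row = {"row": label}
        for tp in [baseline] + follow:
            if arm_filter is None:
                vals = scores.loc[scores["timepoint"] == tp, score_col].to_numpy(float)
                vals = vals[~np.isnan(vals)]
                m = float(vals.mean()) if vals.size else np.nan
                se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 else np.nan
            else:
                m, se, _ = cell(arm_filter, tp)
            row[f"{tp}_mean"] = m
            row[f"{tp}_se"] = se
        rows.append(row)

    # wide per-person scores to form change scores
    wide = scores.pivot_table(
        index=["person_id", "arm"], columns="timepoint", values=score_col, aggfunc="first"
    ).reset_index()
    diff_row = {"row": "difference"}
    # baseline: raw between-arm gap
    b1 = wide.loc[wide["arm"] == a1, baseline].dropna().to_numpy(float)
    b2 = wide.loc[wide["arm"] == a2, baseline].dropna().to_numpy(float)
    d, se, t, p = _welch_gap(b1, b2)
    diff_row.update(
        {f"{baseline}_mean": d, f"{baseline}_se": se, f"{baseline}_p": p,
         f"{baseline}_stars": _stars(p)}
    )
    for tp in follow:
        if tp not in wide.columns:
            continue
        c1 = (wide.loc[wide["arm"] == a1, tp] - wide.loc[wide["arm"] == a1, baseline]).dropna()
        c2 = (wide.loc[wide["arm"] == a2, tp] - wide.loc[wide["arm"] == a2, baseline]).dropna()
        d, se, t, p = _welch_gap(c1.to_numpy(float), c2.to_numpy(float))
        diff_row.update(
            {f"{tp}_mean": d, f"{tp}_se": se, f"{tp}_p": p, f"{tp}_stars": _stars(p)}
        )
    rows.append(diff_row)
    return pd.DataFrame(rows)


def _welch_gap(x1: np.ndarray, x2: np.ndarray):
    """Difference of means with Welch SE, t and two-sided p; NaNs when n < 2."""
    if x1.size < 2 or x2.size < 2:
        return (
            float(x1.mean() - x2.mean()) if x1.size and x2.size else np.nan,
            np.nan, np.nan, np.nan,
        )
    d = float(x1.mean() - x2.mean())
    v1, v2 = x1.var(ddof=1) / x1.size, x2.var(ddof=1) / x2.size
    se = float(np.sqrt(v1 + v2))
    if se == 0.0:
        return d, 0.0, np.nan, np.nan if d != 0 else 1.0
    t, p = sps.ttest_ind(x1, x2, equal_var=False)
    return d, se, float(t), float(p)
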