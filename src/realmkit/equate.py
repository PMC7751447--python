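"""Mean/sigma linear equating of 2PL item parameters across language forms.

Separate calibrations of two language forms of the same instrument sit on
arbitrary latent scales.  Mean/sigma equating rescales the focal form so
that the mean and standard deviation of its item difficulties match the
reference form:

    A = sd(b_ref) / sd(b_focal),  B = mean(b_ref) - A * mean(b_focal)
    b' = A b + B,  a' = a / A

which leaves every item response function invariant under the matching
ability transform theta' = A theta + B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .irt import ItemParameters


@dataclass(frozen=True)
class EquatingTransform:
    focal_language: str | None
    reference_language: str | None
    A: float
    B: float

    def apply_b(self, b):
        return self.A * np.asarray(b, dtype=float) + self.B

    def apply_a(self, a):
        return np.asarray(a, dtype=float) / self.A

    def apply_theta(self, theta):
        return self.A * np.asarray(theta, dtype=float) + self.B


def _usable(params: list[ItemParameters]) -> dict[str, ItemParameters]:
    return {
        p.item_id: p
        for p in params
        if "excluded_degenerate" not in p.flags and np.isfinite(p.b)
    }


def mean_sigma_equate(
    params_focal: list[ItemParameters],
    params_ref: list[ItemParameters],
) -> tuple[EquatingTransform, list[ItemParameters]]:
    """Equate a focal form's parameters onto a reference form's b-scale.

    Both sets must cover the same (>= 3) usable common items.  Returns the
    transform and the transformed focal parameters (all focal items, in
    input order; standard errors are rescaled like their parameters:
    se_b' = A se_b, se_a' = se_a / A).
    """
    focal = _usable(params_focal)
    ref = _usable(params_ref)
    only_focal = sorted(set(focal) - set(ref))
    only_ref = sorted(set(ref) - set(focal))
    if only_focal or only_ref:
        raise ValidationError(
            f"item sets differ: focal-only {only_focal}, reference-only {only_ref}"
        )
    common = [p.item_id for p in params_focal if p.item_id in focal]
    if len(common) < 3:
        raise ValidationError(f"need >= 3 common items, got {len(common)}")
    b_f = np.array([focal[i].b for i in common])
    b_r = np.array([ref[i].b for i in common])
    sd_f = float(np.std(b_f, ddof=1))
    sd_r = float(np.std(b_r, ddof=1))
    if sd_f == 0.0:
        raise ValidationError("zero variance in focal difficulties; cannot equate")
    A = sd_r / sd_f
    B = float(np.mean(b_r)) - A * float(np.mean(b_f))
    tr = EquatingTransform(
        focal_language=params_focal[0].language if params_focal else None,
        reference_language=params_ref[0].language if params_ref else None,
        A=A,
        B=B,
    )
    transformed = []
    for p in params_focal:
        if p.item_id not in focal:
            transformed.append(p)
            continue
        transformed.append(
            ItemParameters(
                p.item_id,
                p.a / A,
                A * p.b + B,
                p.se_a / A,
                A * p.se_b,
                language=p.language,
                flags=p.flags | {"equated"},
            )
        )
    return tr, transformed


@dataclass(frozen=True)
class StratumSummary:
    stratum: str
    n: int
    mean_b: float
    sd_b: float  # NaN when < 2 items


@dataclass(frozen=True)
class SeparationReport:
    """Difficulty separation of the hardest stratum from the two easier ones.

    separation_index = (mean b_high - mean b_{low+medium}) / pooled sd.
    A large positive index reproduces the 'distinct separation' pattern of
    orthographically deep forms; compressed forms score lower.
    """

    by_stratum: list[StratumSummary]
    separation_index: float


def difficulty_separation_report(
    params: list[ItemParameters], stratum_of: dict[str, str]
) -> SeparationReport:
    usable = _usable(params)
    groups: dict[str, list[float]] = {"low": [], "medium": [], "high": []}
    for item_id, p in usable.items():
        s = stratum_of.get(item_id)
        if s not in groups:
            raise ValidationError(f"item {item_id!r}: unknown stratum {s!r}")
        groups[s].append(p.b)
    summaries = []
    for s in ("low", "medium", "high"):
        vals = np.asarray(groups[s], dtype=float)
        summaries.append(
            StratumSummary(
                s,
                vals.size,
                float(vals.mean()) if vals.size else float("nan"),
                float(np.std(vals, ddof=1)) if vals.size >= 2 else float("nan"),
            )
        )
    hard = np.asarray(groups["high"], dtype=float)
    easy = np.asarray(groups["low"] + groups["medium"], dtype=float)
    if hard.size == 0 or easy.size == 0:
        return SeparationReport(summaries, float("nan"))
    n1, n2 = easy.size, hard.size
    if n1 >= 2 and n2 >= 2:
        pooled_var = (
            (n1 - 1) * np.var(easy, ddof=1) + (n2 - 1) * np.var(hard, ddof=1)
        ) / (n1 + n2 - 2)
    else:
        pooled_var = np.var(np.concatenate([easy, hard]), ddof=0)
    pooled_sd = float(np.sqrt(pooled_var))
    diff = float(hard.mean() - easy.mean())
    index = 0.0 if diff == 0.0 else (diff / pooled_sd if pooled_sd > 0 else float("inf"))
    return SeparationReport(summaries, index)


def separation_report_frame(report: SeparationReport) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"stratum": s.stratum, "n": s.n, "mean_b": s.mean_b, "sd_b": s.sd_b}
            for s in report.by_stratum
        ]
    )
    df.attrs["separation_index"] = report.separation_index
    return df
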