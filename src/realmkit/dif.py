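"""Likelihood-ratio differential item functioning (DIF) tests under the 2PL.

For each studied item the constrained model forces its (a, b) equal across
the two language groups while all other items serve as anchors (also
constrained equal); the free model releases the studied item's (a, b) in
the focal group.  Both models estimate the focal group's latent mean and
sd against the reference group's fixed N(0, 1), so true ability-distribution
differences are absorbed before item-level differences are tested.  The
statistic 2 (logL_free - logL_constrained) is referred to chi-square with
2 degrees of freedom; Benjamini–Hochberg adjustment across items is applied
by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from ._errors import ValidationError
from .irt import IRTConfig, _degenerate_items, _prepare, fit_2pl_multigroup


@dataclass(frozen=True)
class DIFResult:
    item_id: str
    statistic: float
    df: int
    p_value: float
    adjusted_p: float
    flagged: bool
    direction: int  # sign of b_focal - b_ref in the free model; 0 if untested
    testable: bool = True


def _testable_columns(X_ref: np.ndarray, X_foc: np.ndarray) -> np.ndarray:
    X0r, Mr = _prepare(X_ref)
    X0f, Mf = _prepare(X_foc)
    return ~(_degenerate_items(X0r, Mr) | _degenerate_items(X0f, Mf))


def dif_test(
    matrix_ref,
    matrix_focal,
    item_ids: list[str] | None = None,
    items_to_test: list[str] | None = None,
    alpha: float = 0.05,
    adjustment: str = "benjamini-hochberg",
    config: IRTConfig | None = None,
    purify: bool = False,
) -> list[DIFResult]:
    """Joint (a, b) likelihood-ratio DIF test per item, all-other-item anchors.

    ``matrix_ref`` / ``matrix_focal`` are persons × items 0/1/NaN arrays (or
    ResponseMatrix) over a shared item set.  Items degenerate in either group
    are reported as not testable.  ``items_to_test`` restricts the studied
    items (ids); adjustment is applied over the items actually tested.
    ``purify=True`` runs one purification pass: items flagged in a first
    sweep are freed (removed from the anchor set) and the sweep repeats.
    """
    from .responses import ResponseMatrix

    cfg = config or IRTConfig()
    if adjustment not in ("none", "benjamini-hochberg"):
        raise ValidationError(f"unknown adjustment {adjustment!r}")

    def unpack(m):
        if isinstance(m, ResponseMatrix):
            return m.to_numpy(), m.item_ids
        return np.asarray(m, dtype=float), None

    X_ref, ids_ref = unpack(matrix_ref)
    X_foc, ids_foc = unpack(matrix_focal)
    ids = item_ids or ids_ref or ids_foc or [f"item_{j + 1}" for j in range(X_ref.shape[1])]
    if ids_ref and ids_foc and ids_ref != ids_foc:
        raise ValidationError("reference and focal groups carry different item sets")
    if X_ref.shape[1] != X_foc.shape[1]:
        raise ValidationError(
            f"item count mismatch: {X_ref.shape[1]} (ref) vs {X_foc.shape[1]} (focal)"
        )

    testable = _testable_columns(X_ref, X_foc)
    usable = np.flatnonzero(testable)
    if usable.size < 2:
        raise ValidationError("fewer than 2 testable items")
    Xr, Xf = X_ref[:, usable], X_foc[:, usable]
    sub_ids = [ids[j] for j in usable]
    study = (
        list(range(len(sub_ids)))
        if items_to_test is None
        else [sub_ids.index(i) for i in items_to_test if i in sub_ids]
    )

    results = _lr_sweep(Xr, Xf, sub_ids, study, cfg, always_free=())
    if purify:
        flagged0 = {j for j, r in zip(study, results) if r["p"] < alpha}
        if flagged0:
            results = _lr_sweep(Xr, Xf, sub_ids, study, cfg, always_free=tuple(flagged0))

    pvals = [r["p"] for r in results]
    if adjustment == "benjamini-hochberg" and pvals:
        reject, adj_p, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    else:
        adj_p = list(pvals)
        reject = [p < alpha for p in pvals]

    out: dict[str, DIFResult] = {}
    for r, padj, rej in zip(results, adj_p, reject):
        out[r["item_id"]] = DIFResult(
            r["item_id"], r["statistic"], 2, r["p"], float(padj), bool(rej), r["direction"]
        )
    final: list[DIFResult] = []
    for j, item_id in enumerate(ids):
        if item_id in out:
            final.append(out[item_id])
        elif not testable[j]:
            final.append(
                DIFResult(item_id, float("nan"), 2, float("nan"), float("nan"),
                          False, 0, testable=False)
            )
    return final


def _lr_sweep(Xr, Xf, sub_ids, study, cfg, always_free=()):
    base_free = tuple(sorted(always_free))
    constrained = fit_2pl_multigroup([Xr, Xf], free_items=base_free, config=cfg)
    rows = []
    for j in study:
        free = tuple(sorted(set(base_free) | {j}))
        if free == base_free:
            # already free in the constrained model (purification pass):
            # compare against a model re-constraining just this item
            re_free = tuple(k for k in base_free if k != j)
            restricted = fit_2pl_multigroup([Xr, Xf], free_items=re_free, config=cfg,
                                            init=constrained)
            stat = 2.0 * (constrained.loglik - restricted.loglik)
            fitted = constrained
        else:
            fitted = fit_2pl_multigroup([Xr, Xf], free_items=free, config=cfg,
                                        init=constrained)
            stat = 2.0 * (fitted.loglik - constrained.loglik)
        stat = max(stat, 0.0)
        direction = int(np.sign(fitted.b[1, j] - fitted.b[0, j]))
        rows.append(
            {
                "item_id": sub_ids[j],
                "statistic": float(stat),
                "p": float(chi2.sf(stat, 2)),
                "direction": direction,
            }
        )
    return rows


def dif_to_frame(results: list[DIFResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "item_id": r.item_id,
                "statistic": r.statistic,
                "df": r.df,
                "p": r.p_value,
                "adjusted_p": r.adjusted_p,
                "flagged": r.flagged,
                "direction": r.direction,
                "testable": r.testable,
            }
            for r in results
        ]
    )
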