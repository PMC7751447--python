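"""Two-parameter logistic IRT estimated by marginal maximum likelihood.

Model: P(X_ij = 1 | theta_i) = 1 / (1 + exp(-a_j (theta_i - b_j))) with
discrimination a_j > 0 and difficulty b_j on the latent (logit) scale;
theta ~ N(0, 1) fixes the scale.  Estimation is Bock–Aitkin EM: the latent
density is discretised on a fixed rectangular quadrature grid, the E-step
accumulates expected per-node response counts from each person's posterior,
and the M-step maximises each item's expected complete-data likelihood by a
damped (step-halved) Newton ascent run vectorised across items.  The
marginal log-likelihood is therefore non-decreasing across cycles up to
the step-halving tolerance.

A multi-group variant shares item parameters across groups (with selected
items freed) and estimates the focal groups' latent mean and variance,
with the reference group fixed at N(0, 1); this is the engine behind the
likelihood-ratio DIF test.

Missing responses are ignored in the likelihood (each person contributes
only administered items).  Items answered all-correct or all-incorrect
have unbounded likelihood and are excluded with a flag before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logsumexp

from ._errors import ValidationError

__all__ = [
    "IRTConfig",
    "ItemParameters",
    "AbilityEstimate",
    "FitTrace",
    "irf",
    "fit_2pl",
    "fit_2pl_multigroup",
    "eap_scores",
    "to_slope_intercept",
    "from_slope_intercept",
]


@dataclass(frozen=True)
class IRTConfig:
    """Quadrature, bounds and convergence settings for the EM fit.

    Defaults: 61 equally spaced nodes on [-6, 6] with renormalised
    standard-normal weights; a in [0.05, 6], b in [-6, 6] with estimates at
    a bound flagged; convergence when the largest parameter change drops
    below ``tol_param`` and the relative log-likelihood change below
    ``tol_loglik``, capped at ``max_iter`` EM cycles.
    """

    n_quadrature: int = 61
    theta_lo: float = -6.0
    theta_hi: float = 6.0
    a_min: float = 0.05
    a_max: float = 6.0
    b_min: float = -6.0
    b_max: float = 6.0
    tol_param: float = 1e-4
    tol_loglik: float = 1e-7
    max_iter: int = 500
    newton_steps: int = 5
    # optional log-normal penalty on a for tiny samples: adds
    # -(log a - mu)^2 / (2 sigma^2) per item when sigma is finite
    a_prior_mu: float = 0.0
    a_prior_sigma: float = float("inf")

    def nodes(self) -> np.ndarray:
        return np.linspace(self.theta_lo, self.theta_hi, self.n_quadrature)

    def log_weights(self, mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
        x = self.nodes()
        logw = -0.5 * ((x - mean) / sd) ** 2
        return logw - logsumexp(logw)


@dataclass(frozen=True)
class ItemParameters:
    """Calibrated 2PL parameters for one item (one language form)."""

    item_id: str
    a: float
    b: float
    se_a: float = float("nan")
    se_b: float = float("nan")
    language: str | None = None
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class AbilityEstimate:
    person_id: str
    theta_eap: float
    theta_sd: float
    flags: frozenset[str] = frozenset()


@dataclass
class FitTrace:
    loglik: list[float] = field(default_factory=list)
    converged: bool = False
    n_quadrature: int = 0
    n_iter: int = 0


def irf(a, b, theta):
    """2PL item response function P(correct | theta) = expit(a (theta - b))."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValidationError("discrimination a must be > 0")
    return expit(a * (np.asarray(theta, dtype=float) - np.asarray(b, dtype=float)))


def to_slope_intercept(a: float, b: float) -> tuple[float, float]:
    """Convert a(theta - b) to slope-intercept (a, c) with c = -a b."""
    return a, -a * b


def from_slope_intercept(a: float, c: float) -> tuple[float, float]:
    return a, -c / a


# ---------------------------------------------------------------------------
# internals


def _prepare(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("response matrix must be 2-D (persons x items)")
    M = (~np.isnan(X)).astype(float)
    X0 = np.where(np.isnan(X), 0.0, X)
    return X0, M


def _degenerate_items(X0: np.ndarray, M: np.ndarray) -> np.ndarray:
    n_obs = M.sum(axis=0)
    n_correct = (X0 * M).sum(axis=0)
    return (n_obs == 0) | (n_correct == 0) | (n_correct == n_obs)


def _item_loglik_tables(a, b, nodes):
    # eta: (J, Q)
    eta = a[:, None] * (nodes[None, :] - b[:, None])
    return log_expit(eta), log_expit(-eta)


def _posterior(X0, M, logP, log1mP, logw):
    """Posterior node weights per person and the marginal log-likelihood."""
    L = X0 @ logP + (M - X0) @ log1mP  # (N, Q)
    L = L + logw[None, :]
    norm = logsumexp(L, axis=1)
    A = np.exp(L - norm[:, None])
    return A, float(norm.sum())


def _mstep_objective(a, b, nodes, r, n, cfg: IRTConfig):
    logP, log1mP = _item_loglik_tables(a, b, nodes)
    obj = (r * logP + (n - r) * log1mP).sum(axis=1)
    if np.isfinite(cfg.a_prior_sigma):
        obj = obj - (np.log(a) - cfg.a_prior_mu) ** 2 / (2 * cfg.a_prior_sigma**2)
    return obj


def _mstep(a, b, nodes, r, n, cfg: IRTConfig):
    """Damped Newton ascent of each item's expected complete-data log-likelihood.

    Uses the Fisher-form 2x2 Hessian (positive definite), vectorised across
    items, with per-item step halving so the objective never decreases —
    this is what guarantees EM monotonicity.
    """
    a = a.copy()
    b = b.copy()
    obj = _mstep_objective(a, b, nodes, r, n, cfg)
    penalized = np.isfinite(cfg.a_prior_sigma)
    for _ in range(cfg.newton_steps):
        t = nodes[None, :] - b[:, None]
        P = expit(a[:, None] * t)
        W = n * P * (1.0 - P)
        R = r - n * P
        ga = (R * t).sum(axis=1)
        gb = -a * R.sum(axis=1)
        Haa = (W * t * t).sum(axis=1)
        Hab = -a * (W * t).sum(axis=1)
        Hbb = a * a * W.sum(axis=1)
        if penalized:
            ga = ga - (np.log(a) - cfg.a_prior_mu) / (cfg.a_prior_sigma**2 * a)
            Haa = Haa + 1.0 / (cfg.a_prior_sigma**2 * a**2)
        Haa = Haa + 1e-10
        Hbb = Hbb + 1e-10
        det = Haa * Hbb - Hab * Hab
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        da = (Hbb * ga - Hab * gb) / det
        db = (Haa * gb - Hab * ga) / det
        step = np.ones_like(a)
        active = np.ones_like(a, dtype=bool)
        new_a, new_b, new_obj = a.copy(), b.copy(), obj.copy()
        for _half in range(12):
            if not active.any():
                break
            cand_a = np.clip(a + step * da, cfg.a_min, cfg.a_max)
            cand_b = np.clip(b + step * db, cfg.b_min, cfg.b_max)
            cand_obj = _mstep_objective(cand_a, cand_b, nodes, r, n, cfg)
            improved = active & (cand_obj >= obj - 1e-12)
            new_a[improved] = cand_a[improved]
            new_b[improved] = cand_b[improved]
            new_obj[improved] = cand_obj[improved]
            active = active & ~improved
            step = np.where(active, step * 0.5, step)
        a, b, obj = new_a, new_b, new_obj
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < 0.1 * cfg.tol_param:
            break
    return a, b


def _start_values(X0, M, cfg: IRTConfig):
    n_obs = np.maximum(M.sum(axis=0), 1.0)
    p = (X0 * M).sum(axis=0) / n_obs
    p = np.clip(p, 0.02, 0.98)
    b0 = np.clip(-np.log(p / (1 - p)) / 1.0, cfg.b_min + 0.5, cfg.b_max - 0.5)
    a0 = np.ones_like(b0)
    return a0, b0


def _standard_errors(X0, M, a, b, nodes, A):
    """Per-item SEs from the cross-product of per-person marginal scores.

    The observed information is approximated block-diagonally: for item j,
    person i's score vector is sum_q A_iq (x_ij - P_jq) (t_jq, -a_j) over
    administered items, and the 2x2 information is the sum of its outer
    products (BHHH).
    """
    t = nodes[None, :] - b[:, None]  # (J, Q)
    P = expit(a[:, None] * t)
    se_a = np.full(a.shape, np.nan)
    se_b = np.full(b.shape, np.nan)
    # E_iq residual weighted: for each item, r_i = sum_q A_iq (x_ij - P_jq)*deriv
    for j in range(a.size):
        resid = (X0[:, j][:, None] - P[j][None, :]) * A  # (N, Q)
        resid = resid * M[:, j][:, None]
        ga = resid @ t[j]  # (N,)
        gb = -a[j] * resid.sum(axis=1)
        info = np.array(
            [[np.dot(ga, ga), np.dot(ga, gb)], [np.dot(ga, gb), np.dot(gb, gb)]]
        )
        try:
            cov = np.linalg.inv(info)
            if cov[0, 0] > 0 and cov[1, 1] > 0:
                se_a[j] = np.sqrt(cov[0, 0])
                se_b[j] = np.sqrt(cov[1, 1])
        except np.linalg.LinAlgError:
            pass
    return se_a, se_b


# ---------------------------------------------------------------------------
# public fits


def fit_2pl(
    matrix,
    item_ids: list[str] | None = None,
    language: str | None = None,
    config: IRTConfig | None = None,
    compute_se: bool = True,
) -> tuple[list[ItemParameters], FitTrace]:
    """Calibrate a 2PL model on one form by Bock–Aitkin MML-EM.

    ``matrix`` is a persons × items array (or ResponseMatrix) of 0/1/NaN.
    Degenerate items (all-correct or all-incorrect) are excluded and flagged
    ``excluded_degenerate``; estimates at a parameter bound are flagged
    ``boundary``; the fit is deterministic given data and config.
    """
    from .responses import ResponseMatrix

    cfg = config or IRTConfig()
    if isinstance(matrix, ResponseMatrix):
        ids = matrix.item_ids
        X = matrix.to_numpy()
    else:
        X = np.asarray(matrix, dtype=float)
        ids = item_ids or [f"item_{j + 1}" for j in range(X.shape[1])]
    X0, M = _prepare(X)
    N, J = X.shape
    degenerate = _degenerate_items(X0, M)
    keep = ~degenerate
    if keep.sum() < 2:
        raise ValidationError("fewer than 2 estimable (non-degenerate) items")

    Xk, Mk = X0[:, keep], M[:, keep]
    nodes = cfg.nodes()
    logw = cfg.log_weights()
    a, b = _start_values(Xk, Mk, cfg)
    trace = FitTrace(n_quadrature=cfg.n_quadrature)
    prev_ll = -np.inf
    for it in range(cfg.max_iter):
        logP, log1mP = _item_loglik_tables(a, b, nodes)
        A, ll = _posterior(Xk, Mk, logP, log1mP, logw)
        trace.loglik.append(ll)
        r = (Xk * Mk).T @ A  # (J, Q) expected correct
        n = Mk.T @ A  # (J, Q) expected administered
        new_a, new_b = _mstep(a, b, nodes, r, n, cfg)
        dpar = max(np.max(np.abs(new_a - a)), np.max(np.abs(new_b - b)))
        a, b = new_a, new_b
        rel_dll = abs(ll - prev_ll) / (abs(ll) + 1.0)
        if it > 0 and dpar < cfg.tol_param and rel_dll < cfg.tol_loglik:
            trace.converged = True
            trace.n_iter = it + 1
            break
        prev_ll = ll
    else:
        trace.n_iter = cfg.max_iter

    if compute_se:
        logP, log1mP = _item_loglik_tables(a, b, nodes)
        A, _ = _posterior(Xk, Mk, logP, log1mP, logw)
        se_a, se_b = _standard_errors(Xk, Mk, a, b, nodes, A)
    else:
        se_a = se_b = np.full(a.shape, np.nan)

    params: list[ItemParameters] = []
    kept_pos = np.flatnonzero(keep)
    pos_of = {int(g): j for j, g in enumerate(kept_pos)}
    eps = 1e-9
    for j, item_id in enumerate(ids):
        if degenerate[j]:
            params.append(
                ItemParameters(
                    item_id,
                    float("nan"),
                    float("nan"),
                    language=language,
                    flags=frozenset({"excluded_degenerate"}),
                )
            )
            continue
        k = pos_of[j]
        flags = set()
        if trace.converged:
            flags.add("converged")
        if (
            a[k] <= cfg.a_min + eps
            or a[k] >= cfg.a_max - eps
            or b[k] <= cfg.b_min + eps
            or b[k] >= cfg.b_max - eps
        ):
            flags.add("boundary")
        params.append(
            ItemParameters(
                item_id,
                float(a[k]),
                float(b[k]),
                float(se_a[k]),
                float(se_b[k]),
                language=language,
                flags=frozenset(flags),
            )
        )
    return params, trace


@dataclass
class MultigroupFit:
    """Result of a shared-parameter multi-group 2PL fit."""

    a: np.ndarray  # (G, J) per-group discriminations (equal unless freed)
    b: np.ndarray  # (G, J)
    group_means: np.ndarray  # (G,) reference fixed at 0
    group_sds: np.ndarray  # (G,) reference fixed at 1
    loglik: float
    trace: FitTrace


def fit_2pl_multigroup(
    matrices: list[np.ndarray],
    free_items: tuple[int, ...] = (),
    config: IRTConfig | None = None,
    init: "MultigroupFit | None" = None,
) -> MultigroupFit:
    """Fit a 2PL jointly over G groups with shared item parameters.

    Items in ``free_items`` (column indices) get group-specific (a, b);
    all others are constrained equal across groups and act as anchors.
    Group 0 is the reference with theta ~ N(0, 1); every other group's
    latent mean and sd are estimated alongside the item parameters.
    Degenerate columns must be handled by the caller (they raise here).
    """
    cfg = config or IRTConfig()
    G = len(matrices)
    prepared = [_prepare(np.asarray(m, dtype=float)) for m in matrices]
    J = prepared[0][0].shape[1]
    for X0, M in prepared:
        if X0.shape[1] != J:
            raise ValidationError("groups must share the same item set")
        if _degenerate_items(X0, M).any():
            raise ValidationError("degenerate item in a group; exclude before fitting")
    free = np.zeros(J, dtype=bool)
    free[list(free_items)] = True

    nodes = cfg.nodes()
    if init is not None:
        a = init.a.copy()
        b = init.b.copy()
        mu = init.group_means.copy()
        sd = init.group_sds.copy()
    else:
        pooled_X0 = np.vstack([p[0] for p in prepared])
        pooled_M = np.vstack([p[1] for p in prepared])
        a1, b1 = _start_values(pooled_X0, pooled_M, cfg)
        a = np.tile(a1, (G, 1))
        b = np.tile(b1, (G, 1))
        mu = np.zeros(G)
        sd = np.ones(G)

    trace = FitTrace(n_quadrature=cfg.n_quadrature)
    prev_ll = -np.inf
    for it in range(cfg.max_iter):
        ll = 0.0
        r_g = np.zeros((G, J, cfg.n_quadrature))
        n_g = np.zeros((G, J, cfg.n_quadrature))
        theta_m1 = np.zeros(G)
        theta_m2 = np.zeros(G)
        for g, (X0, M) in enumerate(prepared):
            logP, log1mP = _item_loglik_tables(a[g], b[g], nodes)
            logw = cfg.log_weights(mu[g], sd[g])
            A, llg = _posterior(X0, M, logP, log1mP, logw)
            ll += llg
            r_g[g] = (X0 * M).T @ A
            n_g[g] = M.T @ A
            w_person = A.mean(axis=0)
            theta_m1[g] = float(w_person @ nodes)
            theta_m2[g] = float(w_person @ nodes**2)
        trace.loglik.append(ll)

        # M-step: anchors use pooled counts; freed items use per-group counts.
        r_pool = r_g.sum(axis=0)
        n_pool = n_g.sum(axis=0)
        anchor_idx = np.flatnonzero(~free)
        if anchor_idx.size:
            a_new, b_new = _mstep(
                a[0, anchor_idx], b[0, anchor_idx], nodes,
                r_pool[anchor_idx], n_pool[anchor_idx], cfg,
            )
        dpar = 0.0
        a_next, b_next = a.copy(), b.copy()
        if anchor_idx.size:
            for g in range(G):
                a_next[g, anchor_idx] = a_new
                b_next[g, anchor_idx] = b_new
            dpar = max(
                np.max(np.abs(a_new - a[0, anchor_idx])),
                np.max(np.abs(b_new - b[0, anchor_idx])),
            )
        free_idx = np.flatnonzero(free)
        for g in range(G):
            if free_idx.size:
                af, bf = _mstep(
                    a[g, free_idx], b[g, free_idx], nodes,
                    r_g[g, free_idx], n_g[g, free_idx], cfg,
                )
                dpar = max(
                    dpar,
                    np.max(np.abs(af - a[g, free_idx])),
                    np.max(np.abs(bf - b[g, free_idx])),
                )
                a_next[g, free_idx] = af
                b_next[g, free_idx] = bf
        a, b = a_next, b_next
        # latent density update for non-reference groups
        for g in range(1, G):
            new_mu = theta_m1[g]
            new_var = max(theta_m2[g] - theta_m1[g] ** 2, 1e-4)
            dpar = max(dpar, abs(new_mu - mu[g]), abs(np.sqrt(new_var) - sd[g]))
            mu[g] = new_mu
            sd[g] = np.sqrt(new_var)

        rel_dll = abs(ll - prev_ll) / (abs(ll) + 1.0)
        if it > 0 and dpar < cfg.tol_param and rel_dll < cfg.tol_loglik:
            trace.converged = True
            trace.n_iter = it + 1
            break
        prev_ll = ll
    else:
        trace.n_iter = cfg.max_iter

    # final marginal log-likelihood at the converged parameters
    ll = 0.0
    for g, (X0, M) in enumerate(prepared):
        logP, log1mP = _item_loglik_tables(a[g], b[g], nodes)
        logw = cfg.log_weights(mu[g], sd[g])
        _, llg = _posterior(X0, M, logP, log1mP, logw)
        ll += llg
    return MultigroupFit(a, b, mu, sd, ll, trace)


def eap_scores(
    matrix,
    params: list[ItemParameters],
    person_ids: list[str] | None = None,
    config: IRTConfig | None = None,
) -> list[AbilityEstimate]:
    """Expected-a-posteriori ability estimates under the N(0, 1) prior.

    Persons with no administered (non-missing) responses get the prior back
    (theta 0, sd 1) with a ``no_responses`` flag.
    """
    from .responses import ResponseMatrix

    cfg = config or IRTConfig()
    if isinstance(matrix, ResponseMatrix):
        X = matrix.to_numpy()
        pids = list(matrix.meta["person_id"].astype(str))
        ids = matrix.item_ids
    else:
        X = np.asarray(matrix, dtype=float)
        pids = person_ids or [f"p{i + 1}" for i in range(X.shape[0])]
        ids = None
    by_id = {p.item_id: p for p in params}
    if ids is not None:
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise ValidationError(f"no parameters for items {missing}")
        plist = [by_id[i] for i in ids]
    else:
        plist = list(params)
    usable = [
        j for j in range(X.shape[1]) if "excluded_degenerate" not in plist[j].flags
    ]
    a = np.array([plist[j].a for j in usable])
    b = np.array([plist[j].b for j in usable])
    X0, M = _prepare(X[:, usable])
    nodes = cfg.nodes()
    logw = cfg.log_weights()
    logP, log1mP = _item_loglik_tables(a, b, nodes)
    A, _ = _posterior(X0, M, logP, log1mP, logw)
    means = A @ nodes
    sds = np.sqrt(np.maximum(A @ nodes**2 - means**2, 1e-12))
    out = []
    none_mask = M.sum(axis=1) == 0
    prior_mean = float(np.exp(logw) @ nodes)
    prior_sd = float(np.sqrt(np.exp(logw) @ nodes**2 - prior_mean**2))
    for i, pid in enumerate(pids):
        if none_mask[i]:
            out.append(AbilityEstimate(pid, 0.0, 1.0, frozenset({"no_responses"})))
        else:
            out.append(AbilityEstimate(pid, float(means[i]), float(sds[i])))
    # keep the quadrature honest: the discretised prior itself should be ~N(0,1)
    assert abs(prior_mean) < 1e-8 and abs(prior_sd - 1.0) < 0.05
    return out


def params_to_frame(params: list[ItemParameters]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "item_id": p.item_id,
                "language": p.language,
                "a": p.a,
                "b": p.b,
                "se_a": p.se_a,
                "se_b": p.se_b,
                "flags": "|".join(sorted(p.flags)),
            }
            for p in params
        ]
    )


def params_from_frame(df: pd.DataFrame) -> list[ItemParameters]:
    out = []
    for _, row in df.iterrows():
        flags = frozenset(
            f for f in str(row.get("flags", "") or "").split("|") if f
        )
        out.append(
            ItemParameters(
                str(row["item_id"]),
                float(row["a"]),
                float(row["b"]),
                float(row.get("se_a", float("nan"))),
                float(row.get("se_b", float("nan"))),
                language=row.get("language"),
                flags=flags,
            )
        )
    return out
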