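"""Seeded generators for synthetic word-recognition scale studies.

The generator reproduces the statistical structure the analysis pipeline
assumes: an 82-item bank in three expert difficulty strata (29/28/25),
three language forms with a shared person-free 2PL response process,
a "separated" difficulty structure for the orthographically deep form
(the hard stratum clearly above the easy ones) versus "compressed"
structures for shallow-orthography forms (stratum means shrunk toward the
grand mean), optional per-item DIF shifts, covariates correlated with the
latent trait, and a two-arm four-timepoint longitudinal design.

Every draw flows from one ``numpy.random.default_rng`` seed, so identical
configs yield byte-identical outputs.  All effect sizes are generator
defaults chosen to mirror the qualitative structure of real instrument
data; they are configuration, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .bank import STRATA, ItemBank, ItemRecord
from .irt import ItemParameters, irf
from .responses import ResponseMatrix

# stratum difficulty means/sds on the latent (logit) scale, separated mode
_SEPARATED_B = {"low": (-0.7, 0.5), "medium": (-0.7, 0.5), "high": (1.3, 0.4)}


@dataclass(frozen=True)
class LanguageSpec:
    """Per-language generating configuration."""

    n: int
    ability_mean: float = 0.0
    ability_sd: float = 1.0
    mode: str = "separated"  # or "compressed"
    compression: float = 0.5  # lambda in (0, 1]; 1 = no compression


@dataclass(frozen=True)
class DIFSpec:
    item_id: str
    language: str
    delta_a: float = 0.0
    delta_b: float = 0.0


@dataclass(frozen=True)
class LongitudinalSpec:
    """Two-arm repeated administration design.

    ``drift``: per-arm ability gain (logits) at each follow-up timepoint;
    ``noise_sd``: within-person occasion noise tau.
    """

    n_per_arm: int = 120
    timepoints: tuple[str, ...] = ("baseline", "m3", "m6", "m12")
    drift: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "intervention": {"m3": 0.40, "m6": 0.35, "m12": 0.50},
            "control": {"m3": 0.0, "m6": 0.0, "m12": 0.0},
        }
    )
    noise_sd: float = 0.30
    language: str = "ko"


@dataclass(frozen=True)
class CovariateSpec:
    """Latent-trait loadings for convergent-validity covariates.

    Each covariate is rho * theta + sqrt(1 - rho^2) * noise, optionally
    discretised into equal-probability ordinal levels.
    """

    loadings: dict[str, float] = field(
        default_factory=lambda: {"nvs": 0.50, "education": 0.45, "dm_knowledge": 0.35}
    )
    levels: dict[str, int] = field(
        default_factory=lambda: {"nvs": 7, "education": 4}
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    items_per_stratum: dict[str, int] = field(
        default_factory=lambda: {"low": 29, "medium": 28, "high": 25}
    )
    languages: dict[str, LanguageSpec] = field(
        default_factory=lambda: {
            "en": LanguageSpec(n=261, mode="separated"),
            "es": LanguageSpec(n=128, mode="compressed"),
            "ko": LanguageSpec(n=245, mode="compressed"),
        }
    )
    discrimination_range: tuple[float, float] = (0.8, 2.0)
    dif: tuple[DIFSpec, ...] = ()
    longitudinal: LongitudinalSpec = field(default_factory=LongitudinalSpec)
    covariates: CovariateSpec = field(default_factory=CovariateSpec)


@dataclass(frozen=True)
class GeneratedBank:
    bank: ItemBank
    truth: pd.DataFrame  # item_id, stratum, language, a, b

    def params_for(self, language: str) -> list[ItemParameters]:
        sub = self.truth[self.truth["language"] == language]
        return [
            ItemParameters(row["item_id"], row["a"], row["b"], language=language)
            for _, row in sub.iterrows()
        ]


def generate_item_bank(config: SimulationConfig | None = None) -> GeneratedBank:
    """Draw an item bank plus true 2PL parameters per language form.

    One standardised difficulty draw per item is shared across languages, so
    a compressed form with lambda = 1 has exactly the separated structure;
    discriminations are shared too, and DIF shifts are applied on top.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    for lang, spec in cfg.languages.items():
        if not (0.0 < spec.compression <= 1.0):
            raise ValidationError(
                f"language {lang!r}: compression must be in (0, 1], got {spec.compression}"
            )
    counts = cfg.items_per_stratum
    items, strata = [], []
    for s in STRATA:
        for k in range(counts.get(s, 0)):
            items.append(f"{s[0]}{k + 1:02d}")
            strata.append(s)
    if not items:
        raise ValidationError("no items configured")
    J = len(items)
    z = rng.standard_normal(J)  # shared standardized difficulty residuals
    a = rng.uniform(*cfg.discrimination_range, size=J)

    n_weights = np.array([counts[s] for s in STRATA if counts.get(s, 0) > 0], float)
    mus = np.array([_SEPARATED_B[s][0] for s in STRATA if counts.get(s, 0) > 0])
    grand_mean = float((n_weights * mus).sum() / n_weights.sum())

    rows = []
    for lang, spec in cfg.languages.items():
        lam = 1.0 if spec.mode == "separated" else spec.compression
        for j, (item_id, s) in enumerate(zip(items, strata)):
            mu, sd = _SEPARATED_B[s]
            mu_lang = grand_mean + lam * (mu - grand_mean)
            b = mu_lang + sd * z[j]
            aj = a[j]
            for d in cfg.dif:
                if d.item_id == item_id and d.language == lang:
                    aj = aj + d.delta_a
                    b = b + d.delta_b
            rows.append(
                {"item_id": item_id, "stratum": s, "language": lang, "a": aj, "b": b}
            )
    truth = pd.DataFrame(rows)
    records = tuple(
        ItemRecord(
            item_id,
            {lang: f"w_{item_id}_{lang}" for lang in cfg.languages},
            s,
        )
        for item_id, s in zip(items, strata)
    )
    bank = ItemBank(records, tuple(cfg.languages))
    return GeneratedBank(bank, truth)


def _responses_from_theta(a, b, theta, rng) -> np.ndarray:
    P = irf(a[None, :], b[None, :], theta[:, None])
    return (rng.random(P.shape) < P).astype(float)


def generate_responses(
    generated: GeneratedBank,
    language: str,
    n: int | None = None,
    ability_mean: float | None = None,
    ability_sd: float | None = None,
    seed: int = 0,
    config: SimulationConfig | None = None,
    person_prefix: str | None = None,
) -> tuple[ResponseMatrix, np.ndarray]:
    """Simulate one cross-sectional administration of a language form.

    theta_i ~ N(mean, sd^2); X_ij ~ Bernoulli(irf(a_j, b_j, theta_i)).
    Returns the response matrix and the generating abilities.
    """
    cfg = config or SimulationConfig()
    spec = cfg.languages.get(language)
    if spec is None:
        spec = LanguageSpec(n=n or 0)
    n = n if n is not None else spec.n
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    mean = ability_mean if ability_mean is not None else spec.ability_mean
    sd = ability_sd if ability_sd is not None else spec.ability_sd
    sub = generated.truth[generated.truth["language"] == language]
    if sub.empty:
        raise ValidationError(f"no truth table for language {language!r}")
    rng = np.random.default_rng(seed)
    theta = mean + sd * rng.standard_normal(n)
    X = _responses_from_theta(
        sub["a"].to_numpy(), sub["b"].to_numpy(), theta, rng
    )
    prefix = person_prefix or language
    meta = pd.DataFrame(
        {
            "person_id": [f"{prefix}{i + 1:04d}" for i in range(n)],
            "language": language,
            "arm": "none",
            "timepoint": "none",
        }
    )
    values = pd.DataFrame(X, columns=sub["item_id"].tolist())
    return ResponseMatrix(values, meta), theta


def generate_longitudinal(
    generated: GeneratedBank,
    spec: LongitudinalSpec | None = None,
    seed: int = 0,
) -> ResponseMatrix:
    """Simulate a two-arm longitudinal administration.

    Person i in arm g at timepoint t has theta_i(t) = theta_i(0) +
    drift_g(t) + eps_it with occasion noise eps ~ N(0, tau^2); responses are
    regenerated from the 2PL at every timepoint.  Rows are stacked per
    timepoint with arm/timepoint metadata.
    """
    spec = spec or LongitudinalSpec()
    if len(spec.timepoints) < 2:
        raise ValidationError("need >= 2 timepoints")
    if spec.timepoints[0] != "baseline":
        raise ValidationError("first timepoint must be 'baseline'")
    sub = generated.truth[generated.truth["language"] == spec.language]
    if sub.empty:
        raise ValidationError(f"no truth table for language {spec.language!r}")
    a, b = sub["a"].to_numpy(), sub["b"].to_numpy()
    rng = np.random.default_rng(seed)
    arms = list(spec.drift)
    frames_vals, frames_meta = [], []
    for arm in arms:
        theta0 = rng.standard_normal(spec.n_per_arm)
        pids = [f"{arm[:3]}{i + 1:04d}" for i in range(spec.n_per_arm)]
        for tp in spec.timepoints:
            delta = 0.0 if tp == "baseline" else spec.drift[arm].get(tp, 0.0)
            eps = (
                np.zeros(spec.n_per_arm)
                if tp == "baseline"
                else spec.noise_sd * rng.standard_normal(spec.n_per_arm)
            )
            theta = theta0 + delta + eps
            X = _responses_from_theta(a, b, theta, rng)
            frames_vals.append(pd.DataFrame(X, columns=sub["item_id"].tolist()))
            frames_meta.append(
                pd.DataFrame(
                    {
                        "person_id": pids,
                        "language": spec.language,
                        "arm": arm,
                        "timepoint": tp,
                    }
                )
            )
    return ResponseMatrix(
        pd.concat(frames_vals, ignore_index=True),
        pd.concat(frames_meta, ignore_index=True),
    )


def generate_covariates(
    theta: np.ndarray,
    spec: CovariateSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw covariates with prescribed latent-trait correlations.

    cov = rho * theta_std + sqrt(1 - rho^2) * z; covariates named in
    ``spec.levels`` are discretised into that many equal-probability ordinal
    levels (0 .. levels-1) by normal quantiles.
    """
    spec = spec or CovariateSpec()
    theta = np.asarray(theta, dtype=float)
    rng = np.random.default_rng(seed)
    sdt = theta.std()
    theta_std = (theta - theta.mean()) / (sdt if sdt > 0 else 1.0)
    out = {}
    for name, rho in spec.loadings.items():
        if abs(rho) > 1.0:
            raise ValidationError(f"covariate {name!r}: |rho| must be <= 1, got {rho}")
        z = rng.standard_normal(theta.size)
        latent = rho * theta_std + np.sqrt(1.0 - rho * rho) * z
        levels = spec.levels.get(name)
        if levels:
            from scipy.stats import norm

            edges = norm.ppf(np.linspace(0, 1, levels + 1)[1:-1])
            latent = np.digitize(latent, edges).astype(float)
        out[f"cov_{name}"] = latent
    return pd.DataFrame(out)


def generate_study(config: SimulationConfig | None = None) -> dict:
    """Full synthetic study: bank + cross-sectional matrices with covariates
    per language + a longitudinal matrix.  Seeds for the sub-draws are
    derived deterministically from ``config.seed``."""
    cfg = config or SimulationConfig()
    gen = generate_item_bank(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    child = ss.spawn(len(cfg.languages) + 1)
    cross: dict[str, ResponseMatrix] = {}
    for k, lang in enumerate(cfg.languages):
        sub_seed = int(child[k].generate_state(1)[0] % (2**31 - 1))
        mat, theta = generate_responses(gen, lang, seed=sub_seed, config=cfg)
        covs = generate_covariates(theta, cfg.covariates, seed=sub_seed + 1)
        mat = ResponseMatrix(mat.values, pd.concat([mat.meta, covs], axis=1))
        cross[lang] = mat
    long_seed = int(child[-1].generate_state(1)[0] % (2**31 - 1))
    longitudinal = generate_longitudinal(gen, cfg.longitudinal, seed=long_seed)
    return {"bank": gen, "cross_sectional": cross, "longitudinal": longitudinal}


def marginal_proportion(a: float, b: float, mean: float = 0.0, sd: float = 1.0,
                        n_nodes: int = 301) -> float:
    """Quadrature-integrated P(correct) = ∫ irf(a,b,theta) dN(mean, sd^2)."""
    x = np.linspace(mean - 8 * sd, mean + 8 * sd, n_nodes)
    w = np.exp(-0.5 * ((x - mean) / sd) ** 2)
    w /= w.sum()
    return float((w * irf(a, b, x)).sum())
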