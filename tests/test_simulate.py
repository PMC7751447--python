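"""Generator determinism and fidelity to the intended response process."""

import numpy as np
import pytest

from realmkit._errors import ValidationError
from realmkit.simulate import (
    CovariateSpec,
    LanguageSpec,
    LongitudinalSpec,
    SimulationConfig,
    generate_covariates,
    generate_item_bank,
    generate_longitudinal,
    generate_responses,
    generate_study,
    marginal_proportion,
)
from realmkit.validity import sensitivity_analysis
import pandas as pd


class TestItemBankGeneration:
    def test_default_stratum_counts(self):
        gen = generate_item_bank(SimulationConfig(seed=0))
        assert gen.bank.stratum_counts() == {"low": 29, "medium": 28, "high": 25}
        assert len(gen.bank) == 82
        assert set(gen.truth["language"]) == {"en", "es", "ko"}

    def test_lambda_one_reproduces_separated_structure(self):
        cfg = SimulationConfig(
            seed=2,
            languages={
                "en": LanguageSpec(n=10, mode="separated"),
                "ko": LanguageSpec(n=10, mode="compressed", compression=1.0),
            },
        )
        gen = generate_item_bank(cfg)
        b_en = gen.truth[gen.truth["language"] == "en"]["b"].to_numpy()
        b_ko = gen.truth[gen.truth["language"] == "ko"]["b"].to_numpy()
        assert np.allclose(b_en, b_ko)

    def test_invalid_compression_rejected(self):
        cfg = SimulationConfig(
            languages={"en": LanguageSpec(n=10, mode="compressed", compression=0.0)}
        )
        with pytest.raises(ValidationError, match="compression"):
            generate_item_bank(cfg)

    def test_dif_spec_shifts_focal_parameters_only(self):
        from realmkit.simulate import DIFSpec

        cfg = SimulationConfig(
            seed=3,
            languages={
                "en": LanguageSpec(n=10),
                "ko": LanguageSpec(n=10, mode="compressed", compression=1.0),
            },
            dif=(DIFSpec("l01", "ko", delta_b=0.9),),
        )
        gen = generate_item_bank(cfg)
        t = gen.truth.set_index(["language", "item_id"])
        assert t.loc[("ko", "l01"), "b"] - t.loc[("en", "l01"), "b"] == pytest.approx(0.9)
        assert t.loc[("ko", "l02"), "b"] == pytest.approx(t.loc[("en", "l02"), "b"])


class TestResponses:
    def test_same_seed_identical_different_seed_differs(self):
        gen = generate_item_bank(SimulationConfig(seed=1))
        m1, _ = generate_responses(gen, "en", n=50, seed=9)
        m2, _ = generate_responses(gen, "en", n=50, seed=9)
        m3, _ = generate_responses(gen, "en", n=50, seed=10)
        assert m1.equals(m2)
        assert not np.array_equal(m1.to_numpy(), m3.to_numpy())

    def test_symmetric_item_hits_half(self):
        import pandas as pd

        from realmkit.bank import ItemBank, ItemRecord
        from realmkit.simulate import GeneratedBank

        truth = pd.DataFrame(
            [{"item_id": "x", "stratum": "low", "language": "en", "a": 1.0, "b": 0.0}]
        )
        bank = ItemBank((ItemRecord("x", {"en": "x"}, "low"),), ("en",))
        gen = GeneratedBank(bank, truth)
        mat, _ = generate_responses(gen, "en", n=10_000, seed=0)
        assert mat.to_numpy().mean() == pytest.approx(0.5, abs=0.02)

    def test_marginal_proportions_match_quadrature(self):
        cfg = SimulationConfig(
            seed=6, languages={"en": LanguageSpec(n=4000)},
            items_per_stratum={"low": 4, "medium": 4, "high": 4},
        )
        gen = generate_item_bank(cfg)
        mat, _ = generate_responses(gen, "en", seed=7, config=cfg)
        truth = gen.truth[gen.truth["language"] == "en"]
        emp = mat.to_numpy().mean(axis=0)
        for j, (_, row) in enumerate(truth.iterrows()):
            expected = marginal_proportion(row["a"], row["b"])
            mc_se = np.sqrt(expected * (1 - expected) / 4000)
            assert abs(emp[j] - expected) < 3.5 * mc_se

    def test_invalid_n_rejected(self):
        gen = generate_item_bank(SimulationConfig(seed=1))
        with pytest.raises(ValidationError, match="n must be"):
            generate_responses(gen, "en", n=0, seed=1)


class TestLongitudinal:
    def small_gen(self):
        return generate_item_bank(
            SimulationConfig(
                seed=4,
                items_per_stratum={"low": 5, "medium": 5, "high": 5},
                languages={"ko": LanguageSpec(n=10, mode="compressed")},
            )
        )

    def test_null_drift_gives_near_zero_change(self):
        spec = LongitudinalSpec(
            n_per_arm=400,
            drift={"intervention": {}, "control": {}},
            language="ko",
        )
        mat = generate_longitudinal(self.small_gen(), spec, seed=5)
        scores = pd.DataFrame(
            {
                "person_id": mat.meta["person_id"],
                "arm": mat.meta["arm"],
                "timepoint": mat.meta["timepoint"],
                "percent": mat.percent_scores(),
            }
        )
        tab = sensitivity_analysis(scores)
        diff = tab[tab["row"] == "difference"].iloc[0]
        for tp in ("m3", "m6", "m12"):
            assert abs(diff[f"{tp}_mean"]) < 3.0 * diff[f"{tp}_se"] + 1e-9

    def test_missing_baseline_rejected(self):
        spec = LongitudinalSpec(timepoints=("m3", "m6"), language="ko")
        with pytest.raises(ValidationError, match="baseline"):
            generate_longitudinal(self.small_gen(), spec, seed=1)

    def test_seeds_change_data_not_structure(self):
        spec = LongitudinalSpec(n_per_arm=20, language="ko")
        m1 = generate_longitudinal(self.small_gen(), spec, seed=1)
        m2 = generate_longitudinal(self.small_gen(), spec, seed=2)
        assert not np.array_equal(m1.to_numpy(), m2.to_numpy())
        assert m1.meta[["arm", "timepoint"]].equals(m2.meta[["arm", "timepoint"]])
        assert m1.n_persons == 2 * 20 * 4


class TestCovariates:
    def test_perfect_loading_perfectly_correlated(self, rng):
        theta = rng.standard_normal(500)
        covs = generate_covariates(theta, CovariateSpec(loadings={"x": 1.0}, levels={}),
                                   seed=3)
        assert np.corrcoef(theta, covs["cov_x"])[0, 1] == pytest.approx(1.0)

    def test_zero_loading_uncorrelated(self, rng):
        theta = rng.standard_normal(2000)
        covs = generate_covariates(theta, CovariateSpec(loadings={"x": 0.0}, levels={}),
                                   seed=4)
        assert abs(np.corrcoef(theta, covs["cov_x"])[0, 1]) < 0.05

    def test_loading_recovered_empirically(self, rng):
        theta = rng.standard_normal(2000)
        covs = generate_covariates(theta, CovariateSpec(loadings={"x": 0.6}, levels={}),
                                   seed=5)
        assert np.corrcoef(theta, covs["cov_x"])[0, 1] == pytest.approx(0.6, abs=0.05)

    def test_invalid_loading_rejected(self, rng):
        with pytest.raises(ValidationError, match="rho"):
            generate_covariates(rng.standard_normal(10),
                                CovariateSpec(loadings={"x": 1.5}, levels={}), seed=1)

    def test_discretized_levels(self, rng):
        theta = rng.standard_normal(1000)
        covs = generate_covariates(
            theta, CovariateSpec(loadings={"edu": 0.5}, levels={"edu": 4}), seed=6
        )
        assert set(np.unique(covs["cov_edu"])) <= {0.0, 1.0, 2.0, 3.0}


class TestFullStudy:
    def test_study_determinism_by_seed(self, tiny_config):
        s1 = generate_study(tiny_config)
        s2 = generate_study(tiny_config)
        for lang in s1["cross_sectional"]:
            assert s1["cross_sectional"][lang].equals(s2["cross_sectional"][lang])
        assert s1["longitudinal"].equals(s2["longitudinal"])

    def test_default_sample_sizes(self):
        cfg = SimulationConfig()
        assert {k: v.n for k, v in cfg.languages.items()} == {
            "en": 261, "es": 128, "ko": 245,
        }
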