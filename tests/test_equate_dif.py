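"""Mean/sigma equating identities and DIF likelihood-ratio behaviour."""

import numpy as np
import pytest

from realmkit._errors import ValidationError
from realmkit.dif import dif_test
from realmkit.equate import (
    difficulty_separation_report,
    mean_sigma_equate,
)
from realmkit.irt import ItemParameters
from realmkit.simulate import LanguageSpec, SimulationConfig, generate_item_bank

from .conftest import simulate_2pl


def make_params(b_values, a_values=None, language=None):
    if a_values is None:
        a_values = [1.0] * len(b_values)
    return [
        ItemParameters(f"i{k}", float(a), float(b), language=language)
        for k, (a, b) in enumerate(zip(a_values, b_values))
    ]


class TestMeanSigmaEquating:
    def test_self_equating_is_identity(self):
        params = make_params([-1.0, 0.2, 1.5], [0.9, 1.3, 1.8])
        tr, transformed = mean_sigma_equate(params, params)
        assert tr.A == pytest.approx(1.0, abs=1e-12)
        assert tr.B == pytest.approx(0.0, abs=1e-12)
        for p, q in zip(params, transformed):
            assert q.b == pytest.approx(p.b, abs=1e-12)
            assert q.a == pytest.approx(p.a, abs=1e-12)

    def test_hand_computed_constants(self):
        focal = make_params([0.0, 1.0, 2.0])
        ref = make_params([-1.0, 1.0, 3.0])
        tr, transformed = mean_sigma_equate(focal, ref)
        assert tr.A == pytest.approx(2.0)
        assert tr.B == pytest.approx(-1.0)
        assert [p.b for p in transformed] == pytest.approx([-1.0, 1.0, 3.0])
        assert [p.a for p in transformed] == pytest.approx([0.5, 0.5, 0.5])

    def test_moment_matching_forced(self, rng):
        focal = make_params(rng.normal(0.5, 1.2, 12), rng.uniform(0.8, 2, 12))
        ref = make_params(rng.normal(-0.2, 0.7, 12), rng.uniform(0.8, 2, 12))
        tr, transformed = mean_sigma_equate(focal, ref)
        b_t = np.array([p.b for p in transformed])
        b_r = np.array([p.b for p in ref])
        assert abs(b_t.mean() - b_r.mean()) < 1e-8
        assert abs(np.std(b_t, ddof=1) - np.std(b_r, ddof=1)) < 1e-8

    def test_idempotent_and_composable(self, rng):
        focal = make_params(rng.normal(1.0, 2.0, 8))
        ref1 = make_params(rng.normal(0.0, 1.0, 8))
        ref2 = make_params(rng.normal(-0.5, 0.6, 8))
        tr1, step1 = mean_sigma_equate(focal, ref1)
        tr_again, _ = mean_sigma_equate(step1, ref1)
        assert tr_again.A == pytest.approx(1.0, abs=1e-8)
        assert tr_again.B == pytest.approx(0.0, abs=1e-8)
        tr12, step12 = mean_sigma_equate(step1, ref2)
        tr_direct, direct = mean_sigma_equate(focal, ref2)
        for p, q in zip(step12, direct):
            assert p.b == pytest.approx(q.b, abs=1e-10)

    def test_zero_focal_sd_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            mean_sigma_equate(make_params([1.0, 1.0, 1.0]), make_params([0.0, 1.0, 2.0]))

    def test_mismatched_item_sets_listed(self):
        focal = make_params([0.0, 1.0, 2.0])
        ref = make_params([0.0, 1.0, 2.0])
        ref[2] = ItemParameters("other", 1.0, 2.0)
        with pytest.raises(ValidationError, match="i2.*other"):
            mean_sigma_equate(focal, ref)


class TestSeparationReport:
    def stratum_map(self, params, strata):
        return {p.item_id: s for p, s in zip(params, strata)}

    def test_separated_strata_positive_index(self):
        params = make_params([-1.0, -1.0, 2.0, 2.0])
        rep = difficulty_separation_report(
            params, self.stratum_map(params, ["low", "low", "high", "high"])
        )
        assert rep.separation_index > 0

    def test_equal_difficulties_zero_index(self):
        params = make_params([0.5, 0.5, 0.5, 0.5])
        rep = difficulty_separation_report(
            params, self.stratum_map(params, ["low", "medium", "high", "high"])
        )
        assert rep.separation_index == 0.0

    def test_single_item_stratum_sd_omitted(self):
        params = make_params([-1.0, 0.0, 2.0])
        rep = difficulty_separation_report(
            params, self.stratum_map(params, ["low", "medium", "high"])
        )
        high = next(s for s in rep.by_stratum if s.stratum == "high")
        assert np.isnan(high.sd_b)

    def test_separated_generator_beats_compressed(self):
        cfg = SimulationConfig(
            seed=3,
            languages={
                "en": LanguageSpec(n=100, mode="separated"),
                "ko": LanguageSpec(n=100, mode="compressed", compression=0.4),
            },
        )
        gen = generate_item_bank(cfg)
        stratum_of = gen.bank.stratum_of()
        rep_en = difficulty_separation_report(gen.params_for("en"), stratum_of)
        rep_ko = difficulty_separation_report(gen.params_for("ko"), stratum_of)
        assert rep_en.separation_index > rep_ko.separation_index


class TestDIF:
    @pytest.fixture(scope="class")
    def truth(self):
        rng = np.random.default_rng(8)
        return rng.uniform(0.8, 2.0, 12), rng.uniform(-1.5, 1.5, 12)

    def test_identical_groups_give_near_zero_statistic(self, truth, rng):
        a, b = truth
        X = simulate_2pl(a, b, rng.standard_normal(250), rng)
        res = dif_test(X, X.copy(), items_to_test=["item_1", "item_5"])
        for r in res:
            assert r.statistic < 0.01
            assert not r.flagged

    def test_large_difficulty_shift_detected_with_direction(self, truth, rng):
        a, b = truth
        b_shifted = b.copy()
        b_shifted[3] += 1.2
        Xr = simulate_2pl(a, b, rng.standard_normal(400), rng)
        Xf = simulate_2pl(a, b_shifted, rng.standard_normal(400) + 0.3, rng)
        res = dif_test(Xr, Xf, items_to_test=["item_4"])
        assert res[0].flagged
        assert res[0].direction == 1
        assert res[0].df == 2

    def test_group_label_swap_preserves_statistic_and_flips_direction(
        self, truth, rng
    ):
        a, b = truth
        b_shifted = b.copy()
        b_shifted[0] += 1.0
        Xr = simulate_2pl(a, b, rng.standard_normal(350), rng)
        Xf = simulate_2pl(a, b_shifted, rng.standard_normal(350), rng)
        fwd = dif_test(Xr, Xf, items_to_test=["item_1"])[0]
        rev = dif_test(Xf, Xr, items_to_test=["item_1"])[0]
        assert fwd.statistic == pytest.approx(rev.statistic, rel=0.05, abs=0.5)
        assert fwd.direction == -rev.direction

    def test_item_order_invariance(self, truth, rng):
        a, b = truth
        Xr = simulate_2pl(a, b, rng.standard_normal(300), rng)
        Xf = simulate_2pl(a, b, rng.standard_normal(300), rng)
        perm = rng.permutation(len(a))
        ids = [f"item_{j + 1}" for j in range(len(a))]
        res1 = dif_test(Xr, Xf, items_to_test=["item_3"])
        res2 = dif_test(
            Xr[:, perm], Xf[:, perm],
            item_ids=[ids[j] for j in perm],
            items_to_test=["item_3"],
        )
        assert res1[0].statistic == pytest.approx(res2[0].statistic, rel=0.02, abs=0.05)

    def test_degenerate_item_reported_not_testable(self, truth, rng):
        a, b = truth
        Xr = simulate_2pl(a, b, rng.standard_normal(200), rng)
        Xf = simulate_2pl(a, b, rng.standard_normal(200), rng)
        Xf[:, 2] = 1.0
        res = dif_test(Xr, Xf)
        by_id = {r.item_id: r for r in res}
        assert not by_id["item_3"].testable
        assert np.isnan(by_id["item_3"].statistic)

    def test_bh_adjustment_never_below_raw_p(self, truth, rng):
        a, b = truth
        Xr = simulate_2pl(a, b, rng.standard_normal(250), rng)
        Xf = simulate_2pl(a, b, rng.standard_normal(250), rng)
        res = dif_test(Xr, Xf)
        for r in res:
            if r.testable:
                assert r.adjusted_p >= r.p_value - 1e-12
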