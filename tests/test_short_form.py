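"""Spline mean curve, largest-remainder quotas and stratified selection."""

import numpy as np
import pandas as pd
import pytest

from realmkit._errors import ValidationError
from realmkit.bank import ItemBank, ItemRecord
from realmkit.ctt import ItemStatistics
from realmkit.short_form import (
    allocate_quotas,
    fit_mean_curve,
    multi_language_review,
    select_items,
)


def stats_from(p, r, prefix="i", language="en"):
    return [
        ItemStatistics(f"{prefix}{k + 1}", language, float(pp), float(rr), 100)
        for k, (pp, rr) in enumerate(zip(p, r))
    ]


def one_stratum_bank(n, stratum="low", prefix="i"):
    items = tuple(
        ItemRecord(f"{prefix}{k + 1}", {"en": f"w{k + 1}"}, stratum) for k in range(n)
    )
    return ItemBank(items, ("en",))


class TestMeanCurve:
    def test_collinear_points_interpolated(self):
        p = np.linspace(20, 90, 12)
        r = 0.3 + 0.002 * p
        curve = fit_mean_curve(stats_from(p, r))
        assert np.allclose(curve(p), r, atol=1e-6)
        assert all(abs(v) < 1e-6 for v in curve.residuals.values())

    def test_recovers_smooth_curve_within_noise(self):
        rng = np.random.default_rng(4)
        p = np.linspace(10, 95, 60)
        truth = 0.5 + 0.2 * np.sin(p / 25.0)
        noise_sd = 0.03
        r = truth + rng.normal(0, noise_sd, p.size)
        curve = fit_mean_curve(stats_from(p, r))
        assert np.max(np.abs(curve(p) - truth)) < 3 * noise_sd

    def test_duplicate_percent_values_fit_succeeds(self):
        p = [20, 30, 30, 50, 50, 70, 70, 90]
        r = [0.15, 0.2, 0.4, 0.5, 0.3, 0.6, 0.7, 0.65]
        curve = fit_mean_curve(stats_from(p, r))
        assert np.isfinite(curve(50.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match=">= 5"):
            fit_mean_curve(stats_from([10, 20, 30], [0.1, 0.2, 0.3]))

    def test_small_sample_uses_fixed_df_fallback(self):
        p = np.array([10, 25, 40, 55, 70, 85, 95], dtype=float)
        r = np.array([0.2, 0.35, 0.5, 0.55, 0.6, 0.58, 0.5])
        curve = fit_mean_curve(stats_from(p, r))
        assert curve.effective_df == pytest.approx(4.0)
        # residuals of a penalized fit average out over the data
        assert abs(np.mean(list(curve.residuals.values()))) < 0.05


class TestQuotas:
    @pytest.mark.parametrize(
        "sizes, L, expected",
        [
            ({"low": 29, "medium": 28, "high": 25}, 40, (14, 14, 12)),
            ({"low": 29, "medium": 28, "high": 25}, 20, (7, 7, 6)),
            ({"low": 10, "medium": 10, "high": 10}, 30, (10, 10, 10)),
            ({"low": 3, "medium": 3, "high": 4}, 5, (2, 1, 2)),
        ],
    )
    def test_largest_remainder(self, sizes, L, expected):
        q = allocate_quotas(sizes, L)
        assert (q.quotas["low"], q.quotas["medium"], q.quotas["high"]) == expected
        assert sum(q.quotas.values()) == L

    def test_overlong_target_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            allocate_quotas({"low": 3, "medium": 3, "high": 3}, 10)

    @pytest.mark.parametrize("L", range(1, 83, 7))
    def test_quota_sum_invariant(self, L):
        q = allocate_quotas({"low": 29, "medium": 28, "high": 25}, L)
        assert sum(q.quotas.values()) == L
        assert all(q.quotas[s] <= q.stratum_sizes[s] for s in q.quotas)


class TestSelection:
    def test_residual_ranking(self):
        bank = one_stratum_bank(6)
        residuals = [0.05, -0.02, 0.03, 0.00, -0.01, 0.04]
        p = np.full(6, 50.0)
        r = np.array(residuals) + 0.5  # flat curve at 0.5
        stats = stats_from(p, r)
        curve = fit_mean_curve(
            stats_from(np.linspace(10, 90, 9), np.full(9, 0.5), prefix="c")
        )
        curve.residuals = {f"i{k + 1}": residuals[k] for k in range(6)}
        quotas = allocate_quotas({"low": 6}, 3)
        sel = select_items(stats, curve, quotas, bank)
        assert sel.selected["low"] == ["i1", "i6", "i3"]

    def test_quota_equal_to_stratum_takes_all(self):
        bank = one_stratum_bank(4)
        stats = stats_from([30, 40, 50, 60], [0.2, 0.8, 0.3, 0.7])
        curve = fit_mean_curve(
            stats_from(np.linspace(10, 90, 9), np.full(9, 0.5), prefix="c")
        )
        sel = select_items(stats, curve, allocate_quotas({"low": 4}, 4), bank)
        assert sorted(sel.selected["low"]) == ["i1", "i2", "i3", "i4"]

    def _three_stratum_setup(self, seed=0, J=(10, 9, 8)):
        rng = np.random.default_rng(seed)
        items, strata = [], []
        for s, n in zip(("low", "medium", "high"), J):
            for k in range(n):
                items.append(f"{s[0]}{k + 1}")
                strata.append(s)
        bank = ItemBank(
            tuple(ItemRecord(i, {"en": i}, s) for i, s in zip(items, strata)), ("en",)
        )
        p = rng.uniform(15, 90, len(items))
        r = 0.4 + 0.002 * p + rng.normal(0, 0.05, len(items))
        stats = [
            ItemStatistics(i, "en", float(pp), float(rr), 100)
            for i, pp, rr in zip(items, p, r)
        ]
        return bank, stats

    def test_nested_selection_is_subset_with_quota_counts(self):
        bank, stats = self._three_stratum_setup()
        curve = fit_mean_curve(stats)
        q40 = allocate_quotas(bank.stratum_counts(), 12)
        sel_long = select_items(stats, curve, q40, bank)
        q20 = allocate_quotas(bank.stratum_counts(), 6)
        sel_short = select_items(stats, curve, q20, bank, parent=sel_long)
        assert set(sel_short.selected_ids) <= set(sel_long.selected_ids)
        assert {s: len(v) for s, v in sel_short.selected.items()} == q20.quotas

    def test_selection_invariant_to_item_input_order(self):
        bank, stats = self._three_stratum_setup(seed=5)
        curve = fit_mean_curve(stats)
        quotas = allocate_quotas(bank.stratum_counts(), 10)
        sel1 = select_items(stats, curve, quotas, bank)
        rng = np.random.default_rng(1)
        shuffled = list(stats)
        rng.shuffle(shuffled)
        sel2 = select_items(shuffled, curve, quotas, bank)
        assert sel1.selected == sel2.selected

    def test_selected_residuals_dominate_unselected(self):
        bank, stats = self._three_stratum_setup(seed=9)
        curve = fit_mean_curve(stats)
        quotas = allocate_quotas(bank.stratum_counts(), 12)
        sel = select_items(stats, curve, quotas, bank)
        table = sel.table
        for stratum in ("low", "medium", "high"):
            sub = table[table["stratum"] == stratum]
            chosen = sub[sub["selected"]]["residual"]
            passed = sub[~sub["selected"]]["residual"]
            if len(chosen) and len(passed):
                assert chosen.min() >= passed.max() - 1e-12

    def test_p_range_excludes_extreme_items(self):
        bank = one_stratum_bank(6)
        stats = stats_from([2, 50, 55, 60, 65, 98], [0.9, 0.5, 0.52, 0.54, 0.56, 0.9])
        curve = fit_mean_curve(
            stats_from(np.linspace(10, 90, 9), np.full(9, 0.5), prefix="c")
        )
        curve.residuals = {s.item_id: s.item_total_corr - 0.5 for s in stats}
        sel = select_items(stats, curve, allocate_quotas({"low": 6}, 2), bank,
                           p_range=(5.0, 95.0))
        assert "i1" not in sel.selected["low"]
        assert "i6" not in sel.selected["low"]

    def test_below_curve_fill_flagged(self):
        bank = one_stratum_bank(4)
        stats = stats_from([40, 50, 60, 70], [0.45, 0.44, 0.43, 0.55])
        curve = fit_mean_curve(
            stats_from(np.linspace(10, 90, 9), np.full(9, 0.5), prefix="c")
        )
        curve.residuals = {s.item_id: s.item_total_corr - 0.5 for s in stats}
        sel = select_items(stats, curve, allocate_quotas({"low": 4}, 3), bank)
        assert "below_curve_fill" in sel.flags


class TestMultiLanguageReview:
    def test_review_rows_count_and_classification(self):
        bank, stats_en = TestSelection()._three_stratum_setup(seed=2)
        curve = fit_mean_curve(stats_en)
        quotas = allocate_quotas(bank.stratum_counts(), 9)
        sel = select_items(stats_en, curve, quotas, bank, language="en")
        rng = np.random.default_rng(3)
        stats_ko = [
            ItemStatistics(s.item_id, "ko", s.percent_correct,
                           min(0.95, max(-0.9, s.item_total_corr + rng.normal(0, 0.1))),
                           100)
            for s in stats_en
        ]
        stats_es = [
            ItemStatistics(s.item_id, "es", s.percent_correct,
                           min(0.95, max(-0.9, s.item_total_corr + rng.normal(0, 0.1))),
                           100)
            for s in stats_en
        ]
        report = multi_language_review(sel, {"ko": stats_ko, "es": stats_es})
        assert len(report) == len(sel.selected_ids) * 2
        for _, row in report.iterrows():
            assert row["review"] == (row["residual"] < 0)
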