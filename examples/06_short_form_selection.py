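"""Build nested 40- and 20-item short forms from an 82-item bank.

Items are plotted as (percent correct, item-total correlation), a cubic
smoothing spline gives the expected discrimination at each difficulty,
and the most above-curve items are taken per stratum with quotas that
preserve the 29/28/25 difficulty distribution: 14/14/12 at length 40,
then 7/7/6 at length 20 from inside the 40-item form.
"""

from realmkit import (
    SimulationConfig,
    allocate_quotas,
    fit_mean_curve,
    generate_item_bank,
    item_statistics,
    select_items,
)
from realmkit.simulate import generate_responses

cfg = SimulationConfig(seed=13)
gen = generate_item_bank(cfg)
mat, _ = generate_responses(gen, "en", seed=14, config=cfg)

stats = item_statistics(mat, language="en")
curve = fit_mean_curve(stats)
sizes = gen.bank.stratum_counts()

sel40 = select_items(stats, curve, allocate_quotas(sizes, 40), gen.bank,
                     p_range=(5.0, 95.0), language="en")
sel20 = select_items(stats, curve, allocate_quotas(sizes, 20), gen.bank,
                     p_range=(5.0, 95.0), parent=sel40, language="en")

print("40-item quotas:", {s: len(v) for s, v in sel40.selected.items()})
print("20-item quotas:", {s: len(v) for s, v in sel20.selected.items()})
print("20-item form nested in 40-item form:",
      set(sel20.selected_ids) <= set(sel40.selected_ids))
print("20-item members:", sel20.selected_ids)
# Optionally: from realmkit.short_form import plot_selection
# plot_selection(stats, curve, sel40, path="scatter.png") writes the
# item-total vs percent-correct scatter with the fitted mean curve.
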