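"""Classical test theory statistics on a simulated administration.

Percent correct indexes item easiness, the corrected item-total
correlation indexes discrimination, and Cronbach's alpha summarises the
internal consistency of the whole form.
"""

from realmkit import (
    SimulationConfig,
    cronbach_alpha,
    generate_item_bank,
    item_statistics,
    summarize_scale,
)
from realmkit.simulate import generate_responses

cfg = SimulationConfig(seed=7)
gen = generate_item_bank(cfg)
mat, _ = generate_responses(gen, "en", seed=8, config=cfg)

alpha = cronbach_alpha(mat)
stats = item_statistics(mat, language="en")
report = summarize_scale(stats, alpha, n=mat.n_persons, language="en")

print(f"n = {report.n} persons, k = {report.k} items")
print(f"Cronbach alpha = {report.alpha:.3f}")
print(f"item-total correlation: median {report.r_it_median:.2f}, "
      f"range {report.r_it_range[0]:.2f}-{report.r_it_range[1]:.2f}")
print(f"percent correct: median {report.p_median:.1f}%, "
      f"range {report.p_range[0]:.0f}%-{report.p_range[1]:.0f}%")
# A high alpha (> .9) with a wide percent-correct range is the pattern a
# well-built graded word list should show.
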