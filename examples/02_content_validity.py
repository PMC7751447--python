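"""Content-validity screening of a candidate word pool.

Six experts rate each word's relevance 1-4; Lynn's item CVI is the share
rating it 3 or 4, and words with I-CVI > .80 survive.  Experts also sort
words into three difficulty strata.
"""

import pandas as pd

from realmkit import compute_cvi

rows = []
ratings = {
    "insulin":  ([4, 4, 4, 4, 4, 4], [1, 1, 1, 1, 2, 1]),
    "glycemic": ([4, 3, 4, 3, 3, 2], [3, 3, 2, 3, 3, 3]),
    "holiday":  ([2, 1, 3, 2, 4, 1], [1, 1, 1, 2, 1, 1]),
}
for word, (rel, diff) in ratings.items():
    for e, (r, d) in enumerate(zip(rel, diff)):
        rows.append({"expert_id": f"e{e}", "item_id": word,
                     "relevance": r, "difficulty": d})

report = compute_cvi(pd.DataFrame(rows))
print(f"scale-level S-CVI: {report.s_cvi:.3f}")
for rec in report.records:
    verdict = "retained" if rec.retained else "removed"
    print(f"{rec.item_id:10s} I-CVI {rec.i_cvi:.3f} -> {verdict:8s} "
          f"stratum={rec.assigned_stratum}")
# "holiday" falls below the .80 agreement bar and is dropped; the two
# clinical words survive with low/high difficulty assignments.
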