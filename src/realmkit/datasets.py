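"""Bundled example data.

``load_dm_realm40()`` returns the published 40-word English form of the
diabetes word-recognition health literacy scale (DM-REALM) as an ItemBank,
with a flag table marking the nested 20-word short form.  Useful for demos
and as a realistic word list; the synthetic generator is used for response
data, since no respondent-level data ship with the package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .bank import ItemBank, bank_from_frame


def load_dm_realm40() -> tuple[ItemBank, pd.DataFrame]:
    """The 40-word English DM-REALM form and its 20-word nested subset flags."""
    with resources.files("realmkit.data").joinpath("dm_realm40_en.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh)
    bank = bank_from_frame(df[["item_id", "stratum", "word_en"]])
    return bank, df[["item_id", "in_20_item_form"]]
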