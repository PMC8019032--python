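"""Small bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["survey_presence_matrix", "SPATIALLY_AUTOCORRELATED_TAXA"]

#: Genera whose per-site visit counts showed significant inverse-distance
#: Moran's I across all periods in the 2016 survey (honey-bee hives on
#: some farms), and are therefore screened out of the visitation models.
SPATIALLY_AUTOCORRELATED_TAXA = ("Apis",)


def survey_presence_matrix() -> pd.DataFrame:
    """Visit totals and sites-present (of 27) per bee genus × time period
    from the 2016 Ontario/Québec farm survey.

    Columns ``T1``..``T4`` hold the number of sites (out of 27) where the
    genus was observed in that period; ``visits_*`` hold visit counts.
    """
    with resources.files("beescape.data").joinpath(
        "bee_presence_2016.csv"
    ).open() as fh:
        return pd.read_csv(fh)
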