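"""Bundled reference table: published satellitome survey of eight
Tettigoniidae species plus a gryllacridid outgroup.

Values are the printed per-species summaries of that survey (repeatome
percent of genome, satellitome percent, satellite family count, gain count
under the z-score rule).  The satellite percentage of E. pallidus was not
printed and is NaN.  The table supports the descriptive-statistics and
correlation examples without any external download.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["tettigoniidae_survey"]

_ROWS = [
    # species, outgroup, repeatome %, satellite %, n families, n gains
    ("Meconema thalassinum", False, 92.0, 16.0, 246, 23),
    ("Pholidoptera griseoaptera", False, 85.0, 5.65, 10, 26),
    ("Ruspolia dubia", False, 60.0, 17.2, 104, 54),
    ("Ruspolia yunnana", False, 59.0, 10.7, 84, 36),
    ("Elimaea pallidus", False, 52.0, np.nan, 45, 28),
    ("Anatlanticus sinensis", False, 60.0, 11.6, 33, 47),
    ("Mecopoda bonneti", False, 64.0, 11.7, 37, 50),
    ("Gampsocleis gratiosa", False, 62.0, 9.11, 30, 28),
    ("Phryganogryllacris superangulata", True, 34.0, 7.0, 17, 8),
]


def tettigoniidae_survey() -> pd.DataFrame:
    """Survey table with columns species, outgroup, repeatome_percent,
    satellite_percent, n_families, n_gain."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "species",
            "outgroup",
            "repeatome_percent",
            "satellite_percent",
            "n_families",
            "n_gain",
        ],
    )
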