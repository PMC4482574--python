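"""Packaged reference datasets.

The published burrow-count survey of the Bolson tortoise (*Gopherus
flavomarginatus*): 22 independent ~1 km^2 plots across the Bolson de
Mapimi (Chihuahuan Desert, Mexico), each with the number of active and
inactive adult burrows per km^2. Plot coordinates were not published, so
the table carries locality names and survey districts only; the historic
census comparisons (Cerros Emilio 88 individuals then vs 8 now, Las
Lolas 25 vs 18) are exposed as constants for decline arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: historical-vs-recent census pairs (individuals counted at the locality)
HISTORIC_CENSUS = {
    "Cerros Emilio": (88, 8),
    "Las Lolas": (25, 18),
}


def mapimi_burrow_counts() -> pd.DataFrame:
    """The 22-plot Bolson tortoise burrow survey (burrows/km^2).

    Columns: ``id`` (sampling locality), ``district``, ``count``.
    """
    ref = resources.files("nichecentroid.data") / "mapimi_burrow_counts.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
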