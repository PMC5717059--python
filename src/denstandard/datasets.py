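"""Packaged reference tables for the Sumatran tiger landscape analysis.

Two small published tables are shipped as CSV:

* ``forest_cover_2000_2012`` — habitat-class forest areas (km²) in the 15
  tiger-occupied landscapes for 2012, with each landscape's 12-year
  deforestation percentage (2000-2012). Transcribed from the published
  compilation; per-row and per-column totals were used as checksums during
  transcription.
* ``subpopulations`` — published adult-tiger subpopulation estimates per
  landscape for 2000 and 2012, breeding-female counts and ±1 SE bounds.
  Note the published totals row (618 / 742) differs by one from the column
  sums (619 / 743) due to rounding of the per-landscape entries.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .project import LandscapeTable

N_PRIORITY = 7  # first seven landscapes are the priority set


def _load(name: str) -> pd.DataFrame:
    with resources.files("denstandard.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def forest_cover_2000_2012() -> LandscapeTable:
    """Landscape habitat-area table (2012 epoch + 12-yr loss percentages)."""
    return LandscapeTable(_load("forest_cover_2000_2012.csv"))


def subpopulations() -> pd.DataFrame:
    """Published per-landscape adult-tiger estimates for 2000 and 2012."""
    return _load("subpopulations.csv")
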