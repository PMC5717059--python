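"""Landscape population projection from habitat-specific densities.

Habitat-class densities (from the meta-regression: a lowland-hill primary
baseline scaled by multiplicative peat/montane and degradation effects) are
priced against per-landscape habitat-area tables for two epochs, giving
adult abundance per landscape, breeding-female counts (1 breeding female
per 2.9 tigers), secure-source-population (SSP) classification, and
change-over-time summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

HABITAT_CLASSES = (
    "montane_primary",
    "lowland_hill_primary",
    "peat_primary",
    "lowland_hill_degraded",
    "peat_degraded",
)
_AREA_COLS = {c: f"{c}_km2" for c in HABITAT_CLASSES}

BF_RATIO = 2.9  # tigers per breeding female (camera-trap studies)
SSP_MIN_BF = 25
SSP_MIN_CORE_KM2 = 1000.0
SSP_MIN_NEARBY_BF = 25


@dataclass
class LandscapeTable:
    """Habitat-class areas (km²) per landscape, with 12-yr loss percentages.

    ``frame`` columns: ``landscape``, one ``<class>_km2`` per habitat class,
    and ``deforestation_12yr_pct``. The table is the 2012 epoch; the 2000
    epoch is obtained by back-casting with the loss percentages.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        need = {"landscape", "deforestation_12yr_pct", *_AREA_COLS.values()}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"landscape table missing columns {sorted(missing)}")
        if (self.frame[list(_AREA_COLS.values())] < 0).any().any():
            raise ValueError("areas must be non-negative")

    @property
    def landscapes(self) -> list:
        return list(self.frame["landscape"])

    def areas(self) -> np.ndarray:
        """(n_landscapes, n_classes) areas in km² (2012 epoch)."""
        return self.frame[[_AREA_COLS[c] for c in HABITAT_CLASSES]].to_numpy(float)

    def areas_backcast_2000(self) -> np.ndarray:
        """2000-epoch areas: each class scaled by the landscape's total
        back-cast factor 1/(1 - loss/100)."""
        loss = self.frame["deforestation_12yr_pct"].to_numpy(float)
        return self.areas() * (1.0 / (1.0 - loss / 100.0))[:, None]


@dataclass
class DensityByHabitat:
    """Animals per 100 km² for each habitat class, plus a shared relative SE."""

    densities: dict
    relative_se: float = 0.0

    def __post_init__(self):
        missing = set(HABITAT_CLASSES) - set(self.densities)
        if missing:
            raise ValueError(f"no density supplied for habitat class {sorted(missing)}")
        if any(v < 0 for v in self.densities.values()):
            raise ValueError("densities must be non-negative")
        if self.relative_se < 0:
            raise ValueError("relative SE must be non-negative")

    def vector(self) -> np.ndarray:
        return np.array([self.densities[c] for c in HABITAT_CLASSES], float)


def densities_from_effects(
    baseline_lowland_hill: float,
    peat_montane_multiplier: float,
    degraded_multiplier: float,
    relative_se: float = 0.0,
) -> DensityByHabitat:
    """Compose habitat-class densities from meta-regression effects.

    Montane and peat classes carry the peat/montane multiplier; degraded
    classes the degradation multiplier; degraded peat composes both
    multiplicatively.
    """
    b = baseline_lowland_hill
    pm = peat_montane_multiplier
    dg = degraded_multiplier
    return DensityByHabitat(
        {
            "montane_primary": b * pm,
            "lowland_hill_primary": b,
            "peat_primary": b * pm,
            "lowland_hill_degraded": b * dg,
            "peat_degraded": b * pm * dg,
        },
        relative_se,
    )


def derive_habitat_densities(
    table: LandscapeTable, adults: np.ndarray, relative_se: float = 0.0
) -> DensityByHabitat:
    """Least-squares habitat densities consistent with a printed projection.

    Solves the non-negative least-squares problem
    ``min || areas/100 @ d - adults ||`` — the documented oracle used to
    recover the habitat-specific densities behind a published subpopulation
    table when the densities themselves were never printed.
    """
    from scipy.optimize import nnls

    d, _ = nnls(table.areas() / 100.0, np.asarray(adults, float))
    return DensityByHabitat(dict(zip(HABITAT_CLASSES, d)), relative_se)


@dataclass
class PopulationEstimate:
    """Projected adults for one landscape (or a totals row)."""

    landscape: str
    adults: float
    se_adults: float
    breeding_females: int
    ssp_flag: bool | None = None

    def __post_init__(self):
        if self.adults < 0 or self.se_adults < 0:
            raise ValueError("adults and se must be non-negative")


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties away from zero (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def breeding_females(adults: float, ratio: float = BF_RATIO) -> int:
    """Breeding females = round(adults / 2.9), half-up."""
    if adults < 0:
        raise ValueError("adults must be non-negative")
    return round_half_up(adults / ratio)


def project_population(
    table: LandscapeTable,
    dens: DensityByHabitat,
    epoch: str = "2012",
) -> pd.DataFrame:
    """Adults per landscape: sum over classes of area x density / 100.

    Standard errors follow the dataset-level rule: per-landscape
    se = relative_se x adults, and totals sum both adults and SEs linearly
    (subpopulation errors are treated as fully correlated through the shared
    density estimates).
    """
    if epoch not in ("2000", "2012"):
        raise ValueError("epoch must be '2000' or '2012'")
    areas = table.areas() if epoch == "2012" else table.areas_backcast_2000()
    adults = areas @ dens.vector() / 100.0
    out = pd.DataFrame({
        "landscape": table.landscapes,
        "adults": adults,
        "se_adults": dens.relative_se * adults,
        "breeding_females": [breeding_females(a) for a in adults],
    })
    total = pd.DataFrame({
        "landscape": ["Total"],
        "adults": [adults.sum()],
        "se_adults": [out["se_adults"].sum()],
        "breeding_females": [breeding_females(adults.sum())],
    })
    return pd.concat([out, total], ignore_index=True)


def classify_ssp(
    estimate: PopulationEstimate | float,
    core_forest_km2: float,
    nearby_bf: float,
    min_bf: int = SSP_MIN_BF,
    min_core_km2: float = SSP_MIN_CORE_KM2,
    min_nearby_bf: float = SSP_MIN_NEARBY_BF,
) -> bool:
    """Secure source population: >25 breeding females in a >1000 km² core,
    with nearby forests holding another >=25 breeding females."""
    bf = estimate.breeding_females if isinstance(estimate, PopulationEstimate) else estimate
    if bf < 0 or core_forest_km2 < 0 or nearby_bf < 0:
        raise ValueError("inputs must be non-negative")
    return bool(bf > min_bf and core_forest_km2 > min_core_km2 and nearby_bf >= min_nearby_bf)


def percent_change(before: float, after: float) -> float:
    """Decline from ``before`` to ``after`` as a percentage, one decimal."""
    if before <= 0:
        raise ValueError("'before' must be positive")
    return round((before - after) / before * 100.0, 1)


def backcast_area(area_2012: float, loss_pct: float) -> float:
    """Invert a loss percentage: area_2000 = area_2012 / (1 - loss/100)."""
    if not 0 <= loss_pct < 100:
        raise ValueError("loss percentage must lie in [0, 100)")
    return float(area_2012 / (1.0 - loss_pct / 100.0))


def island_loss_pct(totals_2012, loss_pct) -> float:
    """Aggregate per-landscape losses into an island-wide loss percentage.

    Back-casts each landscape's 2012 area by its own loss percentage, sums
    both epochs, and returns the aggregate percent decline.
    """
    a12 = np.asarray(totals_2012, float)
    a00 = np.array([backcast_area(a, l) for a, l in zip(a12, np.asarray(loss_pct, float))])
    return percent_change(a00.sum(), a12.sum())
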