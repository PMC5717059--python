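"""Study-level density records: the unit of exchange between estimation,
standardization and meta-regression.

A record mirrors one published (or simulated) density estimate: the study's
abundance and its error, the geometry used to turn abundance into density,
and the habitat/effort covariates the meta-regression consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

METHODS = ("CR", "SCR", "corrected")
FOREST_TYPES = ("lowland-hill", "peat-montane")
DISTURBANCE = ("primary", "logged")


@dataclass
class DensityEstimate:
    """One study-level tiger density estimate (per 100 km²).

    ``n_hat``/``se_n`` are the closed-population abundance and its standard
    error (CR records); SCR records carry density directly. ``correctable``
    is False for published records that report a density but not the
    abundance behind it — those pass through standardization unchanged.
    """

    study_id: str
    landscape: str
    year: float
    method: str  # "CR" | "SCR" | "corrected"
    density: float  # per 100 km²
    se_density: float
    n_hat: float | None = None
    se_n: float | None = None
    mcp_area_km2: float | None = None
    mcp_perimeter_km: float | None = None
    original_buffer_km: float | None = None
    area_km2: float | None = None  # effective sampled area behind `density`
    forest_type: str | None = None  # "lowland-hill" | "peat-montane"
    disturbance: str | None = None  # "primary" | "logged"
    deforestation_rate: float | None = None  # %/yr
    trap_days: float | None = None
    n_cameras: float | None = None
    n_captures: float | None = None
    n_individuals: float | None = None
    parent_study_id: str | None = None  # corrected records point at CR parent
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.forest_type is not None and self.forest_type not in FOREST_TYPES:
            raise ValueError(f"forest_type must be one of {FOREST_TYPES}")
        if self.disturbance is not None and self.disturbance not in DISTURBANCE:
            raise ValueError(f"disturbance must be one of {DISTURBANCE}")
        if self.density is not None and self.density <= 0:
            raise ValueError("density must be positive")
        if self.se_density is not None and self.se_density <= 0:
            raise ValueError("se_density must be positive")

    @property
    def correctable(self) -> bool:
        """True when the record carries the abundance and geometry needed to
        recompute its density under a different buffer."""
        has_geom = self.mcp_area_km2 is not None and (
            self.mcp_perimeter_km is not None
        )
        return self.method == "CR" and self.n_hat is not None and has_geom

    @property
    def relative_se(self) -> float:
        """se(D)/D — the sampling-error weight used on the log scale."""
        return self.se_density / self.density

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("extra")
        d.update(self.extra)
        return d


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate a list of :class:`DensityEstimate` as a DataFrame."""
    return pd.DataFrame([r.to_dict() for r in records])


_CORE_FIELDS = {
    f for f in DensityEstimate.__dataclass_fields__ if f != "extra"
}


def record_from_row(row: dict) -> DensityEstimate:
    """Build a record from a mapping (e.g., a CSV row); unknown keys are
    preserved in ``extra``."""
    core = {}
    extra = {}
    for k, v in row.items():
        if isinstance(v, float) and np.isnan(v):
            v = None
        if k in _CORE_FIELDS:
            core[k] = v
        else:
            extra[k] = v
    return DensityEstimate(**core, extra=extra)
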