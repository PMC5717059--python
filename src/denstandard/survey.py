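"""Core survey containers: detector arrays and binary capture histories.

Coordinates are planar kilometres throughout the package; no geodesy is
performed. Detectors are binary "proximity" detectors: each animal can be
recorded independently at every detector on every occasion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class TrapArray:
    """A set of detector (camera-trap) locations for one trapping session.

    Parameters
    ----------
    ids
        Unique detector identifiers.
    xy
        ``(n_traps, 2)`` array of planar coordinates in km.
    session
        Session label; multi-session analyses use one ``TrapArray`` per
        session.
    """

    ids: tuple
    xy: np.ndarray
    session: str = "session1"

    def __post_init__(self):
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("trap coordinates must be an (n, 2) array of planar km")
        if len(self.ids) != xy.shape[0]:
            raise ValueError("number of trap ids must match number of coordinates")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("trap ids must be unique")
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "xy", xy)

    @property
    def n_traps(self) -> int:
        return self.xy.shape[0]

    def index_of(self, trap_id: str) -> int:
        return self.ids.index(str(trap_id))

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the array."""
        return (
            float(self.xy[:, 0].min()),
            float(self.xy[:, 1].min()),
            float(self.xy[:, 0].max()),
            float(self.xy[:, 1].max()),
        )


@dataclass
class CaptureHistory:
    """Binary detections of identified individuals: individual x trap x occasion.

    Only detected individuals appear (every row of ``detections`` has at
    least one 1); the occasion dimension is shared by all individuals.
    """

    individuals: tuple
    detections: np.ndarray  # (n_individuals, n_traps, n_occasions) in {0, 1}
    traps: TrapArray

    def __post_init__(self):
        det = np.asarray(self.detections)
        if det.ndim != 3:
            raise ValueError("detections must be (individual, trap, occasion)")
        if det.shape[0] != len(self.individuals):
            raise ValueError("individual dimension does not match id list")
        if det.shape[1] != self.traps.n_traps:
            raise ValueError("trap dimension does not match trap array")
        if not np.isin(det, (0, 1)).all():
            raise ValueError("detections must be binary")
        if det.shape[0] and not (det.sum(axis=(1, 2)) > 0).all():
            raise ValueError("every listed individual needs at least one detection")
        self.individuals = tuple(str(i) for i in self.individuals)
        self.detections = det.astype(np.uint8)

    @property
    def n_individuals(self) -> int:
        return self.detections.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.detections.shape[2]

    @property
    def session(self) -> str:
        return self.traps.session

    def counts_by_trap(self) -> np.ndarray:
        """(n_individuals, n_traps) detection counts summed over occasions."""
        return self.detections.sum(axis=2)

    def occasion_captures(self) -> np.ndarray:
        """(n_individuals, n_occasions) 0/1: caught anywhere that occasion.

        This is the non-spatial capture history consumed by closed-population
        abundance models.
        """
        return (self.detections.sum(axis=1) > 0).astype(np.uint8)

    def traps_used(self, individual_index: int) -> np.ndarray:
        """Indices of traps at which the individual was ever detected."""
        return np.flatnonzero(self.detections[individual_index].sum(axis=1) > 0)


def trap_grid_spacing(traps: TrapArray) -> float:
    """Median nearest-neighbour spacing of a detector array (km)."""
    if traps.n_traps < 2:
        raise ValueError("need at least two traps")
    d = pdist(traps.xy)
    from scipy.spatial.distance import squareform

    m = squareform(d)
    np.fill_diagonal(m, np.inf)
    return float(np.median(m.min(axis=1)))
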