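"""Non-spatial closed-population capture-recapture.

The traditional camera-trap density pipeline: estimate the abundance N of
animals exposed to the grid with a closed-population model (M0: constant
per-occasion capture probability), convert the trap array into an effective
sampled area A (minimum convex polygon plus a movement-based buffer), and
report D = N / A. The buffer is classically half the mean maximum distance
moved between recaptures (1/2 MMDM); because trapping grids truncate the
largest movements, that buffer is biased small and the resulting density
biased high — the bias the standardization stage removes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist
from scipy.special import gammaln, polygamma, psi
from shapely.geometry import LineString, MultiPoint, Point, Polygon

from .records import DensityEstimate
from .survey import CaptureHistory, TrapArray


@dataclass
class AbundanceEstimate:
    """Closed-population abundance: N-hat with asymptotic standard error."""

    n_hat: float
    se_n: float
    m_t1: int  # distinct individuals caught
    p_hat: float  # per-occasion capture probability
    log_lik: float
    model_tag: str = "M0"
    boundary: bool = False  # True when N-hat sits on the N = M_t+1 boundary

    def __post_init__(self):
        if self.n_hat < self.m_t1 - 1e-9:
            raise ValueError("n_hat cannot be below the number caught")


@dataclass
class EffectiveArea:
    """MCP hull dilated by a buffer: the CR density denominator."""

    mcp_area_km2: float
    mcp_perimeter_km: float
    buffer_km: float
    area_km2: float
    degenerate: bool = False  # hull collapsed to a segment or point
    clipped: bool = False

    def __post_init__(self):
        if self.buffer_km < 0:
            raise ValueError("buffer must be non-negative")
        if self.area_km2 < self.mcp_area_km2 - 1e-9 and not self.clipped:
            raise ValueError("buffered area cannot be below the hull area")


def _m0_profile_loglik(n: float, m: int, total: int, k: int) -> float:
    """M0 log-likelihood at N=n with p profiled out (p-hat = total/(nK))."""
    p = total / (n * k)
    if p >= 1.0:
        return -np.inf
    return (
        gammaln(n + 1.0)
        - gammaln(n - m + 1.0)
        + total * np.log(p)
        + (n * k - total) * np.log1p(-p)
    )


def estimate_abundance_m0(history: CaptureHistory) -> AbundanceEstimate:
    """Maximum-likelihood abundance under model M0 (constant capture probability).

    The likelihood treats each of K occasions as a Bernoulli trial per animal
    (caught anywhere on the grid or not), so with ``total`` animal-occasion
    captures of ``m`` distinct animals,

        L(N, p) = N!/(N-m)! * p^total * (1-p)^(N*K - total).

    N is profiled continuously (no integer rounding) with p-hat = total/(N*K);
    the standard error comes from the inverse observed information of the
    joint (N, p) likelihood.
    """
    occ = history.occasion_captures()
    m = history.n_individuals
    k = history.n_occasions
    if m == 0:
        raise ValueError("cannot estimate abundance from an empty capture history")
    if k < 2:
        raise ValueError("need at least two occasions to identify capture probability")
    total = int(occ.sum())

    if total == m * k:
        # every animal caught on every occasion: p-hat = 1, N-hat = m exactly
        warnings.warn(
            "all animals caught on all occasions: N-hat = M_t+1 with zero variance",
            RuntimeWarning,
        )
        return AbundanceEstimate(
            n_hat=float(m), se_n=0.0, m_t1=m, p_hat=1.0,
            log_lik=float(gammaln(m + 1.0)),
            boundary=True,
        )

    # Profile score in N: digamma(N+1) - digamma(N-m+1) + K*log(1 - total/(NK))
    def score(n):
        return psi(n + 1.0) - psi(n - m + 1.0) + k * np.log1p(-total / (n * k))

    lo = m + 1e-9
    if score(lo) <= 0:
        n_hat = float(m)
        boundary = True
    else:
        hi = float(m)
        while score(hi * 2 + 10) > 0:
            hi = hi * 2 + 10
            if hi > 1e9:
                raise RuntimeError("M0 likelihood does not attain an interior maximum")
        n_hat = float(brentq(score, lo, hi * 2 + 10, xtol=1e-10, rtol=1e-14))
        boundary = False

    p_hat = total / (n_hat * k)
    ll = _m0_profile_loglik(n_hat, m, total, k)

    # observed information of the joint (N, p) likelihood at the MLE
    i_nn = -(polygamma(1, n_hat + 1.0) - polygamma(1, n_hat - m + 1.0))
    i_np = k / (1.0 - p_hat)
    i_pp = total / p_hat**2 + (n_hat * k - total) / (1.0 - p_hat) ** 2
    info = np.array([[i_nn, i_np], [i_np, i_pp]])
    se_n = np.nan
    det = np.linalg.det(info)
    if det > 0:
        se_n = float(np.sqrt(np.linalg.inv(info)[0, 0]))
    if boundary or not np.isfinite(se_n):
        se_n = 0.0 if boundary else np.nan
    return AbundanceEstimate(
        n_hat=n_hat, se_n=se_n, m_t1=m, p_hat=p_hat, log_lik=ll, boundary=boundary
    )


def mmdm(history: CaptureHistory, traps: TrapArray | None = None) -> float:
    """Mean maximum distance moved (km) over individuals recaptured at >= 2 traps.

    Each qualifying individual contributes its maximum pairwise distance
    between the traps at which it was detected; animals only ever seen at a
    single trap carry no movement information and are excluded.
    """
    traps = traps if traps is not None else history.traps
    maxima = []
    for i in range(history.n_individuals):
        idx = history.traps_used(i)
        if len(idx) >= 2:
            maxima.append(pdist(traps.xy[idx]).max())
    if not maxima:
        raise ValueError(
            "MMDM undefined: no individual was recaptured at a second trap"
        )
    return float(np.mean(maxima))


def half_mmdm(history: CaptureHistory, traps: TrapArray | None = None) -> float:
    """Half the mean maximum distance moved — the classical CR buffer width."""
    return 0.5 * mmdm(history, traps)


def mcp_hull(traps: TrapArray):
    """Minimum convex polygon around the detector array (shapely geometry).

    Fewer than 3 traps, or collinear traps, give a degenerate (zero-area)
    hull; buffered areas remain well defined via segment/point dilation.
    """
    return MultiPoint([tuple(p) for p in traps.xy]).convex_hull


def _hull_area_perimeter(hull) -> tuple[float, float, bool]:
    """(area, perimeter, degenerate) for a convex hull geometry.

    Degenerate hulls: a segment of length L has area 0 and 'perimeter' 2L
    (the boundary traversed both ways), a point has area 0 and perimeter 0;
    with these conventions the convex dilation closed form
    A + P*b + pi*b**2 holds for all three cases.
    """
    if isinstance(hull, Polygon):
        return hull.area, hull.length, False
    if isinstance(hull, LineString):
        return 0.0, 2.0 * hull.length, True
    if isinstance(hull, Point):
        return 0.0, 0.0, True
    raise TypeError(f"unexpected hull geometry {type(hull).__name__}")


def effective_area(
    traps: TrapArray,
    buffer_km: float,
    clip_region=None,
) -> EffectiveArea:
    """Effective sampled area: the trap MCP dilated by ``buffer_km``.

    For a convex hull with area A and perimeter P the Euclidean dilation has
    exact area A + P*b + pi*b**2, which is what is returned unclipped. With a
    ``clip_region`` (a shapely polygon, e.g. a land mask), the dilated hull is
    intersected with it and the polygonal approximation's area returned.
    """
    if buffer_km < 0:
        raise ValueError("buffer must be non-negative")
    hull = mcp_hull(traps)
    a, p, degenerate = _hull_area_perimeter(hull)
    if clip_region is None:
        area = a + p * buffer_km + np.pi * buffer_km**2
        return EffectiveArea(a, p, buffer_km, float(area), degenerate=degenerate)
    if not hasattr(clip_region, "intersection"):
        raise TypeError("clip_region must be a shapely geometry")
    if not clip_region.is_valid:
        raise ValueError("clip_region is not a valid polygon")
    dilated = hull.buffer(buffer_km, quad_segs=64) if buffer_km > 0 else hull
    area = dilated.intersection(clip_region).area
    return EffectiveArea(a, p, buffer_km, float(area), degenerate=degenerate, clipped=True)


def cr_density(
    n_hat: AbundanceEstimate,
    area: EffectiveArea,
    *,
    study_id: str = "study",
    landscape: str = "landscape",
    year: float = np.nan,
    **covariates,
) -> DensityEstimate:
    """Density per 100 km²: D = N / A, with se(D) = se(N) / A.

    The error in the sampled area is not propagated — the standard error of a
    CR density is conventionally derived from that of N alone, so the
    relative standard error of D equals that of N exactly.
    """
    if area.area_km2 <= 0:
        raise ValueError("effective area must be positive")
    scale = 100.0 / area.area_km2
    return DensityEstimate(
        study_id=study_id,
        landscape=landscape,
        year=year,
        method="CR",
        density=n_hat.n_hat * scale,
        # boundary fits carry se_n = 0; keep the record valid with a token se
        se_density=max(n_hat.se_n * scale, 1e-12),
        n_hat=n_hat.n_hat,
        se_n=n_hat.se_n,
        mcp_area_km2=area.mcp_area_km2,
        mcp_perimeter_km=area.mcp_perimeter_km,
        original_buffer_km=area.buffer_km,
        area_km2=area.area_km2,
        **covariates,
    )
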