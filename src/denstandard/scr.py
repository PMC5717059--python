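"""Maximum-likelihood spatial capture-recapture with half-normal detection.

The model: animal activity centres follow a Poisson point process with
intensity D(s) over a discretized habitat mask; an animal centred at s is
detected at a proximity detector at distance d on any one occasion with
probability p(d) = g0 * exp(-d^2 / (2 sigma^2)). The full (unconditional)
likelihood is used: the number of detected individuals is Poisson with mean

    Lambda = sum_s D(s) * pdot(s) * a,       pdot(s) = 1 - prod_j (1 - p_j(s))^K

and each observed history contributes its mask-integrated probability.
Densities are per 100 km²; sigma is in km. Parameters are estimated on a
working scale (log D, logit g0, log sigma) by quasi-Newton optimization,
with standard errors from the inverse observed information and the delta
method.

Multi-session fits share any subset of (D, g0, sigma) across sessions —
the device that lets sparse single-site datasets borrow strength, and that
also implements the "two flanks as two constrained sessions" trick for
single-camera stations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.special import expit, gammaln, logit, logsumexp
from shapely.geometry import Point as _ShpPoint

from .cr import effective_area, half_mmdm, mcp_hull
from .survey import CaptureHistory, TrapArray, trap_grid_spacing

EXCLUDED = "excluded"

# 95% radius of a circular bivariate normal: sqrt(chi2_2,0.95) = 2.4477...
# The 1-D 95% quantile 1.96 is used for the standardization buffer instead;
# both constants are deliberate and exposed as explicit arguments.
HOME_RANGE_MULTIPLIER = 2.45
BUFFER_MULTIPLIER = 1.96


def halfnormal_p(distance_km, g0: float, sigma_km: float):
    """Half-normal detection function: p(d) = g0 * exp(-d^2 / (2 sigma^2))."""
    if sigma_km <= 0:
        raise ValueError("sigma must be positive")
    if not 0 <= g0 <= 1:
        raise ValueError("g0 must lie in [0, 1]")
    d = np.asarray(distance_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = g0 * np.exp(-(d**2) / (2.0 * sigma_km**2))
    return float(out) if np.isscalar(distance_km) else out


def home_range_area(sigma_km: float, quantile_multiplier: float = HOME_RANGE_MULTIPLIER) -> float:
    """Circular home-range area pi * (m * sigma)^2 in km².

    The default multiplier 2.45 ~ sqrt(chi2_2(0.95)) gives the radius
    containing 95% of a circular bivariate-normal utilisation distribution.
    """
    if sigma_km <= 0:
        raise ValueError("sigma must be positive")
    return float(np.pi * (quantile_multiplier * sigma_km) ** 2)


def standard_buffer(sigma_km: float, se_sigma_km: float | None = None,
                    multiplier: float = BUFFER_MULTIPLIER):
    """Standardization buffer 1.96 * sigma (km), with se propagated linearly.

    Returns the buffer, or a (buffer, se) pair when ``se_sigma_km`` is given.
    """
    if sigma_km <= 0:
        raise ValueError("sigma must be positive")
    b = multiplier * sigma_km
    if se_sigma_km is None:
        return float(b)
    return float(b), float(multiplier * se_sigma_km)


@dataclass
class HabitatMask:
    """Discretized state space of potential activity centres.

    ``stratum`` labels each cell; cells labelled ``"excluded"`` (ocean,
    water bodies) carry zero density and contribute nothing to the
    likelihood. Other labels ("habitat", or e.g. "forest"/"nonforest")
    become density strata when a stratified fit is requested.
    """

    points: np.ndarray  # (m, 2) cell centres, planar km
    cell_area_km2: float
    stratum: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("mask points must be (m, 2)")
        if self.cell_area_km2 <= 0:
            raise ValueError("cell area must be positive")
        if self.stratum is None:
            self.stratum = np.full(len(self.points), "habitat", dtype=object)
        self.stratum = np.asarray(self.stratum, dtype=object)
        if len(self.stratum) != len(self.points):
            raise ValueError("stratum labels must match mask points")

    @property
    def n_cells(self) -> int:
        return len(self.points)

    @property
    def active(self) -> np.ndarray:
        return self.stratum != EXCLUDED

    def strata_labels(self) -> list:
        return sorted({s for s in self.stratum if s != EXCLUDED})

    def buffer_beyond_hull(self, traps: TrapArray) -> float:
        """Greatest distance from the trap hull covered by active cells."""
        hull = mcp_hull(traps)
        pts = self.points[self.active]
        return float(max(hull.distance(_ShpPoint(*p)) for p in pts))


def make_mask(
    traps: TrapArray,
    buffer_km: float,
    cell_km: float = 0.5,
    stratum_fn=None,
    rectangular: bool = False,
) -> HabitatMask:
    """Regular-grid habitat mask around a trap array.

    Cells are laid on a ``cell_km`` lattice over the trap bounding box padded
    by ``buffer_km``; unless ``rectangular``, cells further than ``buffer_km``
    from the trap hull are dropped (the usual mask shape). ``stratum_fn``
    maps (x, y) arrays to per-cell labels ("excluded" removes a cell's
    density).
    """
    if buffer_km <= 0 or cell_km <= 0:
        raise ValueError("buffer and cell size must be positive")
    xmin, ymin, xmax, ymax = traps.extent()
    xs = np.arange(xmin - buffer_km + cell_km / 2, xmax + buffer_km, cell_km)
    ys = np.arange(ymin - buffer_km + cell_km / 2, ymax + buffer_km, cell_km)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if not rectangular:
        hull = mcp_hull(traps)
        dil = hull.buffer(buffer_km, quad_segs=32)
        keep = np.array([dil.covers(_ShpPoint(*p)) for p in pts])
        pts = pts[keep]
    stratum = stratum_fn(pts[:, 0], pts[:, 1]) if stratum_fn is not None else None
    return HabitatMask(pts, cell_km**2, stratum)


@dataclass
class ScrSession:
    """One trapping session: a capture history plus the habitat mask over
    which its activity-centre integral runs."""

    history: CaptureHistory
    mask: HabitatMask
    label: str | None = None

    def __post_init__(self):
        if self.label is None:
            self.label = self.history.session


@dataclass
class ScrParamLayout:
    """Mapping between the working-scale parameter vector and the model.

    Vector order: density blocks (log scale) first, then g0 blocks (logit),
    then sigma blocks (log). A shared parameter has one block across
    sessions; an unshared one has one block per session. With stratified
    density each density block has one entry per stratum label.
    """

    n_sessions: int
    strata: list  # density stratum labels, in order
    share: tuple = ("D", "g0", "sigma")

    def __post_init__(self):
        for s in self.share:
            if s not in ("D", "g0", "sigma"):
                raise ValueError(f"unknown shared parameter {s!r}")

    def _blocks(self, name):  # number of blocks for a parameter
        return 1 if name in self.share else self.n_sessions

    @property
    def n_density(self) -> int:
        return self._blocks("D") * len(self.strata)

    @property
    def n_params(self) -> int:
        return self.n_density + self._blocks("g0") + self._blocks("sigma")

    def density_of(self, params, session: int) -> dict:
        """{stratum: D per 100 km²} for a session (natural scale)."""
        block = 0 if "D" in self.share else session
        k = len(self.strata)
        vals = np.exp(params[block * k : (block + 1) * k])
        return dict(zip(self.strata, vals))

    def g0_of(self, params, session: int) -> float:
        i = self.n_density + (0 if "g0" in self.share else session)
        return float(expit(params[i]))

    def sigma_of(self, params, session: int) -> float:
        i = self.n_density + self._blocks("g0") + (0 if "sigma" in self.share else session)
        return float(np.exp(params[i]))

    def names(self) -> list:
        out = []
        dblocks = 1 if "D" in self.share else self.n_sessions
        for b in range(dblocks):
            tag = "" if "D" in self.share else f".s{b}"
            out += [f"logD[{s}]{tag}" for s in self.strata]
        for b in range(1 if "g0" in self.share else self.n_sessions):
            out.append("logit_g0" + ("" if "g0" in self.share else f".s{b}"))
        for b in range(1 if "sigma" in self.share else self.n_sessions):
            out.append("log_sigma" + ("" if "sigma" in self.share else f".s{b}"))
        return out


def _session_loglik(history, mask, density_by_stratum, g0, sigma) -> float:
    """Full-likelihood contribution of one session (natural-scale params)."""
    active = mask.active
    pts = mask.points[active]
    strat = mask.stratum[active]
    a = mask.cell_area_km2
    k_occ = history.n_occasions
    n = history.n_individuals
    # per-cell density (animals per km²; D given per 100 km²)
    dens = np.empty(len(pts))
    for lbl, d in density_by_stratum.items():
        dens[strat == lbl] = d / 100.0
    missing = set(strat) - set(density_by_stratum)
    if missing:
        raise ValueError(f"no density supplied for mask strata {sorted(missing)}")

    d2 = cdist(pts, history.traps.xy, "sqeuclidean")  # (m, J)
    log_p = np.log(g0) - d2 / (2.0 * sigma**2)
    p = np.exp(log_p)
    log_q = np.log1p(-p)  # log(1 - p), p < 1 guaranteed by g0 < 1
    log_pdot_comp = k_occ * log_q.sum(axis=1)  # log prod_j (1-p)^K
    pdot = -np.expm1(log_pdot_comp)

    lam = float(np.sum(dens * pdot) * a)
    with np.errstate(divide="ignore"):
        log_dens_a = np.log(dens * a)
        # Poisson term for the observed count (empty sessions: only this)
        ll = n * np.log(lam) - lam - gammaln(n + 1) if n > 0 else -lam
    if not np.isfinite(ll):
        raise FloatingPointError(
            f"non-finite Poisson term (Lambda={lam!r}, n={n}); "
            "check mask coverage and parameter scales"
        )
    if n == 0:
        return ll
    y = history.counts_by_trap().astype(float)  # (n, J)
    # log P(omega_i | s): binomial per trap over K occasions
    const = (gammaln(k_occ + 1) - gammaln(y + 1) - gammaln(k_occ - y + 1)).sum(axis=1)
    term = y @ log_p.T + (k_occ - y) @ log_q.T  # (n, m)
    log_int = logsumexp(term + log_dens_a[None, :], axis=1)  # (n,)
    ll += float(np.sum(log_int + const) - n * np.log(lam))
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite likelihood contribution from histories")
    return ll


def scr_loglik(params, sessions, layout: ScrParamLayout | None = None) -> float:
    """Multi-session SCR log-likelihood at a working-scale parameter vector.

    ``params`` is ordered per :class:`ScrParamLayout`; the default layout
    (everything shared, single stratum) is ``[log D, logit g0, log sigma]``.
    """
    sessions = [s if isinstance(s, ScrSession) else ScrSession(*s) for s in sessions]
    if layout is None:
        strata = sorted({l for s in sessions for l in s.mask.strata_labels()})
        layout = ScrParamLayout(len(sessions), strata)
    params = np.asarray(params, dtype=float)
    if params.shape != (layout.n_params,):
        raise ValueError(f"expected {layout.n_params} parameters, got {params.shape}")
    total = 0.0
    for j, sess in enumerate(sessions):
        dens = layout.density_of(params, j)
        dens = {l: dens[l] for l in sess.mask.strata_labels()}
        total += _session_loglik(
            sess.history, sess.mask, dens,
            layout.g0_of(params, j), layout.sigma_of(params, j),
        )
    return float(total)


@dataclass
class ScrFit:
    """A fitted SCR model on the natural scale.

    ``density`` maps stratum label (or (session, stratum) when density is
    not shared) to animals per 100 km²; ``se_density`` likewise. The working
    scale covariance is retained for delta-method derivations (e.g. the
    1.96*sigma buffer's se, log-scale Wald intervals for D).
    """

    density: dict
    se_density: dict
    g0: float
    se_g0: float
    sigma_km: float
    se_sigma_km: float
    log_lik: float
    params: np.ndarray
    cov_working: np.ndarray | None
    layout: ScrParamLayout
    converged: bool
    n_individuals: int
    message: str = ""
    se_available: bool = True

    @property
    def n_params(self) -> int:
        return self.layout.n_params

    def density_interval(self, stratum=None, level: float = 0.95) -> tuple:
        """Wald interval for D on the log scale (asymmetric, positive)."""
        from scipy.stats import norm

        key = stratum if stratum is not None else next(iter(self.density))
        if not self.se_available:
            raise ValueError("standard errors unavailable for this fit")
        idx = list(self.density).index(key)
        se_log = float(np.sqrt(self.cov_working[idx, idx]))
        z = norm.ppf(0.5 + level / 2)
        d = self.density[key]
        return d * np.exp(-z * se_log), d * np.exp(z * se_log)

    def home_range_area_km2(self, quantile_multiplier: float = HOME_RANGE_MULTIPLIER) -> float:
        return home_range_area(self.sigma_km, quantile_multiplier)

    def standard_buffer_km(self, multiplier: float = BUFFER_MULTIPLIER) -> tuple:
        return standard_buffer(self.sigma_km, self.se_sigma_km, multiplier)


def _start_values(sessions, layout: ScrParamLayout) -> np.ndarray:
    """Data-driven starting values on the working scale."""
    sigmas, g0s, dens = [], [], []
    for sess in sessions:
        h = sess.history
        try:
            s0 = half_mmdm(h) / 1.6
            if s0 <= 0.05:
                s0 = None
        except ValueError:
            s0 = None
        if s0 is None:
            s0 = max(trap_grid_spacing(h.traps), 0.5)
        sigmas.append(s0)
        if h.n_individuals:
            g0s.append(h.detections.mean(axis=(1, 2)).mean() * h.traps.n_traps / 4)
            area = effective_area(h.traps, 2 * s0).area_km2
            dens.append(100.0 * h.n_individuals / area)
    s0 = float(np.mean(sigmas))
    g0_0 = float(np.clip(np.mean(g0s) if g0s else 0.05, 1e-3, 0.5))
    d0 = float(np.clip(np.mean(dens) if dens else 1.0, 1e-3, None))
    x = []
    dblocks = 1 if "D" in layout.share else layout.n_sessions
    x += [np.log(d0)] * (dblocks * len(layout.strata))
    x += [logit(g0_0)] * (1 if "g0" in layout.share else layout.n_sessions)
    x += [np.log(s0)] * (1 if "sigma" in layout.share else layout.n_sessions)
    return np.array(x)


def fit_scr(
    sessions,
    share: tuple = ("D", "g0", "sigma"),
    stratified_density: bool = False,
    start: np.ndarray | None = None,
    compute_se: bool = True,
    gtol: float = 1e-6,
) -> ScrFit:
    """Fit the half-normal SCR model by maximum likelihood.

    Parameters
    ----------
    sessions
        Iterable of :class:`ScrSession` (or (history, mask) pairs).
    share
        Which of ("D", "g0", "sigma") are common across sessions; the rest
        get session-specific blocks.
    stratified_density
        When True, one density per mask stratum label (e.g. forest /
        nonforest); otherwise all active cells share one density and any
        stratum labels are collapsed.
    """
    sessions = [s if isinstance(s, ScrSession) else ScrSession(*s) for s in sessions]
    if not sessions:
        raise ValueError("need at least one session")
    for sess in sessions:
        buf = sess.mask.buffer_beyond_hull(sess.history.traps)
        if buf <= 0:
            raise ValueError("mask does not extend beyond the trap hull")
    if stratified_density:
        strata = sorted({l for s in sessions for l in s.mask.strata_labels()})
    else:
        strata = ["habitat"]
        for sess in sessions:
            st = sess.mask.stratum
            sess.mask = HabitatMask(
                sess.mask.points,
                sess.mask.cell_area_km2,
                np.where(st == EXCLUDED, EXCLUDED, "habitat"),
            )
    layout = ScrParamLayout(len(sessions), strata, tuple(share))
    x0 = start if start is not None else _start_values(sessions, layout)
    x0 = np.asarray(x0, dtype=float)

    def nll(x):
        try:
            return -scr_loglik(x, sessions, layout)
        except FloatingPointError:
            return 1e12

    res = minimize(nll, x0, method="L-BFGS-B", options={"gtol": gtol, "maxiter": 500})
    if not res.success and abs(res.fun) < 1e11:
        # one restart from a perturbed point before giving up
        res2 = minimize(nll, res.x + 0.1, method="Nelder-Mead",
                        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
        if res2.fun <= res.fun:
            res = res2
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        raise RuntimeError(f"SCR optimization failed: {res.message}")

    xhat = res.x
    cov = None
    se_available = False
    if compute_se:
        from statsmodels.tools.numdiff import approx_hess

        with np.errstate(all="ignore"):
            hess = approx_hess(xhat, nll)
        try:
            cov = np.linalg.inv(hess)
            se_available = bool(np.all(np.diag(cov) > 0))
        except np.linalg.LinAlgError:
            cov = None
        if not se_available:
            warnings.warn("singular information matrix: SEs unavailable", RuntimeWarning)
            cov = None

    se_work = np.sqrt(np.diag(cov)) if cov is not None else np.full(layout.n_params, np.nan)

    density, se_density = {}, {}
    dblocks = 1 if "D" in share else len(sessions)
    i = 0
    for b in range(dblocks):
        for s in strata:
            key = s if dblocks == 1 else (sessions[b].label, s)
            density[key] = float(np.exp(xhat[i]))
            se_density[key] = float(density[key] * se_work[i])
            i += 1
    g0 = layout.g0_of(xhat, 0)
    sigma = layout.sigma_of(xhat, 0)
    ig = layout.n_density
    isig = layout.n_density + (1 if "g0" in share else len(sessions))
    se_g0 = float(g0 * (1 - g0) * se_work[ig])
    se_sigma = float(sigma * se_work[isig])
    return ScrFit(
        density=density,
        se_density=se_density,
        g0=g0,
        se_g0=se_g0,
        sigma_km=sigma,
        se_sigma_km=se_sigma,
        log_lik=float(-res.fun),
        params=xhat,
        cov_working=cov,
        layout=layout,
        converged=bool(res.success),
        n_individuals=sum(s.history.n_individuals for s in sessions),
        message=str(res.message),
        se_available=se_available,
    )
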