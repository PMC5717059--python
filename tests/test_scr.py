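"""Spatial capture-recapture: detection function, likelihood oracles,
multi-session constraints, movement-derived constants."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import logit

import denstandard as ds
from denstandard import scr
from denstandard import simulate as sim

from conftest import make_history


class TestHalfNormal:
    def test_at_zero_distance(self):
        assert ds.halfnormal_p(0.0, 0.3, 2.0) == pytest.approx(0.3)

    def test_half_height(self):
        d = 2.0 * np.sqrt(2 * np.log(2))
        assert ds.halfnormal_p(d, 0.3, 2.0) == pytest.approx(0.15)

    def test_two_sigma(self):
        assert ds.halfnormal_p(4.0, 0.1, 2.0) == pytest.approx(0.1 * np.exp(-2), rel=1e-12)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            ds.halfnormal_p(1.0, 0.1, 0.0)


class TestConstants:
    def test_home_range_reference_value(self):
        """sigma = 4.59 km at the 2.45 multiplier gives a 397 km² range."""
        assert round(ds.home_range_area(4.59)) == 397

    def test_home_range_unit_multiplier(self):
        assert ds.home_range_area(1.0, 1.0) == pytest.approx(np.pi)

    def test_bivariate_normal_95_multiplier(self):
        mult = np.sqrt(stats.chi2.ppf(0.95, 2))
        assert mult == pytest.approx(2.4477, abs=1e-4)
        # the packaged rounding (2.45) changes the area by < 0.2%
        assert ds.home_range_area(1.0) == pytest.approx(
            ds.home_range_area(1.0, mult), rel=2e-3
        )

    def test_standard_buffer_reference_value(self):
        b, se = ds.standard_buffer(4.59, 0.95)
        assert round(b, 1) == 9.0
        assert round(se, 2) == 1.86

    def test_standard_buffer_linearity(self):
        assert ds.standard_buffer(2.0) == pytest.approx(2 * ds.standard_buffer(1.0))


def naive_scr_loglik(history, mask, d_per100, g0, sigma):
    """Brute-force oracle: explicit loops, scipy pmfs, no sharing with the
    vectorized implementation."""
    k = history.n_occasions
    dens = d_per100 / 100.0
    a = mask.cell_area_km2
    active = mask.active
    pts = mask.points[active]
    lam = 0.0
    per_cell_p = []
    for s in pts:
        ps = [
            g0 * np.exp(-((s[0] - t[0]) ** 2 + (s[1] - t[1]) ** 2) / (2 * sigma**2))
            for t in history.traps.xy
        ]
        pdot = 1.0 - np.prod([(1 - p) ** k for p in ps])
        per_cell_p.append(ps)
        lam += dens * pdot * a
    ll = float(stats.poisson.logpmf(history.n_individuals, lam))
    y = history.counts_by_trap()
    for i in range(history.n_individuals):
        tot = 0.0
        for ps in per_cell_p:
            pr = np.prod([stats.binom.pmf(y[i, j], k, p) for j, p in enumerate(ps)])
            tot += dens * pr * a
        ll += np.log(tot / lam)
    return ll


@pytest.fixture
def small_instance(tiny_traps):
    spec = {
        "i1": [(0, 0), (1, 2)],
        "i2": [(2, 1), (3, 3)],
        "i3": [(0, 4)],
    }
    return make_history(tiny_traps, spec, 5)


class TestLoglik:
    def test_matches_bruteforce_oracle(self, small_instance):
        mask = scr.make_mask(small_instance.traps, 4.0, 0.5, rectangular=True)
        params = np.array([np.log(2.0), logit(0.15), np.log(1.2)])
        ll = scr.scr_loglik(params, [(small_instance, mask)])
        oracle = naive_scr_loglik(small_instance, mask, 2.0, 0.15, 1.2)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_single_cell_hand_computation(self):
        """One cell, one trap, one animal caught once in K=2: the likelihood
        collapses to Poisson x binomial, computable by hand."""
        traps = ds.TrapArray(["t"], [[0.0, 0.0]])
        h = make_history(traps, {"i": [(0, 0)]}, 2)
        mask = scr.HabitatMask([[0.3, 0.4]], 1.0)  # d = 0.5 km
        d, g0, sigma = 3.0, 0.2, 1.0
        p = g0 * np.exp(-0.25 / (2 * sigma**2))  # d^2 = 0.3^2 + 0.4^2
        pdot = 1 - (1 - p) ** 2
        lam = d / 100 * pdot * 1.0
        expected = stats.poisson.logpmf(1, lam) + np.log(
            (d / 100 * 2 * p * (1 - p) * 1.0) / lam
        )
        params = np.array([np.log(d), logit(g0), np.log(sigma)])
        assert scr.scr_loglik(params, [(h, mask)]) == pytest.approx(float(expected), abs=1e-10)

    def test_mask_refinement_convergence(self, small_instance):
        params = np.array([np.log(2.0), logit(0.15), np.log(1.2)])
        lls = [
            scr.scr_loglik(
                params,
                [(small_instance, scr.make_mask(small_instance.traps, 5.0, c, rectangular=True))],
            )
            for c in (0.5, 0.25)
        ]
        assert abs(lls[1] - lls[0]) < 1e-2

    def test_excluded_cells_contribute_nothing(self, small_instance):
        mask = scr.make_mask(small_instance.traps, 4.0, 0.5, rectangular=True)
        # duplicate the mask with a slab of excluded cells bolted on
        extra = mask.points + [50.0, 0.0]
        aug = scr.HabitatMask(
            np.vstack([mask.points, extra]),
            mask.cell_area_km2,
            np.r_[mask.stratum, np.full(len(extra), scr.EXCLUDED, dtype=object)],
        )
        params = np.array([np.log(2.0), logit(0.15), np.log(1.2)])
        assert scr.scr_loglik(params, [(small_instance, aug)]) == pytest.approx(
            scr.scr_loglik(params, [(small_instance, mask)]), abs=1e-12
        )

    def test_multisession_is_sum_of_sessions(self, small_instance, tiny_traps):
        other = make_history(tiny_traps, {"j1": [(1, 0)], "j2": [(2, 3)]}, 5)
        mask = scr.make_mask(tiny_traps, 4.0, 0.5, rectangular=True)
        params = np.array([np.log(2.0), logit(0.15), np.log(1.2)])
        both = scr.scr_loglik(params, [(small_instance, mask), (other, mask)])
        a = scr.scr_loglik(params, [(small_instance, mask)])
        b = scr.scr_loglik(params, [(other, mask)])
        assert both == pytest.approx(a + b, abs=1e-10)

    def test_empty_session_is_poisson_zero_term(self, tiny_traps):
        h = ds.CaptureHistory((), np.zeros((0, 4, 5)), tiny_traps)
        mask = scr.make_mask(tiny_traps, 4.0, 0.5, rectangular=True)
        params = np.array([np.log(2.0), logit(0.15), np.log(1.2)])
        ll = scr.scr_loglik(params, [(h, mask)])
        oracle = naive_scr_loglik(h, mask, 2.0, 0.15, 1.2)
        assert ll == pytest.approx(oracle, abs=1e-10)
        assert ll < 0  # -Lambda


class TestFitScr:
    def test_duplicate_session_constraint(self, simulated_survey, grid_traps):
        """Two copies of one session with all parameters shared reproduce the
        single-session estimates (the two-flank device)."""
        _, history = simulated_survey
        mask = scr.make_mask(grid_traps, 8.75, 1.5)
        f1 = ds.fit_scr([(history, mask)], compute_se=False)
        f2 = ds.fit_scr([(history, mask), (history, mask)], compute_se=False)
        assert f2.density["habitat"] == pytest.approx(f1.density["habitat"], rel=1e-4)
        assert f2.sigma_km == pytest.approx(f1.sigma_km, rel=1e-4)
        assert f2.g0 == pytest.approx(f1.g0, rel=1e-3)
        assert f2.log_lik == pytest.approx(2 * f1.log_lik, rel=1e-6)

    def test_scale_equivariance_of_g0(self, simulated_survey, grid_traps):
        """Scaling all coordinates (and the mask) leaves g0-hat invariant and
        maps D-hat and sigma-hat by the corresponding powers of the factor."""
        _, history = simulated_survey
        f = 2.0
        scaled_traps = ds.TrapArray(grid_traps.ids, grid_traps.xy * f)
        scaled_hist = ds.CaptureHistory(
            history.individuals, history.detections, scaled_traps
        )
        m1 = scr.make_mask(grid_traps, 8.75, 1.25, rectangular=True)
        m2 = scr.make_mask(scaled_traps, 8.75 * f, 1.25 * f, rectangular=True)
        f1 = ds.fit_scr([(history, m1)], compute_se=False)
        f2 = ds.fit_scr([(scaled_hist, m2)], compute_se=False)
        assert f2.g0 == pytest.approx(f1.g0, rel=1e-3)
        assert f2.sigma_km == pytest.approx(f * f1.sigma_km, rel=1e-3)
        assert f2.density["habitat"] == pytest.approx(
            f1.density["habitat"] / f**2, rel=1e-3
        )

    def test_parameter_recovery_short(self, survey_config, grid_traps):
        """Mean of D-hat over a few replicates stays within its own
        Monte-Carlo band around the generating density."""
        mask = scr.make_mask(grid_traps, 8.75, 1.5)
        d_hats = []
        for s in np.random.SeedSequence(321).spawn(10):
            _, h = sim.simulate_survey(survey_config, grid_traps, seed=s)
            if h.n_individuals < 2:
                continue
            fit = ds.fit_scr([(h, mask)], compute_se=False)
            d_hats.append(fit.density["habitat"])
        d_hats = np.array(d_hats)
        se = d_hats.std(ddof=1) / np.sqrt(len(d_hats))
        assert abs(d_hats.mean() - 2.0) < max(3 * se, 0.25)

    def test_stratified_recovery(self, grid_traps):
        """Two-stratum fit recovers a non-forest:forest density ratio of 0.29
        within the replicate Monte-Carlo band."""
        x0, y0, x1, y1 = grid_traps.extent()
        m = 10.0
        region = sim.Rectangle(x0 - m, y0 - m, x1 + m, y1 + m)
        split = 5.25
        cfg = sim.SurveyConfig(
            region, 4.0, 0.08, 2.5, 90, seed=6, split_x=split, density_right=4.0 * 0.29
        )
        stratum_fn = lambda x, y: np.where(x < split, "forest", "nonforest")
        mask = scr.make_mask(grid_traps, 8.75, 1.5, stratum_fn=stratum_fn)
        ratios = []
        for s in np.random.SeedSequence(13).spawn(12):
            centers, h = sim.simulate_survey(cfg, grid_traps, seed=s)
            if h.n_individuals < 4:
                continue
            fit = ds.fit_scr([(h, mask)], stratified_density=True, compute_se=False)
            ratios.append(fit.density["nonforest"] / fit.density["forest"])
        ratios = np.array(ratios)
        assert len(ratios) >= 8
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.29) < max(3 * se, 0.12)

    def test_mask_must_extend_beyond_hull(self, simulated_survey):
        _, history = simulated_survey
        inner = scr.HabitatMask(history.traps.xy.copy(), 1.0)
        with pytest.raises(ValueError, match="hull"):
            ds.fit_scr([(history, inner)])
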