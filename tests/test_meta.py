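"""Weighted mixed meta-regression: closed-form reductions, lme4 cross-check,
model-selection machinery, effect conversions."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from denstandard import meta
from denstandard import simulate as sim


def frame(y, s, landscape=None, **cols):
    df = pd.DataFrame({"y": y, "s": s})
    df["landscape"] = landscape if landscape is not None else [f"g{i}" for i in range(len(df))]
    for k, v in cols.items():
        df[k] = v
    return df


class TestClosedForms:
    def test_intercept_only_is_inverse_variance_weighted_mean(self):
        """One landscape per record with tau fixed at 0: beta0 is the
        inverse-(relative-)variance weighted mean of y in both variance
        conventions."""
        y = np.array([0.2, 1.1, -0.4, 0.9, 0.3])
        s = np.array([0.3, 0.6, 0.9, 0.4, 0.5])
        expected = np.sum(y / s**2) / np.sum(1 / s**2)
        for conv in ("estimated", "fixed"):
            fit = meta.fit_meta_lmm(frame(y, s), (), method="ML",
                                    residual_scale=conv, fix_tau2=0.0)
            assert fit.beta["Intercept"] == pytest.approx(expected, rel=1e-8)
        assert fit.tau2 == 0.0

    def test_equal_weights_reduce_to_ols(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        s = np.full(5, 0.7)
        fit = meta.fit_meta_lmm(frame(y, s), (), method="ML", fix_tau2=0.0)
        assert fit.beta["Intercept"] == pytest.approx(y.mean(), rel=1e-8)
        # ML residual variance: sigma2_eps * s^2 = biased sample variance
        assert fit.sigma2_eps * 0.49 == pytest.approx(np.var(y), rel=1e-6)

    def test_gls_consistency_at_optimum(self):
        """Refitting with the optimizer's variance components fixed returns
        the same beta (the GLS profile is internally consistent)."""
        df = sim.simulate_meta_dataset(sim.MetaSimConfig(n_landscapes=25, seed=10))
        fit = meta.fit_meta_lmm(df, ("forest_type",), method="ML")
        refit = meta.fit_meta_lmm(df, ("forest_type",), method="ML",
                                  fix_tau2=fit.tau2)
        assert refit.beta["forest_type[peat-montane]"] == pytest.approx(
            fit.beta["forest_type[peat-montane]"], abs=1e-5
        )

    def test_record_order_invariance(self):
        df = sim.simulate_meta_dataset(sim.MetaSimConfig(n_landscapes=20, seed=11))
        fit1 = meta.fit_meta_lmm(df, ("forest_type", "disturbance"), method="ML")
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        fit2 = meta.fit_meta_lmm(shuffled, ("forest_type", "disturbance"), method="ML")
        for name in fit1.beta.index:
            assert fit2.beta[name] == pytest.approx(fit1.beta[name], abs=1e-7)
        assert fit2.log_lik == pytest.approx(fit1.log_lik, abs=1e-7)

    def test_rank_deficient_design_rejected(self):
        df = sim.simulate_meta_dataset(sim.MetaSimConfig(n_landscapes=15, seed=1))
        df["dup"] = (df["forest_type"] == "peat-montane").astype(float)
        with pytest.raises(ValueError, match="rank"):
            meta.fit_meta_lmm(df, ("forest_type", "dup"))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_matches_lme4_oracle(tmp_path):
    """Point-for-point agreement with lme4's weighted LMM (ML): beta,
    variance components, log-likelihood and SEs."""
    df = sim.simulate_meta_dataset(sim.MetaSimConfig(n_landscapes=30, seed=3))
    df["y"] = np.log(df["density"])
    df["s"] = df["relative_se"]
    df["peat"] = (df["forest_type"] == "peat-montane").astype(int)
    csv = tmp_path / "d.csv"
    df[["y", "s", "landscape", "peat"]].to_csv(csv, index=False)
    script = tmp_path / "m.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(y ~ peat + (1|landscape), data=d, weights=1/s^2, REML=FALSE)
        vc <- as.data.frame(VarCorr(m))
        cat(fixef(m), vc$vcov[1], vc$vcov[2], as.numeric(logLik(m)),
            sqrt(diag(as.matrix(vcov(m)))), sep="\\n")
    """))
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                         check=True, timeout=300)
    b0, b1, tau2, sig2, ll, se0, se1 = map(float, out.stdout.split())
    fit = meta.fit_meta_lmm(df, ("forest_type",), method="ML")
    assert fit.beta["Intercept"] == pytest.approx(b0, abs=1e-5)
    assert fit.beta["forest_type[peat-montane]"] == pytest.approx(b1, abs=1e-5)
    assert fit.tau2 == pytest.approx(tau2, abs=1e-4)
    assert fit.sigma2_eps == pytest.approx(sig2, abs=1e-4)
    assert fit.log_lik == pytest.approx(ll, abs=1e-4)
    assert fit.se_beta["Intercept"] == pytest.approx(se0, abs=1e-5)
    assert fit.se_beta["forest_type[peat-montane]"] == pytest.approx(se1, abs=1e-5)


@pytest.fixture(scope="module")
def fits():
    df = sim.simulate_meta_dataset(sim.MetaSimConfig(n_landscapes=30, seed=21))
    null = meta.fit_meta_lmm(df, (), method="ML")
    alt = meta.fit_meta_lmm(df, ("forest_type", "disturbance"), method="ML")
    return null, alt


class TestLrtAicc:
    def test_identical_models_chi2_zero(self, fits):
        null, _ = fits
        chi2, df_, p = meta.lrt(null, null)
        assert chi2 == 0.0 and p == 1.0

    def test_chi2_tail_fixture(self):
        """A log-likelihood gap of 6.46 on 2 df gives chi2 = 12.92,
        p = 0.00157 (chi-square upper tail)."""
        from scipy import stats as ss

        chi2 = 2 * 6.46
        assert chi2 == pytest.approx(12.92)
        assert ss.chi2.sf(chi2, 2) == pytest.approx(0.001565, abs=2e-5)

    def test_lrt_on_nested_fits(self, fits):
        null, alt = fits
        chi2, df_, p = meta.lrt(null, alt)
        assert df_ == 2
        assert chi2 >= 0
        assert 0 <= p <= 1

    def test_reml_rejected(self):
        df = sim.simulate_meta_dataset(sim.MetaSimConfig(n_landscapes=15, seed=2))
        f1 = meta.fit_meta_lmm(df, (), method="REML")
        f2 = meta.fit_meta_lmm(df, ("forest_type",), method="REML")
        with pytest.raises(ValueError, match="ML"):
            meta.lrt(f1, f2)

    def test_aicc_formula(self, fits):
        null, _ = fits
        n, k = null.n, null.k
        expected = -2 * null.log_lik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert meta.aicc(null) == pytest.approx(expected, rel=1e-12)
        # AICc always exceeds AIC at finite n
        assert meta.aicc(null) > -2 * null.log_lik + 2 * k

    def test_aicc_small_n_rejected(self):
        df = sim.simulate_meta_dataset(
            sim.MetaSimConfig(n_landscapes=4, estimates_per_landscape=(1, 1), seed=5)
        )
        fit = meta.fit_meta_lmm(df, ("forest_type",), method="ML")
        with pytest.raises(ValueError, match="AICc"):
            meta.aicc(fit)

    def test_model_selection_recovers_generating_terms(self):
        """Across seeds, AICc prefers the generating covariate set over an
        intercept-only and an overfitted candidate most of the time."""
        wins = 0
        n_rep = 12
        for i in range(n_rep):
            cfg = sim.MetaSimConfig(n_landscapes=40, effect_year=0.0, seed=500 + i)
            df = sim.simulate_meta_dataset(cfg)
            df["noise"] = np.random.default_rng(i).normal(size=len(df))
            comp = meta.model_comparison(
                df,
                [(), ("forest_type", "disturbance"),
                 ("forest_type", "disturbance", "year", "noise")],
            )
            wins += comp.iloc[0]["terms"] == "forest_type+disturbance"
        assert wins > n_rep / 2


class TestMarginalR2:
    def test_zero_when_no_slopes(self):
        df = sim.simulate_meta_dataset(sim.MetaSimConfig(n_landscapes=20, seed=9))
        fit = meta.fit_meta_lmm(df, (), method="ML")
        assert meta.marginal_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_approaches_one_without_noise(self):
        cfg = sim.MetaSimConfig(n_landscapes=40, tau=0.0,
                                relative_se_range=(1e-4, 1e-4), seed=14)
        df = sim.simulate_meta_dataset(cfg)
        fit = meta.fit_meta_lmm(df, ("forest_type", "disturbance", "year"), method="ML")
        assert meta.marginal_r2(fit) > 0.999

    def test_tracks_generating_variance_partition(self):
        cfg = sim.MetaSimConfig(n_landscapes=150, seed=22)
        df = sim.simulate_meta_dataset(cfg)
        fit = meta.fit_meta_lmm(df, ("forest_type", "disturbance", "year"), method="ML")
        x = fit.fitted_fixed()
        truth_fixed = np.var(np.log(df["true_density"]))
        expect = truth_fixed / (truth_fixed + cfg.tau**2 + np.mean(df["relative_se"] ** 2))
        assert meta.marginal_r2(fit) == pytest.approx(expect, abs=0.08)


class TestEffectConversions:
    def test_logging_effect_percent(self):
        assert meta.effect_percent(np.log(0.681)) == pytest.approx(-31.9)

    def test_peat_montane_effect_percent(self):
        assert meta.effect_percent(np.log(0.501)) == pytest.approx(-49.9)

    def test_zero_is_zero(self):
        assert meta.effect_percent(0.0) == 0.0

    def test_rebased_inverse(self):
        """-31.9% 'lower in logged' re-bases to +46.8% 'higher in primary'."""
        assert meta.effect_percent_rebased(np.log(0.681)) == pytest.approx(46.8, abs=0.05)
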