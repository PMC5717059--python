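"""Weighted mixed meta-regression on a synthetic multi-study dataset whose
generating effects mirror the empirical regime (-49.9% peat/montane, -31.9%
logging, +4.8%/yr)."""

from denstandard import meta, simulate as sim

df = sim.simulate_meta_dataset(sim.MetaSimConfig(seed=4))
print(f"{len(df)} density estimates from {df.landscape.nunique()} landscapes")

fit = meta.fit_meta_lmm(df, ("forest_type", "disturbance", "year"), method="ML")
print(fit.summary().round(3).to_string())
print(f"tau^2 (landscape) = {fit.tau2:.3f}, sigma^2_eps = {fit.sigma2_eps:.3f}")
print(f"AICc = {meta.aicc(fit):.1f}, marginal R² = {meta.marginal_r2(fit):.2f}")

comp = meta.model_comparison(df, [
    (), ("forest_type",), ("forest_type", "disturbance"),
    ("forest_type", "disturbance", "year"),
])
print(comp.round(2).to_string(index=False))
# 'percent' converts each log-scale coefficient to a multiplicative effect;
# the model-comparison table ranks candidate covariate sets by AICc.
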