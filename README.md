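# denstandard

Tools for putting camera-trap density estimates of low-density, individually
identifiable carnivores — Sumatran tigers are the motivating case — on a
common footing across two generations of capture–recapture methodology, and
for turning the standardized estimates into habitat-resolved population
projections.

**Who it is for.** Ecologists compiling published capture–recapture (CR) and
spatial capture–recapture (SCR) density estimates across sites and decades,
who need to (i) remove the systematic study-area bias in older non-spatial
estimates, (ii) meta-regress the standardized densities on habitat and time
while respecting each estimate's precision, and (iii) extrapolate
habitat-specific densities over landscape forest-cover tables.

## The methods

**Non-spatial CR** estimates abundance N̂ over a trapping grid with a
closed-population model (here M0, constant per-occasion capture probability
p) and converts it to density with an effective sampled area Â: the minimum
convex polygon (MCP) around the traps dilated by a movement-derived buffer,
classically half the mean maximum distance moved between recaptures
(½ MMDM). Because a finite grid truncates the largest movements, ½ MMDM
under-estimates ranging distance, Â is too small, and D̂ = N̂/Â is biased
high.

**SCR** models latent activity centres as a Poisson process with intensity
D(s) over a habitat mask and half-normal detection
p(d) = g0·exp(−d²/2σ²) at each detector. The full likelihood combines a
Poisson term for the number of detected individuals,
Λ = Σₛ D(s)·p·(s)·a with p·(s) = 1 − Πⱼ(1−pⱼ(s))^K, with each observed
history's mask-integrated probability. Multi-session fits can share any of
(D, g0, σ) across sessions — including the "two flanks as two constrained
sessions" device for single-camera stations — and densities can be
stratified by mask stratum (e.g. forest vs non-forest).

**Standardization** replaces each CR study's original buffer with the
SCR-derived standard buffer 1.96σ (the 1-D 95% quantile of the movement
kernel; the 2-D 95% home-range radius 2.45σ is kept separate and explicit)
and recomputes D̂* = N̂/Â*, with se(D̂*) = se(N̂)/Â*, preserving relative
error exactly.

**Meta-regression** fits log D̂* against habitat covariates with a
landscape random intercept and lme4-style precision weights: Var(yᵢ) =
σ²ε·sᵢ² + τ², where sᵢ = se(D̂*)/D̂* is the known relative standard error.
β is profiled by GLS inside a two-parameter variance optimization; model
selection uses likelihood-ratio tests and AICc, fit is summarized by the
marginal R² for mixed models, and log-scale coefficients convert to percent
effects via (e^β − 1)·100.

**Projection** prices per-landscape habitat-class areas (five classes:
primary montane / lowland-hill / peat, degraded lowland-hill / peat) with
habitat-specific densities, converts adults to breeding females at 1 bf per
2.9 tigers, applies the secure-source-population rule (>25 bf, >1000 km²
core, ≥25 bf nearby), and back-casts areas through per-landscape
deforestation percentages. A transcription of the published Sumatran
landscape tables ships with the package.

**Simulator.** Every stage is validated against a spatially explicit survey
simulator (homogeneous or two-stratum Poisson activity centres, Bernoulli
half-normal detections) and a synthetic multi-study generator with known
covariate effects and landscape random effects.

## Worked example

`examples/` holds one short script per capability. Simulating a survey on
an 8×8 grid (1.5 km spacing, D = 2/100 km², g0 = 0.05, σ = 2.5 km, K = 90;
`examples/02_cr_density.py` and `examples/03_scr_fit.py`) prints:

```
M_t+1 = 10 caught, N-hat = 10.0 ± 0.0 (per-occasion p = 0.212)
half-MMDM buffer = 3.34 km, effective area = 285 km²
CR density = 3.50 ± 0.00 per 100 km² (truth: 2.0)

D-hat = 1.95 ± 0.63 per 100 km² (95% CI 1.04-3.66; truth 2.0)
g0 = 0.046 ± 0.004 (truth 0.05)
sigma = 2.59 ± 0.13 km (truth 2.5)
```

The CR quotient overshoots the simulated truth by 75% purely through its
too-narrow buffer; the SCR fit recovers density, g0 and σ. With the
reference movement scale σ = 4.59 ± 0.95 km, `standard_buffer` gives the
9.0 ± 1.86 km correction buffer and `home_range_area` a 397 km² home range.
Projection onto the packaged landscape table
(`examples/06_project_population.py`) prints, per landscape, adults ±1 SE
and breeding females — e.g. 140 adults / 48 breeding females in Gunung
Leuser — a seven-landscape priority total of 514, and the island-wide
2000–2012 contrasts (16.6% forest loss, 16.7% potential-population
decline).

The command-line front end mirrors the library:
`denstandard simulate|fit-cr|fit-scr|standardize|meta|project|run`.

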