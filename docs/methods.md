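# Methods

This note records the statistical models implemented in `denstandard`, the
defaults and why they were chosen, what the simulators do and do not
emulate, and the numerical choices that matter for reproducing results.

## Closed-population abundance (M0)

The non-spatial stage uses model M0: each of K occasions is an independent
Bernoulli trial per animal with a single capture probability p, so with m
distinct animals and `total` animal-occasion captures,

    L(N, p) = N!/(N−m)! · p^total · (1−p)^(NK−total).

N is treated as continuous and profiled with p̂(N) = total/(NK); the score
ψ(N+1) − ψ(N−m+1) + K·log(1−p̂(N)) is solved by bracketed root finding, and
no integer rounding is applied. Standard errors come from the inverse of
the analytic observed information of the joint (N, p) likelihood. Two
boundary regimes are handled explicitly: every animal caught on every
occasion (p̂ = 1, N̂ = m, zero variance, warned) and a non-positive score at
N = m (N̂ = m, flagged `boundary`).

M0 is deliberately the only closed-population model offered. The
standardization stage consumes *published* N̂ and se(N̂) rather than
refitting heterogeneous models whose structure the original studies rarely
document; M0 exists so the simulation experiments have an honest in-package
CR estimator. Note that M0 is *not* invariant to doubling K with
proportionally doubled captures — the extra occasions add information and
pull N̂ toward m (verified against the profile-likelihood grid scan in the
tests).

## Geometry

Effective sampled areas use the convex hull of the detector array. For an
unclipped convex hull with area A and perimeter P, the Euclidean dilation
by b has exact area A + P·b + πb², which is what `effective_area` returns;
degenerate hulls use the same formula with (A=0, P=2L) for a segment and
(A=0, P=0) for a point. Clipping against a land/habitat polygon falls back
to a fine polygonal buffer (256 segments per quarter circle). All
coordinates are planar kilometres; there is no geodesy anywhere.

MMDM is the mean, over individuals detected at ≥2 distinct traps, of each
individual's maximum pairwise inter-trap distance; animals seen at a single
trap carry no movement information and are excluded. When no animal is
recaptured at a second trap MMDM is undefined and an error is raised rather
than a default substituted.

## Spatial capture–recapture

Half-normal detection p(d) = g0·exp(−d²/2σ²) at binary proximity detectors
(several animals may share a trap-occasion; single-camera stations give no
grounds for a behavioural-response term). The full (unconditional) Poisson
likelihood is used rather than the conditional-likelihood /
Horvitz–Thompson route — both are standard; one canonical path keeps
standard-error reporting simple. Per session with mask cells s (area a):

    p·(s)  = 1 − Πⱼ (1 − pⱼ(s))^K
    Λ      = Σₛ D(s) · p·(s) · a
    log L  = log Poisson(n; Λ) + Σᵢ log [ Σₛ D(s) · P(ωᵢ|s) · a / Λ ]

with P(ωᵢ|s) the product over traps of binomial probabilities of the
individual's detection counts. Binomial coefficients are included so
likelihood values match hand computations exactly. Excluded mask cells
(water) carry zero density and contribute nothing; this is tested exactly.

Estimation is on the working scale (log D per stratum, logit g0, log σ) by
L-BFGS-B with a Nelder-Mead restart on failure; relative tolerance 1e-6.
Starting values are data heuristics: σ₀ = ½MMDM/1.6 (falling back to the
median trap spacing), g0 from the observed per-animal-occasion detection
rate, D₀ from m divided by the 2σ₀-buffered hull area. Standard errors
invert a numerically differenced Hessian (statsmodels `approx_hess`) and
delta-map to the natural scale; a singular information matrix flags the fit
`se_available=False` instead of failing. Wald intervals for D are formed on
the log scale, so they are asymmetric and positive.

Masks default to a 0.5 km lattice trimmed to within the buffer distance of
the trap hull. For the replicated bias experiment a 1.0 km cell and a 3.5σ
buffer are used — with σ = 2.5 km the likelihood changes by far less than
the Monte-Carlo noise (mask-refinement convergence is tested) at a tenth of
the cost. Multi-session fits share any subset of (D, g0, σ); sharing all
parameters across duplicated sessions reproduces the single-session
estimates exactly, which is the constraint device used when left- and
right-flank photo catalogues cannot be merged.

Two quantile constants coexist deliberately and are never interchanged:
1.96σ (1-D 95% quantile of the half-normal movement kernel) is the
standardization buffer; 2.45σ (≈ √χ²₂(0.95), the 2-D 95% radius of a
circular bivariate normal) scales home-range and effective-area reporting.
Both are explicit arguments with these defaults.

## Standardization

`correct_cr_density` recomputes a CR record's density with the standard
buffer: Â* from full trap coordinates when available, else from the convex
closed form using published hull area and perimeter (compiled datasets
rarely ship coordinates). D̂* = N̂/Â* and se(D̂*) = se(N̂)/Â*, so relative
standard error is preserved exactly — the property the meta-regression
weights rely on. Records lacking N̂ pass through unchanged and are flagged
not-correctable rather than dropped. Â* is not clipped to land by default
(clipping is available through the geometry pathway). A standard buffer
narrower than a study's original buffer would *raise* its density; this is
allowed but warned, since the correction's purpose is the opposite regime.
Hulls are convex throughout; concave outlines for irregular grids are out
of scope.

## Meta-regression

Records are study-level: y = log D̂*, with known relative standard error
s = se(D̂*)/D̂* serving as the standard error of y (abundance sampling
distributions are approximately log-normal). The model is

    yᵢ = xᵢ'β + u_l + eᵢ,  u_l ~ N(0, τ²),  eᵢ ~ N(0, σ²ε·sᵢ²),

i.e. lme4-style weights wᵢ = 1/sᵢ² scaling a *common estimated* residual
variance, plus a landscape random intercept. The strict meta-analytic
convention (Var(eᵢ) = sᵢ², σ²ε ≡ 1) is available via
`residual_scale="fixed"`; the lme4 semantics are the default because they
match the tooling this workflow standardizes on. β is profiled by GLS
inside a Nelder-Mead search over (log σ²ε, log τ²); the per-landscape
block inverses use rank-one (Sherman–Morrison) identities, so an entire
fit costs a few milliseconds. τ² reaching the 1e-6·σ²ε boundary is
reported as 0 with a flag. The implementation agrees with lme4 (ML and
REML: β, variance components, log-likelihood, SEs) to ~1e-5 on simulated
data; that cross-check runs in the test suite via Rscript.

Covariate encodings: forest type baseline lowland-hill, disturbance
baseline primary, year centred at 1996. Wald z statistics are reported;
at n ≈ 26 records these are anti-conservative relative to t references —
a documented caveat, not a correction. LRT and AICc use ML fits only;
k counts fixed effects plus estimated variance parameters, so AICc deltas
are interpretable within this package but not against software that counts
differently. Marginal R² = Var(Xβ̂) / (Var(Xβ̂) + τ² + σ²ε·mean(s²)).

## Projection

Adults per landscape = Σ_class area·density/100. Habitat-class densities
come either from meta-regression effects composed multiplicatively
(`densities_from_effects`: montane and peat carry the peat/montane
multiplier, degraded classes the degradation multiplier, degraded peat
both — the interaction is assumed multiplicative in the absence of an
estimate) or from `derive_habitat_densities`, a documented non-negative
least-squares oracle that back-fits the five class densities from a
published projection table. Breeding females = round(adults/2.9), half-up
(matching published table cells such as 52 → 18). Standard errors use the
dataset-level rule se = relative-SE × adults, and totals sum SEs linearly —
subpopulation errors are treated as fully correlated because they share the
same density estimates. "Nearby" in the SSP rule is a user-supplied
quantity (breeding females in connected forests), not computed from
geometry. The packaged forest-cover transcription was validated against two
independent checksums (per-row totals and per-class column totals); the
published totals row differs from the column sums by one animal (619 vs
618, 743 vs 742) through rounding, and tests carry that ±1 slack.

## Simulators

The survey simulator draws a Poisson number of activity centres uniformly
over a rectangular state space (optionally two density strata split at a
vertical line) and Bernoulli half-normal detections independent across
animal × trap × occasion. It does **not** emulate within-survey movement,
behavioural responses, misidentification, sex-specific movement, or raster
habitat structure — so passing tests demonstrate estimator correctness
under the model's own assumptions, not robustness to their violation. The
state space should exceed the trap hull by ≥4σ (warned otherwise);
activity centres may legitimately fall outside the hull.

Reference survey conditions for the bias experiment: 8×8 grid at 1.5 km
spacing, D = 2/100 km², g0 = 0.05, σ = 2.5 km, K = 90, 100 replicates —
a sparse large-ranging carnivore on a grid much smaller than a home range,
the regime in which ½ MMDM buffers bias CR densities upward. Replicates
with no captures, undefined MMDM, or failed SCR fits are excluded from
summaries with their count reported. The corrected estimator re-buffers
each replicate with 1.96·σ̂ from that replicate's own SCR fit, mirroring a
correction borrowed from SCR fieldwork.

The meta-analysis generator defaults encode the empirical regime the
package targets: 60 landscapes with 1–3 estimates each, baseline
lowland-hill density 1.11/100 km², peat/montane multiplier 0.501, logging
multiplier 0.681, +4.8%/yr time trend, landscape SD τ = 0.3, and relative
standard errors uniform on (0.3, 0.9) — published tiger densities carry
relative SEs of roughly 0.45–0.9. Observed log densities add the landscape
effect and Normal noise with each record's own s, so σ²ε = 1 is the
generating truth.

One master seed feeds per-stage `SeedSequence` spawns everywhere, so
replicates are independently reproducible and a fixed seed gives
byte-identical outputs.

## Known limitations

- M0 only; no Mh/Mb/Mt family, and no refitting of published CR studies.
- Likelihood SCR only (no Bayesian variant), no trend surfaces beyond two
  density strata, no sex- or site-specific σ.
- Wald inference throughout the meta-regression; small-sample t/Kenward-
  Roger corrections are not implemented.
- The compound relationship between an annual percentage trend and its
  multi-year total is not modelled; annual and total figures are reported
  independently.
- Problem sizes in the replicated experiments (replicate counts, mask
  resolution) are the package's reference choices and are stated alongside
  each experiment; enlarging them tightens the Monte-Carlo bands without
  changing any default.
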