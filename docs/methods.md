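# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `exfrac`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Rate estimators

Growth and production rates are literal forward differences assigned to the
left endpoint:

    µ(t)   = [OD(t+Δt) − OD(t)] / (Δt · OD(t))            [h⁻¹]
    ρ_H(t) = [flu(t+Δt) − flu(t)] / (Δt · OD(t))          [flu·OD⁻¹·h⁻¹]

No smoothing or central differencing is applied: the estimators are meant to
reproduce the standard plate-reader workflow, not to improve on it. On
exponential growth OD = A·e^(µ₀t) the forward difference returns
(e^(µ₀Δt) − 1)/Δt, i.e. a first-order bias with coefficient µ₀²/2 — about
2% at µ₀ = 0.7 h⁻¹ and 15-min sampling (verified at two Δt in the tests).

Slowly maturing fluorophores are handled by shifting the fluorescence trace
*earlier* by a whole number of samples, k = round(maturation_time / median Δt)
(1 h at 15-min sampling → 4 samples); the k trailing points are dropped, not
extrapolated. Fractional-interval interpolation is deliberately rejected —
it would smuggle smoothing into an otherwise raw estimator. Default
maturation is 0 for GFP channels (GFPmut3 matures in ~4 min, under one
sampling interval) and should be set to ~1 h for slow RFPs; always
user-overridable. The fraction proxy is φ_H(t) = flu(t)/OD600(t), which
assumes fluorescence ∝ reporter mass and OD ∝ total protein; the constant of
proportionality (κ in the simulator) is unknown for real data, so φ_H and
f_H carry flu/OD units rather than true mass fractions.

## Maximum method

Per replicate, the maximum of φ_H over t ≤ window (default 10 h from
induction) and its time; the per-replicate maxima are averaged and their
sample variance (N − 1) feeds the Hill fit's weights. Maxima are taken per
replicate *before* averaging — the max of a mean curve would be biased by
replicate time-shifts. Ties resolve to the earliest sample (arbitrary but
deterministic). A condition where more than half the replicates peak at the
window edge is flagged `boundary_maximum`: the trace never turned over, the
fixed-point argument does not apply, and the estimate should not be trusted
(continuously accumulating reporters are exactly this failure mode — use the
slope method there).

Two caveats quantified by the validation runs: (i) a culture whose growth
stops inside the window reaches only φ_H = f_H·(1 − M₀/M_final); with the
default simulator (81-fold growth) that is a −1.2% deficit; (ii) the literal
argmax over noisy samples is biased upward by roughly the expected maximum
of the per-sample noise among near-plateau points (+2–3% at 2% noise).

## Slope method

1. **Growth-phase detection.** On the shared replicate grid, a two-sided
   one-sample t-test per time point asks whether the replicate µ values
   differ from zero; a point is growth phase iff p < α (default 0.05) *and*
   mean µ > 0. The conjunction covers both readings of "significantly
   different from zero" for a phase that is by definition µ > 0. Zero-spread
   columns get p = 1 when the common value is 0 (excluded) and p = 0
   otherwise. A single replicate falls back to a fixed threshold
   µ > µ_min (default 0.05 h⁻¹) with a warning.
2. **Pooled OLS with chronological trimming.** All replicates' (µ, ρ_H)
   growth-phase points are pooled into one regression per condition. The
   chronologically earliest remaining point is removed one at a time and the
   fit is kept at the depth where R² peaks. The default stop rule is
   **first-local-max**: trim while each removal strictly improves R² and
   stop at the first depth where it does not. This removes an early "hook"
   (the inducer-equilibration transient, during which f_H is not yet
   constant) cleanly, and under observation noise it degenerates gracefully
   into "no trimming". The alternative `trim_rule="global_max"` (evaluate
   every depth down to `min_points`, keep the global argmax, ties toward
   more points) is retained but not default: with ~80 noisy rate points the
   global argmax almost surely lands on a spurious late window of ~4 points
   whose R² ≈ 1 by chance, producing wild slopes. `min_points` defaults
   to 4 — below that an R² is near-meaningless.
3. **Models.** `free_intercept` fits ρ_H = slope·µ + intercept and reports
   b = −intercept/slope (the growth rate at which production ceases; b > 0
   when the reporter shuts down before growth does). `through_origin`
   forces b = 0 for systems whose rate plot visibly passes through the
   origin; its R² is the uncentred 1 − SSE/Σy² convention. A non-positive
   slope makes b undefined; it is reported as 0 with a warning. Fits with
   R² below 0.9 stay in the dose-response but are flagged `low_r_squared`.

**Known bias (errors in variables).** µ is the regression x-variable and is
itself noisy; forward differencing amplifies per-read OD noise by
√2/Δt ≈ 5.7 at 15-min sampling, and OLS attenuates the slope by
Var(µ_true)/(Var(µ_true) + Var(µ_noise)). At the simulator's default 1% OD
noise this is a −4–5% shrinkage of every slope (measured: OD-noise-only
slope/truth = 0.947, fluorescence-noise-only = 0.999). Because the shrinkage
is nearly concentration-independent it barely moves k_I and n, but it
depresses H. Errors-in-variables correction is deliberately out of scope;
the attenuation is documented rather than silently corrected.

## Hill dose-response

Two algebraic forms: `full`, f_H = H·Iⁿ/((H+1)·Iⁿ + k_Iⁿ), which arises when
the Hill law allocates a finite proteome (plateau H/(H+1)); and the default
`reduced` textbook form f_H = H·Iⁿ/(Iⁿ + k_Iⁿ), valid when the heterologous
fraction is small (the circuit studied stays under ~15% of biomass). They
are exactly related by full(I; H, k, n) = reduced(I; H/(H+1), k·(H+1)^(−1/n), n).

Fitting is bounded trust-region nonlinear least squares (H ≥ 0, k_I ≥ 0,
n ≥ 1) on the weighted residuals √wᵢ·(yᵢ − model), wᵢ = 1/varianceᵢ.
Zero/undefined variances get the group-median variance with a warning.
Initialisation: H₀ = max f_h (or p/(1−p) for the full form), k₀ = the
non-zero concentration whose response is nearest half-max, and a multi-start
over n₀ ∈ {1, 2, 4} — Hill fits are multimodal in n. The zero-concentration
point is included (the model passes through 0 at I = 0; there is no
basal-leak term, by design). Standard errors are asymptotic:
cov = s²·(JᵀJ_w)⁻¹ with s² the reduced chi-square, the convention of
`nls`-style fitters; with trustworthy known variances s² ≈ 1 and the two
conventions coincide. A fit whose curve is already ≥95% saturated at the
smallest tested concentration is flagged `non_identifiable_k_I` — a flat
response constrains the plateau but not the affinity/cooperativity split.

`compare_methods` reports, per parameter, the absolute difference, the
difference relative to the maximum-method value, and z = |Δ|/√(se₁² + se₂²).

## Simulator

The generator integrates a four-fraction allocation model in batch culture —
one concrete instantiation of the framework, with Monod forms everywhere:

    ρ      = k_ρ · φ_R · x/(K_x + x)           biosynthesis (µ ≡ ρ)
    uptake = Y · φ_C · S/(K_S + S)             nutrient fixation per biomass
    f_H    = hill(I·I_int) · g                 inducer-driven allocation
    rest   = 1 − f_Q − f_H;  a = x/(K_a + x)
    f_R    = rest·a;   f_C = rest·(1 − a)      x stimulates f_R, represses f_C
    dφ_i/dt = ρ·(f_i − φ_i);   dx/dt = uptake − ρ − µx
    dM/dt  = µM;   dS/dt = −uptake·M

µ ≡ ρ encodes protein ∝ biomass, the same approximation the slope method
invokes. I_int is the internal-inducer fraction, rising to 1 with time
constant `equilibration_tau` (0 = instantaneous; > 0 produces the early
hook in rate plots, which is invisible at saturating I — the lag shortens
with concentration, qualitatively as observed for slow inducers like IPTG).
g is a production-arrest factor decaying at `arrest_rate` once S <
`arrest_S`, emulating reporters that stop being made before growth stops
(the b > 0 phenotype); off by default.

Defaults (chosen once to emulate a 30 °C minimal-medium microtiter culture):
f_Q = 0.45, ground-truth Hill (hill_H, hill_kI, hill_n) = (0.12, 30 µM, 2.5)
on the fraction scale, k_ρ = 3 h⁻¹, Y = 9 h⁻¹, K_S = 0.25, K_x = K_a = 0.5,
S0 = 8, M0 = 0.1 (so µ_max ≈ 0.70 h⁻¹, nutrient exhaustion ≈ 9.8 h, 81-fold
growth), κ = 8×10⁴ flu/OD per unit φ_H (plateau ≈ 9.6×10³ flu/OD, the scale
of real DE3-system fits), 15-min sampling for 16 h (65 samples), 4
replicates. Observations are OD = M and flu = κ·φ_H·M, each multiplied by
lognormal noise with σ_OD = 0.01 and σ_flu = 0.02 per read (plate-reader
noise scales with signal); slow maturation is modelled as a first-order
filter on the fluorescence signal. The deterministic trajectory is shared
across replicates; only observation noise differs, drawn from per-well
substreams of the single seed, so identical seeds give bit-identical data.

Integration is fixed-step RK4 with 25 substeps per sampling interval
(dt = 0.01 h) — deterministic, dependency-free, and accurate for these
smooth dynamics: halving the substep moves the sampled observables by
< 10⁻⁵ relative, the proteome simplex Σφ_i = 1 is conserved to ~10⁻⁹, and
the trajectory matches an adaptive reference integrator (rtol 10⁻¹⁰) and
the frozen-coefficient closed form φ_H = f_H·(1 − e^(−∫ρ)) to 10⁻⁶. A step
that produces a negative state retries once at dt/10, then raises.

**What the generator does and does not emulate.** It reproduces sigmoidal
batch growth into stationary phase, inducer-dependent reporter allocation
with the fixed-point property, replicate observation noise, inducer-import
lag and early production arrest. It does not model stochastic gene
expression, cell-to-cell heterogeneity, diauxie, plasmid copy-number drift,
active reporter degradation, photobleaching, or additive instrument noise
floors. Passing recovery tests on this generator therefore demonstrates the
estimators' correctness under the model's own assumptions — not robustness
to every artefact of real plate-reader data.

## Validation experiments and what they show

* **Fixed point (theorem check).** Noiseless arrest scenario → interior φ_H
  maximum; at the maximum |φ_H − f_H|/f_H < 1% (the residual is the finite
  time resolution of the integration grid times the f_H decay rate).
* **Slope-method recovery.** 100 titrations (6 concentrations straddling
  k_I, 4 replicates, 5% fluorescence noise, OD noise at the instrument
  default — see the errors-in-variables note for why 5% *OD* noise is not a
  regime where an uncorrected OLS slope can work): median k_I error < 10%,
  median |n̂ − n| < 0.5.
* **Method concordance.** On a default titration the maximum- and
  slope-method estimates agree to a few percent relative, but their
  *z*-scores for H sit near 4–7: two small opposite-signed systematic
  biases (argmax noise bias vs OLS attenuation) against sub-2% standard
  errors. A |z| < 2 concordance across all three parameters is not
  achievable with these estimators at realistic noise — published real-data
  fits of the same design show z ≈ 4.5 for H in their best-agreeing system —
  so agreement between the methods should be judged on relative difference,
  not z.
* **Estimator oracles.** Forward differences reproduce hand-computed toys
  exactly; the untrimmed slope fit equals closed-form OLS to 10⁻¹⁰; the
  bounded Hill fit pins n = 1 on sub-cooperative data and matches a
  profile-scan oracle's RSS.

Problem sizes throughout (65-sample wells, 6-point titrations, 100-titration
recovery batches) match the simulated study design above; the full
validation run takes a few minutes on one CPU.

## Other design notes

* Tidy CSV is the canonical interchange; readers parse floats in
  round-trip mode so read → write → read is bit-exact. Time units are
  converted only via an explicit flag. Blank correction defaults to `none`
  (specific rates normalise raw flu by raw OD); `mean_blank` subtracts the
  per-time mean blank with a positive OD floor ε = 10⁻³.
* Fluorescence channels are treated as incommensurable arbitrary units —
  different detector gains are never cross-calibrated.
* The regression-shaped cores are scikit-learn estimators
  (`SlopeFractionRegressor`, `HillRegressor`) and compose with sklearn
  tooling (`clone`, `get_params`); the spec-level functions are thin
  wrappers returning result records.
* Out of scope: OD→cell-count calibration, absolute protein quantification,
  photobleaching/evaporation correction, robust or total least squares,
  Bayesian dose-response inference, basal-leak terms.
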