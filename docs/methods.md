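# Methods

## Model and assumptions

`lipotrap` treats each forming liposome as an independent renewal system: a
single absorbing *closure* event ends the entrapment of solute, and the
ensemble of liposomes is a set of i.i.d. realizations (no competition for
lipids or for solute between vesicles). Two mechanisms couple the solute to
the closure kinetics:

1. **Jamming.** In state *N* (molecules currently inside) the closure
   propensity is `r_c(N) = r0 / (1 + N)`. The `+1` regularizes the empty
   state; `r0` (units 1/time) is the closing rate of a solute-free liposome.
   *N* counts molecules currently inside, not all molecules that ever
   entered — with outflux these differ, and the current count is the
   physically meaningful one for a surface-crowding mechanism.
2. **Semi-permeability.** Molecules enter with propensity `λ_in` and leave
   with propensity `λ_out ≤ λ_in` (units molecules/time), active only while
   at least one molecule is inside: nothing can leave an empty vesicle. The
   outflux is state-independent while N > 0, matching a constant-flux
   picture; an N-proportional variant is out of scope.

Time units are arbitrary; the rates set the scale. Replacing the fluctuating
count by its mean `⟨N(t)⟩ = λt` (with `λ = λ_in − λ_out`) gives the averaged
hazard `r(t) = r0/(1 + λt)`, the survival law `Ψ(t) = (1 + λt)^(−r0/λ)`, and
— through the change of variables `N = λτ` with N treated as continuous —
the occupancy density `P(N) = (µ−1)/(1+N)^µ` with `µ = 1 + r0/λ`. For
`λ = 0` the closed forms fall back to the exponential (constant-hazard,
Poisson) limit rather than erroring, since that limit is the physically
meaningful no-cooperation case.

The averaging step is uncontrolled in one respect: it averages the hazard
over the whole ensemble rather than over survivors. `ensemble_occupancy_stats`
reports the empirical survivor hazard next to `r0/(1 + λt)` as a diagnostic;
the package asserts only order-of-magnitude and monotonicity agreement, and
the tail-exponent tests show the headline relation `µ = 1 + r0/λ` survives
the full count fluctuations (tail MLE within ±0.15 of the predicted value at
ensemble size 1e5).

## Simulators

* **Event-driven (exact).** Competing exponential clocks: from state *N*
  the total rate is `λ_in + λ_out·[N>0] + r0/(1+N)`; the holding time is
  exponential with that rate, the event kind proportional to the
  propensities. Closure is absorbing. A `max_events` cap (default 1e6)
  guards the heavy-tailed regimes — for `r0 ≤ λ` the mean trapped count is
  infinite (`µ ≤ 2`) — and capped trajectories are returned *censored*,
  excluded from final-state arrays and tallied in `n_censored`, never
  raised. `simulate_ensemble_exact` advances all open trajectories in
  vectorized lockstep from a single seeded generator; results are
  bit-reproducible given `(config, seed)`, and each trajectory consumes
  i.i.d. draws, so the per-trajectory law is identical to the scalar
  simulator. The scalar path (`simulate_liposome_exact`,
  `simulate_trajectories`) records full event histories and uses
  counter-based per-liposome substreams `default_rng((seed, i))`, so any
  single trajectory can be regenerated in isolation.
* **Mean-field.** Closure times by inverse-CDF of the averaged survival law
  (`expm1` is used so the `λ → 0` limit is numerically exact), counts by
  `N = λτ`. The default `count_mode="continuous"` is the literal change of
  variables and makes the exponent relation exact; `"floor"` gives integer
  counts; `"poisson"` draws `N ~ Poisson(λτ)`, restoring counting noise
  about the mean path.
* **Oracle.** For the pure-birth case (`λ_out = 0`) the trapped-count pmf
  has a closed product form from the embedded jump chain; it is computed in
  log space and used as the exact reference for the event-driven simulator.

## Estimators and numerical choices

* **Continuous MLE (default).** For counts ≥ `n_min`,
  `µ̂ = 1 + m / Σ ln((1+N_i)/(1+n_min))`, `se = (µ̂−1)/√m`. Default
  `n_min = 0`: the occupancy law is asserted globally, and zeros are
  retained (they contribute `ln 1 = 0`). Tail-only fits (`n_min = 10` in the
  simulator checks) are used where only the asymptotic law is exact.
  The estimator is the MLE of a continuous density applied to data that may
  be integer-valued; on heavily discrete samples (many 0s and 1s) this
  incurs a systematic discretization offset — see limitations.
* **Discrete MLE.** `P(k) ∝ (1+k)^(−µ)` normalized by the Hurwitz zeta
  `ζ(µ, 1+n_min)`, maximized by bounded scalar minimization on
  `µ ∈ (1, 60]`; the standard error comes from the central-difference
  observed information. Flagged as the non-default variant.
* **Histogram (graphical) fit.** Fixed-width bins `[kw, (k+1)w)` from 0
  (the "BIN" convention); unweighted least squares of `log f` on
  `log(1+center)` over the contiguous run of non-empty bins, stopping at the
  first empty bin. Beyond that point bins hold O(1) draws and sit on a flat
  log-frequency floor that would bias the slope downward severely (measured:
  µ̂ ≈ 1.26 instead of 2.3 at n = 1e5 if the sparse tail is included);
  truncation mirrors fitting the plotted range of a histogram. Excluded
  bins are logged. Binning bias at BIN = 3 is about +0.1 at µ = 2.3.
* **Model comparison.** AIC with k = 1 per model. The power-law side uses
  the *discrete* zeta likelihood so both likelihoods are pmfs on the
  integers; a likelihood-ratio test is not offered (non-nested models).
  Comparisons on fewer than 30 counts are flagged low-confidence.
* **Goodness of fit.** One-sample KS statistic against the tail-conditioned
  CDF `F(n | N ≥ n_min) = 1 − ((1+n_min)/(1+n))^(µ−1)`.
* **Quadrature.** `survival_from_hazard` integrates the hazard with
  adaptive quadrature per grid interval (`epsabs = 1e-13`), so the tabulated
  curve matches the closed form to ≤ 1e-8 over t ∈ [0, 100]. Hazard
  recovery from a curve uses second-order finite differences of `ln Ψ`.
* **Constants.** Avogadro's number is the 2019 SI exact value, so the
  Poisson baseline `N_µ = N_A·V·C₀` reproduces printed digits exactly.

## Synthetic data

Generators are deterministic given `(spec, seed)` and write a ground-truth
JSON sidecar sufficient to re-run any recovery test.

* `powerlaw` — inverse-CDF draws `X = U^(−1/(µ−1)) − 1`; floor mode has the
  discrete law `P(N=k) = (1+k)^(1−µ) − (2+k)^(1−µ)`.
* `poisson` — the independent-trapping baseline.
* `luisi_like` — emulates the reported qualitative structure of cryo-TEM
  ferritin counts: with probability `w` a vesicle is empty, otherwise a
  floor-mode power-law draw with exponent `µ_tail`. A pure power law at
  µ = 2.3 cannot satisfy both reported fractions simultaneously
  (P(N=0) ≈ 0.59 < 0.8 while P(N>20) ≈ 0.018 > 0.01), so zero inflation is
  structural, not cosmetic. Defaults `w = 0.7`, `µ_tail = 2.3` give expected
  empty fraction 0.878 and crowded (>20) fraction 0.0054, inside the
  reported ranges (>80% and 0.1–1%). Draws above `cap = 3000` (ten times
  the reported maximum of ~300) are resampled so fixtures stay in the
  regime the real data occupies; the cap is recorded in the sidecar.
  Infeasible `(w, µ_tail)` combinations raise with the feasible `w` region.

What the fixture does **not** emulate: vesicle-size heterogeneity (which
mixes Poisson means and broadens the empty fraction), measurement error in
molecule counting, finite imaging volumes, or any correlation between
vesicle size and occupancy. Passing fixture tests therefore shows the
inference machinery is self-consistent, not that the mechanism is the one
operating in the experiments.

## Problem sizes

Default verification runs use ensembles of 1e4–1e5 liposomes and 20-replicate
recovery grids at n = 1e4 — sizes at which the exponent MLE's standard error
(≈ 0.004 at n = 1e5) comfortably resolves the effects being checked while
the whole suite runs in well under a minute.

## Known limitations

* The continuous MLE and the zeta-discrete MLE converge to *different*
  population values on integer (floor-law) samples — at µ = 2.3, n_min = 0
  roughly 2.87 and 2.04 respectively — because each assumes a different
  discretization of the same continuous law. The discrepancy shrinks for
  tail fits (≈ 0.07 at n_min = 10) but does not vanish at the 1-standard-
  error level; exponents quoted from integer data should state the
  estimator and `n_min`. For continuous change-of-variables samples the
  continuous MLE is exact and unbiased to O(1/n).
* The censoring cap truncates the extreme tail; for µ ≤ 2 a small fraction
  of trajectories (≈ `(max_events)^(1−µ)` per liposome) is censored and tail
  fits are biased upward by a few hundredths at the default settings.
* Only constant fluxes are modelled; time-varying `λ_in/λ_out` schedules,
  inter-liposome competition, and the alternative variable-influx /
  constant-closure-rate mechanism are out of scope.
* Units are the caller's responsibility (litres and mol/L for the Poisson
  baseline; an ambiguity between mM and µM in published concentration
  captions is deliberately left to the user).
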