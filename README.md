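# lipotrap

Renewal-process modelling and inference for **anomalous solute crowding in
liposomes** — the observation that when lipid vesicles self-assemble in a
solute-containing solution, the number of molecules trapped per vesicle does
not follow the Poisson law expected for independent trapping: most vesicles
are empty, yet a small fraction is extremely crowded, and the occupancy
distribution decays as an inverse power law.

`lipotrap` is for modellers and experimentalists in origin-of-life /
protocell research who want to (a) simulate solute entrapment under a
cooperative "jamming" mechanism and (b) fit per-vesicle count data against
the power-law and Poisson alternatives.

## The model

A forming liposome is open until a single critical *closure* event. Two
hypotheses couple the solute to the closure kinetics:

* **jamming** — trapped molecules slow closure: the closing rate in state
  *N* is `r_c = r0 / (1 + N)`, where `r0` is the bare closing rate;
* **semi-permeability** — solute flows in faster than out, giving a net
  inward flux `λ = λ_in − λ_out > 0`, so `⟨N(t)⟩ = λt`.

Averaging the count in the hazard gives the inverse-linear closing rate
`r(t) = r0 / (1 + λt)`, whose survival function is the shifted power law

```
Ψ(t) = (1 + λt)^(−r0/λ),     ψ(t) = r0 / (1 + λt)^(1 + r0/λ).
```

Mapping closure times to counts through `N = λτ` yields the per-vesicle
occupancy density

```
P(N) = (µ − 1) / (1 + N)^µ,      µ = 1 + r0/λ,
```

against the Poisson baseline `N_µ = N_A·V·C₀` of independent trapping. The
exponent relation `µ = 1 + r0/λ` is the testable prediction; the value
`µ = 2.3` (i.e. `r0/λ = 1.3`) matches the published cryo-TEM ferritin
counts.

The package provides:

* `renewal_core` — the closed forms above plus hazard↔survival conversions
  and the Poisson baseline;
* `trap_simulator` — an exact event-driven (competing-clocks) simulator of
  the full Markov chain `r_c = r0/(1+N)`, a mean-field inverse-CDF sampler,
  and the exact embedded-jump-chain pmf as an oracle;
* `inference` — closed-form continuous MLE of µ, a discrete (Hurwitz-zeta)
  variant, Poisson fit, AIC model comparison, KS goodness of fit, and
  fixed-width ("BIN") histogram fits;
* `synthetic_data` — seeded generators (exact power-law draws, Poisson
  draws, and a zero-inflated fixture emulating the qualitative structure of
  the published data);
* `cli_io` — the `lipotrap` command-line interface and CSV/JSON I/O.

## Worked example

Generate 10,000 vesicles from the occupancy law with µ = 2.3 and refit the
exponent:

```
$ lipotrap synth --scenario powerlaw --mu 2.3 --mode continuous \
      --n 10000 --seed 11 --out counts.csv
$ lipotrap fit --input counts.csv
{
  "model": "powerlaw",
  "estimate": 2.3225749799514865,
  "stderr": 0.013225749799514866,
  "loglik": -14765.202209379016,
  "n_used": 10000,
  "n_min": 0,
  "aic": 29532.404418758033,
  "kind": "fit",
  "seed": 11
}
```

The estimate 2.32 ± 0.013 recovers the generating exponent within two
standard errors. The same pipeline works on the full stochastic simulator,
where the count fluctuates around the mean path but the tail exponent still
obeys `µ = 1 + r0/λ`:

```python
import lipotrap as lt

ens = lt.simulate_ensemble_exact(
    lt.SimConfig(r0=1.3, flux=lt.FluxParams(lam_in=1.0), n_liposomes=50_000, seed=0)
)
fit = lt.fit_powerlaw_mle(lt.CountSample(ens.counts), n_min=10)
print(f"tail exponent: {fit.estimate:.3f} +/- {fit.stderr:.3f} (n_tail={fit.n_used})")
# tail exponent: 2.353 +/- 0.027 (n_tail=2563)
```

Here `n_min=10` restricts the fit to the tail, where the power law is exact;
the fitted 2.35 ± 0.027 brackets the predicted 1 + 1.3/1.0 = 2.3.

Other subcommands: `lipotrap simulate` (exact or mean-field ensembles,
written as `tau,n_trapped` CSV with a JSON sidecar), `lipotrap hist`
(fixed-width occupancy histograms), `lipotrap compare` (AIC: power law vs
Poisson). All randomness is controlled by `--seed`.

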