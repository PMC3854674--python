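# twovar

Two-variable reduction of multi-step biochemical reaction chains.

Many chemical events in the cell — mRNA degradation, poly(A) shortening,
telomere trimming, multi-stage maturation — are linear chains of first-order
conversions

    B1 → B2 → ... → Bn → P,        rates k1 ... kn,

through which every molecule must pass.  Collapsing such a chain to a single
first-order reaction (`dX/dt = -kX`) loses the delay the intermediate steps
impose, which is visible as a shoulder in decay curves.  This package
implements a reduction that keeps two lumped variables instead of one: the
total molecule count `X = Σ [Bi]` and the total *length*
`L = Σ (n-i+1)[Bi]`, where the length of a molecule is the number of steps it
still has to take.  Every reaction event lowers L by one; X drops only when
the event was the final step.  The whole chain then becomes a single
stochastic channel with propensity `kX` (k the harmonic mean of the step
rates) plus a branch probability

    f(X, L, n) = P(next event is the last step  |  X, L),

approximated by the calibrated closed form

    f(X, L, n) = (1 - r)^q(n),     r = (L - X) / (X (n - 1)),
    q(n) = 0.3146 n + 1.3615,

which is exactly 1 when all molecules have length 1 (L = X) and exactly 0
when all are full length (L = nX).

The package provides, for modellers of stochastic gene expression and
reaction-network reduction:

* **Monte-Carlo and exact computation of f** — the uniform-reduction sampler
  and an exact dynamic program over length multisets (`probability`);
* **calibration of the exponent q** against either the Monte-Carlo reference
  or the detailed chain ODE, with per-condition grid search, per-n averaging
  and the OLS line q̄(n) (`calibration`);
* **simulation** — exact Gillespie SSA for the detailed chain and the
  modified SSA whose lumped channel uses an extra uniform draw to pick the
  branch (`simulate`);
* **an mRNA-decay case study** — the 10-reaction detailed model of transcript
  export, poly(A) shortening and fragment production, fitting of (k, L0) to
  normalized decay curves, and a seeded synthetic decay-curve generator
  (`mrna`);
* a `twovar` **command line** (`probability`, `calibrate`, `simulate`, `fit`,
  `synth`) that writes CSV/JSON artifacts plus a reproducibility manifest.

## Worked example

```python
from twovar import (mc_probability_curve, fit_optimal_q, default_q_grid,
                    f_calibrated, synth_decay_data, fit_one_step, fit_twovar)

# Monte-Carlo reference for the last-step probability at n=8, X=15,
# then grid-search the exponent of the two candidate families.
table = mc_probability_curve(8, 15, reps=10_000, seed=1)
q_grid = default_q_grid()                    # 0.01, 0.02, ..., 15.00
q1, d1 = fit_optimal_q(8, 15, "type1", q_grid, table)   # 1 - r^q
q2, d2 = fit_optimal_q(8, 15, "type2", q_grid, table)   # (1 - r)^q
print(f"Type I  optimum: q = {q1:.2f}  (SSE {d1:.4f})")
print(f"Type II optimum: q = {q2:.2f}  (SSE {d2:.4f})")
print(f"f at the midpoint L = 67: MC {table.values[67]:.4f}, "
      f"calibrated {f_calibrated(15, 67, 8):.4f}")

# Synthetic normalized decay curve with a shoulder, then both fits.
data = synth_decay_data(k_true=0.112, L0_frac=371/900, X0=100,
                        noise_sd=3.0, seed=7)
one = fit_one_step(data)
two = fit_twovar(data, X0=20)
print(f"one-step fit:     k = {one.k_hat:.4f}   RSS = {one.objective:.1f}")
print(f"two-variable fit: k = {two.k_hat:.4f}, L0 = {two.L0_hat} "
      f"(ratio {two.ratio:.3f}), RSS = {two.objective:.1f}")
```

Output:

```
Type I  optimum: q = 0.31  (SSE 1.0853)
Type II optimum: q = 3.93  (SSE 0.0066)
f at the midpoint L = 67: MC 0.0639, calibrated 0.0705
one-step fit:     k = 0.0282   RSS = 90.9
two-variable fit: k = 0.1033, L0 = 69 (ratio 0.383), RSS = 36.6
```

The Type II family fits the sampled probability two orders of magnitude
better than Type I, which is why it is the working form.  On the decay curve,
the one-step model can only compromise (k ≈ 0.028 is far below the true
per-step rate 0.112, and its residual is 2.5× larger); the two-variable fit
recovers the generating rate and initial-length ratio (true ratio 0.412) up
to observation noise, from a curve that carries no per-species information.

The same operations are available from a shell, e.g.

```sh
twovar probability --n 8 --x 15 --reps 10000 --seed 1 --out prob_out
twovar synth --k 0.112 --l0-frac 0.412 --x0 100 --noise 3 --seed 7 --out synth_out
twovar fit --data synth_out/decay.csv --model twovar --x0 20 --out fit_out
```

## Layout

| module | contents |
|---|---|
| `twovar.core` | `ChainSpec`, detailed/lumped states, projection, harmonic-mean rate |
| `twovar.probability` | Monte-Carlo sampler, exact enumeration oracle, candidate f families |
| `twovar.calibration` | q grid search, averaging, OLS, detailed and two-variable ODEs |
| `twovar.simulate` | Gillespie SSA, lumped-channel SSA, seeded ensembles |
| `twovar.mrna` | mRNA case study: detailed model, decay fitting, synthetic data |
| `twovar.cli` | `twovar` command-line entry points |

See `docs/methods.md` for the model, its assumptions, numerical choices and
limitations.
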