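# ieakinetics

Kinetic modeling, simulation and quantification for **isothermal
exponential amplification** (IEA) — LAMP, RPA, SDA, HDA — aimed at
people building or analyzing real-time amplification assays: assay
developers choosing primers and temperatures, and analysts turning
fluorescence curves into concentrations.

## The model

The apparent doubling time of the amplicon population is

```
T = T^θ / ξ = S_a / (ξ · S_e)
```

where `S_e` is the polymerase extension rate (bp/min), `S_a` the
apparent amplicon size (for LAMP, the repeating-unit length in bp),
`T^θ = S_a / S_e` the ideal doubling time, and `ξ = log2(1 + η)` the
primer-template binding efficiency.  The binding rate `η` follows from
the annealing competition between template self-annealing and
primer-template annealing,

```
η_t = c_p,t / (c_p,t + 2·K_A·c_t^ν),      c_p,t = c_p0 − (c_t − c_0),
```

so the copy number obeys `N_{t+Δt} = (1 + η_t)^(Δt/T^θ) · N_t`:
exponential at first, then decelerating to a plateau at `c_0 + c_p0` as
primers deplete.  `K_A` (empirical, roughly `S_a/S_p`) and the exponent
`ν` are fitted per assay.  The same algebra implies, via the Taylor
expansion of `2^x`, that concatemeric LAMP product sizes are Poisson
distributed with `λ = Δt·ln2/T^θ` repeat units.

The package provides:

* `model_core` — the scalar physics (η, ξ, doubling times, copies↔µM);
* `simulator` — trajectory integration of the recurrence (plus a
  per-cycle thermocycling analog);
* `curve_fit` — joint multi-start least-squares estimation of
  `(T^θ, K_A, ν, N_0m)` from real-time curves;
* `quantification` — time-to-positive, standard curves with outlier
  exclusion, `T = −slope·ln2`, doubling-time ratios `K_T`, apparent
  extension rates `S_e*`, relative abundance `R_a`;
* `poisson_products` — the product-size distribution and its identities;
* `synthetic_data` — a virtual real-time instrument (20-s sampling,
  serial dilutions, Gaussian noise, start-up delays) with truth records;
* `io` / `cli` — curves CSV and JSON formats, and the `iea` command
  (`simulate`, `fit`, `quantify`, `relquant`, `poisson`, `synth`).

## Worked example

Simulate a 10-fold dilution series of the N-gene assay at 65 °C
(`T^θ = 0.294` min, `K_A = 7.04`, `ν = 1.579`, 1.6 µM primers), refit
it, and read the doubling time off the standard curve:

```python
import numpy as np
from ieakinetics import PRESETS, fit_amplification_curves, normalize_fluorescence
from ieakinetics.quantification import build_standard_curve, time_to_positive
from ieakinetics.synthetic_data import NoiseModel, generate_dilution_experiment

params = PRESETS["N_65C_E"]
curves, truth = generate_dilution_experiment(
    params, stock_N0=1e6, noise=NoiseModel(sigma_frac=0.01, seed=7))

fit = fit_amplification_curves(curves, seed=7)
print(f"T_theta = {fit.params.T_theta:.3f} min, nu = {fit.params.nu:.2f}, "
      f"K_A = {fit.params.K_A:.2f}, MSE x 1e4 = {fit.mse_x1e4:.2f}")

t_P = [time_to_positive(normalize_fluorescence(c)) for c in curves]
sc = build_standard_curve(t_P, [c.dilution_factor for c in curves])
print(f"slope = {sc.slope:.4f} min/ln-unit  ->  T = {sc.T:.3f} min")
```

Output:

```
T_theta = 0.293 min, nu = 1.57, K_A = 7.09, MSE x 1e4 = 1.16
slope = -0.4225 min/ln-unit  ->  T = 0.293 min
```

The fitted ideal doubling time lands on the generator truth (0.294 min)
to within the 1% read noise, and the fit MSE sits at the noise variance
(`0.01² × 10⁴ ≈ 1`).  The standard-curve slope is `−T/ln2`, so each
ln-unit of extra template saves ~0.42 min; the apparent doubling time
`T ≈ T^θ` here because primer binding is near-ideal at these dilutions
(`ξ₀ ≈ 1`).

The same run from the shell:

```sh
iea synth --preset N_65C_E --sigma-frac 0.01 --seed 7 --out curves.csv
iea fit --curves curves.csv --out fit.json --seed 7
iea quantify --curves curves.csv --out-prefix quant
```

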