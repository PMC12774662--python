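# Methods

## Model

Isothermal exponential amplification is described by a single recurrence
on the amplicon copy number `N_t` (copies/µl):

```
N_{t+Δt} = (1 + η_t)^(Δt/T^θ) · N_t
```

`T^θ = S_a/S_e` is the ideal doubling time — the time one polymerase
needs to traverse one amplicon (for LAMP, one repeating unit of the
concatemer) of `S_a` bp at extension rate `S_e` bp/min.  The template
binding rate

```
η_t = c_p,t / (c_p,t + 2·K_A·c_t^ν)
```

collapses the annealing competition between template self-annealing and
primer-template annealing into one empirical constant `K_A` (the ratio
of the two annealing constants, expected to scale with `S_a/S_p`) and an
exponent `ν` that governs how strongly accumulating amplicon suppresses
primer binding.  Primer depletion is strict 1:1 bookkeeping,
`c_p,t = c_p0 − (c_t − c_0)`, so the trajectory is exponential with
apparent doubling time `T = T^θ/ξ`, `ξ = log2(1+η)`, while `c_t ≪ c_p0`,
then decelerates and plateaus at `c_0 + c_p0`.  Enzyme saturation,
product inhibition and related late-phase effects are not modeled
separately; they are absorbed into the decay of `η_t`.  Copies and
molarity interconvert through Avogadro's number fixed at `6.02×10²³`
(the rounded value, so worked examples reproduce published arithmetic
exactly).

Assumptions worth keeping in mind: the reaction is deterministic and
well mixed; a single `η_t` describes all primer species; `S_e` is
constant over the run; and there is no nonspecific amplification.

## Numerical integration

The step form `(1+η)^(Δt/T^θ)` is exact for constant `η`; the step size
only controls how often `η_t` is refreshed.  The refresh uses a midpoint
rule — a half step at the current `η` locates where `η` is evaluated for
the full step — which makes the scheme second order: at the default
`dt = 0.01` min, halving `dt` changes reported copy numbers by far less
than 0.1%.  Concentrations are clamped at the plateau `c_0 + c_p0` and
`η` at 0 once primers are exhausted; both clamps only guard
floating-point undershoot, since `η → 0` smoothly as `c_p → 0`.  The hot
loop is compiled with numba when available, with an identical
pure-NumPy fallback (a unit test compares the two paths to 1e-12).

The per-cycle thermocycling analog (`simulate_qpcr`) applies one
annealing/extension event per cycle, `N_{n+1} = (1+η_n)·N_n`, with the
same primer bookkeeping.  It is an interpretation of the shared kinetic
structure — one full binding opportunity per thermal cycle — not a
calibrated qPCR model, and is labeled as such.

## Curve fitting

`(T^θ, K_A, ν, N_0m)` are estimated by bounded nonlinear least squares
(`scipy.optimize.least_squares`, TRF) on plateau-normalized curves, with
`K_A` and `N_0m` optimized on a log10 scale.  Default bounds:
`T^θ ∈ [0.05, 5]` min, `K_A ∈ [0.1, 100]`, `ν ∈ [0.1, 3]`,
`N_0m ∈ [1e-2, 1e12]` copies/µl.  When curves carry known dilution
factors, one stock `N_0m` is shared across the family.  Multi-start
(default 8, seeded): the first start derives `T^θ` from the spacing of
the 5% and 20% plateau crossings and `N_0m` by extrapolating the 10%
crossing back to `t = 0`; the rest jitter around it or draw uniformly
within bounds.  Iteration stops early once the fit is numerically
perfect (MSE < 1e-12).  All points of every curve are retained — the
model spans the full trajectory, so pre-threshold and plateau samples
are informative, not nuisance.

Normalization maps raw fluorescence through
`(F − baseline)/(plateau − baseline)` with baseline and plateau taken as
medians of the first and last five samples; the transform is invariant
to affine changes of gain and offset.  The *same* window map is applied
to the simulated curve inside the objective, rather than dividing the
model by its theoretical plateau `c_0 + c_p0`: the plateau is approached
only asymptotically, so the theoretical scaling would bias fits of runs
that end near (not at) the plateau.  The matched map converges to
`c_t/(c_0+c_p0)` as the run length grows.  A curve whose plateau rise
does not exceed 10× the early noise level is flagged negative and
excluded rather than fitted.  No per-curve time offset is fitted; a
real start-up delay therefore surfaces as an underestimated `N_0m`
(verified by a property test with a delayed generator), which is the
expected signature on real data.

Reported MSE is the mean squared residual on the normalized scale;
`mse_x1e4` is the customary ×10⁴ reporting magnitude.

## Quantification

The time-to-positive `t_P` is the first crossing of a threshold set at a
fraction (default 0.10, the admissible maximum) of the normalized
plateau, linearly interpolated between the 20-s samples — linear
interpolation because the sampling interval is coarse relative to
`T ≈ 0.25–0.7` min.  A never-crossing well returns a NaN sentinel; a
well already above threshold at the first sample is flagged
"pre-amplified" via warning.

Because the dynamics depend only on the current concentration, dilution
translates a trajectory in time without changing its shape; `t_P` is
therefore linear in `ln(relative concentration)` with slope `−T/ln2`,
where `T` is the dilute-phase apparent doubling time `T^θ/ξ₀`.  The
standard curve is an OLS fit of `t_P` on `ln(c₀/c₀,ᵢ)` with iterative
outlier removal: while the largest externally studentized residual
exceeds 3.0 *and* its raw residual exceeds 0.05 min *and* at least 4
points remain, the worst point is dropped and the line refit.  The
absolute floor (well under one sampling interval) is needed because the
scale-free studentized criterion alone discards points of an almost
perfect line.  Indices of removed points are reported 0-based.

Derived condition-composite quantities: `T = −slope·ln2`;
`S_e* = S_a/T_min` (apparent extension rate across conditions);
`K_T = T_s/T_t` (doubling-time ratio of two targets, insensitive to
global changes of polymerase activity since those scale both extension
rates equally); and the relative abundance

```
R_a = K_S · 2^((t_P,s − K_T·t_P,t)/T_s),      K_S = S_a,s/S_a,t.
```

With per-curve plateau normalization the molar detection threshold is
the same for both targets regardless of amplicon size, so the size
ratio cancels and `K_S = 1` is the consistent choice for data processed
by this package; `K_S` matters when thresholds are set on a shared raw
(mass-proportional) fluorescence scale.  `R_a` is exact when the two
assays share annealing chemistry (`K_A`, `ν`): the deceleration offset
between the exponential phase and the 10% crossing then scales with
each assay's `T` and cancels in `t_P,s − K_T·t_P,t`.  With mismatched
chemistry the offsets differ and bias `R_a` by ~15–20% in simulation —
consistent with the few-tens-of-percent deviations reported for this
class of method on real matrices — so the recovery test uses matched
chemistry and the limitation is stated here rather than hidden.

## Product-size distribution

Expanding `2^(Δt/T^θ)` as a Taylor series and reading the m-th term as
the fraction of products that acquired `m` repeat units during `Δt`
gives a Poisson law with `λ = Δt·ln2/T^θ`.  The pmf is evaluated in log
space (`gammaln`) so `λ` of tens and supports up to 10⁴ repeat units
stay finite; the default truncation `m_max = ⌈λ + 10√λ + 10⌉` leaves
< 1e-9 tail mass.  Identities tested: the growth-factor reconstruction
`e^λ·Σp(m) = 2^(Δt/T^θ)` to 1e-10 relative, mean = variance = λ within
tail mass, and super-exponential decay for `m ≫ λ`.  The mass-weighted
(electropherogram-like) view multiplies each size bin by `m·S_a` and is
explicitly non-quantitative.

## Synthetic data

The generator emulates a plate-based real-time instrument: readings
every 20 s, curves rendered as
`F(t) = baseline + amplitude·c(t−delay)/(c_0+c_p0) + ε` with Gaussian
homoscedastic read noise `ε ~ N(0, σ·amplitude)` (default σ = 1% of the
plateau amplitude, a typical plate-reader level that also places the
normalized fit MSE at the ×10⁻⁴ magnitude seen in practice), serial
10-fold dilutions from a 10⁶ copies/µl stock in triplicate over 20 min,
and optional start-up delays (fixed and/or uniformly jittered).  Named
presets carry the fitted parameters of characterized SARS-CoV-2 N/N1/S
LAMP assays so tests read naturally against reference values; 1.6 µM is
the standard inner-primer concentration of such assays.

What the generator does *not* emulate — and hence what green tests do
not certify on real data: stochastic single-molecule initiation at low
copy input, nonspecific amplification and primer dimers, baseline
drift, heteroscedastic or correlated noise, and pipetting error in the
dilution ladder.  Recovery results here are the clean-instrument limit.

## Problem sizes and determinism

Default test and acceptance workloads use 5-dilution series with single
replicates, 20–40 min virtual runs at `dt = 0.01` min, 20-seed noise
studies, and a 50-draw noiseless recovery sweep — sizes chosen so the
whole suite exercises every pipeline end to end in well under a minute
of compute while leaving estimator errors an order of magnitude below
the tolerances they are tested against.  Every stochastic component
takes an explicit integer seed; hypothesis profiles are derandomized.

## Known limitations

* `K_A` has awkward units (µM^(1−ν)) when `ν ≠ 1`; it is treated as the
  empirical fitted constant it is, not a thermodynamic quantity.
* `T^θ` and `ξ` are not separately identifiable from a single curve
  family in the dilute regime (`ξ₀ ≈ 1`); the fitted `T^θ` is the
  effective dilute-phase doubling time.
* The standard-curve `T` inherits a ±0.2% bias from linearly
  interpolating 20-s samples; negligible against the percent-level
  tolerances used throughout.
* Absolute quantification without a standard curve (digital
  partitioning) is out of scope.
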