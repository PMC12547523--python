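# Methods

## Model and scope

The package treats non-isothermal solid-state decomposition as a single
global step with Arrhenius kinetics,

    dα/dt = k(T)·f(α),   k(T) = A·exp(−Eₐ/RT),   α = (w₀ − wₜ)/(w₀ − w_f),

so that under a constant heating rate β = dT/dt

    dα/dT = (A/β)·f(α)·exp(−Eₐ/RT).                                   (rate law)

All internal units are SI with time in minutes: Eₐ in J/mol, A in min⁻¹
(consistent with β in K/min), temperatures in K. Physical constants are fixed
at R = 8.314462618 J/(mol·K), K_b = 1.380649e−23 J/K, h = 6.62607015e−34 J·s.
Multi-step or parallel reactions, intra-particle heat/mass-transfer gradients
and instrument baseline artifacts are out of scope.

## Synthetic data generator

`simulate_conversion` integrates the rate law in temperature with a
stiff-capable adaptive integrator (LSODA, rtol 1e−8, atol 1e−12); the
temperature integral has no closed form and the exponential onset makes the
problem stiff. The returned dα/dT is the analytic right-hand side evaluated
on the solution, never a finite difference. f(α) is evaluated with α clamped
to (0, 1) open-interval bounds (width 1e−12) so families that vanish (An) or
diverge (D1–D3) at the endpoints stay integrable from α(T_start) = 0.

The reaction-model catalogue covers the standard families used by model-free
studies: reaction order F n, Avrami–Erofeev A m, diffusion D1–D3, contracting
geometry R2/R3. The default is first order (F1); no specific mechanism is
claimed for the pharmaceutical feedstock, F1 is simply the canonical
single-step reference whose DTG peak admits an exact stationarity equation

    Eₐ·β/(R·Tp²) = A·exp(−Eₐ/(R·Tp)),

whose unique root (the residual is strictly monotone in T on the log scale)
is the simulator's independent peak oracle (`predict_peak_temperature`,
bracketed Brent solve, rtol 1e−12).

The default scenario emulates a ~10 mg pharmaceutical powder with one
dominant decomposition stage: w₀ = 10 mg, w_f = 1.5 mg, ramp 450–850 K
sampled every 0.25 K, β ∈ {10, 20, 30, 40} K/min, giving DTG peaks at
582–618 K (309–345 °C) for the default triplet Eₐ = 105 kJ/mol,
A = 1e9 min⁻¹. Measurement noise is multiplicative Gaussian on mass
(default experiments use relative sd 0.002, i.e. 0.2%, the level at which a
laboratory balance noise floor visibly degrades Friedman fits) plus an
optional linear baseline drift; both are seeded and bit-reproducible. The
generator does **not** emulate buoyancy corrections, moisture release,
multi-stage tails or temperature-calibration error, so passing
parameter-recovery tests demonstrate estimator correctness under the model's
own assumptions, not robustness to every artifact of real instrument exports.

## Conversion and rate extraction

`compute_conversion` normalizes mass to α over an optional temperature
window (w₀/w_f default to the window-boundary masses). Noise-induced
inversions are removed by isotonic clipping (running maximum, total
adjustment logged) and α is clipped to [0, 1]. The rate dα/dT is estimated by
Savitzky–Golay local-quadratic differentiation, default window 11 points;
Friedman's method differentiates the data and is the noise-sensitive
consumer of this choice. On a uniform temperature grid the symmetric
quadratic filter's derivative is exact through cubic terms, so the noiseless
bias is O(h⁴) and the noiseless DTG peak moves by less than one sampling
step. Non-uniform grids are handled by monotone (PCHIP) resampling onto a
uniform grid and back.

Iso-conversional temperatures T(α; β) and rates are read off each curve by
shape-preserving monotone piecewise-cubic (PCHIP) interpolation of the
strictly increasing (α, T) pairs — monotone interpolation cannot oscillate
between samples. Conversions outside a curve's span produce missing cells
with a warning; a conversion level with fewer than three usable heating
rates is skipped. The default analysis grid is α = 0.10–0.80 in steps of
0.05, matching the range over which single-step kinetics dominate (low and
high conversions are contaminated by onset and tail processes).

## Isoconversional estimators

Each method is a per-conversion unweighted OLS of its ordinate on 1/T across
heating rates (plain R² = 1 − SS_res/SS_tot on the transformed ordinate; the
tables report R² per fit and no weighting protocol is assumed):

* KAS: ln(β/T²), Eₐ = −slope·R
* FWO: ln β, Eₐ = −slope·R/1.052 (Doyle constants 5.331, 1.052)
* Starink: ln(β/T^1.92), Eₐ = −slope·R/1.0037
* Friedman: ln(β·dα/dT) = ln(dα/dt), Eₐ = −slope·R (single OLS per α; no
  multi-pass fitting scheme is used)

Known accuracy at the default study conditions (x = Eₐ/RT ≈ 21): Friedman is
approximation-free (recovery error set by interpolation/smoothing only,
≈0.002% noiseless); KAS and Starink carry ≈0.2% residual linearization bias;
FWO's Doyle linearization has slope bias (1 + 2/x)/1.052 − 1 ≈ **3.5%**,
verified against an exact temperature-integral quadrature oracle. This bias
is intrinsic to the published constants, not to the implementation — on
points generated exactly on the FWO line the estimator returns the
generating Eₐ to machine precision. Reported-table behaviour is consistent:
the FWO column average sits ≈4% above KAS. With 0.2% mass noise all four
methods stay within 5% of the generating value on the default scenario.

## Kissinger frequency factor and thermodynamics

`kissinger_regression` fits ln(β/Tp²) against 1/Tp (≥3 distinct heating
rates; duplicate β with conflicting Tp rejected): Eₐ = −slope·R,
A = (Eₐ/R)·exp(intercept). Given an isoconversional Eₐ, per-heating-rate
frequency factors A(β) = β·Eₐ·exp(Eₐ/(R·Tp))/(R·Tp²) are combined by
geometric mean — A is exponentially sensitive to Eₐ/(R·Tp), so the log-scale
mean is the natural representative value.

Activation thermodynamics use the transition-state relations
ΔG = Eₐ + R·Tp·ln(K_b·Tp/(h·A)), ΔH = Eₐ − R·T(α) and ΔS = (ΔH − ΔG)/T_m.
The two closures hold exactly by construction for every emitted record.
T(α) is the mean over heating rates of the iso-conversional temperature
(published per-conversion ΔH columns imply a conversion-dependent T: the
back-derived temperature rises from ≈551 K at α = 0.1). T_m defaults to the
DTG peak of the slowest ramp and is a configuration knob
(`tm_policy`), since reference tables do not always distinguish T_m from Tp.

K_b/h has units s·K⁻¹, so A (min⁻¹ internally) is divided by 60 before
forming K_b·Tp/(h·A); this is the default `a_time_unit="s"`. Published
metformin tables are reproduced with `a_time_unit="min"` and T = Tp = T_m at
the fastest-ramp DTG peak (614.85 K): that convention matches their printed
ΔG (152/151 kJ/mol) and ΔS (−86.1, −72.08 J/(mol·K)) to printed precision,
so both conventions are exposed; the physically dimensionless one is the
default. The two differ by exactly R·Tp·ln 60 in ΔG. Per-conversion A values
depend on which (β, Tp) pairing is assumed and agree with published columns
only in order of magnitude; they are reported but not treated as a
reproduction target.

## Product yields

Liquid mass is the summed weight gain of condenser, elbow joint, adopter
joint and collection flask; char is the weight gain of the reactor flask;
gas is the difference from the fed mass. Percentages are computed from
liquid and char, gas percentage by difference, so closure to 100 wt% is
exact by construction. Negative component totals and liquid + char exceeding
the feed raise named errors. Replicates are summarized as mean ± sample sd
per product; gas uncertainty is taken as the simple difference of means, not
propagated.

## Neural-network surrogate

`build_dataset` samples each conversion curve on an even temperature grid
over the common window (840 rows = 4 curves × 210 points by default),
features (T, β) z-scored with a stored scaler, target α ∈ [0, 1]. Rows are
split 60/20/20 (train/test/validation) by seeded random assignment, exact to
rounding.

The network is a fully connected MLP (default one hidden layer of 4 tanh
units, linear output) trained full-batch by L-BFGS with analytic gradients
on MSE + λ‖W‖²/n_train (biases unpenalized; the 1/n scaling puts the λ grid
{1e−4, 1e−3, 1e−2} on the same footing as the MSE). λ is selected on the
validation split; the iterate with the lowest validation MSE is retained
(`best_epoch` = that L-BFGS iteration), which also serves as implicit early
stopping. Everything — split, initialization (Glorot-uniform), optimization —
is deterministic under the spec seed. The epoch budget (default 2000) is
sized so the optimizer converges on the default problem; hitting it returns
the best-so-far weights with `converged=False`. Predictions are clamped to
[0, 1]; monotonicity in T is *not* enforced, and out-of-range temperature
queries warn about extrapolation. On the default noiseless dataset the
4-unit network reaches test correlation r ≈ 0.9998 and test MSE ≈ 7e−5;
exact reproduction of error levels reported for proprietary instrument data
is not a goal.

## Pipeline, provenance and numerical conventions

`run_pipeline` validates a `PipelineConfig` (pydantic) before any
computation, runs load → conversion → peaks → isoconversional →
Kissinger/thermo → yields → ANN, and writes every table as headered CSV with
fixed `%.10g` float formatting so identical config + seed reruns are
byte-identical. The serialized config, SHA-256 manifest of all files read or
written, and a per-stage log land in the output directory; a failing stage
leaves a `FAILED` marker naming the stage and retains partial outputs. No
stage mutates another stage's inputs. Temperatures in files may be °C or K
via a units flag; computation is always in K.

Tie-breaks and degenerate inputs: DTG peak ties resolve to the lowest
temperature, boundary maxima raise an error, and a parabolic refinement
through the three samples around the argmax gives sub-grid peak location
(skipped when the local curvature is not concave). Identical heating rates
raise a singular-design error. Mass scaling leaves α, and therefore every
activation energy, unchanged.

## Problem sizes

Default runs use 1601-point temperature grids per heating rate (0.25 K
steps over 450–850 K), four heating rates, a 15-level conversion grid and
an 840-row surrogate dataset; the full chain completes in a few seconds on
one CPU.

## Known limitations

* Single-step kinetics only; overlapping stages bias all four estimators.
* The FWO implementation inherits the fixed Doyle constants; users who need
  unbiased integral estimates at moderate x should prefer KAS/Starink (or
  Friedman when rates are reliable).
* The surrogate interpolates; it carries no kinetic structure and its
  extrapolation beyond the trained temperature window is unconstrained.
* Real-instrument artifacts (buoyancy, baseline curvature, calibration
  offsets) are neither simulated nor corrected.
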