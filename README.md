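# thermokin

Isoconversional pyrolysis kinetics from thermogravimetric (TGA) data, built
around the decomposition of pharmaceutical waste (metformin powder) but
applicable to any single-dominant-step solid-state decomposition.

Pyrolysis reactor design needs the kinetic triplet — activation energy
*Eₐ*, pre-exponential factor *A*, and reaction model *f(α)* — of the
feedstock. For non-isothermal TGA at constant heating rate β the rate law is

    dα/dT = (A/β) · f(α) · exp(−Eₐ/RT),      α = (w₀ − wₜ)/(w₀ − w_f)

Model-free (isoconversional) methods estimate *Eₐ* at each conversion α from
how the temperature required to reach α shifts with β, without assuming
*f(α)*: at fixed α, ordinary least squares of a method-specific ordinate
against 1/T gives *Eₐ* from the slope —

| method   | ordinate        | Eₐ from slope        |
|----------|-----------------|----------------------|
| KAS      | ln(β/T²)        | −slope·R             |
| FWO      | ln β            | −slope·R / 1.052     |
| Starink  | ln(β/T^1.92)    | −slope·R / 1.0037    |
| Friedman | ln(β·dα/dT)     | −slope·R             |

The Kissinger relation ln(β/Tp²) = −Eₐ/(R·Tp) + ln(AR/Eₐ) over the DTG peak
temperatures Tp yields *A*; transition-state theory then gives the activation
thermodynamics ΔG = Eₐ + R·Tp·ln(K_b·Tp/(h·A)), ΔH = Eₐ − RT and
ΔS = (ΔH − ΔG)/T_m. A mass balance over the condensation train converts
apparatus weighings into char/liquid/gas yields, and a small feed-forward
neural network serves as a (T, β) → mass-loss surrogate.

The package is organised for analysis: every computation lives in the library
(`src/thermokin/`), and the numbered scripts under `analysis/` are thin
narrative drivers that write their tables under `results/`.

## Worked example

Simulate four heating rates with known first-order kinetics and recover the
activation energy:

```python
import numpy as np
from thermokin import (KineticTriplet, HeatingProgram, simulate_conversion,
                       conversion_to_thermogram, compute_conversion,
                       temperatures_at_conversions, rates_at_conversions,
                       fit_isoconversional, get_method)

triplet = KineticTriplet(Ea=105e3, A=1e9)           # J/mol, 1/min, F1 model
curves = [compute_conversion(conversion_to_thermogram(
              simulate_conversion(triplet, HeatingProgram(beta=b))))
          for b in (10, 20, 30, 40)]
grid = np.arange(0.10, 0.801, 0.05)
table = temperatures_at_conversions(curves, grid)
rates = rates_at_conversions(curves, grid)
for name in ("FRIEDMAN", "KAS", "STARINK", "FWO"):
    m = get_method(name)
    prof = fit_isoconversional(m, table, rates if m.needs_rate else None)
    print(f"{name:<9} mean Ea = {prof.mean_Ea/1e3:7.2f} kJ/mol")
```

prints

```
FRIEDMAN  mean Ea =  105.00 kJ/mol
KAS       mean Ea =  104.78 kJ/mol
STARINK   mean Ea =  104.78 kJ/mol
FWO       mean Ea =  108.85 kJ/mol
```

Friedman, which uses no temperature-integral approximation, recovers the
generating 105 kJ/mol essentially exactly; KAS and Starink are ~0.2% low;
FWO is ~3.7% high — the intrinsic bias of its Doyle linearization at
Eₐ/RT ≈ 21 (see `docs/methods.md`). The same chain runs end to end via
`thermokin.run_pipeline(PipelineConfig(...))`, or stage by stage with the
`analysis/01…05` scripts:

```bash
python analysis/01_simulate_thermograms.py   # synthetic multi-rate TGA runs
python analysis/02_isoconversional_kinetics.py
python analysis/03_thermodynamics.py         # Kissinger A, ΔG/ΔH/ΔS table
python analysis/04_product_yields.py         # char/liquid/gas mass balance
python analysis/05_ann_surrogate.py          # (T, β) → mass-loss network
```

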